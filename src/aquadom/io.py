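"""Plain-text I/O: peak lists, assignments, matrices, OTU tables.

Everything is TSV so results stay diffable and portable: peak lists with
columns (mz, intensity, sn), per-sample formula tables, the assembled
formula x sample matrix, OTU count tables (rows = OTUs) and the sample
metadata table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assembly import FormulaMatrix
from .engine import Assignment, Spectrum


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    s.to_frame().to_csv(path, sep="\t", index=False, float_format="%.7f")


def read_spectrum(path: str | Path, **meta) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(
        mz=df["mz"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        sn=df["sn"].to_numpy(),
        **meta,
    )


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": a.sample_id,
                "mz": a.mz,
                "formula": a.formula.hill(),
                "ion_species": a.species,
                "error_ppm": a.error_ppm,
                "n_daughters": a.n_daughters,
                "confirmed": a.confirmed,
                "strict_mode": a.strict_mode,
            }
            for a in assignments
        ]
    )


def write_matrix(m: FormulaMatrix, path: str | Path) -> None:
    m.intensities.to_csv(path, sep="\t", index_label="formula")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="formula")


def write_filter_log(log, path: str | Path) -> None:
    payload = {
        "n_input_formulae": log.n_input_formulae,
        "n_unconfirmed_dropped": log.n_unconfirmed_dropped,
        "n_blank_contaminants": len(log.blank_contaminants),
        "blank_contaminants": log.blank_contaminants,
        "n_singlets_removed": log.n_singlets_removed,
        "n_final_formulae": log.n_final_formulae,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_otu_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="otu")


def read_otu_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="otu")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
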