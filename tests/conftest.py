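import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aquadom.formula import parse_formula
from aquadom.pipeline import process_study
from aquadom.simulate import (
    CommunityDesign,
    SpectrumDesign,
    StudyDesign,
    simulate_community,
    simulate_replicate_study,
)

F = parse_formula


@pytest.fixture(scope="session")
def small_study():
    """A small seeded replicate study plus its processed result, shared
    across tests to keep the suite fast."""
    design = StudyDesign(
        sources=("w1",),
        days=(1, 28),
        reps=3,
        n_formulae=40,
        n_singlets_per_set=2,
        n_contaminants=3,
        n_blanks=5,
        spectrum=SpectrumDesign(ppm_jitter=0.2),
        seed=11,
    )
    spectra, peak_truths, truth = simulate_replicate_study(design)
    result = process_study(spectra)
    return design, spectra, peak_truths, truth, result


@pytest.fixture(scope="session")
def community():
    design = CommunityDesign(n_brands=3, seed=4)
    counts, meta, cells, truth = simulate_community(design)
    return design, counts, meta, cells, truth


@pytest.fixture()
def toy_core_table():
    """Hand-constructed 12-brand OTU table with known core membership.

    Per brand: one well sample, one day-1 bottle, one day-28 bottle.
    OTU_a: 1% everywhere -> all cores. OTU_b: 1% in well+early of brands
    1-8, absent late -> well and early cores only. OTU_c: 1% in late of
    brands 1-6 only -> late core only. OTU_d: 0.4% everywhere -> below
    the abundance floor, no core. OTU_e: 1% in well of brands 1-5 only
    (5 < 6 brands) -> no core. OTU_fill pads each sample to 1000 reads.
    """
    otus = ["OTU_a", "OTU_b", "OTU_c", "OTU_d", "OTU_e", "OTU_fill"]
    cols = {}
    meta_rows = []
    for b in range(1, 13):
        for cat, wt, day in (
            ("well", "well", 1.0),
            ("early", "bottle", 1.0),
            ("late", "bottle", 28.0),
        ):
            sid = f"b{b}_{cat}"
            counts = dict.fromkeys(otus, 0)
            counts["OTU_a"] = 10
            if cat in ("well", "early") and b <= 8:
                counts["OTU_b"] = 10
            if cat == "late" and b <= 6:
                counts["OTU_c"] = 10
            counts["OTU_d"] = 4
            if cat == "well" and b <= 5:
                counts["OTU_e"] = 10
            counts["OTU_fill"] = 1000 - sum(counts.values())
            cols[sid] = [counts[o] for o in otus]
            meta_rows.append(
                {
                    "sample_id": sid,
                    "brand": f"brand{b}",
                    "habitat": "plankton",
                    "water_type": wt,
                    "day": day,
                }
            )
    counts = pd.DataFrame(cols, index=otus)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta
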