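#!/usr/bin/env python
"""Generate the synthetic study datasets: a two-water replicate DOM study
(triplicates over four storage times, plus 20 blanks) and a 12-brand
bottled-water community with planted growing OTUs, negative-control
contaminants and DAPI total-count trajectories.

Writes peak lists, OTU table, metadata and ground truth under
results/data/.
"""

import json
from pathlib import Path

from aquadom.io import write_metadata, write_otu_table, write_spectrum
from aquadom.simulate import (
    CommunityDesign,
    SpectrumDesign,
    StudyDesign,
    simulate_community,
    simulate_replicate_study,
)

SEED = 3
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    study = StudyDesign(
        sources=("water1", "water2"),
        days=(1, 7, 28, 56),
        reps=3,
        n_formulae=150,
        n_singlets_per_set=2,
        n_contaminants=5,
        n_blanks=20,
        spectrum=SpectrumDesign(ppm_jitter=0.2),
        seed=SEED,
    )
    spectra, _, truth = simulate_replicate_study(study)
    spec_dir = OUT / "spectra"
    spec_dir.mkdir(exist_ok=True)
    for s in spectra:
        write_spectrum(s, spec_dir / f"{s.sample_id}.tsv")
    (OUT / "spectra_truth.json").write_text(
        json.dumps(
            {
                "true_formulae": sorted(f.hill() for f in truth.true_formulae),
                "contaminants": sorted(f.hill() for f in truth.contaminants),
                "singlets": {
                    k: sorted(f.hill() for f in v) for k, v in truth.singlets.items()
                },
            },
            indent=2,
        )
    )
    print(
        f"wrote {len(spectra)} spectra "
        f"({sum(not s.is_blank for s in spectra)} samples, "
        f"{sum(s.is_blank for s in spectra)} blanks); "
        f"{study.n_formulae} planted formulae, "
        f"{truth.n_singlets} singlets, {len(truth.contaminants)} contaminants"
    )

    community = CommunityDesign(n_brands=12, seed=SEED + 1)
    counts, meta, cells, ctruth = simulate_community(community)
    write_otu_table(counts, OUT / "otu_table.tsv")
    write_metadata(meta, OUT / "sample_metadata.tsv")
    (OUT / "community_truth.json").write_text(
        json.dumps(
            {
                "growing": sorted(ctruth.growing),
                "contaminants": sorted(ctruth.contaminants),
            },
            indent=2,
        )
    )
    print(
        f"wrote OTU table {counts.shape[0]} OTUs x {counts.shape[1]} samples; "
        f"planted growers {sorted(ctruth.growing)}, "
        f"contaminants {sorted(ctruth.contaminants)}"
    )


if __name__ == "__main__":
    main()
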