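#!/usr/bin/env python
"""Characterize the assembled DOM dataset: molecular descriptors and
12-group classification, per-sample diversity, compositional (clr) PCA,
time-constrained redundancy analysis per water, and Spearman color-coding
of formulae against PC1 for van Krevelen plotting.

Writes descriptor, diversity, ordination and correlation tables under
results/.
"""

from pathlib import Path

import pandas as pd

from aquadom.characterization import (
    clr_pca,
    descriptors,
    diversity,
    pc_correlations,
    rda_time,
    van_krevelen_table,
)
from aquadom.formula import parse_formula
from aquadom.io import read_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 3


def main() -> None:
    rel = read_matrix(ROOT / "formula_matrix.tsv")

    desc = pd.DataFrame(
        [
            {
                "formula": f,
                "mass": d.nominal_mass,
                "oc": d.oc,
                "hc": d.hc,
                "dbe": d.dbe,
                "aimod": d.aimod,
                "group": d.group,
            }
            for f in rel.index
            for d in [descriptors(parse_formula(f))]
        ]
    )
    desc.to_csv(ROOT / "descriptors.tsv", sep="\t", index=False)
    print("molecular groups:")
    print(desc["group"].value_counts().to_string())

    div = pd.DataFrame(
        {c: vars(diversity(rel[c])) for c in rel.columns}
    ).T
    div.to_csv(ROOT / "diversity.tsv", sep="\t")
    print(f"\nmean per-sample richness {div['richness'].mean():.0f}, "
          f"Shannon {div['shannon'].mean():.2f}, "
          f"evenness {div['evenness'].mean():.3f}")

    ordn = clr_pca(rel)
    ordn.scores.to_csv(ROOT / "pca_scores.tsv", sep="\t")
    print(f"PC1 {100 * ordn.explained[0]:.1f}% / "
          f"PC2 {100 * ordn.explained[1]:.1f}% of clr variance")

    # RDA with storage time as the single constraint, per water
    days = {c: float(c.split("_d")[1].split("_")[0]) for c in rel.columns}
    for water in sorted({c.split("_d")[0] for c in rel.columns}):
        cols = [c for c in rel.columns if c.startswith(water)]
        t = [days[c] for c in cols]
        r, p = rda_time(rel[cols], t, n_perm=999, seed=SEED)
        print(f"{water}: canonical R = {r:.2f}, p = {p:.3f} "
              f"({len(cols)} samples)")

    rho, low, high = pc_correlations(rel, ordn.scores["PC1"], min_occurrence=4)
    pd.DataFrame({"rho": rho}).to_csv(ROOT / "pc1_spearman.tsv", sep="\t")
    print(f"\nSpearman vs PC1: {len(rho)} formulae "
          f"({len(low)} below 20% quantile, {len(high)} above 80% quantile)")

    van_krevelen_table(rel, seed=SEED).to_csv(
        ROOT / "van_krevelen.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
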