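import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquadom.characterization import (
    GROUP_LABELS,
    aromaticity_index,
    classify_group,
    clr_matrix,
    clr_pca,
    descriptors,
    diversity,
    pc_correlations,
    rda_time,
    van_krevelen_table,
)
from aquadom.formula import Formula, parse_formula

F = parse_formula


class TestAromaticityIndex:
    def test_condensed_aromatic(self):
        assert aromaticity_index(F("C15H8O4")) == pytest.approx(10 / 13)

    def test_negative_numerator_clamped(self):
        assert aromaticity_index(F("C6H12O6")) == 0.0

    def test_benzene(self):
        assert aromaticity_index(F("C6H6")) == pytest.approx(4 / 6)

    def test_nonpositive_denominator_clamped(self):
        # C2H2O6: denominator 2 - 3 = -1
        assert aromaticity_index(F("C2H2O6")) == 0.0


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "formula,group",
        [
            ("C15H8O4", "condensed_polyaromatic"),
            ("C15H12O4", "polyphenol"),  # AImod = 0.545
            ("C16H26O8", "unsaturated_aliphatic"),
            ("C6H12O6", "carbohydrate"),
            ("C18H38O2", "saturated_fatty_acid"),
            ("C10H19NO3", "peptide_like"),
            ("C15H16O4", "highly_unsaturated_phenolic_o_poor"),
            ("C12H14O9", "highly_unsaturated_phenolic_o_rich"),
            ("C16H28O6S", "unsaturated_aliphatic_heteroatom"),
        ],
    )
    def test_representative_members(self, formula, group):
        assert classify_group(F(formula)) == group

    @given(
        st.builds(
            Formula,
            C=st.integers(1, 60),
            H=st.integers(1, 130),
            O=st.integers(0, 40),
            N=st.integers(0, 4),
            S=st.integers(0, 2),
            P=st.integers(0, 2),
            Cl=st.just(0),
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_total_and_disjoint(self, f):
        """Every formula gets exactly one of the 12 labels."""
        g = classify_group(f)
        assert g in GROUP_LABELS


class TestDiversity:
    def test_uniform_column(self):
        d = diversity([1.0] * 10)
        assert d.richness == 10
        assert d.shannon == pytest.approx(np.log(10))
        assert d.evenness == pytest.approx(1.0)

    def test_single_formula(self):
        d = diversity([5.0])
        assert (d.richness, d.shannon, d.evenness) == (1, 0.0, 1.0)

    def test_zeros_ignored(self):
        d = diversity([0.5, 0.5, 0.0])
        assert d.richness == 2
        assert d.shannon == pytest.approx(np.log(2))

    def test_scale_invariance(self):
        a = diversity([1.0, 2.0, 3.0])
        b = diversity([10.0, 20.0, 30.0])
        assert a.shannon == pytest.approx(b.shannon)
        assert a.evenness == pytest.approx(b.evenness)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            diversity([0.0, 0.0])


def random_rel_matrix(n_formulae=20, n_samples=8, seed=0, zero_frac=0.2):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0, 1, size=(n_formulae, n_samples))
    x[rng.random(x.shape) < zero_frac] = 0.0
    x[:, x.sum(axis=0) == 0] = 1.0
    return pd.DataFrame(
        x,
        index=[f"f{i}" for i in range(n_formulae)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestClrPca:
    def test_clr_rows_sum_to_zero(self):
        m = random_rel_matrix()
        x = clr_matrix(m)
        assert np.abs(x.sum(axis=1)).max() < 1e-9

    def test_duplicated_groups_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(0, 1, 20)
        b = rng.lognormal(0, 1, 20)
        m = pd.DataFrame(
            {"s1": a, "s2": a, "s3": b, "s4": b},
            index=[f"f{i}" for i in range(20)],
        )
        res = clr_pca(m)
        pc1 = res.scores["PC1"]
        assert pc1["s1"] == pytest.approx(pc1["s2"], abs=1e-9)
        assert pc1["s3"] == pytest.approx(pc1["s4"], abs=1e-9)
        assert abs(pc1["s1"] - pc1["s3"]) > 1e-6

    def test_identical_columns_no_variance(self):
        m = pd.DataFrame(
            np.tile(np.arange(1.0, 11.0)[:, None], (1, 4)),
            index=[f"f{i}" for i in range(10)],
            columns=list("abcd"),
        )
        res = clr_pca(m)
        assert np.allclose(res.explained, 0.0)

    def test_explained_fractions_sum_to_one(self):
        res = clr_pca(random_rel_matrix(seed=3))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            clr_pca(random_rel_matrix(n_samples=2))


class TestRdaTime:
    def _linear_matrix(self, t, n_formulae=15, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_formulae)
        b = rng.normal(size=n_formulae) * 0.05
        comps = np.exp(a[:, None] + b[:, None] * np.asarray(t)[None, :])
        comps /= comps.sum(axis=0)
        return pd.DataFrame(
            comps,
            index=[f"f{i}" for i in range(n_formulae)],
            columns=[f"s{j}" for j in range(len(t))],
        )

    def test_noiseless_linear_effect_r_one(self):
        t = [1, 1, 7, 7, 28, 28, 56, 56]
        m = self._linear_matrix(t)
        r, _ = rda_time(m, t, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_constant_time_rejected(self):
        m = self._linear_matrix([1, 1, 1, 1])
        with pytest.raises(ValueError):
            rda_time(m, [1, 1, 1, 1], n_perm=9, seed=0)

    def test_null_p_not_small(self):
        t = [1, 1, 7, 7, 28, 28, 56, 56]
        rng = np.random.default_rng(5)
        hits = 0
        n = 40
        for i in range(n):
            comps = rng.dirichlet(np.full(15, 0.8), size=8).T
            m = pd.DataFrame(
                comps,
                index=[f"f{i}" for i in range(15)],
                columns=[f"s{j}" for j in range(8)],
            )
            _, p = rda_time(m, t, n_perm=99, seed=i)
            hits += p > 0.05
        assert hits >= int(0.85 * n)


class TestPcCorrelations:
    def test_monotone_formula_rho_one(self):
        scores = np.arange(6, dtype=float)
        m = pd.DataFrame(
            {
                f"s{j}": [j + 1.0, 6.0 - j] for j in range(6)
            },
            index=["up", "down"],
        )
        rho, low, high = pc_correlations(m, scores, min_occurrence=4)
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_min_occurrence_excludes_rare(self):
        m = pd.DataFrame(
            {
                "s1": [1.0, 1.0],
                "s2": [2.0, 2.0],
                "s3": [3.0, 1.5],
                "s4": [0.0, 1.2],
                "s5": [0.0, 1.8],
            },
            index=["rare", "common"],
        )
        rho, _, _ = pc_correlations(m, np.arange(5.0), min_occurrence=4)
        assert "rare" not in rho.index
        assert "common" in rho.index


class TestVanKrevelen:
    def test_ratios(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["C6H12O6"])
        t = van_krevelen_table(m, seed=0)
        assert t.loc[0, "oc"] == pytest.approx(1.0)
        assert t.loc[0, "hc"] == pytest.approx(2.0)

    def test_empty(self):
        m = pd.DataFrame({"s1": []}, index=pd.Index([], dtype=object))
        assert len(van_krevelen_table(m, seed=0)) == 0

    def test_seeded_order_reproducible(self):
        m = random_rel_matrix(n_formulae=5, n_samples=3)
        m.index = ["C6H12O6", "C7H14O6", "C8H16O6", "C9H18O6", "C10H20O6"]
        t1 = van_krevelen_table(m, seed=42)
        t2 = van_krevelen_table(m, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
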