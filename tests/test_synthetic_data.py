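import numpy as np
import pandas as pd
import pytest

from aquadom.engine import CHLORIDE_ADDUCT, DEPROTONATED, ion_mz
from aquadom.formula import Formula, monoisotopic_mass, parse_formula
from aquadom.simulate import (
    CommunityDesign,
    SpectrumDesign,
    StudyDesign,
    simulate_community,
    simulate_replicate_study,
    simulate_spectrum,
)

F = parse_formula


class TestSimulateSpectrum:
    def test_glucose_lowest_peak_at_deprotonated_mz(self):
        design = SpectrumDesign(
            true_formulae=[F("C6H12O6")], ppm_jitter=0.0, n_noise_peaks=0, seed=0
        )
        spec, truth = simulate_spectrum(design)
        assert spec.mz[0] == pytest.approx(179.05611, abs=1e-5)
        assert truth.loc[truth["role"] == "parent", "formula"].tolist() == ["C6H12O6"]

    def test_empty_design_empty_spectrum(self):
        design = SpectrumDesign(true_formulae=[], n_noise_peaks=0, seed=0)
        spec, truth = simulate_spectrum(design)
        assert len(spec) == 0 and truth.empty

    def test_ion_mix_one_emits_adduct(self):
        f = F("C10H14O6")
        design = SpectrumDesign(
            true_formulae=[f], ion_mix=1.0, ppm_jitter=0.0, n_noise_peaks=0, seed=0
        )
        spec, truth = simulate_spectrum(design)
        species = set(truth.loc[truth["role"] == "parent", "species"])
        assert species == {DEPROTONATED, CHLORIDE_ADDUCT}
        adduct_mz = ion_mz(monoisotopic_mass(f), CHLORIDE_ADDUCT)
        assert np.min(np.abs(spec.mz - adduct_mz)) < 1e-6

    def test_invalid_formula_names_rule(self):
        with pytest.raises(ValueError, match="nitrogen rule"):
            SpectrumDesign(true_formulae=[F("C5H10NO2")])

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            SpectrumDesign(ppm_jitter=-0.1)

    def test_parent_mass_error_bounded_by_jitter(self):
        rng = np.random.default_rng(0)
        design = SpectrumDesign(
            true_formulae=[F("C10H14O6"), F("C20H24O10")],
            ppm_jitter=0.3,
            n_noise_peaks=0,
            n_daughters=0,
        )
        errs = []
        for seed in range(200):
            spec, truth = simulate_spectrum(design, rng=np.random.default_rng(seed))
            for _, row in truth[truth["role"] == "parent"].iterrows():
                theo = ion_mz(monoisotopic_mass(F(row["formula"])), row["species"])
                errs.append(abs(row["mz"] - theo) / theo * 1e6)
        errs = np.asarray(errs)
        assert (errs <= 4 * 0.3).mean() >= 0.9999

    def test_noise_respects_guard_distance(self):
        design = SpectrumDesign(
            true_formulae=[F("C10H14O6")], n_noise_peaks=50, seed=3
        )
        spec, truth = simulate_spectrum(design)
        noise_mz = truth.loc[truth["role"] == "noise", "mz"].to_numpy()
        other_mz = truth.loc[truth["role"] != "noise", "mz"].to_numpy()
        for nm in noise_mz:
            assert np.min(np.abs(other_mz - nm)) >= design.noise_guard_da
        d = np.diff(np.sort(noise_mz))
        assert d.min() >= design.noise_guard_da

    def test_seeded_determinism(self):
        design = SpectrumDesign(
            true_formulae=[F("C10H14O6"), F("C12H18O8")], n_noise_peaks=10, seed=21
        )
        s1, t1 = simulate_spectrum(design)
        s2, t2 = simulate_spectrum(design)
        np.testing.assert_array_equal(s1.mz, s2.mz)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)
        pd.testing.assert_frame_equal(t1, t2)


class TestReplicateStudy:
    def test_structure_and_singlets(self, small_study):
        design, spectra, peak_truths, truth, _ = small_study
        samples = [s for s in spectra if not s.is_blank]
        blanks = [s for s in spectra if s.is_blank]
        assert len(samples) == len(design.sources) * len(design.days) * design.reps
        assert len(blanks) == design.n_blanks
        # singlets appear in exactly one replicate of their set
        for rep_set, injected in truth.singlets.items():
            for f in injected:
                present = [
                    sid
                    for sid, t in peak_truths.items()
                    if f.hill() in set(t["formula"]) and not sid.startswith("blank")
                ]
                assert len(present) == 1
                assert present[0].startswith(rep_set)

    def test_blanks_carry_contaminants_above_sn5(self, small_study):
        design, spectra, peak_truths, truth, _ = small_study
        for f in truth.contaminants:
            found = False
            for s in spectra:
                if not s.is_blank:
                    continue
                t = peak_truths[s.sample_id]
                rows = t[(t["formula"] == f.hill()) & (t["role"] == "parent")]
                for mz in rows["mz"]:
                    i = int(np.argmin(np.abs(s.mz - mz)))
                    if s.sn[i] > 5:
                        found = True
            assert found

    def test_deterministic(self):
        design = StudyDesign(
            sources=("w1",), days=(1,), reps=2, n_formulae=10,
            n_singlets_per_set=1, n_contaminants=1, n_blanks=2, seed=5,
        )
        s1, t1, g1 = simulate_replicate_study(design)
        s2, t2, g2 = simulate_replicate_study(design)
        assert g1.true_formulae == g2.true_formulae
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.mz, b.mz)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_replicate_study(StudyDesign(sources=(), seed=0))


class TestSimulateCommunity:
    def test_read_conservation(self, community):
        _, counts, meta, _, _ = community
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.apply(lambda d: np.issubdtype(d, np.integer)).all()

    def test_grower_relative_abundance_increases(self):
        d = CommunityDesign(
            n_otus=30,
            n_brands=1,
            growth_otus={"OTU_g": (1e3, 1e5)},
            negctrl_otus={},
            n_negctrl=0,
            include_wells=False,
            seed=8,
        )
        counts, meta, cells, truth = simulate_community(d)
        rel = counts / counts.sum(axis=0)
        by_day = rel.loc["OTU_g"].groupby(meta.loc[counts.columns, "day"]).mean()
        # rises until the plateau day, then stays high
        assert by_day.loc[1.0] < by_day.loc[7.0]
        assert by_day.loc[56.0] > 5 * by_day.loc[1.0]

    def test_no_growers_stays_flat(self):
        d = CommunityDesign(
            n_otus=30, n_brands=1, growth_otus={}, negctrl_otus={},
            n_negctrl=0, include_wells=False, seed=8,
        )
        counts, meta, cells, truth = simulate_community(d)
        totals = truth.true_totals
        assert totals.nunique() == 1

    def test_totals_reach_1e5_after_growth(self, community):
        _, counts, meta, cells, truth = community
        late = meta[(meta["water_type"] == "bottle") & (meta["day"] >= 7)]
        assert (truth.true_totals.loc[late.index] >= 1e5).all()
        # measured DAPI means track the true totals up to counting noise
        assert cells.loc[late.index, "dapi_mean"].mean() >= 1e5

    def test_invalid_reads_model_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(reads_model=0.5)

    def test_negative_growth_trajectory_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(growth_otus={"X": (-1.0, 100.0)})

    def test_determinism(self):
        d = CommunityDesign(n_brands=2, seed=13)
        a = simulate_community(d)
        b = simulate_community(d)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2], b[2])
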