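"""Combination index, interpretation bands and synergy surfaces."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cytohts import simulate
from cytohts.synergy import (
    CombinationDesign,
    ci_value,
    classify_ci,
    combination_ci,
    fraction_affected,
    hsa_expected,
    loewe_expected,
    synergy_matrix,
)

DOSES = np.array([1.0, 10.0, 100.0, 1e3, 1e4, 1e5])


class TestCIValue:
    def test_additivity_identity(self):
        assert ci_value(5, 10, 5, 10) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert ci_value(2, 10, 1, 10) == pytest.approx(0.3)

    def test_degenerates_to_single_agent(self):
        assert ci_value(4, 10, 0, 99) == pytest.approx(0.4)

    def test_nonpositive_dx_rejected(self):
        with pytest.raises(ValueError):
            ci_value(1, 0, 1, 10)


class TestClassify:
    @pytest.mark.parametrize("ci,band", [
        (0.1, "strong_synergism"),
        (0.42, "synergism"),            # the verbal call for CI = 0.42
        (0.3, "synergism"),             # left-closed boundary
        (0.8, "moderate_slight_synergism"),
        (1.04, "nearly_additive"),      # the verbal call for CI = 1.04
        (0.9, "nearly_additive"),
        (1.1, "nearly_additive"),       # right-closed boundary
        (1.3, "slight_moderate_antagonism"),
        (1.45, "slight_moderate_antagonism"),
        (2.0, "strong_antagonism"),
    ])
    def test_bands(self, ci, band):
        assert classify_ci(ci) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_ci(-0.1)

    def test_dense_grid_partition_is_total_and_unique(self):
        """Every CI in [0, 3] maps to exactly one of the six bands."""
        grid = np.linspace(0, 3, 6001)
        labels = [classify_ci(c) for c in grid]
        assert set(labels) == {
            "strong_synergism", "synergism", "moderate_slight_synergism",
            "nearly_additive", "slight_moderate_antagonism",
            "strong_antagonism"}
        # labels change monotonically along the grid (each band is an interval)
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == 5


class TestCombinationCI:
    def test_sham_self_combination_is_additive(self, unit_fit):
        sham = simulate.sham_combination(unit_fit, DOSES, ratio=1.0)
        design = CombinationDesign("a", "a", sham.dose1_nM, sham.dose2_nM)
        for r in combination_ci(design, sham.viability_percent,
                                unit_fit, unit_fit):
            assert r.reachable
            assert r.ci == pytest.approx(1.0, abs=0.02)
            assert r.band == "nearly_additive"

    def test_boosted_combination_flags_synergy(self, unit_fit):
        # 4-fold potency boost over additivity: the combination behaves
        # like the single agent at 4x its total dose
        rows = []
        for d in DOSES:
            from cytohts.dose_response import four_pl
            rows.append(float(four_pl(4 * 2 * d, *unit_fit.params())))
        design = CombinationDesign("a", "b", DOSES, DOSES)
        res = combination_ci(design, rows, unit_fit, unit_fit, levels=(0.5,))
        assert res[0].ci < 0.7

    def test_zero_partner_dose_gives_ci_one(self, unit_fit):
        from cytohts.dose_response import four_pl
        y = [float(four_pl(d, *unit_fit.params())) for d in DOSES]
        design = CombinationDesign("a", "b", DOSES, np.zeros_like(DOSES))
        res = combination_ci(design, y, unit_fit, unit_fit)
        for r in res:
            assert r.ci == pytest.approx(1.0, abs=1e-6)

    def test_noisy_sham_ci_is_unbiased(self, unit_fit):
        """With viability noise sd 5 the sham CI is noisy per run (the
        high-effect dose inversion amplifies fit error) but centred on 1:
        the mean over 20 seeded runs stays within 1 +/- 0.15 (bias
        allowance plus ~2.5 Monte-Carlo standard errors) at every level."""
        cis = {0.5: [], 0.75: [], 0.9: []}
        for seed in range(20):
            sham = simulate.sham_combination(unit_fit, np.logspace(0, 5, 8),
                                             ratio=1.0, noise_sd=5.0,
                                             replicates=4, seed=seed)
            design = CombinationDesign("a", "a", sham.dose1_nM, sham.dose2_nM)
            for r in combination_ci(design, sham.viability_percent,
                                    unit_fit, unit_fit):
                assert r.reachable
                cis[r.effect_level].append(r.ci)
        for level, vals in cis.items():
            assert np.mean(vals) == pytest.approx(1.0, abs=0.15), level


class TestLoewe:
    def test_axes_reduce_to_single_agents(self, unit_fit, steep_fit):
        for d in (10.0, 100.0, 5000.0):
            assert loewe_expected(d, 0.0, unit_fit, steep_fit) == pytest.approx(
                fraction_affected(unit_fit, d), abs=1e-6)
            assert loewe_expected(0.0, d, unit_fit, steep_fit) == pytest.approx(
                fraction_affected(steep_fit, d), abs=1e-6)
        assert loewe_expected(0.0, 0.0, unit_fit, steep_fit) == 0.0

    def test_identical_agents_identity(self, unit_fit):
        """For a drug combined with itself, Loewe expects the single-agent
        effect at the summed dose."""
        for d in (5.0, 50.0, 500.0):
            assert loewe_expected(d, d, unit_fit, unit_fit) == pytest.approx(
                fraction_affected(unit_fit, 2 * d), abs=1e-5)

    def test_monotone_in_each_dose(self, unit_fit, steep_fit):
        grid = np.logspace(0, 5, 8)
        rows = [[loewe_expected(a, b, unit_fit, steep_fit) for b in grid]
                for a in grid]
        rows = np.array(rows)
        assert np.all(np.diff(rows, axis=0) >= -1e-6)
        assert np.all(np.diff(rows, axis=1) >= -1e-6)

    def test_hsa_never_exceeds_loewe(self, unit_fit):
        for d in (5.0, 50.0, 500.0, 5000.0):
            assert (hsa_expected(d, d, unit_fit, unit_fit)
                    <= loewe_expected(d, d, unit_fit, unit_fit) + 1e-6)

    def test_expected_effect_respects_the_plateau_bound(self):
        """With partial-efficacy agents (bottom plateau 60% viability) the
        Loewe expectation approaches but never exceeds the maximum
        attainable fraction affected (40%)."""
        from cytohts.dose_response import Fit4PL
        shallow = Fit4PL(bottom=60.0, top=100.0, log_ic50=1.0, hill=1.0,
                         rss=0.0, converged=True, n_points=8)
        for d in (1e2, 1e4, 1e6):
            e = loewe_expected(d, d, shallow, shallow)
            assert e <= 40.0 + 1e-9
        assert loewe_expected(1e6, 1e6, shallow, shallow) == pytest.approx(
            40.0, abs=0.01)


class TestHSA:
    def test_maximum_of_single_agents(self, unit_fit, steep_fit):
        e1 = fraction_affected(unit_fit, 30.0)
        e2 = fraction_affected(steep_fit, 3000.0)
        assert hsa_expected(30.0, 3000.0, unit_fit, steep_fit) == pytest.approx(
            max(e1, e2))

    def test_zero_doses_give_zero_effect(self, unit_fit, steep_fit):
        assert hsa_expected(0.0, 0.0, unit_fit, steep_fit) == pytest.approx(0.0)


class TestSynergyMatrix:
    @pytest.mark.parametrize("model", ["loewe", "hsa"])
    def test_closure_under_matching_model(self, model, unit_fit, steep_fit):
        spec = simulate.MatrixSimSpec(model=model, fit1=unit_fit,
                                      fit2=steep_fit, noise_sd=0.0, seed=0)
        observed, _ = simulate.simulate_combination_matrix(spec)
        mat = synergy_matrix(spec.doses1_nM, spec.doses2_nM, observed,
                             unit_fit, steep_fit, model=model)
        assert np.max(np.abs(mat.delta)) < 1e-6

    def test_planted_cell_is_the_peak(self, unit_fit, steep_fit):
        spec = simulate.MatrixSimSpec(model="boosted_synergy", fit1=unit_fit,
                                      fit2=steep_fit,
                                      interaction_strength=15.0,
                                      boost_cells=((1, 3),), noise_sd=0.0,
                                      seed=0)
        observed, _ = simulate.simulate_combination_matrix(spec)
        mat = synergy_matrix(spec.doses1_nM, spec.doses2_nM, observed,
                             unit_fit, steep_fit, model="loewe")
        assert mat.peak_cell == (1, 3)
        assert mat.peak_delta == pytest.approx(15.0, abs=1e-6)

    def test_drug_order_transposes_surface(self, unit_fit, steep_fit):
        spec = simulate.MatrixSimSpec(model="loewe", fit1=unit_fit,
                                      fit2=steep_fit, noise_sd=2.0, seed=1)
        observed, _ = simulate.simulate_combination_matrix(spec)
        m12 = synergy_matrix(spec.doses1_nM, spec.doses2_nM, observed,
                             unit_fit, steep_fit, model="loewe")
        m21 = synergy_matrix(spec.doses2_nM, spec.doses1_nM, observed.T,
                             steep_fit, unit_fit, model="loewe")
        np.testing.assert_allclose(m21.delta, m12.delta.T, atol=1e-6)
        assert m21.mean_delta == pytest.approx(m12.mean_delta, abs=1e-9)

    def test_fixed_ratio_validation(self):
        with pytest.raises(ValueError, match="constant"):
            CombinationDesign("a", "b", [1, 10], [2, 30])
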