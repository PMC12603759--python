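"""Death-fraction metrics, normalization and robust-Z hit calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cytohts import simulate
from cytohts.primary_screen import (
    DeathFractionSeries,
    DegeneratePopulationError,
    UndefinedFractionError,
    auc_trapezoid,
    call_hits,
    death_series,
    effect_vs_vehicle,
    normalize_control_based,
    robust_zscores,
    score_primary_screen,
    well_death_fraction,
)


class TestDeathFraction:
    def test_symmetric_fields_pool_to_common_ratio(self):
        assert well_death_fraction([10] * 4, [100] * 4) == pytest.approx(0.10)

    def test_pooling_sums_counts_before_ratio(self):
        # (0/100 + 20/100) averaged per field would give 0.10 too, but
        # pooled sums are the contract: 20/200
        assert well_death_fraction([0, 20], [100, 100]) == pytest.approx(0.10)
        assert well_death_fraction([5, 1], [50, 150]) == pytest.approx(6 / 200)

    def test_zero_pooled_tracker_is_undefined(self):
        with pytest.raises(UndefinedFractionError):
            well_death_fraction([5], [0])


class TestDeathSeries:
    def test_series_passthrough_and_plate_disambiguation(self):
        ds = simulate.simulate_primary_plate(simulate.PlateSimSpec(
            n_compounds=800, n_vehicle=4, n_positive=4, seed=3))
        assert ds.annotations.plate_id.nunique() == 3  # wraps onto plates
        s = death_series(ds, "SIM2", "C5", timepoints=(0, 24, 48, 72))
        assert list(s.timepoints) == [0.0, 24.0, 48.0, 72.0]
        assert np.all(s.fractions >= 0)

    def test_missing_timepoint_is_an_error(self):
        ds = simulate.simulate_primary_plate(simulate.PlateSimSpec(
            n_compounds=10, n_vehicle=4, n_positive=4, seed=3))
        ds.imaging = ds.imaging[ds.imaging.timepoint_h != 48.0]
        with pytest.raises(ValueError, match="incomplete"):
            death_series(ds, "SIM1", "A1", timepoints=(0, 24, 48, 72))


class TestAUC:
    def test_closed_form_trapezoid(self):
        s = DeathFractionSeries("P", "A1", [0, 24, 48, 72],
                                [0.0, 0.5, 0.5, 1.0])
        assert auc_trapezoid(s) == pytest.approx(36.0)  # 6 + 12 + 18

    def test_constant_series_is_rectangle(self):
        s = DeathFractionSeries("P", "A1", [0, 24, 48, 72], [0.3] * 4)
        assert auc_trapezoid(s) == pytest.approx(72 * 0.3)

    def test_matches_brute_force_piecewise_linear_integration(self, rng):
        t = np.sort(rng.uniform(0, 72, 6))
        t[0] = 0.0
        f = rng.uniform(0, 1, 6)
        s = DeathFractionSeries("P", "A1", t, f)
        brute = sum((t[i + 1] - t[i]) * (f[i] + f[i + 1]) / 2
                    for i in range(5))
        assert auc_trapezoid(s) == pytest.approx(brute, abs=1e-12)

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            auc_trapezoid(DeathFractionSeries("P", "A1", [0.0], [0.1]))


class TestNormalization:
    def test_vehicle_median_anchors_zero(self):
        assert effect_vs_vehicle(0.1, [0.1, 0.1, 0.1]) == pytest.approx(0.0)
        assert effect_vs_vehicle(0.4, [0.1, 0.1, 0.1]) == pytest.approx(0.3)

    def test_effect_is_robust_to_a_gross_vehicle_outlier(self):
        clean = effect_vs_vehicle(0.4, [0.1, 0.12, 0.08, 0.11, 0.09])
        dirty = effect_vs_vehicle(0.4, [0.1, 0.12, 0.08, 0.11, 99.0])
        assert dirty == pytest.approx(clean, abs=0.02)

    def test_control_window_anchors(self):
        veh, pos = [0.1, 0.1, 0.1], [0.9, 0.9, 0.9]
        assert normalize_control_based(0.1, veh, pos) == pytest.approx(0.0)
        assert normalize_control_based(0.9, veh, pos) == pytest.approx(100.0)
        assert normalize_control_based(0.5, veh, pos) == pytest.approx(50.0)

    def test_zero_window_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            normalize_control_based(0.5, [0.1, 0.1], [0.1, 0.1])


class TestRobustZ:
    def test_median_maps_to_zero(self):
        z = robust_zscores([1, 2, 3, 4, 5, 6, 7, 8, 9],
                           orient_killing_negative=False)
        assert z[4] == pytest.approx(0.0)

    def test_matches_brute_force_median_mad(self, rng):
        x = rng.normal(size=50)
        x[-1] = 100.0  # gross outlier
        z = robust_zscores(x, orient_killing_negative=False)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        brute = (x - med) / (1.4826 * mad)
        np.testing.assert_allclose(z, brute, atol=1e-12)

    def test_degenerate_population_is_an_error(self):
        with pytest.raises(DegeneratePopulationError):
            robust_zscores([1.0] * 20)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.0, 2.2, 0.1, 4.5, 0.9, 1.7, 2.8, 3.3, 0.5])
        z1 = robust_zscores(x, orient_killing_negative=False)
        z2 = robust_zscores(a * x + b, orient_killing_negative=False)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_killing_orientation_orders_wells(self, rng):
        """Within one population, a larger death metric must map to a more
        negative killing-oriented Z."""
        x = rng.uniform(0, 1, 100)
        z = robust_zscores(x, orient_killing_negative=True)
        order = np.argsort(x)
        assert np.all(np.diff(z[order]) <= 0)


class TestHitCalls:
    def test_strict_threshold_boundary(self):
        calls = call_hits(np.array([-3.0, -3.01, -2.5]),
                          compound_ids=["a", "b", "c"])
        by_id = calls.set_index("compound_id").is_hit
        assert not by_id["a"]   # exactly -3 is not a hit
        assert by_id["b"]
        assert not by_id["c"]
        assert list(calls.compound_id) == ["b", "a", "c"]  # sorted by z

    def test_planted_actives_are_recovered(self):
        ds = simulate.simulate_primary_plate(simulate.PlateSimSpec(
            n_compounds=400, active_fraction=0.05, effect_sigma=8.0, seed=11))
        scores = score_primary_screen(ds)
        truth = ds.metadata["truth"]
        actives = {c for c, v in truth.items() if v["active"]}
        for _, grp in scores.groupby("metric_kind"):
            hits = set(grp.loc[grp.is_hit, "compound_id"])
            assert len(hits & actives) / len(actives) >= 0.95


class TestConstantKineticsRankAgreement:
    def test_auc_and_final_metric_agree_on_constant_series(self, rng):
        """With time-constant death fractions the AUC is 72x the final
        fraction, so the two metrics must rank wells identically."""
        fracs = rng.uniform(0, 1, 30)
        aucs = [auc_trapezoid(DeathFractionSeries("P", "A1", [0, 24, 48, 72],
                                                  [f] * 4)) for f in fracs]
        assert np.array_equal(np.argsort(aucs), np.argsort(fracs))
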