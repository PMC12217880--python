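"""Markov demand estimation, scenario adjustment, suitability, CA
allocation and map validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from ecorisk.geodata import LandUseRaster
from ecorisk.lucc import (
    AccuracyReport,
    ScenarioSpec,
    TransitionModel,
    adjust_scenario,
    allocate,
    cross_tabulate,
    demand_from_matrix,
    estimate_transition_matrix,
    fit_suitability,
    validate_simulation,
)
from ecorisk.presets import TRANSFER_ALLOW_ALL
from ecorisk.synthetic import SyntheticSpec, evolve_landscape, generate_landscape

from conftest import random_raster

stochastic_rows = st.lists(
    st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5), min_size=5, max_size=5
).map(lambda rows: np.array(rows) / np.array(rows).sum(axis=1, keepdims=True))


class TestEstimateTransitionMatrix:
    def test_identical_dates_give_identity(self, raster_100):
        tm = estimate_transition_matrix(raster_100, raster_100)
        np.testing.assert_allclose(tm.P, np.eye(5))

    def test_recovers_known_matrix(self):
        spec = SyntheticSpec(shape=(300, 300), smoothness=8.0, seed=51)
        t0 = generate_landscape(spec)
        t1 = evolve_landscape(t0, spec.transition, seed=52)
        tm = estimate_transition_matrix(t0, t1)
        assert np.abs(tm.P - spec.transition).max() < 0.02

    def test_absent_class_gets_identity_row(self):
        t0 = random_raster((50, 50), seed=1, codes=(1, 3, 5))
        t1 = random_raster((50, 50), seed=2, codes=(1, 3, 5))
        tm = estimate_transition_matrix(t0, t1)
        np.testing.assert_allclose(tm.P[1], np.eye(5)[1])  # water absent
        np.testing.assert_allclose(tm.P[3], np.eye(5)[3])  # grassland absent

    def test_rows_stochastic(self, landscape_100):
        t0, t1, _ = landscape_100["rasters"]
        tm = estimate_transition_matrix(t0, t1)
        np.testing.assert_allclose(tm.P.sum(axis=1), 1.0, atol=1e-12)
        assert (tm.P >= 0).all()


class TestAdjustScenario:
    def test_single_raise_renormalizes_row(self):
        """Raising 0.1 by 20% rescales the rest by X=(1-0.12)/0.9."""
        P = np.eye(5)
        P[0] = [0.6, 0.1, 0.1, 0.1, 0.1]
        spec = ScenarioSpec("toy", (((1, 2, "raise", 0.2)),))
        out = adjust_scenario(P, spec)
        np.testing.assert_allclose(
            out[0], [0.58666667, 0.12, 0.09777778, 0.09777778, 0.09777778], atol=1e-8
        )
        assert out[0].sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out[1:], P[1:])

    def test_zero_entry_leaves_row_unchanged(self):
        P = np.eye(5)
        spec = ScenarioSpec("toy", (((1, 2, "raise", 0.5)),))
        out = adjust_scenario(P, spec)
        np.testing.assert_allclose(out, P)

    def test_nd_preset_is_identity_operation(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(5), size=5)
        np.testing.assert_array_equal(adjust_scenario(P, ScenarioSpec.preset("ND")), P)

    @given(P=stochastic_rows)
    @settings(max_examples=100, deadline=None)
    def test_rows_always_sum_to_one_and_directions_hold(self, P):
        ud = ScenarioSpec.preset("UD")
        cp = ScenarioSpec.preset("CP")
        for spec in (ud, cp):
            out = adjust_scenario(P, spec)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
            assert (out >= -1e-15).all()
        out_ud = adjust_scenario(P, ud)
        # UD raises conversion of classes 3,4,5 into construction (col 0)
        for s in (2, 3, 4):
            assert out_ud[s, 0] >= P[s, 0] - 1e-15
        out_cp = adjust_scenario(P, cp)
        # CP reduces cropland->construction and cropland->grassland
        assert out_cp[4, 0] <= P[4, 0] + 1e-15
        assert out_cp[4, 3] <= P[4, 3] + 1e-15

    def test_clipped_raise_moves_all_mass_to_target(self):
        """A raise clipped at probability 1 drives X to 0, not below."""
        P = np.eye(5)
        P[0] = [0.0, 0.9, 0.1, 0.0, 0.0]
        out = adjust_scenario(P, ScenarioSpec("toy", (((1, 2, "raise", 0.5)),)))
        np.testing.assert_allclose(out[0], [0.0, 1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_infeasible_joint_adjustments_rejected(self):
        P = np.eye(5)
        P[0] = [0.0, 0.6, 0.39, 0.01, 0.0]
        spec = ScenarioSpec(
            "toy", ((1, 2, "raise", 0.9), (1, 3, "raise", 0.9))
        )
        with pytest.raises(ValueError, match="sum"):
            adjust_scenario(P, spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", (((1, 1, "raise", 0.2)),))
        with pytest.raises(ValueError):
            ScenarioSpec("bad", (((1, 2, "raise", 1.5)),))


class TestDemand:
    def test_demand_conserves_total_cells(self, raster_100):
        rng = np.random.default_rng(4)
        P = rng.dirichlet(np.ones(5), size=5)
        demand = demand_from_matrix(raster_100, P)
        assert demand.sum() == raster_100.n_valid

    def test_ud_demand_for_construction_not_below_nd(self, landscape_100):
        t0, t1, _ = landscape_100["rasters"]
        P = estimate_transition_matrix(t0, t1).P
        nd = demand_from_matrix(t1, adjust_scenario(P, ScenarioSpec.preset("ND")))
        ud = demand_from_matrix(t1, adjust_scenario(P, ScenarioSpec.preset("UD")))
        assert ud[0] >= nd[0]


class TestSuitability:
    def test_constant_drivers_give_constant_surfaces(self, landscape_100):
        t0, t1, _ = landscape_100["rasters"]
        drivers = np.full((3,) + t0.shape, 0.5)
        suit = fit_suitability(t0, t1, drivers, seed=0)
        for s in suit:
            assert np.ptp(s) == pytest.approx(0.0, abs=1e-12)

    def test_probabilities_sum_to_one(self, landscape_100):
        t0, t1, _ = landscape_100["rasters"]
        suit = fit_suitability(t0, t1, landscape_100["drivers"], seed=0)
        np.testing.assert_allclose(suit.sum(axis=0), 1.0, atol=1e-9)

    def test_driver_defined_class_correlates_with_driver(self, raster_100):
        rng = np.random.default_rng(6)
        from scipy.ndimage import gaussian_filter

        d1 = gaussian_filter(rng.standard_normal(raster_100.shape), 8)
        d1 = (d1 - d1.min()) / np.ptp(d1)
        drivers = np.stack([d1, rng.random(raster_100.shape)])
        # class 1 wherever driver 1 is high, class 5 elsewhere
        g = np.where(d1 > np.quantile(d1, 0.7), 1, 5).astype(np.int32)
        t1 = LandUseRaster(grid=g, cell_size=raster_100.cell_size)
        suit = fit_suitability(raster_100, t1, drivers, seed=1)
        r = np.corrcoef(suit[0].ravel(), d1.ravel())[0, 1]
        assert r > 0.5

    def test_starved_class_warns_and_gets_uniform(self, raster_100):
        g = raster_100.grid.copy()
        g[g == 2] = 3
        g[0, 0] = 2  # a single water cell
        t1 = LandUseRaster(grid=g, cell_size=raster_100.cell_size)
        drivers = np.random.default_rng(0).random((2,) + raster_100.shape)
        with pytest.warns(UserWarning, match="uniform"):
            suit = fit_suitability(raster_100, t1, drivers, seed=0)
        np.testing.assert_allclose(suit.sum(axis=0), 1.0, atol=1e-9)


class TestAllocate:
    def make_inputs(self, seed=0, shape=(100, 100)):
        spec = SyntheticSpec(shape=shape, smoothness=6.0, seed=seed)
        t0 = generate_landscape(spec)
        t1 = evolve_landscape(t0, spec.transition, seed=seed + 1)
        from ecorisk.synthetic import generate_drivers

        drivers = generate_drivers(t0, 4, smoothness=8.0, seed=seed + 2)
        suit = fit_suitability(t0, t1, drivers, seed=seed + 3)
        return t0, t1, suit

    def test_identity_demand_is_fixed_point(self):
        t0, t1, suit = self.make_inputs(seed=70)
        model = TransitionModel(P=np.eye(5), transfer_cost=TRANSFER_ALLOW_ALL)
        res = allocate(t1, model, suit, ScenarioSpec("ND"), seed=1)
        np.testing.assert_array_equal(res.raster.grid, t1.grid)

    def test_frozen_water_cells_never_change(self):
        t0, t1, suit = self.make_inputs(seed=71)
        P = estimate_transition_matrix(t0, t1).P
        frozen = t1.grid == 2
        model = TransitionModel(
            P=P, transfer_cost=TRANSFER_ALLOW_ALL, restriction_mask=frozen
        )
        res = allocate(t1, model, suit, ScenarioSpec.preset("UD"), seed=2)
        np.testing.assert_array_equal(res.raster.grid[frozen], t1.grid[frozen])

    def test_counts_match_demand_within_rounding(self):
        t0, t1, suit = self.make_inputs(seed=72)
        P = estimate_transition_matrix(t0, t1).P
        model = TransitionModel(P=P, transfer_cost=TRANSFER_ALLOW_ALL)
        res = allocate(t1, model, suit, ScenarioSpec("ND"), seed=3)
        assert np.abs(res.achieved - res.demand).max() <= 5
        assert res.achieved.sum() == t1.n_valid

    def test_recovery_loop_reproduces_realized_counts(self):
        """Estimate P from a synthetic pair, re-allocate: counts within 1%."""
        spec = SyntheticSpec(shape=(150, 150), smoothness=6.0, seed=73)
        t0 = generate_landscape(spec)
        t1 = evolve_landscape(t0, spec.transition, seed=74)
        from ecorisk.synthetic import generate_drivers

        drivers = generate_drivers(t0, 4, smoothness=8.0, seed=75)
        suit = fit_suitability(t0, t1, drivers, seed=76)
        P_hat = estimate_transition_matrix(t0, t1).P
        model = TransitionModel(P=P_hat, transfer_cost=TRANSFER_ALLOW_ALL)
        res = allocate(t0, model, suit, ScenarioSpec("ND"), seed=77)
        realized = np.array([(t1.grid == c).sum() for c in range(1, 6)])
        assert np.abs(res.achieved - realized).max() <= 0.01 * t0.n_valid


class TestValidation:
    def test_identical_maps_perfect_agreement(self, raster_100):
        rep = validate_simulation(raster_100, raster_100)
        assert rep.overall_accuracy == 1.0
        assert rep.kappa == 1.0

    def test_toy_confusion_matrix_hand_computation(self):
        rep = AccuracyReport.from_confusion(np.array([[40, 10], [5, 45]]))
        assert rep.overall_accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_independent_maps_have_near_zero_kappa(self):
        a = random_raster((320, 320), seed=80)
        b = random_raster((320, 320), seed=81)
        rep = validate_simulation(a, b)
        assert abs(rep.kappa) < 0.02

    def test_kappa_matches_sklearn(self, landscape_100):
        t0, t1, _ = landscape_100["rasters"]
        rep = validate_simulation(t0, t1)
        expected = cohen_kappa_score(t1.grid.ravel(), t0.grid.ravel())
        assert rep.kappa == pytest.approx(expected, abs=1e-12)

    def test_cross_tabulate_counts(self):
        g0 = np.array([[1, 1], [2, 3]], dtype=np.int32)
        g1 = np.array([[1, 2], [2, 3]], dtype=np.int32)
        c = cross_tabulate(LandUseRaster(grid=g0), LandUseRaster(grid=g1))
        assert c[0, 0] == 1 and c[0, 1] == 1 and c[1, 1] == 1 and c[2, 2] == 1
        assert c.sum() == 4
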