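"""The correlated-random-walk engine: turn draws, collision inflation,
path invariants, termination and reproducibility."""

from __future__ import annotations

import math

import numpy as np
import pytest
import shapely

from lakewalk import CRWParams, collision_sigma, draw_turn, simulate_ensemble, simulate_path
from lakewalk.crw import FAILURE_CAP, SUCCESS, path_rng

from conftest import make_corridor


def assert_path_invariants(path, basin, params):
    assert path.distance == path.n_steps * params.step_length
    assert path.n_steps <= params.max_steps
    assert len(path.points) == path.n_steps + 1
    assert len(path.headings) == path.n_steps
    # every vertex inside the lake; the final vertex of a successful path may
    # sit in the outside half of the capture disc straddling the shoreline
    pts = path.points[:-1] if path.succeeded else path.points
    for x, y in pts:
        assert shapely.dwithin(basin.polygon, shapely.Point(x, y), 1e-6)
    if path.succeeded:
        fx, fy = path.points[-1]
        cx, cy = basin.capture.center
        assert math.hypot(fx - cx, fy - cy) <= basin.capture.radius + 1e-9


class TestDrawTurn:
    def test_zero_sigma_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(draw_turn(0.0, rng) == 0.0 for _ in range(100))

    def test_sample_sd_recovers_sigma(self):
        rng = np.random.default_rng(1)
        draws = np.array([draw_turn(5.0, rng) for _ in range(100_000)])
        assert np.std(draws) == pytest.approx(5.0, rel=0.02)

    def test_sample_mean_near_zero(self):
        rng = np.random.default_rng(2)
        draws = np.array([draw_turn(25.0, rng) for _ in range(100_000)])
        assert abs(draws.mean()) < 0.3  # ~3 sigma of the mean at n=1e5

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            draw_turn(-1.0, np.random.default_rng(0))


class TestCollisionSigma:
    @pytest.mark.parametrize("k,expected", [(0, 5.0), (1, 5.5), (3, 9.5)])
    def test_default_inflation(self, k, expected):
        assert collision_sigma(5.0, k) == pytest.approx(expected)

    def test_monotone_in_k(self):
        vals = [collision_sigma(5.0, k) for k in range(30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_configurable_coefficient_and_exponent(self):
        assert collision_sigma(5.0, 3, coeff=0.1, exponent=1.0) == pytest.approx(6.5)
        assert collision_sigma(5.0, 2, coeff=0.5, exponent=2.0) == pytest.approx(15.0)
        assert collision_sigma(0.0, 10) == 0.0


class TestSimulatePath:
    def test_straight_line_limit_reaches_capture_exactly(self):
        corridor = make_corridor(length=1000.0)
        params = CRWParams(step_length=100.0, turn_sd=0.0, max_path_length=75_000.0)
        path = simulate_path(corridor, params, np.random.default_rng(0))
        assert path.outcome == SUCCESS
        assert path.n_steps == 10
        assert path.distance == 1000.0
        np.testing.assert_allclose(path.points[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            path.points[:, 1], np.arange(11) * 100.0, atol=1e-9
        )

    def test_cap_binds_immediately_when_capture_behind(self):
        corridor = make_corridor(length=1000.0)
        # one-step budget, capture a kilometer ahead: never reached
        params = CRWParams(step_length=100.0, turn_sd=0.0, max_path_length=100.0)
        path = simulate_path(corridor, params, np.random.default_rng(0))
        assert path.outcome == FAILURE_CAP
        assert path.n_steps == 1
        assert path.distance == 100.0

    @pytest.mark.parametrize("turn_sd", [2.0, 5.0, 15.0, 25.0])
    def test_invariant_sweep_on_circular_basin(self, circular_basin, turn_sd):
        params = CRWParams(step_length=100.0, turn_sd=turn_sd, max_path_length=75_000.0)
        for path in simulate_ensemble(circular_basin, params, 50, seed=[11, int(turn_sd)]):
            assert_path_invariants(path, circular_basin, params)

    def test_capped_paths_share_identical_distance(self, circular_basin):
        params = CRWParams(step_length=150.0, turn_sd=25.0, max_path_length=75_000.0)
        capped = [
            p
            for p in simulate_ensemble(circular_basin, params, 100, seed=13)
            if p.outcome == FAILURE_CAP
        ]
        assert capped, "expected some capped paths at high sigma"
        assert len({p.distance for p in capped}) == 1
        assert capped[0].distance == params.max_steps * 150.0

    def test_sigma_recovery_on_collision_free_run(self, open_water):
        # 1e4 accepted steps with no boundary in reach: the realized
        # turning-angle SD must match the configured sigma
        params = CRWParams(
            step_length=100.0, turn_sd=5.0, max_path_length=100.0 * 10_000
        )
        path = simulate_path(open_water, params, np.random.default_rng(21))
        assert path.n_collisions == 0
        assert path.n_steps == 10_000
        turns = path.turning_angles()
        assert np.std(turns) == pytest.approx(5.0, rel=0.03)
        assert abs(np.mean(turns)) < 0.2

    def test_first_step_turns_around_initial_bearing(self, open_water):
        params = CRWParams(step_length=100.0, turn_sd=10.0, max_path_length=200.0)
        headings = [
            simulate_path(open_water, params, np.random.default_rng([31, i])).headings[0]
            for i in range(500)
        ]
        wrapped = (np.array(headings) + 180.0) % 360.0 - 180.0
        # centred on the initial bearing (0 deg) with SD ~ sigma
        assert abs(wrapped.mean()) < 1.5
        assert np.std(wrapped) == pytest.approx(10.0, rel=0.15)

    def test_start_outside_polygon_rejected(self, circular_basin):
        import dataclasses

        bad = dataclasses.replace(circular_basin, start=(1e6, 1e6))
        with pytest.raises(ValueError):
            simulate_path(bad, CRWParams(step_length=100, turn_sd=5),
                          np.random.default_rng(0))


class TestEnsemble:
    def test_bit_identical_for_same_seed(self, circular_basin):
        params = CRWParams(step_length=100.0, turn_sd=15.0)
        a = simulate_ensemble(circular_basin, params, 40, seed=99)
        b = simulate_ensemble(circular_basin, params, 40, seed=99)
        assert [p.outcome for p in a] == [p.outcome for p in b]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.points, pb.points)

    def test_singleton_equals_substream_zero(self, circular_basin):
        params = CRWParams(step_length=100.0, turn_sd=15.0)
        (one,) = simulate_ensemble(circular_basin, params, 1, seed=5)
        direct = simulate_path(circular_basin, params, path_rng(5, 0))
        np.testing.assert_array_equal(one.points, direct.points)

    def test_different_seeds_agree_within_binomial_bound(self, circular_basin):
        params = CRWParams(step_length=100.0, turn_sd=15.0)
        rates = []
        for seed in (101, 202):
            paths = simulate_ensemble(circular_basin, params, 200, seed=seed)
            rates.append(sum(p.succeeded for p in paths) / 200)
        p = np.mean(rates)
        bound = 4.0 * math.sqrt(p * (1 - p) / 200)
        assert abs(rates[0] - rates[1]) < bound

    def test_requires_a_seed(self, circular_basin):
        with pytest.raises(ValueError):
            simulate_ensemble(
                circular_basin, CRWParams(step_length=100, turn_sd=5), 2
            )
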