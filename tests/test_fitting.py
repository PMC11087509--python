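import numpy as np
import pytest

from ensemblefit.density import ReferenceRegion, map_correlation
from ensemblefit.fitting import (
    SelectionConfig,
    WeightVector,
    best_n_curve,
    brute_force_select,
    optimize_structure_set,
    optimize_weights,
    weighted_average_map,
)
from ensemblefit.models import DensityMap, GridSpec


def _grid(n):
    return GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(n, 1, 1))


def _map(values, mask=None):
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return DensityMap(grid=_grid(values.shape[0]), values=values, mask=mask)


def _region(values):
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    mask = np.ones(values.shape, dtype=bool)
    return ReferenceRegion(
        map=DensityMap(grid=_grid(values.shape[0]), values=values, mask=mask), radius=5.0
    )


class TestWeightVector:
    def test_valid(self):
        w = WeightVector(np.array([0.2, 0.25, 0.55]))
        assert len(w) == 3

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([-0.1, 1.1]))

    def test_sum_enforced(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([0.5, 0.6]))

    def test_normalized(self):
        w = WeightVector.normalized([2.0, 2.0])
        np.testing.assert_allclose(w.weights, [0.5, 0.5])


class TestWeightedAverageMap:
    def test_one_hot_returns_first(self, rng):
        maps = [_map(rng.normal(size=6)) for _ in range(3)]
        out = weighted_average_map(maps, WeightVector(np.array([1.0, 0.0, 0.0])))
        np.testing.assert_array_equal(out.values, maps[0].values)

    def test_equal_maps_any_weights(self, rng):
        m = _map(rng.normal(size=6))
        out = weighted_average_map([m, m, m], WeightVector(np.array([0.2, 0.25, 0.55])))
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)

    def test_two_one_hot_maps(self):
        m1 = _map([1.0, 0.0])
        m2 = _map([0.0, 1.0])
        out = weighted_average_map([m1, m2], WeightVector(np.array([0.25, 0.75])))
        np.testing.assert_allclose(out.values.ravel(), [0.25, 0.75])

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            weighted_average_map([_map(rng.normal(size=4))], WeightVector(np.array([0.5, 0.5])))


def brute_force_weight_oracle(maps, region, step=0.01):
    """Independent exhaustive search: directly correlates every lattice mix."""
    m = int(round(1 / step))
    best = (None, -np.inf)
    for i in range(m + 1):
        for j in range(m + 1 - i):
            k = m - i - j
            w = np.array([i, j, k]) / m
            mix = sum(wi * mp.values for wi, mp in zip(w, maps))
            mixed = DensityMap(grid=maps[0].grid, values=mix)
            try:
                rho = map_correlation(mixed, region.map, region.mask).rho
            except ValueError:
                continue
            if rho > best[1] + 1e-12:
                best = (w, rho)
    return best


class TestOptimizeWeights:
    def test_disjoint_support_mixture_recovery(self):
        # three maps with disjoint supports; target is an exact mixture
        m1 = _map([1.0, 0, 0, 0])
        m2 = _map([0, 1.0, 0, 0])
        m3 = _map([0, 0, 1.0, 0])
        target = _region([0.20, 0.25, 0.55, 0.0])
        result = optimize_weights([m1, m2, m3], target)
        np.testing.assert_allclose(result.weights.weights, [0.20, 0.25, 0.55], atol=1e-12)
        assert result.rho == pytest.approx(1.0, abs=1e-12)
        # independent lattice oracle agrees (coarser step keeps it fast)
        w_oracle, rho_oracle = brute_force_weight_oracle([m1, m2, m3], target, step=0.05)
        coarse = optimize_weights([m1, m2, m3], target, grid_step=0.05)
        assert coarse.rho == pytest.approx(rho_oracle, abs=1e-9)
        np.testing.assert_allclose(coarse.weights.weights, w_oracle, atol=1e-12)

    def test_target_equals_first_map(self, rng):
        maps = [_map(rng.normal(size=8)) for _ in range(3)]
        target = _region(maps[0].values.ravel())
        result = optimize_weights(maps, target)
        np.testing.assert_allclose(result.weights.weights, [1.0, 0.0, 0.0], atol=1e-12)
        assert result.rho == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_tie_break_lexicographic(self, rng):
        m = _map(rng.normal(size=6))
        target = _region(rng.normal(size=6))
        result = optimize_weights([m, m, m], target)
        # all mixtures are equal; lexicographically smallest vector wins
        np.testing.assert_allclose(result.weights.weights, [0.0, 0.0, 1.0], atol=1e-12)

    def test_never_below_best_single_map(self, rng):
        maps = [_map(rng.normal(size=10)) for _ in range(3)]
        target = _region(rng.normal(size=10))
        singles = [map_correlation(m, target.map, target.mask).rho for m in maps]
        result = optimize_weights(maps, target)
        assert result.rho >= max(singles) - 1e-12  # one-hot weights are lattice points

    def test_surface_shape_and_content(self):
        m1, m2 = _map([1.0, 0.0]), _map([0.0, 1.0])
        target = _region([0.3, 0.7])
        result = optimize_weights([m1, m2], target, grid_step=0.1)
        assert result.surface.shape == (11, 3)
        assert result.surface[:, :2].sum(axis=1) == pytest.approx(1.0)

    def test_fewer_than_two_maps_raises(self, rng):
        with pytest.raises(ValueError):
            optimize_weights([_map(rng.normal(size=5))], _region(rng.normal(size=5)))

    def test_bad_grid_step_raises(self, rng):
        maps = [_map(rng.normal(size=5)) for _ in range(2)]
        with pytest.raises(ValueError, match="divide"):
            optimize_weights(maps, _region(rng.normal(size=5)), grid_step=0.03)

    def test_zero_variance_target_raises(self, rng):
        maps = [_map(rng.normal(size=5)) for _ in range(2)]
        with pytest.raises(ValueError, match="variance"):
            optimize_weights(maps, _region(np.ones(5) * 4.2))

    def test_four_map_ascent_matches_three_map_structure(self, rng):
        # 4 disjoint-support maps: ascent must still recover an exact mixture
        maps = [_map(np.eye(5)[i]) for i in range(4)]
        target = _region([0.1, 0.2, 0.3, 0.4, 0.0])
        result = optimize_weights(maps, target)
        np.testing.assert_allclose(result.weights.weights, [0.1, 0.2, 0.3, 0.4], atol=1e-9)
        assert result.rho == pytest.approx(1.0, abs=1e-9)


def _random_pool(rng, n_maps=8, n_vox=30):
    maps = [_map(rng.normal(size=n_vox)) for _ in range(n_maps)]
    target = _region(rng.normal(size=n_vox))
    return maps, target


class TestOptimizeStructureSet:
    def test_pool_contains_exact_target(self, rng):
        maps, _ = _random_pool(rng, n_maps=5)
        target_values = rng.normal(size=30)
        maps.append(_map(target_values))
        target = _region(target_values)
        cfg = SelectionConfig(n_structures=1, seed=1)
        res = optimize_structure_set(maps, target, cfg)
        assert list(res.member_indices) == [5]
        assert res.rho == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        maps, target = _random_pool(rng)
        cfg = SelectionConfig(n_structures=2, n_replicas=5, seed=11)
        res = optimize_structure_set(maps, target, cfg)
        oracle = brute_force_select(maps, target, 2)
        assert res.rho == pytest.approx(oracle.rho, abs=1e-9)
        assert list(res.member_indices) == list(oracle.member_indices)

    def test_replica_spread_within_tolerance(self, rng):
        maps, target = _random_pool(rng)
        cfg = SelectionConfig(n_structures=2, n_replicas=5, convergence_tol=1e-2, seed=5)
        res = optimize_structure_set(maps, target, cfg)
        assert res.converged
        assert max(res.replica_rhos) - min(res.replica_rhos) <= 1e-2 + 1e-12

    def test_traces_monotone_nondecreasing(self, rng):
        maps, target = _random_pool(rng)
        cfg = SelectionConfig(n_structures=3, n_replicas=3, seed=2)
        res = optimize_structure_set(maps, target, cfg)
        for trace in res.replica_traces:
            assert np.all(np.diff(trace) >= 0)  # accepted rho only ever increases
            assert trace[-1] >= trace[0]

    def test_seed_reproducibility(self, rng):
        maps, target = _random_pool(rng)
        cfg = SelectionConfig(n_structures=3, n_replicas=4, seed=123)
        r1 = optimize_structure_set(maps, target, cfg)
        r2 = optimize_structure_set(maps, target, cfg)
        assert r1.rho == r2.rho
        assert list(r1.member_indices) == list(r2.member_indices)
        np.testing.assert_array_equal(r1.weights.weights, r2.weights.weights)
        assert r1.iterations == r2.iterations

    def test_n_larger_than_pool_raises(self, rng):
        maps, target = _random_pool(rng, n_maps=3)
        with pytest.raises(ValueError, match="pool"):
            optimize_structure_set(maps, target, SelectionConfig(n_structures=4))

    def test_result_rho_is_weighted_average_correlation(self, rng):
        maps, target = _random_pool(rng)
        cfg = SelectionConfig(n_structures=3, seed=9)
        res = optimize_structure_set(maps, target, cfg)
        mixed = weighted_average_map([maps[i] for i in res.member_indices], res.weights)
        direct = map_correlation(mixed, target.map, target.mask).rho
        assert res.rho == pytest.approx(direct, abs=1e-9)


class TestBruteForceSelect:
    def test_full_pool(self, rng):
        maps, target = _random_pool(rng, n_maps=4)
        res = brute_force_select(maps, target, 4)
        assert list(res.member_indices) == [0, 1, 2, 3]

    def test_n1_is_argmax_single(self, rng):
        maps, target = _random_pool(rng, n_maps=6)
        res = brute_force_select(maps, target, 1)
        singles = [map_correlation(m, target.map, target.mask).rho for m in maps]
        assert res.member_indices[0] == int(np.argmax(singles))
        assert res.rho == pytest.approx(max(singles), abs=1e-12)

    def test_cap_enforced(self, rng):
        maps, target = _random_pool(rng, n_maps=8)
        with pytest.raises(ValueError, match="cap"):
            brute_force_select(maps, target, 4, enumeration_cap=10)


class TestBestNCurve:
    def test_monotone_and_endpoints(self, rng):
        maps, target = _random_pool(rng, n_maps=6)
        cfg = SelectionConfig(n_structures=6, n_replicas=3, seed=3)
        curve = best_n_curve(maps, target, [1, 2, 3, 6], cfg)
        assert np.all(np.diff(curve.rhos) >= -1e-9)
        # n = pool size: rho equals the full-pool weight optimum
        full = brute_force_select(maps, target, 6)
        assert curve.rhos[-1] == pytest.approx(full.rho, abs=1e-9)

    def test_reference_levels(self, rng):
        maps, target = _random_pool(rng, n_maps=5)
        cfg = SelectionConfig(n_structures=2, n_replicas=2, seed=4)
        curve = best_n_curve(maps, target, [1, 2], cfg, initial_maps=maps[:3])
        uniform = weighted_average_map(maps, WeightVector.uniform(5))
        assert curve.full_ensemble_rho == pytest.approx(
            map_correlation(uniform, target.map, target.mask).rho
        )
        assert curve.initial_rho is not None


class TestWeightRecoveryOnScenario:
    def test_noiseless_recovery_within_lattice_step(self, minimal_data):
        data = minimal_data
        result = optimize_weights(data.conformation_maps, data.target)
        truth = np.asarray(data.truth["true_weights"])
        assert np.abs(result.weights.weights - truth).max() <= 0.01 + 1e-12
        assert result.rho >= 0.999
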