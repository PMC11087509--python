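"""Simplex weight optimization and correlation-optimized structure-set
selection.

Two inference procedures operate on a target reference region:

* :func:`optimize_weights` finds nonnegative, unit-sum weights over a set
  of ensemble maps maximizing Pearson correlation of the weighted average
  with the target.  For up to three maps the barycentric weight lattice is
  searched exhaustively (yielding the full correlation surface); for more
  maps a deterministic multi-start lattice ascent is used.

* :func:`optimize_structure_set` iteratively improves a randomly chosen
  subset of pool maps by swapping members for random non-members,
  re-optimizing weights after each swap and accepting only strict
  improvements, across several replicas that must agree before
  termination.

:func:`brute_force_select` provides an exhaustive-enumeration oracle for
small pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .density import ReferenceRegion, map_correlation
from .models import DensityMap

__all__ = [
    "WeightVector",
    "WeightOptimum",
    "SelectionConfig",
    "SelectionResult",
    "BestNCurve",
    "weighted_average_map",
    "optimize_weights",
    "optimize_structure_set",
    "brute_force_select",
    "best_n_curve",
]


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative mixture weights summing to one."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a nonempty 1-D sequence")
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()})")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size

    def __iter__(self):
        return iter(self.weights)

    @classmethod
    def uniform(cls, k: int) -> "WeightVector":
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def normalized(cls, raw: Sequence[float]) -> "WeightVector":
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise ValueError("cannot normalize nonpositive weights")
        return cls(raw / total)


@dataclass
class WeightOptimum:
    """Result of a simplex weight search."""

    weights: WeightVector
    rho: float
    #: (n_points, k+1) array of lattice weights and their correlations,
    #: or None when the lattice was not enumerated exhaustively.
    surface: Optional[np.ndarray] = None


def weighted_average_map(
    maps: Sequence[DensityMap], weights: WeightVector
) -> DensityMap:
    """Voxelwise weighted sum of maps sharing one grid."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    if len(maps) != len(weights):
        raise ValueError("number of maps must equal number of weights")
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.is_close(m.grid):
            raise ValueError("maps are on different grids")
    values = np.zeros(grid.shape)
    for w, m in zip(weights.weights, maps):
        values += w * m.values
    return DensityMap(grid=grid, values=values)


# ---------------------------------------------------------------------------
# internal machinery: correlation of a weighted combination reduces to
# rho(w) = (w . ct) / (|t| * sqrt(w^T G w)) with centered masked vectors
# ---------------------------------------------------------------------------


def _masked_centered(maps: Sequence[DensityMap], target: ReferenceRegion):
    mask = target.mask
    grid = target.grid
    t = target.map.values[mask].astype(float)
    tc = t - t.mean()
    tnorm = float(np.sqrt(np.dot(tc, tc)))
    if tnorm == 0:
        raise ValueError("target has zero variance inside the mask")
    rows = []
    for m in maps:
        if not grid.is_close(m.grid):
            raise ValueError("map grid does not match the target grid")
        x = m.values[mask].astype(float)
        rows.append(x - x.mean())
    xc = np.array(rows)
    return xc, tc, tnorm


_COMPOSITION_CACHE: Dict[Tuple[int, int], np.ndarray] = {}


def _lattice_compositions(k: int, m: int) -> np.ndarray:
    """All integer vectors of length k summing to m, lexicographically
    ascending. Cached; only used for k <= 3."""
    key = (k, m)
    if key not in _COMPOSITION_CACHE:
        combos = []

        def rec(prefix, remaining, slots):
            if slots == 1:
                combos.append(prefix + [remaining])
                return
            for v in range(remaining + 1):
                rec(prefix + [v], remaining - v, slots - 1)

        rec([], m, k)
        _COMPOSITION_CACHE[key] = np.array(combos, dtype=float) / m
    return _COMPOSITION_CACHE[key]


def _rho_of_weights(w: np.ndarray, gram: np.ndarray, ct: np.ndarray, tnorm: float):
    den2 = float(w @ gram @ w)
    if den2 <= 0:
        return -np.inf
    return float(np.clip(float(w @ ct) / (tnorm * np.sqrt(den2)), -1.0, 1.0))


def _lattice_argmax(gram, ct, tnorm, step):
    """Exhaustive search of the barycentric lattice (k <= 3)."""
    k = ct.size
    m = int(round(1.0 / step))
    lattice = _lattice_compositions(k, m)
    num = lattice @ ct
    den2 = np.einsum("lk,kj,lj->l", lattice, gram, lattice)
    valid = den2 > 0
    rho = np.full(lattice.shape[0], -np.inf)
    rho[valid] = np.clip(num[valid] / (tnorm * np.sqrt(den2[valid])), -1.0, 1.0)
    # first index attaining the max within tolerance = lexicographically
    # smallest weight vector, since the lattice is lex-ascending
    best = float(rho.max())
    idx = int(np.flatnonzero(rho >= best - 1e-12)[0])
    surface = np.column_stack([lattice, rho])
    return lattice[idx].copy(), float(rho[idx]), surface


def _ascent_argmax(gram, ct, tnorm, step, extra_starts=()):
    """Deterministic multi-start single-step ascent on the lattice (k > 3)."""
    k = ct.size
    m = int(round(1.0 / step))

    starts = []
    for i in range(k):  # one-hot corners
        c = np.zeros(k, dtype=int)
        c[i] = m
        starts.append(c)
    base = np.full(k, m // k, dtype=int)  # near-uniform start
    base[: m - base.sum()] += 1
    starts.append(base)
    for extra in extra_starts:
        c = np.asarray(np.round(np.asarray(extra, dtype=float) * m), dtype=int)
        c = np.clip(c, 0, m)
        c[int(np.argmax(c))] += m - c.sum()  # repair rounding drift
        if c.min() >= 0 and c.sum() == m:
            starts.append(c)

    best_c, best_rho = None, -np.inf
    for c0 in starts:
        c = c0.copy()
        rho = _rho_of_weights(c / m, gram, ct, tnorm)
        improved = True
        while improved:
            improved = False
            cand_best, cand_rho = None, rho
            for i in range(k):
                if c[i] == 0:
                    continue
                for j in range(k):
                    if i == j:
                        continue
                    c[i] -= 1
                    c[j] += 1
                    r = _rho_of_weights(c / m, gram, ct, tnorm)
                    if r > cand_rho + 1e-12:
                        cand_rho = r
                        cand_best = c.copy()
                    c[i] += 1
                    c[j] -= 1
            if cand_best is not None:
                c = cand_best
                rho = cand_rho
                improved = True
        if rho > best_rho + 1e-12 or (
            abs(rho - best_rho) <= 1e-12
            and best_c is not None
            and tuple(c) < tuple(best_c)
        ):
            best_c, best_rho = c.copy(), rho
    return best_c / m, float(best_rho), None


def _optimize_prepared(gram, ct, tnorm, step, extra_starts=()):
    if ct.size == 1:
        rho = _rho_of_weights(np.ones(1), gram, ct, tnorm)
        return np.ones(1), rho, None
    if ct.size <= 3:
        return _lattice_argmax(gram, ct, tnorm, step)
    return _ascent_argmax(gram, ct, tnorm, step, extra_starts)


def optimize_weights(
    maps: Sequence[DensityMap],
    target: ReferenceRegion,
    grid_step: float = 0.01,
) -> WeightOptimum:
    """Find simplex weights maximizing correlation with the target.

    For up to three maps the barycentric lattice ``{w : w_i in {0, step,
    ..., 1}, sum w = 1}`` is searched exhaustively and the full (weights,
    rho) surface is returned; ties are broken toward the lexicographically
    smallest weight vector.  For more maps a deterministic lattice ascent
    from multiple starts replaces the exhaustive search (``surface`` is
    then ``None``).

    Raises
    ------
    ValueError
        For fewer than 2 maps, a ``grid_step`` that does not divide 1, or
        a target with zero variance inside the mask.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("optimize_weights requires at least 2 maps")
    m = round(1.0 / grid_step)
    if m < 1 or abs(m * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step {grid_step} must divide 1 evenly")
    xc, tc, tnorm = _masked_centered(maps, target)
    gram = xc @ xc.T
    ct = xc @ tc
    w, rho, surface = _optimize_prepared(gram, ct, tnorm, grid_step)
    return WeightOptimum(weights=WeightVector(w), rho=rho, surface=surface)


# ---------------------------------------------------------------------------
# structure-set selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of the random-swap structure-set search."""

    n_structures: int
    n_replicas: int = 5
    convergence_tol: float = 1e-2
    max_iterations: int = 10000
    seed: int = 0
    weight_grid_step: float = 0.01

    def __post_init__(self):
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of a structure-set search."""

    member_indices: np.ndarray
    weights: WeightVector
    rho: float
    iterations: int
    replica_rhos: List[float]
    converged: bool
    #: per-replica best-rho trace, one value per iteration
    replica_traces: List[np.ndarray] = field(default_factory=list)


class _PooledTarget:
    """Precomputed Gram/cross terms for fast subset weight optimization."""

    def __init__(self, pool_maps: Sequence[DensityMap], target: ReferenceRegion):
        xc, tc, tnorm = _masked_centered(pool_maps, target)
        self.gram = xc @ xc.T
        self.ct = xc @ tc
        self.tnorm = tnorm
        self.n = len(pool_maps)

    def optimize_subset(self, members: np.ndarray, step: float, start_w=None):
        idx = np.asarray(members, dtype=int)
        sub_gram = self.gram[np.ix_(idx, idx)]
        sub_ct = self.ct[idx]
        extra = () if start_w is None else (start_w,)
        w, rho, _ = _optimize_prepared(sub_gram, sub_ct, self.tnorm, step, extra)
        if not np.isfinite(rho):
            raise ValueError("non-finite correlation during subset optimization")
        return w, rho


def optimize_structure_set(
    pool_maps: Sequence[DensityMap],
    target: ReferenceRegion,
    cfg: SelectionConfig,
    warm_members: Optional[Sequence[int]] = None,
    warm_weights: Optional[Sequence[float]] = None,
) -> SelectionResult:
    """Select ``cfg.n_structures`` pool maps maximizing target correlation.

    Each replica starts from a uniformly random subset; every iteration a
    random member is exchanged for a random non-member, weights are
    re-optimized and the swap is accepted only if correlation strictly
    improves.  Replicas run in lockstep until their best correlations
    agree within ``cfg.convergence_tol`` (checked after a burn-in of
    pool-size iterations) or ``cfg.max_iterations`` is reached.  The best
    replica is returned.

    ``warm_members`` optionally seeds replica 0's initial set (padded
    with random non-members), which makes best-N curves provably
    non-decreasing.  With a fixed seed the search is bit-reproducible;
    replica r uses ``seed + r``.
    """
    pool_maps = list(pool_maps)
    pool_size = len(pool_maps)
    n = cfg.n_structures
    if n > pool_size:
        raise ValueError(f"n_structures={n} exceeds pool size {pool_size}")
    pooled = _PooledTarget(pool_maps, target)
    step = cfg.weight_grid_step

    rngs = [np.random.default_rng(cfg.seed + r) for r in range(cfg.n_replicas)]
    members: List[np.ndarray] = []
    weights: List[np.ndarray] = []
    best_rho = np.empty(cfg.n_replicas)
    traces: List[List[float]] = [[] for _ in range(cfg.n_replicas)]
    for r in range(cfg.n_replicas):
        start_w = None
        if r == 0 and warm_members is not None:
            warm = np.asarray([int(i) for i in warm_members], dtype=int)
            if warm.size > n or np.unique(warm).size != warm.size:
                raise ValueError("warm_members must be distinct and fit n_structures")
            remaining = np.setdiff1d(np.arange(pool_size), warm)
            fill = rngs[r].choice(remaining, size=n - warm.size, replace=False)
            init = np.concatenate([warm, fill])
            if warm_weights is not None:
                start_w = np.concatenate(
                    [np.asarray(warm_weights, dtype=float), np.zeros(n - warm.size)]
                )
        else:
            init = rngs[r].choice(pool_size, size=n, replace=False)
        w, rho = pooled.optimize_subset(init, step, start_w=start_w)
        members.append(np.asarray(init, dtype=int))
        weights.append(w)
        best_rho[r] = rho

    burn_in = pool_size
    iterations = 0
    converged = False
    for iteration in range(1, cfg.max_iterations + 1):
        iterations = iteration
        for r in range(cfg.n_replicas):
            rng = rngs[r]
            cur = members[r]
            if pool_size > n:
                out_pos = int(rng.integers(n))
                non_members = np.setdiff1d(np.arange(pool_size), cur)
                incoming = int(rng.choice(non_members))
                proposal = cur.copy()
                proposal[out_pos] = incoming
                w, rho = pooled.optimize_subset(proposal, step, start_w=weights[r])
                if rho > best_rho[r]:  # strict improvement only
                    members[r] = proposal
                    weights[r] = w
                    best_rho[r] = rho
            traces[r].append(best_rho[r])
        if iteration >= burn_in and best_rho.max() - best_rho.min() <= cfg.convergence_tol:
            converged = True
            break
        if pool_size == n:  # nothing to swap; replicas cannot change
            converged = best_rho.max() - best_rho.min() <= cfg.convergence_tol
            break

    best_r = int(np.argmax(best_rho))
    order = np.argsort(members[best_r])
    return SelectionResult(
        member_indices=members[best_r][order],
        weights=WeightVector(weights[best_r][order]),
        rho=float(best_rho[best_r]),
        iterations=iterations,
        replica_rhos=[float(x) for x in best_rho],
        converged=converged,
        replica_traces=[np.asarray(t) for t in traces],
    )


def brute_force_select(
    pool_maps: Sequence[DensityMap],
    target: ReferenceRegion,
    n: int,
    grid_step: float = 0.01,
    enumeration_cap: int = 200_000,
) -> SelectionResult:
    """Exact maximizer by enumerating all C(pool, n) subsets.

    Test oracle for :func:`optimize_structure_set`; refuses to enumerate
    beyond ``enumeration_cap`` subsets.
    """
    pool_maps = list(pool_maps)
    pool_size = len(pool_maps)
    if n > pool_size:
        raise ValueError(f"n={n} exceeds pool size {pool_size}")
    n_subsets = comb(pool_size, n)
    if n_subsets > enumeration_cap:
        raise ValueError(
            f"C({pool_size}, {n}) = {n_subsets} exceeds the enumeration cap"
        )
    pooled = _PooledTarget(pool_maps, target)
    best = None
    for subset in itertools.combinations(range(pool_size), n):
        idx = np.array(subset, dtype=int)
        w, rho = pooled.optimize_subset(idx, grid_step)
        if best is None or rho > best[2] + 1e-15:
            best = (idx, w, rho)
    idx, w, rho = best
    return SelectionResult(
        member_indices=idx,
        weights=WeightVector(w),
        rho=float(rho),
        iterations=n_subsets,
        replica_rhos=[float(rho)],
        converged=True,
    )


@dataclass
class BestNCurve:
    """Maximum correlation as a function of structure-set size."""

    n_values: np.ndarray
    rhos: np.ndarray
    full_ensemble_rho: float
    initial_rho: Optional[float]
    results: Dict[int, SelectionResult]


def best_n_curve(
    pool_maps: Sequence[DensityMap],
    target: ReferenceRegion,
    n_values: Sequence[int],
    cfg: SelectionConfig,
    initial_maps: Optional[Sequence[DensityMap]] = None,
) -> BestNCurve:
    """Run the structure-set search for each N and report reference levels.

    Also computes the correlation of the full equally-weighted pool
    ensemble and (optionally) of the weight-optimized initial structure
    maps — the two dashed reference levels of the selection figure.
    Successive N values warm-start from the previous best set, which
    makes the curve non-decreasing.
    """
    pool_maps = list(pool_maps)
    n_values = sorted(int(v) for v in n_values)
    full_map = weighted_average_map(pool_maps, WeightVector.uniform(len(pool_maps)))
    full_rho = map_correlation(full_map, target.map, target.mask).rho
    initial_rho = None
    if initial_maps is not None:
        initial_rho = optimize_weights(
            list(initial_maps), target, cfg.weight_grid_step
        ).rho

    results: Dict[int, SelectionResult] = {}
    rhos = []
    warm: Optional[np.ndarray] = None
    warm_w: Optional[np.ndarray] = None
    for n in n_values:
        run_cfg = SelectionConfig(
            n_structures=n,
            n_replicas=cfg.n_replicas,
            convergence_tol=cfg.convergence_tol,
            max_iterations=cfg.max_iterations,
            seed=cfg.seed + 1000 * n,
            weight_grid_step=cfg.weight_grid_step,
        )
        res = optimize_structure_set(
            pool_maps, target, run_cfg, warm_members=warm, warm_weights=warm_w
        )
        results[n] = res
        rhos.append(res.rho)
        warm = res.member_indices
        warm_w = res.weights.weights
    return BestNCurve(
        n_values=np.array(n_values),
        rhos=np.array(rhos),
        full_ensemble_rho=float(full_rho),
        initial_rho=initial_rho,
        results=results,
    )
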