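"""Rigid-body superposition and trajectory frame-pool extraction.

Superposition uses the Kabsch algorithm with reflection rejection;
frame-pool extraction implements the discard-then-sample-on-a-lattice
rule that turns a set of trajectories into the structure pool fed to the
selection algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .models import StructureModel, TrajectoryEnsemble

__all__ = [
    "AtomSelection",
    "RigidTransform",
    "FramePoolSpec",
    "PoolEntry",
    "kabsch_superpose",
    "apply_transform",
    "select_pool_times",
    "build_structure_pool",
]


@dataclass
class AtomSelection:
    """A predicate over atoms, resolvable to index lists against a topology.

    Any combination of criteria may be given; atoms must satisfy all of
    them.  ``heavy_only`` excludes hydrogens ("heavy atom" selections).
    """

    atom_names: Optional[Sequence[str]] = None
    elements: Optional[Sequence[str]] = None
    chain_ids: Optional[Sequence[str]] = None
    residue_range: Optional[tuple] = None  # inclusive (lo, hi)
    heavy_only: bool = False

    def resolve(self, topology: StructureModel) -> np.ndarray:
        """Strictly increasing atom indices matching the predicate."""
        names = set(self.atom_names) if self.atom_names is not None else None
        elems = (
            {e.upper() for e in self.elements} if self.elements is not None else None
        )
        chains = set(self.chain_ids) if self.chain_ids is not None else None
        indices = []
        for i, atom in enumerate(topology.atoms):
            if names is not None and atom.atom_name not in names:
                continue
            if elems is not None and atom.element.upper() not in elems:
                continue
            if chains is not None and atom.chain_id not in chains:
                continue
            if self.residue_range is not None:
                lo, hi = self.residue_range
                if not (lo <= atom.residue_index <= hi):
                    continue
            if self.heavy_only and atom.is_hydrogen:
                continue
            indices.append(i)
        return np.array(indices, dtype=int)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1 (no reflections)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, StructureModel):
        return obj.coordinates
    return np.asarray(obj, dtype=float)


def kabsch_superpose(
    mobile,
    reference,
    selection: Optional[Union[AtomSelection, np.ndarray, Sequence[int]]] = None,
    topology: Optional[StructureModel] = None,
):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference:
        (n, 3) coordinate arrays or StructureModels with equal atom counts.
    selection:
        Atom indices (or an :class:`AtomSelection`, resolved against
        ``topology`` or the mobile model) over which the fit and the
        returned RMSD are computed.  Defaults to all atoms.

    Returns
    -------
    (RigidTransform, float)
        The proper-rotation transform minimizing the selection RMSD, and
        the post-fit RMSD over the selection in Å.

    Raises
    ------
    ValueError
        For fewer than 3 selected atoms or a degenerate (collinear)
        selection.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if isinstance(selection, AtomSelection):
        topo = topology if topology is not None else (
            mobile if isinstance(mobile, StructureModel) else None
        )
        if topo is None:
            raise ValueError("AtomSelection requires a topology to resolve against")
        idx = selection.resolve(topo)
    elif selection is None:
        idx = np.arange(mob.shape[0])
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size < 3:
        raise ValueError("superposition requires at least 3 selected atoms")

    m = mob[idx]
    r = ref[idx]
    m_cent = m.mean(axis=0)
    r_cent = r.mean(axis=0)
    mc = m - m_cent
    rc = r - r_cent
    # collinear selections leave the rotation about the line unconstrained
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) atom selection")

    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = r_cent - rot @ m_cent
    transform = RigidTransform(rot, trans)
    fitted = transform.apply(m)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(frame: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to an (n, 3) coordinate array."""
    return transform.apply(frame)


@dataclass(frozen=True)
class FramePoolSpec:
    """Discard-and-sample rule for building the structure pool.

    Defaults: discard the first 500 ns, then sample every 250 ns up to
    and including the last recorded time.
    """

    discard_ns: float = 500.0
    interval_ns: float = 250.0

    def __post_init__(self):
        if self.discard_ns < 0:
            raise ValueError("discard_ns must be nonnegative")
        if self.interval_ns <= 0:
            raise ValueError("interval_ns must be positive")


@dataclass(frozen=True)
class PoolEntry:
    """One pooled frame: its provenance and coordinates."""

    ensemble_index: int
    origin_conformation: str
    replica_id: int
    frame_index: int
    time_ns: float
    coordinates: np.ndarray = field(repr=False, default=None)

    @property
    def tag(self) -> str:
        return f"{self.origin_conformation}/r{self.replica_id}"


def select_pool_times(
    times: np.ndarray, discard_ns: float = 500.0, interval_ns: float = 250.0
) -> np.ndarray:
    """Frame indices on the sampling lattice of one trajectory.

    Keeps frames whose time t satisfies ``t >= discard_ns`` and
    ``(t - discard_ns)`` an integer multiple of ``interval_ns``, up to and
    including the last recorded time.  When no frame sits exactly on a
    lattice point, the nearest recorded frame is taken, with a tolerance
    of half the recording timestep.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[-1] < discard_ns:
        warnings.warn(
            "trajectory shorter than the discard window; contributes no frames",
            stacklevel=2,
        )
        return np.array([], dtype=int)
    if times.size > 1:
        timestep = float(np.median(np.diff(times)))
        tol = timestep / 2 + 1e-9
    else:
        tol = np.inf
    n_lattice = int(np.floor((times[-1] - discard_ns) / interval_ns + 1e-9)) + 1
    lattice = discard_ns + np.arange(n_lattice) * interval_ns
    pos = np.searchsorted(times, lattice)
    indices = []
    for t, p in zip(lattice, pos):
        candidates = [c for c in (p - 1, p) if 0 <= c < times.size]
        best = min(candidates, key=lambda c: abs(times[c] - t))
        if abs(times[best] - t) <= tol:
            indices.append(best)
        else:
            warnings.warn(
                f"no recorded frame within tolerance of lattice time {t} ns",
                stacklevel=2,
            )
    return np.array(indices, dtype=int)


def build_structure_pool(
    ensembles: Sequence[TrajectoryEnsemble],
    spec: FramePoolSpec = FramePoolSpec(),
) -> List[PoolEntry]:
    """Extract the structure pool from a set of trajectories.

    Pool order is trajectory order, then time order.  Trajectories
    shorter than the discard window contribute nothing (with a warning);
    an empty total pool is an error.
    """
    pool: List[PoolEntry] = []
    for e_idx, ens in enumerate(ensembles):
        frame_indices = select_pool_times(
            ens.times, discard_ns=spec.discard_ns, interval_ns=spec.interval_ns
        )
        for f_idx in frame_indices:
            pool.append(
                PoolEntry(
                    ensemble_index=e_idx,
                    origin_conformation=ens.origin_conformation,
                    replica_id=ens.replica_id,
                    frame_index=int(f_idx),
                    time_ns=float(ens.times[f_idx]),
                    coordinates=ens.coordinates[f_idx],
                )
            )
    if not pool:
        raise ValueError("structure pool is empty: no trajectory covers the lattice")
    return pool
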