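"""Principal component analysis of conformational ensembles.

The covariance of mean-centered Cartesian coordinates of a selected atom
subset (typically heavy atoms) is eigendecomposed into conformational
modes; trajectories are then projected onto the dominant modes at full
recording resolution, even though the covariance itself is estimated on
subsampled frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .geometry import AtomSelection, select_pool_times
from .models import StructureModel, TrajectoryEnsemble

__all__ = [
    "ModeBasis",
    "ProjectionSet",
    "HistogramResult",
    "pca_modes",
    "project_frames",
    "extreme_states",
    "projection_histogram",
]


@dataclass
class ModeBasis:
    """Orthonormal conformational modes of a selected atom subset.

    ``eigenvectors`` has shape (3 * n_selected, n_modes), columns sorted
    by descending eigenvalue; eigenvalues are in Å².  Eigenvector signs
    are fixed so the largest-magnitude component is positive, making
    projections deterministic across runs and libraries.
    """

    atom_indices: np.ndarray
    mean_coordinates: np.ndarray  # (n_selected, 3)
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    def __post_init__(self):
        n3 = 3 * self.atom_indices.size
        if self.eigenvectors.shape[0] != n3:
            raise ValueError("eigenvector length must be 3 * n_selected_atoms")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class ProjectionSet:
    """Per-frame coordinates in mode space, with provenance tags."""

    projections: np.ndarray  # (n_points, n_modes)
    times: np.ndarray
    origin_conformations: np.ndarray
    replica_ids: np.ndarray
    ensemble_indices: np.ndarray
    frame_indices: np.ndarray

    def __len__(self) -> int:
        return self.projections.shape[0]


def _resolve_selection(selection, topology: StructureModel) -> np.ndarray:
    if selection is None:
        return np.arange(len(topology))
    if isinstance(selection, AtomSelection):
        return selection.resolve(topology)
    if isinstance(selection, str):
        if selection == "heavy":
            return topology.heavy_indices()
        raise ValueError(f"unknown named selection {selection!r}")
    return np.asarray(selection, dtype=int)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    for k in range(vectors.shape[1]):
        j = int(np.argmax(np.abs(vectors[:, k])))
        if vectors[j, k] < 0:
            vectors[:, k] = -vectors[:, k]
    return vectors


def pca_modes(
    frames: Union[Sequence[TrajectoryEnsemble], np.ndarray],
    selection=None,
    sample_interval_ns: float = 1.0,
) -> ModeBasis:
    """Conformational modes from pooled trajectory frames.

    Frames are subsampled at ``sample_interval_ns`` (nearest recorded
    frame, starting from each trajectory's first time) before the
    covariance of the selected atoms' mean-centered Cartesian coordinates
    is estimated with 1/(n-1) normalization and eigendecomposed.

    ``frames`` is either a sequence of :class:`TrajectoryEnsemble` (frames
    are assumed already rigid-body fitted to a common reference) or a raw
    (n_frames, n_atoms, 3) array, in which case every frame is used.
    """
    if isinstance(frames, np.ndarray):
        coords = np.asarray(frames, dtype=float)
        if coords.ndim != 3:
            raise ValueError("raw frame array must have shape (n_frames, n_atoms, 3)")
        idx = (
            np.arange(coords.shape[1])
            if selection is None
            else np.asarray(selection, dtype=int)
        )
        sampled = coords[:, idx, :]
    else:
        ensembles = list(frames)
        if not ensembles:
            raise ValueError("no ensembles given")
        idx = _resolve_selection(selection, ensembles[0].topology)
        blocks = []
        for ens in ensembles:
            keep = select_pool_times(
                ens.times - ens.times[0], discard_ns=0.0, interval_ns=sample_interval_ns
            )
            blocks.append(ens.coordinates[keep][:, idx, :])
        sampled = np.concatenate(blocks, axis=0)
    if idx.size == 0:
        raise ValueError("atom selection resolves to zero atoms")
    if sampled.shape[0] < 2:
        raise ValueError("PCA requires at least 2 sampled frames")

    flat = sampled.reshape(sampled.shape[0], -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (flat.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = _fix_signs(eigenvectors[:, order])
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ModeBasis(
        atom_indices=idx,
        mean_coordinates=mean.reshape(-1, 3),
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
    )


def project_frames(
    ensembles: Sequence[TrajectoryEnsemble],
    basis: ModeBasis,
    n_modes: int = 2,
) -> ProjectionSet:
    """Project every frame (full recording resolution) onto the leading modes."""
    if isinstance(ensembles, TrajectoryEnsemble):
        ensembles = [ensembles]
    ensembles = list(ensembles)
    mean_flat = basis.mean_coordinates.reshape(-1)
    vecs = basis.eigenvectors[:, :n_modes]
    proj_blocks, time_blocks, conf_blocks, rep_blocks, ens_blocks, frame_blocks = (
        [], [], [], [], [], []
    )
    for e_idx, ens in enumerate(ensembles):
        if len(ens.topology) <= int(basis.atom_indices.max()):
            raise ValueError("ensemble topology incompatible with the mode basis")
        sub = ens.coordinates[:, basis.atom_indices, :].reshape(ens.n_frames, -1)
        proj_blocks.append((sub - mean_flat) @ vecs)
        time_blocks.append(ens.times)
        conf_blocks.append(np.full(ens.n_frames, ens.origin_conformation, dtype=object))
        rep_blocks.append(np.full(ens.n_frames, ens.replica_id, dtype=int))
        ens_blocks.append(np.full(ens.n_frames, e_idx, dtype=int))
        frame_blocks.append(np.arange(ens.n_frames))
    return ProjectionSet(
        projections=np.concatenate(proj_blocks, axis=0),
        times=np.concatenate(time_blocks),
        origin_conformations=np.concatenate(conf_blocks),
        replica_ids=np.concatenate(rep_blocks),
        ensemble_indices=np.concatenate(ens_blocks),
        frame_indices=np.concatenate(frame_blocks),
    )


def extreme_states(
    projections: ProjectionSet,
    ensembles: Sequence[TrajectoryEnsemble],
    n_modes: int = 2,
) -> Dict[int, Tuple[StructureModel, StructureModel]]:
    """Frames attaining the minimal and maximal projection along each mode.

    Returns ``{mode_index: (min_structure, max_structure)}``; ties are
    broken toward the earliest frame time.
    """
    if len(projections) == 0:
        raise ValueError("empty projection set")
    if isinstance(ensembles, TrajectoryEnsemble):
        ensembles = [ensembles]
    ensembles = list(ensembles)
    n_modes = min(n_modes, projections.projections.shape[1])
    out: Dict[int, Tuple[StructureModel, StructureModel]] = {}
    for mode in range(n_modes):
        values = projections.projections[:, mode]
        lo = int(np.lexsort((projections.times, values))[0])
        hi = int(np.lexsort((projections.times, -values))[0])
        pair = []
        for point, tag in ((lo, "min"), (hi, "max")):
            ens = ensembles[projections.ensemble_indices[point]]
            model = ens.frame_model(int(projections.frame_indices[point]))
            model.label = f"mode{mode + 1}_{tag}"
            pair.append(model)
        out[mode] = tuple(pair)
    return out


@dataclass
class HistogramResult:
    """Normalized 2-D projection histogram with per-ensemble outlines."""

    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    outlines: Dict[str, np.ndarray]


def projection_histogram(
    projections: ProjectionSet,
    bins: Union[int, Sequence] = 50,
) -> HistogramResult:
    """2-D density of (mode 1, mode 2) points, normalized to sum to 1.

    For each origin conformation, the outline mask marks occupied bins on
    the boundary of that ensemble's occupied region (occupied bins minus
    their binary erosion).
    """
    if len(projections) == 0:
        raise ValueError("empty projection set")
    x = projections.projections[:, 0]
    y = projections.projections[:, 1]
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    density = counts / counts.sum()
    outlines: Dict[str, np.ndarray] = {}
    for label in np.unique(projections.origin_conformations):
        sel = projections.origin_conformations == label
        sub_counts, _, _ = np.histogram2d(x[sel], y[sel], bins=[x_edges, y_edges])
        occupied = sub_counts > 0
        eroded = ndimage.binary_erosion(occupied, border_value=0)
        outlines[str(label)] = occupied & ~eroded
    return HistogramResult(
        density=density, x_edges=x_edges, y_edges=y_edges, outlines=outlines
    )
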