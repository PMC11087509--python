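"""Synthetic toy systems with known ground truth.

A rigid scaffold (two rings of phosphorus atoms, the stand-in for the
rigid environment used by the superposition selection) holds a short
flexible chain that adopts K distinct base conformations.  Ensembles are
sampled by Gaussian positional perturbation around each base conformation
plus a small random rigid-body offset that the scaffold fit must undo;
target maps are built as known weighted mixtures of the per-conformation
ensemble densities, optionally with voxel noise.

Randomness uses :class:`numpy.random.default_rng` (PCG64) throughout, so
a fixed seed reproduces coordinates bit-for-bit across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .density import (
    DensityMap,
    ReferenceRegion,
    SpreadParams,
    ensemble_density,
    extract_reference_region,
)
from .fitting import WeightVector
from .geometry import AtomSelection, kabsch_superpose
from .models import AtomRecord, GridSpec, StructureModel, TrajectoryEnsemble

__all__ = [
    "SyntheticScenario",
    "ScenarioData",
    "make_toy_system",
    "sample_ensembles",
    "fit_frames_to_scaffold",
    "conformation_maps",
    "make_target_map",
    "realize",
    "paper_like_scenario",
    "minimal_scenario",
    "CHAIN_SELECTION",
    "SCAFFOLD_SELECTION",
]

#: Density is computed from the flexible chain only.
CHAIN_SELECTION = AtomSelection(chain_ids=["A"])
#: Rigid-body fits use the scaffold only (phosphate-fit proxy).
SCAFFOLD_SELECTION = AtomSelection(elements=["P"])


def _default_grid() -> GridSpec:
    shape = (32, 32, 32)
    spacing = np.array([1.25, 1.25, 1.25])
    origin = -(np.array(shape) - 1) / 2 * spacing
    return GridSpec(origin=origin, spacing=spacing, shape=shape)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a synthetic multi-conformation scenario."""

    n_chain_atoms: int = 20
    n_conformations: int = 3
    positional_noise_sigma: float = 0.35  # Å, per-frame chain jitter
    frames_per_replica: int = 41
    n_replicas: int = 5
    timestep_ns: float = 50.0
    true_weights: Tuple[float, ...] = (0.20, 0.25, 0.55)
    map_noise_fraction: float = 0.0
    sigma: float = 1.1  # Å spread width used to build the target
    region_radius: float = 5.0
    n_scaffold_atoms: int = 12
    scaffold_radius: float = 14.0
    scaffold_jitter_sigma: float = 0.02  # Å
    rigid_offset: bool = True  # random per-frame rigid offset the fit must undo
    grid: GridSpec = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self):
        if len(self.true_weights) != self.n_conformations:
            raise ValueError("true_weights length must equal n_conformations")
        WeightVector(np.asarray(self.true_weights))  # validates simplex
        if self.positional_noise_sigma < 0 or self.map_noise_fraction < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.frames_per_replica < 1 or self.n_replicas < 1:
            raise ValueError("need at least one frame and one replica")

    @property
    def conformation_labels(self) -> List[str]:
        roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
        return roman[: self.n_conformations]


def paper_like_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Three metastable conformations, weights (0.20, 0.25, 0.55), 15
    trajectories of 0-2000 ns whose pool-rule extraction yields 105
    structures."""
    params = dict(
        n_conformations=3,
        n_replicas=5,
        frames_per_replica=401,
        timestep_ns=5.0,
        true_weights=(0.20, 0.25, 0.55),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


def minimal_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Tiny two-conformation scenario for fast tests."""
    params = dict(
        n_conformations=2,
        n_chain_atoms=10,
        n_replicas=2,
        frames_per_replica=9,
        timestep_ns=250.0,
        true_weights=(0.3, 0.7),
        grid=GridSpec(
            origin=(-11.25, -11.25, -11.25), spacing=(1.5, 1.5, 1.5), shape=(16, 16, 16)
        ),
        scaffold_radius=9.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


def _chain_coordinates(spec: SyntheticScenario, k: int) -> np.ndarray:
    """Base conformation k: a smooth curve threaded along x, displaced and
    re-phased per conformation so states are well separated."""
    n = spec.n_chain_atoms
    extent = (np.array(spec.grid.shape) - 1) * spec.grid.spacing
    span = 0.55 * extent[0]
    t = np.linspace(-0.5, 0.5, n)
    x = span * t
    amp = 2.5 + 0.7 * k
    phase = 2 * np.pi * k / max(spec.n_conformations, 1)
    offset = (k - (spec.n_conformations - 1) / 2) * 3.5
    y = amp * np.sin(2 * np.pi * (1.0 + 0.5 * k) * t + phase) + offset
    z = amp * np.cos(2 * np.pi * (1.0 + 0.25 * k) * t + phase) - offset / 2
    return np.column_stack([x, y, z])


def make_toy_system(spec: SyntheticScenario):
    """Build the rigid scaffold and the K base chain conformations.

    Returns ``(scaffold, base_conformations, topology)`` where the
    topology orders scaffold atoms first, then chain atoms (chain 'A').
    Deterministic given the scenario.  Raises if the base conformations
    are not separated by more than twice the positional noise.
    """
    n_ring = spec.n_scaffold_atoms
    half = n_ring // 2
    angles = np.linspace(0, 2 * np.pi, half, endpoint=False)
    ring_x = 0.35 * (np.array(spec.grid.shape[0]) - 1) * spec.grid.spacing[0] / 2
    scaffold_coords = []
    for x0 in (-ring_x, ring_x):
        for a in angles:
            scaffold_coords.append(
                [x0, spec.scaffold_radius * np.cos(a), spec.scaffold_radius * np.sin(a)]
            )
    scaffold_coords = np.array(scaffold_coords)
    scaffold_atoms = [
        AtomRecord(
            atom_name="P",
            element="P",
            residue_name="SCF",
            residue_index=i + 1,
            chain_id="S",
            position=c,
        )
        for i, c in enumerate(scaffold_coords)
    ]
    scaffold = StructureModel(atoms=scaffold_atoms, label="scaffold")

    bases = []
    for k in range(spec.n_conformations):
        chain = _chain_coordinates(spec, k)
        chain_atoms = [
            AtomRecord(
                atom_name="CA",
                element="C",
                residue_name="GLY",
                residue_index=j + 1,
                chain_id="A",
                position=c,
            )
            for j, c in enumerate(chain)
        ]
        bases.append(
            StructureModel(
                atoms=scaffold_atoms + chain_atoms,
                label=spec.conformation_labels[k],
            )
        )
    # distinguishability: min pairwise chain RMSD must exceed 2 * noise sigma
    chain_slice = slice(len(scaffold), None)
    for a in range(len(bases)):
        for b in range(a + 1, len(bases)):
            diff = bases[a].coordinates[chain_slice] - bases[b].coordinates[chain_slice]
            rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
            if rmsd <= 2 * spec.positional_noise_sigma:
                raise ValueError(
                    f"base conformations {a} and {b} are indistinguishable at "
                    f"noise sigma {spec.positional_noise_sigma} (RMSD {rmsd:.3f})"
                )
    topology = StructureModel(atoms=list(bases[0].atoms), label="topology")
    return scaffold, bases, topology


def _random_small_rigid(rng: np.random.Generator, max_angle_deg=3.0, max_shift=0.5):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return rot, shift


def sample_ensembles(
    spec: SyntheticScenario,
    system=None,
) -> List[TrajectoryEnsemble]:
    """Sample K x n_replicas ensembles around the base conformations.

    Each frame adds isotropic Gaussian displacement (positional noise
    sigma) to the chain atoms, a tiny jitter to the scaffold, and a small
    random rigid-body offset to the whole frame, so the scaffold fit has
    real work to do.  Times are ``frame_index * timestep_ns``.
    """
    if system is None:
        system = make_toy_system(spec)
    scaffold, bases, topology = system
    n_scaffold = len(scaffold)
    rng = np.random.default_rng(spec.seed)
    ensembles = []
    for k, base in enumerate(bases):
        base_coords = base.coordinates
        for rep in range(spec.n_replicas):
            frames = np.empty((spec.frames_per_replica, len(topology), 3))
            for f in range(spec.frames_per_replica):
                coords = base_coords.copy()
                if spec.scaffold_jitter_sigma > 0:
                    coords[:n_scaffold] += rng.normal(
                        0.0, spec.scaffold_jitter_sigma, (n_scaffold, 3)
                    )
                if spec.positional_noise_sigma > 0:
                    coords[n_scaffold:] += rng.normal(
                        0.0,
                        spec.positional_noise_sigma,
                        (len(topology) - n_scaffold, 3),
                    )
                if spec.rigid_offset:
                    rot, shift = _random_small_rigid(rng)
                    coords = coords @ rot.T + shift
                frames[f] = coords
            ensembles.append(
                TrajectoryEnsemble(
                    topology=topology,
                    times=np.arange(spec.frames_per_replica) * spec.timestep_ns,
                    coordinates=frames,
                    origin_conformation=spec.conformation_labels[k],
                    replica_id=rep,
                )
            )
    return ensembles


def fit_frames_to_scaffold(
    ensemble: TrajectoryEnsemble, reference: StructureModel
) -> TrajectoryEnsemble:
    """Rigid-body fit every frame onto the reference scaffold atoms."""
    sel = SCAFFOLD_SELECTION.resolve(ensemble.topology)
    fitted = np.empty_like(ensemble.coordinates)
    ref_coords = reference.coordinates
    for f in range(ensemble.n_frames):
        transform, _ = kabsch_superpose(
            ensemble.coordinates[f], ref_coords, selection=sel
        )
        fitted[f] = transform.apply(ensemble.coordinates[f])
    return TrajectoryEnsemble(
        topology=ensemble.topology,
        times=ensemble.times,
        coordinates=fitted,
        origin_conformation=ensemble.origin_conformation,
        replica_id=ensemble.replica_id,
    )


def conformation_maps(
    spec: SyntheticScenario,
    ensembles: Sequence[TrajectoryEnsemble],
    topology: StructureModel,
) -> List[DensityMap]:
    """Per-conformation ensemble densities of the chain atoms.

    Frames from all replicas started from the same conformation are
    rigid-body fitted on the scaffold and averaged into one map each.
    """
    chain_idx = CHAIN_SELECTION.resolve(topology)
    params = SpreadParams(sigma=spec.sigma)
    maps = []
    for label in spec.conformation_labels:
        frames = []
        for ens in ensembles:
            if ens.origin_conformation != label:
                continue
            fitted = fit_frames_to_scaffold(ens, topology)
            frames.extend(fitted.coordinates[:, chain_idx, :])
        if not frames:
            raise ValueError(f"no ensembles tagged with conformation {label}")
        maps.append(ensemble_density(frames, spec.grid, params))
    return maps


def make_target_map(
    spec: SyntheticScenario,
    ensembles: Optional[Sequence[TrajectoryEnsemble]] = None,
    maps: Optional[Sequence[DensityMap]] = None,
    system=None,
    noise_rng: Optional[np.random.Generator] = None,
) -> Tuple[ReferenceRegion, Dict]:
    """Known weighted mixture of the conformation maps, plus ground truth.

    Voxel noise (i.i.d. Gaussian, SD = ``map_noise_fraction`` times the
    masked target SD) is drawn from ``noise_rng`` or from a stream derived
    from the scenario seed.  The returned truth record is JSON-serializable.
    """
    if system is None:
        system = make_toy_system(spec)
    scaffold, bases, topology = system
    if maps is None:
        if ensembles is None:
            ensembles = sample_ensembles(spec, system)
        maps = conformation_maps(spec, ensembles, topology)
    weights = np.asarray(spec.true_weights, dtype=float)
    target_values = np.zeros(spec.grid.shape)
    for w, m in zip(weights, maps):
        target_values += w * m.values

    chain_idx = CHAIN_SELECTION.resolve(topology)
    chain_models = [
        StructureModel(atoms=[b.atoms[i] for i in chain_idx], label=b.label)
        for b in bases
    ]
    clean = DensityMap(grid=spec.grid, values=target_values)
    region = extract_reference_region(clean, chain_models, spec.region_radius)

    if spec.map_noise_fraction > 0:
        if noise_rng is None:
            noise_rng = np.random.default_rng(spec.seed + 10_000)
        sd = float(target_values[region.mask].std())
        target_values = target_values + noise_rng.normal(
            0.0, spec.map_noise_fraction * sd, spec.grid.shape
        )
        noisy = DensityMap(grid=spec.grid, values=target_values, mask=region.mask)
        region = ReferenceRegion(map=noisy, radius=spec.region_radius)

    truth = {
        "true_weights": [float(w) for w in weights],
        "sigma": spec.sigma,
        "map_noise_fraction": spec.map_noise_fraction,
        "region_radius": spec.region_radius,
        "n_conformations": spec.n_conformations,
        "conformation_labels": spec.conformation_labels,
        "seed": spec.seed,
    }
    json.dumps(truth)  # guarantee serializability
    return region, truth


@dataclass
class ScenarioData:
    """A fully realized synthetic scenario."""

    spec: SyntheticScenario
    scaffold: StructureModel
    base_conformations: List[StructureModel]
    topology: StructureModel
    ensembles: List[TrajectoryEnsemble]
    conformation_maps: List[DensityMap]
    target: ReferenceRegion
    truth: Dict


def realize(spec: SyntheticScenario) -> ScenarioData:
    """Generate system, ensembles, per-conformation maps and target."""
    system = make_toy_system(spec)
    scaffold, bases, topology = system
    ensembles = sample_ensembles(spec, system)
    maps = conformation_maps(spec, ensembles, topology)
    target, truth = make_target_map(spec, maps=maps, system=system)
    return ScenarioData(
        spec=spec,
        scaffold=scaffold,
        base_conformations=bases,
        topology=topology,
        ensembles=ensembles,
        conformation_maps=maps,
        target=target,
        truth=truth,
    )
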