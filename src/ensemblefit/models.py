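"""Core domain types shared across the pipeline.

Conventions used throughout the package:

* All lengths are in Angstrom (Å).  Any nm-valued user input is converted
  exactly once, at configuration parsing time.
* A :class:`GridSpec` addresses voxel *centers*: the center of voxel
  ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
* Density arrays are indexed ``values[i, j, k]`` with axis 0 = x,
  axis 1 = y, axis 2 = z, regardless of on-disk axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "GridSpec",
    "DensityMap",
    "TrajectoryEnsemble",
    "infer_element",
    "atomic_number",
]

#: Elements whose symbol has two letters and which plausibly occur in
#: biomolecular models; used when falling back to atom-name heuristics.
_TWO_LETTER_ELEMENTS = {
    "MG", "MN", "FE", "ZN", "NA", "CL", "CA", "BR", "SE", "CU", "NI", "CO",
    "CD", "HG", "PB", "PT", "AU", "AG", "SI", "AL", "LI", "BE", "RB", "CS",
    "SR", "BA",
}

_ATOMIC_NUMBERS = {
    "H": 1, "HE": 2, "LI": 3, "BE": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "NE": 10, "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15,
    "S": 16, "CL": 17, "AR": 18, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "RB": 37,
    "SR": 38, "AG": 47, "CD": 48, "I": 53, "CS": 55, "BA": 56, "PT": 78,
    "AU": 79, "HG": 80, "PB": 82,
}


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Infer a chemical element symbol for a PDB-style atom.

    The explicit element column wins; otherwise the leading alphabetic
    characters of the atom name are matched against a curated two-letter
    element list, falling back to the first letter.
    """
    elem = element_field.strip().upper()
    if elem and elem in _ATOMIC_NUMBERS:
        return elem.capitalize()
    name = atom_name.strip()
    letters = "".join(c for c in name if c.isalpha()).upper()
    if not letters:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if letters[:2] in _TWO_LETTER_ELEMENTS:
        return letters[:2].capitalize()
    return letters[0]


def atomic_number(element: str) -> int:
    """Atomic number of ``element`` (case-insensitive symbol)."""
    try:
        return _ATOMIC_NUMBERS[element.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown element symbol {element!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus a position in Å."""

    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        object.__setattr__(self, "position", pos)
        if self.element.strip().upper() not in _ATOMIC_NUMBERS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() == "H"


@dataclass
class StructureModel:
    """An ordered set of atoms forming one conformer.

    Atom order is stable and index-addressable; two models are
    topology-compatible when their ``(atom_name, residue_index)``
    sequences match.
    """

    atoms: list = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        """Indices of non-hydrogen atoms."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int
        )

    def with_coordinates(self, coords: np.ndarray, label: Optional[str] = None) -> "StructureModel":
        """New model with the same topology but replaced positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {coords.shape} incompatible with "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms=atoms, label=self.label if label is None else label)

    def is_topology_compatible(self, other: "StructureModel") -> bool:
        if len(self) != len(other):
            return False
        return all(
            a.atom_name == b.atom_name and a.residue_index == b.residue_index
            for a, b in zip(self.atoms, other.atoms)
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D grid: origin is the center of voxel (0, 0, 0)."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        shape = tuple(int(s) for s in self.shape)
        if origin.shape != (3,) or spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(spacing <= 0):
            raise ValueError("spacing components must be > 0")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be three positive integers")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def is_close(self, other: "GridSpec", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )


@dataclass
class DensityMap:
    """A scalar field on a :class:`GridSpec`, with an optional voxel mask."""

    grid: GridSpec
    values: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("density values must be finite")
        self.values = values
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != self.grid.shape:
                raise ValueError("mask shape must equal grid shape")
            self.mask = mask

    def copy(self) -> "DensityMap":
        return DensityMap(
            grid=self.grid,
            values=self.values.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass
class TrajectoryEnsemble:
    """Time-stamped coordinate frames sharing one topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is in
    ns and strictly increasing.  Each ensemble is tagged by the
    conformation it was started from and a replica index.
    """

    topology: StructureModel
    times: np.ndarray
    coordinates: np.ndarray
    origin_conformation: str = ""
    replica_id: int = 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        coords = np.asarray(self.coordinates, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(times < 0):
            raise ValueError("frame times must be nonnegative")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if coords.ndim != 3 or coords.shape[0] != times.size:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate count per frame ({coords.shape[1]}) does not match "
                f"topology atom count ({len(self.topology)})"
            )
        self.times = times
        self.coordinates = coords

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def tag(self) -> str:
        return f"{self.origin_conformation}/r{self.replica_id}"

    def frame_model(self, index: int) -> StructureModel:
        """The frame at ``index`` as a StructureModel."""
        return self.topology.with_coordinates(
            self.coordinates[index], label=f"{self.tag}@{self.times[index]:g}ns"
        )
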