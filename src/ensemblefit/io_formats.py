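"""Reading and writing of the structure and map formats the pipeline touches.

PDB files are parsed and serialized through :mod:`biotite`; MRC/CCP4 maps
through :mod:`mrcfile`.  Whatever the on-disk axis order of a map
(MAPC/MAPR/MAPS permutation), :func:`read_map` canonicalizes the array to
``values[i, j, k]`` with axis 0 = x, 1 = y, 2 = z, matching
:class:`~ensemblefit.models.GridSpec`.
"""

from __future__ import annotations

import os
import re
from typing import List, Optional, Sequence, Union

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

import mrcfile

from .models import (
    AtomRecord,
    DensityMap,
    GridSpec,
    StructureModel,
    TrajectoryEnsemble,
    infer_element,
)

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_map",
    "write_map",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_trajectory",
]

# Fixed-column PDB coordinate field is %8.3f
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def _atom_array_to_model(arr: "struc.AtomArray", label: str = "") -> StructureModel:
    atoms = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        elem_field = str(arr.element[i]) if "element" in arr.get_annotation_categories() else ""
        element = infer_element(name, elem_field)
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=np.asarray(arr.coord[i], dtype=float),
            )
        )
    return StructureModel(atoms=atoms, label=label)


def read_pdb(
    path: Union[str, os.PathLike], model: Optional[int] = None
) -> Union[StructureModel, List[StructureModel]]:
    """Read a PDB file.

    Parameters
    ----------
    path:
        Path to a fixed-column PDB file.
    model:
        1-based model number to read.  ``None`` (default) returns a single
        :class:`StructureModel` for single-model files and a list of
        topology-compatible models for multi-model files.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file contains no ATOM/HETATM records, or MODEL blocks have
        inconsistent atom counts.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such PDB file: {path}")
    pdb_file = PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no coordinate records found")
    if model is not None:
        arr = pdb_file.get_structure(model=model)
        return _atom_array_to_model(arr, label=f"model{model}")
    if n_models == 1:
        arr = pdb_file.get_structure(model=1)
        if arr.array_length() == 0:
            raise ValueError(f"{path}: zero atom records")
        return _atom_array_to_model(arr)
    # biotite raises on inconsistent atom counts across MODEL blocks
    stack = pdb_file.get_structure(model=None)
    return [
        _atom_array_to_model(stack[m], label=f"model{m + 1}")
        for m in range(stack.stack_depth())
    ]


def _model_to_atom_array(model: StructureModel) -> "struc.AtomArray":
    n = len(model)
    if n == 0:
        raise ValueError("cannot write an empty StructureModel")
    arr = struc.AtomArray(n)
    arr.coord = model.coordinates
    arr.chain_id = np.array([a.chain_id or "A" for a in model.atoms])
    arr.res_id = np.array([a.residue_index for a in model.atoms])
    arr.res_name = np.array([a.residue_name for a in model.atoms])
    arr.atom_name = np.array([a.atom_name for a in model.atoms])
    arr.element = np.array([a.element.upper() for a in model.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(
    models: Union[StructureModel, Sequence[StructureModel]],
    path: Union[str, os.PathLike],
) -> None:
    """Write one model or a topology-compatible sequence of models.

    Multi-model output uses MODEL/ENDMDL blocks.  Coordinates that do not
    fit the fixed 8.3 column raise instead of being silently truncated.
    """
    if isinstance(models, StructureModel):
        model_list = [models]
    else:
        model_list = list(models)
    if not model_list:
        raise ValueError("no models to write")
    for m in model_list:
        coords = m.coordinates
        if coords.size and (
            coords.max() > _PDB_COORD_MAX or coords.min() < _PDB_COORD_MIN
        ):
            raise ValueError(
                "coordinates exceed the fixed-column PDB field width "
                f"({_PDB_COORD_MIN} .. {_PDB_COORD_MAX} Å)"
            )
    arrays = [_model_to_atom_array(m) for m in model_list]
    pdb_file = PDBFile()
    if len(arrays) == 1:
        pdb_file.set_structure(arrays[0])
    else:
        pdb_file.set_structure(struc.stack(arrays))
    pdb_file.write(str(path))


def read_map(path: Union[str, os.PathLike]) -> DensityMap:
    """Read an MRC/CCP4 map into the canonical x/y/z axis convention.

    The on-disk MAPC/MAPR/MAPS permutation is undone, so two files holding
    the same volume with different axis orders yield identical arrays.
    The grid origin is taken from the ORIGIN header words when nonzero,
    else from the NXSTART/NYSTART/NZSTART fields.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such map file: {path}")
    try:
        with mrcfile.open(str(path), mode="r") as mrc:
            if mrc.data is None or mrc.data.ndim != 3:
                raise ValueError(f"{path}: not a 3-D volume")
            header = mrc.header
            data = np.asarray(mrc.data, dtype=float)
            # file array dims, slow -> fast, carry crystal axes (maps, mapr, mapc)
            axis_of_dim = (int(header.maps), int(header.mapr), int(header.mapc))
            if sorted(axis_of_dim) != [1, 2, 3]:
                raise ValueError(f"{path}: invalid MAPC/MAPR/MAPS permutation")
            # result dim d (crystal axis d+1) comes from the file dim holding it
            perm = tuple(axis_of_dim.index(d + 1) for d in range(3))
            values = np.transpose(data, axes=perm)
            voxel = mrc.voxel_size
            spacing = np.array([voxel.x, voxel.y, voxel.z], dtype=float)
            starts = np.zeros(3)
            starts[int(header.mapc) - 1] = float(header.nxstart)
            starts[int(header.mapr) - 1] = float(header.nystart)
            starts[int(header.maps) - 1] = float(header.nzstart)
            origin = np.array(
                [header.origin.x, header.origin.y, header.origin.z], dtype=float
            )
            if np.allclose(origin, 0.0):
                origin = starts * spacing
    except ValueError:
        raise
    except Exception as exc:  # corrupt/truncated headers surface here
        raise ValueError(f"{path}: cannot parse MRC/CCP4 file ({exc})") from exc
    grid = GridSpec(origin=origin, spacing=spacing, shape=values.shape)
    return DensityMap(grid=grid, values=values)


def write_map(density: DensityMap, path: Union[str, os.PathLike]) -> None:
    """Write a map as MRC/CCP4 2014 (mode 2, ISPG=1).

    Cell dimensions are spacing x shape; the origin is recorded both in
    the ORIGIN words and in the nstart fields (rounded to voxel units).
    """
    grid = density.grid
    data = np.ascontiguousarray(density.values.T, dtype=np.float32)  # (z, y, x)
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(data)
        mrc.voxel_size = tuple(grid.spacing)
        mrc.header.origin = tuple(grid.origin)
        nstart = np.round(grid.origin / grid.spacing).astype(int)
        mrc.header.nxstart = int(nstart[0])
        mrc.header.nystart = int(nstart[1])
        mrc.header.nzstart = int(nstart[2])
        mrc.header.ispg = 1
        mrc.update_header_stats()


_XYZ_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def read_xyz_frames(path: Union[str, os.PathLike]):
    """Read a whitespace multi-frame XYZ file.

    Returns ``(elements, coordinates, times)`` where ``coordinates`` has
    shape (n_frames, n_atoms, 3) and ``times`` is an array of ns values
    parsed from ``t = <value>`` comment lines, or ``None`` if any frame
    lacks one.
    """
    elements: List[str] = []
    frames = []
    times = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines):
        line = lines[pos].strip()
        if not line:
            pos += 1
            continue
        n_atoms = int(line)
        comment = lines[pos + 1]
        match = _XYZ_TIME_RE.search(comment)
        times.append(float(match.group(1)) if match else None)
        frame_elems = []
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            frame_elems.append(parts[0])
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not elements:
            elements = frame_elems
        elif frame_elems != elements:
            raise ValueError(f"{path}: inconsistent atom elements across frames")
        frames.append(coords)
        pos += 2 + n_atoms
    if not frames:
        raise ValueError(f"{path}: no XYZ frames found")
    coords = np.stack(frames)
    time_arr = None
    if all(t is not None for t in times):
        time_arr = np.array(times, dtype=float)
    return elements, coords, time_arr


def write_xyz_frames(
    elements: Sequence[str],
    coordinates: np.ndarray,
    path: Union[str, os.PathLike],
    times: Optional[Sequence[float]] = None,
) -> None:
    """Write frames as plain multi-frame XYZ with ``t = <ns>`` comments."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 2:
        coordinates = coordinates[None]
    with open(path, "w") as fh:
        for f in range(coordinates.shape[0]):
            fh.write(f"{len(elements)}\n")
            if times is not None:
                fh.write(f"t = {times[f]:.9g} ns\n")
            else:
                fh.write(f"frame {f}\n")
            for el, (x, y, z) in zip(elements, coordinates[f]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(
    paths: Union[str, os.PathLike, Sequence[Union[str, os.PathLike]]],
    topology: StructureModel,
    timestep_ns: float = 0.005,
    origin_conformation: str = "",
    replica_id: int = 0,
) -> TrajectoryEnsemble:
    """Read trajectory frames from multi-model PDB or multi-frame XYZ files.

    Frame times are taken from file metadata when present (XYZ ``t =``
    comments); otherwise they are assigned as ``frame_index * timestep_ns``.
    The default timestep is 5 ps.

    Raises
    ------
    ValueError
        If any frame's atom count differs from the topology.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    all_coords = []
    all_times: Optional[list] = []
    for p in paths:
        suffix = os.path.splitext(str(p))[1].lower()
        if suffix == ".xyz":
            elements, coords, times = read_xyz_frames(p)
            if len(elements) != len(topology):
                raise ValueError(
                    f"{p}: frame atom count {len(elements)} does not match "
                    f"topology ({len(topology)} atoms)"
                )
            all_coords.append(coords)
            if times is None:
                all_times = None
            elif all_times is not None:
                all_times.extend(times.tolist())
        else:
            models = read_pdb(p)
            if isinstance(models, StructureModel):
                models = [models]
            for m in models:
                if len(m) != len(topology):
                    raise ValueError(
                        f"{p}: frame atom count {len(m)} does not match "
                        f"topology ({len(topology)} atoms)"
                    )
                all_coords.append(m.coordinates[None])
            all_times = None
    coords = np.concatenate(all_coords, axis=0)
    if all_times is not None and len(all_times) == coords.shape[0]:
        times = np.asarray(all_times, dtype=float)
    else:
        times = np.arange(coords.shape[0]) * float(timestep_ns)
    return TrajectoryEnsemble(
        topology=topology,
        times=times,
        coordinates=coords,
        origin_conformation=origin_conformation,
        replica_id=replica_id,
    )
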