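"""Trajectory and feature-matrix containers with plain-text and binary I/O.

Coordinates are stored in Angstrom, times in nanoseconds.  The multi-model
PDB dialect (MODEL/ENDMDL records, fixed columns) is the only structural
text format supported; arbitrary feature time series travel as CSV with a
descriptor header or as a compressed ``.npz`` array container with the
descriptors embedded as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Trajectory",
    "FeatureMatrix",
    "read_trajectory",
    "write_trajectory",
    "read_features",
    "write_features",
]


@dataclass(frozen=True)
class AtomRecord:
    """Minimal per-atom metadata: residue index, residue name, atom name."""

    residue_index: int
    residue_name: str
    atom_name: str

    @property
    def is_heavy(self) -> bool:
        # hydrogen by atom-name convention: names starting with H
        return not self.atom_name.strip().upper().startswith("H")


@dataclass
class Trajectory:
    """Per-frame 3-D coordinates with atom metadata.

    Parameters
    ----------
    coordinates
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atom_meta
        One :class:`AtomRecord` per atom.
    frame_interval
        Time between consecutive frames in nanoseconds.
    """

    coordinates: np.ndarray
    atom_meta: Sequence[AtomRecord]
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (frames, atoms, 3); "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.atom_meta) != self.coordinates.shape[1]:
            raise ValueError(
                f"atom_meta length {len(self.atom_meta)} does not match "
                f"atom count {self.coordinates.shape[1]}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, predicate) -> np.ndarray:
        """Indices of atoms for which ``predicate(AtomRecord)`` is true."""
        idx = np.array(
            [i for i, a in enumerate(self.atom_meta) if predicate(a)], dtype=int
        )
        return idx


@dataclass
class FeatureMatrix:
    """Frames x features time series with per-feature provenance.

    ``descriptors`` records where each column came from (an atom pair, a
    dihedral quadruplet, a circular-embedding tag, ...), one string per
    column.
    """

    values: np.ndarray
    descriptors: Sequence[str]
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")
        if len(self.descriptors) != self.values.shape[1]:
            raise ValueError(
                f"descriptor count {len(self.descriptors)} does not match "
                f"column count {self.values.shape[1]}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.descriptors = list(self.descriptors)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via biotite)
# ---------------------------------------------------------------------------


def _to_atom_array_stack(traj: Trajectory):
    import biotite.structure as struc

    n_atoms = traj.n_atoms
    template = struc.AtomArray(n_atoms)
    template.res_id = np.array([a.residue_index for a in traj.atom_meta], dtype=int)
    template.res_name = np.array([a.residue_name for a in traj.atom_meta])
    template.atom_name = np.array([a.atom_name for a in traj.atom_meta])
    template.chain_id = np.full(n_atoms, "A")
    template.element = np.array(
        [a.atom_name.strip()[:1].upper() or "C" for a in traj.atom_meta]
    )
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coordinates.astype(np.float32)
    return stack


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or as a binary array container."""
    path = Path(path)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(_to_atom_array_stack(traj))
        pdb.write(str(path))
    elif format == "npz":
        meta = [
            (a.residue_index, a.residue_name, a.atom_name) for a in traj.atom_meta
        ]
        np.savez_compressed(
            path,
            coordinates=traj.coordinates,
            atom_meta=json.dumps(meta),
            frame_interval=traj.frame_interval,
        )
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(
    path: str | Path, format: str = "pdb", frame_interval: float = 0.1
) -> Trajectory:
    """Read a multi-model PDB or binary array container written by this package.

    Raises
    ------
    ValueError
        If the file is empty, malformed, or its models disagree in atom count
        (biotite reports the offending record).
    """
    path = Path(path)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        try:
            pdb = PDBFile.read(str(path))
            stack = pdb.get_structure(model=None)
        except Exception as exc:  # normalize parser failures
            raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
        if stack.array_length() == 0:
            raise ValueError(f"PDB file {path} contains no atoms")
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:  # single model
            coords = coords[None]
        meta = [
            AtomRecord(int(r), str(n), str(a))
            for r, n, a in zip(stack.res_id, stack.res_name, stack.atom_name)
        ]
        return Trajectory(coords, meta, frame_interval=frame_interval)
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            meta = [
                AtomRecord(int(r), str(n), str(a))
                for r, n, a in json.loads(str(data["atom_meta"]))
            ]
            return Trajectory(
                data["coordinates"],
                meta,
                frame_interval=float(data["frame_interval"]),
            )
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# FeatureMatrix I/O
# ---------------------------------------------------------------------------


def write_features(fm: FeatureMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a feature matrix as CSV (descriptor header) or ``.npz``."""
    path = Path(path)
    if format == "csv":
        header = ",".join(fm.descriptors)
        np.savetxt(
            path,
            fm.values,
            delimiter=",",
            header=header + f"\n# frame_interval_ns={fm.frame_interval!r}",
            comments="",
            fmt="%.10g",
        )
    elif format == "npz":
        np.savez_compressed(
            path,
            values=fm.values,
            descriptors=json.dumps(fm.descriptors),
            frame_interval=fm.frame_interval,
        )
    else:
        raise ValueError(f"unknown feature format {format!r}")


def read_features(path: str | Path, format: str = "csv") -> FeatureMatrix:
    path = Path(path)
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().strip()
            interval_line = fh.readline().strip()
            if not header:
                raise ValueError(f"empty feature file {path}")
            descriptors = header.split(",")
            frame_interval = 0.1
            if interval_line.startswith("# frame_interval_ns="):
                frame_interval = float(interval_line.split("=", 1)[1])
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        return FeatureMatrix(values, descriptors, frame_interval=frame_interval)
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            return FeatureMatrix(
                data["values"],
                json.loads(str(data["descriptors"])),
                frame_interval=float(data["frame_interval"]),
            )
    raise ValueError(f"unknown feature format {format!r}")
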