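"""Structure and trajectory I/O.

Reads and writes fixed-column PDB files (single- and multi-model) through
biotite and exposes lightweight in-memory containers: :class:`Topology`
(atom metadata without coordinates) and :class:`Trajectory` (topology plus
an ordered stack of coordinate frames).

Residue identifiers are *opaque strings* assembled from the author residue
number plus any insertion code ("100", "100F", ...). They are ordered by
file appearance and never parsed as integers, because antibody structures
frequently use Kabat-style numbering with insertion codes.

The trajectory exchange format is multi-model PDB: universal, text-based
and dependency-free. Binary formats (DCD/XTC/NetCDF) are intentionally not
supported; convert externally if needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    DimensionError,
    EmptyStructureError,
    PDBParseError,
    TrajectoryConsistencyError,
)

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "read_pdb",
    "read_multimodel_pdb",
    "write_pdb",
    "write_multimodel_pdb",
    "write_series_table",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's metadata (coordinates live in separate arrays)."""

    serial: int
    name: str
    element: str
    residue_number: str  # author numbering + insertion code, opaque
    residue_name: str
    chain_id: str


class Topology:
    """Ordered atom metadata of a structure, without coordinates.

    Internally stores parallel numpy arrays; ``res_id``/``ins_code`` are
    kept separately so that PDB writing round-trips exactly, while the
    public residue identifier is the concatenated opaque string.
    """

    def __init__(
        self,
        serial: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
        res_id: np.ndarray,
        ins_code: np.ndarray,
        res_name: np.ndarray,
        chain_id: np.ndarray,
    ):
        n = len(serial)
        for arr in (atom_name, element, res_id, ins_code, res_name, chain_id):
            if len(arr) != n:
                raise DimensionError("topology annotation arrays differ in length")
        self.serial = np.asarray(serial, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.res_id = np.asarray(res_id, dtype=int)
        self.ins_code = np.asarray(ins_code, dtype="U1")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self._build_residue_index()

    def _build_residue_index(self) -> None:
        resnum = self.residue_number
        residues: list[tuple[str, str, str]] = []
        residue_index = np.empty(self.n_atoms, dtype=int)
        seen: dict[tuple[str, str], int] = {}
        for i in range(self.n_atoms):
            key = (str(self.chain_id[i]), str(resnum[i]))
            if key not in seen:
                seen[key] = len(residues)
                residues.append((key[0], key[1], str(self.res_name[i])))
            residue_index[i] = seen[key]
        self.residues: list[tuple[str, str, str]] = residues
        self.residue_index = residue_index
        chains: list[str] = []
        for c in self.chain_id:
            if c not in chains:
                chains.append(str(c))
        self.chains: list[str] = chains

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def residue_number(self) -> np.ndarray:
        """Opaque per-atom residue identifier strings."""
        return np.array(
            [f"{r}{i}" for r, i in zip(self.res_id, self.ins_code)], dtype="U6"
        )

    def atom_records(self) -> list[AtomRecord]:
        resnum = self.residue_number
        return [
            AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.atom_name[i]),
                element=str(self.element[i]),
                residue_number=str(resnum[i]),
                residue_name=str(self.res_name[i]),
                chain_id=str(self.chain_id[i]),
            )
            for i in range(self.n_atoms)
        ]

    def chain_residues(self, chain_id: str) -> list[str]:
        """Residue identifiers of one chain, in file order."""
        return [r[1] for r in self.residues if r[0] == chain_id]

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_name, other.atom_name)
            and np.array_equal(self.element, other.element)
            and np.array_equal(self.res_id, other.res_id)
            and np.array_equal(self.ins_code, other.ins_code)
            and np.array_equal(self.res_name, other.res_name)
            and np.array_equal(self.chain_id, other.chain_id)
        )


@dataclass
class Trajectory:
    """Topology plus ordered coordinate frames (Å) with times (ns)."""

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise DimensionError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryConsistencyError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != self.n_frames:
            raise DimensionError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryConsistencyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# PDB reading


def _locate_malformed_line(path: Path) -> str:
    """Best-effort scan for the first unparseable ATOM/HETATM line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[6:11])
                except (ValueError, IndexError):
                    return f" (first malformed record at line {lineno})"
    return ""


def _topology_from_atom_array(arr) -> Topology:
    return Topology(
        serial=arr.atom_id if "atom_id" in arr.get_annotation_categories() else np.arange(1, arr.array_length() + 1),
        atom_name=arr.atom_name,
        element=arr.element,
        res_id=arr.res_id,
        ins_code=arr.ins_code,
        res_name=arr.res_name,
        chain_id=arr.chain_id,
    )


def read_pdb(path) -> tuple[Topology, np.ndarray]:
    """Read the first model of a PDB file.

    Returns ``(topology, coordinates)`` with coordinates in Å. Alternate
    locations keep altloc 'A'/blank only; author residue numbering is
    preserved verbatim (insertion codes included).
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(
            f"cannot parse PDB file {path}: {exc}{_locate_malformed_line(path)}"
        ) from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    return _topology_from_atom_array(arr), np.asarray(arr.coord, dtype=float)


def read_multimodel_pdb(path, frame_time_step: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Parameters
    ----------
    path:
        Multi-model PDB whose MODEL/ENDMDL blocks share identical atom lists.
    frame_time_step:
        Time between consecutive models in ns; times are ``0, dt, 2 dt, ...``.
        The saving interval of a simulation is not stored in PDB files, so it
        must be supplied by the caller.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:
        msg = str(exc)
        if "atom" in msg.lower() or "model" in msg.lower():
            raise TrajectoryConsistencyError(
                f"inconsistent models in {path}: {exc}"
            ) from exc
        raise PDBParseError(
            f"cannot parse PDB file {path}: {exc}{_locate_malformed_line(path)}"
        ) from exc
    if stack.array_length() == 0:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    topo = _topology_from_atom_array(stack[0])
    frames = np.asarray(stack.coord, dtype=float)
    times = np.arange(frames.shape[0]) * float(frame_time_step)
    return Trajectory(topology=topo, frames=frames, times=times)


# ---------------------------------------------------------------------------
# PDB writing


def _atom_array_from_topology(topology: Topology, coords: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise DimensionError(
            f"coordinates shape {coords.shape} does not match topology "
            f"({topology.n_atoms} atoms)"
        )
    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = coords
    arr.chain_id = topology.chain_id.copy()
    arr.res_id = topology.res_id.copy()
    arr.ins_code = topology.ins_code.copy()
    arr.res_name = topology.res_name.copy()
    arr.atom_name = topology.atom_name.copy()
    arr.element = topology.element.copy()
    arr.hetero = np.zeros(topology.n_atoms, dtype=bool)
    return arr


def write_pdb(topology: Topology, coords: np.ndarray, path) -> None:
    """Write a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_topology(topology, coords))
    pdb.write(str(path))


def write_multimodel_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    topo = trajectory.topology
    stack = struc.AtomArrayStack(trajectory.n_frames, topo.n_atoms)
    stack.coord = trajectory.frames
    stack.chain_id = topo.chain_id.copy()
    stack.res_id = topo.res_id.copy()
    stack.ins_code = topo.ins_code.copy()
    stack.res_name = topo.res_name.copy()
    stack.atom_name = topo.atom_name.copy()
    stack.element = topo.element.copy()
    stack.hetero = np.zeros(topo.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tabular output


def write_series_table(
    rows,
    path,
    columns: Sequence[str] | None = None,
    decimals: int | None = None,
) -> None:
    """Write time-indexed records or summary rows as CSV with header.

    ``rows`` may be a DataFrame or an iterable of dicts sharing a schema.
    ``decimals=2`` gives the fixed two-decimal formatting used for Å / deg /
    kcal·mol⁻¹ summary tables; ``decimals=None`` writes full precision
    (used for per-frame series so that summaries remain exactly
    recomputable from the retained files).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows and columns is None:
            raise ValueError("empty series needs an explicit column list")
        df = pd.DataFrame(rows, columns=columns if rows == [] else None)
        if columns is not None and list(df.columns) != list(columns):
            df = df.reindex(columns=columns)
    fmt = f"%.{decimals}f" if decimals is not None else None
    df.to_csv(path, index=False, float_format=fmt)
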