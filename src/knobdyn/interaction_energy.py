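"""Group-group van der Waals interaction energies and contact analysis.

The headline readout of the pipeline's energetic stage is the 12-6
Lennard-Jones interaction energy between two atom groups (e.g., the knob
and the light chain):

    E = Σ_{i∈A, j∈B, r_ij ≤ cutoff}  ε_ij [ (r_min,ij / r_ij)^12 − 2 (r_min,ij / r_ij)^6 ]

with AMBER-convention parameters per atom type (r_min/2 in Å, ε in
kcal/mol) and combining rules r_min,ij = r_min/2_i + r_min/2_j,
ε_ij = sqrt(ε_i ε_j). Being short-ranged, favorable values of this energy
indicate direct contact between the groups; electrostatics is deliberately
not part of this readout.

Parameters ship as an editable delimited table
(residue_name, atom_name, type, r_min_half_A, epsilon_kcal); the bundled
``ff14sb_lj`` table covers the heavy atoms of the 20 standard residues
exactly and hydrogens through documented name-pattern rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fnmatch import fnmatchcase
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial import cKDTree

from .domain_model import AtomSelection
from .errors import DimensionError, ParameterAssignmentError, PartitionError
from .structure_io import Topology, Trajectory

__all__ = [
    "LJParameterSet",
    "EnergySeries",
    "ContactEntry",
    "ContactReport",
    "load_lj_table",
    "assign_lj_parameters",
    "group_vdw_energy",
    "energy_series",
    "summarize_energy",
    "find_local_minima",
    "classify_contacts",
    "infer_bonds",
    "bonded_exclusion_pairs",
]

_WILDCARD_CHARS = set("*?[")

POLAR_ELEMENTS = ("N", "O")


@dataclass
class LJParameterSet:
    """Atom-type LJ parameters plus the (residue, atom) -> type rule table.

    ``rows`` preserves file order: exact (residue_name, atom_name) rows take
    precedence; wildcard rows apply in order of appearance.
    """

    rows: pd.DataFrame  # residue_name, atom_name, type, r_min_half_A, epsilon_kcal

    def __post_init__(self):
        required = {"residue_name", "atom_name", "type", "r_min_half_A", "epsilon_kcal"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ParameterAssignmentError(f"LJ table missing columns: {sorted(missing)}")
        if (self.rows["epsilon_kcal"] < 0).any():
            raise ParameterAssignmentError("epsilon must be >= 0")
        if (self.rows["r_min_half_A"] <= 0).any() and not (
            (self.rows["epsilon_kcal"] == 0)
            | (self.rows["r_min_half_A"] > 0)
        ).all():
            raise ParameterAssignmentError("r_min/2 must be > 0 (unless epsilon is 0)")
        exact = {}
        patterns = []
        for row in self.rows.itertuples(index=False):
            res, atom = str(row.residue_name), str(row.atom_name)
            vals = (float(row.r_min_half_A), float(row.epsilon_kcal), str(row.type))
            if _WILDCARD_CHARS & (set(res) | set(atom)):
                patterns.append((res, atom, vals))
            else:
                exact.setdefault((res, atom), vals)
        self._exact = exact
        self._patterns = patterns

    def lookup(self, residue_name: str, atom_name: str):
        """Return (r_min/2, epsilon, type) or None if unmapped."""
        hit = self._exact.get((residue_name, atom_name))
        if hit is not None:
            return hit
        for res_pat, atom_pat, vals in self._patterns:
            if fnmatchcase(residue_name, res_pat) and fnmatchcase(atom_name, atom_pat):
                return vals
        return None


def load_lj_table(source: str | Path = "ff14sb_lj") -> LJParameterSet:
    """Load an LJ parameter table.

    ``source`` is either the name of a bundled table ("ff14sb_lj",
    "toy_lj") or a path to a whitespace/tab-delimited file with columns
    residue_name, atom_name, type, r_min_half_A, epsilon_kcal.
    """
    bundled = {"ff14sb_lj", "toy_lj"}
    if str(source) in bundled:
        ref = resources.files("knobdyn.data").joinpath(f"{source}.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep=r"\s+", comment="#")
    else:
        df = pd.read_csv(source, sep=r"\s+", comment="#")
    return LJParameterSet(rows=df)


def assign_lj_parameters(
    topology: Topology, params: LJParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (r_min/2, ε) arrays for a topology.

    Raises :class:`ParameterAssignmentError` listing every
    (residue_name, atom_name) pair without a table entry.
    """
    n = topology.n_atoms
    rmin_half = np.empty(n)
    eps = np.empty(n)
    unmapped: list[tuple[str, str]] = []
    for i in range(n):
        res = str(topology.res_name[i])
        atom = str(topology.atom_name[i])
        hit = params.lookup(res, atom)
        if hit is None:
            unmapped.append((res, atom))
        else:
            rmin_half[i], eps[i] = hit[0], hit[1]
    if unmapped:
        uniq = sorted(set(unmapped))
        raise ParameterAssignmentError(
            f"no LJ parameters for {len(uniq)} (residue, atom) pairs: {uniq[:20]}"
        )
    return rmin_half, eps


# ---------------------------------------------------------------------------
# Bond inference and exclusions (needed only for intra-chain group pairs)


def infer_bonds(coords: np.ndarray, topology: Topology, bond_cutoff: float = 1.9):
    """Distance-inferred covalent bond list between heavy atoms (< cutoff Å)."""
    coords = np.asarray(coords, dtype=float)
    heavy = np.array(
        [str(e).upper() not in ("H", "D") for e in topology.element], dtype=bool
    )
    idx = np.where(heavy)[0]
    tree = cKDTree(coords[idx])
    pairs = tree.query_pairs(r=bond_cutoff)
    return [(int(idx[i]), int(idx[j])) for i, j in pairs]


def bonded_exclusion_pairs(bonds, max_separation: int = 3) -> set[tuple[int, int]]:
    """All atom pairs within ``max_separation`` bonds of each other (1-2,
    1-3, 1-4 for the default of 3), as sorted index tuples."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded: set[tuple[int, int]] = set()
    for start in adj:
        frontier = {start}
        seen = {start}
        for _ in range(max_separation):
            frontier = {n for f in frontier for n in adj.get(f, ())} - seen
            seen |= frontier
            for n in frontier:
                excluded.add((min(start, n), max(start, n)))
    return excluded


# ---------------------------------------------------------------------------
# Pairwise energy


def _pair_tables(
    group_a: AtomSelection,
    group_b: AtomSelection,
    rmin_half: np.ndarray,
    eps: np.ndarray,
):
    ia, ib = group_a.indices, group_b.indices
    if np.intersect1d(ia, ib).size:
        raise PartitionError("energy groups must be disjoint")
    if len(ia) and len(ib) and ia[0] > ib[0]:
        # canonical group order makes E(A,B) == E(B,A) bit-exact
        ia, ib = ib, ia
    rmin_ij = rmin_half[ia][:, None] + rmin_half[ib][None, :]
    eps_ij = np.sqrt(eps[ia][:, None] * eps[ib][None, :])
    return ia, ib, rmin_ij, eps_ij


def group_vdw_energy(
    frame: np.ndarray,
    group_a: AtomSelection,
    group_b: AtomSelection,
    rmin_half: np.ndarray,
    eps: np.ndarray,
    cutoff: float = 12.0,
    exclusions: set[tuple[int, int]] | None = None,
) -> float:
    """12-6 LJ interaction energy (kcal/mol) between two disjoint groups.

    Pairs beyond ``cutoff`` contribute nothing; pairs separated by ≤3 bonds
    are skipped when ``exclusions`` (from :func:`bonded_exclusion_pairs`)
    is supplied. Overlapping atoms (r < 0.1 Å) trigger a warning naming the
    pair — the 1/r¹² term makes such energies meaningless.
    """
    frame = np.asarray(frame, dtype=float)
    ia, ib, rmin_ij, eps_ij = _pair_tables(group_a, group_b, rmin_half, eps)
    r = cdist(frame[ia], frame[ib])
    mask = r <= cutoff
    if exclusions:
        for ai, a in enumerate(ia):
            for bi, b in enumerate(ib):
                if (min(a, b), max(a, b)) in exclusions:
                    mask[ai, bi] = False
    close = (r < 0.1) & mask
    if close.any():
        ai, bi = np.argwhere(close)[0]
        warnings.warn(
            f"near-singular atom pair at r={r[ai, bi]:.3f} Å between atom "
            f"indices {ia[ai]} and {ib[bi]}",
            stacklevel=2,
        )
    if not mask.any():
        return 0.0
    rr = r[mask]
    q = (rmin_ij[mask] / rr) ** 6
    return float(np.sum(eps_ij[mask] * (q * q - 2.0 * q)))


@dataclass
class EnergySeries:
    """Per-frame group-group vdW energy time course."""

    label: str  # e.g. "knob-LC"
    times: np.ndarray  # ns
    e_vdw: np.ndarray  # kcal/mol

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.e_vdw = np.asarray(self.e_vdw, dtype=float)
        if len(self.times) != len(self.e_vdw):
            raise DimensionError("times and e_vdw length mismatch")
        if not np.all(np.isfinite(self.e_vdw)):
            raise DimensionError("energy series contains non-finite values")

    def __len__(self) -> int:
        return len(self.e_vdw)


def energy_series(
    traj: Trajectory,
    group_a: AtomSelection,
    group_b: AtomSelection,
    rmin_half: np.ndarray,
    eps: np.ndarray,
    cutoff: float = 12.0,
    exclusions: set[tuple[int, int]] | None = None,
    label: str = "A-B",
) -> EnergySeries:
    """Per-frame :func:`group_vdw_energy` over a trajectory."""
    ia, ib, rmin_ij, eps_ij = _pair_tables(group_a, group_b, rmin_half, eps)
    excl_mask = None
    if exclusions:
        excl_mask = np.zeros((len(ia), len(ib)), dtype=bool)
        for ai, a in enumerate(ia):
            for bi, b in enumerate(ib):
                if (min(a, b), max(a, b)) in exclusions:
                    excl_mask[ai, bi] = True
    energies = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        r = cdist(traj.frames[f, ia], traj.frames[f, ib])
        mask = r <= cutoff
        if excl_mask is not None:
            mask &= ~excl_mask
        if not mask.any():
            energies[f] = 0.0
            continue
        rr = r[mask]
        q = (rmin_ij[mask] / rr) ** 6
        energies[f] = np.sum(eps_ij[mask] * (q * q - 2.0 * q))
    return EnergySeries(label=label, times=traj.times.copy(), e_vdw=energies)


def summarize_energy(series_per_run: dict[str, EnergySeries]) -> dict[str, float]:
    """Time-mean energy per run plus the unweighted cross-run 'Average'.

    Averages run over the entire series (no equilibration discard).
    Rounding to two decimals is presentation-only and left to the writer.
    """
    if not series_per_run:
        raise DimensionError("need at least one run")
    out = {run: float(np.mean(s.e_vdw)) for run, s in series_per_run.items()}
    out["Average"] = float(np.mean(list(out.values())))
    return out


def find_local_minima(
    series: EnergySeries,
    smooth_window: int = 11,
    min_separation: int = 50,
) -> list[int]:
    """Frames at strict local minima of the smoothed energy time course.

    The series is smoothed with a centered running mean of
    ``smooth_window`` frames; a frame qualifies if its smoothed value is
    strictly below every other frame within ±``min_separation`` and the
    full window lies inside the series (endpoints of a monotone series are
    not minima). Returned frames are sorted by smoothed energy, most
    favorable first.
    """
    n = len(series)
    if n <= smooth_window:
        raise DimensionError("series must be longer than the smoothing window")
    smoothed = (
        pd.Series(series.e_vdw)
        .rolling(window=smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    minima: list[int] = []
    for i in range(min_separation, n - min_separation):
        window = smoothed[i - min_separation : i + min_separation + 1]
        if np.sum(window < smoothed[i]) == 0 and np.sum(window == smoothed[i]) == 1:
            minima.append(i)
    minima.sort(key=lambda i: smoothed[i])
    return minima


# ---------------------------------------------------------------------------
# Contact classification


@dataclass(frozen=True)
class ContactEntry:
    knob_residue: tuple[str, str]
    partner_residue: tuple[str, str]
    contact_class: str  # "nonpolar" | "polar"
    min_distance: float  # Å, heavy-atom


@dataclass
class ContactReport:
    frame: int
    time_ns: float
    contacts: list[ContactEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "frame": self.frame,
                    "time_ns": self.time_ns,
                    "knob_chain": c.knob_residue[0],
                    "knob_residue": c.knob_residue[1],
                    "partner_chain": c.partner_residue[0],
                    "partner_residue": c.partner_residue[1],
                    "contact_class": c.contact_class,
                    "min_distance_A": c.min_distance,
                }
                for c in self.contacts
            ],
            columns=[
                "frame",
                "time_ns",
                "knob_chain",
                "knob_residue",
                "partner_chain",
                "partner_residue",
                "contact_class",
                "min_distance_A",
            ],
        )


def classify_contacts(
    frame: np.ndarray,
    topology: Topology,
    knob_sel: AtomSelection,
    partner_sel: AtomSelection,
    contact_cutoff: float = 4.5,
    polar_cutoff: float = 3.5,
    frame_index: int = 0,
    time_ns: float = 0.0,
) -> ContactReport:
    """Residue-pair contacts between knob and partner group in one frame.

    A residue pair is in contact if any heavy-atom pair is within
    ``contact_cutoff`` (default 4.5 Å); the contact is *polar* if
    additionally some N/O-N/O atom pair is within ``polar_cutoff``
    (default 3.5 Å, a canonical hydrogen-bond distance), else *nonpolar*.
    Selections should be at heavy-atom granularity.
    """
    frame = np.asarray(frame, dtype=float)
    resnum = topology.residue_number

    def by_residue(sel: AtomSelection):
        groups: dict[tuple[str, str], list[int]] = {}
        for i in sel.indices:
            if str(topology.element[i]).upper() in ("H", "D"):
                continue
            res = (str(topology.chain_id[i]), str(resnum[i]))
            groups.setdefault(res, []).append(int(i))
        return groups

    knob_res = by_residue(knob_sel)
    part_res = by_residue(partner_sel)
    contacts: list[ContactEntry] = []
    for kres, kidx in knob_res.items():
        for pres, pidx in part_res.items():
            d = cdist(frame[kidx], frame[pidx])
            dmin = float(d.min())
            if dmin > contact_cutoff:
                continue
            k_polar = np.array(
                [str(topology.element[i]).upper() in POLAR_ELEMENTS for i in kidx]
            )
            p_polar = np.array(
                [str(topology.element[i]).upper() in POLAR_ELEMENTS for i in pidx]
            )
            polar = bool(
                k_polar.any()
                and p_polar.any()
                and (d[np.ix_(k_polar, p_polar)] <= polar_cutoff).any()
            )
            contacts.append(
                ContactEntry(
                    knob_residue=kres,
                    partner_residue=pres,
                    contact_class="polar" if polar else "nonpolar",
                    min_distance=dmin,
                )
            )
    contacts.sort(key=lambda c: c.min_distance)
    return ContactReport(frame=frame_index, time_ns=time_ns, contacts=contacts)
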