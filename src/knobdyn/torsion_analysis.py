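"""Backbone φ/ψ torsions, Ramachandran time-evolution, and TAF hinge mapping.

The torsion-angle fluctuation (TAF) of a backbone dihedral over a
trajectory is the circular variance

    TAF = 1 − R,   R = | mean over frames of (cos θ, sin θ) |,

a dimensionless dispersion in [0, 1]: 0 for a rigidly held angle, 1 for two
equally populated values 180° apart. Residues whose φ or ψ TAF exceeds a
threshold (default 0.6) are flagged as hinge sites. The formula is isolated
in :func:`compute_taf` so an alternative dispersion statistic can be
swapped without touching the rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DihedralUndefinedError
from .structure_io import Topology, Trajectory

__all__ = [
    "TorsionSeries",
    "TAFEntry",
    "TAFProfile",
    "dihedral",
    "compute_backbone_torsions",
    "compute_taf",
    "flag_hinge_residues",
    "ramachandran_evolution",
]

Residue = tuple[str, str]


@dataclass
class TorsionSeries:
    """Per-frame φ/ψ angles (deg, in (−180, 180]) of one residue.

    ``phi`` is None for a chain-start residue (no preceding C), ``psi``
    None for a chain-end residue (no following N). Within an array,
    individual frames are never NaN — an angle is defined for all frames
    or for none.
    """

    residue: Residue
    times: np.ndarray  # ns
    phi: np.ndarray | None
    psi: np.ndarray | None


@dataclass(frozen=True)
class TAFEntry:
    residue: Residue
    taf_phi: float | None
    taf_psi: float | None

    def max_taf(self) -> float:
        vals = [v for v in (self.taf_phi, self.taf_psi) if v is not None]
        return max(vals) if vals else 0.0


@dataclass
class TAFProfile:
    """Per-residue TAF values plus the hinge threshold used for flagging."""

    entries: list[TAFEntry]
    threshold: float = 0.6

    def hinge_flags(self) -> dict[Residue, bool]:
        return {e.residue: e.max_taf() > self.threshold for e in self.entries}


def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Signed dihedral angle (deg) of four points, IUPAC sign convention.

    cis (eclipsed) = 0°, trans = 180°; range (−180, 180]. Accepts single
    points or (..., 3) stacks and broadcasts over leading axes.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=-1)
    n2_norm = np.linalg.norm(n2, axis=-1)
    scale = max(
        float(np.max(np.linalg.norm(b2, axis=-1))), 1e-30
    )  # degeneracy detection relative to bond length
    if np.any(n1_norm < 1e-9 * scale) or np.any(n2_norm < 1e-9 * scale):
        raise DihedralUndefinedError(
            "three consecutive points are collinear; dihedral undefined"
        )
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    # IUPAC sign: positive = clockwise rotation of the far bond viewed
    # along the central bond
    y = -np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    if ang.ndim == 0:
        return float(ang)
    return ang


def _backbone_atom_map(topology: Topology) -> dict[tuple[Residue, str], int]:
    out: dict[tuple[Residue, str], int] = {}
    resnum = topology.residue_number
    for i in range(topology.n_atoms):
        name = str(topology.atom_name[i])
        if name in ("N", "CA", "C"):
            res = (str(topology.chain_id[i]), str(resnum[i]))
            out[(res, name)] = i
    return out


def compute_backbone_torsions(
    traj: Trajectory, residues: list[Residue]
) -> list[TorsionSeries]:
    """φ/ψ time series for the given residues.

    φᵢ = dihedral(Cᵢ₋₁, Nᵢ, CAᵢ, Cᵢ) and ψᵢ = dihedral(Nᵢ, CAᵢ, Cᵢ, Nᵢ₊₁),
    where the neighbours are the adjacent residues in chain file order.
    Missing neighbour atoms mark the corresponding angle undefined (None)
    instead of failing.
    """
    topo = traj.topology
    amap = _backbone_atom_map(topo)
    out: list[TorsionSeries] = []
    for res in residues:
        chain, resnum = res
        chain_res = topo.chain_residues(chain)
        try:
            k = chain_res.index(resnum)
        except ValueError:
            raise DihedralUndefinedError(
                f"residue {chain}:{resnum} not found in topology"
            ) from None
        prev_res = (chain, chain_res[k - 1]) if k > 0 else None
        next_res = (chain, chain_res[k + 1]) if k + 1 < len(chain_res) else None

        def idx(r, name):
            return amap.get((r, name)) if r is not None else None

        i_n, i_ca, i_c = idx(res, "N"), idx(res, "CA"), idx(res, "C")
        i_cprev = idx(prev_res, "C")
        i_nnext = idx(next_res, "N")
        phi = psi = None
        if None not in (i_cprev, i_n, i_ca, i_c):
            phi = dihedral(
                traj.frames[:, i_cprev],
                traj.frames[:, i_n],
                traj.frames[:, i_ca],
                traj.frames[:, i_c],
            )
        if None not in (i_n, i_ca, i_c, i_nnext):
            psi = dihedral(
                traj.frames[:, i_n],
                traj.frames[:, i_ca],
                traj.frames[:, i_c],
                traj.frames[:, i_nnext],
            )
        out.append(TorsionSeries(residue=res, times=traj.times, phi=phi, psi=psi))
    return out


def circular_variance(angles_deg: np.ndarray) -> float:
    """1 − |mean unit vector| of a sample of angles in degrees."""
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size < 2:
        raise ValueError("need at least 2 defined frames for a TAF")
    # center on the first sample: the statistic is rotation-invariant, and
    # this keeps a constant series at exactly zero dispersion
    theta = np.radians(angles - angles[0])
    r = np.hypot(np.mean(np.cos(theta)), np.mean(np.sin(theta)))
    return float(np.clip(1.0 - r, 0.0, 1.0))


def compute_taf(series: TorsionSeries) -> TAFEntry | None:
    """Circular-variance TAF of one residue's φ and ψ, each in [0, 1].

    Returns None (with a warning) if both angles are undefined.
    """
    taf_phi = circular_variance(series.phi) if series.phi is not None else None
    taf_psi = circular_variance(series.psi) if series.psi is not None else None
    if taf_phi is None and taf_psi is None:
        warnings.warn(
            f"residue {series.residue} has no defined backbone torsions; "
            "omitted from TAF profile",
            stacklevel=2,
        )
        return None
    return TAFEntry(residue=series.residue, taf_phi=taf_phi, taf_psi=taf_psi)


def flag_hinge_residues(profile: TAFProfile, threshold: float | None = None) -> list[Residue]:
    """Residues whose φ- or ψ-TAF strictly exceeds the threshold.

    The comparison is strict: a TAF exactly at the threshold is not a hinge.
    """
    thr = profile.threshold if threshold is None else threshold
    return [
        e.residue
        for e in profile.entries
        if (e.taf_phi is not None and e.taf_phi > thr)
        or (e.taf_psi is not None and e.taf_psi > thr)
    ]


def ramachandran_evolution(series: TorsionSeries) -> np.ndarray:
    """Time-annotated (time_ns, φ, ψ) triples for frames where both angles
    are defined — the raw material of a time-colored Ramachandran plot.
    No binning is applied."""
    if series.phi is None or series.psi is None:
        return np.empty((0, 3))
    return np.column_stack([series.times, series.phi, series.psi])
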