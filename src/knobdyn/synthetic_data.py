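"""Synthetic hinged-domain trajectories with exact ground truth.

Real microsecond trajectories of antibody variable fragments are too
expensive to regenerate, so every stage of the pipeline is validated
against geometry built here: a poly-alanine-like backbone with four
labeled domains (core_heavy, core_light = "light chain", stalk, knob), a
rigid core, and a knob whose position follows a prescribed per-frame
rotation schedule about a hinge in the N-terminal stalk strand.

The hinge is implemented as a rotation of everything C-terminal of the
hinge residue's CA about the axis along that residue's CA→C bond. This has
two exact consequences that make ground truth trivial to state:

* the ψ dihedral of the hinge residue changes by exactly the applied
  angle, and no other backbone torsion changes — so hinge flagging has a
  single known positive;
* the knob moves rigidly, so the applied angle and the noiseless centroid
  displacement are the exact targets for the two-step offset analysis.

Optional *contact episodes* override the schedule with a fixed bent angle
during given frame intervals; the light-chain helix is placed (once,
deterministically) so that the bent knob sits at van der Waals contact
distance from it, giving planted energy minima and known contact pairs.

Isotropic Gaussian coordinate noise is applied after the rigid motion,
i.i.d. per atom per frame, from a single ``numpy.random.default_rng``
stream — fixed seed means bit-identical output. This is a geometry
generator, not a physics simulator: no forces, solvent, or thermostats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SyntheticSpecError
from .structure_io import Topology, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_hinged_trajectory",
    "generate_torsion_process",
    "generate_two_domain_lj_system",
    "sinusoidal_schedule",
    "two_state_schedule",
    "rigid_schedule",
]

Residue = tuple[str, str]

# idealized backbone internal coordinates (Å / deg)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.6
_ANG_C_N_CA = 121.9
_ANG_CA_C_O = 120.5
_OMEGA = 180.0

_HELIX = (-57.0, -47.0)
_STRAND = (-135.0, 135.0)


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates
    (natural extension reference frame)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _build_backbone(torsions: list[tuple[float, float]]) -> np.ndarray:
    """Backbone coordinates (N, CA, C, O per residue) for given (φ, ψ)."""
    n_res = len(torsions)
    coords = np.empty((4 * n_res, 3))
    # seed residue in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    alpha = np.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    coords[0], coords[1], coords[2] = n0, ca0, c0
    coords[3] = _nerf(n0, ca0, c0, _BOND_C_O, _ANG_CA_C_O, torsions[0][1] + 180.0)
    for i in range(1, n_res):
        phi, psi = torsions[i]
        psi_prev = torsions[i - 1][1]
        n_prev, ca_prev, c_prev = coords[4 * (i - 1)], coords[4 * (i - 1) + 1], coords[4 * (i - 1) + 2]
        n_i = _nerf(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi_prev)
        ca_i = _nerf(ca_prev, c_prev, n_i, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = _nerf(c_prev, n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi)
        o_i = _nerf(n_i, ca_i, c_i, _BOND_C_O, _ANG_CA_C_O, torsions[i][1] + 180.0)
        coords[4 * i : 4 * i + 4] = [n_i, ca_i, c_i, o_i]
    return coords


def _compactify(
    coords: np.ndarray,
    n_res: int,
    seg_res: int = 10,
    spacing: float = 12.0,
    anchor: str = "last",
) -> np.ndarray:
    """Fold a long helix into a compact bundle of parallel rods.

    The helix is cut into segments of ``seg_res`` residues which are
    translated onto a grid perpendicular to the helix axis, emulating a
    globular domain. The ``anchor`` segment ("first" or "last") stays in
    place so a chain continuation attached to it remains attached. The
    resulting chain has nonphysical breaks between segments — acceptable
    for a rigid body whose internal torsions are never analyzed.
    """
    coords = coords.copy()
    n_seg = int(np.ceil(n_res / seg_res))
    if n_seg < 2:
        return coords
    seg_centroids = [
        coords[4 * s * seg_res : 4 * min((s + 1) * seg_res, n_res)].mean(axis=0)
        for s in range(n_seg)
    ]
    axis = seg_centroids[-1] - seg_centroids[0]
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    grid = [(0, 0), (1, 0), (0, 1), (1, 1), (-1, 0), (0, -1), (-1, 1), (1, -1), (-1, -1)]
    anchor_idx = n_seg - 1 if anchor == "last" else 0
    anchor_centroid = seg_centroids[anchor_idx]
    g = 1
    for s in range(n_seg):
        if s == anchor_idx:
            continue
        a, b = grid[g % len(grid)]
        g += 1
        target = anchor_centroid + spacing * (a * e1 + b * e2)
        lo, hi = 4 * s * seg_res, 4 * min((s + 1) * seg_res, n_res)
        coords[lo:hi] += target - seg_centroids[s]
    return coords


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    theta = np.radians(angle_deg)
    u = axis / np.linalg.norm(axis)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def _fold_angle(angle_deg: float) -> float:
    """Magnitude of a rotation, folded into [0, 180]."""
    a = abs(angle_deg) % 360.0
    return 360.0 - a if a > 180.0 else a


# ---------------------------------------------------------------------------
# schedules


def rigid_schedule(n_frames: int) -> np.ndarray:
    """No hinge motion: every frame at the reference angle."""
    return np.zeros(n_frames)


def sinusoidal_schedule(
    n_frames: int, amplitude_deg: float = 40.0, periods: float = 3.0
) -> np.ndarray:
    """Smooth reversible bending: amplitude · sin(2π · periods · f / n)."""
    f = np.arange(n_frames)
    return amplitude_deg * np.sin(2.0 * np.pi * periods * f / n_frames)


def two_state_schedule(
    n_frames: int, low_deg: float = 0.0, high_deg: float = 150.0, block: int = 25
) -> np.ndarray:
    """Alternating equal blocks of two hinge angles (basin flipping)."""
    f = np.arange(n_frames)
    return np.where((f // block) % 2 == 0, low_deg, high_deg).astype(float)


# ---------------------------------------------------------------------------
# spec and ground truth


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic hinged two-domain trajectory.

    Domain sizes default to the scale of an antibody Fv with an ultralong
    CDRH3: ~40-residue globular heavy/light core pieces, a 6+6-residue
    two-stranded stalk and a 20-residue knob. The hinge sits in the
    N-terminal stalk strand (``hinge_position`` is a 0-based index into
    that strand). ``contact_gap`` is the minimum heavy-atom distance (Å)
    between the bent knob and the light-chain group, chosen slightly
    beyond the LJ minimum so planted episodes are attractive.
    """

    n_frames: int = 1000
    frame_dt: float = 1.0  # ns between saved frames
    core_heavy_residues: int = 40
    core_light_residues: int = 40
    stalk_residues_per_strand: int = 6
    knob_residues: int = 20
    hinge_position: int = 3
    schedule_deg: np.ndarray | None = None  # default: rigid
    knob_translation: np.ndarray | None = None  # optional (n_frames, 3) extra shift
    contact_episodes: tuple[tuple[int, int], ...] = ()
    contact_angle_deg: float = 150.0
    contact_gap: float = 3.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SyntheticSpecError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise SyntheticSpecError("noise_sigma must be >= 0")
        if self.schedule_deg is None:
            self.schedule_deg = rigid_schedule(self.n_frames)
        self.schedule_deg = np.asarray(self.schedule_deg, dtype=float)
        if len(self.schedule_deg) != self.n_frames:
            raise SyntheticSpecError(
                f"schedule length {len(self.schedule_deg)} != n_frames {self.n_frames}"
            )
        if self.knob_translation is not None:
            self.knob_translation = np.asarray(self.knob_translation, dtype=float)
            if self.knob_translation.shape != (self.n_frames, 3):
                raise SyntheticSpecError("knob_translation must have shape (n_frames, 3)")
        for start, stop in self.contact_episodes:
            if not (0 <= start <= stop < self.n_frames):
                raise SyntheticSpecError(
                    f"contact episode ({start}, {stop}) outside [0, {self.n_frames})"
                )
        if not (0 <= self.hinge_position < self.stalk_residues_per_strand):
            raise SyntheticSpecError("hinge_position outside the N-terminal strand")

    def effective_schedule(self) -> np.ndarray:
        """Schedule with contact episodes overriding the base angles."""
        sched = self.schedule_deg.copy()
        for start, stop in self.contact_episodes:
            sched[start : stop + 1] = self.contact_angle_deg
        return sched


@dataclass
class GroundTruth:
    """Exact applied motions, recorded before noise."""

    rotation_deg: np.ndarray  # per-frame applied rotation magnitude, [0, 180]
    displacement_A: np.ndarray  # per-frame exact knob-centroid displacement
    flexible_residues: tuple[Residue, ...]
    contact_episodes: tuple[tuple[int, int], ...]
    contact_pairs: tuple[tuple[Residue, Residue], ...]
    reference_coords: np.ndarray  # noiseless base conformation (angle 0)
    domain_config: dict  # domain document matching the generated topology


def _domain_config(spec: SyntheticSpec) -> dict:
    nh, ns, nk = spec.core_heavy_residues, spec.stalk_residues_per_strand, spec.knob_residues
    def rng(a, b):
        return [[str(a), str(b)]]
    return {
        "domains": {
            "core_heavy": {"chain": "H", "residues": rng(1, nh)},
            "core_light": {"chain": "L", "residues": rng(1, spec.core_light_residues)},
            "stalk_n": {"chain": "H", "residues": rng(nh + 1, nh + ns)},
            "knob": {"chain": "H", "residues": rng(nh + ns + 1, nh + ns + nk)},
            "stalk_c": {"chain": "H", "residues": rng(nh + ns + nk + 1, nh + 2 * ns + nk)},
        }
    }


def _make_topology(n_heavy_res: int, n_light_res: int) -> Topology:
    names, elements, res_ids, chains = [], [], [], []
    for chain, n_res in (("H", n_heavy_res), ("L", n_light_res)):
        for r in range(1, n_res + 1):
            for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                names.append(name)
                elements.append(elem)
                res_ids.append(r)
                chains.append(chain)
    n = len(names)
    return Topology(
        serial=np.arange(1, n + 1),
        atom_name=np.array(names),
        element=np.array(elements),
        res_id=np.array(res_ids),
        ins_code=np.array([""] * n),
        res_name=np.array(["ALA"] * n),
        chain_id=np.array(chains),
    )


def generate_hinged_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Build a hinged two-domain trajectory and its exact ground truth."""
    nh = spec.core_heavy_residues
    ns = spec.stalk_residues_per_strand
    nk = spec.knob_residues
    n_heavy_res = nh + 2 * ns + nk

    torsions: list[tuple[float, float]] = (
        [_HELIX] * nh + [_STRAND] * ns + [_HELIX] * nk + [_STRAND] * ns
    )
    heavy = _build_backbone(torsions)
    # fold the core-heavy helix into a compact bundle; the last segment
    # stays put so the stalk remains attached to it
    heavy[: 4 * nh] = _compactify(heavy[: 4 * nh], nh, anchor="last")
    light = _compactify(
        _build_backbone([_HELIX] * spec.core_light_residues),
        spec.core_light_residues,
        anchor="first",
    )

    hinge_res = nh + spec.hinge_position  # 0-based residue index in chain H
    ca_idx = 4 * hinge_res + 1
    c_idx = 4 * hinge_res + 2
    anchor = heavy[ca_idx].copy()
    axis = heavy[c_idx] - heavy[ca_idx]
    axis = axis / np.linalg.norm(axis)
    moving = np.arange(len(heavy)) > ca_idx  # C-terminal of the hinge CA

    # ground-truth displacement uses the backbone (N, CA, C) centroid of the
    # knob, matching the backbone-only convention of the offset analysis
    knob_atoms = np.array(
        [4 * r + k for r in range(nh + ns, nh + ns + nk) for k in (0, 1, 2)]
    )
    knob_centroid0 = heavy[knob_atoms].mean(axis=0)

    def pose(angle_deg: float) -> np.ndarray:
        rot = _rotation_about_axis(axis, angle_deg)
        out = heavy.copy()
        out[moving] = (out[moving] - anchor) @ rot.T + anchor
        return out

    # place the light chain at contact distance from the *knob* in its bent
    # pose, approaching along the direction away from the static core
    knob_all = np.arange(4 * (nh + ns), 4 * (nh + ns + nk))
    bent = pose(spec.contact_angle_deg)
    static_centroid = heavy[~moving].mean(axis=0)
    bent_knob = bent[knob_all]
    u_dir = bent_knob.mean(axis=0) - static_centroid
    u_dir = u_dir / np.linalg.norm(u_dir)
    light = light - light.mean(axis=0) + bent_knob.mean(axis=0) + 40.0 * u_dir
    for _ in range(30):
        dmin = cdist(light, bent_knob).min()
        if abs(dmin - spec.contact_gap) < 0.05:
            break
        light = light - u_dir * (dmin - spec.contact_gap)
    # back off if anything other than the knob would clash (extended or bent)
    others = np.vstack([heavy, bent[moving]])
    for _ in range(40):
        if cdist(light, others).min() >= 2.8:
            break
        light = light + 0.5 * u_dir

    base = np.vstack([heavy, light])
    n_atoms = len(base)
    light_offset = len(heavy)

    # ground-truth contact pairs in the bent pose; the 3.9 Å threshold is
    # deliberately tighter than the 4.5 Å detection cutoff so that planted
    # pairs remain detectable under coordinate noise
    bent_full = np.vstack([bent, light])
    contact_pairs: list[tuple[Residue, Residue]] = []
    for kr in range(nh + ns, nh + ns + nk):
        kcoords = bent_full[4 * kr : 4 * kr + 4]
        for lr in range(spec.core_light_residues):
            lcoords = bent_full[light_offset + 4 * lr : light_offset + 4 * lr + 4]
            if cdist(kcoords, lcoords).min() <= 3.9:
                contact_pairs.append((("H", str(kr + 1)), ("L", str(lr + 1))))

    sched = spec.effective_schedule()
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    displacement = np.empty(spec.n_frames)
    for f in range(spec.n_frames):
        coords = base.copy()
        if sched[f] != 0.0:  # keep the zero-angle frame bit-identical to base
            rot = _rotation_about_axis(axis, sched[f])
            coords[:light_offset][moving] = (heavy[moving] - anchor) @ rot.T + anchor
        if spec.knob_translation is not None:
            coords[:light_offset][moving] += spec.knob_translation[f]
        centroid = coords[knob_atoms].mean(axis=0)
        displacement[f] = np.linalg.norm(centroid - knob_centroid0)
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        frames[f] = coords

    topo = _make_topology(n_heavy_res, spec.core_light_residues)
    traj = Trajectory(
        topology=topo,
        frames=frames,
        times=np.arange(spec.n_frames) * spec.frame_dt,
    )
    truth = GroundTruth(
        rotation_deg=np.array([_fold_angle(a) for a in sched]),
        displacement_A=displacement,
        flexible_residues=(("H", str(hinge_res + 1)),),
        contact_episodes=tuple(spec.contact_episodes),
        contact_pairs=tuple(contact_pairs),
        reference_coords=base,
        domain_config=_domain_config(spec),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# torsion processes


def generate_torsion_process(
    n: int,
    distribution: str,
    seed: int = 0,
    value: float = 60.0,
    delta: float = 180.0,
    kappa: float = 2.0,
    mu: float = 0.0,
) -> np.ndarray:
    """Angle series (deg, in (−180, 180]) for TAF validation.

    Distributions: ``constant`` (all frames at ``value``), ``two_state``
    (random equal-probability choice between ``value`` and
    ``value + delta``), ``von_mises`` (concentration ``kappa`` about
    ``mu``).
    """
    if n < 2:
        raise SyntheticSpecError("need n >= 2 frames")
    rng = np.random.default_rng(seed)
    if distribution == "constant":
        angles = np.full(n, value, dtype=float)
    elif distribution == "two_state":
        angles = value + delta * rng.integers(0, 2, size=n)
    elif distribution == "von_mises":
        if kappa <= 0:
            raise SyntheticSpecError("von Mises concentration kappa must be > 0")
        angles = np.degrees(rng.vonmises(np.radians(mu), kappa, size=n))
    else:
        raise SyntheticSpecError(f"unknown distribution '{distribution}'")
    angles = np.mod(angles + 180.0, 360.0) - 180.0
    angles[angles == -180.0] = 180.0
    return angles


# ---------------------------------------------------------------------------
# toy LJ systems


def generate_two_domain_lj_system(
    n_a: int,
    n_b: int,
    separation: float,
    rmin_half: float = 1.908,
    epsilon: float = 0.1094,
    seed: int = 0,
    cloud_radius: float = 1.0,
) -> tuple[Topology, np.ndarray, float | None]:
    """Two atom clouds on chains A and B at a given centroid separation.

    Every atom is its own residue (carbon, generic type). For the 1+1 case
    the closed-form pair energy at the exact separation is returned as the
    third element; otherwise None.
    """
    if n_a < 1 or n_b < 1:
        raise SyntheticSpecError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    coords_a = np.zeros((n_a, 3))
    coords_b = np.zeros((n_b, 3))
    coords_b[:, 0] = separation
    if n_a > 1:
        coords_a += rng.uniform(-cloud_radius, cloud_radius, size=(n_a, 3))
    if n_b > 1:
        coords_b += rng.uniform(-cloud_radius, cloud_radius, size=(n_b, 3))
    n = n_a + n_b
    topo = Topology(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["C1"] * n),
        element=np.array(["C"] * n),
        res_id=np.concatenate([np.arange(1, n_a + 1), np.arange(1, n_b + 1)]),
        ins_code=np.array([""] * n),
        res_name=np.array(["LJT"] * n),
        chain_id=np.array(["A"] * n_a + ["B"] * n_b),
    )
    analytic = None
    if n_a == 1 and n_b == 1:
        rmin_ij = 2.0 * rmin_half
        q = (rmin_ij / separation) ** 6
        analytic = epsilon * (q * q - 2.0 * q)
    return topo, np.vstack([coords_a, coords_b]), analytic
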