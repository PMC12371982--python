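"""Rigid-body least-squares superposition and rotation decomposition.

This is the numeric kernel behind every motion analysis in the package:
SVD-based Kabsch superposition with a proper-rotation sign fix, plain RMSD,
and extraction of the rotation magnitude from a rigid transform. Fits are
unweighted (no mass weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, FitError

__all__ = [
    "RigidTransform",
    "kabsch_fit",
    "rmsd_nofit",
    "rotation_angle",
    "apply_transform",
]

_ORTHO_TOL = 1e-9


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise FitError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if err > _ORTHO_TOL:
        raise FitError(f"rotation matrix not orthonormal (deviation {err:.2e})")
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > _ORTHO_TOL:
        raise FitError(f"rotation matrix determinant {det:.12f} != +1 (reflection?)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x' = R x + t`` (rotation R, translation t in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to one point or an (..., 3) array of points."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


def _as_points(coords, name: str) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DimensionError(f"{name} must be an (n, 3) array, got {arr.shape}")
    return arr


def rmsd_nofit(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two equally indexed point sets, without fitting."""
    a = _as_points(a, "a")
    b = _as_points(b, "b")
    if a.shape != b.shape:
        raise DimensionError(f"point counts differ: {a.shape[0]} vs {b.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns the proper rigid transform minimizing the RMSD of the
    transformed mobile set against the reference, and that minimum RMSD.
    A reflection is excluded by flipping the sign of the smallest singular
    value when the naive solution has determinant −1.
    """
    mobile = _as_points(mobile, "mobile")
    reference = _as_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise DimensionError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 points for a rigid fit, got {n}")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    m = mobile - mob_c
    r = reference - ref_c
    # collinear point sets leave a rotation about the line undetermined
    for pts, label in ((m, "mobile"), (r, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise FitError(f"{label} points are (near-)collinear; fit is degenerate")
    h = m.T @ r
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # re-orthonormalize to guard against accumulated round-off
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    trans = ref_c - rot @ mob_c
    transform = RigidTransform(rot, trans)
    fitted = transform.apply(mobile)
    return transform, rmsd_nofit(fitted, reference)


def rotation_angle(transform) -> float:
    """Rotation magnitude of a rigid transform, in degrees within [0, 180].

    The angle satisfies ``cos(theta) = (trace(R) - 1) / 2`` and is
    independent of the rotation axis. It is evaluated as
    ``atan2(|antisymmetric part|, trace form)``: near 0 and 180 degrees the
    bare arccos amplifies rounding in the matrix by a square root, while
    the atan2 form stays accurate at both endpoints.
    """
    rot = transform.rotation if isinstance(transform, RigidTransform) else transform
    rot = _check_rotation(rot)
    cos_theta = (np.trace(rot) - 1.0) / 2.0
    skew = rot - rot.T
    sin_theta = 0.5 * np.sqrt(
        skew[2, 1] ** 2 + skew[0, 2] ** 2 + skew[1, 0] ** 2
    )
    return float(np.degrees(np.arctan2(sin_theta, cos_theta)))


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`RigidTransform.apply`."""
    return transform.apply(coords)
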