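"""Independent reference implementations used to cross-check the package.

These deliberately take different algorithmic routes from the library code
(quaternion eigenvalue method instead of SVD Kabsch, explicit double loops
instead of vectorized sums, projection-based dihedrals instead of the
atan2-on-normals construction) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD after optimal proper rotation, via Horn's quaternion
    eigenvalue method (largest eigenvalue of the 4x4 key matrix)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    s = ac.T @ bc  # correlation matrix
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(key)[-1]
    g = np.sum(ac**2) + np.sum(bc**2)
    return float(np.sqrt(max(g - 2.0 * lam_max, 0.0) / n))


def axis_angle_rotation(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix from axis and angle (Rodrigues), for construct-then-
    recover checks of the rotation-magnitude extraction."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    t = np.radians(angle_deg)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def loop_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Direct double-loop RMSD without fitting."""
    total = 0.0
    for p, q in zip(a, b):
        d = 0.0
        for k in range(3):
            d += (p[k] - q[k]) ** 2
        total += d
    return float(np.sqrt(total / len(a)))


def loop_lj_energy(
    coords_a, coords_b, rmin_half_a, rmin_half_b, eps_a, eps_b, cutoff
) -> float:
    """Unconditional double-loop 12-6 LJ sum over in-cutoff pairs."""
    total = 0.0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            r = float(np.linalg.norm(np.asarray(coords_a[i]) - np.asarray(coords_b[j])))
            if r > cutoff:
                continue
            rmin = rmin_half_a[i] + rmin_half_b[j]
            eps = np.sqrt(eps_a[i] * eps_b[j])
            q = (rmin / r) ** 6
            total += eps * (q * q - 2.0 * q)
    return total


def projection_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral (deg) via Gram-Schmidt projection onto the plane normal to
    the central bond, with the sign from a triple product."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    v = (p1 - p2) - ((p1 - p2) @ b) * b
    w = (p4 - p3) - ((p4 - p3) @ b) * b
    cos_t = (v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
    ang = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    if np.cross(v, w) @ b < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
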