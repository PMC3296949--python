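"""Low-level vector geometry: dihedrals, internal-coordinate placement, rigid fits.

All coordinates are Cartesian, in angstroms; all angles at this layer are in
degrees unless a name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral_deg",
    "angle_deg",
    "place_internal",
    "rotate_about_axis",
    "kabsch",
    "ideal_cb",
]


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in (-180, 180] degrees.

    Raises ValueError when three consecutive points are colinear (the
    torsion is then undefined).
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("degenerate torsion: coincident axis atoms")
    b1n = b1 / nb1
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("degenerate torsion: colinear atoms")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_internal(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    dihedral: float,
) -> np.ndarray:
    """Place atom d from internal coordinates relative to references a, b, c.

    d has |c-d| = bond, angle(b, c, d) = ``angle`` and torsion
    (a, b, c, d) = ``dihedral`` (natural extension reference frame).
    """
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + local[0] * bc + local[1] * m + local[2] * n


def rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_degrees: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis`` (Rodrigues)."""
    k = axis / np.linalg.norm(axis)
    theta = np.radians(angle_degrees)
    p = points - origin
    cross = np.cross(k, p)
    dot = p @ k
    rot = p * np.cos(theta) + cross * np.sin(theta) + np.outer(dot, k) * (1 - np.cos(theta))
    return rot + origin


def kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rigid fit of ``mov`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` with
    ``mov @ rotation.T + translation ~= ref``. The rotation is constrained
    to determinant +1 (no reflections).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise ValueError("superposition needs two equal point sets of >= 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    # guard against colinear degenerate input
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (colinear) point sets cannot define a rigid frame")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mov_c
    fitted = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


# Tetrahedral half-angle machinery for the ideal C-beta direction: the
# direction makes ~110.5 deg with both the N and C bond vectors.
_CB_LENGTH = 1.53
_CB_ANGLE = 110.5


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Construct an ideal C-beta position from backbone N, CA, C.

    Uses the L-amino-acid branch of the tetrahedral geometry, so attaching
    to glycine reproduces the side-chain direction of a standard residue.
    """
    u = n - ca
    u = u / np.linalg.norm(u)
    v = c - ca
    v = v / np.linalg.norm(v)
    bis = u + v
    bis = bis / np.linalg.norm(bis)
    nrm = np.cross(u, v)  # sign picks the L configuration
    nrm = nrm / np.linalg.norm(nrm)
    target = np.cos(np.radians(_CB_ANGLE))
    a = target / np.dot(bis, u)
    b = np.sqrt(max(0.0, 1.0 - a * a))
    direction = a * bis + b * nrm
    return ca + _CB_LENGTH * direction / np.linalg.norm(direction)
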