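"""Small geometry kernel: minimum-image distances, dihedrals, internal-coordinate
atom placement, and least-squares rigid superposition."""

from __future__ import annotations

import numpy as np


def minimum_image(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Works on the last axis; ``box`` holds orthorhombic box lengths.
    """
    box = np.asarray(box, dtype=float)
    return dx - box * np.round(dx / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise min-image distances between point sets a (n,d) and b (m,d) -> (n, m)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    dx = a[:, None, :] - b[None, :, :]
    dx = minimum_image(dx, np.asarray(box, dtype=float)[: a.shape[1]])
    return np.sqrt((dx * dx).sum(axis=-1))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """NeRF placement: position D given chain a-b-c, |c-D|, angle(b,c,D), torsion(a,b,c,D)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    angle = np.radians(angle_deg)
    torsion = -np.radians(torsion_deg)  # sign matches dihedral()
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto centered ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, transformed mobile coordinates) such that
    ``mobile @ R.T + t`` best matches ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot = kabsch_rotation(mobile - cm, reference - cr)
    trans = cr - cm @ rot.T
    return rot, trans, mobile @ rot.T + trans
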