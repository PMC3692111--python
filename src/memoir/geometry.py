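"""Small 3D geometry toolkit: torsions, internal-coordinate placement, Kabsch.

All angles are in degrees at the API surface; coordinates are in Angstroms.
"""
from __future__ import annotations

import numpy as np

__all__ = ["unit", "dihedral", "bond_angle", "nerf_place", "kabsch", "apply_transform"]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    a = unit(np.asarray(p0, float) - np.asarray(p1, float))
    b = unit(np.asarray(p2, float) - np.asarray(p1, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal least-squares superposition of point set P onto Q.

    Returns (R, t, rmsd) such that P @ R.T + t best fits Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords @ R.T + t
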