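"""Internal-coordinate geometry: distances, angles, signed dihedrals.

All functions are batched: ``positions`` may have any number of leading
axes before the trailing ``(n_atoms, 3)``. Index arguments are integer
arrays selecting atoms; results broadcast over both the batch axes and
the term axis.

Dihedrals follow the IUPAC sign convention: looking down the j->k bond,
phi is positive for a clockwise rotation of the l atom relative to i,
computed with the standard atan2 construction so phi lies in (-pi, pi].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distances",
    "distance_gradients",
    "angles",
    "angle_gradients",
    "dihedrals",
    "dihedral_gradients",
    "wrap_angle",
]


def wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle (radians) onto (-pi, pi]."""
    out = -np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi) + np.pi
    return out


def distances(positions: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Pairwise distances |r_j - r_i| for each (i, j) in ``pairs``."""
    d = positions[..., pairs[:, 1], :] - positions[..., pairs[:, 0], :]
    return np.linalg.norm(d, axis=-1)


def distance_gradients(positions: np.ndarray, pairs: np.ndarray):
    """Distances and unit vectors u = (r_j - r_i)/r; grad_j r = u, grad_i r = -u."""
    d = positions[..., pairs[:, 1], :] - positions[..., pairs[:, 0], :]
    r = np.linalg.norm(d, axis=-1)
    u = d / r[..., None]
    return r, u


def angles(positions: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angle at the middle atom j of each (i, j, k), in radians [0, pi]."""
    u = positions[..., triples[:, 0], :] - positions[..., triples[:, 1], :]
    v = positions[..., triples[:, 2], :] - positions[..., triples[:, 1], :]
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return np.arctan2(cross, dot)


def angle_gradients(positions: np.ndarray, triples: np.ndarray):
    """Angles plus gradients w.r.t. the three atoms.

    Returns ``(theta, gi, gj, gk)`` with gradient shapes
    ``(..., n_terms, 3)``. Near-linear angles (sin theta < 1e-8) get a
    zero gradient to avoid overflow; no angle term in this package has
    theta0 near 0 or pi.
    """
    ri = positions[..., triples[:, 0], :]
    rj = positions[..., triples[:, 1], :]
    rk = positions[..., triples[:, 2], :]
    u = ri - rj
    v = rk - rj
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    uh = u / nu[..., None]
    vh = v / nv[..., None]
    cos = np.sum(uh * vh, axis=-1)
    sin = np.linalg.norm(np.cross(uh, vh), axis=-1)
    theta = np.arctan2(sin, cos)
    safe = np.where(sin > 1e-8, sin, 1.0)
    gi = -(vh - cos[..., None] * uh) / (nu * safe)[..., None]
    gk = -(uh - cos[..., None] * vh) / (nv * safe)[..., None]
    mask = (sin > 1e-8)[..., None]
    gi = np.where(mask, gi, 0.0)
    gk = np.where(mask, gk, 0.0)
    gj = -(gi + gk)
    return theta, gi, gj, gk


def dihedrals(positions: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral phi(i, j, k, l) in (-pi, pi] for each quad."""
    b1 = positions[..., quads[:, 1], :] - positions[..., quads[:, 0], :]
    b2 = positions[..., quads[:, 2], :] - positions[..., quads[:, 1], :]
    b3 = positions[..., quads[:, 3], :] - positions[..., quads[:, 2], :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / b2n
    x = np.sum(n1 * n2, axis=-1)
    return np.arctan2(y, x)


def dihedral_gradients(positions: np.ndarray, quads: np.ndarray):
    """Dihedrals plus analytic gradients (Blondel-Karplus form).

    Returns ``(phi, g1, g2, g3, g4)``; the four gradients sum to zero,
    so dihedral forces exert no net force or torque.
    """
    r1 = positions[..., quads[:, 0], :]
    r2 = positions[..., quads[:, 1], :]
    r3 = positions[..., quads[:, 2], :]
    r4 = positions[..., quads[:, 3], :]
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    n1sq = np.sum(n1 * n1, axis=-1)
    n2sq = np.sum(n2 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / b2n
    x = np.sum(n1 * n2, axis=-1)
    phi = np.arctan2(y, x)
    g1 = -(b2n / n1sq)[..., None] * n1
    g4 = (b2n / n2sq)[..., None] * n2
    p = (np.sum(b1 * b2, axis=-1) / b2n**2)[..., None]
    q = (np.sum(b3 * b2, axis=-1) / b2n**2)[..., None]
    g2 = -(1.0 + p) * g1 + q * g4
    g3 = p * g1 - (1.0 + q) * g4
    return phi, g1, g2, g3, g4
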