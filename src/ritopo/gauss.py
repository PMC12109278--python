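"""Closed-form Gauss linking kernels for piecewise-linear curves.

The mutual linking charge of two straight segments is the signed solid
angle of the spherical quadrilateral spanned by the four endpoint
directions, divided by 4*pi.  Summed over all segment pairs of two
closed oriented curves this yields the (integer) linking number Lk;
summed over distinct pairs of a single curve (times two) it yields the
writhe Wr.  All heavy loops are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = [
    "segment_pair_charge",
    "pair_charge_matrix",
    "curve_pair_sum",
    "writhe_sum",
]

_EPS = 1e-12


@njit(cache=True, fastmath=False)
def _pair_charge_scalar(p1x, p1y, p1z, p2x, p2y, p2z,
                        q1x, q1y, q1z, q2x, q2y, q2z):
    # relative endpoint vectors
    r13x, r13y, r13z = q1x - p1x, q1y - p1y, q1z - p1z
    r14x, r14y, r14z = q2x - p1x, q2y - p1y, q2z - p1z
    r23x, r23y, r23z = q1x - p2x, q1y - p2y, q1z - p2z
    r24x, r24y, r24z = q2x - p2x, q2y - p2y, q2z - p2z

    # unit normals of the four faces of the spherical quadrilateral
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    a1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    a2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    a3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    a4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if a1 < _EPS or a2 < _EPS or a3 < _EPS or a4 < _EPS:
        # coplanar / collinear configuration: solid angle vanishes
        return 0.0

    d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (a1 * a2)
    d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (a2 * a3)
    d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (a3 * a4)
    d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (a4 * a1)
    d12 = min(1.0, max(-1.0, d12))
    d23 = min(1.0, max(-1.0, d23))
    d34 = min(1.0, max(-1.0, d34))
    d41 = min(1.0, max(-1.0, d41))

    omega = (np.arcsin(d12) + np.arcsin(d23)
             + np.arcsin(d34) + np.arcsin(d41))

    # sign: (q2-q1) x (p2-p1) . r13
    ux, uy, uz = q2x - q1x, q2y - q1y, q2z - q1z
    vx, vy, vz = p2x - p1x, p2y - p1y, p2z - p1z
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    s = cx * r13x + cy * r13y + cz * r13z
    if s > 0.0:
        return omega / (4.0 * np.pi)
    elif s < 0.0:
        return -omega / (4.0 * np.pi)
    return 0.0


@njit(cache=True)
def _charge_matrix_kernel(a0, a1, b0, b1):
    na = a0.shape[0]
    nb = b0.shape[0]
    out = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            out[i, j] = _pair_charge_scalar(
                a0[i, 0], a0[i, 1], a0[i, 2], a1[i, 0], a1[i, 1], a1[i, 2],
                b0[j, 0], b0[j, 1], b0[j, 2], b1[j, 0], b1[j, 1], b1[j, 2])
    return out


@njit(cache=True)
def _curve_pair_sum_kernel(a0, a1, b0, b1):
    na = a0.shape[0]
    nb = b0.shape[0]
    total = 0.0
    for i in range(na):
        for j in range(nb):
            total += _pair_charge_scalar(
                a0[i, 0], a0[i, 1], a0[i, 2], a1[i, 0], a1[i, 1], a1[i, 2],
                b0[j, 0], b0[j, 1], b0[j, 2], b1[j, 0], b1[j, 1], b1[j, 2])
    return total


@njit(cache=True)
def _writhe_kernel(s0, s1):
    n = s0.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # cyclically adjacent
            total += _pair_charge_scalar(
                s0[i, 0], s0[i, 1], s0[i, 2], s1[i, 0], s1[i, 1], s1[i, 2],
                s0[j, 0], s0[j, 1], s0[j, 2], s1[j, 0], s1[j, 1], s1[j, 2])
    return 2.0 * total


def segments_of(points: np.ndarray, closed: bool):
    """Return (starts, ends) arrays of the segments of a polyline.

    A closed curve with n points has n segments (the last one wrapping
    back to the first point); an open curve has n - 1.
    """
    pts = np.asarray(points, dtype=np.float64)
    if closed:
        return pts, np.roll(pts, -1, axis=0)
    return pts[:-1], pts[1:]


def segment_pair_charge(seg1_start, seg1_end, seg2_start, seg2_end) -> float:
    """Linking charge Omega/(4*pi) of two oriented straight segments.

    Antisymmetric under reversal of either segment's orientation.
    Raises for zero-length or touching segments.
    """
    p1 = np.asarray(seg1_start, dtype=np.float64)
    p2 = np.asarray(seg1_end, dtype=np.float64)
    q1 = np.asarray(seg2_start, dtype=np.float64)
    q2 = np.asarray(seg2_end, dtype=np.float64)
    if np.linalg.norm(p2 - p1) < _EPS or np.linalg.norm(q2 - q1) < _EPS:
        raise ValueError("zero-length segment")
    from .collisions import segment_distance
    if segment_distance(p1, p2, q1, q2) < 1e-9:
        raise ValueError("degenerate geometry: segments touch or intersect")
    return float(_pair_charge_scalar(
        p1[0], p1[1], p1[2], p2[0], p2[1], p2[2],
        q1[0], q1[1], q1[2], q2[0], q2[1], q2[2]))


def pair_charge_matrix(pointsA: np.ndarray, pointsB: np.ndarray,
                       closedA: bool = True, closedB: bool = True) -> np.ndarray:
    """Matrix of per-segment-pair linking charges between two curves."""
    a0, a1 = segments_of(pointsA, closedA)
    b0, b1 = segments_of(pointsB, closedB)
    return _charge_matrix_kernel(np.ascontiguousarray(a0), np.ascontiguousarray(a1),
                                 np.ascontiguousarray(b0), np.ascontiguousarray(b1))


def curve_pair_sum(pointsA: np.ndarray, pointsB: np.ndarray,
                   closedA: bool = True, closedB: bool = True) -> float:
    """Total linking charge between two curves (Lk when both closed)."""
    a0, a1 = segments_of(pointsA, closedA)
    b0, b1 = segments_of(pointsB, closedB)
    return float(_curve_pair_sum_kernel(
        np.ascontiguousarray(a0), np.ascontiguousarray(a1),
        np.ascontiguousarray(b0), np.ascontiguousarray(b1)))


def writhe_sum(points: np.ndarray, closed: bool = True) -> float:
    """Writhe of a polyline: Gauss self-integral over distinct segment pairs."""
    s0, s1 = segments_of(points, closed)
    if closed:
        return float(_writhe_kernel(np.ascontiguousarray(s0),
                                    np.ascontiguousarray(s1)))
    # open curve: no cyclic adjacency to skip; reuse kernel on padded logic
    n = s0.shape[0]
    total = 0.0
    m = _charge_matrix_kernel(np.ascontiguousarray(s0), np.ascontiguousarray(s1),
                              np.ascontiguousarray(s0), np.ascontiguousarray(s1))
    iu = np.triu_indices(n, k=2)
    total = 2.0 * float(m[iu].sum())
    return total
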