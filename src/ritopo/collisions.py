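"""Juxtaposition (collision) detection on reduced midpoint curves.

A collision is a pair of contour-distal duplex sites brought within a
cutoff distance (default 10 nm, the size of a protein bridging two DNA
sites).  Sites live on *reduced midpoint curves*: one point per base
pair midway between the paired strands, subsampled every 10 nt (about
one helical turn).  Events are the strict local minima of the
segment-segment distance landscape, classified into four types by
region, and assigned a chirality and a topological sign from the local
crossing geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .curves import (REGION_DAUGHTER1, REGION_DAUGHTER2, REGION_UNREPLICATED,
                     DuplexConformation, ReplicationIntermediate,
                     TrajectoryFrame)

__all__ = [
    "ReducedCurve",
    "CollisionEvent",
    "IndeterminateCrossingError",
    "midpoint_curve",
    "reduce_curve",
    "segment_distance",
    "build_reduced_curves",
    "detect_collisions",
    "classify_type",
    "crossing_geometry",
    "tally",
]

CUTOFF_NM = 10.0
EXCLUSION_BP = 147      # one dsDNA persistence length (~50 nm) in bp
BRAID_WINDOW_BP = 100   # braid-coordinate window separating types 3 / 4


class IndeterminateCrossingError(ValueError):
    """Projected tangents are (anti)parallel: crossing geometry undefined."""


@dataclass
class ReducedCurve:
    """A subsampled duplex midpoint curve with contour bookkeeping."""

    points: np.ndarray
    source_nucleotide_indices: np.ndarray
    region_label: Optional[str] = None
    arc_coordinate: Optional[np.ndarray] = None  # bp along this curve
    closed: bool = False
    curve_id: str = "curve"
    # forks joined by the two ends of an open RI curve (None for circles)
    fork_at_start: Optional[int] = None
    fork_at_end: Optional[int] = None
    length_bp: Optional[float] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.source_nucleotide_indices = np.asarray(
            self.source_nucleotide_indices, dtype=np.int64)
        if self.arc_coordinate is None:
            self.arc_coordinate = self.source_nucleotide_indices.astype(float)
        if self.length_bp is None:
            self.length_bp = float(self.arc_coordinate[-1]
                                   if not self.closed else
                                   self.arc_coordinate[-1] + 1)

    @property
    def n_segments(self) -> int:
        return len(self.points) if self.closed else len(self.points) - 1

    def segment_endpoints(self):
        if self.closed:
            return self.points, np.roll(self.points, -1, axis=0)
        return self.points[:-1], self.points[1:]

    def segment_arc(self) -> np.ndarray:
        """Arc coordinate (bp) of each segment midpoint."""
        c = self.arc_coordinate
        if self.closed:
            nxt = np.roll(c, -1)
            nxt[-1] = self.length_bp  # wrap
            return 0.5 * (c + nxt)
        return 0.5 * (c[:-1] + c[1:])


@dataclass
class CollisionEvent:
    """A detected juxtaposition between two reduced-curve segments."""

    curve_i: str
    index_i: int
    curve_j: str
    index_j: int
    distance: float
    point_i: np.ndarray
    point_j: np.ndarray
    tangent_i: np.ndarray
    tangent_j: np.ndarray
    arc_i: float
    arc_j: float
    region_i: Optional[str] = None
    region_j: Optional[str] = None
    type: Optional[int] = None
    chirality: Optional[str] = None
    sign: Optional[int] = None
    frame_time: float = 0.0


def midpoint_curve(strandA_region, strandB_region, closed: bool = False,
                   region_label: Optional[str] = None,
                   start_index: int = 0) -> ReducedCurve:
    """Full-resolution midpoint curve of a paired duplex region."""
    a = np.asarray(strandA_region, dtype=np.float64)
    b = np.asarray(strandB_region, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired strand regions must have equal length")
    mid = 0.5 * (a + b)
    idx = np.arange(start_index, start_index + len(mid))
    return ReducedCurve(points=mid, source_nucleotide_indices=idx,
                        region_label=region_label, closed=closed,
                        arc_coordinate=np.arange(len(mid), dtype=float))


def reduce_curve(midpoints: ReducedCurve, step: int = 10,
                 offset: int = 0) -> ReducedCurve:
    """Keep every ``step``-th point of a midpoint curve, starting at
    ``offset``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    sel = np.arange(offset % step, len(midpoints.points), step)
    return ReducedCurve(
        points=midpoints.points[sel],
        source_nucleotide_indices=midpoints.source_nucleotide_indices[sel],
        region_label=midpoints.region_label,
        arc_coordinate=midpoints.arc_coordinate[sel],
        closed=midpoints.closed,
        curve_id=midpoints.curve_id,
        fork_at_start=midpoints.fork_at_start,
        fork_at_end=midpoints.fork_at_end,
        length_bp=midpoints.length_bp)


@njit(cache=True)
def _seg_dist_scalar(p1x, p1y, p1z, p2x, p2y, p2z,
                     q1x, q1y, q1z, q2x, q2y, q2z):
    # clamped minimum distance between segments p1-p2 and q1-q2
    d1x, d1y, d1z = p2x - p1x, p2y - p1y, p2z - p1z
    d2x, d2y, d2z = q2x - q1x, q2y - q1y, q2z - q1z
    rx, ry, rz = p1x - q1x, p1y - q1y, p1z - q1z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    if a <= 1e-18 and e <= 1e-18:
        return np.sqrt(rx * rx + ry * ry + rz * rz)
    if a <= 1e-18:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= 1e-18:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > 1e-18:
                s = min(1.0, max(0.0, (b * f - c * e) / denom))
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    cx = p1x + s * d1x - (q1x + t * d2x)
    cy = p1y + s * d1y - (q1y + t * d2y)
    cz = p1z + s * d1z - (q1z + t * d2z)
    return np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True)
def _seg_dist_params(p1, p2, q1, q2):
    """Clamped closest-approach parameters (s, t) of two segments."""
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-18 and e <= 1e-18:
        return 0.0, 0.0
    if a <= 1e-18:
        return 0.0, min(1.0, max(0.0, f / e))
    c = d1 @ r
    if e <= 1e-18:
        return min(1.0, max(0.0, -c / a)), 0.0
    b = d1 @ d2
    denom = a * e - b * b
    if denom > 1e-18:
        s = min(1.0, max(0.0, (b * f - c * e) / denom))
    else:
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    elif t > 1.0:
        t = 1.0
        s = min(1.0, max(0.0, (b - c) / a))
    return s, t


@njit(cache=True)
def _seg_dist_matrix(a0, a1, b0, b1):
    na = a0.shape[0]
    nb = b0.shape[0]
    out = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            out[i, j] = _seg_dist_scalar(
                a0[i, 0], a0[i, 1], a0[i, 2], a1[i, 0], a1[i, 1], a1[i, 2],
                b0[j, 0], b0[j, 1], b0[j, 2], b1[j, 0], b1[j, 1], b1[j, 2])
    return out


def segment_distance(p1, p2, q1, q2) -> float:
    """Minimum Euclidean distance between two closed straight segments."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    q1 = np.asarray(q1, dtype=np.float64)
    q2 = np.asarray(q2, dtype=np.float64)
    return float(_seg_dist_scalar(p1[0], p1[1], p1[2], p2[0], p2[1], p2[2],
                                  q1[0], q1[1], q1[2], q2[0], q2[1], q2[2]))


def build_reduced_curves(conformation, step: int = 10,
                         offset: int = 0) -> list[ReducedCurve]:
    """Reduced midpoint curves of a conformation.

    One closed curve for a non-replicating duplex; three open curves
    (unreplicated, daughter 1, daughter 2) for an RI, each running
    between the two fork junctions.
    """
    if isinstance(conformation, DuplexConformation):
        full = midpoint_curve(conformation.strandA.points,
                              conformation.strandB.points, closed=True)
        full.curve_id = "duplex"
        red = reduce_curve(full, step, offset)
        return [red]
    if isinstance(conformation, ReplicationIntermediate):
        ri = conformation
        curves = []
        specs = [
            ("unrep", ri.a1, ri.b1, REGION_UNREPLICATED, 1, 0),
            ("daughter1", ri.a2,
             ri.daughter_new1.points if ri.daughter_new1 is not None else None,
             REGION_DAUGHTER1, 0, 1),
            ("daughter2", ri.b2,
             ri.daughter_new2.points if ri.daughter_new2 is not None else None,
             REGION_DAUGHTER2, 0, 1),
        ]
        for cid, sa, sb, label, f0, f1 in specs:
            if sb is None:
                # midpoint falls back to the stored axis
                if cid == "daughter1":
                    pts = ri.daughter1_axis_points
                else:
                    pts = ri.daughter2_axis_points
                full = ReducedCurve(points=pts,
                                    source_nucleotide_indices=np.arange(len(pts)),
                                    region_label=label,
                                    arc_coordinate=np.arange(len(pts), dtype=float))
            else:
                full = midpoint_curve(sa, sb, closed=False, region_label=label)
            full.curve_id = cid
            full.fork_at_start = f0
            full.fork_at_end = f1
            red = reduce_curve(full, step, offset)
            curves.append(red)
        return curves
    raise TypeError(f"unsupported conformation {type(conformation)!r}")


def _fork_graph_lengths(curves: Sequence[ReducedCurve]) -> dict:
    return {c.curve_id: float(c.length_bp) for c in curves}


def _contour_separation(ci: ReducedCurve, ai: float, cj: ReducedCurve,
                        aj: float, lengths: dict) -> float:
    """Contour distance in bp between two sites, through fork junctions."""
    if ci.curve_id == cj.curve_id:
        direct = abs(ai - aj)
        if ci.closed:
            return min(direct, ci.length_bp - direct)
        if ci.fork_at_start is None:
            return direct
        # alternative route out one end, through another curve, back the other
        other = min((lengths[c] for c in lengths if c != ci.curve_id),
                    default=np.inf)
        around = min(ai, aj) + other + (ci.length_bp - max(ai, aj))
        return min(direct, around)
    # different curves of an RI: shortest path through a shared fork
    best = np.inf
    ends_i = ((ci.fork_at_start, ai), (ci.fork_at_end, ci.length_bp - ai))
    ends_j = ((cj.fork_at_start, aj), (cj.fork_at_end, cj.length_bp - aj))
    for fi, di in ends_i:
        for fj, dj in ends_j:
            if fi is None or fj is None:
                continue
            hop = 0.0 if fi == fj else min(lengths.values())
            best = min(best, di + hop + dj)
    return best


def crossing_geometry(point_i, point_j, tangent_i, tangent_j,
                      angle_tol_deg: float = 1.0):
    """Chirality and topological sign of a juxtaposition.

    The view axis points from the underlying site toward the overlying
    one.  Chirality follows the rotation of the underlying *line* onto
    the overlying line about the view axis: a counter-clockwise angle
    below 90 degrees is left-handed, above is right-handed.  The sign
    follows the sense of the rotation carrying the overlying tangent
    onto the underlying tangent: counter-clockwise is +, clockwise is -.
    Both outputs are invariant under swapping the two sites.
    """
    pi = np.asarray(point_i, dtype=np.float64)
    pj = np.asarray(point_j, dtype=np.float64)
    v = pi - pj
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise IndeterminateCrossingError("coincident collision points")
    v = v / nv
    t_over = np.asarray(tangent_i, dtype=np.float64)
    t_under = np.asarray(tangent_j, dtype=np.float64)

    def _proj(t):
        p = t - np.dot(t, v) * v
        n = np.linalg.norm(p)
        if n < 1e-9:
            raise IndeterminateCrossingError("tangent parallel to view axis")
        return p / n

    po = _proj(t_over)
    pu = _proj(t_under)
    sin_ou = float(np.dot(np.cross(po, pu), v))
    cos_ou = float(np.dot(po, pu))
    psi = np.arctan2(sin_ou, cos_ou)  # over -> under, CCW positive about +v
    tol = np.deg2rad(angle_tol_deg)
    if abs(psi) < tol or abs(abs(psi) - np.pi) < tol:
        raise IndeterminateCrossingError("projected tangents (anti)parallel")

    # chirality from the unoriented line angle, under -> over
    theta = np.arctan2(-sin_ou, cos_ou) % np.pi  # in (0, pi)
    chirality = "left" if theta < np.pi / 2 else "right"
    sign = 1 if psi > 0 else -1
    return chirality, sign


def detect_collisions(frame, cutoff: float = CUTOFF_NM,
                      exclusion_bp: float = EXCLUSION_BP,
                      step: int = 10, offset: int = 0,
                      braid_window_bp: float = BRAID_WINDOW_BP,
                      drop_indeterminate: bool = True) -> list[CollisionEvent]:
    """Detect juxtaposition events on the reduced midpoint curves.

    Events are strict 2D local minima of the segment-pair distance
    landscape that lie within ``cutoff`` nm; pairs closer than
    ``exclusion_bp`` along the molecular contour (through the forks for
    RIs) are not admissible.
    """
    if isinstance(frame, TrajectoryFrame):
        conf = frame.conformation
        time = frame.time
    else:
        conf = frame
        time = 0.0
    curves = build_reduced_curves(conf, step=step, offset=offset)
    lengths = _fork_graph_lengths(curves)
    events: list[CollisionEvent] = []
    for a in range(len(curves)):
        for b in range(a, len(curves)):
            events.extend(_detect_pair(curves[a], curves[b], lengths, cutoff,
                                       exclusion_bp, time, drop_indeterminate))
    if isinstance(conf, ReplicationIntermediate):
        for ev in events:
            classify_type(ev, conf, braid_window_bp=braid_window_bp)
    return events


def _detect_pair(cu: ReducedCurve, cv: ReducedCurve, lengths: dict,
                 cutoff: float, exclusion_bp: float, time: float,
                 drop_indeterminate: bool) -> list[CollisionEvent]:
    a0, a1 = cu.segment_endpoints()
    b0, b1 = cv.segment_endpoints()
    D = _seg_dist_matrix(np.ascontiguousarray(a0), np.ascontiguousarray(a1),
                         np.ascontiguousarray(b0), np.ascontiguousarray(b1))
    arc_u = cu.segment_arc()
    arc_v = cv.segment_arc()
    same = cu.curve_id == cv.curve_id
    nu, nv = D.shape

    admissible = np.ones_like(D, dtype=bool)
    for i in range(nu):
        for j in range(nv):
            if same and j <= i:
                admissible[i, j] = False
                continue
            sep = _contour_separation(cu, arc_u[i], cv, arc_v[j], lengths)
            if sep <= exclusion_bp:
                admissible[i, j] = False
    candidates = []
    for i in range(nu):
        for j in range(nv):
            if not admissible[i, j] or D[i, j] > cutoff:
                continue
            if _is_local_min(D, i, j, cu.closed, cv.closed):
                candidates.append((i, j))
    # plateau tie-break: keep the lexicographically smallest of equal pairs
    kept = []
    cand = set(candidates)
    for (i, j) in candidates:
        tie_lower = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = _wrap(i + di, nu, cu.closed), _wrap(j + dj, nv, cv.closed)
                if ii is None or jj is None or (ii, jj) == (i, j):
                    continue
                if (ii, jj) in cand and D[ii, jj] == D[i, j] and (ii, jj) < (i, j):
                    tie_lower = True
        if not tie_lower:
            kept.append((i, j))

    events = []
    for (i, j) in kept:
        s, t = _seg_dist_params(a0[i], a1[i], b0[j], b1[j])
        p_i = a0[i] + s * (a1[i] - a0[i])
        p_j = b0[j] + t * (b1[j] - b0[j])
        t_i = a1[i] - a0[i]
        t_j = b1[j] - b0[j]
        ev = CollisionEvent(
            curve_i=cu.curve_id, index_i=int(i),
            curve_j=cv.curve_id, index_j=int(j),
            distance=float(D[i, j]), point_i=p_i, point_j=p_j,
            tangent_i=t_i / np.linalg.norm(t_i),
            tangent_j=t_j / np.linalg.norm(t_j),
            arc_i=float(arc_u[i]), arc_j=float(arc_v[j]),
            region_i=cu.region_label, region_j=cv.region_label,
            frame_time=time)
        try:
            ev.chirality, ev.sign = crossing_geometry(
                ev.point_i, ev.point_j, ev.tangent_i, ev.tangent_j)
        except IndeterminateCrossingError:
            if drop_indeterminate:
                continue
        events.append(ev)
    return events


def _wrap(k: int, n: int, closed: bool):
    if closed:
        return k % n
    if 0 <= k < n:
        return k
    return None


def _is_local_min(D: np.ndarray, i: int, j: int, closed_u: bool,
                  closed_v: bool) -> bool:
    nu, nv = D.shape
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii = _wrap(i + di, nu, closed_u)
            jj = _wrap(j + dj, nv, closed_v)
            if ii is None or jj is None:
                continue
            if D[ii, jj] < D[i, j]:
                return False
    return True


def classify_type(event: CollisionEvent, ri: ReplicationIntermediate,
                  braid_window_bp: float = BRAID_WINDOW_BP) -> int:
    """Assign collision type 1-4 from the region labels of the two sites.

    Both sites unreplicated: type 1.  Mixed: type 2.  Both replicated:
    type 3 within ``braid_window_bp`` of braid-coordinate separation
    (a precatenane contact), type 4 beyond it (a contact created by
    plectonemic folding of the braid).
    """
    ri_labels = (REGION_DAUGHTER1, REGION_DAUGHTER2)
    li, lj = event.region_i, event.region_j
    if li is None or lj is None:
        raise ValueError("collision event lacks region labels")
    unrep_i = li == REGION_UNREPLICATED
    unrep_j = lj == REGION_UNREPLICATED
    if unrep_i and unrep_j:
        event.type = 1
    elif unrep_i or unrep_j:
        event.type = 2
    else:
        if li not in ri_labels or lj not in ri_labels:
            raise ValueError(f"unexpected region labels {li!r}, {lj!r}")
        # braid coordinate: arc position along the replicated region
        # measured from the fork at coordinate 0 of each daughter curve
        if abs(event.arc_i - event.arc_j) <= braid_window_bp:
            event.type = 3
        else:
            event.type = 4
    return event.type


def tally(events: Sequence[CollisionEvent]):
    """Count events per (type, chirality); returns a pandas DataFrame."""
    import pandas as pd

    counts = {(t, c): 0 for t in (1, 2, 3, 4) for c in ("left", "right")}
    for ev in events:
        t = ev.type if ev.type is not None else 1
        if ev.chirality is None:
            continue
        counts[(t, ev.chirality)] += 1
    df = pd.DataFrame(
        {"left": [counts[(t, "left")] for t in (1, 2, 3, 4)],
         "right": [counts[(t, "right")] for t in (1, 2, 3, 4)]},
        index=pd.Index([1, 2, 3, 4], name="type"))
    df["total"] = df["left"] + df["right"]
    return df
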