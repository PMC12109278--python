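"""Readers and writers for oxDNA-style topology/configuration text files.

Conformations are stored with one particle per nucleotide.  The
topology file holds per-nucleotide strand membership and 3'/5'
neighbours (circular strands close via the neighbour fields); each
configuration block holds a time header, box and energy lines, then one
line per nucleotide with position, base vector, base-normal vector,
velocity and angular velocity.  Positions convert between nm (internal)
and oxDNA length units (0.8518 nm per unit).  Region membership of a
replication intermediate is not expressible in plain topology files, so
a sidecar JSON region map is written and read alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .curves import (REGION_DAUGHTER1, REGION_DAUGHTER2, DuplexConformation,
                     ReplicationIntermediate, StrandCurve, TrajectoryFrame)

__all__ = ["read_oxdna", "write_oxdna", "OXDNA_LENGTH_NM",
           "region_map_path", "OxdnaFormatError"]

OXDNA_LENGTH_NM = 0.8518


class OxdnaFormatError(ValueError):
    pass


def region_map_path(topology_path) -> Path:
    return Path(str(topology_path) + ".regions.json")


def _unit_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def _tangents(points: np.ndarray, closed: bool) -> np.ndarray:
    if closed:
        t = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    else:
        t = np.empty_like(points)
        t[1:-1] = points[2:] - points[:-2]
        t[0] = points[1] - points[0]
        t[-1] = points[-1] - points[-2]
    return _unit_rows(t)


def _strand_records(conf):
    """Yield (points, closed, partner_points, role) per output strand."""
    if isinstance(conf, DuplexConformation):
        yield conf.strandA.points, True, conf.strandB.points, "strandA"
        yield conf.strandB.points, True, conf.strandA.points, "strandB"
        return
    if isinstance(conf, ReplicationIntermediate):
        ri = conf
        pa, pb = ri.parentalA.points, ri.parentalB.points
        # partner of a1 is b1; of a2 is daughter_new1, etc.
        partA = np.vstack([pb[:ri.n_unrep],
                           ri.daughter_new1.points if ri.daughter_new1 is not None
                           else pa[ri.n_unrep:]])
        partB = np.vstack([pa[:ri.n_unrep],
                           ri.daughter_new2.points if ri.daughter_new2 is not None
                           else pb[ri.n_unrep:]])
        yield pa, True, partA, "parentalA"
        yield pb, True, partB, "parentalB"
        if ri.daughter_new1 is not None:
            yield (ri.daughter_new1.points, False, pa[ri.n_unrep:],
                   "daughter_new1")
        if ri.daughter_new2 is not None:
            yield (ri.daughter_new2.points, False, pb[ri.n_unrep:],
                   "daughter_new2")
        return
    raise TypeError(f"unsupported conformation {type(conf)!r}")


def write_oxdna(frames, topology_path, configuration_path,
                length_unit_nm: float = OXDNA_LENGTH_NM) -> None:
    """Write one or more frames as an oxDNA topology/configuration pair.

    Base vectors point toward the paired strand; base normals follow the
    local backbone tangent; velocities are zeros.  For a replication
    intermediate a region-map JSON sidecar is written next to the
    topology file.
    """
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    conf0 = frames[0].conformation

    strands = list(_strand_records(conf0))
    n_nt = sum(len(pts) for pts, _, _, _ in strands)

    top_lines = [f"{n_nt} {len(strands)}"]
    nid = 0
    for sid, (pts, closed, _, _) in enumerate(strands, start=1):
        n = len(pts)
        for i in range(n):
            three = nid + i - 1
            five = nid + i + 1
            if i == 0:
                three = nid + n - 1 if closed else -1
            if i == n - 1:
                five = nid if closed else -1
            top_lines.append(f"{sid} A {three} {five}")
        nid += n
    Path(topology_path).write_text("\n".join(top_lines) + "\n")

    scale = 1.0 / length_unit_nm
    all_pts = np.vstack([pts for pts, _, _, _ in strands])
    box = max(1.0, 2.2 * float(np.abs(all_pts).max()) * scale)
    out = []
    for frame in frames:
        conf = frame.conformation
        recs = list(_strand_records(conf))
        if sum(len(p) for p, _, _, _ in recs) != n_nt:
            raise OxdnaFormatError("frames have differing nucleotide counts")
        out.append(f"t = {frame.time}")
        out.append(f"b = {box:.4f} {box:.4f} {box:.4f}")
        out.append("E = 0 0 0")
        for pts, closed, partner, _ in recs:
            bvec = _unit_rows(partner - pts)
            nvec = _tangents(pts, closed)
            for p, b, nv in zip(pts * scale, bvec, nvec):
                out.append(
                    f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} "
                    f"{b[0]:.6f} {b[1]:.6f} {b[2]:.6f} "
                    f"{nv[0]:.6f} {nv[1]:.6f} {nv[2]:.6f} "
                    "0 0 0 0 0 0")
    Path(configuration_path).write_text("\n".join(out) + "\n")

    meta = {"helical_repeat_h": getattr(conf0, "helical_repeat_h", 10.5)}
    if isinstance(conf0, DuplexConformation):
        meta.update(kind="duplex", n_bp=conf0.n_bp,
                    strand_roles={"1": "strandA", "2": "strandB"})
    else:
        meta.update(kind="replication_intermediate",
                    n_unrep=conf0.n_unrep, n_rep=conf0.n_rep,
                    strand_roles={str(i + 1): role for i, (_, _, _, role)
                                  in enumerate(strands)},
                    regions={
                        "unreplicated": [[0, conf0.n_unrep]],
                        REGION_DAUGHTER1: [[conf0.n_unrep, conf0.n_bp_total]],
                        REGION_DAUGHTER2: [[conf0.n_unrep, conf0.n_bp_total]],
                    })
    region_map_path(topology_path).write_text(json.dumps(meta, indent=1))


def _parse_topology(topology_path):
    lines = Path(topology_path).read_text().splitlines()
    if not lines:
        raise OxdnaFormatError(f"{topology_path}: empty topology")
    try:
        n_nt, n_strands = (int(x) for x in lines[0].split()[:2])
    except ValueError as err:
        raise OxdnaFormatError(
            f"{topology_path}:1: bad header {lines[0]!r}") from err
    if len(lines) < n_nt + 1:
        raise OxdnaFormatError(
            f"{topology_path}: expected {n_nt} nucleotide records, "
            f"found {len(lines) - 1}")
    strand_of = np.empty(n_nt, dtype=np.int64)
    three = np.empty(n_nt, dtype=np.int64)
    five = np.empty(n_nt, dtype=np.int64)
    for i in range(n_nt):
        parts = lines[1 + i].split()
        try:
            strand_of[i] = int(parts[0])
            three[i] = int(parts[2])
            five[i] = int(parts[3])
        except (IndexError, ValueError) as err:
            raise OxdnaFormatError(
                f"{topology_path}:{i + 2}: bad record {lines[1 + i]!r}") from err
    return n_nt, n_strands, strand_of, three, five


def read_oxdna(topology_path, configuration_path, region_map=None,
               length_unit_nm: float = OXDNA_LENGTH_NM):
    """Read an oxDNA topology/configuration pair into trajectory frames.

    Returns one TrajectoryFrame per configuration block.  Velocities are
    ignored.  ``region_map`` may be a path or dict; by default the
    sidecar next to the topology file is used when present.
    """
    n_nt, n_strands, strand_of, three, five = _parse_topology(topology_path)

    if region_map is None:
        side = region_map_path(topology_path)
        region_map = json.loads(side.read_text()) if side.exists() else {}
    elif not isinstance(region_map, dict):
        region_map = json.loads(Path(region_map).read_text())

    lines = Path(configuration_path).read_text().splitlines()
    frames = []
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].lstrip().startswith("t"):
            raise OxdnaFormatError(
                f"{configuration_path}:{i + 1}: expected 't = ...' header, "
                f"got {lines[i]!r}")
        try:
            time = float(lines[i].split("=", 1)[1])
        except (IndexError, ValueError) as err:
            raise OxdnaFormatError(
                f"{configuration_path}:{i + 1}: bad time header") from err
        i += 3  # skip box and energy lines
        if i + n_nt > len(lines):
            raise OxdnaFormatError(
                f"{configuration_path}: truncated block at line {i + 1}: "
                f"need {n_nt} nucleotide lines")
        pos = np.empty((n_nt, 3))
        for k in range(n_nt):
            parts = lines[i + k].split()
            try:
                pos[k] = [float(parts[0]), float(parts[1]), float(parts[2])]
            except (IndexError, ValueError) as err:
                raise OxdnaFormatError(
                    f"{configuration_path}:{i + k + 1}: non-numeric "
                    f"position in {lines[i + k]!r}") from err
        pos *= length_unit_nm
        frames.append(TrajectoryFrame(
            time=time,
            conformation=_build_conformation(pos, strand_of, three, five,
                                             region_map)))
        i += n_nt
    if not frames:
        raise OxdnaFormatError(f"{configuration_path}: no frames found")
    return frames


def _build_conformation(pos, strand_of, three, five, meta):
    sids = sorted(set(strand_of.tolist()))
    by_strand = {}
    closed = {}
    for sid in sids:
        idx = np.nonzero(strand_of == sid)[0]
        by_strand[sid] = pos[idx]
        first, last = idx[0], idx[-1]
        closed[sid] = (three[first] == last) or (five[last] == first)
    h = float(meta.get("helical_repeat_h", 10.5))
    kind = meta.get("kind")
    if kind is None:
        kind = "duplex" if len(sids) == 2 else "replication_intermediate"
    if kind == "duplex":
        if len(sids) != 2:
            raise OxdnaFormatError("duplex requires exactly 2 strands")
        a, b = (by_strand[s] for s in sids[:2])
        if len(a) != len(b):
            raise OxdnaFormatError(
                f"strand lengths differ: {len(a)} vs {len(b)}")
        return DuplexConformation(
            strandA=StrandCurve(a, closed=closed[sids[0]]),
            strandB=StrandCurve(b, closed=closed[sids[1]]),
            n_bp=len(a), helical_repeat_h=h)
    if len(sids) < 2:
        raise OxdnaFormatError("replication intermediate needs >= 2 strands")
    roles = meta.get("strand_roles",
                     {str(s): r for s, r in zip(
                         sids, ["parentalA", "parentalB",
                                "daughter_new1", "daughter_new2"])})
    role_of = {roles.get(str(s), f"strand{s}"): s for s in sids}
    n_unrep = int(meta.get("n_unrep"))
    n_rep = int(meta.get("n_rep"))
    pa = by_strand[role_of["parentalA"]]
    pb = by_strand[role_of["parentalB"]]
    d1 = by_strand.get(role_of.get("daughter_new1"))
    d2 = by_strand.get(role_of.get("daughter_new2"))
    return ReplicationIntermediate(
        parentalA=StrandCurve(pa, closed=True),
        parentalB=StrandCurve(pb, closed=True),
        daughter_new1=(StrandCurve(d1, region_label=REGION_DAUGHTER1)
                       if d1 is not None else None),
        daughter_new2=(StrandCurve(d2, region_label=REGION_DAUGHTER2)
                       if d2 is not None else None),
        n_unrep=n_unrep, n_rep=n_rep, helical_repeat_h=h)
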