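"""oxDNA topology/configuration readers and writers: hand-written
minimal files, roundtrip identity, trajectories, and format errors."""

import numpy as np
import pytest

from ritopo import (TrajectoryFrame, make_relaxed_circle, read_oxdna,
                    write_oxdna)
from ritopo.curves import DuplexConformation, StrandCurve
from ritopo.oxdna import OXDNA_LENGTH_NM, OxdnaFormatError, region_map_path


def write_minimal_pair(tmp_path, n_blocks=1):
    """Hand-written 2-strand, 6-nt pair: two closed 3-point triangles."""
    top = tmp_path / "mini.top"
    dat = tmp_path / "mini.dat"
    top.write_text(
        "6 2\n"
        "1 A 2 1\n1 A 0 2\n1 A 1 0\n"
        "2 A 5 4\n2 A 3 5\n2 A 4 3\n")
    # positions in oxDNA units; strand separation ~2 nm per index
    tri = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [1.0, 1.7, 0.0]])
    tri2 = tri + [0.0, 0.0, 2.0 / OXDNA_LENGTH_NM]
    blocks = []
    for b in range(n_blocks):
        lines = [f"t = {100 * b}", "b = 50 50 50", "E = 0 0 0"]
        for p in np.vstack([tri, tri2]) + 0.01 * b:
            lines.append(f"{p[0]} {p[1]} {p[2]} 1 0 0 0 0 1 0 0 0 0 0 0")
        blocks.append("\n".join(lines))
    dat.write_text("\n".join(blocks) + "\n")
    return top, dat


def test_minimal_pair_reads_as_two_triangles(tmp_path):
    top, dat = write_minimal_pair(tmp_path)
    frames = read_oxdna(top, dat)
    assert len(frames) == 1
    conf = frames[0].conformation
    assert isinstance(conf, DuplexConformation)
    assert len(conf.strandA) == 3 and len(conf.strandB) == 3
    assert conf.strandA.closed and conf.strandB.closed
    # first point maps to nm via the length unit
    assert conf.strandA.points[1][0] == pytest.approx(2.0 * OXDNA_LENGTH_NM)


def test_two_blocks_give_two_frames_with_times(tmp_path):
    top, dat = write_minimal_pair(tmp_path, n_blocks=2)
    frames = read_oxdna(top, dat)
    assert [f.time for f in frames] == [0.0, 100.0]


def test_roundtrip_preserves_coordinates(tmp_path, relaxed_210):
    frame = TrajectoryFrame(time=0.0, conformation=relaxed_210)
    write_oxdna(frame, tmp_path / "c.top", tmp_path / "c.dat")
    back = read_oxdna(tmp_path / "c.top", tmp_path / "c.dat")
    conf = back[0].conformation
    assert np.abs(conf.strandA.points
                  - relaxed_210.strandA.points).max() < 1e-6
    assert conf.strandA.closed  # closure via the neighbour wrap


def test_21bp_circle_writes_42_records(tmp_path):
    # tiny hand-built circle (below the generator's minimum size)
    n = 21
    th = 2 * np.pi * np.arange(n) / n
    R = 8.0
    axis = np.c_[R * np.cos(th), R * np.sin(th), np.zeros(n)]
    e1 = np.c_[np.cos(th), np.sin(th), np.zeros(n)]
    ph = 2 * np.pi * 2 * np.arange(n) / n
    off = np.cos(ph)[:, None] * e1 + np.sin(ph)[:, None] * np.c_[
        np.zeros(n), np.zeros(n), np.ones(n)]
    conf = DuplexConformation(StrandCurve(axis + off, closed=True),
                              StrandCurve(axis - off, closed=True), n_bp=n)
    write_oxdna(TrajectoryFrame(0.0, conf), tmp_path / "s.top",
                tmp_path / "s.dat")
    lines = (tmp_path / "s.top").read_text().splitlines()
    assert lines[0].split()[0] == "42"
    assert len(lines) == 43


def test_ri_region_sidecar_roundtrip(tmp_path, early_ri):
    write_oxdna(TrajectoryFrame(0.0, early_ri), tmp_path / "ri.top",
                tmp_path / "ri.dat")
    assert region_map_path(tmp_path / "ri.top").exists()
    back = read_oxdna(tmp_path / "ri.top", tmp_path / "ri.dat")
    ri = back[0].conformation
    assert ri.n_unrep == 1491 and ri.n_rep == 509
    assert np.abs(ri.daughter_new1.points
                  - early_ri.daughter_new1.points).max() < 1e-6


def test_count_mismatch_names_the_problem(tmp_path):
    top, dat = write_minimal_pair(tmp_path)
    dat.write_text("\n".join(dat.read_text().splitlines()[:-2]) + "\n")
    with pytest.raises(OxdnaFormatError, match="truncated|need"):
        read_oxdna(top, dat)


def test_non_numeric_field_rejected(tmp_path):
    top, dat = write_minimal_pair(tmp_path)
    lines = dat.read_text().splitlines()
    lines[3] = lines[3].replace(lines[3].split()[0], "oops", 1)
    dat.write_text("\n".join(lines) + "\n")
    with pytest.raises(OxdnaFormatError, match="non-numeric"):
        read_oxdna(top, dat)
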