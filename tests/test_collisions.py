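"""Juxtaposition detection: segment distances, reduced curves, crossing
chirality/sign, type classification, and the fixture-level counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ritopo import (GeneratorConfig, PrescribedPartition, classify_type,
                    crossing_geometry, detect_collisions, make_ri,
                    midpoint_curve, reduce_curve, segment_distance, tally)
from ritopo.collisions import (CollisionEvent, IndeterminateCrossingError,
                               ReducedCurve, _detect_pair)
from ritopo.curves import (REGION_DAUGHTER1, REGION_DAUGHTER2,
                           REGION_UNREPLICATED, DuplexConformation,
                           StrandCurve)
from conftest import straight_duplex


class TestSegmentDistance:
    def test_parallel_offset(self):
        assert segment_distance([0, 0, 0], [1, 0, 0],
                                [0, 0, 3], [1, 0, 3]) == pytest.approx(3.0)

    def test_intersecting(self):
        assert segment_distance([-1, 0, 0], [1, 0, 0],
                                [0, -1, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_degenerate_point_fallback(self):
        assert segment_distance([0, 0, 0], [0, 0, 0],
                                [1, 0, 0], [1, 1, 0]) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_dense_sampling(self, seed):
        rng = np.random.default_rng(seed)
        p1, p2, q1, q2 = rng.uniform(-4, 4, size=(4, 3))
        d = segment_distance(p1, p2, q1, q2)
        u = np.linspace(0, 1, 400)
        pa = p1 + u[:, None] * (p2 - p1)
        qb = q1 + u[:, None] * (q2 - q1)
        brute = np.linalg.norm(pa[:, None, :] - qb[None, :, :], axis=2).min()
        assert d <= brute + 1e-12
        assert d == pytest.approx(brute, abs=1e-4 * max(1.0, brute))


class TestReducedCurves:
    def test_midpoints_on_constructed_axis(self):
        a, b, axis = straight_duplex(50)
        mc = midpoint_curve(a, b)
        assert np.abs(mc.points - axis).max() < 1e-9
        assert len(mc.points) == 50

    def test_circle_has_one_midpoint_per_bp(self, relaxed_210):
        mc = midpoint_curve(relaxed_210.strandA.points,
                            relaxed_210.strandB.points, closed=True)
        assert len(mc.points) == 210

    def test_ri_gives_three_curves(self, early_ri):
        from ritopo.collisions import build_reduced_curves
        curves = build_reduced_curves(early_ri, step=10)
        assert [c.curve_id for c in curves] == ["unrep", "daughter1",
                                                "daughter2"]
        assert [c.region_label for c in curves] == [
            REGION_UNREPLICATED, REGION_DAUGHTER1, REGION_DAUGHTER2]

    def test_reduction_counts(self):
        a, b, _ = straight_duplex(2000)
        full = midpoint_curve(a, b)
        assert len(reduce_curve(full, 10).points) == 200
        assert np.array_equal(reduce_curve(full, 1).points, full.points)
        a, b, _ = straight_duplex(509)
        assert len(reduce_curve(midpoint_curve(a, b), 10).points) == 51

    def test_consecutive_source_indices_step_apart(self):
        a, b, _ = straight_duplex(300)
        red = reduce_curve(midpoint_curve(a, b), 10)
        assert np.all(np.diff(red.source_nucleotide_indices) == 10)


class TestCrossingGeometry:
    def test_constructed_left_positive(self):
        # under-tangent +x; over-tangent 135 degrees clockwise of it,
        # seen from the over side: line angle 45 (left), and the over
        # strand rotates counter-clockwise onto the under strand (+)
        t_under = np.array([1.0, 0.0, 0.0])
        ang = -3 * np.pi / 4
        t_over = np.array([np.cos(ang), np.sin(ang), 0.0])
        chir, sign = crossing_geometry([0, 0, 5], [0, 0, 0], t_over, t_under)
        assert (chir, sign) == ("left", 1)

    def test_mirror_flips_both(self):
        t_under = np.array([1.0, 0.0, 0.0])
        ang = -3 * np.pi / 4
        t_over = np.array([np.cos(ang), np.sin(ang), 0.0])
        m = np.array([1.0, -1.0, 1.0])  # reflect through the xz-plane
        chir, sign = crossing_geometry([0, 0, 5] * m, [0, 0, 0] * m,
                                       t_over * m, t_under * m)
        assert (chir, sign) == ("right", -1)

    def test_double_orientation_reversal_keeps_sign(self):
        t_under = np.array([1.0, 0.0, 0.0])
        t_over = np.array([-0.5, 0.7, 0.1])
        c1, s1 = crossing_geometry([0, 0, 4], [0, 0, 0], t_over, t_under)
        c2, s2 = crossing_geometry([0, 0, 4], [0, 0, 0], -t_over, -t_under)
        assert (c1, s1) == (c2, s2)

    def test_swap_symmetric(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p_i, p_j = rng.uniform(-2, 2, (2, 3))
            t_i, t_j = rng.uniform(-1, 1, (2, 3))
            try:
                a = crossing_geometry(p_i, p_j, t_i, t_j)
                b = crossing_geometry(p_j, p_i, t_j, t_i)
            except IndeterminateCrossingError:
                continue
            assert a == b

    def test_parallel_projections_indeterminate(self):
        with pytest.raises(IndeterminateCrossingError):
            crossing_geometry([0, 0, 3], [0, 0, 0],
                              [1, 0, 0], [1, 0, 0])


def _line_curve(p0, direction, n=40, cid="c", region=None, arc0=0.0):
    d = np.asarray(direction, float)
    pts = np.asarray(p0, float) + np.arange(n)[:, None] * d
    return ReducedCurve(points=pts,
                        source_nucleotide_indices=np.arange(n) * 10,
                        region_label=region,
                        arc_coordinate=arc0 + 10.0 * np.arange(n),
                        curve_id=cid)


class TestDetection:
    def test_two_crossing_stretches_one_event(self):
        # two straight reduced curves crossing at 5 nm vertical offset
        cu = _line_curve([-60, 0, 0], [3.4, 0, 0], n=40, cid="u")
        cv = _line_curve([0, -60, 5], [0, 3.4, 0], n=40, cid="v")
        events = _detect_pair(cu, cv, {"u": 400.0, "v": 400.0}, 10.0, 147.0,
                              0.0, True)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(5.0, abs=0.2)

    def test_relaxed_circle_has_no_events(self, relaxed_210):
        assert detect_collisions(relaxed_210) == []

    def test_plectoneme_counts_and_handedness(self, plectoneme_5x):
        events = detect_collisions(plectoneme_5x)
        assert len(events) == pytest.approx(5, abs=1)
        assert all(e.chirality == "right" and e.sign == -1 for e in events)

    def test_mirror_plectoneme_flips(self, plectoneme_5x):
        m = np.array([1.0, 1.0, -1.0])
        mirrored = DuplexConformation(
            strandA=StrandCurve(plectoneme_5x.strandA.points * m, closed=True),
            strandB=StrandCurve(plectoneme_5x.strandB.points * m, closed=True),
            n_bp=plectoneme_5x.n_bp,
            axis=StrandCurve(plectoneme_5x.axis_points * m, closed=True,
                             region_label="axis"))
        events = detect_collisions(mirrored)
        assert events
        assert all(e.chirality == "left" and e.sign == 1 for e in events)

    def test_event_count_stable_under_phase_shift(self, plectoneme_5x):
        n0 = len(detect_collisions(plectoneme_5x, offset=0))
        n5 = len(detect_collisions(plectoneme_5x, offset=5))
        assert abs(n0 - n5) <= 1


def _event(region_i, region_j, arc_i=0.0, arc_j=0.0):
    return CollisionEvent(
        curve_i="i", index_i=0, curve_j="j", index_j=1, distance=5.0,
        point_i=np.zeros(3), point_j=np.array([0, 0, 5.0]),
        tangent_i=np.array([1.0, 0, 0]), tangent_j=np.array([0, 1.0, 0]),
        arc_i=arc_i, arc_j=arc_j, region_i=region_i, region_j=region_j)


class TestClassification:
    def test_type_rules(self, early_ri):
        u, d1, d2 = (REGION_UNREPLICATED, REGION_DAUGHTER1, REGION_DAUGHTER2)
        assert classify_type(_event(u, u), early_ri) == 1
        assert classify_type(_event(u, d1), early_ri) == 2
        assert classify_type(_event(d1, d2, 100, 120), early_ri) == 3
        assert classify_type(_event(d1, d2, 100, 500), early_ri) == 4

    def test_unlabeled_event_rejected(self, early_ri):
        with pytest.raises(ValueError):
            classify_type(_event(None, None), early_ri)

    def test_left_handed_precatenanes_fixture(self):
        # negative (in-vitro-like) precatenanes: left-handed type-3 mass
        cfg = GeneratorConfig(
            n_bp=2000, frac_replicated=509 / 2000, seed=3,
            prescribed_partition=PrescribedPartition(
                q_unrep=-8.0, q_wrap=0.0, q_rep=-2.0,
                precatenane_Ca=-2.0, braid_writhe=0.0))
        events = detect_collisions(make_ri(cfg))
        t3 = [e for e in events if e.type == 3]
        assert t3
        assert sum(e.chirality == "left" for e in t3) > len(t3) / 2


class TestTally:
    def test_empty_is_all_zero(self):
        df = tally([])
        assert df["total"].sum() == 0

    def test_plectoneme_mass_in_type1_right(self, plectoneme_5x):
        df = tally(detect_collisions(plectoneme_5x))
        assert df.loc[1, "right"] == df["total"].sum()
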