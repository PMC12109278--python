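"""Linking number, twist, writhe, the Calugareanu-White identity, and
the scalar descriptors (Lk0, dLk, sigma, radius of gyration)."""

import numpy as np
import pytest

from ritopo import (contribution_matrix, delta_lk, diagonal_band_profile,
                    linking_number, lk0, make_relaxed_circle, mc_relax,
                    plectoneme_axis, radius_of_gyration, sigma, twist, writhe)
from conftest import hopf_link, straight_duplex


class TestLinkingNumber:
    def test_hopf_link_is_unit(self):
        c1, c2 = hopf_link(64)
        assert abs(linking_number(c1, c2)) == pytest.approx(1.0, abs=1e-3)

    def test_separated_circles_unlinked(self):
        c1, c2 = hopf_link(64)
        assert linking_number(c1, c2 + [10, 0, 0]) == pytest.approx(0, abs=1e-6)

    def test_torus_link_2_4(self):
        t = np.linspace(0, 2 * np.pi, 401)[:-1]

        def comp(phase):
            R, r = 3.0, 1.0
            return np.c_[(R + r * np.cos(2 * t + phase)) * np.cos(t),
                         (R + r * np.cos(2 * t + phase)) * np.sin(t),
                         r * np.sin(2 * t + phase)]

        assert abs(linking_number(comp(0), comp(np.pi))) == pytest.approx(
            2.0, abs=1e-3)

    def test_rigid_motion_invariance(self):
        c1, c2 = hopf_link(64)
        lk = linking_number(c1, c2)
        ang = 0.7
        R = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                      [-np.sin(ang), 0, np.cos(ang)]])
        t = np.array([3.0, -2.0, 5.0])
        assert linking_number(c1 @ R.T + t, c2 @ R.T + t) == pytest.approx(
            lk, abs=1e-6)

    def test_open_curve_rejected(self):
        from ritopo import StrandCurve
        c1, c2 = hopf_link(16)
        with pytest.raises(ValueError):
            linking_number(StrandCurve(c1, closed=False),
                           StrandCurve(c2, closed=True))

    def test_matrix_total_equals_lk(self, relaxed_210):
        m = contribution_matrix(relaxed_210.strandA, relaxed_210.strandB)
        assert m.total == pytest.approx(20.0, abs=1e-3)
        # dominant charge hugs the main diagonal band
        prof = diagonal_band_profile(m, band_halfwidth_bp=15)
        assert prof["main_band_sum"] / m.total > 0.99


class TestWrithe:
    def test_planar_circle_zero(self):
        t = np.linspace(0, 2 * np.pi, 201)[:-1]
        circle = np.c_[np.cos(t), np.sin(t), np.zeros_like(t)]
        assert writhe(circle) == pytest.approx(0.0, abs=1e-6)

    def test_interwound_five_crossings(self):
        axis = plectoneme_axis(1200, -5.0, 1)
        assert writhe(axis) == pytest.approx(-5.0, abs=0.3)

    def test_mirror_image_negates(self):
        axis = plectoneme_axis(800, -3.0, 1)
        w = writhe(axis)
        assert writhe(axis * np.array([1, 1, -1])) == pytest.approx(
            -w, abs=1e-9)


class TestTwistAndWhite:
    def test_straight_duplex_ten_turns(self):
        a, b, axis = straight_duplex(106)
        assert twist(a, b, axis, closed=False) == pytest.approx(10.0, abs=1e-3)

    def test_relaxed_circle_white_identity(self, relaxed_210):
        tw = twist(relaxed_210.strandA.points, relaxed_210.strandB.points,
                   relaxed_210.axis_points, closed=True)
        wr = writhe(relaxed_210.axis_points)
        assert tw == pytest.approx(20.0, abs=1e-3)
        assert wr == pytest.approx(0.0, abs=1e-6)

    def test_white_identity_after_relaxation(self, relaxed_210):
        frames = mc_relax(relaxed_210, 4000, seed=3, n_snapshots=2)
        conf = frames[-1].conformation
        lk = linking_number(conf.strandA.points, conf.strandB.points)
        tw = twist(conf.strandA.points, conf.strandB.points,
                   conf.axis_points, closed=True)
        wr = writhe(conf.axis_points)
        assert tw + wr == pytest.approx(lk, abs=0.05)

    def test_zero_offset_rejected(self):
        a, b, axis = straight_duplex(20)
        with pytest.raises(ValueError):
            twist(axis, axis, axis, closed=False)


class TestScalars:
    def test_lk0_exact(self):
        assert lk0(2100, 10.5) == 200.0
        assert lk0(1491, 10.5) == 142.0

    def test_delta_lk_and_sigma(self):
        assert delta_lk(190, 2000 / 10.5) == pytest.approx(-0.47619, abs=1e-5)
        assert sigma(-10, 200) == -0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lk0(0, 10.5)
        with pytest.raises(ValueError):
            lk0(100, -1)
        with pytest.raises(ValueError):
            sigma(-10, 0)


class TestRadiusOfGyration:
    def test_ring(self):
        t = np.linspace(0, 2 * np.pi, 500)[:-1]
        ring = 7.5 * np.c_[np.cos(t), np.sin(t), np.zeros_like(t)]
        assert radius_of_gyration(ring) == pytest.approx(7.5, abs=1e-9)

    def test_single_point_and_pair(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0
        assert radius_of_gyration([[0, 0, 0], [4, 0, 0]]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestBandProfile:
    def test_band_width_validation(self, relaxed_210):
        m = contribution_matrix(relaxed_210.strandA, relaxed_210.strandB)
        with pytest.raises(ValueError):
            diagonal_band_profile(m, band_halfwidth_bp=200)

    def test_off_band_tracks_writhe(self, supercoiled_2000):
        m = contribution_matrix(supercoiled_2000.strandA,
                                supercoiled_2000.strandB)
        prof = diagonal_band_profile(m)
        wr = writhe(supercoiled_2000.axis_points)
        assert prof["off_band_sum"] == pytest.approx(wr, abs=0.5)
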