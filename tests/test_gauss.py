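"""The closed-form segment-pair linking charge against an independent
numerical quadrature of the Gauss integrand, plus its symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from ritopo import segment_pair_charge


def quadrature_charge(p1, p2, q1, q2, tol=1e-10):
    """Adaptive double quadrature of the Gauss linking integrand."""
    p1, p2, q1, q2 = (np.asarray(x, float) for x in (p1, p2, q1, q2))
    u = p2 - p1
    v = q2 - q1

    def integrand(t, s):
        r = (q1 + t * v) - (p1 + s * u)
        return float(np.dot(np.cross(v, u), r) / np.linalg.norm(r) ** 3)

    val, _ = integrate.dblquad(integrand, 0, 1, 0, 1,
                               epsabs=tol, epsrel=tol)
    return val / (4 * np.pi)


def random_pair(rng):
    while True:
        pts = rng.uniform(-3, 3, size=(4, 3))
        p1, p2, q1, q2 = pts
        if (np.linalg.norm(p2 - p1) > 0.3 and np.linalg.norm(q2 - q1) > 0.3):
            from ritopo import segment_distance
            if segment_distance(p1, p2, q1, q2) > 0.3:
                return p1, p2, q1, q2


@pytest.mark.parametrize("seed", range(6))
def test_matches_adaptive_quadrature(seed):
    rng = np.random.default_rng(seed)
    for _ in range(8):
        p1, p2, q1, q2 = random_pair(rng)
        exact = segment_pair_charge(p1, p2, q1, q2)
        quad = quadrature_charge(p1, p2, q1, q2)
        assert exact == pytest.approx(quad, abs=1e-6)


def test_antisymmetric_under_orientation_reversal():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p1, p2, q1, q2 = random_pair(rng)
        w = segment_pair_charge(p1, p2, q1, q2)
        assert segment_pair_charge(p2, p1, q1, q2) == pytest.approx(-w, abs=1e-14)
        assert segment_pair_charge(p1, p2, q2, q1) == pytest.approx(-w, abs=1e-14)
        assert segment_pair_charge(p2, p1, q2, q1) == pytest.approx(w, abs=1e-14)


def test_coplanar_segments_have_zero_charge():
    # solid angle vanishes when both segments lie in one plane
    assert segment_pair_charge([0, 0, 0], [1, 0, 0],
                               [0, 1, 0], [1, 2, 0]) == 0.0
    assert segment_pair_charge([0, 0, 1], [1, 1, 1],
                               [2, 0, 1], [3, -1, 1]) == 0.0


def test_degenerate_geometry_raises():
    with pytest.raises(ValueError):
        segment_pair_charge([0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0])
    with pytest.raises(ValueError):  # crossing segments
        segment_pair_charge([-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(-np.pi, np.pi),
       st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
def test_invariant_under_rigid_motion(seed, angle, tx, ty, tz):
    rng = np.random.default_rng(seed)
    p1, p2, q1, q2 = random_pair(rng)
    w = segment_pair_charge(p1, p2, q1, q2)
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    t = np.array([tx, ty, tz])
    moved = [x @ R.T + t for x in (p1, p2, q1, q2)]
    assert segment_pair_charge(*moved) == pytest.approx(w, abs=1e-9)
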