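"""Monte-Carlo relaxer: topological conservation, fork-controlled
charge redistribution, and trajectory plumbing.  Long-run conservation
at the full move budget lives in the acceptance suite; these runs are
shorter."""

import numpy as np
import pytest

from ritopo import (decompose_ri, linking_number, make_supercoiled_circle,
                    mc_relax, validate_excluded_volume)


@pytest.fixture(scope="module")
def small_circle():
    return make_supercoiled_circle(840, -4, 1, seed=3)


def test_closed_molecule_lk_invariant(small_circle):
    lk0 = linking_number(small_circle.strandA.points,
                         small_circle.strandB.points)
    frames = mc_relax(small_circle, 15000, seed=11, n_snapshots=3)
    for f in frames[1:]:
        c = f.conformation
        lk = linking_number(c.strandA.points, c.strandB.points)
        assert lk == pytest.approx(lk0, abs=0.05)
    # the molecule actually moved
    disp = np.linalg.norm(frames[-1].conformation.axis_points
                          - small_circle.axis_points, axis=1).max()
    assert disp > 1.0


def test_fixed_forks_conserve_region_charges(early_ri):
    d0 = decompose_ri(early_ri)
    frames = mc_relax(early_ri, 15000, forks_free=False, seed=5,
                      n_snapshots=2)
    d1 = decompose_ri(frames[-1].conformation)
    assert d1.delta_lk_total == pytest.approx(d0.delta_lk_total, abs=0.1)
    assert d1.q_unrep == pytest.approx(d0.q_unrep, abs=0.3)
    assert d1.q_rep == pytest.approx(d0.q_rep, abs=0.3)


def test_free_forks_conserve_total_only(early_ri):
    d0 = decompose_ri(early_ri)
    frames = mc_relax(early_ri, 20000, forks_free=True, seed=7,
                      n_snapshots=2)
    d1 = decompose_ri(frames[-1].conformation)
    assert d1.delta_lk_total == pytest.approx(d0.delta_lk_total, abs=0.1)


def test_zero_moves_returns_initial(small_circle):
    frames = mc_relax(small_circle, 0, seed=1)
    assert len(frames) == 1
    assert np.array_equal(frames[0].conformation.strandA.points,
                          small_circle.strandA.points)


def test_snapshot_times_monotonic(small_circle):
    frames = mc_relax(small_circle, 3000, seed=2, n_snapshots=5)
    times = [f.time for f in frames]
    assert times == sorted(times)
    assert times[-1] == 3000


def test_same_seed_reproduces(small_circle):
    f1 = mc_relax(small_circle, 2000, seed=9, n_snapshots=1)
    f2 = mc_relax(small_circle, 2000, seed=9, n_snapshots=1)
    assert np.array_equal(f1[-1].conformation.strandA.points,
                          f2[-1].conformation.strandA.points)


def test_generator_output_passes_guard(early_ri, late_ri):
    validate_excluded_volume(early_ri)
    validate_excluded_volume(late_ri)
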