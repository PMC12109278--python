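import numpy as np
import pytest

from ritopo import (early_invivo_config, late_invivo_config,
                    make_relaxed_circle, make_ri, make_supercoiled_circle)


@pytest.fixture(scope="session")
def early_ri():
    """Early-stage in-vivo replication intermediate (25% replicated)."""
    return make_ri(early_invivo_config(seed=1))


@pytest.fixture(scope="session")
def late_ri():
    """Late-stage in-vivo replication intermediate (75% replicated)."""
    return make_ri(late_invivo_config(seed=1))


@pytest.fixture(scope="session")
def relaxed_210():
    """Small torsionally relaxed circle (210 bp, Lk = 20)."""
    return make_relaxed_circle(210)


@pytest.fixture(scope="session")
def supercoiled_2000():
    """2 kb circle with a single interwound branch and dLk = -10."""
    return make_supercoiled_circle(2000, -10, 1, seed=1)


@pytest.fixture(scope="session")
def branched_2000():
    """2 kb circle with three plectonemic branches and dLk = -10."""
    return make_supercoiled_circle(2000, -10, 3, seed=1)


@pytest.fixture(scope="session")
def plectoneme_5x():
    """Negatively supercoiled circle whose axis carries ~5 crossings."""
    return make_supercoiled_circle(2000, -8, 1, seed=2)


def hopf_link(n=64):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    c1 = np.c_[np.cos(t), np.sin(t), np.zeros_like(t)]
    c2 = np.c_[1 + np.cos(t), np.zeros_like(t), np.sin(t)]
    return c1, c2


def straight_duplex(n_points=106, h=10.5, rise=0.34, radius=1.0):
    """Open straight duplex: n_points vertices, n_points - 1 segments."""
    z = np.arange(n_points) * rise
    phase = 2 * np.pi * np.arange(n_points) / h
    axis = np.c_[np.zeros(n_points), np.zeros(n_points), z]
    off = radius * np.c_[np.cos(phase), np.sin(phase), np.zeros(n_points)]
    return axis + off, axis - off, axis
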