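"""Topology-preserving Monte-Carlo relaxation of coarse-grained DNA.

Moves are crankshaft rotations of axis sub-chains (strands carried
rigidly) and, optionally, fork-swivel rotations that twist the
unreplicated duplex through a fork while counter-rotating the daughter
ends.  Acceptance is purely constraint-based: a move is rejected if it
brings contour-distal parts of the molecule closer than a hard-core
distance.  Together with a per-move displacement cap this forbids
strand passage, so the total linking number of a closed molecule (and
the total linking difference of a replication intermediate) is
conserved exactly; the per-region charges of an RI can change only
through fork swivels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .curves import (DuplexConformation, ReplicationIntermediate, StrandCurve,
                     TrajectoryFrame)

__all__ = ["mc_relax", "validate_excluded_volume", "RelaxError"]

AXIS_CORE_NM = 2.0      # hard core between contour-distal axis points
AXIS_MID_CORE_NM = 1.45  # softer core at contour separations 5-12 points
STRAND_CORE_FAR = 0.95   # parental A-B strand core, separation >= 9
STRAND_CORE_MID = 0.80   # ... separation 5-8 (bent superhelix caps)
STRAND_CORE_NEAR = 0.60  # ... separation <= 4 (junction-torsion guard)
NEAR_NM = 4.5            # axis distance triggering strand-level checks
LOCAL_WINDOW = 12        # contour window exempt from the distal axis core
MAX_DISP_NM = 0.35       # per-move displacement cap (passage-proofing)
MAX_BOND_NM = 1.05       # strand-bond stretch limit at move junctions


class RelaxError(RuntimeError):
    pass


@dataclass
class _System:
    ax: np.ndarray     # (N, 3) duplex axis points
    s1: np.ndarray     # (N, 3) first strand of each duplex unit
    s2: np.ndarray     # (N, 3) second strand
    sep: np.ndarray    # (N, N) uint8 contour separation (points), clipped
    mol1: np.ndarray   # (N,) int8 molecule id of s1 points
    mol2: np.ndarray   # (N,) int8 molecule id of s2 points
    closed: bool       # single closed duplex vs three open RI curves
    bounds: tuple      # curve boundaries: (n,) or (nu, nr)


def _cyclic_sep(n: int) -> np.ndarray:
    i = np.arange(n)
    d = np.abs(i[:, None] - i[None, :])
    d = np.minimum(d, n - d)
    return np.minimum(d, 255).astype(np.uint8)


def _ri_sep(nu: int, nr: int) -> np.ndarray:
    """Contour separation in points through the fork junctions.

    Curve coordinates: unreplicated 0..nu-1 (fork2 at 0, fork1 at
    nu-1); each daughter 0..nr-1 (fork1 at 0, fork2 at nr-1).  Crossing
    a fork costs one step.
    """
    cap = 255
    N = nu + 2 * nr
    iu = np.arange(nu)
    ir = np.arange(nr)
    # distances of each point to the two forks, in points
    d_f1 = {"u": nu - 1 - iu, "d": ir}
    d_f2 = {"u": iu, "d": nr - 1 - ir}
    sep = np.full((N, N), cap, dtype=np.int64)

    def block(sl_a, sl_b, val):
        cur = sep[sl_a, sl_b]
        np.minimum(cur, val, out=cur)
        sep[sl_a, sl_b] = cur

    su = slice(0, nu)
    s1 = slice(nu, nu + nr)
    s2 = slice(nu + nr, N)
    # same curve: direct distance
    block(su, su, np.abs(iu[:, None] - iu[None, :]))
    for sd in (s1, s2):
        block(sd, sd, np.abs(ir[:, None] - ir[None, :]))
    # unrep vs daughter: through either fork (one step to cross)
    for sd in (s1, s2):
        block(su, sd, d_f1["u"][:, None] + 1 + d_f1["d"][None, :])
        block(su, sd, d_f2["u"][:, None] + 1 + d_f2["d"][None, :])
    # daughter vs daughter: through either fork (two steps via junction)
    block(s1, s2, d_f1["d"][:, None] + 2 + d_f1["d"][None, :])
    block(s1, s2, d_f2["d"][:, None] + 2 + d_f2["d"][None, :])
    # the two forks sit a few nm apart; points near opposite forks are
    # neighbours through the fork gap (treated as ~8 contour steps)
    f_gap = 8
    df1_all = np.concatenate([d_f1["u"], d_f1["d"], d_f1["d"]])
    df2_all = np.concatenate([d_f2["u"], d_f2["d"], d_f2["d"]])
    via_gap = np.minimum(
        df1_all[:, None] + f_gap + df2_all[None, :],
        df2_all[:, None] + f_gap + df1_all[None, :])
    sep = np.minimum(sep, via_gap)
    sep = np.minimum(sep, sep.T)
    return np.minimum(sep, cap).astype(np.uint8)


def _system_from(conf) -> _System:
    if isinstance(conf, DuplexConformation):
        n = conf.n_bp
        return _System(
            ax=conf.axis_points.copy(), s1=conf.strandA.points.copy(),
            s2=conf.strandB.points.copy(), sep=_cyclic_sep(n),
            mol1=np.zeros(n, dtype=np.int8), mol2=np.ones(n, dtype=np.int8),
            closed=True, bounds=(n,))
    if isinstance(conf, ReplicationIntermediate):
        if conf.daughter_new1 is None or conf.daughter_new2 is None:
            raise RelaxError("mc_relax needs daughter strands on the RI")
        nu, nr = conf.n_unrep, conf.n_rep
        ax = np.vstack([conf.unrep_axis_points, conf.daughter1_axis_points,
                        conf.daughter2_axis_points])
        s1 = np.vstack([conf.a1, conf.a2, conf.b2])
        s2 = np.vstack([conf.b1, conf.daughter_new1.points,
                        conf.daughter_new2.points])
        mol1 = np.concatenate([np.zeros(nu), np.zeros(nr), np.ones(nr)])
        mol2 = np.concatenate([np.ones(nu), np.full(nr, 2), np.full(nr, 3)])
        return _System(ax=ax.copy(), s1=s1.copy(), s2=s2.copy(),
                       sep=_ri_sep(nu, nr), mol1=mol1.astype(np.int8),
                       mol2=mol2.astype(np.int8), closed=False,
                       bounds=(nu, nr))
    raise TypeError(f"unsupported conformation {type(conf)!r}")


def _conf_from(sys_: _System, template) -> object:
    if isinstance(template, DuplexConformation):
        return DuplexConformation(
            strandA=StrandCurve(sys_.s1.copy(), closed=True),
            strandB=StrandCurve(sys_.s2.copy(), closed=True),
            n_bp=template.n_bp, helical_repeat_h=template.helical_repeat_h,
            axis=StrandCurve(sys_.ax.copy(), closed=True, region_label="axis"))
    nu, nr = sys_.bounds
    t = template
    return ReplicationIntermediate(
        parentalA=StrandCurve(np.vstack([sys_.s1[:nu], sys_.s1[nu:nu + nr]]),
                              closed=True),
        parentalB=StrandCurve(np.vstack([sys_.s2[:nu],
                                         sys_.s1[nu + nr:]]), closed=True),
        daughter_new1=StrandCurve(sys_.s2[nu:nu + nr].copy(),
                                  region_label=t.daughter_new1.region_label),
        daughter_new2=StrandCurve(sys_.s2[nu + nr:].copy(),
                                  region_label=t.daughter_new2.region_label),
        n_unrep=nu, n_rep=nr, helical_repeat_h=t.helical_repeat_h,
        unrep_axis=StrandCurve(sys_.ax[:nu].copy(), region_label="axis"),
        daughter1_axis=StrandCurve(sys_.ax[nu:nu + nr].copy(),
                                   region_label="axis"),
        daughter2_axis=StrandCurve(sys_.ax[nu + nr:].copy(),
                                   region_label="axis"))


@njit(cache=True)
def _pair_violates(d2, sp, ax_far2, ax_mid2):
    if sp > 12:
        return d2 < ax_far2
    if sp >= 5:
        return d2 < ax_mid2
    return False


@njit(cache=True)
def _strand_core2(sp):
    if sp <= 4:
        return 0.36   # 0.60 ** 2
    if sp <= 8:
        return 0.64   # 0.80 ** 2
    return 0.9025     # 0.95 ** 2


@njit(cache=True)
def _guard_ok(ax, s1, s2, pax, ps1, ps2, idx, moved, sep, mol1, mol2,
              ax_far2, ax_mid2, near2):
    n = ax.shape[0]
    m = idx.shape[0]
    for a in range(m):
        i = idx[a]
        xi, yi, zi = pax[a, 0], pax[a, 1], pax[a, 2]
        for j in range(n):
            if moved[j]:
                continue
            dx = xi - ax[j, 0]
            dy = yi - ax[j, 1]
            dz = zi - ax[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= near2:
                continue
            sp = sep[i, j]
            if _pair_violates(d2, sp, ax_far2, ax_mid2):
                return False
            # parental A x parental B strand passage guard
            core2 = _strand_core2(sp)
            for u in range(2):
                if u == 0:
                    px, py, pz = ps1[a, 0], ps1[a, 1], ps1[a, 2]
                    mu = mol1[i]
                else:
                    px, py, pz = ps2[a, 0], ps2[a, 1], ps2[a, 2]
                    mu = mol2[i]
                if mu > 1:
                    continue
                for v in range(2):
                    if v == 0:
                        qx, qy, qz = s1[j, 0], s1[j, 1], s1[j, 2]
                        mv = mol1[j]
                    else:
                        qx, qy, qz = s2[j, 0], s2[j, 1], s2[j, 2]
                        mv = mol2[j]
                    if mv > 1 or mv == mu:
                        continue
                    ex = px - qx
                    ey = py - qy
                    ez = pz - qz
                    if ex * ex + ey * ey + ez * ez < core2:
                        return False
    return True


@njit(cache=True)
def _validate_kernel(ax, s1, s2, sep, mol1, mol2, ax_far2, ax_mid2, near2):
    n = ax.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = ax[i, 0] - ax[j, 0]
            dy = ax[i, 1] - ax[j, 1]
            dz = ax[i, 2] - ax[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= near2:
                continue
            sp = sep[i, j]
            if _pair_violates(d2, sp, ax_far2, ax_mid2):
                return i * n + j
            core2 = _strand_core2(sp)
            for u in range(2):
                if u == 0:
                    px, py, pz = s1[i, 0], s1[i, 1], s1[i, 2]
                    mu = mol1[i]
                else:
                    px, py, pz = s2[i, 0], s2[i, 1], s2[i, 2]
                    mu = mol2[i]
                if mu > 1:
                    continue
                for v in range(2):
                    if v == 0:
                        qx, qy, qz = s1[j, 0], s1[j, 1], s1[j, 2]
                        mv = mol1[j]
                    else:
                        qx, qy, qz = s2[j, 0], s2[j, 1], s2[j, 2]
                        mv = mol2[j]
                    if mv > 1 or mv == mu:
                        continue
                    ex = px - qx
                    ey = py - qy
                    ez = pz - qz
                    if ex * ex + ey * ey + ez * ez < core2:
                        return i * n + j
    return -1


def validate_excluded_volume(conf) -> None:
    """Raise if the conformation violates the hard-core geometry the
    Monte-Carlo guard assumes: contour-distal axis pairs closer than the
    axis cores, or parental strand A-B pairs closer than the banded
    strand cores."""
    sys_ = _system_from(conf)
    bad = _validate_kernel(sys_.ax, sys_.s1, sys_.s2, sys_.sep, sys_.mol1,
                           sys_.mol2, AXIS_CORE_NM ** 2,
                           AXIS_MID_CORE_NM ** 2, NEAR_NM ** 2)
    if bad >= 0:
        n = sys_.ax.shape[0]
        raise RelaxError(
            f"excluded-volume violation between points {bad // n} and {bad % n}")


def _rot_matrix(k: np.ndarray, ang: float) -> np.ndarray:
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def _try_crankshaft(sys_: _System, rng: np.random.Generator,
                    min_span: int = 4, max_span: int = 50) -> bool:
    N = sys_.ax.shape[0]
    if sys_.closed:
        n = sys_.bounds[0]
        i = int(rng.integers(0, n))
        span = int(rng.integers(min_span, max_span + 1))
        idx = (i + 1 + np.arange(span - 1)) % n
        p0 = sys_.ax[i]
        p1 = sys_.ax[(i + span) % n]
    else:
        nu, nr = sys_.bounds
        # pick a curve weighted by interior length
        starts = np.array([0, nu, nu + nr])
        lens = np.array([nu, nr, nr])
        c = int(rng.choice(3, p=lens / lens.sum()))
        span = int(rng.integers(min_span, max_span + 1))
        if lens[c] < span + 2:
            return False
        i = int(rng.integers(0, lens[c] - span))
        idx = starts[c] + i + 1 + np.arange(span - 1)
        p0 = sys_.ax[starts[c] + i]
        p1 = sys_.ax[starts[c] + i + span]
    axis_vec = p1 - p0
    norm = np.linalg.norm(axis_vec)
    if norm < 0.5:
        return False
    k = axis_vec / norm
    theta = float(rng.uniform(-0.5, 0.5))
    rel = sys_.ax[idx] - p0
    r_perp = np.linalg.norm(rel - np.outer(rel @ k, k), axis=1)
    r_max = float(r_perp.max()) if len(r_perp) else 0.0
    if r_max * abs(theta) > MAX_DISP_NM:
        theta = np.sign(theta) * MAX_DISP_NM / r_max
    R = _rot_matrix(k, theta)

    pax = (sys_.ax[idx] - p0) @ R.T + p0
    ps1 = (sys_.s1[idx] - p0) @ R.T + p0
    ps2 = (sys_.s2[idx] - p0) @ R.T + p0
    # junction torsion limit: strand bonds at the two pivots must not
    # stretch beyond MAX_BOND_NM (blocks local strand passage)
    if sys_.closed:
        n0 = sys_.bounds[0]
        jl, jr = idx[0] - 1, idx[-1] + 1
        lims = [(0, (jl % n0,)), (len(idx) - 1, ((jr) % n0,))]
    else:
        lims = [(0, (idx[0] - 1,)), (len(idx) - 1, (idx[-1] + 1,))]
    for a, nbrs in lims:
        for jn in nbrs:
            if np.linalg.norm(ps1[a] - sys_.s1[jn]) > MAX_BOND_NM or \
                    np.linalg.norm(ps2[a] - sys_.s2[jn]) > MAX_BOND_NM:
                return False
    moved = np.zeros(N, dtype=np.bool_)
    moved[idx] = True
    ok = _guard_ok(sys_.ax, sys_.s1, sys_.s2, pax, ps1, ps2, idx, moved,
                   sys_.sep, sys_.mol1, sys_.mol2, AXIS_CORE_NM ** 2,
                   AXIS_MID_CORE_NM ** 2, NEAR_NM ** 2)
    if ok:
        sys_.ax[idx] = pax
        sys_.s1[idx] = ps1
        sys_.s2[idx] = ps2
    return ok


def _try_fork_swivel(sys_: _System, rng: np.random.Generator,
                     ramp: int = 30, ramp_d: int = 6) -> bool:
    """Twist the unreplicated duplex through a fork: strand points near
    the fork rotate about the local axis tangent with a 0 -> dphi ramp,
    and both daughter ends counter-rotate rigidly about the fork
    tangent with a dphi -> 0 ramp, keeping the strands continuous."""
    nu, nr = sys_.bounds
    w = min(ramp, nu // 3, nr // 3)
    wd = min(ramp_d, nr // 3)
    if w < 4 or wd < 4:
        return False
    fork = int(rng.integers(0, 2))
    dphi = float(rng.uniform(-0.35, 0.35))

    if fork == 0:  # fork1: unrep end nu-1, daughter starts at 0
        u_idx = np.arange(nu - w, nu)
        lam_u = (np.arange(w) + 1) / w          # -> 1 at the fork
        d_idx = np.concatenate([nu + np.arange(wd), nu + nr + np.arange(wd)])
        lam_d = 1.0 - np.arange(wd) / wd        # 1 at the fork -> 0
        pivot = sys_.ax[nu - 1]
        tang = sys_.ax[nu - 1] - sys_.ax[nu - 2]
    else:          # fork2: unrep start 0, daughter ends nr-1
        u_idx = np.arange(0, w)
        lam_u = 1.0 - np.arange(w) / w
        d_idx = np.concatenate([nu + nr - wd + np.arange(wd),
                                nu + 2 * nr - wd + np.arange(wd)])
        lam_d = (np.arange(wd) + 1) / wd
        pivot = sys_.ax[0]
        tang = sys_.ax[0] - sys_.ax[1]
    tang = tang / np.linalg.norm(tang)
    lam_d_full = np.tile(lam_d, 2)

    # displacement cap: daughter points are the far movers
    rel = sys_.ax[d_idx] - pivot
    r_perp = np.linalg.norm(rel - np.outer(rel @ tang, tang), axis=1)
    r_eff = float(np.max(r_perp * lam_d_full)) if len(r_perp) else 0.0
    r_eff = max(r_eff, 2.0)  # strand lever arm on the unrep side
    cap = 1.4 * MAX_DISP_NM  # localized move; slightly looser cap
    if r_eff * abs(dphi) > cap:
        dphi = np.sign(dphi) * cap / r_eff

    # unrep side: strands rotate about the local axis tangent
    t_loc = np.empty((len(u_idx), 3))
    for a, i in enumerate(u_idx):
        j = min(i + 1, nu - 1)
        k = max(i - 1, 0)
        t = sys_.ax[j] - sys_.ax[k]
        t_loc[a] = t / np.linalg.norm(t)
    pax_u = sys_.ax[u_idx].copy()
    ps1_u = np.empty_like(pax_u)
    ps2_u = np.empty_like(pax_u)
    for a, i in enumerate(u_idx):
        R = _rot_matrix(t_loc[a], lam_u[a] * dphi)
        ps1_u[a] = (sys_.s1[i] - sys_.ax[i]) @ R.T + sys_.ax[i]
        ps2_u[a] = (sys_.s2[i] - sys_.ax[i]) @ R.T + sys_.ax[i]

    # daughter side: rigid ramped rotation about the fork tangent line
    pax_d = np.empty((len(d_idx), 3))
    ps1_d = np.empty_like(pax_d)
    ps2_d = np.empty_like(pax_d)
    for a, i in enumerate(d_idx):
        R = _rot_matrix(tang, lam_d_full[a] * dphi)
        pax_d[a] = (sys_.ax[i] - pivot) @ R.T + pivot
        ps1_d[a] = (sys_.s1[i] - pivot) @ R.T + pivot
        ps2_d[a] = (sys_.s2[i] - pivot) @ R.T + pivot

    idx = np.concatenate([u_idx, d_idx])
    pax = np.vstack([pax_u, pax_d])
    ps1 = np.vstack([ps1_u, ps1_d])
    ps2 = np.vstack([ps2_u, ps2_d])
    # strand-bond stretch limit across the moved windows and their edges
    prop_s1 = sys_.s1.copy()
    prop_s2 = sys_.s2.copy()
    prop_s1[idx] = ps1
    prop_s2[idx] = ps2
    check = np.unique(np.concatenate([idx, idx - 1]))
    check = check[(check >= 0) & (check + 1 < sys_.ax.shape[0])]
    # only bonds along a single curve (skip the unrep/daughter seams)
    seam = {nu - 1, nu + nr - 1}
    for i in check:
        if int(i) in seam:
            continue
        if np.linalg.norm(prop_s1[i + 1] - prop_s1[i]) > MAX_BOND_NM or \
            np.linalg.norm(prop_s2[i + 1] - prop_s2[i]) > MAX_BOND_NM:
            return False
    N = sys_.ax.shape[0]
    moved = np.zeros(N, dtype=np.bool_)
    moved[idx] = True
    ok = _guard_ok(sys_.ax, sys_.s1, sys_.s2, pax, ps1, ps2, idx, moved,
                   sys_.sep, sys_.mol1, sys_.mol2, AXIS_CORE_NM ** 2,
                   AXIS_MID_CORE_NM ** 2, NEAR_NM ** 2)
    if ok:
        sys_.ax[idx] = pax
        sys_.s1[idx] = ps1
        sys_.s2[idx] = ps2
    return ok


def _try_twist_slide(sys_: _System, rng: np.random.Generator,
                     min_span: int = 24, max_span: int = 100,
                     edge: int = 6) -> bool:
    """Rotate the strand offsets of a sub-chain about the local axis
    tangents by a constant angle with ramped edges: redistributes twist
    along the contour without moving the axis or changing any region's
    total charge."""
    N = sys_.ax.shape[0]
    if sys_.closed:
        n = sys_.bounds[0]
        span = int(rng.integers(min_span, max_span + 1))
        i = int(rng.integers(0, n))
        idx = (i + np.arange(span)) % n
    else:
        nu, nr = sys_.bounds
        starts = np.array([0, nu, nu + nr])
        lens = np.array([nu, nr, nr])
        c = int(rng.choice(3, p=lens / lens.sum()))
        span = int(rng.integers(min_span, min(max_span, lens[c] - 4) + 1))
        if lens[c] < span + 4:
            return False
        i = int(rng.integers(1, lens[c] - span - 1))
        idx = starts[c] + i + np.arange(span)
    dphi = float(rng.uniform(-0.35, 0.35))
    lam = np.minimum(np.minimum(np.arange(span), span - 1 - np.arange(span))
                     / edge, 1.0)
    ps1 = np.empty((span, 3))
    ps2 = np.empty((span, 3))
    for a, k in enumerate(idx):
        kp = (k + 1) % N if sys_.closed else min(k + 1, N - 1)
        km = (k - 1) % N if sys_.closed else max(k - 1, 0)
        t = sys_.ax[kp] - sys_.ax[km]
        t = t / np.linalg.norm(t)
        R = _rot_matrix(t, lam[a] * dphi)
        ps1[a] = (sys_.s1[k] - sys_.ax[k]) @ R.T + sys_.ax[k]
        ps2[a] = (sys_.s2[k] - sys_.ax[k]) @ R.T + sys_.ax[k]
    # bond stretch at the window edges
    prop_s1 = sys_.s1.copy()
    prop_s2 = sys_.s2.copy()
    prop_s1[idx] = ps1
    prop_s2[idx] = ps2
    for a in (0, len(idx) - 1):
        k = idx[a]
        for kn in ((k - 1) % N if sys_.closed else max(k - 1, 0),
                   (k + 1) % N if sys_.closed else min(k + 1, N - 1)):
            if np.linalg.norm(prop_s1[k] - prop_s1[kn]) > MAX_BOND_NM or \
                    np.linalg.norm(prop_s2[k] - prop_s2[kn]) > MAX_BOND_NM:
                return False
    moved = np.zeros(N, dtype=np.bool_)
    moved[idx] = True
    ok = _guard_ok(sys_.ax, sys_.s1, sys_.s2, sys_.ax[idx], ps1, ps2,
                   idx, moved, sys_.sep, sys_.mol1, sys_.mol2,
                   AXIS_CORE_NM ** 2, AXIS_MID_CORE_NM ** 2, NEAR_NM ** 2)
    if ok:
        sys_.s1[idx] = ps1
        sys_.s2[idx] = ps2
    return ok


def mc_relax(frame, n_moves: int, forks_free: bool = False, seed: int = 0,
             n_snapshots: int = 6, swivel_prob: float = 0.25):
    """Run constraint-based Monte-Carlo mixing and return a trajectory.

    Returns ``n_snapshots + 1`` frames (including the initial state),
    with the attempted-move count as pseudo-time.  ``forks_free``
    enables fork-swivel moves on replication intermediates, letting
    superhelical stress redistribute between regions while the total
    linking difference is conserved.
    """
    if isinstance(frame, TrajectoryFrame):
        conf = frame.conformation
        t0 = frame.time
    else:
        conf, t0 = frame, 0.0
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    sys_ = _system_from(conf)
    validate_excluded_volume(conf)
    rng = np.random.default_rng(seed)
    is_ri = isinstance(conf, ReplicationIntermediate)
    frames = [TrajectoryFrame(time=t0, conformation=_conf_from(sys_, conf))]
    if n_moves == 0:
        return frames
    snap_at = set(np.unique(np.linspace(1, n_moves,
                                        max(n_snapshots, 1)).astype(int)))
    for step in range(1, n_moves + 1):
        u = rng.uniform()
        if is_ri and forks_free and u < swivel_prob:
            _try_fork_swivel(sys_, rng)
        elif u < swivel_prob + 0.25:
            _try_twist_slide(sys_, rng)
        else:
            _try_crankshaft(sys_, rng)
        if step in snap_at:
            frames.append(TrajectoryFrame(time=t0 + step,
                                          conformation=_conf_from(sys_, conf)))
    return frames
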