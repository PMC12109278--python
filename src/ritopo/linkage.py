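"""Linking-number analysis: contribution matrices, Tw/Wr, and the
five-component decomposition of the linking-number difference of a
replication intermediate.

Conventions
-----------
* Lk of a covalently closed duplex is the Gauss double sum over all
  segment pairs of the two strand curves; for a relaxed circle it equals
  the integer number of helical turns.
* For an RI the parental strands stay closed circles; splitting the
  segment index set at the two forks partitions Lk into the block sums
  a1*b1 (unreplicated), a1*b2 + a2*b1 (wrapping) and a2*b2 (replicated).
* Region charges are reported relative to the relaxed baseline of the
  unreplicated region, n_unrep / h, so that they sum to the total
  linking-number difference of the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import gauss
from .curves import ReplicationIntermediate, StrandCurve

__all__ = [
    "ContributionMatrix",
    "ChargeDecomposition",
    "segment_pair_charge",
    "contribution_matrix",
    "linking_number",
    "writhe",
    "twist",
    "decompose_ri",
    "lk0",
    "delta_lk",
    "sigma",
    "radius_of_gyration",
    "diagonal_band_profile",
]

segment_pair_charge = gauss.segment_pair_charge


def _as_points(curve, what="curve"):
    if isinstance(curve, StrandCurve):
        return curve.points, curve.closed
    pts = np.asarray(curve, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{what} must be a StrandCurve or (n, 3) array")
    return pts, True


@dataclass
class ContributionMatrix:
    """Per-segment-pair linking charges of two curves (units: turns)."""

    entries: np.ndarray
    row_curve: str = "A"
    col_curve: str = "B"
    block_bounds: Optional[dict] = None  # {"n_unrep": int} for RIs

    @property
    def total(self) -> float:
        return float(self.entries.sum())

    def block_sums(self) -> dict:
        """Eq.-style block sums over the a1/a2 x b1/b2 index partition."""
        if not self.block_bounds or "n_unrep" not in self.block_bounds:
            raise ValueError("matrix carries no replication block metadata")
        k = self.block_bounds["n_unrep"]
        e = self.entries
        return {
            "a1b1": float(e[:k, :k].sum()),
            "a1b2": float(e[:k, k:].sum()),
            "a2b1": float(e[k:, :k].sum()),
            "a2b2": float(e[k:, k:].sum()),
        }

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.entries, delimiter="\t", fmt="%.6e")

    def plot_heatmap(self, path, vmax: Optional[float] = None) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        e = self.entries
        if vmax is None:
            vmax = float(np.percentile(np.abs(e), 99.9)) or 1e-4
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(e, origin="lower", cmap="seismic", vmin=-vmax, vmax=vmax)
        if self.block_bounds and "n_unrep" in self.block_bounds:
            k = self.block_bounds["n_unrep"]
            ax.axhline(k - 0.5, color="k", lw=0.8)
            ax.axvline(k - 0.5, color="k", lw=0.8)
        ax.set_xlabel(f"segment index, strand {self.col_curve}")
        ax.set_ylabel(f"segment index, strand {self.row_curve}")
        fig.colorbar(im, ax=ax, label="topological charge (turns)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class ChargeDecomposition:
    """Region charges and the five components of the RI linking difference.

    c1: twist change of the unreplicated region; c2: writhe of the
    unreplicated region; c3: wrapping between the regions; c4:
    precatenation of the daughter duplexes; c5: plectonemic folding of
    the precatenated braid.  c1 + c2 = q_unrep, c3 = q_wrap,
    c4 + c5 = q_rep by construction.
    """

    q_unrep: float
    q_wrap: float
    q_rep: float
    c1_dTw_unrep: float
    c2_Wr_unrep: float
    c3_wrapping: float
    c4_precatenanes: float
    c5_plectonemes_of_precatenanes: float
    delta_lk_total: float
    baseline_unrep: float

    @property
    def components(self) -> np.ndarray:
        return np.array([self.c1_dTw_unrep, self.c2_Wr_unrep,
                         self.c3_wrapping, self.c4_precatenanes,
                         self.c5_plectonemes_of_precatenanes])

    def as_dict(self) -> dict:
        return {
            "q_unrep": self.q_unrep, "q_wrap": self.q_wrap,
            "q_rep": self.q_rep,
            "c1": self.c1_dTw_unrep, "c2": self.c2_Wr_unrep,
            "c3": self.c3_wrapping, "c4": self.c4_precatenanes,
            "c5": self.c5_plectonemes_of_precatenanes,
            "delta_lk_total": self.delta_lk_total,
            "baseline_unrep": self.baseline_unrep,
        }


def contribution_matrix(curveA, curveB, closedA: Optional[bool] = None,
                        closedB: Optional[bool] = None,
                        block_n_unrep: Optional[int] = None) -> ContributionMatrix:
    """Gauss linking contribution matrix between two strand curves."""
    ptsA, cA = _as_points(curveA, "curveA")
    ptsB, cB = _as_points(curveB, "curveB")
    if closedA is not None:
        cA = closedA
    if closedB is not None:
        cB = closedB
    entries = gauss.pair_charge_matrix(ptsA, ptsB, cA, cB)
    bounds = {"n_unrep": block_n_unrep} if block_n_unrep is not None else None
    return ContributionMatrix(entries=entries, block_bounds=bounds)


def linking_number(curveA, curveB) -> float:
    """Lk of two closed curves by the Gauss double sum."""
    ptsA, cA = _as_points(curveA, "curveA")
    ptsB, cB = _as_points(curveB, "curveB")
    if not (cA and cB):
        raise ValueError("linking_number requires two closed curves")
    return gauss.curve_pair_sum(ptsA, ptsB, True, True)


def writhe(curve, closed: Optional[bool] = None) -> float:
    """Writhe of a curve (Gauss self-integral, both pair orders counted)."""
    pts, c = _as_points(curve, "curve")
    if closed is not None:
        c = closed
    return gauss.writhe_sum(pts, c)


def _vertex_tangents(axis: np.ndarray, closed: bool) -> np.ndarray:
    if closed:
        t = np.roll(axis, -1, axis=0) - np.roll(axis, 1, axis=0)
    else:
        t = np.empty_like(axis)
        t[1:-1] = axis[2:] - axis[:-2]
        t[0] = axis[1] - axis[0]
        t[-1] = axis[-1] - axis[-2]
    n = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("degenerate axis tangent")
    return t / n


def twist(strandA_region, strandB_region, axis, closed: bool = False) -> float:
    """Winding of the strand-offset vector about the duplex axis, in turns.

    Sums the signed rotation of the perpendicular component of
    strandA - strandB about the local axis tangent between successive
    base pairs, parallel-transporting across the change of tangent.
    """
    a, _ = _as_points(strandA_region, "strandA_region")
    b, _ = _as_points(strandB_region, "strandB_region")
    ax, _ = _as_points(axis, "axis")
    if not (len(a) == len(b) == len(ax)):
        raise ValueError("strand regions and axis must have equal length")
    t = _vertex_tangents(ax, closed)
    off = a - b
    # perpendicular components
    u = off - (np.einsum("ij,ij->i", off, t))[:, None] * t
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("strand offset parallel to axis (zero-length offset)")
    u = u / norms[:, None]

    n = len(ax)
    steps = range(n) if closed else range(n - 1)
    total = 0.0
    for i in steps:
        j = (i + 1) % n
        ti, tj = t[i], t[j]
        ui = u[i]
        # parallel transport ui across the tangent rotation ti -> tj
        c = np.cross(ti, tj)
        s = np.linalg.norm(c)
        d = float(np.dot(ti, tj))
        if s > 1e-12:
            k = c / s
            ang = np.arctan2(s, d)
            ui = (ui * np.cos(ang) + np.cross(k, ui) * np.sin(ang)
                  + k * np.dot(k, ui) * (1 - np.cos(ang)))
        # signed angle from transported ui to u[j] about tj
        cross = np.cross(ui, u[j])
        total += np.arctan2(float(np.dot(cross, tj)), float(np.dot(ui, u[j])))
    return total / (2.0 * np.pi)


def lk0(n_bp: float, h: float = 10.5) -> float:
    """Relaxed linking number N / h."""
    if n_bp <= 0 or h <= 0:
        raise ValueError("n_bp and h must be positive")
    return n_bp / h


def delta_lk(lk: float, lk0_value: float) -> float:
    """Linking-number difference Lk - Lk0."""
    return lk - lk0_value


def sigma(delta_lk_value: float, lk0_value: float) -> float:
    """Superhelical density sigma = dLk / Lk0."""
    if lk0_value == 0:
        raise ValueError("Lk0 must be non-zero")
    return delta_lk_value / lk0_value


def radius_of_gyration(points) -> float:
    """Root-mean-square distance of the points from their center of mass."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if len(pts) == 0:
        raise ValueError("radius_of_gyration of an empty point set")
    com = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1))))


def decompose_ri(ri: ReplicationIntermediate,
                 matrix: Optional[ContributionMatrix] = None) -> ChargeDecomposition:
    """Five-component decomposition of the RI linking-number difference.

    Region charges come from the block sums of the full parental-strand
    contribution matrix; the twist of the unreplicated region and the
    linking of the two daughter midpoint curves (each closed through the
    fork junctions) split them into the five components.
    """
    h = ri.helical_repeat_h
    k = ri.n_unrep
    if matrix is None:
        matrix = contribution_matrix(ri.parentalA, ri.parentalB,
                                     block_n_unrep=k)
    elif not matrix.block_bounds:
        matrix.block_bounds = {"n_unrep": k}
    blocks = matrix.block_sums()

    baseline = k / h
    q_unrep = blocks["a1b1"] - baseline
    q_wrap = blocks["a1b2"] + blocks["a2b1"]
    q_rep = blocks["a2b2"]

    c1 = twist(ri.a1, ri.b1, ri.unrep_axis_points, closed=False) - baseline
    c2 = q_unrep - c1
    c3 = q_wrap
    c4 = gauss.curve_pair_sum(ri.daughter1_axis_points,
                              ri.daughter2_axis_points, True, True)
    c5 = q_rep - c4
    total = q_unrep + q_wrap + q_rep
    return ChargeDecomposition(
        q_unrep=q_unrep, q_wrap=q_wrap, q_rep=q_rep,
        c1_dTw_unrep=c1, c2_Wr_unrep=c2, c3_wrapping=c3,
        c4_precatenanes=c4, c5_plectonemes_of_precatenanes=c5,
        delta_lk_total=total, baseline_unrep=baseline)


def diagonal_band_profile(matrix: ContributionMatrix,
                          band_halfwidth_bp: int = 15,
                          smooth_bp: int = 30,
                          peak_frac: float = 0.35,
                          min_off_charge: float = 1.0) -> dict:
    """Split a square contribution matrix into the main diagonal band and
    off-band charge, and count the secondary (plectonemic) bands.

    Band membership uses cyclic index distance |i - j| <= halfwidth.
    An interwound branch juxtaposes contour positions i and j with
    i + j roughly constant, so its charge forms a ridge at fixed
    anti-diagonal coordinate (i + j) mod n; the off-band |charge| is
    accumulated over that coordinate, smoothed, and the cyclic runs
    above ``peak_frac`` of the maximum are counted as bands.  Molecules
    whose total off-band charge magnitude is below ``min_off_charge``
    report zero bands.  Branches placed half a contour apart alias onto
    the same anti-diagonal coordinate and are counted once.
    """
    e = matrix.entries
    n, m = e.shape
    if n != m:
        raise ValueError("band profile requires a square matrix")
    w = int(band_halfwidth_bp)
    if w >= n // 2:
        raise ValueError("band half-width must be < n/2")
    i = np.arange(n)
    dist = np.abs(i[:, None] - i[None, :])
    dist = np.minimum(dist, n - dist)
    band = dist <= w
    main_band_sum = float(e[band].sum())
    off = np.where(band, 0.0, e)
    off_band_sum = float(off.sum())

    n_bands = 0
    if abs(off_band_sum) >= min_off_charge:
        ii, jj = np.nonzero(off)
        coord = (ii + jj) % n
        prof = np.bincount(coord, weights=np.abs(off[ii, jj]), minlength=n)
        k = np.ones(smooth_bp) / smooth_bp
        prof = np.convolve(np.tile(prof, 3), k, mode="same")[n:2 * n]
        above = prof > peak_frac * prof.max()
        runs = int((np.diff(above.astype(int)) == 1).sum())
        if above[0] and not above[-1]:
            runs += 1
        if runs == 0 and above.any():
            runs = 1
        n_bands = runs
    return {"main_band_sum": main_band_sum,
            "off_band_sum": off_band_sum,
            "n_secondary_bands": n_bands}
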