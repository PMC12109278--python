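"""Per-frame analysis orchestration: decomposition, collisions, and
radius of gyration over a trajectory, with replicate averaging and
early/late-stage comparison summaries."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import collisions as coll
from . import linkage
from .curves import (DuplexConformation, ReplicationIntermediate,
                     TrajectoryFrame, check_trajectory)

__all__ = ["AnalysisConfig", "TimeSeriesReport", "analyze_trajectory",
           "average_reports", "compare_stages"]

_COUNT_COLS = [f"n_type{t}_{c}" for t in (1, 2, 3, 4) for c in ("left", "right")]
_COLUMNS = (["time", "c1", "c2", "c3", "c4", "c5", "q_unrep", "q_wrap",
             "q_rep", "delta_lk_total", "rg_nm"] + _COUNT_COLS
            + ["collisions_total"])


@dataclass
class AnalysisConfig:
    cutoff_nm: float = coll.CUTOFF_NM
    exclusion_bp: float = coll.EXCLUSION_BP
    reduce_step: int = 10
    braid_window_bp: float = coll.BRAID_WINDOW_BP
    helical_repeat_h: float = 10.5
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class TimeSeriesReport:
    """Per-frame topology and collision report for one trajectory."""

    table: pd.DataFrame
    config_hash: str = ""
    seed: int = 0
    version: str = _version

    def __post_init__(self):
        bad = (self.table[["c1", "c2", "c3", "c4", "c5"]].sum(axis=1)
               - self.table["delta_lk_total"]).abs()
        if (bad > 1e-6).any():
            raise ValueError("component sums do not match delta_lk_total")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# config_hash={self.config_hash} seed={self.seed} "
                     f"version={self.version}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesReport":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(kv.split("=", 1) for kv in first[1:].split())
                table = pd.read_csv(fh)
            else:
                fh.seek(0)
                table = pd.read_csv(fh)
        return cls(table=table, config_hash=meta.get("config_hash", ""),
                   seed=int(meta.get("seed", 0)),
                   version=meta.get("version", _version))


def _analyze_frame(frame: TrajectoryFrame, cfg: AnalysisConfig) -> dict:
    conf = frame.conformation
    row = {"time": frame.time}
    if isinstance(conf, ReplicationIntermediate):
        dec = linkage.decompose_ri(conf)
        row.update(c1=dec.c1_dTw_unrep, c2=dec.c2_Wr_unrep,
                   c3=dec.c3_wrapping, c4=dec.c4_precatenanes,
                   c5=dec.c5_plectonemes_of_precatenanes,
                   q_unrep=dec.q_unrep, q_wrap=dec.q_wrap, q_rep=dec.q_rep,
                   delta_lk_total=dec.delta_lk_total)
        pts = conf.all_nucleotide_points()
    elif isinstance(conf, DuplexConformation):
        lk = linkage.linking_number(conf.strandA.points, conf.strandB.points)
        wr = linkage.writhe(conf.axis_points)
        dlk = lk - round(conf.n_bp / conf.helical_repeat_h)
        row.update(c1=dlk - wr, c2=wr, c3=0.0, c4=0.0, c5=0.0,
                   q_unrep=dlk, q_wrap=0.0, q_rep=0.0, delta_lk_total=dlk)
        pts = np.vstack([conf.strandA.points, conf.strandB.points])
    else:
        raise TypeError(f"unsupported conformation {type(conf)!r}")
    row["rg_nm"] = linkage.radius_of_gyration(pts)

    events = coll.detect_collisions(
        frame, cutoff=cfg.cutoff_nm, exclusion_bp=cfg.exclusion_bp,
        step=cfg.reduce_step, braid_window_bp=cfg.braid_window_bp)
    tal = coll.tally(events)
    for t in (1, 2, 3, 4):
        for c in ("left", "right"):
            row[f"n_type{t}_{c}"] = int(tal.loc[t, c])
    row["collisions_total"] = int(tal["total"].sum())
    return row


def analyze_trajectory(frames: Sequence[TrajectoryFrame],
                       config: Optional[AnalysisConfig] = None) -> TimeSeriesReport:
    """Decomposition + collision tally + radius of gyration per frame."""
    frames = list(frames)
    if not frames:
        raise ValueError("analyze_trajectory needs at least one frame")
    check_trajectory(frames)
    sizes = {f.conformation.n_bp if isinstance(f.conformation, DuplexConformation)
             else f.conformation.n_bp_total for f in frames}
    if len(sizes) != 1:
        raise ValueError(f"mixed molecule sizes across frames: {sizes}")
    cfg = config or AnalysisConfig()
    rows = [_analyze_frame(f, cfg) for f in frames]
    table = pd.DataFrame(rows, columns=_COLUMNS)
    return TimeSeriesReport(table=table, config_hash=cfg.hash(), seed=cfg.seed)


def average_reports(reports: Sequence[TimeSeriesReport]) -> TimeSeriesReport:
    """Mean trace across replicate trajectories, plus per-point spread.

    All reports must share the same frame count; values are averaged per
    time point and each numeric column gains a ``<name>_sd`` companion.
    """
    if not reports:
        raise ValueError("no reports to average")
    n_rows = {len(r.table) for r in reports}
    if len(n_rows) != 1:
        raise ValueError("replicate reports have different frame counts")
    stack = np.stack([r.table[_COLUMNS].to_numpy(dtype=float)
                      for r in reports])
    mean = pd.DataFrame(stack.mean(axis=0), columns=_COLUMNS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0),
                      columns=[f"{c}_sd" for c in _COLUMNS])
    table = pd.concat([mean, sd.drop(columns=["time_sd"])], axis=1)
    return TimeSeriesReport(table=table,
                            config_hash=reports[0].config_hash,
                            seed=reports[0].seed)


def _component_shares(row: pd.Series) -> dict:
    comps = row[["c1", "c2", "c3", "c4", "c5"]].to_numpy(dtype=float)
    total = float(row["delta_lk_total"])
    abs_sum = float(np.abs(comps).sum())
    out = {}
    for i, c in enumerate(comps, start=1):
        out[f"c{i}_share_signed_pct"] = 100.0 * c / total if total else np.nan
        out[f"c{i}_share_abs_pct"] = 100.0 * abs(c) / abs_sum if abs_sum else np.nan
    return out


def compare_stages(report_early: TimeSeriesReport,
                   report_late: TimeSeriesReport) -> pd.DataFrame:
    """Per-stage means: radius of gyration, collision counts by type,
    and the percentage share of each linking-difference component
    (signed share of the total, and share of the absolute sum)."""
    rows = {}
    for name, rep in (("early", report_early), ("late", report_late)):
        t = rep.table
        row = {"rg_nm": float(t["rg_nm"].mean()),
               "collisions_total": float(t["collisions_total"].mean())}
        for tp in (1, 2, 3, 4):
            row[f"n_type{tp}"] = float(
                (t[f"n_type{tp}_left"] + t[f"n_type{tp}_right"]).mean())
        mean_row = t.mean(numeric_only=True)
        row.update(_component_shares(mean_row))
        rows[name] = row
    return pd.DataFrame(rows).T
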