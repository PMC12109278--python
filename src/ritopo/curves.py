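"""Domain types for coarse-grained DNA conformations.

A conformation is a set of oriented piecewise-linear 3D curves in nm:
one curve per DNA single strand plus, optionally, duplex axis curves.
A replication intermediate (RI) keeps each parental strand as a closed
circle partitioned into an unreplicated part (a1/b1) and a replicated
part (a2/b2) that lives in one of the two daughter duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REGION_UNREPLICATED = "unreplicated"
REGION_DAUGHTER1 = "replicated_daughter1"
REGION_DAUGHTER2 = "replicated_daughter2"
REGION_AXIS = "axis"

_VALID_REGIONS = {REGION_UNREPLICATED, REGION_DAUGHTER1, REGION_DAUGHTER2,
                  REGION_AXIS}


@dataclass
class StrandCurve:
    """An oriented piecewise-linear 3D curve for one strand (or an axis).

    Coordinates are in nm.  If ``closed``, the final point connects back
    to the first implicitly (no duplicated endpoint).
    """

    points: np.ndarray
    closed: bool = False
    nucleotide_index_map: Optional[np.ndarray] = None
    region_label: Optional[str] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 3:
            raise ValueError("a strand curve needs at least 3 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) <= 0.0):
            raise ValueError("consecutive points must be distinct")
        if self.closed and np.linalg.norm(self.points[-1] - self.points[0]) <= 0.0:
            raise ValueError("closed curves must not duplicate the endpoint")
        if self.region_label is not None and self.region_label not in _VALID_REGIONS:
            raise ValueError(f"unknown region label {self.region_label!r}")
        if self.nucleotide_index_map is None:
            self.nucleotide_index_map = np.arange(len(self.points))
        else:
            self.nucleotide_index_map = np.asarray(self.nucleotide_index_map,
                                                   dtype=np.int64)
            if len(self.nucleotide_index_map) != len(self.points):
                raise ValueError("nucleotide_index_map length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_segments(self) -> int:
        return len(self.points) if self.closed else len(self.points) - 1


@dataclass
class DuplexConformation:
    """A covalently closed circular duplex: two closed strands plus axis."""

    strandA: StrandCurve
    strandB: StrandCurve
    n_bp: int
    helical_repeat_h: float = 10.5
    axis: Optional[StrandCurve] = None

    def __post_init__(self):
        if not (self.strandA.closed and self.strandB.closed):
            raise ValueError("both strands of a CCC duplex must be closed")
        if len(self.strandA) != len(self.strandB):
            raise ValueError("strand point counts differ")
        if len(self.strandA) != self.n_bp:
            raise ValueError("strand point count must equal n_bp")
        sep = np.linalg.norm(self.strandA.points - self.strandB.points, axis=1)
        if np.any(sep < 1.5) or np.any(sep > 2.5):
            raise ValueError("per-index strand separation outside [1.5, 2.5] nm")

    @property
    def axis_points(self) -> np.ndarray:
        if self.axis is not None:
            return self.axis.points
        return 0.5 * (self.strandA.points + self.strandB.points)


@dataclass
class ReplicationIntermediate:
    """A partially replicated circular molecule.

    Parental strand A is the closed concatenation a1 (unreplicated,
    indices [0, n_unrep)) then a2 (replicated, daughter duplex 1);
    parental strand B is b1 then b2 (daughter duplex 2).  The two fork
    junctions sit between index n_unrep - 1 / n_unrep and at the
    wrap-around n_unrep + n_rep - 1 / 0.
    """

    parentalA: StrandCurve
    parentalB: StrandCurve
    daughter_new1: Optional[StrandCurve]
    daughter_new2: Optional[StrandCurve]
    n_unrep: int
    n_rep: int
    helical_repeat_h: float = 10.5
    unrep_axis: Optional[StrandCurve] = None
    daughter1_axis: Optional[StrandCurve] = None
    daughter2_axis: Optional[StrandCurve] = None

    def __post_init__(self):
        n = self.n_unrep + self.n_rep
        if len(self.parentalA) != n or len(self.parentalB) != n:
            raise ValueError("parental strand length must be n_unrep + n_rep")
        if not (self.parentalA.closed and self.parentalB.closed):
            raise ValueError("parental strands must be closed circles")
        for d in (self.daughter_new1, self.daughter_new2):
            if d is not None and len(d) != self.n_rep:
                raise ValueError("daughter strand length must equal n_rep")

    @property
    def n_bp_total(self) -> int:
        return self.n_unrep + self.n_rep

    @property
    def fork_indices(self) -> tuple[int, int]:
        """Parental-strand indices just before each fork junction."""
        return (self.n_unrep - 1, self.n_bp_total - 1)

    # region slices on the parental strands
    @property
    def a1(self) -> np.ndarray:
        return self.parentalA.points[: self.n_unrep]

    @property
    def a2(self) -> np.ndarray:
        return self.parentalA.points[self.n_unrep:]

    @property
    def b1(self) -> np.ndarray:
        return self.parentalB.points[: self.n_unrep]

    @property
    def b2(self) -> np.ndarray:
        return self.parentalB.points[self.n_unrep:]

    @property
    def unrep_axis_points(self) -> np.ndarray:
        if self.unrep_axis is not None:
            return self.unrep_axis.points
        return 0.5 * (self.a1 + self.b1)

    @property
    def daughter1_axis_points(self) -> np.ndarray:
        if self.daughter1_axis is not None:
            return self.daughter1_axis.points
        if self.daughter_new1 is None:
            raise ValueError("daughter 1 has neither axis nor new strand")
        return 0.5 * (self.a2 + self.daughter_new1.points)

    @property
    def daughter2_axis_points(self) -> np.ndarray:
        if self.daughter2_axis is not None:
            return self.daughter2_axis.points
        if self.daughter_new2 is None:
            raise ValueError("daughter 2 has neither axis nor new strand")
        return 0.5 * (self.b2 + self.daughter_new2.points)

    def all_nucleotide_points(self) -> np.ndarray:
        """Coordinates of every nucleotide in the molecule (4 strands)."""
        parts = [self.parentalA.points, self.parentalB.points]
        for d in (self.daughter_new1, self.daughter_new2):
            if d is not None:
                parts.append(d.points)
        return np.concatenate(parts, axis=0)


Conformation = DuplexConformation | ReplicationIntermediate


@dataclass
class TrajectoryFrame:
    """One time point of a trajectory (time in simulation units or moves)."""

    time: float
    conformation: Conformation


def check_trajectory(frames: Sequence[TrajectoryFrame]) -> None:
    times = [f.time for f in frames]
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frame times must be non-decreasing")
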