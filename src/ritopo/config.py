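"""Generator configuration: the topological state a synthetic molecule
is built to carry, plus the geometric constants of the coarse-grained
B-DNA model.

The prescribed partition fixes the region charges of a replication
intermediate: ``q_unrep`` (supercoiling of the unreplicated region),
``q_wrap`` (inter-region wrapping) and ``q_rep`` (replicated region,
split into ``precatenane_Ca`` winding and ``braid_writhe``).  Their sum
is the molecule's linking-number difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PrescribedPartition", "GeneratorConfig",
           "early_invivo_config", "late_invivo_config"]


@dataclass
class PrescribedPartition:
    q_unrep: float = 0.0
    q_wrap: float = 0.0
    q_rep: float = 0.0
    precatenane_Ca: float = 0.0
    braid_writhe: float = 0.0

    def __post_init__(self):
        if abs(self.precatenane_Ca + self.braid_writhe - self.q_rep) > 1e-9:
            raise ValueError("precatenane_Ca + braid_writhe must equal q_rep")

    @property
    def delta_lk(self) -> float:
        return self.q_unrep + self.q_wrap + self.q_rep


@dataclass
class GeneratorConfig:
    n_bp: int = 2000
    frac_replicated: float = 0.2545
    helical_repeat_h: float = 10.5
    rise_per_bp: float = 0.34
    duplex_radius: float = 1.0
    superhelix_radius: float = 4.5
    braid_radius: float = 4.0
    writhe_fraction: float = 0.6
    n_plectoneme_branches: int = 1
    prescribed_partition: PrescribedPartition = field(
        default_factory=PrescribedPartition)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.prescribed_partition, dict):
            self.prescribed_partition = PrescribedPartition(
                **self.prescribed_partition)
        if not 0.0 < self.frac_replicated < 1.0:
            raise ValueError("frac_replicated must be in (0, 1)")
        if self.n_bp < 200:
            raise ValueError("n_bp too small for a replication intermediate")

    @property
    def n_rep(self) -> int:
        return int(round(self.n_bp * self.frac_replicated))

    @property
    def n_unrep(self) -> int:
        return self.n_bp - self.n_rep

    @property
    def delta_lk(self) -> float:
        return self.prescribed_partition.delta_lk

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def early_invivo_config(seed: int = 0) -> GeneratorConfig:
    """Early-stage RI as built in vivo: 25% replicated 2 kb circle,
    charge -12 in the unreplicated region and +2 (right-handed
    precatenanes) in the replicated region; total linking difference -10.
    """
    return GeneratorConfig(
        n_bp=2000, frac_replicated=509 / 2000,
        prescribed_partition=PrescribedPartition(
            q_unrep=-12.0, q_wrap=0.0, q_rep=2.0,
            precatenane_Ca=2.0, braid_writhe=0.0),
        seed=seed)


def late_invivo_config(seed: int = 0) -> GeneratorConfig:
    """Late-stage RI as built in vivo: 75% replicated (504 bp
    unreplicated + 1506 bp replicated), charge -2 unreplicated and +12
    in precatenanes; total linking difference +10.
    """
    return GeneratorConfig(
        n_bp=2010, frac_replicated=1506 / 2010,
        prescribed_partition=PrescribedPartition(
            q_unrep=-2.0, q_wrap=0.0, q_rep=12.0,
            precatenane_Ca=12.0, braid_writhe=0.0),
        seed=seed)
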