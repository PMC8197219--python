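"""Pipeline configuration: one serializable object that, together with the
input files and the global seed, fully determines a run.

Every constant of the method is surfaced as a named key with its default:
1-Å voxels, 3-Å grid padding, 6-Å binding cutoff, 24 cubic rotations,
16 atom types (+1 non-surface channel), 9:1 split, 1000 atoms per cluster,
5x score inflation, 2 second-round clusters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig
from .postprocess import ClusterConfig
from .surface import SasaParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    grid_padding: float = 3.0
    binding_cutoff: float = 6.0
    eval_radius: float = 6.0
    keep_hetero: bool = False
    n_rotations: int = 24
    sasa: SasaParams = field(default_factory=SasaParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)

    def __post_init__(self) -> None:
        # propagate the global seed into stages that left theirs at default
        for sub in (self.model, self.training, self.clustering):
            if sub.seed == 0:
                sub.seed = self.seed

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["sasa"].pop("radii_table", None)  # defaults live in code
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("sasa", SasaParams), ("model", ModelConfig),
                         ("training", TrainConfig), ("clustering", ClusterConfig)):
            if key in data:
                kwargs[key] = sub(**data.pop(key))
        kwargs.update(data)
        return cls(**kwargs)
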