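"""Validated pipeline configuration (YAML-serializable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class GraphOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shrinkage: float | str = "auto"
    edge_rule: str = "complete"  # or "top_k"
    top_k: int = 10


class SelectionOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_keep: int = 30
    step_fraction: float = Field(0.1, gt=0.0, le=1.0)
    C: float = 1.0
    importance: str = "weight"


class ModelOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d1: int = 64
    d2: int = 16
    clf_hidden: int = 32
    pfe_layers: int = 1
    use_phenotype: bool = True


class TrainOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 0.05
    lr_step_size: int = 20
    lr_gamma: float = 0.5
    optimizer: str = "adam"
    split_ratio: tuple[float, float] = (0.8, 0.2)
    stratified: bool = False


class PipelineConfig(BaseModel):
    """Everything needed to reproduce a run, given the seed."""

    model_config = ConfigDict(extra="forbid")
    timeseries_dir: str | None = None
    phenotype_csv: str | None = None
    output_dir: str = "outputs"
    label_column: str = "label"
    graph: GraphOptions = GraphOptions()
    selection: SelectionOptions = SelectionOptions()
    model: ModelOptions = ModelOptions()
    train: TrainOptions = TrainOptions()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))
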