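"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
import json
import pathlib
import tomllib
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    """Hyperparameters for the full association-prediction pipeline.

    Defaults follow the reference protocol: 5 / 30 KNN neighbours for the
    disease / microbe similarity-fusion step, three latent scales of
    16, 32 and 64 units, Adam with step-decayed learning rate, and
    tenfold cross-validation of a gradient-boosted-tree pair classifier.
    """

    knn_k_disease: int = 5
    knn_k_microbe: int = 30
    snf_iterations: int = 20
    scales: list[int] = field(default_factory=lambda: [16, 32, 64])
    base_hidden_dims: list[int] = field(default_factory=lambda: [256, 128])
    learning_rate: float = 0.001
    lr_step: int = 300
    lr_gamma: float = 0.5
    epochs: int = 1200
    sinkhorn_epsilon: float = 0.1
    sinkhorn_iters: int = 30
    wd_mode: str = "sinkhorn"  # "sinkhorn" (empirical clouds) or "gaussian" (closed form)
    negative_ratio: float = 1.0
    cv_folds: int = 10
    decision_threshold: float = 0.5
    omega: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be a nonempty list of positive ints")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.knn_k_disease < 1 or self.knn_k_microbe < 1:
            raise ValueError("KNN neighbour counts must be >= 1")
        if self.epochs < 1 or self.snf_iterations < 1:
            raise ValueError("epochs and snf_iterations must be >= 1")
        if self.sinkhorn_epsilon <= 0:
            raise ValueError("sinkhorn_epsilon must be > 0")
        if self.negative_ratio < 0:
            raise ValueError("negative_ratio must be >= 0")
        if self.wd_mode not in ("sinkhorn", "gaussian"):
            raise ValueError("wd_mode must be 'sinkhorn' or 'gaussian'")

    @property
    def embedding_dim(self) -> int:
        """Dimension of the concatenated multi-scale embedding."""
        return int(sum(self.scales))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "RunConfig":
        """Load from TOML, YAML or JSON, keyed by file extension."""
        path = pathlib.Path(path)
        suffix = path.suffix.lower()
        if suffix == ".toml":
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        elif suffix in (".yaml", ".yml"):
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        elif suffix == ".json":
            with open(path) as fh:
                data = json.load(fh)
        else:
            raise ValueError(f"unsupported config format: {path.name}")
        return cls.from_dict(data)
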