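"""Pipeline configuration: one seeded, serializable object per run.

Every stochastic stage derives its own seed deterministically from the
global seed and the stage name, so a single integer pins the whole run.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed in [0, 2**31)."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class MLPConfig:
    width_grid: tuple[int, ...] = (4, 8, 16)
    l2_penalty: float = 1e-3
    validation_fraction: float = 0.2
    learning_rate: float = 0.01
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 512


@dataclass
class AnovaConfig:
    n_grid: int = 101
    max_order: int = 2
    max_pairs: int | None = None  # cap candidate pairs by response variance


@dataclass
class LassoConfig:
    n_lambdas: int = 100
    lambda_ratio: float = 1e-4
    folds: int = 10
    rule: str = "min_cv"
    standardize: bool = False


@dataclass
class PRNConfig:
    epochs: int = 500
    learning_rate: float = 0.005
    patience: int = 20
    l2: float = 1e-4
    batch_size: int = 512
    allow_new_pairs: bool = False


@dataclass
class ImputeConfig:
    method: str = "zero"  # zero | multiple
    m: int = 10
    strata: str | None = None


@dataclass
class EvalConfig:
    groups: int = 10
    level: float = 0.95
    test_fraction: float = 0.25


@dataclass
class PipelineConfig:
    seed: int = 0
    mlp: MLPConfig = field(default_factory=MLPConfig)
    anova: AnovaConfig = field(default_factory=AnovaConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    prn: PRNConfig = field(default_factory=PRNConfig)
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        cfg = cls()
        for key, sub in (("mlp", MLPConfig), ("anova", AnovaConfig),
                         ("lasso", LassoConfig), ("prn", PRNConfig),
                         ("impute", ImputeConfig), ("evaluation", EvalConfig)):
            if key in doc:
                params = dict(doc[key])
                if key == "mlp" and "width_grid" in params:
                    params["width_grid"] = tuple(params["width_grid"])
                setattr(cfg, key, sub(**params))
        for key in ("seed", "log_level"):
            if key in doc:
                setattr(cfg, key, doc[key])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
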