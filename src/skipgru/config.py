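"""Run configuration dataclasses and deterministic seed derivation.

All randomness in the pipeline flows from one root seed in
:class:`PipelineConfig`; each stage derives its own stream with
:func:`spawn_seed` so stages stay reproducible independently of one another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ImputationConfig",
    "MPAConfig",
    "SkipGRUConfig",
    "CVConfig",
    "PipelineConfig",
    "spawn_seed",
]


def spawn_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the root seed, deterministically.

    Uses CRC32 over ``"<seed>:<stage>"`` so the mapping is stable across
    Python versions (unlike ``hash``). Result is in ``[0, 2**31)``.
    """
    return zlib.crc32(f"{root_seed}:{stage}".encode()) % (2**31)


@dataclass
class ImputationConfig:
    """Polynomial-regression imputation settings.

    ``missing_threshold`` is the decision fraction: strictly above it the
    feature is imputed by polynomial regression; at or below it (but above
    zero) the affected rows are dropped.
    """

    degree: int = 2
    missing_threshold: float = 0.05

    def validate(self) -> None:
        if self.degree < 1:
            raise ValueError("imputation degree must be >= 1")
        if not 0.0 < self.missing_threshold < 1.0:
            raise ValueError("missing_threshold must lie in (0, 1)")


@dataclass
class MPAConfig:
    """Settings for the RSFS-MPA wrapper feature selector.

    ``fitness_alpha``/``fitness_beta`` weight the surrogate's
    cross-validated error against the selected-feature fraction; they must
    sum to 1. ``step_coeff`` is the 0.5 multiplier in the prey position
    updates; ``fads`` the fish-aggregation-device jump probability.
    """

    n_pop: int = 30
    max_iter: int = 100
    fads: float = 0.2
    step_coeff: float = 0.5
    levy_exponent: float = 1.5
    lower: float = 0.0
    upper: float = 1.0
    rsfs_prob: float = 0.5
    k_min: float = 0.0
    k_max: float = 1.0
    transfer_threshold: float = 0.5
    fitness_alpha: float = 0.99
    fitness_beta: float = 0.01
    surrogate_folds: int = 3

    def validate(self) -> None:
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")
        if self.max_iter < 3:
            raise ValueError("max_iter must be >= 3")
        for name in ("fads", "rsfs_prob", "transfer_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be < upper bound")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (1, 2]")
        if abs(self.fitness_alpha + self.fitness_beta - 1.0) > 1e-12:
            raise ValueError("fitness_alpha + fitness_beta must equal 1")
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")


@dataclass
class SkipGRUConfig:
    """Skip-GRU classifier hyperparameters.

    Defaults follow the published configuration for clinical tabular risk
    data: hidden size 128, dropout 0.3, weight decay 0.1, learning rate
    1e-4, Adam, batch 32, clip-by-norm threshold 1.0, skip threshold 0.5.
    """

    hidden_size: int = 128
    gate_hidden: int | None = None  # defaults to hidden_size when None
    dropout: float = 0.3
    weight_decay: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 32
    clip_threshold: float = 1.0
    skip_threshold: float = 0.5
    gate_cost: float = 0.01
    epochs: int = 100
    optimizer: str = "adam"

    def validate(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.clip_threshold <= 0.0:
            raise ValueError("clip_threshold must be > 0")
        if not 0.0 < self.skip_threshold < 1.0:
            raise ValueError("skip_threshold must lie in (0, 1)")
        if self.gate_cost < 0.0:
            raise ValueError("gate_cost must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class CVConfig:
    k: int = 5
    stratified: bool = True

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("cv k must be >= 2")


@dataclass
class PipelineConfig:
    """Top-level configuration: one root seed plus per-stage settings."""

    seed: int = 0
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    fs: MPAConfig = field(default_factory=MPAConfig)
    model: SkipGRUConfig = field(default_factory=SkipGRUConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def validate(self) -> None:
        self.imputation.validate()
        self.fs.validate()
        self.model.validate()
        self.cv.validate()

    def stage_seed(self, stage: str) -> int:
        return spawn_seed(self.seed, stage)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(data.get("seed", 0)),
            imputation=ImputationConfig(**data.get("imputation", {})),
            fs=MPAConfig(**data.get("fs", {})),
            model=SkipGRUConfig(**data.get("model", {})),
            cv=CVConfig(**data.get("cv", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
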