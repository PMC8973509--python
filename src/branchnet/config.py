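"""Declarative run configuration.

Every user-settable knob of every stage lives in one :class:`RunConfig` that
round-trips losslessly through YAML, so a finished session's config file can be
fed back in to reproduce the run exactly (given the same input files). Scalars
are coerced leniently on load ("150" becomes the integer 150) and unknown keys
produce a warning rather than an error, so configs written by newer versions
still load.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

BRANCH_NAMES = ("sequence", "structure", "conservation")
SUBSET_NAMES = ("train", "validation", "evaluation", "blackbox")


class LayerSpec(BaseModel):
    """One layer of a network section.

    Only the fields relevant to ``kind`` may be set: convolutional layers take
    ``filters`` and ``kernel_size``; recurrent layers take ``units``,
    ``recurrent_cell`` and ``bidirectional``; dense layers take ``units``.
    ``dropout_rate`` and ``batch_norm`` apply to any kind.
    """

    kind: Literal["conv", "recurrent", "dense"]
    filters: Optional[int] = None
    kernel_size: Optional[int] = None
    units: Optional[int] = None
    recurrent_cell: Literal["GRU", "LSTM"] = "GRU"
    bidirectional: bool = False
    dropout_rate: float = 0.0
    batch_norm: bool = False

    @field_validator("dropout_rate")
    @classmethod
    def _rate_range(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        return v

    @model_validator(mode="after")
    def _fields_match_kind(self):
        if self.kind == "conv":
            if self.filters is None or self.kernel_size is None:
                raise ValueError("conv layer requires filters and kernel_size")
            if self.units is not None:
                raise ValueError("conv layer does not take units")
            if self.filters < 1 or self.kernel_size < 1:
                raise ValueError("filters and kernel_size must be positive")
        else:
            if self.filters is not None or self.kernel_size is not None:
                raise ValueError(f"{self.kind} layer does not take filters/kernel_size")
            if self.units is None or self.units < 1:
                raise ValueError(f"{self.kind} layer requires positive units")
        return self


class ModelSpec(BaseModel):
    """Declarative multi-branch architecture: one section per input branch and
    one common section applied after the branch outputs are concatenated."""

    input_length: int = 150
    branch_sections: dict[str, list[LayerSpec]] = Field(default_factory=dict)
    common_section: list[LayerSpec] = Field(default_factory=list)
    n_classes: int = 2


class TrainingConfig(BaseModel):
    """Optimisation hyper-parameters.

    The learning-rate scheduler and the one-cycle policy are only available
    with SGD; early stopping monitors validation loss with the given patience
    (consecutive epochs) and minimum improvement ``min_delta``.
    """

    batch_size: int = 32
    epochs: int = 30
    optimizer: Literal["sgd", "rmsprop", "adam"] = "adam"
    learning_rate: float = 1e-3
    lr_mode: Literal["constant", "scheduler", "one_cycle"] = "constant"
    early_stopping: bool = True
    patience: int = 10
    min_delta: float = 0.01
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_mode != "constant" and self.optimizer != "sgd":
            raise ValueError("lr_mode 'scheduler'/'one_cycle' requires the sgd optimizer")
        return self


class AttributionConfig(BaseModel):
    """Integrated Gradients settings: path resolution ``m_steps`` (default 50),
    target class (None = each sample's predicted class), and the tolerance
    above which a completeness-delta warning is emitted."""

    m_steps: int = 50
    target_class: Optional[int] = None
    top_k: int = 10
    completeness_tolerance: float = 1e-3

    @field_validator("m_steps")
    @classmethod
    def _steps(cls, v):
        if v < 1:
            raise ValueError("m_steps must be >= 1")
        return v


class FixtureSpec(BaseModel):
    """Parameters of the synthetic study system.

    A toy multi-chromosome genome of i.i.d. uniform bases, a positive class of
    windows carrying a planted motif at their centre, a motif-free negative
    class, and a per-base conservation track of Gaussian noise elevated by
    ``conservation_signal`` over motif-covered bases.
    """

    n_chroms: int = 4
    chrom_length: int = 100_000
    motif: str = "TGCATGC"
    n_per_class: int = 1000
    window: int = 150
    conservation_signal: float = 2.0
    conservation_noise_sd: float = 0.5
    seed: int = 0
    neg_strand_fraction: float = 0.0
    # Variant used to probe the value of the conservation branch: the motif is
    # planted in both classes and only the conservation signal separates them.
    motif_in_negatives: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.n_chroms < 1 or self.chrom_length < 1 or self.n_per_class < 1 or self.window < 1:
            raise ValueError("fixture dimensions must be positive")
        if self.chrom_length < self.window:
            raise ValueError(
                f"chrom_length ({self.chrom_length}) must be >= window ({self.window})"
            )
        if not set(self.motif) <= set("ACGT"):
            raise ValueError("motif must be over the alphabet {A,C,G,T}")
        if len(self.motif) >= self.window:
            raise ValueError("motif must be shorter than the window")
        if not 0.0 <= self.neg_strand_fraction <= 1.0:
            raise ValueError("neg_strand_fraction must be in [0, 1]")
        return self


class SplitConfig(BaseModel):
    mode: Literal["random", "by_chromosome"] = "random"
    ratios: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05)
    chromosome_assignment: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "random":
            if any(r < 0 for r in self.ratios):
                raise ValueError("split ratios must be non-negative")
            if abs(sum(self.ratios) - 1.0) > 1e-9:
                raise ValueError("split ratios must sum to 1")
        for subset in self.chromosome_assignment.values():
            if subset not in SUBSET_NAMES:
                raise ValueError(f"unknown subset '{subset}' in chromosome assignment")
        return self


class PreprocessingConfig(BaseModel):
    window: int = 150
    branches: list[str] = Field(default_factory=lambda: ["sequence"])
    reduce: dict[str, float] = Field(default_factory=dict)
    fold_engine: Literal["builtin", "vienna"] = "builtin"
    cores: int = 1

    @field_validator("branches")
    @classmethod
    def _known_branches(cls, v):
        unknown = set(v) - set(BRANCH_NAMES)
        if unknown:
            raise ValueError(f"unknown branches {sorted(unknown)}; allowed: {BRANCH_NAMES}")
        return v


class PathsConfig(BaseModel):
    beds: dict[str, str] = Field(default_factory=dict)  # class name -> BED path
    fasta: Optional[str] = None
    conservation: Optional[str] = None
    output_dir: Optional[str] = None


class RunConfig(BaseModel):
    """Everything a session needs, in one serialisable object."""

    paths: PathsConfig = Field(default_factory=PathsConfig)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    model: Optional[ModelSpec] = None
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    attribution: AttributionConfig = Field(default_factory=AttributionConfig)
    seed: int = 0


def save_run_config(config: RunConfig, path) -> None:
    """Write the config as YAML (the session's reproducibility log)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def _warn_unknown_keys(data, model_cls, prefix=""):
    if not isinstance(data, dict) or not (isinstance(model_cls, type) and issubclass(model_cls, BaseModel)):
        return
    fields = model_cls.model_fields
    for key, value in data.items():
        if key not in fields:
            warnings.warn(f"unknown config key '{prefix}{key}' ignored", stacklevel=3)
            continue
        ann = fields[key].annotation
        # unwrap Optional[Model]
        for candidate in getattr(ann, "__args__", (ann,)):
            if isinstance(candidate, type) and issubclass(candidate, BaseModel):
                _warn_unknown_keys(value, candidate, prefix=f"{prefix}{key}.")


def load_run_config(path) -> RunConfig:
    """Load a YAML run-config; unknown keys warn, scalars are coerced leniently."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"run config {path} does not contain a mapping")
    _warn_unknown_keys(data, RunConfig)

    def strip(d, model_cls):
        fields = model_cls.model_fields
        out = {}
        for k, v in d.items():
            if k not in fields:
                continue
            ann = fields[k].annotation
            sub = None
            for candidate in getattr(ann, "__args__", (ann,)):
                if isinstance(candidate, type) and issubclass(candidate, BaseModel):
                    sub = candidate
            if sub is not None and isinstance(v, dict):
                out[k] = strip(v, sub)
            else:
                out[k] = v
        return out

    return RunConfig(**strip(data, RunConfig))
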