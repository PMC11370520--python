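"""Pipeline configuration: YAML loading and validation.

A single root seed drives every stochastic stage through a documented
splitting rule: the simulator derives per-stage child streams
``default_rng([seed, stage_id])`` and the pipeline assigns stage seeds
``root_seed + k`` for its k-th stochastic consumer (CV folds, bootstraps).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigurationError
from .simulate import SimConfig


@dataclass
class MetaBlock:
    alphas: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    collapse_mode: str = "sd_scaled"  # or "literal"

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("meta.n_folds must be >= 2")
        if self.collapse_mode not in ("sd_scaled", "literal"):
            raise ConfigurationError(f"unknown collapse_mode {self.collapse_mode!r}")
        for a in self.alphas:
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError("meta.alphas must lie in [0,1]")


@dataclass
class EvalBlock:
    n_boot_auc: int = 2000
    n_boot_delta: int = 1000
    n_boot_nri: int = 1000
    n_boot_screen: int = 500
    horizon: float = 10.0
    stage1_threshold: float = 0.056
    nri_threshold: float = 0.10
    stage2_threshold: float = 0.143

    def validate(self) -> None:
        for name in ("n_boot_auc", "n_boot_delta", "n_boot_nri", "n_boot_screen"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"evaluate.{name} must be >= 1")
        for name in ("stage1_threshold", "nri_threshold", "stage2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"evaluate.{name} outside (0,1)")


@dataclass
class SplitBlock:
    """Tuning / training / testing sample fractions (testing = remainder)."""

    tune_frac: float = 0.15
    train_frac: float = 0.45

    def validate(self) -> None:
        if not (0 < self.tune_frac < 1 and 0 < self.train_frac < 1):
            raise ConfigurationError("split fractions must lie in (0,1)")
        if self.tune_frac + self.train_frac >= 1.0:
            raise ConfigurationError("tune_frac + train_frac must leave a test set")


@dataclass
class PipelineConfig:
    output_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimConfig = field(default_factory=SimConfig)
    split: SplitBlock = field(default_factory=SplitBlock)
    meta: MetaBlock = field(default_factory=MetaBlock)
    evaluate: EvalBlock = field(default_factory=EvalBlock)
    # optional external inputs; when set, the simulate stage is skipped
    genotypes_path: str | None = None
    cohort_path: str | None = None
    weight_table_paths: list[str] = field(default_factory=list)

    def validate(self) -> None:
        self.split.validate()
        self.meta.validate()
        self.evaluate.validate()
        for p in [self.genotypes_path, self.cohort_path, *self.weight_table_paths]:
            if p is not None and not os.path.exists(p):
                raise ConfigurationError(f"input path does not exist: {p}")


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    kwargs = dict(raw)
    if "simulate" in kwargs:
        sim = dict(kwargs["simulate"])
        for key in ("maf_range", "candidate_pvalues"):
            if key in sim:
                sim[key] = tuple(sim[key])
        kwargs["simulate"] = _build(SimConfig, sim)
    if "split" in kwargs:
        kwargs["split"] = _build(SplitBlock, kwargs["split"])
    if "meta" in kwargs:
        meta = dict(kwargs["meta"])
        if "alphas" in meta:
            meta["alphas"] = tuple(meta["alphas"])
        kwargs["meta"] = _build(MetaBlock, meta)
    if "evaluate" in kwargs:
        kwargs["evaluate"] = _build(EvalBlock, kwargs["evaluate"])
    cfg = _build(PipelineConfig, kwargs)
    cfg.validate()
    return cfg
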