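"""Pipeline configuration and reproducible random-stream management.

All stochastic stages of the pipeline (cohort simulation, resampling
splits, cross-validation fold shuffling, random-CpG controls) draw from
named substreams derived from a single master seed, so that a pipeline
run is fully determined by one integer.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config", "substream"]


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return an independent RNG for a named pipeline stage.

    The stream is keyed by ``(seed, crc32(stage), index)`` through
    :class:`numpy.random.SeedSequence`, so the same (seed, stage, index)
    triple always yields the same stream and distinct stages never share
    one, regardless of the order in which stages execute.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(index)]))


_DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the marker-discovery workflow.

    Defaults reproduce the published workflow: 1,000 stratified 70/30
    resampling splits, an accuracy gate of 80% on held-out predictions,
    a 10% consensus-frequency threshold, a variance filter removing CpGs
    consistently below 5% or above 95% methylation, Benjamini-Hochberg
    FDR at 0.05 for differential methylation, and a 15x random control
    of 1,500 CpGs for PAM clustering.
    """

    seed: int = 0
    n_splits: int = 1000
    train_fraction: float = 0.70
    accuracy_gate: float = 0.80
    consensus_threshold: float = 0.10
    alpha_grid: tuple[float, ...] = _DEFAULT_ALPHA_GRID
    cv_folds: int = 5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01  # glmnet's n < p convention
    variance_filter_low: float = 0.05
    variance_filter_high: float = 0.95
    dmp_fdr: float = 0.05
    n_random_cpgs: int = 1500
    n_random_repeats: int = 15
    spearman_alpha: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            ("train_fraction", 0.0 < self.train_fraction < 1.0),
            ("consensus_threshold", 0.0 < self.consensus_threshold <= 1.0),
            ("accuracy_gate", 0.0 <= self.accuracy_gate <= 1.0),
            ("n_splits", self.n_splits >= 1),
            ("cv_folds", self.cv_folds >= 2),
            ("n_lambda", self.n_lambda >= 2),
            ("lambda_min_ratio", 0.0 < self.lambda_min_ratio < 1.0),
            (
                "variance_filter_low",
                0.0 <= self.variance_filter_low < self.variance_filter_high <= 1.0,
            ),
            ("dmp_fdr", 0.0 <= self.dmp_fdr <= 1.0),
            ("n_random_cpgs", self.n_random_cpgs >= 1),
            ("n_random_repeats", self.n_random_repeats >= 1),
            ("spearman_alpha", 0.0 < self.spearman_alpha < 1.0),
            (
                "alpha_grid",
                len(self.alpha_grid) > 0
                and all(0.0 < a <= 1.0 for a in self.alpha_grid),
            ),
        ]
        for key, ok in checks:
            if not ok:
                raise ValueError(f"config value out of range: {key}={getattr(self, key)!r}")
        object.__setattr__(self, "alpha_grid", tuple(float(a) for a in self.alpha_grid))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_grid"] = list(self.alpha_grid)
        return d

    def rng(self, stage: str, index: int = 0) -> np.random.Generator:
        """Substream of the master seed for a named stage."""
        return substream(self.seed, stage, index)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key/value file.

    Absent keys take their defaults; keyword overrides win over the
    file. An empty or missing file yields the default configuration.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a key/value mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "alpha_grid" in values:
        values["alpha_grid"] = tuple(values["alpha_grid"])
    return PipelineConfig(**values)
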