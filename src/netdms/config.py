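"""YAML run configuration for the command-line interface.

A config file supplies input paths, the search and resampling parameters,
selection thresholds, per-study genomic-control lambdas and the seeds of
every stochastic stage.  Validation is strict: unknown keys and
out-of-range values are configuration errors (CLI exit code 2).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError
from .pipeline import PipelineParams
from .selection import SelectionCriteria


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    r: float = 0.1
    d: int = 2
    flank: int = 20_000
    B_assessment: int = 1000
    B_replication: int = 10_000
    n_strata: int = 10
    alpha_zm: float = 0.05
    alpha_gl: float = 0.05
    alpha_nsnps: float = 0.05
    alpha_topo: float = 0.05
    alpha_emp: float = 0.05
    alpha_zm_eval: float = 0.05
    alpha_emp_eval: float = 0.05
    max_missing_fraction: float = 0.2
    seed: int | None = None
    lambdas: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1 < self.r:
            raise ConfigError(f"r must exceed -1, got {self.r}")
        if self.d < 1:
            raise ConfigError(f"d must be >= 1, got {self.d}")
        if self.flank < 0:
            raise ConfigError(f"flank must be >= 0, got {self.flank}")
        for name in ("B_assessment", "B_replication"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100")
        for f_ in fields(self):
            if f_.name.startswith("alpha"):
                v = getattr(self, f_.name)
                if not 0 < v < 1:
                    raise ConfigError(f"{f_.name} must be in (0, 1), got {v}")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ConfigError("max_missing_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        known = {f_.name for f_ in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            alpha_zm=self.alpha_zm, alpha_gl=self.alpha_gl,
            alpha_nsnps=self.alpha_nsnps, alpha_topo=self.alpha_topo,
            alpha_emp=self.alpha_emp, alpha_zm_eval=self.alpha_zm_eval,
            alpha_emp_eval=self.alpha_emp_eval,
        )

    def pipeline_params(self) -> PipelineParams:
        if self.seed is None:
            raise ConfigError("a seed is required for stochastic stages")
        return PipelineParams(
            r=self.r, d=self.d, flank=self.flank, B=self.B_assessment,
            n_strata=self.n_strata, criteria=self.criteria(),
            max_missing_fraction=self.max_missing_fraction, seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)
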