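"""Run configuration for the end-to-end pipeline.

All printed analysis thresholds live in one overridable block
(``analysis_defaults``): the 500-kcal valid-day cutoff, the 50-kcal
eating-occasion threshold, the 5-valid-day inclusion minimum, and the
0.50 correlation cutoff for second-hit retention.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class AnalysisDefaults:
    valid_day_kcal: float = 500.0
    occasion_kcal: float = 50.0
    min_valid_days: int = 5
    correlation_cutoff: float = 0.50

    def __post_init__(self) -> None:
        for name in ("valid_day_kcal", "occasion_kcal"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.min_valid_days < 1:
            raise ConfigurationError("min_valid_days must be >= 1")
        if not 0 < self.correlation_cutoff <= 1:
            raise ConfigurationError("correlation_cutoff must lie in (0, 1]")


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the output directory."""

    seed: int = 0
    n_participants: int = 2000
    n_days: int = 7
    thresholds: AnalysisDefaults = field(default_factory=AnalysisDefaults)
    k_range: tuple[int, int] = (1, 10)
    n_restarts: int = 100
    linkage: str = "complete"
    silhouette_method: str = "classical"
    model2_covariates: tuple[str, ...] = (
        "region",
        "education",
        "work_hours",
        "sleep_duration",
    )
    plots: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        lo, hi = self.k_range
        if not 1 <= lo <= hi:
            raise ConfigurationError(f"k_range must be increasing from >= 1, got {self.k_range}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["k_range"] = list(self.k_range)
        d["model2_covariates"] = list(self.model2_covariates)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = AnalysisDefaults(**raw.pop("analysis_defaults", {}))
        synth = raw.pop("synthesis", {})
        kw = dict(raw)
        kw.update(synth)
        if "k_range" in kw:
            kw["k_range"] = tuple(kw["k_range"])
        if "model2_covariates" in kw:
            kw["model2_covariates"] = tuple(kw["model2_covariates"])
        try:
            return cls(thresholds=thresholds, **kw)
        except TypeError as exc:
            raise ConfigurationError(f"unknown configuration key: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        out = {
            "analysis_defaults": d.pop("thresholds"),
            "synthesis": {
                "n_participants": d.pop("n_participants"),
                "n_days": d.pop("n_days"),
            },
        }
        out.update(d)
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
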