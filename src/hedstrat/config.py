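"""Analysis configuration: every cohort-level constant in one place.

Defaults are the study constants of the GI-cancer ICB analysis this
package implements: locus-specific HED cutpoints from the maximally
selected rank statistics on overall survival (HLA-A 6.06, HLA-B 8.61,
HLA-C 2.55; HLA-B 10.19 for the MSK validation cohort), the Youden-index
TMB cutoff 5.22 mut/Mb, the somatic filter constants (depth 40, VAF 0.03,
population AF 0.002), the 24-week stable-disease window for durable
clinical benefit, and the differential-expression thresholds
(|log2FC| > 0.5849, p < 0.05).  All are overridable per run; every run
report echoes the effective configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError


@dataclass
class AnalysisConfig:
    matrix_mode: str = "published-integer"
    minprop: float = 0.1
    hed_cuts: dict = field(default_factory=lambda: {
        "A": 6.06, "B": 8.61, "C": 2.55, "B_msk": 10.19})
    tmb_cut: float = 5.22
    min_depth: int = 40
    min_vaf: float = 0.03
    max_pop_af: float = 0.002
    dcb_sd_weeks: float = 24.0
    deg_lfc: float = 0.5849
    deg_p: float = 0.05
    deg_method: str = "moderated"
    seed: int = 0

    def __post_init__(self) -> None:
        import math
        for name in ("minprop", "tmb_cut", "min_vaf", "max_pop_af",
                     "dcb_sd_weeks", "deg_lfc", "deg_p"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if not (0 < self.minprop < 0.5):
            raise ConfigurationError("minprop must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
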