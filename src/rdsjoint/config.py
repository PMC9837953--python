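"""Model configuration: covariate lists per submodel, baseline families,
random-effect structure and quadrature settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .model_core import FAMILIES

# derived episode-level covariates understood by the data layer
EPISODE_COVARIATES = ("n_prior", "n_prior_severe")

TIME_UNITS = {"days": 1.0, "weeks": 7.0, "years": 365.25}


@dataclass
class ModelConfig:
    """Which covariates enter each submodel, which baseline hazard families
    are used, and which components carry a random effect.

    Covariate names refer to columns of the long-format data; the special
    names ``n_prior`` and ``n_prior_severe`` (counts of completed prior
    exacerbations / prior severe ones at the onset of each exacerbation-free
    period) are derived automatically when `derive_episode_covariates` is on.
    Intercepts are implicit in every submodel.
    """

    rate_covariates: list = field(default_factory=list)
    duration_covariates: list = field(default_factory=list)
    severity_covariates: list = field(default_factory=list)
    zi_covariates: list = field(default_factory=list)
    family_rate: str = "lognormal"
    family_duration: str = "lognormal"
    include_duration: bool = True
    include_severity: bool = True
    include_zi: bool = True
    re_components: str = "BWS"
    derive_episode_covariates: bool = True
    quad_points: int = 5
    quad_mode: str = "adaptive"
    time_unit: str = "days"

    def __post_init__(self):
        for fam in (self.family_rate, self.family_duration):
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}; expected one of {FAMILIES}")
        if any(c not in "BWS" for c in self.re_components):
            raise ValueError("re_components must be a subset of 'BWS'")
        if self.quad_points < 1:
            raise ValueError("quad_points must be >= 1")
        if self.quad_mode not in ("adaptive", "fixed"):
            raise ValueError("quad_mode must be 'adaptive' or 'fixed'")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {sorted(TIME_UNITS)}")
        for name in self.zi_covariates:
            if name in EPISODE_COVARIATES:
                raise ValueError(
                    "the zero-inflation submodel uses baseline covariates only; "
                    f"{name!r} is episode-specific"
                )

    @property
    def active_re(self) -> tuple:
        """Indices (into B=0, W=1, S=2) of components carrying a random effect."""
        comps = []
        if "B" in self.re_components:
            comps.append(0)
        if "W" in self.re_components and self.include_duration:
            comps.append(1)
        if "S" in self.re_components and self.include_severity:
            comps.append(2)
        return tuple(comps)

    def baseline_covariate_names(self) -> list:
        names = []
        for group in (
            self.rate_covariates,
            self.duration_covariates,
            self.severity_covariates,
            self.zi_covariates,
        ):
            for n in group:
                if n not in names and n not in EPISODE_COVARIATES:
                    names.append(n)
        return names

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
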