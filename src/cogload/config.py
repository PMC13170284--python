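"""Configuration objects for the synthetic-cohort simulator.

The defaults encode the study conditions the downstream stages assume:
a ~215-type event vocabulary, provider-type shares of roughly
82%/12%/6% (physician/NP/PA), 73%/24%/3% of encounters involving one,
two or three providers, heavy-tailed (log-normal) dwell times, and an
initiation outcome generated from a logistic model that is quadratic in
loop count and distinct-event count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class DurationLaw:
    """A parametric law for strictly positive durations, in seconds.

    Supported names:

    * ``"lognormal"`` — parameters ``median`` (seconds) and ``sigma``
      (log-scale SD); heavy right tail, the default family because
      observed dwell distributions have mean far above median.
    * ``"exponential"`` — parameter ``mean``.
    * ``"gamma"`` — parameters ``shape`` and ``scale``.
    """

    name: str = "lognormal"
    params: dict = field(default_factory=lambda: {"median": 5.0, "sigma": 1.0})

    def __post_init__(self):
        if self.name not in ("lognormal", "exponential", "gamma"):
            raise ConfigurationError(f"duration law name {self.name!r} not supported")
        for key, val in self.params.items():
            if not (val > 0):
                raise ConfigurationError(
                    f"duration law parameter {key!r} must be positive, got {val!r}"
                )

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.name == "lognormal":
            mu = math.log(self.params["median"])
            return rng.lognormal(mu, self.params["sigma"], size)
        if self.name == "exponential":
            return rng.exponential(self.params["mean"], size)
        return rng.gamma(self.params["shape"], self.params["scale"], size)

    def mean(self) -> float:
        if self.name == "lognormal":
            return self.params["median"] * math.exp(self.params["sigma"] ** 2 / 2.0)
        if self.name == "exponential":
            return self.params["mean"]
        return self.params["shape"] * self.params["scale"]


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Coefficients of the quadratic logistic model generating initiation.

    Metric and covariate coefficients default to the fitted point
    estimates of the study's final regression model (log-odds scale;
    loops and distinct-event counts enter with quadratic terms).  The
    intercept is not reported there; the default of -0.5 puts the implied
    initiation rate near the observed 45.5% at mean covariate values.
    Provider intercepts are drawn from a zero-mean normal with SD
    ``provider_effect_sd``.
    """

    intercept: float = -0.5
    loops: float = -1.239e-02
    loops_sq: float = 6.597e-05
    distinct_events: float = 6.412e-02
    distinct_events_sq: float = -1.787e-03
    duration_minutes: float = 8.223e-03
    avg_event_seconds: float = -5.017e-04
    race_black: float = 1.967e-01
    race_hispanic: float = 5.906e-01
    race_asian: float = 4.425e-01
    race_other: float = 6.839e-01
    age: float = 1.023e-02
    female: float = -8.218e-02
    non_commercial: float = 5.738e-02
    n_active_diagnoses: float = -4.879e-02
    elixhauser: float = -9.656e-03
    provider_effect_sd: float = 0.25

    #: columns of the metrics/covariate frame each coefficient applies to,
    #: in (coefficient attribute, column, power) form.
    TERMS = (
        ("loops", "loops", 1),
        ("loops_sq", "loops", 2),
        ("distinct_events", "distinct_events", 1),
        ("distinct_events_sq", "distinct_events", 2),
        ("duration_minutes", "duration_minutes", 1),
        ("avg_event_seconds", "avg_event_seconds", 1),
        ("age", "age", 1),
        ("n_active_diagnoses", "n_active_diagnoses", 1),
        ("elixhauser", "elixhauser", 1),
    )

    def as_dict(self) -> dict:
        return asdict(self)


#: Race/ethnicity categories used throughout (reference level first).
RACE_LEVELS = ("White", "Black", "Hispanic", "Asian", "Other")

#: Provider types and their default shares.
PROVIDER_TYPES = ("physician", "NP", "PA")


def _check_probs(name, probs, length):
    """Validate a probability vector; printed shares that sum to 1 only up
    to rounding (within 0.005, e.g. 0.732/0.237/0.030) are renormalised to
    an exact simplex point."""
    probs = tuple(float(p) for p in probs)
    if len(probs) != length:
        raise ConfigurationError(f"{name} must have {length} entries, got {len(probs)}")
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"{name} entries must be non-negative")
    total = sum(probs)
    if abs(total - 1.0) > 5e-3:
        raise ConfigurationError(f"{name} must sum to 1 (got {total})")
    if abs(total - 1.0) > _PROB_TOL:
        probs = tuple(p / total for p in probs)
    return probs


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration for the synthetic audit-log/cohort generator."""

    n_patients: int = 2000
    n_providers: int = 50
    event_vocabulary_size: int = 215
    provider_type_probs: tuple = (0.8241, 0.1166, 0.0593)
    multi_provider_probs: tuple = (0.732, 0.237, 0.030)
    #: per-event active dwell within a segment, seconds (truncated below
    #: the timeout so a dwell never splits its own segment)
    dwell_time_law: DurationLaw = field(default_factory=DurationLaw)
    #: extra idle time beyond the timeout between active segments, seconds
    gap_time_law: DurationLaw = field(
        default_factory=lambda: DurationLaw("lognormal", {"median": 1800.0, "sigma": 1.0})
    )
    after_hours_prob: float = 0.30
    #: law of the merged-event count per provider-encounter (log-normal,
    #: rounded); median 100 with sigma 0.35 reproduces loop/distinct-event
    #: marginals near the study's (loops ~73, distinct ~34)
    merged_events_median: float = 100.0
    merged_events_sigma: float = 0.35
    #: mean probability that a merged event visits a new (unseen) type;
    #: 0.31 yields ~34 distinct types per ~107 merged events
    new_event_prob: float = 0.31
    #: Beta concentration of the per-encounter new-event probability
    new_event_concentration: float = 60.0
    #: log-scale SD of a per-provider-encounter dwell pace multiplier
    #: (log-normal, mean log 0); captures the strong between-encounter
    #: dispersion of average dwell (observed SD exceeds the mean) and
    #: decouples average event time from the merged-event count
    dwell_scale_sigma: float = 0.6
    #: probability a merged event is logged as two consecutive raw rows
    split_prob: float = 0.25
    timeout_seconds: float = 600.0
    outcome_coefficients: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    seed: int = 0

    def __post_init__(self):
        for fld in ("n_patients", "n_providers", "event_vocabulary_size"):
            val = getattr(self, fld)
            if not isinstance(val, (int, np.integer)) or isinstance(val, bool):
                raise ConfigurationError(f"{fld} must be an integer, got {val!r}")
            if fld == "n_patients":
                if val < 0:
                    raise ConfigurationError(f"{fld} must be non-negative, got {val}")
            elif val <= 0:
                raise ConfigurationError(f"{fld} must be positive, got {val}")
        object.__setattr__(
            self,
            "provider_type_probs",
            _check_probs("provider_type_probs", self.provider_type_probs, 3),
        )
        object.__setattr__(
            self,
            "multi_provider_probs",
            _check_probs("multi_provider_probs", self.multi_provider_probs, 3),
        )
        if self.dwell_scale_sigma < 0:
            raise ConfigurationError("dwell_scale_sigma must be non-negative")
        for fld in ("after_hours_prob", "new_event_prob", "split_prob"):
            val = getattr(self, fld)
            if not (0.0 <= val <= 1.0):
                raise ConfigurationError(f"{fld} must lie in [0, 1], got {val}")
        for fld in (
            "merged_events_median",
            "merged_events_sigma",
            "new_event_concentration",
            "timeout_seconds",
        ):
            if not (getattr(self, fld) > 0):
                raise ConfigurationError(f"{fld} must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(salt)))
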