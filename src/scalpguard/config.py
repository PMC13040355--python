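"""Configuration objects for the registration-stream simulator and pipeline.

The simulator emulates an outpatient appointment registration system in which
a small fraction of accounts (default 5%) are operated by automated "scalpers":
actors who book sought-after slots speculatively for resale.  Scalpers leave
three behavioral signatures that the ground-truth labeling rule keys on:

* bursts of cancelations (more than three within a 48 h window),
* one device ID fanning out to many medical-card IDs (more than five),
* operation completion times faster than any manual user (e.g. under 2 s).

All knobs live here so that the generator, the labeler and the model share one
source of truth.  Every probability vector must sum to one and every rate must
be positive; violations raise :class:`~scalpguard.errors.ConfigurationError`
naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Mapping

from .errors import ConfigurationError

_PROB_TOL = 1e-9


def _check_prob_vector(name: str, probs: Mapping[str, float]) -> None:
    if not probs:
        raise ConfigurationError(name, "must be a non-empty mapping")
    for key, p in probs.items():
        if not (0.0 <= float(p) <= 1.0):
            raise ConfigurationError(name, f"probability for {key!r} is {p}, outside [0, 1]")
    total = float(sum(probs.values()))
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigurationError(name, f"probabilities sum to {total!r}, not 1")


def _as_utc(d: date) -> datetime:
    if isinstance(d, datetime):
        return d if d.tzinfo else d.replace(tzinfo=timezone.utc)
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc)


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal duration distribution parameterized by its median (seconds)."""

    median_s: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median_s <= 0:
            raise ConfigurationError("median_s", f"must be > 0, got {self.median_s}")
        if self.sigma < 0:
            raise ConfigurationError("sigma", f"must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class CardFanoutSpec:
    """Distribution of medical-card IDs bound to one scalper device.

    Cards per device are ``min_cards + Poisson(extra_lam)``; the default floor
    of 6 puts the whole mass above the ">5 cards per device" signature.
    """

    min_cards: int = 6
    extra_lam: float = 1.5

    def __post_init__(self) -> None:
        if self.min_cards < 1:
            raise ConfigurationError("scalper_cards_per_device.min_cards", "must be >= 1")
        if self.extra_lam < 0:
            raise ConfigurationError("scalper_cards_per_device.extra_lam", "must be >= 0")


@dataclass(frozen=True)
class InterventionEffect:
    """Exogenous post-period shifts applied by the generator itself.

    These are calibration knobs for producing pre/post outcome tables, not
    claims about the real system: the study reports outcomes, not generative
    parameters.  With the defaults the generator is stationary and any
    pre/post difference is produced by the intervention policy alone.
    """

    scalper_activity_multiplier: float = 1.0
    legit_completion_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.scalper_activity_multiplier < 0:
            raise ConfigurationError("intervention_effect.scalper_activity_multiplier", "must be >= 0")
        if not -1.0 <= self.legit_completion_shift <= 1.0:
            raise ConfigurationError("intervention_effect.legit_completion_shift", "must be in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic registration stream.

    The default scenario is a scaled-down stand-in for a multi-year hospital
    registration window: 5,000 accounts over 360 days with the intervention at
    day 180, ~400 bookings per day, and 5% scalper prevalence.

    Notes on selected fields
    ------------------------
    arrival_rate_per_day
        Rate of the cohort-wide Poisson booking arrival process.  Arrivals are
        then attributed to accounts, scalpers drawing
        ``scalper_activity_weight`` times the weight of a legitimate account.
    legit_op_duration / scalper_op_duration
        Lognormal operation-completion times.  The scalper median of 0.8 s
        puts essentially all scalper mass below the 2 s manual-speed floor,
        while the legitimate median of 25 s leaves a negligible fast tail, so
        the fixed 2 s cut and a fast-1%-tail percentile rule roughly coincide.
    burst_size / burst_span_hours
        Scalper bookings are re-clustered into automated runs of
        ``burst_size`` bookings inside ``burst_span_hours``, anchored near the
        morning slot-release hour.
    label_noise
        Probability that a ground-truth label is flipped before "manual
        verification", emulating audit error.  Default 0 (audited labels).
    """

    n_accounts: int = 5000
    scalper_fraction: float = 0.05
    period_start: date = date(2020, 7, 5)
    intervention_date: date = date(2021, 1, 1)
    period_end: date = date(2021, 6, 30)
    arrival_rate_per_day: float = 400.0

    legit_op_duration: LognormalSpec = LognormalSpec(25.0, 0.6)
    scalper_op_duration: LognormalSpec = LognormalSpec(0.8, 0.5)

    legit_cancel_prob: float = 0.08
    scalper_cancel_prob: float = 0.55
    legit_complete_given_kept: float = 0.87
    scalper_complete_given_kept: float = 0.045

    scalper_cards_per_device: CardFanoutSpec = CardFanoutSpec()
    scalper_activity_weight: float = 6.0
    burst_size: int = 8
    burst_span_hours: float = 2.0
    min_scalper_bookings: int = 6
    scalper_department_focus: float = 0.85
    scalper_target_department: str = "cardiology"
    slot_release_hour: float = 7.0

    channel_mix: Mapping[str, float] = field(
        default_factory=lambda: {"online": 0.70, "on_site": 0.25, "telephone": 0.05}
    )
    departments: Mapping[str, float] = field(
        default_factory=lambda: {
            "internal_medicine": 0.30,
            "surgery": 0.22,
            "pediatrics": 0.18,
            "cardiology": 0.15,
            "dermatology": 0.15,
        }
    )
    age_bands: Mapping[str, float] = field(
        default_factory=lambda: {"18-30": 0.25, "31-45": 0.30, "46-60": 0.25, "60+": 0.20}
    )
    socio_bands: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.30, "middle": 0.50, "high": 0.20}
    )
    regions: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 0.60, "suburban": 0.25, "rural": 0.15}
    )

    intervention_effect: InterventionEffect = InterventionEffect()
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accounts < 1:
            raise ConfigurationError("n_accounts", f"must be >= 1, got {self.n_accounts}")
        if not 0.0 <= self.scalper_fraction <= 1.0:
            raise ConfigurationError("scalper_fraction", f"must be in [0, 1], got {self.scalper_fraction}")
        if not self.period_start < self.intervention_date < self.period_end:
            raise ConfigurationError(
                "intervention_date",
                f"dates must satisfy period_start < intervention_date < period_end, "
                f"got {self.period_start} / {self.intervention_date} / {self.period_end}",
            )
        if self.arrival_rate_per_day <= 0:
            raise ConfigurationError("arrival_rate_per_day", "must be > 0")
        for name in ("legit_cancel_prob", "scalper_cancel_prob",
                     "legit_complete_given_kept", "scalper_complete_given_kept",
                     "label_noise", "scalper_department_focus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, f"must be in [0, 1], got {v}")
        if self.scalper_activity_weight <= 0:
            raise ConfigurationError("scalper_activity_weight", "must be > 0")
        if self.burst_size < 1:
            raise ConfigurationError("burst_size", "must be >= 1")
        if self.burst_span_hours <= 0:
            raise ConfigurationError("burst_span_hours", "must be > 0")
        if not 0.0 <= self.slot_release_hour < 24.0:
            raise ConfigurationError("slot_release_hour", "must be in [0, 24)")
        _check_prob_vector("channel_mix", self.channel_mix)
        _check_prob_vector("departments", self.departments)
        _check_prob_vector("age_bands", self.age_bands)
        _check_prob_vector("socio_bands", self.socio_bands)
        _check_prob_vector("regions", self.regions)
        if self.scalper_target_department not in self.departments:
            raise ConfigurationError(
                "scalper_target_department",
                f"{self.scalper_target_department!r} not among departments",
            )

    # -- derived clock helpers -------------------------------------------------

    @property
    def start_dt(self) -> datetime:
        return _as_utc(self.period_start)

    @property
    def intervention_dt(self) -> datetime:
        return _as_utc(self.intervention_date)

    @property
    def end_dt(self) -> datetime:
        return _as_utc(self.period_end)

    @property
    def horizon_days(self) -> float:
        return (self.end_dt - self.start_dt).total_seconds() / 86400.0

    @property
    def pre_days(self) -> float:
        return (self.intervention_dt - self.start_dt).total_seconds() / 86400.0

    @property
    def post_days(self) -> float:
        return (self.end_dt - self.intervention_dt).total_seconds() / 86400.0

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class LabelingConfig:
    """Parameters of the two-of-three ground-truth labeling rule.

    ``speed_threshold_s`` is the documented fixed default (2 s); set it to
    ``None`` to derive the cut from the fast tail of reference operation
    durations via ``speed_percentile`` instead.  Thresholds are strict:
    a burst fires at 4+ cancels, fan-out at 6+ cards.
    """

    window_hours: float = 48.0
    min_cancels: int = 4          # "more than three"
    min_cards: int = 6            # "more than five"
    speed_threshold_s: float | None = 2.0
    speed_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ConfigurationError("window_hours", "must be > 0")
        if self.min_cancels < 1 or self.min_cards < 1:
            raise ConfigurationError("min_cancels/min_cards", "must be >= 1")
        if not 0 < self.speed_percentile < 100:
            raise ConfigurationError("speed_percentile", "must be in (0, 100)")
        if self.speed_threshold_s is not None and self.speed_threshold_s <= 0:
            raise ConfigurationError("speed_threshold_s", "must be > 0 or None")
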