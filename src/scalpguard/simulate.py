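"""Seeded generator of synthetic outpatient registration event streams.

The generator stands in for raw hospital registration data, which is not
publicly deposited.  It emulates the statistical structure the downstream
analysis assumes:

* a cohort of accounts, each independently a scalper with probability
  ``scalper_fraction`` (default 5%, the audited baseline prevalence);
* cohort-wide booking arrivals following a Poisson process at
  ``arrival_rate_per_day``, attributed to accounts with higher weight on
  scalpers (automated actors book far more than patients);
* scalper signatures generated by construction: bookings re-clustered into
  short automated runs anchored at the slot-release hour, sub-second
  operation times, one device cycling through six-plus medical cards, and a
  high cancel probability that yields cancel bursts;
* every booking resolved to exactly one of cancel / complete / no-show, so
  outcome tables satisfy the conservation identity by construction;
* a pre/post period structure around ``intervention_date``.

Event logs are plain :class:`pandas.DataFrame` objects with the column set
:data:`EVENT_COLUMNS`; timestamps are timezone-aware UTC at millisecond
resolution.  All randomness flows from ``config.seed`` (or an explicit seed)
through :class:`numpy.random.SeedSequence` spawning, so identical
(config, seed) pairs give field-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError, SchemaError

#: canonical column order of an event log
EVENT_COLUMNS = [
    "event_id", "account_id", "device_id", "ip", "card_id", "timestamp",
    "department", "channel", "action", "op_duration_s", "session_id",
    "ref_event_id",
]

ACTIONS = ("book", "cancel", "complete", "no_show")
#: actions performed interactively by the user; only these carry a
#: meaningful operation duration for speed analysis
USER_ACTIONS = ("book", "cancel")

LEGIT, SCALPER = "legitimate", "scalper"


@dataclass(frozen=True)
class AccountProfile:
    """One simulated actor with a latent class and identifier pools."""

    account_id: str
    latent_class: str  # "legitimate" | "scalper"
    age_band: str
    socio_band: str
    region: str
    home_device_ids: tuple[str, ...]
    card_ids: tuple[str, ...]
    ip_ids: tuple[str, ...] = field(default=())

    @property
    def is_scalper(self) -> bool:
        return self.latent_class == SCALPER


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> list[AccountProfile]:
    """Draw the account cohort.

    Each account is independently a scalper with probability
    ``config.scalper_fraction``.  Scalpers get a single home device bound to
    ``6 + Poisson(extra_lam)`` medical cards and several IPs; legitimate
    accounts get one device, one or two cards (family bookings) and one to
    three IPs.  Demographic attributes are drawn identically for both classes
    so that fairness audits compare like with like.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed if seed is None else seed))
    n = config.n_accounts
    is_scalper = rng.random(n) < config.scalper_fraction

    ages = rng.choice(list(config.age_bands), size=n, p=list(config.age_bands.values()))
    socio = rng.choice(list(config.socio_bands), size=n, p=list(config.socio_bands.values()))
    regions = rng.choice(list(config.regions), size=n, p=list(config.regions.values()))

    fan = config.scalper_cards_per_device
    cohort: list[AccountProfile] = []
    for i in range(n):
        acct = f"a{i:06d}"
        if is_scalper[i]:
            n_cards = fan.min_cards + int(rng.poisson(fan.extra_lam))
            n_ips = 2 + int(rng.poisson(2.0))
            devices = (f"d{i:06d}_0",)
        else:
            n_cards = 1 if rng.random() < 0.8 else 2
            n_ips = 1 + int(rng.integers(0, 3))
            devices = (f"d{i:06d}_0",)
        cohort.append(AccountProfile(
            account_id=acct,
            latent_class=SCALPER if is_scalper[i] else LEGIT,
            age_band=str(ages[i]), socio_band=str(socio[i]), region=str(regions[i]),
            home_device_ids=devices,
            card_ids=tuple(f"c{i:06d}_{k}" for k in range(n_cards)),
            ip_ids=tuple(f"ip{i:06d}_{k}" for k in range(n_ips)),
        ))
    return cohort


def cohort_frame(cohort: Sequence[AccountProfile]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per account)."""
    return pd.DataFrame({
        "account_id": [a.account_id for a in cohort],
        "latent_class": [a.latent_class for a in cohort],
        "age_band": [a.age_band for a in cohort],
        "socio_band": [a.socio_band for a in cohort],
        "region": [a.region for a in cohort],
        "n_devices": [len(a.home_device_ids) for a in cohort],
        "n_cards": [len(a.card_ids) for a in cohort],
    })


# ---------------------------------------------------------------------------
# event-log generation
# ---------------------------------------------------------------------------

def _assign_accounts(rng, n_events: int, weights: np.ndarray) -> np.ndarray:
    p = weights / weights.sum()
    return rng.choice(len(weights), size=n_events, p=p)


def generate_event_log(
    cohort: Sequence[AccountProfile],
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a schema-valid registration event log for ``cohort``.

    Returns a DataFrame with columns :data:`EVENT_COLUMNS`, sorted by
    timestamp.  Every cancel/complete/no_show row references the
    ``event_id`` of an earlier book row by the same account through
    ``ref_event_id``; book rows have a null reference.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort", "must be non-empty")
    if config.arrival_rate_per_day <= 0:
        raise ConfigurationError("arrival_rate_per_day", "must be > 0")

    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed if seed is None else seed, 1))
    )
    n_acc = len(cohort)
    scalper_mask = np.array([a.is_scalper for a in cohort])
    horizon_s = config.horizon_days * 86400.0
    t_interv = config.pre_days * 86400.0

    # --- cohort-wide Poisson arrivals, uniform given the count -------------
    n_book = rng.poisson(config.arrival_rate_per_day * config.horizon_days)
    t = np.sort(rng.uniform(0.0, horizon_s, size=n_book))

    # --- attribute arrivals to accounts, post-period multiplier applied ----
    w_pre = np.where(scalper_mask, config.scalper_activity_weight, 1.0)
    mult = config.intervention_effect.scalper_activity_multiplier
    w_post = np.where(scalper_mask, config.scalper_activity_weight * mult, 1.0)
    pre = t < t_interv
    owner = np.empty(n_book, dtype=np.int64)
    if pre.any():
        owner[pre] = _assign_accounts(rng, int(pre.sum()), w_pre)
    if (~pre).any():
        owner[~pre] = _assign_accounts(rng, int((~pre).sum()), w_post)

    # guarantee each scalper enough pre-period bookings to express its
    # signature (reassigned from legitimate bookings, preserving the total)
    scalper_idx = np.flatnonzero(scalper_mask)
    if len(scalper_idx) and pre.any():
        pre_owner = owner[pre]
        counts = np.bincount(pre_owner, minlength=n_acc)
        legit_pre_positions = np.flatnonzero(pre & ~scalper_mask[owner])
        rng.shuffle(legit_pre_positions)
        cursor = 0
        for si in scalper_idx:
            deficit = config.min_scalper_bookings - counts[si]
            while deficit > 0 and cursor < len(legit_pre_positions):
                owner[legit_pre_positions[cursor]] = si
                cursor += 1
                deficit -= 1

    # --- time-of-day shaping ------------------------------------------------
    day = np.floor(t / 86400.0)
    hour = np.clip(rng.normal(10.5, 3.0, size=n_book), 7.0, 18.0)
    t = day * 86400.0 + hour * 3600.0 + rng.uniform(0.0, 60.0, size=n_book)
    t = np.minimum(t, horizon_s - 1.0)

    # --- re-cluster scalper bookings into automated runs --------------------
    session = np.empty(n_book, dtype=object)
    for k in range(n_book):
        session[k] = f"s{k:07d}"
    # (the intervention boundary is day-aligned and a burst never leaves the
    # calendar day of its anchor booking, so bursts stay on their own side)
    burst_counter = 0
    for si in scalper_idx:
        for side in (pre, ~pre):
            pos = np.flatnonzero((owner == si) & side)
            if len(pos) == 0:
                continue
            pos = pos[np.argsort(t[pos])]
            for g0 in range(0, len(pos), config.burst_size):
                grp = pos[g0:g0 + config.burst_size]
                anchor_day = np.floor(t[grp[0]] / 86400.0)
                anchor = (anchor_day * 86400.0
                          + config.slot_release_hour * 3600.0
                          + rng.uniform(0.0, 1800.0))
                offs = np.sort(rng.uniform(0.0, config.burst_span_hours * 3600.0, size=len(grp)))
                t[grp] = np.minimum(anchor + offs, horizon_s - 1.0)
                for p in grp:
                    session[p] = f"burst{burst_counter:06d}"
                burst_counter += 1

    is_scalp_ev = scalper_mask[owner]

    # --- per-event attributes ----------------------------------------------
    def _logn(spec, size):
        return rng.lognormal(mean=np.log(spec.median_s), sigma=spec.sigma, size=size)

    op_dur = np.where(is_scalp_ev,
                      _logn(config.scalper_op_duration, n_book),
                      _logn(config.legit_op_duration, n_book))

    channels = np.array(list(config.channel_mix))
    chan = rng.choice(channels, size=n_book, p=list(config.channel_mix.values()))
    chan = np.where(is_scalp_ev, "online", chan)

    depts = np.array(list(config.departments))
    dept = rng.choice(depts, size=n_book, p=list(config.departments.values()))
    hot = rng.random(n_book) < config.scalper_department_focus
    dept = np.where(is_scalp_ev & hot, config.scalper_target_department, dept)

    # identifier pools: scalper cards cycle deterministically so the fan-out
    # signature (>5 distinct cards on one device) is realized by construction
    device = np.empty(n_book, dtype=object)
    card = np.empty(n_book, dtype=object)
    ip = np.empty(n_book, dtype=object)
    per_acct_seq = np.zeros(n_acc, dtype=np.int64)
    for k in range(n_book):
        a = cohort[owner[k]]
        j = per_acct_seq[owner[k]]
        per_acct_seq[owner[k]] += 1
        device[k] = a.home_device_ids[j % len(a.home_device_ids)]
        if a.is_scalper:
            card[k] = a.card_ids[j % len(a.card_ids)]
        else:
            card[k] = a.card_ids[int(rng.integers(len(a.card_ids)))]
        ip[k] = a.ip_ids[int(rng.integers(len(a.ip_ids)))]

    # --- resolve every booking to cancel / complete / no_show ---------------
    cancel_p = np.where(is_scalp_ev, config.scalper_cancel_prob, config.legit_cancel_prob)
    u = rng.random(n_book)
    cancels = u < cancel_p
    comp_base = np.where(is_scalp_ev, config.scalper_complete_given_kept,
                         config.legit_complete_given_kept)
    shift = config.intervention_effect.legit_completion_shift
    comp_p = np.where(~is_scalp_ev & (t >= t_interv),
                      np.clip(comp_base + shift, 0.0, 1.0), comp_base)
    completes = ~cancels & (rng.random(n_book) < comp_p)

    # resolution timestamps: cancels shortly after booking (automated runs
    # cancel within hours once resale fails), completes/no-shows at slot time
    cancel_delay = np.where(is_scalp_ev,
                            rng.uniform(12.0, 36.0, n_book) * 3600.0,
                            rng.uniform(6.0, 72.0, n_book) * 3600.0)
    slot_delay = rng.uniform(2.0, 14.0, n_book) * 86400.0
    res_t = np.where(cancels, t + cancel_delay, t + slot_delay)
    res_t = np.minimum(res_t, horizon_s - 0.5)
    res_action = np.where(cancels, "cancel", np.where(completes, "complete", "no_show"))
    res_dur = np.where(
        res_action == "cancel",
        np.where(is_scalp_ev,
                 _logn(config.scalper_op_duration, n_book),
                 _logn(config.legit_op_duration, n_book)),
        0.0,
    )

    # --- assemble ------------------------------------------------------------
    start = config.start_dt
    book_ids = np.arange(n_book, dtype=np.int64)
    res_ids = np.arange(n_book, 2 * n_book, dtype=np.int64)
    acct_ids = np.array([a.account_id for a in cohort], dtype=object)

    def _ts(seconds: np.ndarray) -> pd.Series:
        ms = np.round(np.asarray(seconds) * 1000.0).astype("int64")
        return pd.Series(pd.Timestamp(start) + pd.to_timedelta(ms, unit="ms"))

    books = pd.DataFrame({
        "event_id": book_ids,
        "account_id": acct_ids[owner],
        "device_id": device, "ip": ip, "card_id": card,
        "timestamp": _ts(t),
        "department": dept, "channel": chan,
        "action": "book", "op_duration_s": op_dur,
        "session_id": session,
        "ref_event_id": pd.array([pd.NA] * n_book, dtype="Int64"),
    })
    resolutions = pd.DataFrame({
        "event_id": res_ids,
        "account_id": acct_ids[owner],
        "device_id": device, "ip": ip, "card_id": card,
        "timestamp": _ts(res_t),
        "department": dept, "channel": chan,
        "action": res_action, "op_duration_s": res_dur,
        "session_id": np.array([f"r{int(i):07d}" for i in book_ids], dtype=object),
        "ref_event_id": pd.array(book_ids, dtype="Int64"),
    })
    log = pd.concat([books, resolutions], ignore_index=True)
    log = log.sort_values(["timestamp", "event_id"], kind="mergesort").reset_index(drop=True)
    log["op_duration_s"] = log["op_duration_s"].astype(float)
    return log[EVENT_COLUMNS]


def validate_event_log(events: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` if ``events`` violates the event-log schema.

    Checks column presence, action domain, nonnegative durations, and
    referential integrity (every non-book action resolves to exactly one
    earlier book event by the same account).
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if len(events) == 0:
        return
    bad = set(events["action"]) - set(ACTIONS)
    if bad:
        raise SchemaError(f"unknown actions: {sorted(bad)}")
    if (events["op_duration_s"] < 0).any():
        raise SchemaError("negative op_duration_s")
    books = events[events["action"] == "book"].set_index("event_id")
    nonbook = events[events["action"] != "book"]
    refs = nonbook["ref_event_id"]
    if refs.isna().any():
        raise SchemaError("non-book event without ref_event_id")
    unknown = ~refs.isin(books.index)
    if unknown.any():
        raise SchemaError("non-book event references a missing book event")
    ref_rows = books.loc[refs.astype("int64")]
    if not (ref_rows["account_id"].to_numpy() == nonbook["account_id"].to_numpy()).all():
        raise SchemaError("referenced booking belongs to a different account")
    if (ref_rows["timestamp"].to_numpy() > nonbook["timestamp"].to_numpy()).any():
        raise SchemaError("resolution precedes its booking")


def simulate(config: SimulationConfig, seed: int | None = None):
    """Convenience wrapper: draw a cohort and its event log in one call."""
    base = config.seed if seed is None else seed
    cohort = generate_cohort(config, seed=base)
    events = generate_event_log(cohort, config, seed=base)
    return cohort, events
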