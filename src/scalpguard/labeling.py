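"""Ground-truth labeling: an account is "abnormal" when at least two of three
behavioral criteria hold.

Criteria (strict inequalities):

1. **cancel burst** — more than three cancelations inside some sliding 48 h
   window (windows are closed on the left, open on the right);
2. **card fan-out** — the account used a device that is associated with more
   than five distinct medical-card IDs over the whole log;
3. **fast ops** — any user operation (book or cancel) faster than the speed
   threshold, by default the fixed 2 s manual-speed floor, optionally derived
   as the fast 1% tail of reference operation durations.

A device-level fan-out flag marks every account that used that device, since
the criterion is stated per device but labels are per account.  An optional
label-noise flip emulates imperfect manual audit of the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LabelingConfig
from .errors import ScalpGuardError
from .simulate import USER_ACTIONS

ABNORMAL, NORMAL = "abnormal", "normal"


@dataclass(frozen=True)
class CriteriaFlags:
    cancel_burst: bool
    card_fanout: bool
    fast_ops: bool

    @property
    def n_true(self) -> int:
        return int(self.cancel_burst) + int(self.card_fanout) + int(self.fast_ops)


@dataclass(frozen=True)
class GroundTruthLabel:
    account_id: str
    flags: CriteriaFlags
    label: str

    def __post_init__(self):
        expected = ABNORMAL if self.flags.n_true >= 2 else NORMAL
        if self.label not in (ABNORMAL, NORMAL):
            raise ScalpGuardError(f"unknown label {self.label!r}")
        # noise-flipped labels are allowed to disagree with the flags; the
        # invariant label⇔flags is asserted by label_accounts at noise 0


def _max_count_in_window(times_s: np.ndarray, window_s: float) -> int:
    """Max number of points of ``times_s`` in any [x, x+window_s) interval.

    Two-pointer sweep anchored at each point; equals brute-force window
    enumeration because an optimal window can always be slid left until its
    left edge touches a point.
    """
    if len(times_s) == 0:
        return 0
    ts = np.sort(np.asarray(times_s, dtype=float))
    best = 1
    j = 0
    for i in range(len(ts)):
        while ts[i] - ts[j] >= window_s:
            j += 1
        best = max(best, i - j + 1)
    return best


def max_cancels_in_window(events: pd.DataFrame, account_id: str,
                          window_hours: float = 48.0) -> int:
    """Maximum number of the account's cancel events in any sliding window.

    Unknown accounts (or accounts without cancels) yield 0 — absence, not an
    error.
    """
    sub = events[(events["account_id"] == account_id) & (events["action"] == "cancel")]
    if len(sub) == 0:
        return 0
    t0 = sub["timestamp"].min()
    secs = (sub["timestamp"] - t0).dt.total_seconds().to_numpy()
    return _max_count_in_window(secs, window_hours * 3600.0)


def cards_per_device(events: pd.DataFrame) -> dict[str, int]:
    """Distinct card IDs ever seen with each device over the whole log."""
    if len(events) == 0:
        return {}
    return events.groupby("device_id")["card_id"].nunique().to_dict()


def speed_threshold(events: pd.DataFrame, percentile: float = 99.0,
                    fixed: float | None = None,
                    reference_accounts=None) -> float:
    """Speed cut separating the fastest (100−percentile)% of operations.

    Manual operation durations are right-skewed, so "faster than the 99th
    percentile of manual operation times" is read as the fast tail: the cut
    is the (100−percentile)-th percentile of reference durations, below which
    only the fastest 1% of manual operations fall.  Supplying ``fixed``
    (e.g. the documented 2 s default) bypasses the computation.  The
    reference set is all user operations, or only those of
    ``reference_accounts`` (e.g. accounts currently unflagged).
    """
    if fixed is not None:
        return float(fixed)
    ops = events[events["action"].isin(USER_ACTIONS)]
    if reference_accounts is not None:
        ops = ops[ops["account_id"].isin(set(reference_accounts))]
    if len(ops) == 0:
        raise ScalpGuardError("no reference operations to derive a speed threshold from")
    return float(np.percentile(ops["op_duration_s"].to_numpy(), 100.0 - percentile))


def account_flags(events: pd.DataFrame, config: LabelingConfig = LabelingConfig()) -> pd.DataFrame:
    """Per-account criteria flags for every account appearing in ``events``.

    Returns a DataFrame indexed by account_id with boolean columns
    ``cancel_burst``, ``card_fanout``, ``fast_ops``.
    """
    accounts = pd.Index(events["account_id"].unique(), name="account_id")
    out = pd.DataFrame(False, index=accounts,
                       columns=["cancel_burst", "card_fanout", "fast_ops"])
    if len(events) == 0:
        return out

    # fast ops: min user-operation duration under the threshold
    thr = speed_threshold(events, percentile=config.speed_percentile,
                          fixed=config.speed_threshold_s)
    ops = events[events["action"].isin(USER_ACTIONS)]
    fast = ops.groupby("account_id")["op_duration_s"].min() < thr
    out.loc[fast.index, "fast_ops"] = fast

    # card fan-out: flag every account that used an over-fanned device
    fan = events.groupby("device_id")["card_id"].nunique()
    hot_devices = set(fan.index[fan >= config.min_cards])
    if hot_devices:
        hit = events.loc[events["device_id"].isin(hot_devices), "account_id"].unique()
        out.loc[hit, "card_fanout"] = True

    # cancel burst: sliding-window count per account (only accounts with
    # enough cancels overall can possibly qualify)
    cancels = events[events["action"] == "cancel"]
    if len(cancels):
        t0 = cancels["timestamp"].min()
        secs = (cancels["timestamp"] - t0).dt.total_seconds()
        counts = cancels.groupby("account_id").size()
        window_s = config.window_hours * 3600.0
        for acct in counts.index[counts >= config.min_cancels]:
            ts = secs[cancels["account_id"] == acct].to_numpy()
            if _max_count_in_window(ts, window_s) >= config.min_cancels:
                out.loc[acct, "cancel_burst"] = True
    return out


def label_accounts(events: pd.DataFrame,
                   config: LabelingConfig = LabelingConfig(),
                   accounts=None,
                   label_noise: float = 0.0,
                   seed: int | None = None) -> pd.DataFrame:
    """Apply the two-of-three rule to every account.

    Parameters
    ----------
    accounts : optional iterable
        Accounts to include even if they have no events (labeled normal with
        all flags false).
    label_noise : float
        Probability of flipping each final label, emulating audit error in
        the "manually verified" ground truth.  Default 0.

    Returns a DataFrame with columns ``account_id``, the three flag columns,
    ``n_criteria`` and ``label``; deterministic given (events, config, seed).
    """
    flags = account_flags(events, config)
    if accounts is not None:
        idx = pd.Index(pd.unique(pd.Series(list(accounts))), name="account_id")
        flags = flags.reindex(flags.index.union(idx, sort=False), fill_value=False)
    flags = flags.sort_index()
    n_crit = flags.sum(axis=1).astype(int)
    label = np.where(n_crit >= 2, ABNORMAL, NORMAL)
    if label_noise > 0.0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(label)) < label_noise
        label = np.where(flip, np.where(label == ABNORMAL, NORMAL, ABNORMAL), label)
    out = flags.reset_index()
    out["n_criteria"] = n_crit.to_numpy()
    out["label"] = label
    return out


def labels_as_records(frame: pd.DataFrame) -> list[GroundTruthLabel]:
    """Convert a label frame to typed records."""
    return [
        GroundTruthLabel(
            account_id=row.account_id,
            flags=CriteriaFlags(bool(row.cancel_burst), bool(row.card_fanout),
                                bool(row.fast_ops)),
            label=row.label,
        )
        for row in frame.itertuples(index=False)
    ]
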