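"""Per-account behavioral feature extraction (the 12-variable vector X1–X12).

The committed definitions, computed from an account's event history:

=====  ====================================================================
X1     booking hour-of-day (circular; expanded to a sin/cos column pair)
X2     department-choice entropy over bookings (nats)
X3     bookings per active day (bookings / distinct calendar days w/ events)
X4     mean inter-operation interval (s); single-op accounts get a cap
X5     minimum user-operation duration (s)
X6     maximum cancels in any sliding 48 h window (count)
X7     cancel-to-book ratio in [0, 1]
X8     maximum card fan-out over the account's devices (count, log-wide)
X9     distinct IPs (count)
X10    mean session duration (s); one-event sessions use op_duration_s
X11    account history length (days, first event to end of log)
X12    online-channel share of bookings in [0, 1]
=====  ====================================================================

X1 is one named feature but two matrix columns (sin, cos of the circular
mean booking hour); the model operates on the 13-column expanded matrix.
Feature extraction is a pure function of the event multiset: permuting the
log leaves every value unchanged.

Duration-like columns (X4, X5, X10) are heavily right-skewed, so the design
matrix applies log1p to them before standardization; the standardization
parameters (per-column mean/SD on training data) are stored on the
:class:`DesignMatrix` for reuse when scoring new accounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LabelingConfig
from .errors import ScalpGuardError
from .labeling import account_flags, _max_count_in_window
from .simulate import USER_ACTIONS

FEATURE_NAMES = [
    "x1_hour", "x2_dept_entropy", "x3_bookings_per_day", "x4_interop_s",
    "x5_min_op_s", "x6_max_cancels_48h", "x7_cancel_ratio", "x8_card_fanout",
    "x9_distinct_ips", "x10_session_s", "x11_history_days", "x12_online_share",
]

MATRIX_COLUMNS = [
    "x1_hour_sin", "x1_hour_cos", "x2_dept_entropy", "x3_bookings_per_day",
    "x4_interop_s", "x5_min_op_s", "x6_max_cancels_48h", "x7_cancel_ratio",
    "x8_card_fanout", "x9_distinct_ips", "x10_session_s", "x11_history_days",
    "x12_online_share",
]

#: columns log1p-transformed before standardization (right-skewed durations)
LOG_COLUMNS = ["x4_interop_s", "x5_min_op_s", "x10_session_s"]

#: X4 value assigned to accounts with a single operation (one day, seconds)
SINGLE_OP_INTEROP_CAP_S = 86_400.0


def _entropy_nats(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def compute_feature_frame(events: pd.DataFrame,
                          labeling: LabelingConfig = LabelingConfig()) -> pd.DataFrame:
    """Feature table (13 expanded columns) for every account with events."""
    if len(events) == 0:
        raise ScalpGuardError("cannot extract features from an empty event log")
    ev = events.sort_values("timestamp", kind="mergesort")
    t_end = ev["timestamp"].max()
    secs = (ev["timestamp"] - ev["timestamp"].min()).dt.total_seconds()
    day_secs = (ev["timestamp"].dt.hour * 3600 + ev["timestamp"].dt.minute * 60
                + ev["timestamp"].dt.second
                + ev["timestamp"].dt.microsecond / 1e6)
    ev = ev.assign(_secs=secs.to_numpy(), _day_secs=day_secs.to_numpy(),
                   _day=ev["timestamp"].dt.floor("D").to_numpy())

    books = ev[ev["action"] == "book"]
    cancels = ev[ev["action"] == "cancel"]
    ops = ev[ev["action"].isin(USER_ACTIONS)]
    g_all = ev.groupby("account_id", sort=True)
    g_book = books.groupby("account_id")
    g_ops = ops.groupby("account_id")

    accounts = pd.Index(ev["account_id"].unique()).sort_values()
    out = pd.DataFrame(index=accounts)

    # X1 circular mean booking hour (clock time, not log-relative time)
    hour = books["_day_secs"] / 3600.0 * (2 * np.pi / 24.0)
    hsin = hour.groupby(books["account_id"]).apply(lambda h: np.mean(np.sin(h)))
    hcos = hour.groupby(books["account_id"]).apply(lambda h: np.mean(np.cos(h)))
    out["x1_hour_sin"] = hsin.reindex(accounts).fillna(0.0)
    out["x1_hour_cos"] = hcos.reindex(accounts).fillna(0.0)

    # X2 department entropy over bookings
    dept_counts = books.groupby(["account_id", "department"]).size()
    ent = dept_counts.groupby("account_id").apply(lambda c: _entropy_nats(c.to_numpy()))
    out["x2_dept_entropy"] = ent.reindex(accounts).fillna(0.0)

    # X3 bookings per active day
    n_books = g_book.size().reindex(accounts).fillna(0.0)
    active_days = g_all["_day"].nunique().reindex(accounts)
    out["x3_bookings_per_day"] = (n_books / active_days).fillna(0.0)

    # X4 mean inter-operation interval (user ops, chronological)
    def _mean_gap(s: pd.Series) -> float:
        v = np.sort(s.to_numpy())
        if len(v) < 2:
            return SINGLE_OP_INTEROP_CAP_S
        return float(np.mean(np.diff(v)))
    out["x4_interop_s"] = (g_ops["_secs"].apply(_mean_gap)
                           .reindex(accounts).fillna(SINGLE_OP_INTEROP_CAP_S))

    # X5 minimum user-operation duration
    out["x5_min_op_s"] = g_ops["op_duration_s"].min().reindex(accounts) \
        .fillna(SINGLE_OP_INTEROP_CAP_S)

    # X6 max cancels in the labeling window
    window_s = labeling.window_hours * 3600.0
    x6 = cancels.groupby("account_id")["_secs"] \
        .apply(lambda s: _max_count_in_window(s.to_numpy(), window_s))
    out["x6_max_cancels_48h"] = x6.reindex(accounts).fillna(0).astype(float)

    # X7 cancel-to-book ratio
    n_cancel = cancels.groupby("account_id").size().reindex(accounts).fillna(0.0)
    with np.errstate(invalid="ignore"):
        out["x7_cancel_ratio"] = (n_cancel / n_books.replace(0, np.nan)).fillna(0.0)

    # X8 max card fan-out over the account's devices (device counts log-wide)
    fan = ev.groupby("device_id")["card_id"].nunique()
    dev_fan = ev[["account_id", "device_id"]].drop_duplicates()
    dev_fan = dev_fan.assign(fan=dev_fan["device_id"].map(fan))
    out["x8_card_fanout"] = dev_fan.groupby("account_id")["fan"].max() \
        .reindex(accounts).fillna(0).astype(float)

    # X9 distinct IPs
    out["x9_distinct_ips"] = g_all["ip"].nunique().reindex(accounts).astype(float)

    # X10 mean session duration
    sess = ev.groupby(["account_id", "session_id"]).agg(
        span=("_secs", lambda s: s.max() - s.min()),
        n=("_secs", "size"),
        dur=("op_duration_s", "first"),
    )
    sess_dur = np.where(sess["n"] > 1, sess["span"], sess["dur"])
    out["x10_session_s"] = pd.Series(sess_dur, index=sess.index) \
        .groupby("account_id").mean().reindex(accounts)

    # X11 history length in days (first event to end of log)
    first = g_all["timestamp"].min().reindex(accounts)
    out["x11_history_days"] = (t_end - first).dt.total_seconds() / 86400.0

    # X12 online share of bookings
    online = books.groupby("account_id")["channel"] \
        .apply(lambda c: float(np.mean(c.to_numpy() == "online")))
    out["x12_online_share"] = online.reindex(accounts).fillna(0.0)

    out.index.name = "account_id"
    assert list(out.columns) == MATRIX_COLUMNS
    if not np.isfinite(out.to_numpy(dtype=float)).all():
        raise ScalpGuardError("non-finite feature value produced")
    return out


def extract_features(events: pd.DataFrame, account_id: str,
                     labeling: LabelingConfig = LabelingConfig()) -> pd.Series:
    """Feature vector for one account (errors if the account has no events)."""
    sub = events[events["account_id"] == account_id]
    if len(sub) == 0:
        raise ScalpGuardError(f"account {account_id!r} has no events")
    # history length must be measured against the whole log's clock
    row = compute_feature_frame(events, labeling).loc[account_id].copy()
    return row


@dataclass
class DesignMatrix:
    """Feature matrix with aligned labels, groups and a frozen standardizer.

    ``X`` holds natural-unit features (13 expanded columns); ``Xs`` the
    log1p+standardized matrix the Gaussian model consumes.  ``mean_`` and
    ``sd_`` are the training-time standardization parameters, stored so new
    accounts are mapped through the identical pipeline at scoring time.
    """

    X: pd.DataFrame
    y: np.ndarray                     # 1 = abnormal/scalper, 0 = normal
    groups: pd.DataFrame | None = None
    mean_: pd.Series | None = None
    sd_: pd.Series | None = None
    log_columns: tuple = tuple(LOG_COLUMNS)
    feature_names: tuple = tuple(FEATURE_NAMES)

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ScalpGuardError(
                f"label/account mismatch: {len(self.X)} rows vs {len(self.y)} labels")
        if self.mean_ is None:
            Xt = self._transform_raw(self.X)
            self.mean_ = Xt.mean()
            sd = Xt.std(ddof=0)
            self.sd_ = sd.mask(sd < 1e-12, 1.0)  # constant columns pass through

    def _transform_raw(self, X: pd.DataFrame) -> pd.DataFrame:
        Xt = X.copy()
        for c in self.log_columns:
            Xt[c] = np.log1p(Xt[c])
        return Xt

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """log1p + standardize with the stored training parameters."""
        Xt = self._transform_raw(self.X if X is None else X[self.X.columns])
        return (Xt - self.mean_) / self.sd_

    @property
    def Xs(self) -> pd.DataFrame:
        return self.transform()

    @property
    def account_ids(self) -> pd.Index:
        return self.X.index

    def __len__(self) -> int:
        return len(self.X)


def build_design_matrix(events: pd.DataFrame, labels: pd.DataFrame,
                        groups: pd.DataFrame | None = None,
                        labeling: LabelingConfig = LabelingConfig()) -> DesignMatrix:
    """One row per labeled account, aligned to ``labels``.

    ``labels`` must cover every account present in ``events`` (the
    ground-truth frame from :func:`scalpguard.labeling.label_accounts`);
    ``groups`` optionally carries protected attributes (age band, socio
    band) for fairness audits, indexed or keyed by ``account_id``.
    """
    X = compute_feature_frame(events, labeling)
    lab = labels.set_index("account_id") if "account_id" in labels.columns else labels
    missing = X.index.difference(lab.index)
    if len(missing):
        raise ScalpGuardError(
            f"labels missing for {len(missing)} accounts (e.g. {list(missing[:3])})")
    y = (lab.loc[X.index, "label"].to_numpy() == "abnormal").astype(int)
    g = None
    if groups is not None:
        g = groups.set_index("account_id") if "account_id" in groups.columns else groups
        g = g.reindex(X.index)
    return DesignMatrix(X=X, y=y, groups=g)
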