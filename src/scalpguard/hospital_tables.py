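"""Published summary tables from the deployment hospital, as literal inputs.

The raw registration records behind the study are not deposited; what is
reproducible at the desk are the printed annual summary tables and the
reported detection metrics.  They ship as small packaged CSVs and are used
as *inputs* — e.g. recomputing appointment rates from volumes, or the risk
ratio from completion rates — never as oracles wired into the model.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import RiskRatioResult, risk_ratio

#: reported detection-performance operating point of the deployed model
REPORTED_DETECTION = {"precision_pct": 85.1, "recall_pct": 89.2,
                      "accuracy_pct": 93.7, "auc": 0.91}


def _read(name: str) -> pd.DataFrame:
    with resources.files("scalpguard").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_annual_registration() -> pd.DataFrame:
    """Annual outpatient volume and appointment volume, 2020–2023."""
    return _read("annual_registration.csv")


def load_completion_rates() -> pd.DataFrame:
    """Annual completion / no-show rates (completed + no-show = 100%)."""
    return _read("completion_rates.csv")


def load_channel_mix() -> pd.DataFrame:
    """Annual booking-channel shares (online / on-site / telephone)."""
    return _read("channel_mix.csv")


def appointment_rates() -> pd.Series:
    """Appointment rate (%) per year recomputed from the volume table."""
    t = load_annual_registration()
    rates = (100.0 * t["appointment_volume"] / t["outpatient_volume"]).to_numpy()
    return pd.Series(rates, index=t["year"].to_numpy(), name="appointment_rate_pct")


def pooled_appointment_rate() -> float:
    """Pooled (volume-weighted) mean appointment rate (%), all years."""
    t = load_annual_registration()
    return float(100.0 * t["appointment_volume"].sum() / t["outpatient_volume"].sum())


def completion_risk_ratio(year_ref: int = 2019, year_cmp: int = 2022,
                          level: float = 0.95) -> RiskRatioResult:
    """RR of appointment completion between two years, from counts
    reconstructed off the printed rates and yearly n."""
    t = load_completion_rates().set_index("year")
    e1 = int(round(t.loc[year_ref, "n"] * t.loc[year_ref, "completion_rate_pct"] / 100.0))
    e2 = int(round(t.loc[year_cmp, "n"] * t.loc[year_cmp, "completion_rate_pct"] / 100.0))
    return risk_ratio(e1, int(t.loc[year_ref, "n"]), e2, int(t.loc[year_cmp, "n"]),
                      level=level)


def completion_improvement_pp(year_ref: int = 2019, year_cmp: int = 2022) -> float:
    """Completion-rate change in percentage points between two years."""
    t = load_completion_rates().set_index("year")
    return float(t.loc[year_cmp, "completion_rate_pct"]
                 - t.loc[year_ref, "completion_rate_pct"])


def f1_from_reported(precision_pct: float | None = None,
                     recall_pct: float | None = None) -> float:
    """F1 via the harmonic-mean identity from reported precision/recall."""
    p = (REPORTED_DETECTION["precision_pct"] if precision_pct is None else precision_pct) / 100.0
    r = (REPORTED_DETECTION["recall_pct"] if recall_pct is None else recall_pct) / 100.0
    return 2.0 * p * r / (p + r)
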