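"""Shared fixtures: small seeded simulation scenarios reused across tests."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scalpguard as sg
from scalpguard.features import build_design_matrix
from scalpguard.simulate import cohort_frame

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sm_config() -> sg.SimulationConfig:
    """A small but behaviorally complete scenario (400 accounts, 360 days)."""
    return sg.SimulationConfig(n_accounts=400, arrival_rate_per_day=60, seed=11)


@pytest.fixture(scope="session")
def sm_sim(sm_config):
    cohort, events = sg.simulate(sm_config)
    return cohort, events


@pytest.fixture(scope="session")
def sm_cohort(sm_sim):
    return sm_sim[0]


@pytest.fixture(scope="session")
def sm_events(sm_sim):
    return sm_sim[1]


@pytest.fixture(scope="session")
def sm_labels(sm_events):
    return sg.label_accounts(sm_events)


@pytest.fixture(scope="session")
def sm_dm(sm_events, sm_labels, sm_cohort):
    groups = cohort_frame(sm_cohort).set_index("account_id")
    return build_design_matrix(sm_events, sm_labels,
                               groups=groups[["age_band", "socio_band", "latent_class"]])


@pytest.fixture(scope="session")
def short_config() -> sg.SimulationConfig:
    """10-day horizon used for arrival-process checks."""
    return sg.SimulationConfig(
        n_accounts=50, arrival_rate_per_day=50,
        period_start=date(2021, 1, 1), intervention_date=date(2021, 1, 6),
        period_end=date(2021, 1, 11), seed=7)


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Hand-built event frames for unit tests.

    Each row dict may give ``hours`` (offset from 2021-01-01 UTC), plus any
    schema columns; sensible defaults fill the rest.
    """
    base = pd.Timestamp("2021-01-01", tz="UTC")
    out = []
    for i, row in enumerate(rows):
        r = {
            "event_id": i, "account_id": "acct", "device_id": "dev",
            "ip": "ip0", "card_id": "card", "department": "surgery",
            "channel": "online", "action": "book", "op_duration_s": 20.0,
            "session_id": f"s{i}", "ref_event_id": pd.NA,
        }
        r.update({k: v for k, v in row.items() if k != "hours"})
        r["timestamp"] = base + pd.Timedelta(hours=float(row.get("hours", i)))
        out.append(r)
    df = pd.DataFrame(out)
    df["ref_event_id"] = df["ref_event_id"].astype("Int64")
    return df[sg.EVENT_COLUMNS]
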