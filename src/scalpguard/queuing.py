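"""Patient-flow queueing model feeding the dynamic prior.

Arrivals are Poisson, service exponential, ``c`` parallel servers, FIFO,
infinite waiting room (M/M/c).  A discrete-event simulation produces
time-averaged congestion metrics; closed-form M/M/1 and Erlang-C formulas
serve as analytic cross-checks.  The coupling surface to the risk model is
the scalar ``congestion_index`` in [0, 1].
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class QueueConfig:
    arrival_rate: float          # per hour
    service_rate: float          # per hour per server
    servers: int = 1
    horizon_hours: float = 10_000.0
    burn_in_frac: float = 0.10   # leading fraction excluded from time averages
    seed: int = 0

    def __post_init__(self):
        if self.arrival_rate <= 0 or self.service_rate <= 0:
            raise ConfigurationError("arrival_rate/service_rate", "must be > 0")
        if self.servers < 1:
            raise ConfigurationError("servers", "must be >= 1")
        if not 0.0 <= self.burn_in_frac < 1.0:
            raise ConfigurationError("burn_in_frac", "must be in [0, 1)")


@dataclass
class QueueMetrics:
    utilization: float            # rho = lambda / (c mu)
    L: float                      # time-averaged number in system
    W: float                      # mean sojourn time (hours)
    congestion_index: float
    stable: bool
    n_served: int
    queue_length_ts: tuple = field(default=(), repr=False)  # (times, counts)


def analytic_mm1(lam: float, mu: float) -> tuple[float, float, float]:
    """(rho, L, W) for the single-server queue; requires lam < mu."""
    if lam <= 0 or mu <= 0:
        raise ConfigurationError("lam/mu", "must be > 0")
    if lam >= mu:
        raise ConfigurationError("lam", f"no steady state: lam={lam} >= mu={mu}")
    rho = lam / mu
    return rho, rho / (1.0 - rho), 1.0 / (mu - lam)


def erlang_c(lam: float, mu: float, c: int) -> dict:
    """Erlang-C waiting probability and steady-state L, W for M/M/c."""
    if lam <= 0 or mu <= 0 or c < 1:
        raise ConfigurationError("lam/mu/c", "must be positive")
    a = lam / mu                      # offered load
    rho = a / c
    if rho >= 1:
        raise ConfigurationError("lam", f"no steady state: rho={rho} >= 1")
    s = sum(a ** k / math.factorial(k) for k in range(c))
    tail = a ** c / (math.factorial(c) * (1.0 - rho))
    p_wait = tail / (s + tail)
    lq = p_wait * rho / (1.0 - rho)
    l_tot = lq + a
    return {"p_wait": p_wait, "Lq": lq, "L": l_tot,
            "Wq": lq / lam, "W": l_tot / lam, "rho": rho}


def congestion_index(metrics_or_rho, mapping: str = "utilization") -> float:
    """Monotone map of load to [0, 1]; default is clamped utilization."""
    rho = metrics_or_rho.utilization if isinstance(metrics_or_rho, QueueMetrics) \
        else float(metrics_or_rho)
    if mapping == "utilization":
        return float(min(max(rho, 0.0), 1.0))
    if mapping == "softplus":
        return float(1.0 - math.exp(-max(rho, 0.0)))
    raise ConfigurationError("mapping", f"unknown congestion mapping {mapping!r}")


def simulate_queue(config: QueueConfig) -> QueueMetrics:
    """Seeded discrete-event simulation of the M/M/c queue.

    L is the time integral of the number-in-system over the post-burn-in
    window divided by its length; W averages sojourn times of customers
    arriving after burn-in.  For rho >= 1 metrics are still computed but the
    result carries ``stable=False``.
    """
    rng = np.random.default_rng(config.seed)
    lam, mu, c, T = (config.arrival_rate, config.service_rate,
                     config.servers, config.horizon_hours)
    rho = lam / (c * mu)

    # arrival times on [0, T)
    n_exp = int(lam * T * 1.3 + 10 * math.sqrt(lam * T) + 10)
    gaps = rng.exponential(1.0 / lam, size=n_exp)
    arrivals = np.cumsum(gaps)
    while arrivals[-1] < T:  # extremely unlikely; extend defensively
        more = np.cumsum(rng.exponential(1.0 / lam, size=n_exp)) + arrivals[-1]
        arrivals = np.concatenate([arrivals, more])
    arrivals = arrivals[arrivals < T]
    services = rng.exponential(1.0 / mu, size=len(arrivals))

    avail = [0.0] * c           # heap of per-server next-available times
    departures = np.empty(len(arrivals))
    sojourn = np.empty(len(arrivals))
    for i, (a, s) in enumerate(zip(arrivals, services)):
        free = heapq.heappop(avail)        # FIFO: earliest-available server
        start = max(a, free)
        comp = start + s
        heapq.heappush(avail, comp)
        departures[i] = comp
        sojourn[i] = comp - a

    burn = config.burn_in_frac * T
    # number-in-system step function from merged arrival/departure marks
    times = np.concatenate([arrivals, departures])
    steps = np.concatenate([np.ones_like(arrivals), -np.ones_like(departures)])
    order = np.argsort(times, kind="mergesort")
    times, steps = times[order], np.cumsum(steps[order])
    inside = (times >= burn) & (times <= T)
    t_knots = np.concatenate([[burn], times[inside], [T]])
    # count just before each knot: value carried from the last event <= knot
    idx = np.searchsorted(times, t_knots[:-1], side="right") - 1
    n_at = np.where(idx >= 0, steps[np.clip(idx, 0, None)], 0)
    L = float(np.sum(n_at * np.diff(t_knots)) / (T - burn))

    after = arrivals >= burn
    W = float(sojourn[after].mean()) if after.any() else float("nan")
    return QueueMetrics(
        utilization=rho, L=L, W=W,
        congestion_index=congestion_index(rho),
        stable=rho < 1.0, n_served=int(after.sum()),
        queue_length_ts=(tuple(t_knots[:-1]), tuple(n_at)),
    )
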