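"""Synthetic SCCS case series, estimation, and Monte Carlo verification.

The generative model mirrors the analytic reduction used by the power
engine: each case contributes one event day in a ``T``-day window whose
first ``e`` days (the post-vaccination risk window) carry relative incidence
``rho``.  The event lands in the risk window with probability
``rho * e / (rho * e + (T - e))`` and is uniform within whichever segment it
lands in.  Placing the risk window at days ``1..e`` is a labelling
convention only; the in/out dichotomy is all the statistics see.

Monte Carlo power and type-I error computed here verify the exact analytic
values from :mod:`sccspool.power` without any shared code path beyond the
critical value itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .power import (
    SccsDesign,
    binomial_critical_value,
    case_position_probability,
    exposed_fraction,
)

__all__ = [
    "DEFAULT_SEED",
    "SccsDataset",
    "EstimateResult",
    "simulate_dataset",
    "count_in_risk",
    "estimate_relative_incidence",
    "empirical_power",
    "empirical_type1",
    "write_dataset_csv",
    "read_dataset_csv",
]

logger = logging.getLogger(__name__)

#: Default RNG seed recorded in logs so reported simulation numbers reproduce.
DEFAULT_SEED = 20240914

_Z = {  # standard normal quantiles for common confidence levels
    0.90: 1.6448536269514722,
    0.95: 1.959963984540054,
    0.99: 2.5758293035489004,
}


@dataclass(frozen=True)
class SccsDataset:
    """A simulated case series: one event day per case.

    ``event_days`` are 1-based day indices in ``[1, observation_days]``; days
    ``1..risk_days`` are the risk window.
    """

    risk_days: int
    observation_days: int
    event_days: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.event_days)
        if days.size and (days.min() < 1 or days.max() > self.observation_days):
            raise ValueError("event days must lie in [1, observation_days]")

    @property
    def n_cases(self) -> int:
        return int(np.asarray(self.event_days).size)


@dataclass(frozen=True)
class EstimateResult:
    """Conditional ML estimate of the relative incidence with a Wald CI.

    Degenerate counts (no events in one of the two window segments) yield
    0/inf/nan sentinels rather than exceptions.
    """

    rho_hat: float
    ci_low: float
    ci_high: float
    n_in_risk: int


def _draw_event_days(
    rng: np.random.Generator, design: SccsDesign, shape: tuple[int, ...]
) -> np.ndarray:
    """Draw event days under the weighted-window model, vectorized."""
    e, T = design.risk_days, design.observation_days
    p_risk = case_position_probability(
        design.relative_incidence, exposed_fraction(design)
    )
    in_risk = rng.random(shape) < p_risk
    days = np.where(
        in_risk,
        rng.integers(1, e + 1, size=shape),
        rng.integers(e + 1, T + 1, size=shape),
    )
    return days


def simulate_dataset(n_cases: int, design: SccsDesign, seed: int) -> SccsDataset:
    """Simulate a case series of ``n_cases`` independent events.

    Reproducible: the same seed always yields the same dataset.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be at least 1")
    rng = np.random.default_rng(seed)
    days = _draw_event_days(rng, design, (n_cases,))
    return SccsDataset(design.risk_days, design.observation_days, days)


def count_in_risk(dataset: SccsDataset) -> int:
    """Number of events in the risk window (days 1..e inclusive)."""
    return int((np.asarray(dataset.event_days) <= dataset.risk_days).sum())


def estimate_relative_incidence(
    dataset: SccsDataset, confidence: float = 0.95
) -> EstimateResult:
    """Conditional ML estimate of ``rho`` from a single-interval case series.

    With ``X`` of ``n`` events in the risk window,
    ``rho_hat = (X / (n - X)) * ((T - e) / e)`` and the log-scale variance is
    ``1/X + 1/(n - X)`` (Wald interval on the log scale).
    """
    n = dataset.n_cases
    if n < 1:
        raise ValueError("dataset has no cases")
    x = count_in_risk(dataset)
    e, T = dataset.risk_days, dataset.observation_days
    z = _Z.get(confidence)
    if z is None:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + confidence / 2.0))
    if x == 0:
        return EstimateResult(0.0, 0.0, np.nan, 0)
    if x == n:
        return EstimateResult(np.inf, np.nan, np.inf, n)
    rho_hat = (x / (n - x)) * ((T - e) / e)
    se = np.sqrt(1.0 / x + 1.0 / (n - x))
    log_rho = np.log(rho_hat)
    return EstimateResult(
        rho_hat=float(rho_hat),
        ci_low=float(np.exp(log_rho - z * se)),
        ci_high=float(np.exp(log_rho + z * se)),
        n_in_risk=x,
    )


def _empirical_rejection_rate(
    design: SccsDesign, n_cases: int, reps: int, seed: int
) -> tuple[float, float]:
    if reps < 100:
        raise ValueError("reps must be at least 100")
    r = exposed_fraction(design)
    c = binomial_critical_value(n_cases, r, design.alpha)
    if c is None:
        logger.warning(
            "no rejection region exists at n=%d, alpha=%g (cannot-reject); "
            "reporting power 0",
            n_cases,
            design.alpha,
        )
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    days = _draw_event_days(rng, design, (reps, n_cases))
    counts = (days <= design.risk_days).sum(axis=1)
    p_hat = float((counts >= c).mean())
    mc_se = float(np.sqrt(p_hat * (1.0 - p_hat) / reps))
    return p_hat, mc_se


def empirical_power(
    design: SccsDesign, n_cases: int, reps: int = 10_000, seed: int = DEFAULT_SEED
) -> tuple[float, float]:
    """Monte Carlo power of the exact test, with its binomial standard error.

    Simulates ``reps`` case series of ``n_cases`` events under the design's
    relative incidence and reports the fraction whose in-risk count reaches
    the critical value, alongside the Monte Carlo standard error of that
    fraction.
    """
    return _empirical_rejection_rate(design, n_cases, reps, seed)


def empirical_type1(
    design: SccsDesign, n_cases: int, reps: int = 10_000, seed: int = DEFAULT_SEED
) -> tuple[float, float]:
    """Monte Carlo type-I error: the same machinery with ``rho`` forced to 1."""
    null_design = SccsDesign(
        relative_incidence=1.0,
        risk_days=design.risk_days,
        observation_days=design.observation_days,
        alpha=design.alpha,
        target_power=design.target_power,
    )
    return _empirical_rejection_rate(null_design, n_cases, reps, seed)


def write_dataset_csv(dataset: SccsDataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "event_day"])
        for i, day in enumerate(np.asarray(dataset.event_days), start=1):
            writer.writerow([i, int(day)])


def read_dataset_csv(
    path: str | Path, risk_days: int, observation_days: int
) -> SccsDataset:
    days = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            days.append(int(row["event_day"]))
    return SccsDataset(risk_days, observation_days, np.asarray(days, dtype=int))
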