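"""Exact power and sample-size calculations for the self-controlled case series.

A self-controlled case series (SCCS) with a single post-vaccination risk
window reduces to a binomial problem: each case contributes one event day
inside a ``T``-day observation window, of which the first ``e`` days carry a
relative incidence ``rho`` compared with the remaining ``T - e`` control
days.  Conditional on being a case, the probability that the event falls in
the risk window is

    p(rho) = rho * r / (1 + (rho - 1) * r),     r = e / T,

so testing ``rho = 1`` against ``rho > 1`` on ``n`` cases is a one-sample
binomial test of ``p = r`` against ``p = p(rho)``, and the number of *events*
(not subjects) drives the power of the design.

The sample-size engine finds the smallest number of events whose one-sided
binomial test at level ``alpha/2`` (the upper half of a two-sided ``alpha``;
surveillance only ever flags elevated risk) attains the target power.  The
rejection threshold follows the classical sample-size convention: the
critical count is the smallest ``c`` whose continuity-corrected normal
upper-tail probability under the null is at most ``alpha/2``, while the
power attained at that threshold is always an exact binomial tail summed in
log space.  A fully exact-tail threshold is available via
``tail_method="exact"``; see the package methods note for how the two differ
on small designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, norm

__all__ = [
    "SccsDesign",
    "SampleSizeResult",
    "exposed_fraction",
    "case_position_probability",
    "binomial_critical_value",
    "attained_power",
    "required_events",
    "approx_required_events",
]

TailMethod = Literal["normal", "exact"]

#: Cap on the event-count search in :func:`required_events`.
_MAX_EVENTS_SEARCH = 100_000


@dataclass(frozen=True)
class SccsDesign:
    """An SCCS surveillance design.

    Parameters
    ----------
    relative_incidence:
        Ratio ``rho`` of event incidence inside the risk window to incidence
        during control time.  ``rho = 1`` is the null of no elevated risk.
    risk_days:
        Length ``e`` of the post-vaccination risk window, in days.
    observation_days:
        Length ``T`` of the full observation window, in days; must exceed
        ``risk_days``.
    alpha:
        Two-sided significance level of the signal test (default 0.05).
    target_power:
        Required probability of detecting ``rho`` when it is real
        (default 0.90).
    """

    relative_incidence: float
    risk_days: int
    observation_days: int
    alpha: float = 0.05
    target_power: float = 0.90

    def __post_init__(self) -> None:
        if not self.relative_incidence > 0:
            raise ValueError("relative_incidence must be positive")
        if not 0 < self.risk_days < self.observation_days:
            raise ValueError(
                "risk window must be shorter than the observation window "
                f"(got risk_days={self.risk_days}, "
                f"observation_days={self.observation_days})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search.

    ``n_required`` is the minimal number of observed events, ``critical_value``
    the in-risk-window count at which the test rejects, ``attained_power`` the
    exact power at that sample size, and ``p_null``/``p_alt`` the in-window
    probabilities under ``rho = 1`` and the design's ``rho``.
    """

    n_required: int
    critical_value: int
    attained_power: float
    p_null: float
    p_alt: float


def exposed_fraction(design: SccsDesign) -> float:
    """Fraction ``r = e / T`` of the observation window at elevated risk."""
    return design.risk_days / design.observation_days


def case_position_probability(relative_incidence: float, exposed_fraction: float) -> float:
    """Probability a case's event falls in the risk window.

    ``p = rho * r / (1 + (rho - 1) * r)``; this is the single-risk-interval
    SCCS reduction, with ``p = r`` when ``rho = 1``.
    """
    if not relative_incidence > 0:
        raise ValueError("relative_incidence must be positive")
    if not 0 < exposed_fraction < 1:
        raise ValueError("exposed_fraction must lie strictly in (0, 1)")
    rho, r = relative_incidence, exposed_fraction
    return rho * r / (1.0 + (rho - 1.0) * r)


def binomial_critical_value(
    n_events: int,
    null_probability: float,
    alpha: float,
    tail_method: TailMethod = "normal",
) -> int | None:
    """Smallest in-window count at which the upper-tail test rejects.

    Returns the smallest ``c`` such that the upper-tail probability
    ``P(X >= c | n, p0)`` is at most ``alpha / 2``, or ``None`` when even
    ``c = n`` fails (the "cannot-reject" sentinel: no rejection region of the
    requested size exists).

    With ``tail_method="normal"`` (default) the tail probability is the
    continuity-corrected normal approximation used throughout the classical
    sample-size literature; with ``"exact"`` it is the exact binomial tail
    summed in log space.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if not 0 < null_probability < 1:
        raise ValueError("null_probability must lie in (0, 1)")
    level = alpha / 2.0
    if tail_method == "normal":
        mu = n_events * null_probability
        sd = math.sqrt(n_events * null_probability * (1.0 - null_probability))
        for c in range(n_events + 1):
            if norm.sf((c - 0.5 - mu) / sd) <= level:
                return c
        return None
    if tail_method == "exact":
        for c in range(n_events + 1):
            if _exact_upper_tail(n_events, null_probability, c) <= level:
                return c
        return None
    raise ValueError(f"unknown tail_method: {tail_method!r}")


def _exact_upper_tail(n: int, p: float, c: int) -> float:
    """P(X >= c) for X ~ Binomial(n, p), by log-space mass summation."""
    if c <= 0:
        return 1.0
    if c > n:
        return 0.0
    k = np.arange(c, n + 1)
    return float(np.exp(logsumexp(binom.logpmf(k, n, p))))


def attained_power(
    n_events: int,
    design: SccsDesign,
    tail_method: TailMethod = "normal",
) -> float:
    """Exact probability of rejecting the null with ``n_events`` cases.

    The critical count comes from :func:`binomial_critical_value` at the
    design's null probability ``e / T``; the power is the exact binomial
    upper tail at the alternative probability.  Returns 0 when no rejection
    region exists at this ``n``.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    r = exposed_fraction(design)
    c = binomial_critical_value(n_events, r, design.alpha, tail_method)
    if c is None:
        return 0.0
    p_alt = case_position_probability(design.relative_incidence, r)
    return _exact_upper_tail(n_events, p_alt, c)


def required_events(
    design: SccsDesign,
    tail_method: TailMethod = "normal",
    strict: bool = False,
    strict_horizon_factor: int = 5,
) -> SampleSizeResult:
    """Minimal number of observed events meeting the design's target power.

    Searches upward from ``n = 1`` and returns the first ``n`` whose exact
    power reaches ``target_power``.  Because exact-test power is sawtoothed
    in ``n``, ``strict=True`` additionally requires every larger ``n`` up to
    ``strict_horizon_factor * n`` to meet the target as well.

    Raises
    ------
    ValueError
        If ``relative_incidence <= 1``: no finite number of events can detect
        a non-elevated risk with an upper-tail test.
    """
    if design.relative_incidence <= 1.0:
        raise ValueError(
            "no finite sample size for non-elevated risk "
            f"(relative_incidence={design.relative_incidence})"
        )
    r = exposed_fraction(design)
    p_alt = case_position_probability(design.relative_incidence, r)

    def _passes(n: int) -> bool:
        return attained_power(n, design, tail_method) >= design.target_power

    for n in range(1, _MAX_EVENTS_SEARCH + 1):
        if not _passes(n):
            continue
        if strict and not all(
            _passes(m) for m in range(n + 1, strict_horizon_factor * n + 1)
        ):
            continue
        c = binomial_critical_value(n, r, design.alpha, tail_method)
        assert c is not None
        return SampleSizeResult(
            n_required=n,
            critical_value=c,
            attained_power=attained_power(n, design, tail_method),
            p_null=r,
            p_alt=p_alt,
        )
    raise RuntimeError(
        f"no sample size up to {_MAX_EVENTS_SEARCH} attains the target power"
    )


def approx_required_events(
    design: SccsDesign,
    method: Literal["wald-mixed", "likelihood-ratio"] = "wald-mixed",
) -> int:
    """Normal-approximation sample sizes, as asymptotic cross-checks.

    ``"wald-mixed"`` is the two-variance normal formula
    ``[z_{1-a/2} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1)]^2 / (p1 - p0)^2``;
    ``"likelihood-ratio"`` divides ``(z_{1-a/2} + z_{1-b})^2`` by twice the
    per-case Kullback-Leibler divergence of Bernoulli(p1) from Bernoulli(p0).
    Both round up.  Neither replaces the exact engine; they bracket it.
    """
    if design.relative_incidence <= 1.0:
        raise ValueError(
            "no finite sample size for non-elevated risk "
            f"(relative_incidence={design.relative_incidence})"
        )
    p0 = exposed_fraction(design)
    p1 = case_position_probability(design.relative_incidence, p0)
    q0, q1 = 1.0 - p0, 1.0 - p1
    z_a = norm.ppf(1.0 - design.alpha / 2.0)
    z_b = norm.ppf(design.target_power)
    if method == "wald-mixed":
        num = z_a * math.sqrt(p0 * q0) + z_b * math.sqrt(p1 * q1)
        return math.ceil((num / (p1 - p0)) ** 2)
    if method == "likelihood-ratio":
        kl = p1 * math.log(p1 / p0) + q1 * math.log(q1 / q0)
        return math.ceil((z_a + z_b) ** 2 / (2.0 * kl))
    raise ValueError(f"unknown method: {method!r}")
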