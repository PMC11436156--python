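"""Days-of-throughput-to-detect scenarios over jurisdictions and pools.

Given an SCCS design, a per-dose adverse-event risk, and a mass-vaccination
throughput model, each scenario row converts a jurisdiction's (or pool's)
population into doses per day, doses into expected events per day, and the
design's required event count into whole days of vaccination throughput
needed before the safety signal can be declared.

All scenario-side probabilities are carried as :class:`fractions.Fraction`
so that the floor in the throughput step and the ceiling in the days step
are exact integer arithmetic rather than float rounding.  Displayed
events-per-day values are rounded for humans only; every day count is
computed from the unrounded rate.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .populations import ABBREVIATIONS, Registry, default_registry
from .power import SccsDesign, required_events

__all__ = [
    "ThroughputModel",
    "ScenarioSpec",
    "RowSpec",
    "ScenarioRow",
    "SignalNeverAccruesError",
    "jurisdiction_throughput",
    "expected_events_per_day",
    "days_to_detect",
    "events_averted",
    "deaths_averted",
    "expected_adverse_events",
    "run_scenario",
    "load_config",
    "load_config_multi",
    "parse_probability",
    "write_csv",
    "render_table",
]


class SignalNeverAccruesError(ValueError):
    """Raised when the expected event rate is zero or negative."""


def parse_probability(value: float | str | Fraction) -> Fraction:
    """Normalize a probability given as 0.00001, "0.00001", or "1/100000".

    The scientific sources for these rates mix decimal and ratio notation;
    both are accepted, and ratio numerators may themselves be decimal
    ("1.5/100000").  Floats are interpreted via their shortest decimal
    representation.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        if "/" in value:
            num, den = value.split("/", 1)
            return Fraction(num.strip()) / Fraction(den.strip())
        return Fraction(value.strip())
    if isinstance(value, int):
        return Fraction(value)
    return Fraction(repr(float(value)))


@dataclass(frozen=True)
class ThroughputModel:
    """How a jurisdiction's daily vaccination throughput is derived.

    Modes
    -----
    anchored:
        Scale an anchor jurisdiction's absolute throughput by population:
        every jurisdiction achieves the same *relative* throughput
        (``anchor_doses_per_day / anchor_population`` of its own population
        per day).
    flat:
        A fixed fraction of the stratum population vaccinated per day.
    explicit:
        A directly specified doses-per-day figure, population ignored.
    """

    mode: str
    anchor_doses_per_day: int | None = None
    anchor_population: int | None = None
    daily_fraction: Fraction | None = None
    doses_per_day: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "anchored":
            if not (self.anchor_doses_per_day and self.anchor_doses_per_day > 0):
                raise ValueError("anchored mode needs anchor_doses_per_day > 0")
            if not (self.anchor_population and self.anchor_population > 0):
                raise ValueError("anchored mode needs anchor_population > 0")
        elif self.mode == "flat":
            if self.daily_fraction is None or not 0 < self.daily_fraction < 1:
                raise ValueError("flat mode needs 0 < daily_fraction < 1")
        elif self.mode == "explicit":
            if not (self.doses_per_day and self.doses_per_day > 0):
                raise ValueError("explicit mode needs doses_per_day > 0")
        else:
            raise ValueError(f"unknown throughput mode: {self.mode!r}")

    @classmethod
    def anchored(cls, anchor_doses_per_day: int, anchor_population: int) -> "ThroughputModel":
        return cls("anchored", anchor_doses_per_day=anchor_doses_per_day,
                   anchor_population=anchor_population)

    @classmethod
    def flat(cls, daily_fraction: float | str | Fraction) -> "ThroughputModel":
        return cls("flat", daily_fraction=parse_probability(daily_fraction))

    @classmethod
    def explicit(cls, doses_per_day: int) -> "ThroughputModel":
        return cls("explicit", doses_per_day=doses_per_day)


def jurisdiction_throughput(population: int, model: ThroughputModel) -> int:
    """Whole vaccine doses per day for a jurisdiction of this population.

    Anchored and flat modes floor to whole doses; explicit mode passes its
    figure through unchanged.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if model.mode == "anchored":
        return (population * model.anchor_doses_per_day) // model.anchor_population
    if model.mode == "flat":
        return math.floor(population * model.daily_fraction)
    return model.doses_per_day


def expected_events_per_day(
    throughput: int, per_dose_risk: float | str | Fraction
) -> Fraction:
    """Expected adverse events per day: throughput times per-dose risk.

    Exact and unrounded; this is the rate every day count is derived from.
    """
    if throughput < 0:
        raise ValueError("throughput must be non-negative")
    return throughput * parse_probability(per_dose_risk)


def days_to_detect(n_required: int, events_per_day: float | str | Fraction) -> int:
    """Whole days of throughput needed to accrue ``n_required`` events."""
    rate = parse_probability(events_per_day)
    if rate <= 0:
        raise SignalNeverAccruesError(
            "expected events per day must be positive; the signal never accrues"
        )
    return int(math.ceil(Fraction(n_required) / rate))


def events_averted(
    days_alone: int, days_pooled: int, pooled_events_per_day: float | str | Fraction
) -> int:
    """Events avoided by intervening when the pooled analysis detects.

    The days saved by pooling, times the pooled event rate, rounded up to
    whole events.
    """
    if days_alone < days_pooled:
        raise ValueError("days_alone must be at least days_pooled")
    rate = parse_probability(pooled_events_per_day)
    return int(math.ceil((days_alone - days_pooled) * rate))


def deaths_averted(events: int, case_fatality: float | str | Fraction) -> int:
    """Whole deaths averted at a given case-fatality proportion (floored)."""
    cf = parse_probability(case_fatality)
    if not 0 <= cf <= 1:
        raise ValueError("case_fatality must lie in [0, 1]")
    return int(math.floor(events * cf))


def expected_adverse_events(
    population: int,
    acceptance: float | str | Fraction,
    ae_risk: float | str | Fraction,
) -> float:
    """Expected adverse-event count: population x uptake x per-person risk."""
    acc, risk = parse_probability(acceptance), parse_probability(ae_risk)
    for p in (acc, risk):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    return float(population * acc * risk)


@dataclass(frozen=True)
class RowSpec:
    """One scenario row: a set of jurisdictions, with an optional label."""

    members: tuple[str, ...]
    label: str | None = None

    def resolved_label(self) -> str:
        if self.label:
            return self.label
        if len(self.members) == 1:
            return self.members[0]
        return " + ".join(ABBREVIATIONS.get(m, m) for m in self.members)


@dataclass(frozen=True)
class ScenarioSpec:
    """A full scenario: design, risk, stratum, throughput, and rows."""

    design: SccsDesign
    per_dose_risk: Fraction
    stratum: str
    throughput: ThroughputModel
    rows: tuple[RowSpec, ...]
    national_aggregation: str = "summed"

    def __post_init__(self) -> None:
        if not 0 < self.per_dose_risk < 1:
            raise ValueError("per_dose_risk must lie strictly in (0, 1)")
        if self.national_aggregation not in ("summed", "direct"):
            raise ValueError(
                "national_aggregation must be 'summed' or 'direct'"
            )


@dataclass(frozen=True)
class ScenarioRow:
    """One evaluated row of a scenario table."""

    label: str
    population: int
    throughput: int
    events_per_day: Fraction
    days_to_detect: int

    @property
    def events_per_day_float(self) -> float:
        return float(self.events_per_day)


def _national_throughput(spec: ScenarioSpec, registry: Registry) -> int:
    """Throughput for a "Canada" row under the chosen aggregation mode.

    "summed" adds the floored throughputs of all individual jurisdictions
    (the mode consistent with the whole-population tables); "direct" applies
    the throughput model to the printed national population (used for strata
    where not every jurisdiction has a separate count).
    """
    if spec.national_aggregation == "direct":
        pop = registry.get("Canada").population(spec.stratum)
        return jurisdiction_throughput(pop, spec.throughput)
    members = registry.jurisdiction_names()
    missing = [m for m in members
               if spec.stratum not in registry.get(m).strata]
    if missing:
        raise KeyError(
            f"summed national aggregation needs the {spec.stratum!r} stratum "
            f"for every jurisdiction; missing for: {missing}"
        )
    return sum(
        jurisdiction_throughput(
            registry.get(m).population(spec.stratum), spec.throughput
        )
        for m in members
    )


def run_scenario(
    spec: ScenarioSpec, registry: Registry | None = None
) -> list[ScenarioRow]:
    """Evaluate every row of a scenario.

    Pooled rows sum the per-member *floored* throughputs, so pooling is
    exactly additive in whole doses per day; the required event count is
    computed once from the design.
    """
    registry = registry or default_registry()
    n_required = required_events(spec.design).n_required
    out = []
    for row in spec.rows:
        if row.members == ("Canada",):
            population = registry.get("Canada").population(spec.stratum)
            throughput = _national_throughput(spec, registry)
        else:
            population = registry.pool(row.members, spec.stratum).population
            throughput = sum(
                jurisdiction_throughput(
                    registry.get(m).population(spec.stratum), spec.throughput
                )
                for m in row.members
            )
        rate = expected_events_per_day(throughput, spec.per_dose_risk)
        out.append(
            ScenarioRow(
                label=row.resolved_label(),
                population=population,
                throughput=throughput,
                events_per_day=rate,
                days_to_detect=days_to_detect(n_required, rate),
            )
        )
    return out


# -- configuration and output -------------------------------------------------

def _rows_from_config(raw_rows: Iterable) -> tuple[RowSpec, ...]:
    rows = []
    for entry in raw_rows:
        if isinstance(entry, dict):
            rows.append(RowSpec(tuple(entry["members"]), entry.get("label")))
        else:
            rows.append(RowSpec(tuple(entry)))
    return tuple(rows)


def load_config(
    source: str | Path | dict, registry: Registry | None = None
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a JSON document or parsed dict.

    The throughput block may name an ``anchor_jurisdiction`` instead of an
    absolute ``anchor_population``; it is resolved against the registry's
    stratum-appropriate count at load time.  Configs whose ``per_dose_risk``
    is a list must go through :func:`load_config_multi`.
    """
    registry = registry or default_registry()
    if isinstance(source, dict):
        doc = source
    else:
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    if isinstance(doc.get("per_dose_risk"), (list, tuple)):
        raise ValueError(
            "config lists several per_dose_risk values; use load_config_multi"
        )

    d = doc["design"]
    design = SccsDesign(
        relative_incidence=float(d["relative_incidence"]),
        risk_days=int(d["risk_days"]),
        observation_days=int(d["observation_days"]),
        alpha=float(d.get("alpha", 0.05)),
        target_power=float(d.get("power", d.get("target_power", 0.90))),
    )
    stratum = doc.get("stratum", "total")

    t = doc["throughput"]
    mode = t["mode"]
    if mode == "anchored":
        if "anchor_population" in t:
            anchor_pop = int(t["anchor_population"])
        else:
            anchor_pop = registry.get(t["anchor_jurisdiction"]).population(stratum)
        model = ThroughputModel.anchored(int(t["anchor_doses_per_day"]), anchor_pop)
    elif mode == "flat":
        model = ThroughputModel.flat(t["daily_fraction"])
    elif mode == "explicit":
        model = ThroughputModel.explicit(int(t["doses_per_day"]))
    else:
        raise ValueError(f"unknown throughput mode in config: {mode!r}")

    return ScenarioSpec(
        design=design,
        per_dose_risk=parse_probability(doc["per_dose_risk"]),
        stratum=stratum,
        throughput=model,
        rows=_rows_from_config(doc["rows"]),
        national_aggregation=doc.get("national_aggregation", "summed"),
    )


def load_config_multi(
    source: str | Path | dict, registry: Registry | None = None
) -> list[ScenarioSpec]:
    """Expand a config into one :class:`ScenarioSpec` per adverse-event rate.

    ``per_dose_risk`` may be a single value or a list; single-rate configs
    yield a one-element list.
    """
    if isinstance(source, dict):
        doc = dict(source)
    else:
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    risks = doc.get("per_dose_risk")
    if not isinstance(risks, (list, tuple)):
        risks = [risks]
    specs = []
    for risk in risks:
        sub = dict(doc)
        sub["per_dose_risk"] = risk
        specs.append(load_config(sub, registry))
    return specs


def write_csv(rows: Sequence[ScenarioRow], path: str | Path) -> None:
    """Machine-readable scenario output, events/day at full precision."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["label", "population", "throughput_per_day",
             "events_per_day", "days_to_detect"]
        )
        for row in rows:
            writer.writerow(
                [row.label, row.population, row.throughput,
                 repr(row.events_per_day_float), row.days_to_detect]
            )


def _display_rate(rate: Fraction) -> str:
    value = float(rate)
    if 0 < value < 0.005:
        return "<0.01"
    return f"{value:.2f}"


def render_table(rows: Sequence[ScenarioRow]) -> str:
    """Human-readable scenario table (events/day shown to 2 decimals)."""
    header = ("Jurisdiction", "Population", "Doses/Day", "Events/Day", "Days")
    body = [
        (row.label, f"{row.population:,}", f"{row.throughput:,}",
         _display_rate(row.events_per_day), str(row.days_to_detect))
        for row in rows
    ]
    widths = [
        max(len(header[i]), *(len(r[i]) for r in body)) for i in range(len(header))
    ]
    def fmt(cells):
        first = cells[0].ljust(widths[0])
        rest = [c.rjust(w) for c, w in zip(cells[1:], widths[1:])]
        return "  ".join([first, *rest]).rstrip()
    rule = "  ".join("-" * w for w in widths)
    return "\n".join([fmt(header), rule, *(fmt(r) for r in body)])
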