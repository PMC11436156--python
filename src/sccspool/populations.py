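"""Packaged 2021 Canadian census populations, with jurisdiction pooling.

The registry ships as a CSV resource (``data/census_2021.csv``) holding, per
jurisdiction, the total population and the population aged 18-39 where
available (the three territories carry only a total, derived from the census
so that all thirteen jurisdictions sum to the national total).  Pooling sums
member counts within one stratum; it exists because the surveillance
scenarios compare single provinces against multi-province pools and the
national population.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "JurisdictionRecord",
    "PooledPopulation",
    "Registry",
    "get_jurisdiction",
    "pool",
    "default_registry",
    "ABBREVIATIONS",
]

#: Conventional short codes used when labelling pooled scenario rows.
ABBREVIATIONS: Mapping[str, str] = {
    "Ontario": "ON",
    "Quebec": "PQ",
    "British Columbia": "BC",
    "Alberta": "AB",
    "Manitoba": "MB",
    "Saskatchewan": "SK",
    "Nova Scotia": "NS",
    "New Brunswick": "NB",
    "Newfoundland and Labrador": "NL",
    "Prince Edward Island": "PE",
    "Yukon": "YT",
    "Northwest Territories": "NT",
    "Nunavut": "NU",
    "Canada": "Canada",
}


@dataclass(frozen=True)
class JurisdictionRecord:
    """A jurisdiction's census counts, keyed by stratum label."""

    name: str
    strata: Mapping[str, int]

    def __post_init__(self) -> None:
        for stratum, count in self.strata.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(
                    f"{self.name}/{stratum}: population must be a "
                    f"non-negative integer, got {count!r}"
                )
        if "total" in self.strata and "18-39" in self.strata:
            if self.strata["18-39"] > self.strata["total"]:
                raise ValueError(
                    f"{self.name}: 18-39 count exceeds the total population"
                )

    def population(self, stratum: str = "total") -> int:
        try:
            return self.strata[stratum]
        except KeyError:
            raise KeyError(
                f"{self.name} has no {stratum!r} stratum; "
                f"available: {sorted(self.strata)}"
            ) from None


@dataclass(frozen=True)
class PooledPopulation:
    """The result of pooling several jurisdictions within one stratum."""

    members: tuple[str, ...]
    stratum: str
    population: int


class Registry:
    """Lookup table of jurisdiction census counts."""

    def __init__(self, records: Mapping[str, JurisdictionRecord]):
        self._records = dict(records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Registry":
        records = {}
        for name, group in frame.groupby("jurisdiction", sort=False):
            strata = {
                str(row.stratum): int(row.population)
                for row in group.itertuples()
            }
            records[str(name)] = JurisdictionRecord(str(name), strata)
        return cls(records)

    @classmethod
    def packaged(cls) -> "Registry":
        """Load the census CSV shipped with the package."""
        ref = resources.files("sccspool").joinpath("data/census_2021.csv")
        with ref.open("r", encoding="utf-8") as fh:
            frame = pd.read_csv(fh, comment="#")
        return cls.from_frame(frame)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._records)

    def jurisdiction_names(self, stratum: str | None = None) -> tuple[str, ...]:
        """All individual jurisdictions (excluding the national aggregate),
        optionally restricted to those carrying ``stratum``."""
        out = []
        for name, rec in self._records.items():
            if name == "Canada":
                continue
            if stratum is not None and stratum not in rec.strata:
                continue
            out.append(name)
        return tuple(out)

    def get(self, name: str) -> JurisdictionRecord:
        try:
            return self._records[name]
        except KeyError:
            raise KeyError(
                f"unknown jurisdiction {name!r}; valid names: "
                f"{', '.join(self._records)}"
            ) from None

    def pool(self, names: Sequence[str], stratum: str = "total") -> PooledPopulation:
        """Sum the ``stratum`` counts of the named jurisdictions."""
        if not names:
            raise ValueError("cannot pool an empty set of jurisdictions")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if list(names).count(n) > 1})
            raise ValueError(f"duplicate jurisdiction(s) in pool: {dupes}")
        total = sum(self.get(name).population(stratum) for name in names)
        return PooledPopulation(tuple(names), stratum, total)


_default: Registry | None = None


def default_registry() -> Registry:
    """The packaged census registry, loaded once per process."""
    global _default
    if _default is None:
        _default = Registry.packaged()
    return _default


def get_jurisdiction(name: str) -> JurisdictionRecord:
    """Census record for one of the 13 jurisdictions or "Canada"."""
    return default_registry().get(name)


def pool(names: Sequence[str], stratum: str = "total") -> PooledPopulation:
    """Pool census counts across jurisdictions in one stratum."""
    return default_registry().pool(names, stratum)
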