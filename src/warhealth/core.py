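"""Domain types for the conflict counterfactual analysis.

The analysis compares the health trajectory a unit (a district, or the
national aggregate) actually followed through a conflict period against the
trajectory implied by its pre-war momentum.  Everything downstream consumes
the small set of records defined here: an annual indicator series, per-unit
metadata (conflict exposure class, endpoint-year availability), and the study
configuration (baseline year, endpoint year, projection shape, tie
tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class Indicator(str, Enum):
    """Health indicator, both measured per 1,000 live births."""

    IMR = "IMR"  # infant mortality rate
    MMR = "MMR"  # maternal mortality ratio

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConflictClass(str, Enum):
    """Three-way district taxonomy plus the national pseudo-unit.

    HIGH: site of frequent military encounters; INTERMITTENT: borders the
    conflict zone; NONE: no conflict.  NATIONAL tags the country-level
    aggregate, which is carried through the pipeline as an ordinary unit but
    excluded from district tallies.
    """

    HIGH = "HIGH"
    INTERMITTENT = "INTERMITTENT"
    NONE = "NONE"
    NATIONAL = "NATIONAL"


class Flag(str, Enum):
    """Outcome of an actual-vs-counterfactual comparison."""

    WORSE = "WORSE"
    BETTER = "BETTER"
    SAME = "SAME"
    NOT_ASSESSABLE = "NOT_ASSESSABLE"


class Shape(str, Enum):
    """Functional form used to extend the pre-war rate past the baseline."""

    COMPOUND = "COMPOUND"
    LINEAR = "LINEAR"
    EXPONENTIAL = "EXPONENTIAL"
    LOGARITHMIC = "LOGARITHMIC"


NATIONAL_UNIT = "NATIONAL"


@dataclass
class IndicatorSeries:
    """Annual observations of one indicator for one unit.

    ``observations`` maps year -> value (deaths per 1,000 live births).
    Missing years are simply absent; values must be finite and non-negative.
    """

    unit_id: str
    indicator: Indicator
    observations: dict[int, float]
    source: str = ""

    def __post_init__(self) -> None:
        self.indicator = Indicator(self.indicator)
        clean: dict[int, float] = {}
        for year, value in sorted(self.observations.items()):
            year = int(year)
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{self.unit_id}/{self.indicator.value} year {year}: "
                    f"value must be finite and >= 0, got {value}"
                )
            clean[year] = value
        self.observations = clean

    @property
    def years(self) -> list[int]:
        return list(self.observations)

    def value(self, year: int) -> Optional[float]:
        return self.observations.get(year)

    def first_year_in(self, start: int, end: int) -> Optional[int]:
        """Earliest observed year within [start, end], or None."""
        for year in self.observations:
            if start <= year <= end:
                return year
        return None

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class UnitMeta:
    """Per-unit metadata controlling assessability and endpoints.

    ``creation_year`` later than the start of the observation record flags a
    late-created unit (no pre-war data, hence no counterfactual).  Endpoint
    years are 2002 where data reach the third ceasefire, 1999 otherwise.
    """

    unit_id: str
    conflict_class: ConflictClass
    creation_year: Optional[int] = None
    imr_endpoint_year: int = 2002
    mmr_endpoint_year: int = 2002

    def __post_init__(self) -> None:
        self.conflict_class = ConflictClass(self.conflict_class)
        for year in (self.imr_endpoint_year, self.mmr_endpoint_year):
            if year not in (1999, 2002):
                raise ValueError(
                    f"{self.unit_id}: endpoint year must be 1999 or 2002, got {year}"
                )

    def endpoint_year(self, indicator: Indicator) -> int:
        if Indicator(indicator) is Indicator.IMR:
            return self.imr_endpoint_year
        return self.mmr_endpoint_year


@dataclass
class StudyConfig:
    """Parameters of the primary analysis.

    Defaults reproduce the published design: pre-war window 1975-1982 for
    districts, baseline 1982, endpoint 2002 (1999 fallback via UnitMeta),
    discrete compound projection, strict ties, 2-decimal reporting.
    """

    baseline_year: int = 1982
    endpoint_year: int = 2002
    prewar_start_year: int = 1975
    rounding_decimals: int = 2
    tie_tolerance: float = 0.0
    projection_shape: Shape = Shape.COMPOUND

    def __post_init__(self) -> None:
        self.projection_shape = Shape(self.projection_shape)
        if self.baseline_year >= self.endpoint_year:
            raise ValueError("baseline_year must precede endpoint_year")
        if self.prewar_start_year >= self.baseline_year:
            raise ValueError("pre-war window must end at baseline_year")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be non-negative")

    def with_shape(self, shape: Shape) -> "StudyConfig":
        return replace(self, projection_shape=Shape(shape))


@dataclass(frozen=True)
class PrintedInterpretation:
    """A published per-unit interpretation label, kept verbatim.

    The published summary tables occasionally disagree with their own raw
    columns; these records preserve the printed wording so tallies can be
    run from either surface and discrepancies surfaced explicitly.
    """

    unit_id: str
    indicator: Indicator
    label: str


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, as the published tables do."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
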