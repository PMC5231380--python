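"""Two-point average annual rate-of-change estimation.

The estimator is deliberately the simplest one defensible with sparse
administrative series: the proportional change between the first and last
observation of a window, divided by the window length in years,

    rate = ((V_end - V_start) / V_start) / n_years .

A negative rate is an improvement (mortality falling).  Rates are kept
unrounded internally; rounding happens only when reports are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import Indicator, IndicatorSeries


class UndefinedRateError(ValueError):
    """Raised when the rate of change is undefined (zero base, empty window)."""


@dataclass(frozen=True)
class TrendEstimate:
    """Average annual proportional change over a stated window."""

    unit_id: str
    indicator: Indicator
    rate: float
    window_start: int
    window_end: int
    basis: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if self.window_end <= self.window_start:
            raise ValueError("window must span at least one year")

    @property
    def n_years(self) -> int:
        return self.window_end - self.window_start


def average_annual_change(
    value_past: float, value_present: float, n_years: int
) -> float:
    """Average annual proportional change from ``value_past`` to ``value_present``.

    ``value_past`` must be positive and ``n_years`` at least 1; the result is
    returned unrounded.
    """
    if value_past <= 0:
        raise UndefinedRateError(
            f"rate undefined for non-positive base value {value_past}"
        )
    if n_years < 1:
        raise UndefinedRateError(f"n_years must be >= 1, got {n_years}")
    if value_present < 0:
        raise ValueError(f"value_present must be >= 0, got {value_present}")
    return ((value_present - value_past) / value_past) / n_years


def estimate_window_trend(
    series: IndicatorSeries,
    window_start: int,
    window_end: int,
    basis: str = "",
) -> Optional[TrendEstimate]:
    """Estimate the average annual change between the window bounds.

    Uses the observations at ``window_start`` and ``window_end``.  If the
    start year is unobserved, the earliest available year inside the window
    substitutes and the estimate records the span actually used.  With fewer
    than two usable observations (or a zero base value) the window is not
    assessable and ``None`` is returned — the condition propagates rather
    than raises, because unassessable units are an expected outcome.
    """
    end_value = series.value(window_end)
    if end_value is None:
        return None
    start_year = (
        window_start
        if series.value(window_start) is not None
        else series.first_year_in(window_start, window_end - 1)
    )
    if start_year is None or start_year >= window_end:
        return None
    start_value = series.observations[start_year]
    if start_value <= 0:
        return None
    rate = average_annual_change(start_value, end_value, window_end - start_year)
    return TrendEstimate(
        unit_id=series.unit_id,
        indicator=series.indicator,
        rate=rate,
        window_start=start_year,
        window_end=window_end,
        basis=basis,
    )


def lost_momentum(
    prewar_rate: float, conflict_rate: float, scale: float = 100.0, decimals: int = 1
) -> float:
    """Annual improvement forgone during the conflict, in report units.

    Both rates are proportional declines per year; each magnitude is scaled
    (percent by default) and rounded to the printed precision before the
    subtraction, matching how the headline figure is quoted.
    """
    pre = round(abs(prewar_rate) * scale, decimals)
    con = round(abs(conflict_rate) * scale, decimals)
    return round(pre - con, decimals)
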