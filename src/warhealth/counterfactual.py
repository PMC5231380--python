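"""Counterfactual projection of a baseline value under a rate and shape.

The default shape is discrete annual compounding, V0*(1+r)^t: it is the only
form that reproduces the published national counterfactuals from the
published rates (0.60 compounded at -0.08 for 20 years gives 0.11; an
arithmetic-linear reading, 34*(1-0.04*20)=6.8, contradicts every printed
value).  Linear, continuous-exponential and logarithmic variants are kept
for the projection-shape sensitivity analysis; all four anchor at the
baseline and share the same first-order slope, so they diverge only as the
horizon grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import Flag, Indicator, IndicatorSeries, Shape, StudyConfig, UnitMeta
from .trends import estimate_window_trend


class NegativeProjectionWarning(UserWarning):
    """A projected value crossed zero (possible with LINEAR/LOGARITHMIC shapes)."""


class ProjectionError(ValueError):
    """Undefined projection (e.g. compounding at a rate <= -1)."""


def project(
    baseline_value: float,
    rate: float,
    years_elapsed: int,
    shape: Shape = Shape.COMPOUND,
) -> float:
    """Project ``baseline_value`` forward ``years_elapsed`` years at ``rate``.

    COMPOUND: V0*(1+r)^t; LINEAR: V0*(1+r*t); EXPONENTIAL: V0*e^(r*t);
    LOGARITHMIC: V0*(1+r*ln(1+t)).  Negative results are allowed but emit a
    :class:`NegativeProjectionWarning`.
    """
    if baseline_value <= 0:
        raise ProjectionError(f"baseline must be positive, got {baseline_value}")
    if years_elapsed < 0:
        raise ProjectionError("years_elapsed must be non-negative")
    shape = Shape(shape)
    t = years_elapsed
    if shape is Shape.COMPOUND:
        if rate <= -1 and t > 0:
            raise ProjectionError(f"compounding undefined for rate {rate} <= -1")
        value = baseline_value * (1.0 + rate) ** t
    elif shape is Shape.LINEAR:
        value = baseline_value * (1.0 + rate * t)
    elif shape is Shape.EXPONENTIAL:
        value = baseline_value * math.exp(rate * t)
    else:  # LOGARITHMIC
        value = baseline_value * (1.0 + rate * math.log1p(t))
    if value < 0:
        warnings.warn(
            f"projection fell below zero ({value:.4g}) at t={t} under {shape.value}",
            NegativeProjectionWarning,
            stacklevel=2,
        )
    return value


def back_solve_rate(
    baseline_value: float,
    target_value: float,
    years_elapsed: int,
    shape: Shape = Shape.COMPOUND,
) -> float:
    """The unique rate for which ``project`` maps baseline to target.

    Closed forms exist for every shape; COMPOUND is
    (target/baseline)^(1/t) - 1.
    """
    if baseline_value <= 0 or target_value <= 0:
        raise ProjectionError("back-solving needs positive baseline and target")
    if years_elapsed < 1:
        raise ProjectionError("years_elapsed must be >= 1")
    shape = Shape(shape)
    ratio = target_value / baseline_value
    t = years_elapsed
    if shape is Shape.COMPOUND:
        return ratio ** (1.0 / t) - 1.0
    if shape is Shape.LINEAR:
        return (ratio - 1.0) / t
    if shape is Shape.EXPONENTIAL:
        return math.log(ratio) / t
    return (ratio - 1.0) / math.log1p(t)  # LOGARITHMIC


@dataclass
class CounterfactualTrajectory:
    """Projected annual values from a baseline under one rate and shape."""

    unit_id: str
    indicator: Indicator
    baseline_year: int
    baseline_value: float
    rate: float
    shape: Shape
    values: dict[int, float] = field(default_factory=dict)

    @property
    def endpoint_year(self) -> int:
        return max(self.values)

    @property
    def endpoint_value(self) -> float:
        return self.values[self.endpoint_year]


def build_counterfactual(
    series: IndicatorSeries,
    meta: UnitMeta,
    config: StudyConfig,
) -> Optional[CounterfactualTrajectory]:
    """Trajectory from the baseline year to the unit's endpoint year.

    Returns ``None`` (not assessable) for units created after the start of
    the pre-war window, units without a baseline observation, and units whose
    pre-war trend cannot be estimated — these surface downstream as
    "Unable to determine".
    """
    if meta.creation_year is not None and meta.creation_year > config.prewar_start_year:
        return None
    baseline_value = series.value(config.baseline_year)
    if baseline_value is None or baseline_value <= 0:
        return None
    trend = estimate_window_trend(
        series, config.prewar_start_year, config.baseline_year, basis="PREWAR"
    )
    if trend is None:
        return None
    endpoint = min(meta.endpoint_year(series.indicator), config.endpoint_year)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeProjectionWarning)
        values = {
            year: project(
                baseline_value,
                trend.rate,
                year - config.baseline_year,
                config.projection_shape,
            )
            for year in range(config.baseline_year, endpoint + 1)
        }
    if values[max(values)] < 0:
        warnings.warn(
            f"{series.unit_id}/{series.indicator.value}: counterfactual endpoint "
            f"is negative under {config.projection_shape.value}",
            NegativeProjectionWarning,
            stacklevel=2,
        )
    return CounterfactualTrajectory(
        unit_id=series.unit_id,
        indicator=series.indicator,
        baseline_year=config.baseline_year,
        baseline_value=baseline_value,
        rate=trend.rate,
        shape=config.projection_shape,
        values=values,
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Endpoint classification of one unit/indicator under each shape."""

    unit_id: str
    indicator: Indicator
    flags: Mapping[Shape, Flag]
    consistent: bool


def endpoint_flag(
    actual: float, counterfactual: float, tolerance: float = 0.0
) -> Flag:
    """WORSE/BETTER/SAME for a lower-is-better indicator (thin wrapper)."""
    from .classify import classify_endpoint

    return classify_endpoint(actual, counterfactual, True, tolerance)


def flags_by_shape(
    baseline_value: float,
    rate: float,
    years_elapsed: int,
    actual: float,
    shapes: Sequence[Shape],
    tolerance: float = 0.0,
) -> dict[Shape, Flag]:
    """Endpoint flag under each projection shape for one unit/indicator."""
    out: dict[Shape, Flag] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeProjectionWarning)
        for shape in shapes:
            cf = project(baseline_value, rate, years_elapsed, shape)
            out[Shape(shape)] = endpoint_flag(actual, cf, tolerance)
    return out


def sensitivity_analysis(
    series_list: Iterable[IndicatorSeries],
    meta_map: Mapping[str, UnitMeta],
    config: StudyConfig,
    shapes: Sequence[Shape],
) -> list[SensitivityResult]:
    """Classify every assessable unit/indicator endpoint under each shape.

    ``consistent`` is true when all shapes yield the same flag, i.e. the
    worse/better verdict does not depend on the assumed trajectory shape.
    """
    shapes = [Shape(s) for s in shapes]
    if len(shapes) < 2:
        raise ValueError("sensitivity analysis needs at least two shapes")
    results = []
    for series in series_list:
        meta = meta_map.get(series.unit_id)
        if meta is None:
            continue
        cf = build_counterfactual(series, meta, config)
        if cf is None:
            continue
        endpoint = cf.endpoint_year
        actual = series.value(endpoint)
        if actual is None:
            continue
        flags = flags_by_shape(
            cf.baseline_value,
            cf.rate,
            endpoint - config.baseline_year,
            actual,
            shapes,
            config.tie_tolerance,
        )
        results.append(
            SensitivityResult(
                unit_id=series.unit_id,
                indicator=series.indicator,
                flags=flags,
                consistent=len(set(flags.values())) == 1,
            )
        )
    return results
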