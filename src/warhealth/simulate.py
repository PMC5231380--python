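"""Synthetic indicator panels with known ground truth.

The generator emulates the statistical regime of the district tables: a
steady pre-war proportional improvement, a conflict-period change of a
different magnitude, multiplicative observation noise, missing interior
years, late-created units without pre-war data, and a fraction of units
whose usable endpoint is 1999 rather than 2002.

Construction convention (this matters for exactness):

* the pre-war segment is pinned so that the two-point average-annual-change
  estimator recovers ``prewar_rate`` exactly — the start value is
  V_b / (1 + r*k) for a k-year window ending at the baseline value V_b, with
  geometric interpolation in between;
* the conflict segment compounds at ``prewar_rate * conflict_rate_multiplier``
  per year from the baseline, so a multiplier of 1 continues the projected
  counterfactual exactly and the endpoint flag is SAME by construction.

A consequence the oracle reproduces honestly: because the analysis compares
an arithmetic average over a short pre-war window with one over a long
conflict window of a compounding path, the *rate* flag is WORSE-biased even
under a null effect.  ``expected_flags`` computes both flags analytically
from the true parameters, so end-to-end recovery tests compare the pipeline
against a closed-form oracle, not against itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ConflictClass,
    Flag,
    Indicator,
    IndicatorSeries,
    Shape,
    StudyConfig,
    UnitMeta,
)
from .classify import _compare

# baseline (1982) levels typical of the district tables, per 1,000 live births
_BASELINE_MEDIAN = {Indicator.IMR: 27.0, Indicator.MMR: 0.6}
_BASELINE_SPREAD = 0.35  # lognormal sigma of the baseline level across units


@dataclass
class SyntheticConfig:
    """Study conditions for the generated panel.

    Defaults mirror the district-table regime: 25 units observed 1975-2002
    with a 1982 baseline, pre-war improvement around -5.8%/yr (the median
    pre-conflict average of the published IMR table), a halving of momentum
    during the conflict, 5% multiplicative observation noise, occasional
    missing interior years, two late-created units per 25, and roughly the
    published share of 1999 endpoints.
    """

    n_units: int = 25
    start_year: int = 1975
    end_year: int = 2002
    baseline_year: int = 1982
    prewar_rate: float = -0.058
    conflict_rate_multiplier: float = 0.5
    affected_fraction: float = 1.0
    noise_cv: float = 0.05
    missing_prob: float = 0.05
    late_creation_fraction: float = 0.08
    endpoint_1999_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if not self.start_year < self.baseline_year < self.end_year:
            raise ValueError("need start_year < baseline_year < end_year")
        for name in ("missing_prob", "late_creation_fraction",
                     "endpoint_1999_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {p}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        k = self.baseline_year - self.start_year
        if 1.0 + self.prewar_rate * k <= 0:
            raise ValueError(
                "prewar_rate too steep for the window: 1 + r*k must be positive"
            )
        c = self.prewar_rate * self.conflict_rate_multiplier
        if c <= -1.0:
            raise ValueError("conflict-period rate must exceed -1")

    # -- deterministic unit attributes (independent of the noise rng) -------

    def unit_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_units)]

    def n_late(self) -> int:
        return int(math.floor(self.late_creation_fraction * self.n_units))

    def n_1999(self) -> int:
        return int(math.floor(self.endpoint_1999_fraction * self.n_units))

    def is_late(self, i: int) -> bool:
        return i >= self.n_units - self.n_late()

    def has_1999_endpoint(self, i: int) -> bool:
        return not self.is_late(i) and i < self.n_1999()

    def is_affected(self, i: int) -> bool:
        return i < int(round(self.affected_fraction * self.n_units))

    def multiplier(self, i: int) -> float:
        return self.conflict_rate_multiplier if self.is_affected(i) else 1.0

    def endpoint_year_of(self, i: int) -> int:
        return 1999 if self.has_1999_endpoint(i) else self.end_year

    def creation_year_of(self, i: int) -> Optional[int]:
        return self.baseline_year + 2 if self.is_late(i) else None


def _noise_free_path(
    v_baseline: float, cfg: SyntheticConfig, unit_index: int
) -> dict[int, float]:
    """Smooth trajectory: pinned pre-war segment, compound conflict segment."""
    k = cfg.baseline_year - cfg.start_year
    r = cfg.prewar_rate
    c = r * cfg.multiplier(unit_index)
    v_start = v_baseline / (1.0 + r * k)
    path: dict[int, float] = {}
    start = (
        cfg.creation_year_of(unit_index)
        if cfg.is_late(unit_index)
        else cfg.start_year
    )
    end = cfg.endpoint_year_of(unit_index)
    for year in range(start, end + 1):
        if year <= cfg.baseline_year:
            frac = (year - cfg.start_year) / k
            path[year] = v_start * (v_baseline / v_start) ** frac
        else:
            path[year] = v_baseline * (1.0 + c) ** (year - cfg.baseline_year)
    return path


def generate_panel(
    config: SyntheticConfig,
) -> tuple[list[IndicatorSeries], dict[str, UnitMeta], pd.DataFrame]:
    """Generate series, metadata and a ground-truth table.

    The same seed always yields the identical panel.  Noise is multiplicative
    lognormal with unit mean and coefficient of variation ``noise_cv``
    (mortality rates are positive and right-skewed).  Missing years never hit
    the window bounds (pre-war start, baseline, endpoint), mirroring the
    published design where endpoint availability, not interior gaps, decides
    assessability.
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log1p(config.noise_cv**2)) if config.noise_cv else 0.0
    series: list[IndicatorSeries] = []
    meta: dict[str, UnitMeta] = {}
    truth_rows = []
    for i, unit in enumerate(config.unit_ids()):
        meta[unit] = UnitMeta(
            unit_id=unit,
            conflict_class=ConflictClass.HIGH if config.is_affected(i) else ConflictClass.NONE,
            creation_year=config.creation_year_of(i),
            imr_endpoint_year=config.endpoint_year_of(i),
            mmr_endpoint_year=config.endpoint_year_of(i),
        )
        for indicator in (Indicator.IMR, Indicator.MMR):
            level = _BASELINE_MEDIAN[indicator] * math.exp(
                rng.normal(0.0, _BASELINE_SPREAD)
            )
            path = _noise_free_path(level, config, i)
            protected = {
                config.start_year,
                config.baseline_year,
                config.endpoint_year_of(i),
                config.creation_year_of(i) or config.start_year,
            }
            obs: dict[int, float] = {}
            for year, value in path.items():
                if (
                    year not in protected
                    and config.missing_prob
                    and rng.random() < config.missing_prob
                ):
                    continue
                noisy = value
                if sigma:
                    noisy = value * math.exp(rng.normal(-0.5 * sigma**2, sigma))
                obs[year] = noisy
            series.append(IndicatorSeries(unit, indicator, obs, source="synthetic"))
            truth_rows.append(
                _truth_row(config, i, unit, indicator, level)
            )
    truth = pd.DataFrame(truth_rows)
    return series, meta, truth


def _truth_row(
    cfg: SyntheticConfig, i: int, unit: str, indicator: Indicator, baseline: float
) -> dict:
    rate_flag, endpoint_flag = _analytic_flags(cfg, i)
    return {
        "unit_id": unit,
        "indicator": indicator.value,
        "baseline_value": baseline,
        "prewar_rate": cfg.prewar_rate,
        "conflict_rate": cfg.prewar_rate * cfg.multiplier(i),
        "multiplier": cfg.multiplier(i),
        "late_created": cfg.is_late(i),
        "endpoint_year": cfg.endpoint_year_of(i),
        "expected_rate_flag": rate_flag.value,
        "expected_endpoint_flag": endpoint_flag.value,
    }


def _analytic_flags(
    cfg: SyntheticConfig, i: int, tolerance: float = 0.0
) -> tuple[Flag, Flag]:
    """Closed-form flags implied by the true parameters (no estimation).

    The estimated pre-war rate equals ``prewar_rate`` by construction.  The
    estimated conflict-period rate over T years of compounding at c is
    ((1+c)^T - 1)/T; the endpoint comparison reduces to (1+c)^T versus
    (1+r)^T.
    """
    if cfg.is_late(i):
        return Flag.NOT_ASSESSABLE, Flag.NOT_ASSESSABLE
    r = cfg.prewar_rate
    c = r * cfg.multiplier(i)
    T = cfg.endpoint_year_of(i) - cfg.baseline_year
    est_conflict = ((1.0 + c) ** T - 1.0) / T
    rate_flag = _compare(est_conflict, r, tolerance)
    endpoint_flag = _compare((1.0 + c) ** T, (1.0 + r) ** T, tolerance)
    return rate_flag, endpoint_flag


def expected_flags(
    config: SyntheticConfig, tolerance: float = 0.0
) -> pd.DataFrame:
    """Ground-truth classification per unit/indicator, derived analytically.

    Serves as the oracle for end-to-end recovery tests: the pipeline's flags
    on a noise-free panel must reproduce these exactly (up to the stated tie
    tolerance).
    """
    rows = []
    for i, unit in enumerate(config.unit_ids()):
        rate_flag, endpoint_flag = _analytic_flags(config, i, tolerance)
        for indicator in (Indicator.IMR, Indicator.MMR):
            rows.append(
                {
                    "unit_id": unit,
                    "indicator": indicator.value,
                    "rate_flag": rate_flag.value,
                    "endpoint_flag": endpoint_flag.value,
                }
            )
    return pd.DataFrame(rows)


def study_config_for(config: SyntheticConfig, tie_tolerance: float = 0.0) -> StudyConfig:
    """The StudyConfig matching a synthetic panel's windows."""
    return StudyConfig(
        baseline_year=config.baseline_year,
        endpoint_year=config.end_year,
        prewar_start_year=config.start_year,
        tie_tolerance=tie_tolerance,
        projection_shape=Shape.COMPOUND,
    )
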