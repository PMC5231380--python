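"""Recomputation surfaces over the packaged published tables.

These functions re-run the method on the fixture inputs: national
conflict-period trends from the printed 1982/2002 levels, the national
counterfactuals from the printed pre-war trends, district classifications
from the raw district columns, headline tallies from both the raw columns
and the printed labels, the 0-4 impact index, and a reconciliation report
comparing printed rates, printed counterfactuals, and what each implies
about the other.

Two published quirks are deliberately surfaced rather than resolved:

* the district counterfactual cells are not reproducible from the printed
  (2-decimal) rates under any projection shape — the unrounded inputs were
  never published; the reconciliation report quantifies the gap;
* for the MMR the printed summary labels disagree with the raw columns in
  two districts, so headline MMR counts are taken from the labels (the
  published analysis surface) while IMR counts come from the raw columns,
  which do reproduce the published headline figures.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import pandas as pd

from .classify import UnitClassification, classify_unit, reconcile_labels
from .core import Indicator, PrintedInterpretation, Shape, StudyConfig, round_half_up
from .counterfactual import back_solve_rate, flags_by_shape, project
from .fixtures import load_fixture
from .io import read_meta
from .fixtures import fixture_path
from .trends import average_annual_change, lost_momentum


def _get(row, column: str) -> Optional[float]:
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def district_meta():
    """Unit metadata (conflict class, creation year, endpoints) as packaged."""
    return read_meta(fixture_path("unit_meta"))


# ---------------------------------------------------------------------------
# national level


def national_summary(decimals: int = 2) -> dict:
    """Recompute the national comparison from the packaged levels and trends.

    Conflict-period trends come from the two-point formula on the printed
    1982 and 2002 levels; counterfactual endpoints from compounding the
    printed pre-war trends over 20 years; back-solved rates invert the
    printed counterfactuals.  Values are rounded to the table's precision.
    """
    t2 = load_fixture("table2").set_index(["indicator", "year"])
    out: dict[str, dict] = {}
    for ind in ("IMR", "MMR"):
        base = float(t2.loc[(ind, 1982), "actual"])
        end = float(t2.loc[(ind, 2002), "actual"])
        years = 20
        conflict_rate = average_annual_change(base, end, years)
        trend_5 = float(t2.loc[(ind, 1982), "trend_5yr"])
        trend_10 = float(t2.loc[(ind, 1982), "trend_10yr"])
        cf_printed_5 = float(t2.loc[(ind, 2002), "cf_5yr"])
        cf_printed_10 = float(t2.loc[(ind, 2002), "cf_10yr"])
        out[ind] = {
            "baseline_1982": base,
            "actual_2002": end,
            "conflict_trend": round_half_up(conflict_rate, decimals),
            "conflict_trend_unrounded": conflict_rate,
            "cf_5yr_from_printed_trend": round_half_up(
                project(base, trend_5, years, Shape.COMPOUND), decimals
            ),
            "cf_10yr_from_printed_trend": round_half_up(
                project(base, trend_10, years, Shape.COMPOUND), decimals
            ),
            "cf_5yr_printed": cf_printed_5,
            "cf_10yr_printed": cf_printed_10,
            "backsolved_rate_5yr": round_half_up(
                back_solve_rate(base, cf_printed_5, years, Shape.COMPOUND), decimals
            ),
            "backsolved_rate_10yr": round_half_up(
                back_solve_rate(base, cf_printed_10, years, Shape.COMPOUND), decimals
            ),
            "printed_trend_5yr": trend_5,
            "printed_trend_10yr": trend_10,
        }
    return out


def national_lost_momentum() -> float:
    """Annual IMR improvement forgone nationally, per 100 (percentage points).

    The pre-war decline is the rate implied by the 10-year counterfactual
    (back-solved from the printed endpoint), the wartime decline is the
    two-point rate over 1982-2002; each is quoted at 1 decimal before the
    subtraction, as the headline figure is.
    """
    t2 = load_fixture("table2").set_index(["indicator", "year"])
    base = float(t2.loc[("IMR", 1982), "actual"])
    end = float(t2.loc[("IMR", 2002), "actual"])
    cf10 = float(t2.loc[("IMR", 2002), "cf_10yr"])
    prewar = back_solve_rate(base, cf10, 20, Shape.COMPOUND)
    wartime = average_annual_change(base, end, 20)
    return lost_momentum(prewar, wartime)


# ---------------------------------------------------------------------------
# district level


def imr_classifications(tolerance: float = 0.0) -> list[UnitClassification]:
    """Classify every district from the raw IMR columns."""
    t3 = load_fixture("table3")
    return [
        classify_unit(
            row["district"],
            Indicator.IMR,
            _get(row, "rate_pre"),
            _get(row, "rate_conflict"),
            _get(row, "imr_2002"),
            _get(row, "cf_2002"),
            tolerance,
        )
        for _, row in t3.iterrows()
    ]


def mmr_classifications(tolerance: float = 0.0) -> list[UnitClassification]:
    """Classify every district from the raw MMR columns."""
    t5 = load_fixture("table5")
    return [
        classify_unit(
            row["district"],
            Indicator.MMR,
            _get(row, "rate_pre"),
            _get(row, "rate_conflict"),
            _get(row, "mmr_end"),
            _get(row, "cf_end"),
            tolerance,
        )
        for _, row in t5.iterrows()
    ]


def imr_printed() -> list[PrintedInterpretation]:
    t4 = load_fixture("table4")
    return [
        PrintedInterpretation(row["district"], Indicator.IMR, row["label"])
        for _, row in t4.iterrows()
    ]


def mmr_printed() -> list[PrintedInterpretation]:
    t6 = load_fixture("table6")
    return [
        PrintedInterpretation(row["district"], Indicator.MMR, row["label"])
        for _, row in t6.iterrows()
    ]


def label_reconciliation() -> dict[str, list]:
    """Computed-vs-printed label discrepancies for both indicators."""
    return {
        "IMR": reconcile_labels(imr_classifications(), imr_printed()),
        "MMR": reconcile_labels(mmr_classifications(), mmr_printed()),
    }


def counterfactual_reconciliation() -> pd.DataFrame:
    """Printed rate vs printed counterfactual, district by district.

    For each assessable district and indicator: the endpoint recomputed by
    compounding the printed pre-war rate, the rate back-solved from the
    printed counterfactual, and the absolute gap between printed and
    recomputed endpoints.  The gaps are the honest record of what the
    2-decimal published inputs cannot pin down.
    """
    rows = []
    t3 = load_fixture("table3")
    for _, row in t3.iterrows():
        rows.append(
            _reconcile_row(
                row["district"], "IMR", _get(row, "imr_1982"),
                _get(row, "cf_2002"), _get(row, "rate_pre"), 20,
            )
        )
    t5 = load_fixture("table5")
    for _, row in t5.iterrows():
        years = int(row["endpoint_year"]) - 1982
        rows.append(
            _reconcile_row(
                row["district"], "MMR", _get(row, "mmr_1982"),
                _get(row, "cf_end"), _get(row, "rate_pre"), years,
            )
        )
    return pd.DataFrame([r for r in rows if r is not None])


def _reconcile_row(district, indicator, baseline, cf_printed, rate_printed, years):
    if baseline is None or cf_printed is None or rate_printed is None:
        return None
    recomputed = project(baseline, rate_printed, years, Shape.COMPOUND)
    solved = back_solve_rate(baseline, cf_printed, years, Shape.COMPOUND)
    return {
        "unit_id": district,
        "indicator": indicator,
        "printed_rate": rate_printed,
        "printed_cf": cf_printed,
        "recomputed_cf": recomputed,
        "back_solved_rate": solved,
        "abs_discrepancy": abs(recomputed - cf_printed),
    }


def imr_tally():
    """Headline IMR counts from the raw district columns."""
    from .classify import tally

    return tally(imr_classifications(), (), district_meta())


def mmr_label_tally():
    """Headline MMR counts from the printed summary labels."""
    from .classify import tally_from_labels

    return tally_from_labels(mmr_printed(), district_meta())


def impact_index(use_printed_mmr: bool = True) -> list:
    """The 0-4 conflict impact index per district.

    MMR components default to the printed labels (the published analysis
    surface); IMR components always come from the raw columns.
    """
    from .classify import impact_weight, label_to_flags

    imr = {c.unit_id: c for c in imr_classifications()}
    if use_printed_mmr:
        mmr = {}
        for p in mmr_printed():
            rate_flag, endpoint_flag = label_to_flags(p.label)
            mmr[p.unit_id] = UnitClassification(
                p.unit_id, Indicator.MMR, rate_flag, endpoint_flag, p.label
            )
    else:
        mmr = {c.unit_id: c for c in mmr_classifications()}
    return [
        impact_weight(imr.get(unit), mmr.get(unit))
        for unit in sorted(set(imr) | set(mmr))
    ]


def district_sensitivity(
    shapes: Sequence[Shape] = (
        Shape.COMPOUND,
        Shape.LINEAR,
        Shape.EXPONENTIAL,
        Shape.LOGARITHMIC,
    ),
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Endpoint flags under each shape for every assessable district row."""
    rows = []
    t3 = load_fixture("table3")
    for _, row in t3.iterrows():
        rows.append(
            _sensitivity_row(
                row["district"], "IMR", _get(row, "imr_1982"),
                _get(row, "rate_pre"), _get(row, "imr_2002"), 20, shapes, tolerance,
            )
        )
    t5 = load_fixture("table5")
    for _, row in t5.iterrows():
        rows.append(
            _sensitivity_row(
                row["district"], "MMR", _get(row, "mmr_1982"),
                _get(row, "rate_pre"), _get(row, "mmr_end"),
                int(row["endpoint_year"]) - 1982, shapes, tolerance,
            )
        )
    return pd.DataFrame([r for r in rows if r is not None])


def _sensitivity_row(district, indicator, baseline, rate, actual, years, shapes, tol):
    if baseline is None or rate is None or actual is None:
        return None
    flags = flags_by_shape(baseline, rate, years, actual, list(shapes), tol)
    row = {"unit_id": district, "indicator": indicator}
    row.update({s.value.lower(): f.value for s, f in flags.items()})
    row["consistent"] = len(set(flags.values())) == 1
    return row
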