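"""Worse/better classification, interpretation labels, impact index, tallies.

A unit/indicator gets two flags: whether the during-conflict rate of change
was slower than the pre-war rate (rate flag), and whether the achieved
endpoint level was worse than the counterfactual projection (endpoint flag).
Mortality indicators are lower-is-better throughout, so "worse" means a
larger value, or a rate of decline closer to zero (or positive).

The 0-4 conflict impact index adds one point for each WORSE flag across
{IMR rate, IMR endpoint, MMR rate, MMR endpoint}; SAME and BETTER never
score.  The tally functions produce the headline counts (endpoint-worse
districts, how many of those lie outside the high-conflict zone, slowed
rates, and the weight histogram).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import ConflictClass, Flag, Indicator, PrintedInterpretation, UnitMeta


def _compare(a: float, b: float, tolerance: float) -> Flag:
    if a > b + tolerance:
        return Flag.WORSE
    if a < b - tolerance:
        return Flag.BETTER
    return Flag.SAME


def classify_rate_change(
    rate_pre: float, rate_conflict: float, tolerance: float = 0.0
) -> Flag:
    """WORSE when improvement slowed or reversed during the conflict.

    Rates are proportional changes per year (negative = improvement), so the
    conflict-period rate being *greater* than the pre-war rate means lost
    momentum.
    """
    return _compare(rate_conflict, rate_pre, tolerance)


def classify_endpoint(
    actual: Optional[float],
    counterfactual: Optional[float],
    lower_is_better: bool = True,
    tolerance: float = 0.0,
) -> Flag:
    """Compare the achieved endpoint level against the counterfactual."""
    if actual is None or counterfactual is None:
        return Flag.NOT_ASSESSABLE
    if not lower_is_better:
        actual, counterfactual = counterfactual, actual
    return _compare(actual, counterfactual, tolerance)


_WORD = {Flag.WORSE: "worse", Flag.BETTER: "better", Flag.SAME: "same"}


def interpret(rate_flag: Flag, endpoint_flag: Flag, indicator: Indicator) -> str:
    """Map the two flags onto the published interpretation vocabulary.

    An unassessable rate yields "Unable to determine"; a known rate with an
    unassessable endpoint yields the published partial label ("Rate is
    worse").
    """
    name = Indicator(indicator).value
    rate_flag, endpoint_flag = Flag(rate_flag), Flag(endpoint_flag)
    if rate_flag is Flag.NOT_ASSESSABLE:
        return "Unable to determine"
    if endpoint_flag is Flag.NOT_ASSESSABLE:
        return f"Rate is {_WORD[rate_flag]}"
    if rate_flag is endpoint_flag:
        return f"Rate and {name} are {_WORD[rate_flag]}"
    return f"Rate is {_WORD[rate_flag]}; {name} is {_WORD[endpoint_flag]}"


_LABEL_RE = re.compile(
    r"^Rate is (?P<rate>worse|better|same)"
    r"(?:; (?:IMR|MMR|outcome) is (?P<end>worse|better|same))?$"
)
_BOTH_RE = re.compile(r"^Rate and (?:IMR|MMR|outcome) are (?P<both>worse|better|same)$")
_FLAG = {"worse": Flag.WORSE, "better": Flag.BETTER, "same": Flag.SAME}


def label_to_flags(label: str) -> tuple[Flag, Flag]:
    """Invert a printed interpretation label to (rate_flag, endpoint_flag)."""
    label = label.strip()
    if label == "Unable to determine":
        return Flag.NOT_ASSESSABLE, Flag.NOT_ASSESSABLE
    m = _BOTH_RE.match(label)
    if m:
        f = _FLAG[m.group("both")]
        return f, f
    m = _LABEL_RE.match(label)
    if m:
        rate = _FLAG[m.group("rate")]
        end = _FLAG[m.group("end")] if m.group("end") else Flag.NOT_ASSESSABLE
        return rate, end
    raise ValueError(f"label outside the published vocabulary: {label!r}")


@dataclass(frozen=True)
class UnitClassification:
    """Both flags plus the interpretation label for one unit/indicator."""

    unit_id: str
    indicator: Indicator
    rate_flag: Flag
    endpoint_flag: Flag
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(
                self, "label", interpret(self.rate_flag, self.endpoint_flag, self.indicator)
            )


def classify_unit(
    unit_id: str,
    indicator: Indicator,
    rate_pre: Optional[float],
    rate_conflict: Optional[float],
    actual: Optional[float],
    counterfactual: Optional[float],
    tolerance: float = 0.0,
) -> UnitClassification:
    """Build a full classification from raw rates and endpoint levels."""
    if rate_pre is None or rate_conflict is None:
        rate_flag = Flag.NOT_ASSESSABLE
    else:
        rate_flag = classify_rate_change(rate_pre, rate_conflict, tolerance)
    endpoint = classify_endpoint(actual, counterfactual, True, tolerance)
    return UnitClassification(unit_id, Indicator(indicator), rate_flag, endpoint)


@dataclass(frozen=True)
class ImpactIndexRecord:
    """Per-district 0-4 conflict impact weight with its component flags.

    ``weight`` is None (not assessable) when either indicator is wholly
    unassessable — matching the published treatment, where a district
    without a usable IMR analysis is reported as having insufficient data
    even if its MMR columns are complete.
    """

    unit_id: str
    weight: Optional[int]
    components: dict[str, Flag] = field(default_factory=dict)


def impact_weight(
    imr: Optional[UnitClassification], mmr: Optional[UnitClassification]
) -> ImpactIndexRecord:
    """Count WORSE flags among the four components (one point each)."""
    na = Flag.NOT_ASSESSABLE
    components = {
        "imr_rate": imr.rate_flag if imr else na,
        "imr_endpoint": imr.endpoint_flag if imr else na,
        "mmr_rate": mmr.rate_flag if mmr else na,
        "mmr_endpoint": mmr.endpoint_flag if mmr else na,
    }
    unit = (imr or mmr).unit_id if (imr or mmr) else ""
    imr_gone = components["imr_rate"] is na and components["imr_endpoint"] is na
    mmr_gone = components["mmr_rate"] is na and components["mmr_endpoint"] is na
    if imr_gone or mmr_gone:
        return ImpactIndexRecord(unit, None, components)
    weight = sum(1 for f in components.values() if f is Flag.WORSE)
    return ImpactIndexRecord(unit, weight, components)


@dataclass
class TallySummary:
    """Headline district counts (the NATIONAL pseudo-unit is excluded)."""

    endpoint_worse: dict[str, int] = field(default_factory=dict)
    endpoint_worse_outside_conflict: dict[str, int] = field(default_factory=dict)
    rate_worse: dict[str, int] = field(default_factory=dict)
    rate_worse_endpoint_not_worse: dict[str, int] = field(default_factory=dict)
    weight_histogram: dict[str, int] = field(default_factory=dict)
    n_units: dict[str, int] = field(default_factory=dict)


def tally(
    classifications: Iterable[UnitClassification],
    index_records: Iterable[ImpactIndexRecord] = (),
    meta: Mapping[str, UnitMeta] | None = None,
) -> TallySummary:
    """Count the headline quantities over districts.

    "Outside the conflict zone" means conflict class is not HIGH — both
    intermittent-conflict and no-conflict districts count as outside.
    """
    meta = meta or {}
    summary = TallySummary()
    for c in classifications:
        m = meta.get(c.unit_id)
        if m is not None and m.conflict_class is ConflictClass.NATIONAL:
            continue
        ind = c.indicator.value
        summary.n_units[ind] = summary.n_units.get(ind, 0) + 1
        if c.endpoint_flag is Flag.WORSE:
            summary.endpoint_worse[ind] = summary.endpoint_worse.get(ind, 0) + 1
            if m is None or m.conflict_class is not ConflictClass.HIGH:
                summary.endpoint_worse_outside_conflict[ind] = (
                    summary.endpoint_worse_outside_conflict.get(ind, 0) + 1
                )
        if c.rate_flag is Flag.WORSE:
            summary.rate_worse[ind] = summary.rate_worse.get(ind, 0) + 1
            if c.endpoint_flag is not Flag.WORSE:
                summary.rate_worse_endpoint_not_worse[ind] = (
                    summary.rate_worse_endpoint_not_worse.get(ind, 0) + 1
                )
    hist: Counter[str] = Counter()
    for record in index_records:
        key = "N/A" if record.weight is None else str(record.weight)
        hist[key] += 1
    summary.weight_histogram = dict(sorted(hist.items()))
    return summary


def tally_from_labels(
    printed: Iterable[PrintedInterpretation],
    meta: Mapping[str, UnitMeta] | None = None,
) -> TallySummary:
    """Headline counts computed from printed labels instead of raw columns.

    The published summary tables are the authoritative surface for the MMR
    headline counts (their raw columns disagree for two districts); this
    path inverts each label back to flags and re-counts.
    """
    classifications = []
    for p in printed:
        rate_flag, endpoint_flag = label_to_flags(p.label)
        classifications.append(
            UnitClassification(p.unit_id, p.indicator, rate_flag, endpoint_flag, p.label)
        )
    return tally(classifications, (), meta)


@dataclass(frozen=True)
class LabelDiscrepancy:
    unit_id: str
    indicator: Indicator
    computed: str
    printed: str


def reconcile_labels(
    computed: Iterable[UnitClassification],
    printed: Iterable[PrintedInterpretation],
) -> list[LabelDiscrepancy]:
    """Every unit/indicator whose computed label differs from the printed one."""
    printed_map = {(p.unit_id, Indicator(p.indicator)): p.label for p in printed}
    out = []
    for c in computed:
        key = (c.unit_id, c.indicator)
        if key in printed_map and printed_map[key] != c.label:
            out.append(LabelDiscrepancy(c.unit_id, c.indicator, c.label, printed_map[key]))
    out.sort(key=lambda d: (d.unit_id, d.indicator.value))
    return out
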