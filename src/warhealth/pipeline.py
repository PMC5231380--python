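"""End-to-end analysis over a series panel, plus export utilities.

``analyze_panel`` runs trend estimation -> counterfactual projection ->
classification -> impact index -> tallies for every (unit, indicator) in a
panel, treating the NATIONAL pseudo-unit exactly like a district until the
tally stage.  ``run_analyze`` is the file-level wrapper used by the CLI: it
reads the input CSVs, writes the classification table, tally JSON and a run
manifest, and returns the in-memory result.

``map_export`` attaches impact weights to a GeoJSON FeatureCollection for
choropleth rendering; geometry is passed through untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

from . import __version__
from .classify import (
    ImpactIndexRecord,
    TallySummary,
    UnitClassification,
    classify_endpoint,
    classify_rate_change,
    impact_weight,
    tally,
)
from .core import Flag, Indicator, IndicatorSeries, StudyConfig, UnitMeta
from .counterfactual import (
    NegativeProjectionWarning,
    build_counterfactual,
    sensitivity_analysis,
)
from .io import read_meta, read_series, write_results
from .names import normalize_unit
from .trends import estimate_window_trend


@dataclass
class AnalysisResult:
    classifications: list[UnitClassification]
    index_records: list[ImpactIndexRecord]
    tally: TallySummary
    warnings: list[str] = field(default_factory=list)


def classify_series(
    series: IndicatorSeries, meta: UnitMeta, config: StudyConfig
) -> UnitClassification:
    """Classify one unit/indicator from its raw series.

    Either flag degrades to NOT_ASSESSABLE when its inputs are missing
    (late-created unit, no baseline, no endpoint observation); the
    interpretation label follows from the flags.
    """
    cf = build_counterfactual(series, meta, config)
    if cf is None:
        return UnitClassification(
            series.unit_id, series.indicator, Flag.NOT_ASSESSABLE, Flag.NOT_ASSESSABLE
        )
    endpoint_year = cf.endpoint_year
    conflict_trend = estimate_window_trend(
        series, config.baseline_year, endpoint_year, basis="CONFLICT"
    )
    rate_flag = (
        classify_rate_change(cf.rate, conflict_trend.rate, config.tie_tolerance)
        if conflict_trend is not None
        else Flag.NOT_ASSESSABLE
    )
    endpoint_flag = classify_endpoint(
        series.value(endpoint_year), cf.endpoint_value, True, config.tie_tolerance
    )
    return UnitClassification(series.unit_id, series.indicator, rate_flag, endpoint_flag)


def analyze_panel(
    series_list: Sequence[IndicatorSeries],
    meta_map: Mapping[str, UnitMeta],
    config: StudyConfig,
) -> AnalysisResult:
    """Full pipeline over a panel; collects projection warnings as text."""
    if not series_list:
        raise ValueError("no series loaded")
    missing = sorted(
        {s.unit_id for s in series_list if s.unit_id not in meta_map}
    )
    if missing:
        raise KeyError(f"units missing from metadata: {', '.join(missing)}")
    classifications: list[UnitClassification] = []
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", NegativeProjectionWarning)
        for series in series_list:
            classifications.append(
                classify_series(series, meta_map[series.unit_id], config)
            )
        captured = [str(w.message) for w in caught]
    by_unit: dict[str, dict[Indicator, UnitClassification]] = {}
    for c in classifications:
        by_unit.setdefault(c.unit_id, {})[c.indicator] = c
    index_records = [
        impact_weight(pair.get(Indicator.IMR), pair.get(Indicator.MMR))
        for unit, pair in sorted(by_unit.items())
        if meta_map[unit].conflict_class.value != "NATIONAL"
    ]
    summary = tally(classifications, index_records, meta_map)
    return AnalysisResult(classifications, index_records, summary, captured)


# ---------------------------------------------------------------------------
# file-level drivers


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(
    config: StudyConfig,
    inputs: Mapping[str, Path],
    warnings_emitted: Sequence[str],
    extra: Mapping[str, Any] | None = None,
) -> dict:
    manifest = {
        "software": {"name": "warhealth", "version": __version__},
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
        },
        "warnings": list(warnings_emitted),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    manifest["config"]["projection_shape"] = config.projection_shape.value
    if extra:
        manifest.update(extra)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def tally_to_dict(summary: TallySummary) -> dict:
    return dataclasses.asdict(summary)


def run_analyze(
    series_csv: str | Path,
    meta_csv: str | Path,
    config: StudyConfig,
    out_dir: str | Path,
) -> AnalysisResult:
    """Read inputs, run the pipeline, write the result files.

    Outputs: classification.csv, index.csv, tally.json, manifest.json.
    """
    series_csv, meta_csv = Path(series_csv), Path(meta_csv)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, report = read_series(series_csv)
    meta = read_meta(meta_csv)
    result = analyze_panel(series, meta, config)
    write_results(
        result.classifications,
        out_dir / "classification.csv",
        columns=("unit_id", "indicator", "rate_flag", "endpoint_flag", "label"),
    )
    write_results(
        [
            {
                "unit_id": r.unit_id,
                "weight": "N/A" if r.weight is None else r.weight,
                **{k: v.value for k, v in r.components.items()},
            }
            for r in result.index_records
        ],
        out_dir / "index.csv",
        columns=(
            "unit_id",
            "weight",
            "imr_rate",
            "imr_endpoint",
            "mmr_rate",
            "mmr_endpoint",
        ),
    )
    with (out_dir / "tally.json").open("w", encoding="utf-8") as fh:
        json.dump(tally_to_dict(result.tally), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = build_manifest(
        config,
        {"series": series_csv, "meta": meta_csv},
        result.warnings,
        extra={"load_report": dataclasses.asdict(report)},
    )
    _write_manifest(manifest, out_dir)
    return result


def run_sensitivity(
    series_csv: str | Path,
    meta_csv: str | Path,
    config: StudyConfig,
    shapes: Sequence[str],
    out_dir: str | Path,
) -> list:
    """Per-shape endpoint classification plus a consistency table on disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, _ = read_series(series_csv)
    meta = read_meta(meta_csv)
    results = sensitivity_analysis(series, meta, config, list(shapes))
    rows = [
        {
            "unit_id": r.unit_id,
            "indicator": r.indicator.value,
            **{shape.value.lower(): flag.value for shape, flag in r.flags.items()},
            "consistent": r.consistent,
        }
        for r in results
    ]
    columns = (
        ["unit_id", "indicator"]
        + [str(s).split(".")[-1].lower() for s in results[0].flags]
        + ["consistent"]
    ) if rows else ["unit_id", "indicator", "consistent"]
    write_results(rows, out_dir / "sensitivity.csv", columns=columns)
    summary = {
        "n_assessed": len(results),
        "n_consistent": sum(r.consistent for r in results),
    }
    with (out_dir / "sensitivity_summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return results


# ---------------------------------------------------------------------------
# choropleth-ready GeoJSON export


def weight_class(weight: Optional[int]) -> str:
    if weight is None:
        return "not assessable"
    return {0: "none", 1: "minimal", 2: "minimal", 3: "noticeable", 4: "high"}[weight]


def map_export(
    index_records: Iterable[ImpactIndexRecord],
    boundaries: dict,
    name_property: str = "name",
) -> tuple[dict, list[str]]:
    """Join impact weights onto boundary features by district name.

    Returns the enriched FeatureCollection and the list of index districts
    that matched no feature.  Spelling variants resolve through the alias
    table.  Zero successful joins is a hard error (wrong boundary file).
    """
    records = {normalize_unit(r.unit_id): r for r in index_records}
    if not records:
        raise ValueError("empty impact index")
    if boundaries.get("type") != "FeatureCollection":
        raise ValueError("boundaries must be a GeoJSON FeatureCollection")
    matched: set[str] = set()
    features_out = []
    for feature in boundaries.get("features", []):
        props = dict(feature.get("properties") or {})
        unit = normalize_unit(str(props.get(name_property, "")))
        record = records.get(unit)
        if record is not None:
            matched.add(unit)
            props["weight"] = record.weight if record.weight is not None else None
            props["weight_class"] = weight_class(record.weight)
        features_out.append({**feature, "properties": props})
    if not matched:
        raise ValueError(
            f"no boundary feature matched any index district via {name_property!r}"
        )
    unmatched = sorted(set(records) - matched)
    return {**boundaries, "features": features_out}, unmatched
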