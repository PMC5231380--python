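"""Readers and writers for the long-format indicator CSVs.

Input series CSV: ``unit_id,indicator,year,value`` with an empty value cell
meaning "not observed".  Metadata CSV:
``unit_id,conflict_class,creation_year,imr_endpoint_year,mmr_endpoint_year``.
All output writers emit deterministic row and column order so repeat runs are
byte-identical.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .core import Indicator, IndicatorSeries, UnitMeta
from .names import normalize_unit

SERIES_COLUMNS = ("unit_id", "indicator", "year", "value")


@dataclass
class LoadReport:
    """What happened while ingesting a series CSV."""

    n_rows: int = 0
    n_values: int = 0
    n_blank_dropped: int = 0
    n_series: int = 0
    aliases_applied: dict[str, str] = field(default_factory=dict)


class SeriesFormatError(ValueError):
    """Raised for malformed rows: bad numbers, conflicting duplicates."""


def read_series(path: str | Path) -> tuple[list[IndicatorSeries], LoadReport]:
    """Load one IndicatorSeries per (unit, indicator) from a long CSV.

    Blank value cells are dropped (and counted); a non-numeric value or a
    duplicate (unit, indicator, year) with a conflicting value is a hard
    error naming the offending row.
    """
    path = Path(path)
    report = LoadReport()
    obs: dict[tuple[str, str], dict[int, float]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(SERIES_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise SeriesFormatError(
                f"{path}: expected columns {SERIES_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            raw_value = (row["value"] or "").strip()
            if raw_value == "":
                report.n_blank_dropped += 1
                continue
            unit = normalize_unit(row["unit_id"])
            if unit != row["unit_id"].strip():
                report.aliases_applied[row["unit_id"].strip()] = unit
            indicator = Indicator(row["indicator"].strip().upper())
            try:
                year = int(row["year"])
                value = float(raw_value)
            except ValueError as exc:
                raise SeriesFormatError(
                    f"{path} line {lineno}: non-numeric cell "
                    f"({row['year']!r}, {raw_value!r})"
                ) from exc
            key = (unit, indicator.value)
            seen = obs.setdefault(key, {})
            if year in seen and seen[year] != value:
                raise SeriesFormatError(
                    f"{path} line {lineno}: duplicate ({unit}, {indicator.value}, "
                    f"{year}) with conflicting values {seen[year]} != {value}"
                )
            seen[year] = value
            report.n_values += 1
    series = [
        IndicatorSeries(unit, Indicator(ind), values, source=str(path))
        for (unit, ind), values in sorted(obs.items())
    ]
    report.n_series = len(series)
    return series, report


def read_meta(path: str | Path) -> dict[str, UnitMeta]:
    """Load unit metadata keyed by canonical unit id."""
    path = Path(path)
    out: dict[str, UnitMeta] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            unit = normalize_unit(row["unit_id"])
            creation = (row.get("creation_year") or "").strip()
            out[unit] = UnitMeta(
                unit_id=unit,
                conflict_class=row["conflict_class"].strip().upper(),
                creation_year=int(creation) if creation else None,
                imr_endpoint_year=int(row.get("imr_endpoint_year") or 2002),
                mmr_endpoint_year=int(row.get("mmr_endpoint_year") or 2002),
            )
    return out


def series_to_rows(series: Iterable[IndicatorSeries]) -> list[dict[str, Any]]:
    rows = []
    for s in series:
        for year, value in s.observations.items():
            rows.append(
                {
                    "unit_id": s.unit_id,
                    "indicator": s.indicator.value,
                    "year": year,
                    "value": value,
                }
            )
    rows.sort(key=lambda r: (r["unit_id"], r["indicator"], r["year"]))
    return rows


def _record_to_dict(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        d = dataclasses.asdict(record)
    elif isinstance(record, Mapping):
        d = dict(record)
    else:
        raise TypeError(f"cannot serialize record of type {type(record)!r}")
    out = {}
    for key, value in d.items():
        if hasattr(value, "value") and not isinstance(value, (int, float)):
            value = value.value  # enums
        out[key] = value
    return out


def write_results(
    records: Sequence[Any],
    path: str | Path,
    format: str = "csv",
    columns: Sequence[str] | None = None,
) -> Path:
    """Write records (dataclasses or mappings) deterministically.

    Rows are sorted by ``unit_id`` (then all remaining columns) so repeat runs
    are byte-identical; an empty record set yields a header-only file when the
    column set is supplied.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dicts = [_record_to_dict(r) for r in records]
    if columns is None:
        if not dicts:
            raise ValueError("empty record set needs an explicit column list")
        columns = list(dicts[0])
    sort_key = lambda d: tuple(str(d.get(c, "")) for c in columns)
    dicts.sort(key=sort_key)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(columns), lineterminator="\n")
            writer.writeheader()
            for d in dicts:
                writer.writerow({c: _fmt(d.get(c)) for c in columns})
    elif format == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(dicts, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _fmt(value: Any) -> Any:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        # keep integral floats compact and stable across platforms
        return repr(value)
    return value
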