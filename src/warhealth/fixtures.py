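"""Packaged copies of the published summary tables.

Each fixture is a CSV transcription of one printed table, cell for cell.
Printed "n/a" cells are normalized to empty cells at packaging time, with the
affected column names preserved in an ``na_fields`` provenance column.
``load_fixture`` never recomputes anything; a JSON manifest pins each file's
SHA-256 so accidental edits fail loudly in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Iterable

import pandas as pd

_FILES = {
    "table2": "table2_national.csv",
    "table3": "table3_district_imr.csv",
    "table4": "table4_imr_labels.csv",
    "table5": "table5_district_mmr.csv",
    "table6": "table6_mmr_labels.csv",
    "table9": "table9_impact_histogram.csv",
    "unit_meta": "unit_meta.csv",
}

FIXTURE_NAMES: tuple[str, ...] = tuple(_FILES)


def _data_dir():
    return resources.files("warhealth") / "data"


def fixture_path(name: str):
    if name not in _FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FILES)}"
        )
    return _data_dir() / _FILES[name]


def load_fixture(name: str) -> pd.DataFrame:
    """Return one packaged table exactly as printed (empty cell = printed n/a)."""
    path = fixture_path(name)
    # only truly empty cells are missing; literal "N/A" tokens (the weight
    # histogram's first row) are data, not NaN
    df = pd.read_csv(
        path,
        dtype={"na_fields": "string", "weight": "string"},
        keep_default_na=False,
        na_values=[""],
    )
    if "na_fields" in df.columns:
        df["na_fields"] = df["na_fields"].fillna("")
    return df


def load_manifest() -> dict:
    with (_data_dir() / "manifest.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def file_sha256(path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def verify_fixtures(names: Iterable[str] = FIXTURE_NAMES) -> dict[str, bool]:
    """Check every packaged fixture against the manifest checksums."""
    manifest = load_manifest()
    out = {}
    for name in names:
        path = fixture_path(name)
        out[name] = file_sha256(path) == manifest[name]["sha256"]
    return out
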