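import json

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from warhealth.core import Indicator, IndicatorSeries  # noqa: E402
from warhealth.replicate import district_meta  # noqa: E402


@pytest.fixture(scope="session")
def meta():
    """Packaged unit metadata (25 districts + NATIONAL)."""
    return district_meta()


@pytest.fixture()
def boundary_geojson():
    """Five synthetic square polygons named like real districts.

    One name uses a published variant spelling to exercise the alias table.
    """
    def square(i):
        return {
            "type": "Polygon",
            "coordinates": [
                [[i, 0], [i + 1, 0], [i + 1, 1], [i, 1], [i, 0]]
            ],
        }

    names = ["Jaffna", "Kilinochi", "Colombo", "Badulla", "Ampara"]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": square(i),
                "properties": {"name": name, "id": i},
            }
            for i, name in enumerate(names)
        ],
    }


def make_series(unit, indicator, values, **kw):
    return IndicatorSeries(unit, Indicator(indicator), dict(values), **kw)


def write_series_csv(path, rows):
    path.write_text(
        "unit_id,indicator,year,value\n"
        + "".join(f"{u},{i},{y},{v}\n" for u, i, y, v in rows)
    )
    return path


def write_meta_csv(path, rows):
    path.write_text(
        "unit_id,conflict_class,creation_year,imr_endpoint_year,mmr_endpoint_year\n"
        + "".join(
            f"{u},{c},{cr},{ie},{me}\n" for u, c, cr, ie, me in rows
        )
    )
    return path
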