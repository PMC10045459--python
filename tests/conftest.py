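"""Shared fixtures: tiny hand-built landscapes and capture datasets."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from shapely.geometry import Polygon

from meadowmrr.core import CaptureRecord, Dataset, OccasionCalendar, Patch
from meadowmrr.geo import LocalProjection

ORIGIN = (19.80, 46.10)


def make_square(cx_m: float, cy_m: float, side_m: float, proj: LocalProjection) -> Polygon:
    """Axis-aligned square patch (metric frame) as a WGS84 polygon."""
    h = side_m / 2.0
    xs = [cx_m - h, cx_m + h, cx_m + h, cx_m - h, cx_m - h]
    ys = [cy_m - h, cy_m - h, cy_m + h, cy_m + h, cy_m - h]
    lon, lat = proj.inverse(np.array(xs), np.array(ys))
    return Polygon(zip(lon, lat))


def point(proj: LocalProjection, x_m: float, y_m: float) -> tuple[float, float]:
    lon, lat = proj.inverse(x_m, y_m)
    return float(lon), float(lat)


@pytest.fixture(scope="session")
def proj() -> LocalProjection:
    return LocalProjection(*ORIGIN)


@pytest.fixture(scope="session")
def toy_patches(proj) -> list[Patch]:
    """Three 100 m squares: P1 at the origin, P2 exactly 1 km east, P3 offset."""
    mk = lambda cx, cy: make_square(cx, cy, 100.0, proj)
    return [
        Patch("P1", "A", mk(0.0, 0.0), 10_000.0, "unmown"),
        Patch("P2", "A", mk(1000.0, 0.0), 10_000.0, "mown",
              mowing_date=dt.date(2014, 7, 10)),
        Patch("P3", "B", mk(250.0, 400.0), 10_000.0, "recovered",
              mowing_date=dt.date(2014, 6, 20)),
    ]


@pytest.fixture(scope="session")
def toy_calendar() -> OccasionCalendar:
    return OccasionCalendar(
        (dt.date(2014, 7, 19), dt.date(2014, 7, 20), dt.date(2014, 7, 22))
    )


@pytest.fixture(scope="session")
def toy_dataset(proj, toy_patches, toy_calendar) -> Dataset:
    """ind1 moves within P1 (50 m) then disperses to P2; ind2 stays in P1;
    ind3 is captured once in P2."""
    cal = toy_calendar
    rec = lambda ind, occ, sex, pid, x, y: CaptureRecord(
        ind, occ, cal.dates[occ], sex, pid, *point(proj, x, y)
    )
    records = [
        rec("ind1", 0, "F", "P1", 0.0, 0.0),
        rec("ind1", 1, "F", "P1", 30.0, 40.0),
        rec("ind1", 2, "F", "P2", 990.0, 10.0),
        rec("ind2", 0, "M", "P1", -20.0, 5.0),
        rec("ind2", 2, "M", "P1", 25.0, -10.0),
        rec("ind3", 1, "F", "P2", 1005.0, -12.0),
    ]
    return Dataset(records=records, patches=list(toy_patches), calendar=cal)


@pytest.fixture(scope="session")
def emigration_toy(proj, toy_calendar) -> Dataset:
    """One origin patch with 10 recaptured individuals, 3 of them emigrants."""
    mk = lambda cx, cy: make_square(cx, cy, 100.0, proj)
    patches = [
        Patch("P1", "A", mk(0.0, 0.0), 10_000.0, "unmown"),
        Patch("P2", "A", mk(500.0, 0.0), 10_000.0, "mown"),
    ]
    cal = toy_calendar
    records = []
    for i in range(10):
        records.append(
            CaptureRecord(f"b{i}", 0, cal.dates[0], "F", "P1", *point(proj, 0, 0))
        )
        dest = "P2" if i < 3 else "P1"
        x = 500.0 if i < 3 else 10.0
        records.append(
            CaptureRecord(f"b{i}", 1, cal.dates[1], "F", dest, *point(proj, x, 0))
        )
    return Dataset(records=records, patches=patches, calendar=cal)
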