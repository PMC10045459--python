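"""Core domain model for patch-based mark-release-recapture (MRR) data.

The spatial unit is the habitat *patch* (a meadow fragment with the host
plant), grouped into *localities* (geographic sampling blocks). Individuals
are uniquely marked butterflies; each capture is a record with a date that
maps onto an ordered calendar of sampling occasions. A patch carries a
mowing *regime*: unmown, recovered (mown long enough before the flight
period for the vegetation to reflower) or mown (cut shortly before or
during the flight period).
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

from .geo import LocalProjection, polygon_area_m2, polygon_centroid

REGIMES = ("unmown", "recovered", "mown")
RECORD_COLUMNS = ["individual_id", "date", "sex", "patch_id", "lon", "lat"]

#: Days between mowing and the start of the flight period at or above which a
#: mown meadow counts as "recovered" (host plants have reflowered).
DEFAULT_REGIME_THRESHOLD_DAYS = 15

#: Default GPS tolerance (m) for point-in-patch validation.
DEFAULT_POINT_TOLERANCE_M = 25.0


class SchemaError(ValueError):
    """A required column or property is missing or malformed."""


class ReferentialError(ValueError):
    """A record references an unknown patch or occasion."""


class GeometryError(ValueError):
    """A patch polygon is invalid (open ring, self-intersection, zero area)."""


class DuplicateKeyError(ValueError):
    """Duplicate (individual_id, occasion) capture."""


@dataclass(frozen=True)
class Patch:
    """A habitat patch: polygon, locality, area and mowing regime."""

    patch_id: str
    locality: str
    polygon: Polygon
    area_m2: float
    regime: str
    mowing_date: dt.date | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not self.locality:
            raise ValueError("locality must be non-empty")
        if not self.area_m2 > 0:
            raise ValueError("area_m2 must be positive")
        geo_area = polygon_area_m2(self.polygon)
        if abs(geo_area - self.area_m2) > 0.01 * max(geo_area, self.area_m2):
            raise GeometryError(
                f"patch {self.patch_id}: declared area {self.area_m2:.1f} m2 "
                f"differs from polygon area {geo_area:.1f} m2 by more than 1%"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return polygon_centroid(self.polygon)


@dataclass(frozen=True)
class CaptureRecord:
    """One capture of a marked individual at a date, patch and GPS point."""

    individual_id: str
    occasion: int
    date: dt.date
    sex: str
    patch_id: str
    lon: float
    lat: float

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass(frozen=True)
class OccasionCalendar:
    """Ordered dates of the capture sessions.

    ``intervals[i]`` is the number of days between occasion i and i+1
    (the l_i entering interval survival phi**l_i).
    """

    dates: tuple[dt.date, ...]

    def __post_init__(self):
        if len(self.dates) == 0:
            raise ValueError("calendar needs at least one date")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("calendar dates must be strictly increasing")

    @property
    def n_occasions(self) -> int:
        return len(self.dates)

    @property
    def intervals(self) -> np.ndarray:
        """Day counts l_i between consecutive occasions (length n-1)."""
        return np.array(
            [(b - a).days for a, b in zip(self.dates, self.dates[1:])], dtype=int
        )

    def occasion_of(self, date: dt.date) -> int:
        try:
            return self.dates.index(date)
        except ValueError:
            raise ReferentialError(f"date {date} is not a sampling occasion") from None

    def max_gap(self) -> int:
        iv = self.intervals
        return int(iv.max()) if iv.size else 0


@dataclass
class Dataset:
    """Validated MRR dataset: capture records, patches and the calendar."""

    records: list[CaptureRecord]
    patches: list[Patch]
    calendar: OccasionCalendar

    def __post_init__(self):
        patch_ids = {p.patch_id for p in self.patches}
        seen: set[tuple[str, int]] = set()
        for r in self.records:
            if r.patch_id not in patch_ids:
                raise ReferentialError(
                    f"record for {r.individual_id} references unknown patch "
                    f"{r.patch_id!r}"
                )
            if not (0 <= r.occasion < self.calendar.n_occasions):
                raise ReferentialError(
                    f"record for {r.individual_id} has occasion {r.occasion} "
                    f"outside the calendar"
                )
            if self.calendar.dates[r.occasion] != r.date:
                raise ReferentialError(
                    f"record for {r.individual_id}: occasion {r.occasion} does "
                    f"not match date {r.date}"
                )
            key = (r.individual_id, r.occasion)
            if key in seen:
                raise DuplicateKeyError(
                    f"duplicate capture of {r.individual_id} at occasion {r.occasion}"
                )
            seen.add(key)

    @property
    def patch_by_id(self) -> dict[str, Patch]:
        return {p.patch_id: p for p in self.patches}

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "occasion": [r.occasion for r in self.records],
                "date": [r.date.isoformat() for r in self.records],
                "sex": [r.sex for r in self.records],
                "patch_id": [r.patch_id for r in self.records],
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
            }
        )

    def n_individuals(self) -> int:
        return len({r.individual_id for r in self.records})


def assign_regime(
    mowing_date: dt.date | None,
    flight_start: dt.date,
    threshold_days: int = DEFAULT_REGIME_THRESHOLD_DAYS,
    season_end: dt.date | None = None,
) -> str:
    """Classify a patch's mowing regime relative to the flight period.

    No mowing date -> ``unmown``. Mown at least ``threshold_days`` days
    before ``flight_start`` -> ``recovered`` (vegetation had time to
    reflower). Mown later than that -> ``mown``.
    """
    if threshold_days < 0:
        raise ValueError("threshold_days must be >= 0")
    if mowing_date is None:
        return "unmown"
    if season_end is not None and mowing_date > season_end:
        raise ValueError(
            f"mowing date {mowing_date} falls after the flight season end "
            f"{season_end}"
        )
    if (flight_start - mowing_date).days >= threshold_days:
        return "recovered"
    return "mown"


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value))


def read_patches(
    patches_path: str | Path,
    flight_start: dt.date | None = None,
    threshold_days: int = DEFAULT_REGIME_THRESHOLD_DAYS,
) -> list[Patch]:
    """Read a GeoJSON FeatureCollection of habitat patches.

    Each feature needs properties ``patch_id`` and ``locality`` plus either
    an explicit ``regime`` or a ``mowing_date`` from which the regime is
    derived (the explicit column wins on conflict, with a warning).
    """
    with open(patches_path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("patches file must be a GeoJSON FeatureCollection")
    patches = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        for key in ("patch_id", "locality"):
            if key not in props:
                raise SchemaError(f"patch feature missing property {key!r}")
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise GeometryError(
                f"patch {props['patch_id']}: geometry must be a Polygon"
            )
        if not geom.is_valid or geom.area == 0:
            raise GeometryError(f"patch {props['patch_id']}: invalid polygon")
        mow = props.get("mowing_date")
        mowing_date = _parse_date(mow) if mow else None
        explicit = props.get("regime")
        derived = None
        if mowing_date is not None or explicit is None:
            if flight_start is None and explicit is None:
                raise SchemaError(
                    f"patch {props['patch_id']}: no regime and no flight_start "
                    f"to derive one from mowing_date"
                )
            if flight_start is not None:
                derived = assign_regime(mowing_date, flight_start, threshold_days)
        regime = explicit or derived
        if explicit and derived and explicit != derived:
            warnings.warn(
                f"patch {props['patch_id']}: explicit regime {explicit!r} "
                f"conflicts with regime {derived!r} derived from mowing_date; "
                f"keeping the explicit value",
                stacklevel=2,
            )
        patches.append(
            Patch(
                patch_id=str(props["patch_id"]),
                locality=str(props["locality"]),
                polygon=geom,
                area_m2=polygon_area_m2(geom),
                regime=regime,
                mowing_date=mowing_date,
            )
        )
    return patches


def read_dataset(
    records_path: str | Path,
    patches_path: str | Path,
    threshold_days: int = DEFAULT_REGIME_THRESHOLD_DAYS,
) -> Dataset:
    """Read capture records (CSV/TSV) and patches (GeoJSON) into a Dataset.

    The occasion calendar is inferred from the distinct record dates; the
    flight period is taken to start at the first record date. An optional
    ``occasion`` column is checked against the inferred calendar.
    """
    sep = "\t" if str(records_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(records_path, sep=sep, dtype={"individual_id": str, "patch_id": str})
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"records file missing required column {col!r}")
    dates = sorted({_parse_date(d) for d in df["date"]})
    calendar = OccasionCalendar(tuple(dates))
    flight_start = dates[0]
    patches = read_patches(patches_path, flight_start, threshold_days)
    records = []
    for row in df.itertuples(index=False):
        date = _parse_date(row.date)
        occ = calendar.occasion_of(date)
        if "occasion" in df.columns and not pd.isna(getattr(row, "occasion", np.nan)):
            if int(row.occasion) != occ:
                raise ReferentialError(
                    f"record for {row.individual_id}: stated occasion "
                    f"{row.occasion} conflicts with calendar position {occ}"
                )
        records.append(
            CaptureRecord(
                individual_id=str(row.individual_id),
                occasion=occ,
                date=date,
                sex=str(row.sex),
                patch_id=str(row.patch_id),
                lon=float(row.lon),
                lat=float(row.lat),
            )
        )
    return Dataset(records=records, patches=patches, calendar=calendar)


def write_dataset(
    ds: Dataset, records_path: str | Path, patches_path: str | Path
) -> None:
    """Write a Dataset back to the CSV + GeoJSON dialects read_dataset reads.

    Output is canonical (sorted keys, fixed float formatting) so that a
    write/read/write cycle is byte-identical.
    """
    df = ds.records_frame()
    df.to_csv(records_path, index=False, float_format="%.8f")
    features = []
    for p in ds.patches:
        props = {"patch_id": p.patch_id, "locality": p.locality, "regime": p.regime}
        if p.mowing_date is not None:
            props["mowing_date"] = p.mowing_date.isoformat()
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": json.loads(json.dumps(mapping(p.polygon))),
            }
        )
    with open(patches_path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": features},
            fh,
            sort_keys=True,
            separators=(",", ":"),
        )
        fh.write("\n")


@dataclass
class ValidationReport:
    """Report-only findings from validate_dataset."""

    out_of_patch: list[tuple[str, int, float]] = field(default_factory=list)
    calendar_gaps: list[tuple[int, int]] = field(default_factory=list)
    sex_inconsistencies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.out_of_patch or self.calendar_gaps or self.sex_inconsistencies)


def point_to_patch_distance_m(lon: float, lat: float, patch: Patch) -> float:
    """Metric distance from a point to a patch polygon (0 if inside)."""
    c = patch.polygon.centroid
    proj = LocalProjection(c.x, c.y)
    px, py = proj.forward(lon, lat)
    from shapely.ops import transform as shapely_transform

    poly_m = shapely_transform(lambda lo, la, z=None: proj.forward(lo, la), patch.polygon)
    return float(poly_m.distance(Point(float(px), float(py))))


def validate_dataset(
    ds: Dataset,
    tolerance_m: float = DEFAULT_POINT_TOLERANCE_M,
    max_gap_days: int = 3,
) -> ValidationReport:
    """Flag GPS points outside their declared patch, long calendar gaps and
    within-individual sex conflicts. Report-only; nothing is modified."""
    report = ValidationReport()
    by_id = ds.patch_by_id
    for i, r in enumerate(ds.records):
        d = point_to_patch_distance_m(r.lon, r.lat, by_id[r.patch_id])
        if d > tolerance_m:
            report.out_of_patch.append((r.individual_id, r.occasion, d))
    for i, gap in enumerate(ds.calendar.intervals):
        if gap > max_gap_days:
            report.calendar_gaps.append((i, int(gap)))
    sexes: dict[str, set[str]] = {}
    for r in ds.records:
        sexes.setdefault(r.individual_id, set()).add(r.sex)
    report.sex_inconsistencies = sorted(k for k, v in sexes.items() if len(v) > 1)
    return report
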