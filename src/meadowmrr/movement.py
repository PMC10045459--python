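"""Movement classification and per-patch emigration probabilities.

Two movement kinds are distinguished between consecutive captures of the
same individual: *dispersal* (the individual changed habitat patch) and
*displacement* (a move within the same patch). Emigration probability of a
patch is the fraction, among recaptured individuals first captured there,
that were ever recaptured in a different patch — individuals that stayed
put count in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CaptureRecord, Dataset
from .geo import geodesic_distance_m

MOVEMENT_COLUMNS = [
    "individual_id",
    "kind",
    "origin_patch",
    "dest_patch",
    "origin_regime",
    "sex",
    "distance_m",
]


@dataclass(frozen=True)
class MovementEvent:
    """A move between two consecutive captures of one individual."""

    individual_id: str
    from_record: CaptureRecord
    to_record: CaptureRecord
    distance_m: float
    kind: str  # "dispersal" | "displacement"
    origin_patch_id: str
    origin_regime: str
    sex: str


def classify_movements(ds: Dataset) -> list[MovementEvent]:
    """One MovementEvent per consecutive capture pair of each individual.

    Kind is ``dispersal`` iff the patch id changed between the two captures;
    the distance is the geodesic between the two capture points. Sex is the
    sex recorded at the individual's first capture.
    """
    by_patch = ds.patch_by_id
    per_ind: dict[str, list[CaptureRecord]] = {}
    for r in ds.records:
        per_ind.setdefault(r.individual_id, []).append(r)
    events: list[MovementEvent] = []
    for ind, recs in per_ind.items():
        recs = sorted(recs, key=lambda r: r.occasion)
        sex = recs[0].sex
        for a, b in zip(recs, recs[1:]):
            kind = "dispersal" if a.patch_id != b.patch_id else "displacement"
            events.append(
                MovementEvent(
                    individual_id=ind,
                    from_record=a,
                    to_record=b,
                    distance_m=geodesic_distance_m((a.lon, a.lat), (b.lon, b.lat)),
                    kind=kind,
                    origin_patch_id=a.patch_id,
                    origin_regime=by_patch[a.patch_id].regime,
                    sex=sex,
                )
            )
    return events


def movements_frame(events: list[MovementEvent]) -> pd.DataFrame:
    """Tabulate MovementEvents in the exportable CSV layout."""
    return pd.DataFrame(
        {
            "individual_id": [e.individual_id for e in events],
            "kind": [e.kind for e in events],
            "origin_patch": [e.origin_patch_id for e in events],
            "dest_patch": [e.to_record.patch_id for e in events],
            "origin_regime": [e.origin_regime for e in events],
            "sex": [e.sex for e in events],
            "distance_m": [e.distance_m for e in events],
        },
        columns=MOVEMENT_COLUMNS,
    )


def emigration_table(ds: Dataset, by_sex: bool = False) -> pd.DataFrame:
    """Per-patch emigration summary.

    For each patch: ``n_recaptured`` individuals first captured there and
    recaptured anywhere at least once, ``n_emigrants`` of those ever
    recaptured in another patch, and their ratio. A patch with no recaptured
    individuals gets probability NaN (undefined, not zero). With
    ``by_sex=True`` the table is additionally stratified by the sex at
    first capture.
    """
    per_ind: dict[str, list[CaptureRecord]] = {}
    for r in ds.records:
        per_ind.setdefault(r.individual_id, []).append(r)
    rows = []
    for ind, recs in per_ind.items():
        recs = sorted(recs, key=lambda r: r.occasion)
        if len(recs) < 2:
            continue
        origin = recs[0].patch_id
        emigrated = any(r.patch_id != origin for r in recs[1:])
        rows.append((origin, recs[0].sex, emigrated))
    obs = pd.DataFrame(rows, columns=["patch_id", "sex", "emigrated"])
    keys = ["patch_id", "sex"] if by_sex else ["patch_id"]
    patch_ids = [p.patch_id for p in ds.patches]
    regimes = {p.patch_id: p.regime for p in ds.patches}
    if obs.empty:
        grouped = pd.DataFrame(columns=keys + ["n_recaptured", "n_emigrants"])
    else:
        grouped = (
            obs.groupby(keys)["emigrated"]
            .agg(n_recaptured="size", n_emigrants="sum")
            .reset_index()
        )
    if by_sex:
        index = pd.MultiIndex.from_product(
            [patch_ids, ["F", "M"]], names=["patch_id", "sex"]
        )
        grouped = (
            grouped.set_index(keys).reindex(index, fill_value=0).reset_index()
        )
    else:
        grouped = (
            grouped.set_index("patch_id")
            .reindex(patch_ids, fill_value=0)
            .rename_axis("patch_id")
            .reset_index()
        )
    grouped["regime"] = grouped["patch_id"].map(regimes)
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["emigration_probability"] = np.where(
            grouped["n_recaptured"] > 0,
            grouped["n_emigrants"] / grouped["n_recaptured"],
            np.nan,
        )
    return grouped


def regime_emigration(table: pd.DataFrame) -> pd.DataFrame:
    """Pool an emigration table over patches within each mowing regime."""
    pooled = (
        table.groupby("regime")[["n_recaptured", "n_emigrants"]].sum().reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled["emigration_probability"] = np.where(
            pooled["n_recaptured"] > 0,
            pooled["n_emigrants"] / pooled["n_recaptured"],
            np.nan,
        )
    return pooled
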