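"""Synthetic metapopulation MRR generator with known truth.

Emulates the structure of a season-long butterfly mark-release-recapture
campaign: ~46 rectangular habitat patches clustered in 5 localities, a
six-week near-daily occasion calendar (weather gaps of up to 3 days), and
a few thousand marked individuals. Demography is individual-based and
daily: emergence follows a peaked seasonal curve, death strikes with
probability 1 - phi per day, and emigration to a neighbouring patch
(chosen by the distance- and area-weighted connectivity kernel) occurs
with a per-day hazard derived from the regime's lifetime emigration
probability. On capture occasions every living individual is recorded
with probability p at its current coordinates.

Observed movement distances follow the configured gamma kernels: a
between-patch move spans a gamma step with the origin regime's mean
(mown 102 m < recovered 198 m < unmown 246 m by default) and a
within-patch move a gamma step with the sex's mean (females 57 m, males
43 m). Steps are realised at capture and emigration events so that the
recorded between-capture distances are draws from those kernels — the
distributional assumption the gamma GLMMs in the analysis make.

All defaults equal the study-condition estimates the analysis targets, so
running the full pipeline on a default simulation is a parameter-recovery
experiment.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import CaptureRecord, Dataset, OccasionCalendar, Patch, write_dataset
from .geo import LocalProjection

#: reference origin of the synthetic landscape (wet meadows at ~46.1 N)
ORIGIN_LON, ORIGIN_LAT = 19.80, 46.12

#: locality centre offsets (km east, km north) from the origin
LOCALITY_OFFSETS = {
    "A": (-6.0, 4.0),
    "B": (0.0, 0.0),
    "C": (1.5, -2.5),
    "D": (7.0, 2.0),
    "E": (9.5, -1.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters; defaults are the study conditions."""

    seed: int = 0
    n_patches: int = 46
    n_localities: int = 5
    #: log-uniform patch area range in m^2 (median ~0.9 ha)
    area_range_m2: tuple[float, float] = (800.0, 100_000.0)
    regime_probs: dict = field(
        default_factory=lambda: {"unmown": 0.45, "recovered": 0.30, "mown": 0.25}
    )
    season_start: str = "2014-07-19"
    n_days: int = 41
    #: probability a day is skipped (bad weather); gaps never exceed max_gap
    gap_rate: float = 0.15
    max_gap: int = 3
    phi: float = 0.79  # daily apparent survival
    p: float = 0.32  # per-occasion capture probability
    #: lifetime (per-individual) emigration probability by regime
    emigration_lifetime: dict = field(
        default_factory=lambda: {"mown": 0.22, "recovered": 0.16, "unmown": 0.09}
    )
    #: mean observed dispersal step by origin regime (m)
    dispersal_mean_m: dict = field(
        default_factory=lambda: {"mown": 102.0, "recovered": 198.0, "unmown": 246.0}
    )
    #: mean observed within-patch displacement step by sex (m)
    displacement_mean_m: dict = field(default_factory=lambda: {"F": 57.0, "M": 43.0})
    step_shape: float = 2.0  # gamma shape of movement steps
    sex_ratio: float = 0.5  # P(female)
    #: expected recruits per patch by regime (unmown patches ~2x larger)
    recruits_per_patch: dict = field(
        default_factory=lambda: {"unmown": 150.0, "recovered": 75.0, "mown": 70.0}
    )
    #: optional override: rescale expectations so they sum to this total
    total_recruits: int | None = None
    #: seasonal emergence curve peaks at this fraction of the season
    emergence_peak: float = 0.4
    xi: float = 0.5
    buffer_km: float = 3.0

    @property
    def mean_dispersal_m(self) -> float:
        return sum(
            self.regime_probs[r] * self.dispersal_mean_m[r] for r in self.regime_probs
        )

    @property
    def alpha(self) -> float:
        """Destination-kernel alpha: 1 / mean dispersal distance in km."""
        return 1.0 / (self.mean_dispersal_m / 1000.0)

    def daily_emigration_hazard(self, regime: str) -> float:
        """Per-day emigration hazard whose lifetime probability equals the
        regime's target.

        Adult lifespan L (days alive) is geometric with mean 1/(1-phi). A
        constant per-day hazard h gives a lifetime emigration probability
        1 - E[(1-h)^L] = 1 - (1-h)(1-phi) / (1 - phi (1-h)); solving this
        for h at the target P yields the exact inversion
        1 - h = (1 - P) / (1 - phi P)."""
        P = self.emigration_lifetime[regime]
        return 1.0 - (1.0 - P) / (1.0 - self.phi * P)


@dataclass
class SimTruth:
    """Generating parameters and realised per-patch truths."""

    config: SimConfig
    ever_alive_per_patch: dict
    n_emerged: int
    realized_emigrants: dict  # regime -> individuals that ever emigrated from it
    realized_residents: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "ever_alive_per_patch": self.ever_alive_per_patch,
            "n_emerged": self.n_emerged,
            "realized_emigrants": self.realized_emigrants,
            "realized_residents": self.realized_residents,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)


def _locality_names(n: int) -> list[str]:
    base = list(LOCALITY_OFFSETS)
    if n <= len(base):
        return base[:n]
    return base + [f"L{i}" for i in range(len(base), n)]


def generate_patches(config: SimConfig, rng: np.random.Generator | None = None):
    """Lay out non-overlapping square patches around the locality centres.

    Returns (patches, projection); the projection maps the local metric
    frame used by the simulator to WGS84.
    """
    rng = rng or np.random.default_rng(config.seed)
    proj = LocalProjection(ORIGIN_LON, ORIGIN_LAT)
    localities = _locality_names(config.n_localities)
    spacing = 500.0  # m between grid cells; max patch side is ~316 m
    patches: list[Patch] = []
    # fixed landscape composition: exact regime counts by largest remainder,
    # randomly assigned to patch slots (the field landscape's mowing mosaic
    # is a fixed design, not an iid draw)
    regimes = list(config.regime_probs)
    probs = np.array([config.regime_probs[r] for r in regimes], dtype=float)
    probs = probs / probs.sum()
    counts = np.floor(probs * config.n_patches).astype(int)
    remainder = probs * config.n_patches - counts
    for j in np.argsort(-remainder)[: config.n_patches - counts.sum()]:
        counts[j] += 1
    regime_assignment = np.repeat(np.array(regimes, dtype=object), counts)
    rng_regimes = rng.permutation(regime_assignment)
    flight_start = dt.date.fromisoformat(config.season_start)
    for k in range(config.n_patches):
        loc = localities[k % len(localities)]
        slot = k // len(localities)
        cx_km, cy_km = LOCALITY_OFFSETS.get(loc, (0.0, 0.0))
        # row-major grid around the locality centre
        gx, gy = slot % 4, slot // 4
        cx = cx_km * 1000.0 + (gx - 1.5) * spacing
        cy = cy_km * 1000.0 + (gy - 1.0) * spacing
        area = math.exp(
            rng.uniform(math.log(config.area_range_m2[0]), math.log(config.area_range_m2[1]))
        )
        side = math.sqrt(area)
        jitter = (spacing - side) / 2.0 - 10.0
        cx += rng.uniform(-jitter, jitter)
        cy += rng.uniform(-jitter, jitter)
        regime = str(rng_regimes[k])
        if regime == "recovered":
            mowing_date = flight_start - dt.timedelta(days=int(rng.integers(15, 40)))
        elif regime == "mown":
            mowing_date = flight_start - dt.timedelta(days=int(rng.integers(0, 15)))
        else:
            mowing_date = None
        xs = [cx - side / 2, cx + side / 2, cx + side / 2, cx - side / 2, cx - side / 2]
        ys = [cy - side / 2, cy - side / 2, cy + side / 2, cy + side / 2, cy - side / 2]
        lon, lat = proj.inverse(np.array(xs), np.array(ys))
        poly = Polygon(zip(lon, lat))
        patches.append(
            Patch(
                patch_id=f"{loc}{slot + 1:02d}",
                locality=loc,
                polygon=poly,
                area_m2=side * side,
                regime=regime,
                mowing_date=mowing_date,
            )
        )
    return patches, proj


def _make_calendar(config: SimConfig, rng: np.random.Generator) -> OccasionCalendar:
    start = dt.date.fromisoformat(config.season_start)
    days = [0]
    skipped = 0
    for d in range(1, config.n_days):
        if (
            d < config.n_days - 1
            and skipped < config.max_gap - 1
            and rng.random() < config.gap_rate
        ):
            skipped += 1
            continue
        days.append(d)
        skipped = 0
    return OccasionCalendar(tuple(start + dt.timedelta(days=d) for d in days))


def _patch_frames(patches: list[Patch], proj: LocalProjection):
    """Rectangle bounds and centroids of the patches in the metric frame."""
    bounds = np.empty((len(patches), 4))
    cents = np.empty((len(patches), 2))
    for i, p in enumerate(patches):
        lon, lat = p.polygon.exterior.xy
        x, y = proj.forward(np.array(lon), np.array(lat))
        bounds[i] = (x.min(), x.max(), y.min(), y.max())
        cents[i] = ((x.min() + x.max()) / 2.0, (y.min() + y.max()) / 2.0)
    return bounds, cents


def simulate_mrr(
    config: SimConfig,
    patches: list[Patch] | None = None,
    proj: LocalProjection | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Dataset, SimTruth]:
    """Run the daily individual-based simulation; returns (Dataset, truth)."""
    rng = rng or np.random.default_rng(config.seed)
    if patches is None:
        patches, proj = generate_patches(config, rng)
    assert proj is not None
    calendar = _make_calendar(config, rng)
    start = calendar.dates[0]
    occasion_by_day = {(d - start).days: i for i, d in enumerate(calendar.dates)}

    bounds, cents = _patch_frames(patches, proj)
    n_patch = len(patches)
    regimes = np.array([p.regime for p in patches], dtype=object)
    areas = np.array([p.area_m2 for p in patches])
    hazards = np.array([config.daily_emigration_hazard(r) for r in regimes])

    # destination kernel: exp(-alpha d) * A^xi among neighbours within buffer
    D = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1)) / 1000.0
    W = np.exp(-config.alpha * D) * areas[None, :] ** config.xi
    W[(D > config.buffer_km) | np.eye(n_patch, dtype=bool)] = 0.0
    dest_probs = np.where(
        W.sum(1, keepdims=True) > 0, W / np.clip(W.sum(1, keepdims=True), 1e-300, None), 0.0
    )

    # expected recruits per patch
    lam = np.array([config.recruits_per_patch[r] for r in regimes], dtype=float)
    if config.total_recruits is not None:
        lam = lam * (config.total_recruits / lam.sum())
    n_per_patch = rng.poisson(lam)
    n_total = int(n_per_patch.sum())

    # emergence days from a triangular seasonal curve
    days = np.arange(config.n_days)
    peak = config.emergence_peak * (config.n_days - 1)
    w = np.where(
        days <= peak,
        (days + 0.5) / (peak + 0.5),
        (config.n_days - days) / (config.n_days - peak),
    )
    w = np.clip(w, 1e-6, None)
    w = w / w.sum()

    home = np.repeat(np.arange(n_patch), n_per_patch)
    emerge = rng.choice(config.n_days, size=n_total, p=w)
    lifespan = rng.geometric(1.0 - config.phi, size=n_total)  # days alive
    death_after = emerge + lifespan  # first day no longer alive
    sex = np.where(rng.random(n_total) < config.sex_ratio, "F", "M").astype(object)
    is_female = sex == "F"

    cur_patch = home.copy()
    # last observed state per individual (-1 = never captured)
    last_x = np.full(n_total, np.nan)
    last_y = np.full(n_total, np.nan)
    last_patch = np.full(n_total, -1, dtype=int)
    ever_alive = np.bincount(home, minlength=n_patch)

    disp_scale = {
        r: config.dispersal_mean_m[r] / config.step_shape for r in config.dispersal_mean_m
    }
    step_scale_f = config.displacement_mean_m["F"] / config.step_shape
    step_scale_m = config.displacement_mean_m["M"] / config.step_shape

    emigrated_from: dict[str, set] = {r: set() for r in config.regime_probs}
    resident_of: dict[str, set] = {r: set() for r in config.regime_probs}

    rows_ind: list[int] = []
    rows_occ: list[int] = []
    rows_x: list[float] = []
    rows_y: list[float] = []
    rows_patch: list[int] = []

    for day in range(config.n_days):
        alive = (emerge <= day) & (day < death_after)
        if not alive.any():
            continue
        idx = np.flatnonzero(alive)
        # emigration happens before the day's capture session
        moves = rng.random(idx.size) < hazards[cur_patch[idx]]
        for i in idx[moves]:
            pr = dest_probs[cur_patch[i]]
            if pr.sum() <= 0:
                continue
            origin_regime = regimes[cur_patch[i]]
            emigrated_from[origin_regime].add(int(i))
            cur_patch[i] = rng.choice(n_patch, p=pr)
        occ = occasion_by_day.get(day)
        if occ is None:
            continue
        captured = idx[rng.random(idx.size) < config.p]
        for i in captured:
            pk = cur_patch[i]
            xmin, xmax, ymin, ymax = bounds[pk]
            if last_patch[i] == -1:
                x = rng.uniform(xmin, xmax)
                y = rng.uniform(ymin, ymax)
            elif last_patch[i] == pk:
                scale = step_scale_f if is_female[i] else step_scale_m
                dist = rng.gamma(config.step_shape, scale)
                x = y = None
                for _ in range(40):
                    ang = rng.uniform(0.0, 2.0 * math.pi)
                    cx = last_x[i] + dist * math.cos(ang)
                    cy = last_y[i] + dist * math.sin(ang)
                    if xmin <= cx <= xmax and ymin <= cy <= ymax:
                        x, y = cx, cy
                        break
                if x is None:  # step does not fit the patch: relocate within it
                    x = rng.uniform(xmin, xmax)
                    y = rng.uniform(ymin, ymax)
            else:
                origin_regime = regimes[last_patch[i]]
                dist = rng.gamma(config.step_shape, disp_scale[origin_regime])
                tx, ty = cents[pk]
                ang = math.atan2(ty - last_y[i], tx - last_x[i]) + rng.normal(0.0, 0.3)
                x = last_x[i] + dist * math.cos(ang)
                y = last_y[i] + dist * math.sin(ang)
            last_x[i], last_y[i], last_patch[i] = x, y, pk
            rows_ind.append(int(i))
            rows_occ.append(occ)
            rows_x.append(float(x))
            rows_y.append(float(y))
            rows_patch.append(int(pk))

    for r in config.regime_probs:
        home_in_regime = {int(i) for i in np.flatnonzero(regimes[home] == r)}
        resident_of[r] = home_in_regime - emigrated_from[r]

    lon, lat = proj.inverse(np.array(rows_x), np.array(rows_y))
    records = [
        CaptureRecord(
            individual_id=f"ind{ind:06d}",
            occasion=occ,
            date=calendar.dates[occ],
            sex=str(sex[ind]),
            patch_id=patches[pk].patch_id,
            lon=float(lo),
            lat=float(la),
        )
        for ind, occ, pk, lo, la in zip(rows_ind, rows_occ, rows_patch, lon, lat)
    ]
    ds = Dataset(records=records, patches=patches, calendar=calendar)
    truth = SimTruth(
        config=config,
        ever_alive_per_patch={
            patches[k].patch_id: int(ever_alive[k]) for k in range(n_patch)
        },
        n_emerged=n_total,
        realized_emigrants={r: len(s) for r, s in emigrated_from.items()},
        realized_residents={r: len(s) for r, s in resident_of.items()},
    )
    return ds, truth


def simulate_movement_events(
    config: SimConfig,
    n_per_group: int,
    kind: str = "dispersal",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw movement events straight from the configured distance kernels.

    ``dispersal``: n events per mowing regime (random sexes);
    ``displacement``: n events per sex (random regimes). Events carry a
    random locality label so mixed models with a locality intercept can be
    exercised; no locality effect is generated.
    """
    rng = rng or np.random.default_rng(config.seed)
    localities = _locality_names(config.n_localities)
    rows = []
    if kind == "dispersal":
        for regime, mean in config.dispersal_mean_m.items():
            d = rng.gamma(config.step_shape, mean / config.step_shape, size=n_per_group)
            sexes = np.where(rng.random(n_per_group) < config.sex_ratio, "F", "M")
            locs = rng.choice(localities, size=n_per_group)
            rows.append(
                pd.DataFrame(
                    {"distance_m": d, "regime": regime, "sex": sexes, "locality": locs}
                )
            )
    elif kind == "displacement":
        for s, mean in config.displacement_mean_m.items():
            d = rng.gamma(config.step_shape, mean / config.step_shape, size=n_per_group)
            regimes = rng.choice(list(config.regime_probs), size=n_per_group)
            locs = rng.choice(localities, size=n_per_group)
            rows.append(
                pd.DataFrame(
                    {"distance_m": d, "regime": regimes, "sex": s, "locality": locs}
                )
            )
    else:
        raise ValueError("kind must be 'dispersal' or 'displacement'")
    return pd.concat(rows, ignore_index=True)


def write_simulation(
    ds: Dataset, truth: SimTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write records.csv, patches.geojson and truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "patches": out / "patches.geojson",
        "truth": out / "truth.json",
    }
    write_dataset(ds, paths["records"], paths["patches"])
    truth.to_json(paths["truth"])
    return paths
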