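"""End-to-end orchestration: data (read or simulate) -> movements ->
connectivity -> CJS -> abundance -> mixed models, with all tables written
as CSV plus a short Markdown summary.

The run configuration is a plain dict (typically loaded from YAML):

    simulate: {seed: 1, n_patches: 46, ...}      # or
    input: {records: records.csv, patches: patches.geojson}
    connectivity: {xi: 0.5, buffer_km: 3.0, distance_mode: centroid, alpha: null}
    cjs: {min_individuals: 20, min_transitions: 5}
    glmm: {random: locality}                     # null -> plain GLMs
    out: runs/demo

With ``alpha: null`` the connectivity decay is 1 / the mean observed
dispersal distance (km) of the dataset itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import cjs as cjs_mod
from .connectivity import (
    ConnectivityParams,
    alpha_from_dispersal,
    connectivity,
    connectivity_frame,
    pairwise_patch_distance_km,
)
from .core import Dataset, read_dataset, validate_dataset
from .glmm import EstimationError, ModelSpec, fit_glm, fit_glmm
from .movement import classify_movements, emigration_table, movements_frame, regime_emigration
from .simulate import SimConfig, simulate_mrr, write_simulation

log = logging.getLogger("meadowmrr")


@dataclass
class RunReport:
    """All output tables of one analysis run plus reproducibility metadata."""

    dataset_hash: str
    seed: int | None
    movements: pd.DataFrame
    emigration: pd.DataFrame
    emigration_by_regime: pd.DataFrame
    connectivity: pd.DataFrame
    cjs_table: pd.DataFrame
    abundance_table: pd.DataFrame
    model_tables: dict[str, pd.DataFrame]
    selected_models: dict[str, str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.movements.to_csv(out / "movements.csv", index=False, float_format="%.6f")
        self.emigration.to_csv(out / "emigration.csv", index=False, float_format="%.6f")
        self.emigration_by_regime.to_csv(
            out / "emigration_by_regime.csv", index=False, float_format="%.6f"
        )
        self.connectivity.to_csv(out / "connectivity.csv", index=False, float_format="%.6f")
        self.cjs_table.to_csv(out / "cjs_fits.csv", index=False, float_format="%.6f")
        self.abundance_table.to_csv(out / "abundance.csv", index=False, float_format="%.6f")
        for name, table in self.model_tables.items():
            table.to_csv(out / f"model_{name}.csv", index=False, float_format="%.6f")
        lines = [
            "# Run summary",
            "",
            f"- dataset hash: `{self.dataset_hash}`",
            f"- seed: {self.seed}",
            f"- movements: {len(self.movements)} "
            f"({(self.movements['kind'] == 'dispersal').sum()} dispersal)",
            f"- patches with CJS fit: {self.cjs_table['patch_id'].nunique()}",
            "",
            "## Selected models",
        ]
        lines += [f"- {k}: {v}" for k, v in self.selected_models.items()]
        (out / "summary.md").write_text("\n".join(lines) + "\n")


def _hash_dataset(ds: Dataset) -> str:
    frame = ds.records_frame().sort_values(["individual_id", "occasion"])
    payload = frame.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _obtain_dataset(config: dict):
    if "input" in config and config["input"]:
        inp = config["input"]
        log.info("reading dataset from %s / %s", inp["records"], inp["patches"])
        return read_dataset(inp["records"], inp["patches"]), None, None
    sim_over = dict(config.get("simulate") or {})
    sim = SimConfig(**sim_over)
    log.info("simulating dataset (seed=%d)", sim.seed)
    ds, truth = simulate_mrr(sim)
    return ds, truth, sim


def _patch_covariates(ds, conn_frame, n_totals: dict[str, float]) -> pd.DataFrame:
    rows = []
    for p in ds.patches:
        rows.append(
            {
                "patch_id": p.patch_id,
                "locality": p.locality,
                "regime": p.regime,
                "area": p.area_m2,
                "connectivity": float(
                    conn_frame.set_index("patch_id").loc[p.patch_id, "S_j"]
                ),
                "pop_size": n_totals.get(p.patch_id, np.nan),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: dict) -> RunReport:
    """Execute the full analysis chain; see the module docstring for the
    configuration schema."""
    ds, truth, sim = _obtain_dataset(config)
    seed = sim.seed if sim is not None else config.get("seed")
    report_issues = validate_dataset(ds)
    if not report_issues.ok:
        log.info(
            "validation: %d points off-patch, %d long gaps, %d sex conflicts",
            len(report_issues.out_of_patch),
            len(report_issues.calendar_gaps),
            len(report_issues.sex_inconsistencies),
        )

    # --- movements ---------------------------------------------------------
    events = classify_movements(ds)
    mv = movements_frame(events)
    emi = emigration_table(ds)
    emi_regime = regime_emigration(emi)
    log.info("movements: %d events (%d dispersal)", len(mv), (mv["kind"] == "dispersal").sum())

    # --- connectivity ------------------------------------------------------
    conn_cfg = dict(config.get("connectivity") or {})
    disp = mv.loc[mv["kind"] == "dispersal", "distance_m"]
    alpha = conn_cfg.get("alpha") or (
        alpha_from_dispersal(float(disp.mean())) if len(disp) else 5.0
    )
    params = ConnectivityParams(
        alpha=alpha,
        xi=conn_cfg.get("xi", 0.5),
        buffer_km=conn_cfg.get("buffer_km", 3.0),
        distance_mode=conn_cfg.get("distance_mode", "centroid"),
    )
    D = pairwise_patch_distance_km(ds.patches, params.distance_mode)
    conn = connectivity_frame(connectivity(ds.patches, params, D))

    # --- CJS + abundance per eligible patch --------------------------------
    cjs_cfg = dict(config.get("cjs") or {})
    min_ind = cjs_cfg.get("min_individuals", cjs_mod.MIN_INDIVIDUALS)
    min_tr = cjs_cfg.get("min_transitions", cjs_mod.MIN_TRANSITIONS)
    cjs_rows, abu_rows = [], []
    n_totals: dict[str, float] = {}
    for p in ds.patches:
        chm = cjs_mod.build_capture_histories(ds, p.patch_id)
        if not cjs_mod.eligible_for_cjs(chm, min_ind, min_tr):
            continue
        try:
            fits, selected = cjs_mod.fit_cjs(chm, seed=0)
        except (ValueError, RuntimeError) as exc:
            log.warning("CJS failed for patch %s: %s", p.patch_id, exc)
            continue
        cjs_rows.append(cjs_mod.fits_frame(fits, selected))
        try:
            est = abundance_mod.estimate_abundance(chm, selected)
        except ValueError as exc:
            log.warning("abundance failed for patch %s: %s", p.patch_id, exc)
            continue
        abu = est.frame()
        abu_rows.append(abu)
        n_totals[p.patch_id] = est.N_total
    cjs_table = (
        pd.concat(cjs_rows, ignore_index=True) if cjs_rows else pd.DataFrame()
    )
    abundance_table = (
        pd.concat(abu_rows, ignore_index=True) if abu_rows else pd.DataFrame()
    )
    log.info("CJS fitted for %d patches", len(n_totals))

    # --- mixed models ------------------------------------------------------
    glmm_cfg = dict(config.get("glmm") or {"random": "locality"})
    group = glmm_cfg.get("random", "locality")
    if group is None:
        warnings.warn(
            "no random term configured; fitting plain GLMs", stacklevel=2
        )
    covars = _patch_covariates(ds, conn, n_totals)
    model_tables: dict[str, pd.DataFrame] = {}
    selected_models: dict[str, str] = {}

    def _fit(name: str, spec: ModelSpec, data: pd.DataFrame):
        if len(data) == 0:
            log.warning("%s: no data, skipped", name)
            return
        try:
            if spec.group is not None and data[spec.group].nunique() < 2:
                raise EstimationError("grouping factor has < 2 levels")
            fit = fit_glmm(spec, data) if spec.group else fit_glm(spec, data)
        except EstimationError as exc:
            if spec.group is not None:
                warnings.warn(
                    f"{name}: mixed model failed ({exc}); falling back to GLM",
                    stacklevel=2,
                )
                try:
                    fit = fit_glm(dataclasses.replace(spec, group=None), data)
                except EstimationError as exc2:
                    log.warning("%s failed: %s", name, exc2)
                    return
            else:
                log.warning("%s failed: %s", name, exc)
                return
        model_tables[name] = fit.coef_frame()
        selected_models[name] = fit.spec.label

    # emigration probability: per-individual Bernoulli with origin-patch covariates
    emig_data = (
        _emigration_rows(ds).merge(covars, on="patch_id", how="left").dropna(
            subset=["pop_size", "connectivity", "area"]
        )
    )
    _fit(
        "emigration_probability",
        ModelSpec(
            family="binomial",
            response="emigrated",
            terms=(
                "regime",
                "sex",
                "pop_size",
                "connectivity",
                "pop_size:connectivity",
                "pop_size:connectivity:area",
            ),
            group=group,
            scale=("pop_size", "connectivity", "area"),
        ),
        emig_data,
    )

    mv_cov = mv.merge(
        covars.rename(columns={"patch_id": "origin_patch"}),
        on="origin_patch",
        how="left",
        suffixes=("", "_patch"),
    )
    n_zero = int((mv_cov["distance_m"] <= 0).sum())
    if n_zero:
        log.info("%d zero-distance movement(s) excluded from gamma fits", n_zero)
    mv_cov = mv_cov[mv_cov["distance_m"] > 0]
    disp_data = mv_cov[mv_cov["kind"] == "dispersal"].dropna(subset=["area"])
    _fit(
        "dispersal_distance",
        ModelSpec(
            family="gamma",
            response="distance_m",
            terms=("origin_regime", "sex", "area"),
            group=group,
            scale=("area",),
        ),
        disp_data,
    )
    displ_data = mv_cov[mv_cov["kind"] == "displacement"].dropna(
        subset=["pop_size", "area"]
    )
    _fit(
        "displacement_distance",
        ModelSpec(
            family="gamma",
            response="distance_m",
            terms=("sex", "pop_size", "pop_size:area"),
            group=group,
            scale=("pop_size", "area"),
        ),
        displ_data,
    )
    pop_data = covars.dropna(subset=["pop_size"]).copy()
    pop_data["pop_size_int"] = pop_data["pop_size"].round().astype(int)
    _fit(
        "population_size",
        ModelSpec(
            family="poisson",
            response="pop_size_int",
            terms=("regime", "connectivity", "area", "connectivity:area"),
            group=group,
            scale=("connectivity", "area"),
        ),
        pop_data,
    )

    report = RunReport(
        dataset_hash=_hash_dataset(ds),
        seed=seed,
        movements=mv,
        emigration=emi,
        emigration_by_regime=emi_regime,
        connectivity=conn,
        cjs_table=cjs_table,
        abundance_table=abundance_table,
        model_tables=model_tables,
        selected_models=selected_models,
    )
    out = config.get("out")
    if out:
        report.write(out)
        if truth is not None and config.get("write_simulation", False):
            write_simulation(ds, truth, Path(out) / "simulated_input")
    return report


def _emigration_rows(ds: Dataset) -> pd.DataFrame:
    """Per recaptured individual: origin patch, sex and emigrated yes/no."""
    per_ind: dict[str, list] = {}
    for r in ds.records:
        per_ind.setdefault(r.individual_id, []).append(r)
    rows = []
    for ind, recs in per_ind.items():
        recs = sorted(recs, key=lambda r: r.occasion)
        if len(recs) < 2:
            continue
        origin = recs[0].patch_id
        rows.append(
            {
                "individual_id": ind,
                "patch_id": origin,
                "sex": recs[0].sex,
                "emigrated": int(any(r.patch_id != origin for r in recs[1:])),
            }
        )
    return pd.DataFrame(rows)
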