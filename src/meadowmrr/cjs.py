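"""Cormack-Jolly-Seber (CJS) estimation of apparent survival and capture
probability by maximum likelihood.

The model conditions on each individual's first capture and estimates a
*daily* apparent survival probability phi and a per-occasion capture
probability p. Occasions may be unequally spaced; survival over an interval
of l days is phi**l. Both parameters may differ between the sexes but are
constant over time; the four resulting models are compared by AIC.

Two likelihood routes are implemented: the multinomial m-array form used
for fitting, and an explicit per-capture-history form (with the chi
"never seen again" recursion) retained as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._numeric import invlogit, logit, numeric_hessian
from .core import Dataset, OccasionCalendar

MODEL_SET = ("phi(.)p(.)", "phi(sex)p(.)", "phi(.)p(sex)", "phi(sex)p(sex)")

#: Default eligibility for fitting a patch-level CJS model: the study fits
#: one model per patch "with a large enough sample" of (re)captures.
MIN_INDIVIDUALS = 20
MIN_TRANSITIONS = 5


@dataclass
class CaptureHistoryMatrix:
    """Binary individuals x occasions matrix plus sex vector and calendar."""

    matrix: np.ndarray
    sex: np.ndarray
    calendar: OccasionCalendar
    patch_id: str | None = None
    individual_ids: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.sex = np.asarray(self.sex, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("capture history matrix must be 2-D")
        if self.matrix.shape[1] != self.calendar.n_occasions:
            raise ValueError("matrix columns must match calendar occasions")
        if self.matrix.shape[0] != self.sex.size:
            raise ValueError("sex vector length must match number of individuals")
        if self.matrix.size and not (self.matrix.sum(axis=1) >= 1).all():
            raise ValueError("every capture history needs at least one capture")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def captures_per_occasion(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def n_recapture_transitions(self) -> int:
        counts = self.matrix.sum(axis=1)
        return int((counts[counts >= 2] - 1).sum())

    def subset(self, mask: np.ndarray) -> "CaptureHistoryMatrix":
        ids = None
        if self.individual_ids is not None:
            ids = [i for i, m in zip(self.individual_ids, mask) if m]
        return CaptureHistoryMatrix(
            self.matrix[mask], self.sex[mask], self.calendar, self.patch_id, ids
        )


def build_capture_histories(
    ds: Dataset, patch_id: str | None = None
) -> CaptureHistoryMatrix:
    """Capture-history matrix from a Dataset.

    With ``patch_id`` given, individuals are assigned to the patch of their
    first capture and all their captures (anywhere) are retained, so
    emigrants are still followed.
    """
    per_ind: dict[str, list] = {}
    for r in ds.records:
        per_ind.setdefault(r.individual_id, []).append(r)
    ids, rows, sexes = [], [], []
    for ind in sorted(per_ind):
        recs = sorted(per_ind[ind], key=lambda r: r.occasion)
        if patch_id is not None and recs[0].patch_id != patch_id:
            continue
        row = np.zeros(ds.calendar.n_occasions, dtype=int)
        for r in recs:
            row[r.occasion] = 1
        ids.append(ind)
        rows.append(row)
        sexes.append(recs[0].sex)
    matrix = np.array(rows, dtype=int) if rows else np.zeros((0, ds.calendar.n_occasions), int)
    return CaptureHistoryMatrix(matrix, np.array(sexes, dtype=object), ds.calendar, patch_id, ids)


@dataclass
class MArray:
    """Sufficient statistic for the CJS likelihood.

    ``released[i]`` animals released at occasion i; ``m[i, j]`` of them
    first recaptured at occasion j > i; the remainder never seen again.
    """

    released: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.released = np.asarray(self.released, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        K = self.released.size
        if self.m.shape != (K, K):
            raise ValueError("m must be K x K")
        if np.any(self.m.sum(axis=1) > self.released + 1e-9):
            raise ValueError("sum_j m_ij must not exceed releases R_i")

    @property
    def n_occasions(self) -> int:
        return self.released.size


def build_m_array(chm: CaptureHistoryMatrix, mask: np.ndarray | None = None) -> MArray:
    """Tabulate releases and first recaptures from capture histories."""
    X = chm.matrix if mask is None else chm.matrix[mask]
    if X.shape[0] == 0:
        raise ValueError("empty capture history matrix")
    K = X.shape[1]
    released = np.zeros(K)
    m = np.zeros((K, K))
    for row in X:
        occ = np.flatnonzero(row)
        for a, b in zip(occ, occ[1:]):
            m[a, b] += 1
        # every capture except at the final occasion is a release
        for a in occ:
            if a < K - 1:
                released[a] += 1
    return MArray(released, m)


def _cell_log_probs(phi: float, p: float, intervals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log P_ij (first recapture at j after release at i) and log chi_i."""
    K = intervals.size + 1
    with np.errstate(divide="ignore"):
        log_phi_int = intervals * np.log(phi)  # survival log-prob per interval
        log_p = np.log(p)
        log_q = np.log1p(-p)
    logP = np.full((K, K), -np.inf)
    for i in range(K - 1):
        acc = 0.0
        for j in range(i + 1, K):
            acc += log_phi_int[j - 1]
            logP[i, j] = acc + (j - i - 1) * log_q + log_p
    with np.errstate(over="ignore"):
        chi_row = 1.0 - np.exp(logP[: K - 1]).sum(axis=1)
    chi_row = np.clip(chi_row, 1e-300, 1.0)
    return logP, np.log(chi_row)


def _sex_params(params: np.ndarray, model: str) -> dict[str, tuple[float, float]]:
    """Map the unconstrained parameter vector to (phi, p) per sex."""
    phi_sex = "phi(sex)" in model
    p_sex = "p(sex)" in model
    k = 0
    phi_f = params[k]
    k += 1
    phi_m = phi_f + (params[k] if phi_sex else 0.0)
    if phi_sex:
        k += 1
    p_f = params[k]
    k += 1
    p_m = p_f + (params[k] if p_sex else 0.0)
    return {
        "F": (float(invlogit(phi_f)), float(invlogit(p_f))),
        "M": (float(invlogit(phi_m)), float(invlogit(p_m))),
    }


def n_params(model: str) -> int:
    return 2 + ("phi(sex)" in model) + ("p(sex)" in model)


def cjs_loglik(
    params: np.ndarray,
    marrays: dict[str, MArray],
    calendar: OccasionCalendar,
    model: str = "phi(.)p(.)",
) -> float:
    """Multinomial m-array CJS log-likelihood on the logit scale.

    ``marrays`` maps sex ("F"/"M") to its m-array; for sex-free data pass a
    single entry (the sex offsets are simply unused).
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    intervals = calendar.intervals
    by_sex = _sex_params(params, model)
    total = 0.0
    for sex, ma in marrays.items():
        phi, p = by_sex[sex]
        if not (0.0 < phi < 1.0 and 0.0 < p < 1.0):
            return -np.inf
        logP, log_chi = _cell_log_probs(phi, p, intervals)
        K = ma.n_occasions
        for i in range(K - 1):
            if ma.released[i] == 0:
                continue
            recaptured = ma.m[i].sum()
            total += float((ma.m[i] * np.where(np.isfinite(logP[i]), logP[i], 0.0)).sum())
            total += float((ma.released[i] - recaptured) * log_chi[i])
    return total


def cjs_loglik_individual(
    params: np.ndarray,
    chm: CaptureHistoryMatrix,
    model: str = "phi(.)p(.)",
) -> float:
    """Per-history CJS log-likelihood (chi recursion); testing oracle.

    Computes, for each individual, the probability of its capture history
    between first and last capture times the probability of never being
    seen after the last capture.
    """
    params = np.asarray(params, dtype=float)
    intervals = chm.calendar.intervals
    by_sex = _sex_params(params, model)
    K = chm.n_occasions
    total = 0.0
    for row, sex in zip(chm.matrix, chm.sex):
        phi, p = by_sex[str(sex)]
        if not (0.0 < phi < 1.0 and 0.0 < p < 1.0):
            return -np.inf
        occ = np.flatnonzero(row)
        first, last = occ[0], occ[-1]
        # chi_t: P(never seen after t | alive at t)
        chi = np.ones(K)
        for t in range(K - 2, -1, -1):
            s = phi ** intervals[t]
            chi[t] = (1.0 - s) + s * (1.0 - p) * chi[t + 1]
        ll = 0.0
        for t in range(first, last):
            s = phi ** intervals[t]
            ll += np.log(s)
            ll += np.log(p) if row[t + 1] else np.log1p(-p)
        ll += np.log(chi[last])
        total += ll
    return total


@dataclass
class CJSFit:
    """A fitted CJS model: daily survival and capture probability per sex."""

    model: str
    phi: dict[str, float]
    p: dict[str, float]
    phi_se: dict[str, float]
    p_se: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    params: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    patch_id: str | None = None

    @property
    def k(self) -> int:
        return n_params(self.model)


def _delta_se(cov: np.ndarray, grad_eta: np.ndarray, prob: float) -> float:
    var_eta = float(grad_eta @ cov @ grad_eta)
    return float(np.sqrt(max(var_eta, 0.0)) * prob * (1.0 - prob))


def fit_cjs(
    chm: CaptureHistoryMatrix,
    models: tuple[str, ...] = MODEL_SET,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[list[CJSFit], CJSFit]:
    """Fit the candidate CJS models and select by AIC.

    Each model is optimised on the logit scale (quasi-Newton, several
    random restarts); standard errors come from the inverse observed
    information via the delta method. Selection follows the lowest-AIC rule
    with the "simpler model within 2 AIC units" relaxation.
    """
    if chm.n_recapture_transitions() < 1:
        raise ValueError("need at least one recapture transition to fit CJS")
    rng = np.random.default_rng(seed)
    sexes = [s for s in ("F", "M") if (chm.sex == s).any()]
    marrays = {s: build_m_array(chm, chm.sex == s) for s in sexes}
    fits: list[CJSFit] = []
    for model in models:
        k = n_params(model)
        nll = lambda x: -cjs_loglik(x, marrays, chm.calendar, model)
        best = None
        starts = [np.zeros(k)] + [rng.normal(0.0, 1.0, size=k) for _ in range(n_starts - 1)]
        for x0 in starts:
            res = minimize(nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        H = numeric_hessian(nll, best.x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        by_sex = _sex_params(best.x, model)
        phi_sex = "phi(sex)" in model
        p_sex = "p(sex)" in model
        idx_phi0 = 0
        idx_p0 = 1 + phi_sex
        grads = {}
        for sex in ("F", "M"):
            g_phi = np.zeros(k)
            g_phi[idx_phi0] = 1.0
            if phi_sex and sex == "M":
                g_phi[1] = 1.0
            g_p = np.zeros(k)
            g_p[idx_p0] = 1.0
            if p_sex and sex == "M":
                g_p[idx_p0 + 1] = 1.0
            grads[sex] = (g_phi, g_p)
        phi = {s: by_sex[s][0] for s in ("F", "M")}
        p = {s: by_sex[s][1] for s in ("F", "M")}
        phi_se = {
            s: _delta_se(cov, grads[s][0], phi[s]) if np.all(np.isfinite(cov)) else np.nan
            for s in ("F", "M")
        }
        p_se = {
            s: _delta_se(cov, grads[s][1], p[s]) if np.all(np.isfinite(cov)) else np.nan
            for s in ("F", "M")
        }
        loglik = -best.fun
        # relative gradient test: BFGS can report precision loss at large n
        # even though the optimum is located to far better than 1 SE
        jac = np.asarray(getattr(best, "jac", np.zeros(k)))
        converged = bool(
            best.success or np.max(np.abs(jac)) < 1e-4 * (1.0 + abs(best.fun))
        )
        fits.append(
            CJSFit(
                model=model,
                phi=phi,
                p=p,
                phi_se=phi_se,
                p_se=p_se,
                loglik=loglik,
                aic=2.0 * k - 2.0 * loglik,
                converged=converged,
                params=best.x,
                cov=cov,
                patch_id=chm.patch_id,
            )
        )
    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no CJS model converged")
    selected = select_by_aic(usable)
    return fits, selected


def select_by_aic(fits: list[CJSFit]) -> CJSFit:
    """Lowest AIC, unless a simpler model lies within 2 AIC units."""
    best = min(fits, key=lambda f: (f.aic, f.k, f.model))
    candidates = [f for f in fits if f.aic - best.aic < 2.0 and f.k < best.k]
    if candidates:
        return min(candidates, key=lambda f: (f.k, f.aic, f.model))
    return best


def eligible_for_cjs(
    chm: CaptureHistoryMatrix,
    min_individuals: int = MIN_INDIVIDUALS,
    min_transitions: int = MIN_TRANSITIONS,
) -> bool:
    """Sample-size rule for fitting a patch-level model."""
    return (
        chm.n_individuals >= min_individuals
        and chm.n_recapture_transitions() >= min_transitions
    )


def fits_frame(fits: list[CJSFit], selected: CJSFit) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "patch_id": f.patch_id or "all",
                "model": f.model,
                "phi_F": f.phi["F"],
                "phi_M": f.phi["M"],
                "phi_se_F": f.phi_se["F"],
                "phi_se_M": f.phi_se["M"],
                "p_F": f.p["F"],
                "p_M": f.p["M"],
                "p_se_F": f.p_se["F"],
                "p_se_M": f.p_se["M"],
                "loglik": f.loglik,
                "AIC": f.aic,
                "selected": f.model == selected.model,
            }
        )
    return pd.DataFrame(rows)
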