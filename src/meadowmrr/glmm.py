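"""Generalised linear (mixed) models for the movement and abundance analyses.

Families: binomial (logit), Poisson (log), gamma (log) and Gaussian
(identity). Fixed-effect terms are given as column names, with ``a:b:c``
denoting an interaction (non-hierarchical term lists are allowed). A single
scalar random intercept per group (the sampling locality) is integrated out
by a Laplace approximation; an adaptive Gauss-Hermite route is provided for
validating the Laplace log-likelihood.

GLMs are fitted by iteratively reweighted least squares (IRLS); the gamma
shape is profiled by maximum likelihood. Continuous covariates are z-scaled
(mean/SD) before fitting, and the scaling record is kept so predictions can
be made on the original scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

from ._numeric import numeric_hessian

MAX_IRLS_ITER = 200
LOGLIK_RTOL = 1e-9


class EstimationError(RuntimeError):
    """Model could not be estimated (rank deficiency, separation, ...)."""


# ---------------------------------------------------------------------------
# Families


class Family:
    """GLM family with its canonical-by-default link."""

    name: str
    has_dispersion = False
    wald_stat = "z"

    def linkinv(self, eta):
        raise NotImplementedError

    def dlinkinv(self, eta):
        """d mu / d eta, for delta-method prediction SEs."""
        raise NotImplementedError

    def irls_weights(self, mu):
        raise NotImplementedError

    def irls_z(self, eta, mu, y):
        raise NotImplementedError

    def loglik(self, y, mu, dispersion=None):
        raise NotImplementedError

    def score_eta(self, y, mu, dispersion=None):
        """d loglik / d eta, elementwise."""
        raise NotImplementedError

    def hess_eta(self, y, mu, dispersion=None):
        """d2 loglik / d eta2, elementwise."""
        raise NotImplementedError

    def validate_response(self, y):
        pass


class Binomial(Family):
    name = "binomial"

    def validate_response(self, y):
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binomial response must be coded 0/1")

    def linkinv(self, eta):
        out = np.empty_like(eta)
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        ex = np.exp(eta[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def dlinkinv(self, eta):
        mu = self.linkinv(eta)
        return mu * (1.0 - mu)

    def irls_weights(self, mu):
        return mu * (1.0 - mu)

    def irls_z(self, eta, mu, y):
        return eta + (y - mu) / (mu * (1.0 - mu))

    def loglik(self, y, mu, dispersion=None):
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))

    def score_eta(self, y, mu, dispersion=None):
        return y - mu

    def hess_eta(self, y, mu, dispersion=None):
        return -mu * (1.0 - mu)


class Poisson(Family):
    name = "poisson"

    def validate_response(self, y):
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("poisson response must be non-negative integers")

    def linkinv(self, eta):
        return np.exp(eta)

    def dlinkinv(self, eta):
        return np.exp(eta)

    def irls_weights(self, mu):
        return mu

    def irls_z(self, eta, mu, y):
        return eta + (y - mu) / mu

    def loglik(self, y, mu, dispersion=None):
        mu = np.clip(mu, 1e-300, None)
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))

    def score_eta(self, y, mu, dispersion=None):
        return y - mu

    def hess_eta(self, y, mu, dispersion=None):
        return -mu


class Gamma(Family):
    """Gamma with log link, parameterised by mean mu and shape nu."""

    name = "gamma"
    has_dispersion = True
    wald_stat = "t"

    def validate_response(self, y):
        if (y <= 0).any():
            raise ValueError("gamma response must be strictly positive")

    def linkinv(self, eta):
        return np.exp(eta)

    def dlinkinv(self, eta):
        return np.exp(eta)

    def irls_weights(self, mu):
        return np.ones_like(mu)

    def irls_z(self, eta, mu, y):
        return eta + (y - mu) / mu

    def loglik(self, y, mu, dispersion=1.0):
        nu = dispersion
        return float(
            np.sum(
                nu * (np.log(nu) - np.log(mu))
                + (nu - 1.0) * np.log(y)
                - nu * y / mu
                - special.gammaln(nu)
            )
        )

    def score_eta(self, y, mu, dispersion=1.0):
        return dispersion * (y / mu - 1.0)

    def hess_eta(self, y, mu, dispersion=1.0):
        return -dispersion * y / mu

    @staticmethod
    def shape_mle(y, mu) -> float:
        """Maximum-likelihood gamma shape given fitted means."""
        c = float(np.mean(np.log(y) - np.log(mu) - y / mu + 1.0))

        def grad(log_nu):
            nu = math.exp(log_nu)
            return math.log(nu) - special.digamma(nu) + c

        lo, hi = -10.0, 15.0
        if grad(lo) < 0:
            return math.exp(lo)
        if grad(hi) > 0:
            return math.exp(hi)
        return math.exp(brentq(grad, lo, hi, xtol=1e-10))


class Gaussian(Family):
    name = "gaussian"
    has_dispersion = True
    wald_stat = "t"

    def linkinv(self, eta):
        return eta.copy()

    def dlinkinv(self, eta):
        return np.ones_like(eta)

    def irls_weights(self, mu):
        return np.ones_like(mu)

    def irls_z(self, eta, mu, y):
        return y.astype(float)

    def loglik(self, y, mu, dispersion=1.0):
        s2 = dispersion
        n = y.size
        return float(-0.5 * n * np.log(2.0 * np.pi * s2) - np.sum((y - mu) ** 2) / (2.0 * s2))

    def score_eta(self, y, mu, dispersion=1.0):
        return (y - mu) / dispersion

    def hess_eta(self, y, mu, dispersion=1.0):
        return np.full_like(mu, -1.0 / dispersion)


FAMILIES = {
    "binomial": Binomial(),
    "poisson": Poisson(),
    "gamma": Gamma(),
    "gaussian": Gaussian(),
}


# ---------------------------------------------------------------------------
# Covariate scaling


def scale_covariates(
    data: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """z-scale the named numeric columns; returns the scaled frame and the
    (mean, sd) record needed to transform new data the same way."""
    out = data.copy()
    record: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = pd.to_numeric(out[col])
        sd = float(x.std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero or undefined SD")
        mean = float(x.mean())
        out[col] = (x - mean) / sd
        record[col] = (mean, sd)
    return out, record


def apply_scaling(data: pd.DataFrame, record: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = data.copy()
    for col, (mean, sd) in record.items():
        if col in out.columns:
            out[col] = (pd.to_numeric(out[col]) - mean) / sd
    return out


def unscale(values, col: str, record: dict[str, tuple[float, float]]):
    mean, sd = record[col]
    return np.asarray(values) * sd + mean


# ---------------------------------------------------------------------------
# Model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Family, response column, fixed terms and optional random intercept.

    Terms are column names; ``a:b`` is an interaction product. The term
    list is taken verbatim, so models without all lower-order margins are
    representable.
    """

    family: str
    response: str
    terms: tuple[str, ...] = ()
    group: str | None = None
    scale: tuple[str, ...] = ()
    name: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        rhs = " + ".join(self.terms) if self.terms else "1"
        grp = f" + (1|{self.group})" if self.group else ""
        return f"{self.response} ~ {rhs}{grp} [{self.family}]"


@dataclass
class DesignInfo:
    """Encoder from a data frame to a fixed-effects design matrix."""

    terms: tuple[str, ...]
    var_kinds: dict[str, tuple] = field(default_factory=dict)

    @classmethod
    def from_data(cls, terms: tuple[str, ...], data: pd.DataFrame) -> "DesignInfo":
        info = cls(terms=tuple(terms))
        for term in terms:
            for var in term.split(":"):
                if var in info.var_kinds:
                    continue
                if var not in data.columns:
                    raise EstimationError(f"term references unknown column {var!r}")
                col = data[var]
                if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                    levels = tuple(sorted(pd.unique(col.astype(str))))
                    info.var_kinds[var] = ("categorical", levels)
                else:
                    info.var_kinds[var] = ("numeric",)
        return info

    def _var_columns(self, var: str, data: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
        kind = self.var_kinds[var]
        if kind[0] == "numeric":
            return [(var, pd.to_numeric(data[var]).to_numpy(dtype=float))]
        levels = kind[1]
        values = data[var].astype(str).to_numpy()
        unseen = set(values) - set(levels)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} for factor {var!r}")
        return [
            (f"{var}[{lvl}]", (values == lvl).astype(float)) for lvl in levels[1:]
        ]

    def build(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(data)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["(Intercept)"]
        for term in self.terms:
            var_cols = [self._var_columns(v, data) for v in term.split(":")]
            for combo in itertools.product(*var_cols):
                name = ":".join(c[0] for c in combo)
                x = np.ones(n)
                for c in combo:
                    x = x * c[1]
                cols.append(x)
                names.append(name)
        X = np.column_stack(cols)
        return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise EstimationError(
            f"design matrix is rank deficient; offending column(s): {bad}"
        )


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class GLMMFit:
    """Estimated fixed effects, random-intercept variance and fit statistics."""

    spec: ModelSpec
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    dispersion: float | None = None  # gamma shape or gaussian error variance
    re_variance: float | None = None
    re_levels: tuple[str, ...] | None = None
    boundary: bool = False
    converged: bool = True
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    design: DesignInfo | None = None
    n_obs: int = 0
    stat_kind: str = "z"

    @property
    def k(self) -> int:
        """Parameter count entering the AIC."""
        k = len(self.coef)
        if FAMILIES[self.spec.family].has_dispersion:
            k += 1
        if self.spec.group is not None:
            k += 1
        return k

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "stat": self.stat,
                "p_value": self.pvalues,
            }
        )


def _wald_table(family: Family, coef, vcov, n, p):
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = coef / se
    if family.wald_stat == "t":
        df = max(n - p, 1)
        pvals = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(stat))
    return se, stat, pvals


# ---------------------------------------------------------------------------
# GLM via IRLS


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    family = FAMILIES[spec.family]
    scaled, record = scale_covariates(data, list(spec.scale)) if spec.scale else (data, {})
    y = pd.to_numeric(scaled[spec.response]).to_numpy(dtype=float)
    family.validate_response(y)
    design = DesignInfo.from_data(spec.terms, scaled)
    X, names = design.build(scaled)
    _check_rank(X, names)
    return family, scaled, record, y, design, X, names


def _mu_start(family: Family, y: np.ndarray) -> np.ndarray:
    if family.name == "binomial":
        return (y + 0.5) / 2.0
    if family.name in ("poisson", "gamma"):
        return np.clip(y, np.mean(y) * 1e-3 + 1e-9, None) * 0.5 + np.mean(y) * 0.5
    return np.full_like(y, np.mean(y))


def _irls(family: Family, X: np.ndarray, y: np.ndarray, trace: list | None = None):
    mu = _mu_start(family, y)
    if family.name == "gaussian":
        eta = mu.copy()
    else:
        eta = np.log(mu / (1.0 - mu)) if family.name == "binomial" else np.log(mu)
    beta = np.zeros(X.shape[1])
    last = -np.inf
    for it in range(MAX_IRLS_ITER):
        W = family.irls_weights(mu)
        z = family.irls_z(eta, mu, y)
        WX = X * W[:, None]
        beta_new, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
        eta = X @ beta_new
        if np.max(np.abs(eta)) > 40 and family.name == "binomial":
            raise EstimationError(
                "binomial IRLS diverged (perfect separation suspected)"
            )
        mu = family.linkinv(eta)
        ll = family.loglik(y, mu, 1.0 if family.has_dispersion else None)
        beta = beta_new
        if trace is not None:
            trace.append(ll)
        if it > 0 and abs(ll - last) <= LOGLIK_RTOL * (abs(last) + 1.0):
            break
        last = ll
    return beta, eta, mu


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> GLMMFit:
    """Fixed-effects-only GLM (IRLS); gamma shape by maximum likelihood."""
    family, scaled, record, y, design, X, names = _prepare(spec, data)
    n, p = X.shape
    beta, eta, mu = _irls(family, X, y)
    dispersion = None
    if family.name == "gamma":
        dispersion = Gamma.shape_mle(y, mu)
        vcov = np.linalg.inv(X.T @ X) / dispersion
    elif family.name == "gaussian":
        dispersion = float(np.sum((y - mu) ** 2) / n)
        vcov = np.linalg.inv(X.T @ X) * dispersion
    else:
        W = family.irls_weights(mu)
        vcov = np.linalg.inv((X * W[:, None]).T @ X)
    loglik = family.loglik(y, mu, dispersion)
    se, stat, pvals = _wald_table(family, beta, vcov, n, p)
    k = p + (1 if family.has_dispersion else 0)
    return GLMMFit(
        spec=spec,
        names=names,
        coef=beta,
        se=se,
        stat=stat,
        pvalues=pvals,
        vcov=vcov,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        dispersion=dispersion,
        scaling=record,
        design=design,
        n_obs=n,
        stat_kind=family.wald_stat,
    )


# ---------------------------------------------------------------------------
# GLMM: Laplace-approximate marginal likelihood over a scalar random intercept


def _inner_mode(family, Xb_eta, y, sigma2, dispersion, b0=0.0):
    """Newton maximisation of l_g(b) - b^2/(2 sigma^2); returns (b_hat, W)."""
    b = b0
    for _ in range(50):
        eta = Xb_eta + b
        mu = family.linkinv(eta)
        g = float(np.sum(family.score_eta(y, mu, dispersion))) - b / sigma2
        h = float(np.sum(family.hess_eta(y, mu, dispersion))) - 1.0 / sigma2
        step = -g / h
        # dampen large steps for stability
        if abs(step) > 5.0:
            step = math.copysign(5.0, step)
        b += step
        if abs(step) < 1e-10:
            break
    eta = Xb_eta + b
    mu = family.linkinv(eta)
    curv = -float(np.sum(family.hess_eta(y, mu, dispersion)))  # -l''(b)
    return b, curv


def glmm_marginal_loglik(
    family: Family,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma_b: float,
    dispersion: float | None,
    method: str = "laplace",
    agq_nodes: int = 25,
) -> float:
    """Marginal log-likelihood integrating the group intercepts out.

    ``method="laplace"`` (fitting route) or ``"agq"`` (adaptive
    Gauss-Hermite with ``agq_nodes`` nodes, validation route).
    """
    eta_fix = X @ beta
    total = 0.0
    sigma2 = sigma_b * sigma_b
    for gid in np.unique(groups):
        idx = groups == gid
        xb, yg = eta_fix[idx], y[idx]
        if sigma_b <= 0.0:
            mu = family.linkinv(xb)
            total += family.loglik(yg, mu, dispersion)
            continue
        b_hat, curv = _inner_mode(family, xb, yg, sigma2, dispersion)
        mu_hat = family.linkinv(xb + b_hat)
        ll_hat = family.loglik(yg, mu_hat, dispersion)
        if method == "laplace":
            total += ll_hat - b_hat**2 / (2.0 * sigma2) - 0.5 * math.log(
                sigma2 * curv + 1.0
            )
        elif method == "agq":
            tau = 1.0 / math.sqrt(curv + 1.0 / sigma2)
            nodes, weights = np.polynomial.hermite.hermgauss(agq_nodes)
            log_terms = np.empty(agq_nodes)
            for k, (xk, wk) in enumerate(zip(nodes, weights)):
                b = b_hat + math.sqrt(2.0) * tau * xk
                mu = family.linkinv(xb + b)
                h = (
                    family.loglik(yg, mu, dispersion)
                    - b * b / (2.0 * sigma2)
                    - 0.5 * math.log(2.0 * math.pi * sigma2)
                )
                log_terms[k] = math.log(wk) + xk * xk + h
            total += float(logsumexp(log_terms)) + 0.5 * math.log(2.0) + math.log(tau)
        else:
            raise ValueError(f"unknown method {method!r}")
    return total


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, agq_check: bool = False) -> GLMMFit:
    """Maximum likelihood GLMM with a single scalar random intercept.

    Falls back to the GLM when no grouping factor is given. A variance
    estimate pinned at zero is returned with ``boundary=True`` (the fixed
    effects then coincide with the GLM's).
    """
    if spec.group is None:
        return fit_glm(spec, data)
    family, scaled, record, y, design, X, names = _prepare(spec, data)
    groups = scaled[spec.group].astype(str).to_numpy()
    levels = tuple(sorted(np.unique(groups)))
    if len(levels) < 2:
        raise EstimationError("grouping factor needs at least 2 levels")
    n, p = X.shape

    glm = fit_glm(replace(spec, group=None), data)
    beta0 = glm.coef
    disp0 = glm.dispersion

    def unpack(theta):
        beta = theta[:p]
        sigma_b = theta[p]
        dispersion = math.exp(theta[p + 1]) if family.has_dispersion else None
        return beta, sigma_b, dispersion

    def nll(theta):
        beta, sigma_b, dispersion = unpack(theta)
        if sigma_b < 0:
            return np.inf
        ll = glmm_marginal_loglik(family, X, y, groups, beta, sigma_b, dispersion)
        return -ll if np.isfinite(ll) else np.inf

    theta0 = np.concatenate(
        [beta0, [0.3], [math.log(disp0)] if family.has_dispersion else []]
    )
    bounds = [(None, None)] * p + [(0.0, None)] + (
        [(None, None)] if family.has_dispersion else []
    )
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    beta, sigma_b, dispersion = unpack(res.x)
    boundary = sigma_b < 1e-4
    if boundary:
        sigma_b = 0.0
        beta = res.x.copy()
        # re-optimise fixed effects exactly at the boundary
        res2 = minimize(
            lambda th: nll(np.concatenate([th[:p], [0.0], th[p:]])),
            np.concatenate([res.x[:p], res.x[p + 1 :]]),
            method="BFGS",
        )
        beta = res2.x[:p]
        dispersion = math.exp(res2.x[p]) if family.has_dispersion else None
        loglik = -res2.fun
        H = numeric_hessian(
            lambda th: nll(np.concatenate([th, [0.0], res2.x[p:]])), beta
        )
    else:
        loglik = -res.fun
        H_full = numeric_hessian(nll, res.x)
        try:
            H = np.linalg.inv(np.linalg.inv(H_full)[:p, :p])
        except np.linalg.LinAlgError:
            H = H_full[:p, :p]
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((p, p), np.nan)
    se, stat, pvals = _wald_table(family, beta, vcov, n, p)
    k = p + 1 + (1 if family.has_dispersion else 0)
    fit = GLMMFit(
        spec=spec,
        names=names,
        coef=beta,
        se=se,
        stat=stat,
        pvalues=pvals,
        vcov=vcov,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        dispersion=dispersion,
        re_variance=sigma_b**2,
        re_levels=levels,
        boundary=boundary,
        converged=bool(res.success),
        scaling=record,
        design=design,
        n_obs=n,
        stat_kind=family.wald_stat,
    )
    if agq_check and sigma_b > 0:
        fit.loglik_agq = glmm_marginal_loglik(
            family, X, y, groups, beta, sigma_b, dispersion, method="agq"
        )
    return fit


# ---------------------------------------------------------------------------
# Prediction and model selection


def predict_response(
    fit: GLMMFit, newdata: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted mean and delta-method SE on the response scale.

    Predictions are at random effect 0 (a typical locality); covariates in
    ``newdata`` are given on the original scale and re-scaled with the
    fit's scaling record.
    """
    family = FAMILIES[fit.spec.family]
    scaled = apply_scaling(newdata, fit.scaling)
    X, _ = fit.design.build(scaled)
    eta = X @ fit.coef
    var_eta = np.einsum("ij,jk,ik->i", X, fit.vcov, X)
    mu = family.linkinv(eta)
    se = np.abs(family.dlinkinv(eta)) * np.sqrt(np.clip(var_eta, 0.0, None))
    return mu, se


def aic_select(fits: list[GLMMFit]) -> GLMMFit:
    """Lowest AIC wins unless a simpler model lies within 2 AIC units, in
    which case the simplest such model is chosen (ties: fewer parameters,
    then label order)."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    best = min(usable, key=lambda f: (f.aic, f.k, f.spec.label))
    simpler = [f for f in usable if f.aic - best.aic < 2.0 and f.k < best.k]
    if simpler:
        return min(simpler, key=lambda f: (f.k, f.aic, f.spec.label))
    return best
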