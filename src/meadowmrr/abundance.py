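"""Occasion abundances, recruitment and seasonal total population size.

Abundance at occasion i is estimated as N_i = n_i / p-hat (captures scaled
by the CJS capture probability). Raw recruitment between occasions is
B_i = N_{i+1} - phi**l_i * N_i. Because individuals can emerge and die
within a multi-day gap without ever being available for capture, raw
recruitment undercounts; under uniform daily emergence within the interval
and daily survival phi, the expected fraction of an interval's recruits
still alive at its end is (1 - phi**l) / (l * (1 - phi)), so the corrected
recruitment is B*_i = B_i * l_i * (1 - phi) / (1 - phi**l_i). The seasonal
total is N_total = N_1 + sum_i B*_i (everything alive at the first occasion
plus everything recruited after it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cjs import CaptureHistoryMatrix, CJSFit
from .core import OccasionCalendar

log = logging.getLogger("meadowmrr")


@dataclass
class AbundanceEstimate:
    """Per-occasion abundances and recruitment plus the seasonal total."""

    n_i: np.ndarray  # captures per occasion
    N_i: np.ndarray  # estimated alive per occasion
    N_i_se: np.ndarray
    B_i: np.ndarray  # raw recruitment per interval (length K-1)
    B_star_i: np.ndarray  # corrected recruitment
    N_total: float
    N_total_se: float
    patch_id: str | None = None

    def frame(self) -> pd.DataFrame:
        K = self.n_i.size
        df = pd.DataFrame(
            {
                "patch_id": self.patch_id or "all",
                "occasion": np.arange(K),
                "n_i": self.n_i,
                "N_i": self.N_i,
                "B_i": np.append(self.B_i, np.nan),
                "B_star_i": np.append(self.B_star_i, np.nan),
            }
        )
        return df


def occasion_abundance(
    chm: CaptureHistoryMatrix, fit: CJSFit
) -> tuple[np.ndarray, np.ndarray]:
    """N_i = n_i / p-hat with a delta-method SE.

    If the selected model lets p differ between sexes, each sex's captures
    are scaled by its own p-hat and the two contributions are summed.
    """
    if not fit.converged:
        raise ValueError("CJS fit did not converge")
    K = chm.n_occasions
    N = np.zeros(K)
    var = np.zeros(K)
    for sex in ("F", "M"):
        mask = chm.sex == sex
        if not mask.any():
            continue
        p = fit.p[sex]
        if not 0.0 < p < 1.0:
            raise ValueError(f"capture probability at boundary (p={p}) for sex {sex}")
        n_sex = chm.matrix[mask].sum(axis=0).astype(float)
        N += n_sex / p
        # var(n/p) ~ (n/p^2)^2 var(p) with var(p) from the fit
        var += (n_sex / p**2) ** 2 * fit.p_se[sex] ** 2
    return N, np.sqrt(var)


def recruitment(
    N: np.ndarray, phi: float, calendar: OccasionCalendar
) -> np.ndarray:
    """Raw recruitment B_i = N_{i+1} - phi**l_i * N_i, truncated at 0."""
    N = np.asarray(N, dtype=float)
    intervals = calendar.intervals
    if N.size != intervals.size + 1:
        raise ValueError("N series length must match calendar occasions")
    B = N[1:] - phi ** intervals.astype(float) * N[:-1]
    if (B < -1e-9).any():
        log.info(
            "%d negative raw recruitment value(s) truncated to 0",
            int((B < -1e-9).sum()),
        )
    return np.clip(B, 0.0, None)


def correction_factor(phi: float, l: float) -> float:
    """Within-interval mortality correction l*(1-phi)/(1-phi**l).

    Equals 1 at l=1 and in the phi->1 limit; always >= 1; grows with the
    interval length and with daily mortality.
    """
    if l < 1:
        raise ValueError("interval length must be >= 1 day")
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must be in (0, 1]")
    if phi == 1.0:
        return 1.0
    return float(l * (1.0 - phi) / (1.0 - phi**l))


def corrected_recruitment(
    B: np.ndarray, phi: float, calendar: OccasionCalendar
) -> np.ndarray:
    """B*_i = B_i scaled by the within-interval mortality correction."""
    intervals = calendar.intervals.astype(float)
    B = np.asarray(B, dtype=float)
    factors = np.array([correction_factor(phi, l) for l in intervals])
    return B * factors


def total_population(N1: float, B_star: np.ndarray, N1_se: float = 0.0) -> tuple[float, float]:
    """N_total = N_1 + sum_i B*_i (seasonal number of adults ever alive)."""
    return float(N1 + np.sum(B_star)), float(N1_se)


def estimate_abundance(
    chm: CaptureHistoryMatrix, fit: CJSFit, phi: float | None = None
) -> AbundanceEstimate:
    """Full chain: N_i series, recruitment, correction, seasonal total.

    ``phi`` defaults to the fitted daily survival averaged over the sexes
    present (weighted by individuals).
    """
    N, N_se = occasion_abundance(chm, fit)
    if phi is None:
        weights = {s: float((chm.sex == s).sum()) for s in ("F", "M")}
        tot = sum(weights.values())
        phi = sum(fit.phi[s] * w for s, w in weights.items()) / tot
    B = recruitment(N, phi, chm.calendar)
    B_star = corrected_recruitment(B, phi, chm.calendar)
    N_total, N_total_se = total_population(N[0], B_star, N_se[0])
    return AbundanceEstimate(
        n_i=chm.captures_per_occasion().astype(float),
        N_i=N,
        N_i_se=N_se,
        B_i=B,
        B_star_i=B_star,
        N_total=N_total,
        N_total_se=N_total_se,
        patch_id=chm.patch_id,
    )
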