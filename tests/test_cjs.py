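"""CJS likelihoods (m-array vs per-history oracle), fitting and selection."""

import datetime as dt

import numpy as np
import pytest

from meadowmrr._numeric import logit
from meadowmrr.cjs import (
    CaptureHistoryMatrix,
    CJSFit,
    build_capture_histories,
    build_m_array,
    cjs_loglik,
    cjs_loglik_individual,
    fit_cjs,
    select_by_aic,
)
from meadowmrr.core import OccasionCalendar
from meadowmrr.simulate import SimConfig, simulate_mrr


def daily_calendar(n):
    start = dt.date(2014, 7, 19)
    return OccasionCalendar(tuple(start + dt.timedelta(days=i) for i in range(n)))


def chm_from_strings(histories, sexes=None, calendar=None):
    matrix = np.array([[int(c) for c in h] for h in histories])
    sexes = sexes or ["F"] * len(histories)
    calendar = calendar or daily_calendar(matrix.shape[1])
    return CaptureHistoryMatrix(matrix, np.array(sexes, dtype=object), calendar)


def random_chm(rng, n=25, K=6):
    matrix = (rng.random((n, K)) < 0.4).astype(int)
    matrix[matrix.sum(axis=1) == 0, 0] = 1
    sexes = np.where(rng.random(n) < 0.5, "F", "M").astype(object)
    return CaptureHistoryMatrix(matrix, sexes, daily_calendar(K))


class TestMArray:
    def test_hand_tabulation(self):
        chm = chm_from_strings(["101", "110", "100"])
        ma = build_m_array(chm)
        assert ma.released[0] == 3
        assert ma.m[0, 1] == 1  # "110" recaptured at occasion 1
        assert ma.m[0, 2] == 1  # "101" first recaptured at occasion 2
        assert ma.released[1] == 1  # "110" re-released after its recapture
        assert ma.m[1].sum() == 0

    def test_singletons_give_empty_m(self):
        chm = chm_from_strings(["100", "010", "001"])
        ma = build_m_array(chm)
        assert ma.m.sum() == 0

    def test_row_sums_bounded_by_releases(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            ma = build_m_array(random_chm(rng))
            assert (ma.m.sum(axis=1) <= ma.released + 1e-12).all()

    def test_empty_matrix_rejected(self):
        chm = chm_from_strings(["10"])
        with pytest.raises(ValueError):
            build_m_array(chm.subset(np.array([False])))


class TestLikelihood:
    def test_closed_forms_for_two_occasions(self):
        phi, p = 0.7, 0.4
        params = np.array([logit(phi), logit(p)])
        chm11 = chm_from_strings(["11"])
        assert cjs_loglik_individual(params, chm11) == pytest.approx(
            np.log(phi * p), abs=1e-12
        )
        chm10 = chm_from_strings(["10"])
        assert cjs_loglik_individual(params, chm10) == pytest.approx(
            np.log(1.0 - phi * p), abs=1e-12
        )

    def test_marray_equals_individual_likelihood(self):
        """The multinomial m-array likelihood and the explicit per-history
        product agree everywhere (they are algebraically identical)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            chm = random_chm(rng, n=20, K=5)
            sexes = [s for s in ("F", "M") if (chm.sex == s).any()]
            marrays = {s: build_m_array(chm, chm.sex == s) for s in sexes}
            for model in ("phi(.)p(.)", "phi(sex)p(sex)"):
                k = 2 + 2 * (model == "phi(sex)p(sex)")
                params = rng.normal(0.0, 1.0, size=k)
                ll_m = cjs_loglik(params, marrays, chm.calendar, model)
                ll_i = cjs_loglik_individual(params, chm, model)
                assert ll_m == pytest.approx(ll_i, abs=1e-8)

    def test_certain_detection_gives_zero_loglik(self):
        chm = chm_from_strings(["111", "111"])
        ma = {"F": build_m_array(chm)}
        params = np.array([logit(1.0 - 1e-12), logit(1.0 - 1e-12)])
        assert cjs_loglik(params, ma, chm.calendar) == pytest.approx(0.0, abs=1e-6)

    def test_interval_reparameterisation_identity(self):
        """Doubling every interval while mapping phi -> sqrt(phi) leaves the
        interval survival phi**l, hence the likelihood, unchanged."""
        histories = ["101", "110", "111", "100"]
        phi, p = 0.8, 0.3
        cal1 = daily_calendar(3)
        start = dt.date(2014, 7, 19)
        cal2 = OccasionCalendar(tuple(start + dt.timedelta(days=2 * i) for i in range(3)))
        chm1 = chm_from_strings(histories, calendar=cal1)
        chm2 = chm_from_strings(histories, calendar=cal2)
        ll1 = cjs_loglik_individual(np.array([logit(phi), logit(p)]), chm1)
        ll2 = cjs_loglik_individual(np.array([logit(np.sqrt(phi)), logit(p)]), chm2)
        assert ll1 == pytest.approx(ll2, abs=1e-10)


class TestFitting:
    def test_two_occasion_mle_matches_grid_search(self):
        # with 2 occasions only the product phi**l * p is identifiable
        chm = chm_from_strings(["11"] * 30 + ["10"] * 70)
        fits, _ = fit_cjs(chm, models=("phi(.)p(.)",), seed=0)
        fit = fits[0]
        product = fit.phi["F"] * fit.p["F"]
        grid = np.linspace(0.01, 0.99, 981)
        ll = 30 * np.log(grid) + 70 * np.log(1 - grid)
        best = grid[np.argmax(ll)]
        assert product == pytest.approx(best, abs=1e-3)
        assert fit.loglik == pytest.approx(ll.max(), abs=1e-6)

    def test_recovers_generating_parameters(self):
        cfg = SimConfig(seed=23, total_recruits=500, n_days=30, gap_rate=0.0)
        ds, _ = simulate_mrr(cfg)
        chm = build_capture_histories(ds)
        fits, selected = fit_cjs(chm, seed=0)
        null = next(f for f in fits if f.model == "phi(.)p(.)")
        assert null.phi["F"] == pytest.approx(cfg.phi, abs=3 * null.phi_se["F"])
        assert null.p["F"] == pytest.approx(cfg.p, abs=3 * null.p_se["F"])

    def test_adding_sex_terms_never_lowers_loglik(self):
        cfg = SimConfig(seed=31, total_recruits=400, n_days=25, gap_rate=0.0)
        ds, _ = simulate_mrr(cfg)
        fits, _ = fit_cjs(build_capture_histories(ds), seed=0)
        ll = {f.model: f.loglik for f in fits}
        assert ll["phi(sex)p(.)"] >= ll["phi(.)p(.)"] - 1e-6
        assert ll["phi(.)p(sex)"] >= ll["phi(.)p(.)"] - 1e-6
        assert ll["phi(sex)p(sex)"] >= ll["phi(sex)p(.)"] - 1e-6
        assert ll["phi(sex)p(sex)"] >= ll["phi(.)p(sex)"] - 1e-6

    def test_no_recaptures_rejected(self):
        chm = chm_from_strings(["100", "010"])
        with pytest.raises(ValueError):
            fit_cjs(chm)


class TestSelection:
    def _fit(self, model, aic):
        return CJSFit(
            model=model, phi={}, p={}, phi_se={}, p_se={},
            loglik=0.0, aic=aic, converged=True,
        )

    def test_lowest_aic_wins(self):
        fits = [self._fit("phi(.)p(.)", 100.0), self._fit("phi(sex)p(.)", 105.0)]
        assert select_by_aic(fits).model == "phi(.)p(.)"

    def test_simpler_model_within_two_units_preferred(self):
        fits = [self._fit("phi(sex)p(sex)", 100.0), self._fit("phi(.)p(.)", 101.5)]
        assert select_by_aic(fits).model == "phi(.)p(.)"

    def test_exact_tie_breaks_lexicographically(self):
        fits = [self._fit("phi(sex)p(.)", 100.0), self._fit("phi(.)p(sex)", 100.0)]
        assert select_by_aic(fits).model == "phi(.)p(sex)"
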