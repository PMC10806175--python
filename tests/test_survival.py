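import numpy as np
import pandas as pd
import pytest

from radcrt.survival import (
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank,
    run_prognosis,
    UNIVARIATE_VARIABLES,
)

from oracles import cox_grid_mle, cox_score_test, km_product_limit


def _records(times, events):
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


class TestKaplanMeier:
    def test_hand_product_limit_toy(self):
        # times 1+, 2, 3+, 4 (+ = censored)
        km = km_estimate(_records([1, 2, 3, 4], [0, 1, 0, 1]))
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(4) == pytest.approx(0.0)
        assert km.median == 4.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(_records([1, 2, 3], [0, 0, 0]))
        assert km.survival_at(99) == 1.0
        assert km.median is None  # "not reached"

    def test_no_censoring_reduces_to_ecdf_complement(self, rng):
        times = rng.exponential(5, 40)
        km = km_estimate(_records(times, np.ones(40)))
        for t, s in km_product_limit(times, np.ones(40)):
            assert km.survival_at(t) == pytest.approx(s)
            assert s == pytest.approx((times > t).mean())

    def test_survival_monotone_nonincreasing(self, rng):
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        km = km_estimate(_records(times, events))
        assert np.all(np.diff(km.survival) <= 1e-12)


class TestLogrank:
    def test_identical_groups(self):
        g = _records([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = logrank(_records([1, 2], [0, 0]), _records([3], [0]))
        assert p == 1.0

    def test_power_against_hazard_ratio_four(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            a = rng.exponential(1.0, 22)
            b = rng.exponential(4.0, 22)
            if logrank(_records(a, np.ones(22)), _records(b, np.ones(22)))[1] < 0.05:
                rejections += 1
        assert rejections / n_sims > 0.8

    def test_matches_cox_score_test_without_ties(self, rng):
        times = rng.exponential(10, 30)
        x = np.array([1] * 15 + [0] * 15)
        chi2, _ = logrank(
            _records(times[x == 1], np.ones(15)),
            _records(times[x == 0], np.ones(15)),
        )
        assert chi2 == pytest.approx(cox_score_test(times, np.ones(30), x),
                                     abs=1e-6)


class TestCox:
    def test_matches_grid_search_partial_likelihood(self):
        times = [1.0, 2.5, 3.0, 4.5, 6.0, 7.5]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 0, 1, 0, 0, 1]
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.coefficients["x"] == pytest.approx(
            cox_grid_mle(times, events, x), abs=1e-3)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 0, 1],
                           "x": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_collinear_covariates_rejected(self, rng):
        x = rng.integers(0, 2, 30)
        df = pd.DataFrame({"time": rng.exponential(5, 30), "event": 1,
                           "a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            cox_fit(df, ["a", "b"])

    def test_ci_brackets_hazard_ratio(self, rng):
        x = np.array([1] * 20 + [0] * 20)
        t = rng.exponential(np.where(x == 1, 8, 3))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.ci_lower["x"] <= fit.hazard_ratios["x"] <= fit.ci_upper["x"]
        assert fit.hazard_ratios["x"] > 0

    def test_recovers_simulated_hazard_ratio_quarter(self):
        """True HR 0.25 at the study's n = 44: mean estimate lands near it."""
        rng = np.random.default_rng(30)
        hrs = []
        for _ in range(200):
            x = np.array([1] * 15 + [0] * 29)
            t = rng.exponential(np.where(x == 1, 4.0, 1.0))  # HR = 0.25
            df = pd.DataFrame({"time": t, "event": 1, "x": x})
            hrs.append(cox_fit(df, ["x"]).hazard_ratios["x"])
        assert 0.18 <= np.mean(hrs) <= 0.35

    def test_log_hr_bias_small_at_large_n(self):
        rng = np.random.default_rng(31)
        for true_hr in (0.25, 0.5, 1.0):
            betas = []
            for _ in range(60):
                x = rng.integers(0, 2, 200)
                t = rng.exponential(np.where(x == 1, 1.0 / true_hr, 1.0))
                df = pd.DataFrame({"time": t, "event": 1, "x": x})
                betas.append(cox_fit(df, ["x"]).coefficients["x"])
            bias = abs(np.mean(betas) - np.log(true_hr))
            tol = 0.1 * abs(np.log(true_hr)) if true_hr != 1.0 else 0.05
            assert bias < max(tol, 0.05), f"HR {true_hr}: bias {bias}"


class TestPrognosisReport:
    def _clinical(self, n, rng, hr=0.25):
        resp = np.array([1] * (n // 3) + [0] * (n - n // 3))
        pfs = rng.exponential(np.where(resp == 1, 6 / hr, 6), n)
        osm = pfs + rng.exponential(8, n)
        return pd.DataFrame({
            "cohort": ["validation"] * n,
            "response": resp,
            "pfs_months": pfs, "pfs_event": 1,
            "os_months": osm, "os_event": 1,
            "age": rng.normal(70, 8, n),
            "sex": rng.choice(["M", "F"], n),
            "t_stage": rng.integers(1, 5, n),
            "n_stage": rng.integers(0, 5, n),
            "scc": rng.uniform(0.5, 4, n),
            "location": rng.choice(["Ut", "Mt", "Lt"], n),
        }, index=[f"c{i}" for i in range(n)])

    def test_report_has_seven_univariate_rows(self, rng):
        clin = self._clinical(44, rng)
        scores = pd.Series(clin["response"] * 0.4 + 0.1
                           + rng.normal(0, 0.02, 44), index=clin.index)
        rep = run_prognosis(clin, scores, 0.3)
        for ep in ("pfs", "os"):
            uni = rep["endpoints"][ep]["univariate"]
            assert tuple(uni) == UNIVARIATE_VARIABLES
            assert len(uni) == 7

    def test_strong_effect_orders_medians(self, rng):
        clin = self._clinical(44, rng, hr=0.1)
        scores = pd.Series((clin["response"] * 0.5 + 0.05).astype(float),
                           index=clin.index)
        rep = run_prognosis(clin, scores, 0.3)
        ep = rep["endpoints"]["pfs"]
        high, low = ep["median_high"], ep["median_low"]
        assert high is None or high > low
        assert ep["logrank_p"] < 0.05

    def test_empty_stratum_rejected(self, rng):
        clin = self._clinical(20, rng)
        scores = pd.Series(np.full(20, 0.9), index=clin.index)
        with pytest.raises(ValueError, match="stratum"):
            run_prognosis(clin, scores, 0.95)

    def test_null_scores_give_uniformish_logrank_p(self):
        rng = np.random.default_rng(40)
        ps = []
        for _ in range(40):
            clin = self._clinical(44, rng, hr=1.0)
            scores = pd.Series(rng.random(44), index=clin.index)
            rep = run_prognosis(clin, scores, 0.5)
            ps.append(rep["endpoints"]["pfs"]["logrank_p"])
        # under the null, small p-values are rare
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.mean(ps) > 0.3
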