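import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import minimize_scalar

import hapattern as hp


def _random_survival(rng, n, tie_round=None, beta=0.0, p=1):
    x = rng.normal(size=(n, p))
    lam = 0.1 * np.exp(x @ (np.full(p, beta)))
    t = rng.exponential(1 / lam)
    if tie_round is not None:
        t = np.round(t, tie_round) + 10.0 ** (-tie_round)
    e = (rng.uniform(size=n) < 0.75).astype(int)
    return t, e, x


class TestKmCurve:
    def test_all_censored_is_flat_one(self):
        km = hp.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.at(5.0) == 1.0

    def test_hand_product_limit(self):
        # subjects: 1 censored, death at 2 (3 at risk), censored at 3,
        # death at 4 (1 at risk)
        km = hp.km_curve([1, 2, 3, 4], [0, 1, 0, 1])
        assert np.allclose(km.event_times, [2, 4])
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert list(km.at_risk) == [3, 1]

    def test_duplicating_subjects_preserves_curve(self):
        t = np.array([1.5, 2.0, 3.0, 4.0, 6.0])
        e = np.array([1, 0, 1, 1, 0])
        a = hp.km_curve(t, e)
        b = hp.km_curve(np.repeat(t, 2), np.repeat(e, 2))
        assert np.allclose(a.survival, b.survival)
        assert np.allclose(a.event_times, b.event_times)


class TestLogrank:
    def test_exchangeable_groups_give_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0] * 4 + [1] * 4
        chi2, df, p = hp.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_direct_oe_tabulation_oracle(self):
        # group A events at 1, 2; group B events at 3, 4; no censoring
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        g = np.array(["A", "A", "B", "B"])
        O1, E1, V = 0.0, 0.0, 0.0
        for u in [1.0, 2.0, 3.0, 4.0]:
            at = t >= u
            n = at.sum()
            n1 = (at & (g == "A")).sum()
            d = 1
            O1 += ((t == u) & (g == "A")).sum()
            E1 += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2, df, p = hp.logrank_test(t, e, g)
        assert chi2 == pytest.approx((O1 - E1) ** 2 / V, rel=1e-12)
        assert df == 1

    def test_matches_lifelines_three_groups(self):
        rng = np.random.default_rng(2)
        t, e, _ = _random_survival(rng, 90, tie_round=1)
        g = rng.integers(0, 3, size=90)
        chi2, df, p = hp.logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            hp.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_zstat_squared_equals_chi2(self):
        rng = np.random.default_rng(4)
        t, e, x = _random_survival(rng, 60, tie_round=1)
        grp = x[:, 0] > 0
        chi2, _, _ = hp.logrank_test(t, e, grp.astype(int))
        z = hp.logrank_zstat(t, e, grp)
        assert z**2 == pytest.approx(chi2, abs=1e-9)


def efron_loglik(beta, t, e, x):
    """Hand-coded Efron partial likelihood for one covariate."""
    ll = 0.0
    for u in np.unique(t[e == 1]):
        risk = t >= u
        dead = (t == u) & (e == 1)
        d = dead.sum()
        phi_r = np.exp(beta * x[risk]).sum()
        phi_d = np.exp(beta * x[dead]).sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(phi_r - l / d * phi_d)
    return ll


class TestCoxFit:
    def test_exchangeable_binary_covariate_beta_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = hp.cox_fit(t, e, x)
        assert abs(fit.beta[0]) < 1e-6

    def test_beta_matches_gridsearch_of_hand_coded_likelihood(self):
        t = np.array([3.0, 5.0, 7.0, 2.0, 9.0, 4.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([0.5, -1.2, 0.3, 1.7, -0.6, 0.9])
        fit = hp.cox_fit(t, e, x)
        res = minimize_scalar(lambda b: -efron_loglik(b, t, e, x),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)
        assert fit.converged

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(6)
        t, e, x = _random_survival(rng, 150, tie_round=1, beta=0.4, p=3)
        fit = hp.cox_fit(t, e, x)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, ref.params_.values, atol=1e-6)
        assert np.allclose(fit.se, ref.standard_errors_.values, atol=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(
            ref.log_likelihood_, rel=1e-9)

    def test_ci_brackets_hr_and_wald(self):
        rng = np.random.default_rng(8)
        t, e, x = _random_survival(rng, 80, beta=0.5)
        fit = hp.cox_fit(t, e, x)
        ci = fit.ci95
        assert ci[0, 0] < fit.hr[0] < ci[0, 1]
        assert 0 <= fit.wald_p[0] <= 1

    def test_constant_covariate_named(self):
        with pytest.raises(ValueError, match="const"):
            hp.cox_fit([1, 2, 3, 4], [1, 1, 1, 0],
                       pd.DataFrame({"const": [1.0] * 4,
                                     "ok": [1.0, 2, 3, 4]}))

    def test_separation_flagged_and_capped(self):
        # perfect separation: all early deaths have x=1, survivors x=0
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        with pytest.warns(UserWarning, match="monotone"):
            fit = hp.cox_fit(t, e, x)
        assert fit.separation
        assert abs(fit.beta[0]) <= 20.0


class TestBestCutpoint:
    def test_separable_clusters(self):
        rng = np.random.default_rng(1)
        n = 40
        score = np.concatenate([rng.normal(-3, 0.3, n // 2),
                                rng.normal(3, 0.3, n // 2)])
        # low-score samples are long-term survivors, high-score die early
        time = np.concatenate([rng.uniform(10, 11, n // 2),
                               rng.uniform(1, 2, n // 2)])
        event = np.ones(n, dtype=int)
        cut, stat = hp.best_cutpoint(score, time, event, minprop=0.1)
        assert score[:n // 2].max() <= cut < score[n // 2:].min()
        assert stat > 3

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(9)
        n = 50
        score = rng.normal(size=n)
        time = rng.exponential(1, n) + 0.01
        event = (rng.uniform(size=n) < 0.7).astype(int)
        cut, stat = hp.best_cutpoint(score, time, event, minprop=0.15)
        # independent scan using lifelines' log-rank at every split
        best = (None, -1.0)
        min_n = int(np.ceil(0.15 * n))
        for c in np.unique(score):
            low = score <= c
            if low.sum() < min_n or (~low).sum() < min_n:
                continue
            ref = multivariate_logrank_test(time, low.astype(int), event)
            z = np.sqrt(ref.test_statistic)
            if z > best[1] + 1e-12:
                best = (c, z)
        assert cut == pytest.approx(best[0])
        assert stat == pytest.approx(best[1], abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        score = rng.normal(size=30)
        time = rng.exponential(1, 30) + 0.01
        event = np.ones(30, dtype=int)
        c1, s1 = hp.best_cutpoint(score, time, event)
        c2, s2 = hp.best_cutpoint(np.exp(score), time, event)
        assert np.array_equal(score <= c1, np.exp(score) <= c2)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_no_admissible_cutpoint(self):
        with pytest.raises(ValueError, match="admissible"):
            hp.best_cutpoint([1.0] * 10, np.arange(1, 11.0),
                             np.ones(10, dtype=int), minprop=0.3)
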