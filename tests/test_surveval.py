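import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from anthropoage import (
    compare_auc_bootstrap,
    fit_cox,
    kaplan_meier,
    log_rank,
    ph_test,
    tauc,
    uno_c,
)
from anthropoage.surveval import censoring_survival, delta_tauc


def _censored_fixture(n=200, seed=1):
    rng = np.random.default_rng(seed)
    t = rng.exponential(5.0, n)
    ev = (rng.random(n) < 0.7).astype(int)
    lp = 0.5 * -t + rng.normal(0, 1, n)  # informative but noisy score
    return lp, t, ev


class TestCox:
    def test_coefficient_matches_brute_force_partial_likelihood(self):
        # 6 subjects, all events, binary group, interleaved so the partial-
        # likelihood maximizer is finite; Efron = Breslow (no ties)
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"time_years": t, "event": 1, "g": g})

        def neg_pl(beta):
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                risk = t >= t[i]
                ll += beta * g[i] - np.log(np.sum(np.exp(beta * g[risk])))
            return -ll

        brute = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded").x
        fit = fit_cox(df, ["g"])
        assert fit.coefficients["g"] == pytest.approx(brute, abs=1e-5)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_years": [1.0, 2, 3], "event": [1, 1, 0], "g": 1.0})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, ["g"])

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"time_years": [1.0, 2.0], "event": [0, 0], "g": [0.0, 1.0]})
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(df, ["g"])

    def test_equal_weights_match_unweighted(self):
        lp, t, ev = _censored_fixture(80, 3)
        df = pd.DataFrame({"time_years": t, "event": ev, "x": lp, "w": 2.0})
        a = fit_cox(df, ["x"])
        b = fit_cox(df, ["x"], weights_col="w")
        assert a.coefficients["x"] == pytest.approx(b.coefficients["x"], rel=1e-8)


class TestUnoC:
    def test_perfect_and_null_discrimination(self):
        t = np.arange(1.0, 11.0)
        ev = np.ones(10, dtype=int)
        assert uno_c(-t, t, ev).estimate == 1.0
        assert uno_c(np.zeros(10), t, ev).estimate == 0.5

    def test_equals_brute_force_pair_sum(self):
        lp, t, ev = _censored_fixture()
        est = uno_c(lp, t, ev).estimate
        _, G_minus = censoring_survival(t, ev)
        g = np.asarray(G_minus(t))
        tau = t.max()
        num = den = 0.0
        for i in range(len(t)):
            if ev[i] == 1 and t[i] < tau:
                for j in range(len(t)):
                    if t[j] > t[i]:
                        w = 1.0 / g[i] ** 2
                        den += w
                        num += w * ((lp[i] > lp[j]) + 0.5 * (lp[i] == lp[j]))
        assert est == pytest.approx(num / den, abs=1e-12)

    def test_no_censoring_reduces_to_harrell(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(3, 120)
        lp = rng.normal(size=120)
        ev = np.ones(120, dtype=int)
        est = uno_c(lp, t, ev).estimate
        conc = disc = ties = 0
        for i in range(120):
            for j in range(120):
                if t[i] < t[j]:
                    if lp[i] > lp[j]:
                        conc += 1
                    elif lp[i] < lp[j]:
                        disc += 1
                    else:
                        ties += 1
        harrell = (conc + 0.5 * ties) / (conc + disc + ties)
        assert est == pytest.approx(harrell, abs=1e-12)

    def test_monotone_transform_invariance(self):
        lp, t, ev = _censored_fixture(150, 5)
        a = uno_c(lp, t, ev).estimate
        b = uno_c(np.exp(2.0 * lp) + 3, t, ev).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            uno_c([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestTauc:
    def test_oracle_predictor_gives_auc_one(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(4, 300)
        ev = np.ones(300, dtype=int)
        tau = np.median(t)
        lp = (t <= tau).astype(float)  # oracle: knows who dies by tau
        res = tauc(lp, t, ev, [tau])
        assert res["auc"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_random_predictor_near_half(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(4, 4000)
        ev = (rng.random(4000) < 0.8).astype(int)
        lp = rng.normal(size=4000)
        res = tauc(lp, t, ev, [3.0])
        assert res["auc"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_equals_brute_force_ipcw_pair_sum(self):
        lp, t, ev = _censored_fixture(150, 6)
        tau = 3.0
        res = tauc(lp, t, ev, [tau])["auc"].iloc[0]
        _, G_minus = censoring_survival(t, ev)
        g = np.asarray(G_minus(t))
        cases = (ev == 1) & (t <= tau)
        ctrl = t > tau
        g_tau = float(np.asarray(G_minus(tau + 1e-12)))
        num = den = 0.0
        for i in np.flatnonzero(cases):
            for j in np.flatnonzero(ctrl):
                w = (1.0 / g[i]) * (1.0 / g_tau)
                den += w
                num += w * ((lp[i] > lp[j]) + 0.5 * (lp[i] == lp[j]))
        assert res == pytest.approx(num / den, abs=1e-12)

    def test_time_without_cases_flagged_missing(self):
        lp, t, ev = _censored_fixture(50, 7)
        res = tauc(lp, t, ev, [1e-9, 2.0])
        assert np.isnan(res["auc"].iloc[0]) and not np.isnan(res["auc"].iloc[1])

    def test_delta_tauc_sign_convention(self):
        lp, t, ev = _censored_fixture(200, 9)
        out = delta_tauc(lp, -lp, t, ev, [2.0, 4.0])
        assert (out["delta"] > 0).all()  # informative beats anti-informative


class TestAgainstScikitSurvival:
    """Independent cross-check of the IPCW metrics against scikit-survival's
    implementations (same estimand, independently coded)."""

    def test_uno_c_and_tauc_match_sksurv(self):
        from sksurv.metrics import concordance_index_ipcw, cumulative_dynamic_auc
        from sksurv.util import Surv

        lp, t, ev = _censored_fixture(300, 55)
        y = Surv.from_arrays(ev.astype(bool), t)
        tau = float(np.quantile(t, 0.8))
        c_ref = concordance_index_ipcw(y, y, lp, tau=tau)[0]
        assert uno_c(lp, t, ev, tau=tau).estimate == pytest.approx(c_ref, abs=1e-12)
        times = [2.0, 4.0]
        auc_ref, _ = cumulative_dynamic_auc(y, y, lp, times)
        mine = tauc(lp, t, ev, times)["auc"].to_numpy()
        np.testing.assert_allclose(mine, auc_ref, atol=1e-12)


class TestCompareAUC:
    def test_identical_predictors(self):
        lp, t, ev = _censored_fixture(150, 10)
        res = compare_auc_bootstrap(lp, lp, t, ev, horizon=3.0, n_boot=100, seed=0)
        assert res["delta"] == 0.0 and res["p"] == 1.0

    def test_determinism(self):
        lp, t, ev = _censored_fixture(150, 11)
        r1 = compare_auc_bootstrap(lp, np.roll(lp, 1), t, ev, 3.0, n_boot=100, seed=42)
        r2 = compare_auc_bootstrap(lp, np.roll(lp, 1), t, ev, 3.0, n_boot=100, seed=42)
        assert r1 == r2

    def test_power_oracle_vs_noise(self):
        rng = np.random.default_rng(12)
        n = 500
        t = rng.exponential(4, n)
        ev = np.ones(n, dtype=int)
        tau = float(np.median(t))
        oracle = -(t - tau)
        noise = rng.normal(size=n)
        res = compare_auc_bootstrap(oracle, noise, t, ev, tau, n_boot=500, seed=1)
        assert res["delta"] > 0 and res["p"] < 0.01


class TestKMLogRank:
    def test_product_limit_hand_value(self):
        t = np.array([1, 1, 2, 3, 4, 5, 6, 7, 8, 9.0])
        ev = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        km = kaplan_meier(t, ev)[0]
        assert km.loc[km["time"] == 1.0, "survival"].iloc[0] == pytest.approx(0.8)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(3, 100)
        km = kaplan_meier(t, np.ones(100, dtype=int))[0]
        for _, row in km.iloc[1:].iterrows():
            emp = np.mean(t > row["time"])
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_log_rank_null_on_identical_groups(self):
        t = np.tile(np.arange(1.0, 11.0), 2)
        ev = np.tile(np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0]), 2)
        g = np.repeat([0, 1], 10)
        chi2, p, _ = log_rank(t, ev, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_log_rank_matches_hand_computation(self):
        # 8 subjects, two groups, censoring; O-E / V summed by hand below
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        ev = np.array([1, 0, 1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # hand computation of the two-group log-rank statistic
        O1 = E1 = V = 0.0
        for ti in np.unique(t[ev == 1]):
            at_risk = t >= ti
            d = float(np.sum((t == ti) & (ev == 1)))
            n_r = float(at_risk.sum())
            n1 = float(np.sum(at_risk & (g == 0)))
            d1 = float(np.sum((t == ti) & (ev == 1) & (g == 0)))
            O1 += d1
            E1 += d * n1 / n_r
            if n_r > 1:
                V += d * (n1 / n_r) * (1 - n1 / n_r) * (n_r - d) / (n_r - 1)
        expected = (O1 - E1) ** 2 / V
        chi2, _, dof = log_rank(t, ev, g)
        assert dof == 1
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_four_groups_supported(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(3, 200)
        ev = (rng.random(200) < 0.7).astype(int)
        g = rng.integers(0, 4, 200)
        chi2, p, dof = log_rank(t, ev, g)
        assert dof == 3 and 0 <= p <= 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="groups"):
            log_rank([1.0, 2.0], [1, 1], [0, 0])


class TestPHTest:
    def _ph_data(self, n, seed, reverse=False):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        u = rng.random(n)
        if not reverse:
            t = -np.log(u) / np.exp(0.7 * x)
        else:
            # effect flips sign at t=1: build by inverting a piecewise hazard
            t1 = -np.log(u) / np.exp(1.0 * x)
            t = np.where(t1 <= 1.0, t1, 1.0 + (t1 - 1.0) * np.exp(2.0 * x))
        cens = rng.exponential(5, n)
        return pd.DataFrame(
            {"time_years": np.minimum(t, cens), "event": (t <= cens).astype(int), "x": x}
        )

    def test_non_proportional_effect_detected(self):
        df = self._ph_data(2000, 21, reverse=True)
        fit = fit_cox(df, ["x"])
        res = ph_test(fit, df)
        assert res["per_covariate_p"]["x"] < 0.01
        assert res["global_p"] < 0.01

    def test_calibrated_under_proportional_hazards(self):
        ps = []
        for s in range(40):
            df = self._ph_data(300, 100 + s)
            fit = fit_cox(df, ["x"])
            ps.append(ph_test(fit, df)["global_p"])
        ps = np.asarray(ps)
        # under PH the p-values should not pile up near 0
        assert (ps < 0.05).mean() <= 0.2
        assert ps.mean() > 0.25

    def test_single_event_errors(self):
        df = pd.DataFrame({"time_years": [1.0, 2.0, 3.0], "event": [1, 0, 0],
                           "x": [0.1, 0.5, 0.9]})
        fit = fit_cox(df, ["x"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ph_test(fit, df)

    def test_residual_series_returned(self):
        df = self._ph_data(300, 33)
        fit = fit_cox(df, ["x"])
        res = ph_test(fit, df)
        assert len(res["residuals"]) == df["event"].sum()
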