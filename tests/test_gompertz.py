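import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from anthropoage import (
    GompertzCAFit,
    RiskHorizon,
    anthropoage,
    anthropoage_accel,
    anthropoage_batch,
    fit_gompertz,
    gompertz_cdf,
    gompertz_loglik,
    read_coefficients,
    write_coefficients,
)
from anthropoage.synth import _gompertz_time_months


def _cdf_ca(fit, t, age):
    """Independent scalar evaluation of the CA-only Gompertz CDF.

    Computed on the log scale so root-finding brackets can be wide without
    overflowing.
    """
    z = fit.beta0 + fit.beta1 * age + math.log((math.exp(fit.gamma0 * t) - 1.0) / fit.gamma0)
    return -math.expm1(-math.exp(min(z, 50.0)))


FIT = GompertzCAFit(gamma0=0.005, beta0=-10.0, beta1=0.08, sex="test", loglik=0.0)


class TestCDF:
    def test_limits(self):
        assert gompertz_cdf(0.005, -1e3) == pytest.approx(0.0, abs=1e-12)
        assert gompertz_cdf(0.005, 1e3) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_value(self):
        # 1 - exp(-e^{-5.2} (e^{0.6}-1)/0.005), evaluated directly
        expected = 1.0 - math.exp(-math.exp(-5.2) * (math.exp(0.6) - 1.0) / 0.005)
        assert gompertz_cdf(0.005, -5.2, RiskHorizon(120)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5963, abs=1e-4)

    def test_exponential_limit_as_gamma_vanishes(self):
        xb, t = -6.0, 120.0
        target = 1.0 - math.exp(-math.exp(xb) * t)
        assert gompertz_cdf(1e-8, xb, RiskHorizon(t)) == pytest.approx(target, rel=1e-6)


class TestAnthropoAgeTransform:
    def test_round_trip_identity_over_age_range(self):
        ages = np.linspace(50, 94, 45)
        M = gompertz_cdf(FIT.gamma0, FIT.linear_predictor(ages))
        back = anthropoage(FIT, M)
        np.testing.assert_allclose(back, ages, atol=1e-8)

    def test_matches_numeric_inversion_at_m_010(self):
        root = brentq(lambda a: _cdf_ca(FIT, 120.0, a) - 0.10, -200, 300, xtol=1e-12)
        assert anthropoage(FIT, 0.10) == pytest.approx(root, abs=1e-8)
        assert root == pytest.approx(33.0898, abs=1e-3)

    def test_closed_form_equals_brute_force_inversion(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            fit = GompertzCAFit(
                gamma0=rng.uniform(0.001, 0.02),
                beta0=rng.uniform(-14, -6),
                beta1=rng.uniform(0.03, 0.15),
                sex="x",
                loglik=0.0,
            )
            m = rng.uniform(0.001, 0.999)
            closed = anthropoage(fit, m)
            root = brentq(lambda a: _cdf_ca(fit, 120.0, a) - m, -1e4, 1e4, xtol=1e-10)
            assert abs(closed - root) < 1e-8

    def test_monotone_in_m(self):
        ms = np.linspace(0.01, 0.99, 50)
        ba = anthropoage(FIT, ms)
        assert np.all(np.diff(ba) > 0)

    def test_m_outside_open_interval(self):
        with pytest.raises(ValueError, match="outside the open interval"):
            anthropoage(FIT, 1.0)
        with pytest.raises(ValueError):
            anthropoage(FIT, 0.0)
        with pytest.warns(UserWarning, match="clamped"):
            v = anthropoage(FIT, 1.0, clamp_eps=1e-12)
        assert np.isfinite(v)


class TestLikelihood:
    def test_loglik_matches_hand_sum_on_four_subjects(self):
        t = np.array([10.0, 25.0, 60.0, 100.0])
        d = np.array([1, 0, 1, 0])
        xb = np.array([-5.0, -4.5, -6.0, -5.5])
        g = 0.004
        hand = 0.0
        for ti, di, xi in zip(t, d, xb):
            hand += di * (xi + g * ti) - math.exp(xi) * (math.exp(g * ti) - 1) / g
        assert gompertz_loglik(g, xb, t, d) == pytest.approx(hand, rel=1e-12)

    def test_fit_recovers_simulation_parameters(self):
        rng = np.random.default_rng(99)
        n = 20000
        age = 50 + 44 * rng.beta(1.3, 3.0, n)
        xb = -10.0 + 0.08 * age
        t = _gompertz_time_months(rng.random(n), 0.005, xb)
        ev = (t <= 144.0).astype(int)
        tt = np.minimum(t, 144.0)
        fit = fit_gompertz(tt, ev, age[:, None])
        se = np.sqrt(np.diag(fit.covariance))
        est = np.array([fit.gamma0, fit.beta0, fit.beta1])
        assert np.all(np.abs(est - [0.005, -10.0, 0.08]) < 4 * se)
        # reported loglik is the maximized likelihood, at least that at truth
        lp = fit.beta0 + fit.beta1 * age
        assert fit.loglik >= gompertz_loglik(0.005, -10.0 + 0.08 * age, tt, ev)
        assert fit.loglik == pytest.approx(gompertz_loglik(fit.gamma0, lp, tt, ev), rel=1e-9)

    def test_zero_events_errors(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_gompertz([10.0, 20.0], [0, 0], np.array([[60.0], [70.0]]))

    def test_nonpositive_time_errors(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gompertz([0.0, 20.0], [1, 1], np.array([[60.0], [70.0]]))


class TestBatch:
    def test_batch_equals_scalar_calls_and_sex_stratification(self, ba_panel):
        panel, _, ca_fits, anthro_fits = ba_panel
        sub = panel.head(50)
        batch = anthropoage_batch(sub, ca_fits, anthro_fits)
        for i, (_, row) in enumerate(sub.iterrows()):
            afit = anthro_fits[row["sex"]]
            xb = afit.linear_predictor(row["age"], row["bmi"], row["whtr"])
            m = gompertz_cdf(afit.gammas[row["ethnicity"]], xb)
            scalar = anthropoage(ca_fits[row["sex"]], float(m))
            assert batch[i] == pytest.approx(scalar, abs=1e-10)
        # flipping sex changes the models applied, hence the result
        flipped = sub.copy()
        flipped["sex"] = np.where(sub["sex"] == "female", "male", "female")
        other = anthropoage_batch(flipped, ca_fits, anthro_fits)
        assert not np.allclose(batch, other)

    def test_row_order_invariance(self, ba_panel):
        panel, _, ca_fits, anthro_fits = ba_panel
        sub = panel.head(80)
        a = anthropoage_batch(sub, ca_fits, anthro_fits)
        perm = sub.sample(frac=1.0, random_state=5)
        b = anthropoage_batch(perm, ca_fits, anthro_fits)
        lookup = dict(zip(perm.index, b))
        np.testing.assert_allclose(a, [lookup[i] for i in sub.index], atol=1e-12)

    def test_unknown_ethnicity_errors(self, ba_panel):
        panel, _, ca_fits, anthro_fits = ba_panel
        sub = panel.head(5).copy()
        sub.loc[sub.index[0], "ethnicity"] = "Martian"
        with pytest.raises(KeyError, match="Martian"):
            anthropoage_batch(sub, ca_fits, anthro_fits)


class TestAccel:
    def _identity_panel(self):
        rng = np.random.default_rng(3)
        n = 200
        return pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "sex": rng.choice(["female", "male"], n),
                "study": rng.choice(["A", "B"], n),
                "age": rng.uniform(50, 94, n),
            }
        ).assign(anthropoage=lambda d: d["age"])

    def test_identity_panel_gives_zero_acceleration(self):
        out = anthropoage_accel(self._identity_panel(), mode="pooled-ols-by-sex")
        np.testing.assert_allclose(out["accel"], 0.0, atol=1e-10)
        assert not out["accelerated"].any()

    def test_ols_orthogonality(self, ba_panel):
        panel, _, _, _ = ba_panel
        out = anthropoage_accel(panel, mode="pooled-ols-by-sex")
        for _, sub in out.groupby("sex"):
            r = sub["accel"].to_numpy()
            ca = sub["age"].to_numpy()
            assert abs(r.sum()) < 1e-8 * len(r)
            assert abs(np.corrcoef(r, ca)[0, 1]) < 1e-10

    def test_study_intercepts_absorb_constant_offset(self):
        rng = np.random.default_rng(11)
        n = 300
        base = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "sex": "female",
                "study": "A",
                "age": rng.uniform(50, 94, n),
            }
        )
        base["anthropoage"] = base["age"] + rng.normal(0, 2, n)
        shifted = base.copy()
        shifted["study"] = "B"
        shifted["anthropoage"] += 3.0  # constant study offset
        two = pd.concat([base, shifted], ignore_index=True)
        res_single = anthropoage_accel(base, mode="pooled-ols-by-sex")["accel"]
        res_two = anthropoage_accel(two, mode="study-intercepts")["accel"]
        np.testing.assert_allclose(res_two[:n], res_single, atol=1e-8)
        np.testing.assert_allclose(res_two[n:], res_single, atol=1e-8)

    def test_quartiles_partition_per_sex(self, ba_panel):
        panel, _, _, _ = ba_panel
        out = anthropoage_accel(panel)
        for _, sub in out.groupby("sex"):
            counts = sub["accel_quartile"].value_counts(normalize=True)
            assert set(counts.index) == {1, 2, 3, 4}
            assert counts.max() < 0.30

    def test_small_stratum_errors(self):
        df = self._identity_panel().head(4)
        df["sex"] = ["female", "female", "male", "male"]
        with pytest.raises(ValueError, match="fewer than 3"):
            anthropoage_accel(df, mode="pooled-ols-by-sex")


def test_coefficient_file_roundtrip_bit_exact(tmp_path, ba_panel):
    _, _, ca_fits, anthro_fits = ba_panel
    p = tmp_path / "coefs.tsv"
    write_coefficients(p, ca_fits, anthro_fits)
    ca2, an2 = read_coefficients(p)
    for sx in ca_fits:
        assert ca2[sx].gamma0 == ca_fits[sx].gamma0
        assert ca2[sx].beta0 == ca_fits[sx].beta0
        assert ca2[sx].beta1 == ca_fits[sx].beta1
    for sx in anthro_fits:
        assert an2[sx].gammas == anthro_fits[sx].gammas
        assert an2[sx].coefs == anthro_fits[sx].coefs
        assert an2[sx].rate == anthro_fits[sx].rate
        assert an2[sx].basis == anthro_fits[sx].basis
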