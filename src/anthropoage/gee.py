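"""Generalized estimating equations for population aging trends and
new-onset outcome models.

Thin, convention-fixing layer over ``statsmodels`` GEE: Gaussian / Poisson /
binomial variance functions, independence or AR(1) working correlation on
the wave index, robust sandwich covariance, frequency-style survey weights
normalized to mean 1, and QIC model comparison (Pan 2001).

Note on QIC scale: for Gaussian models both QICs in a comparison are
computed at the scale of the larger model so that the difference is
well-defined; only the *sign and ordering* of delta-QIC is interpreted, not
its level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GEEFit", "fit_gee", "aging_trend", "new_onset_model",
           "qic_compare", "weighted_prevalence_over_time"]

_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "binomial": sm.families.Binomial,
}


@dataclass
class GEEFit:
    """Fitted GEE with robust (sandwich) inference."""

    coefficients: pd.Series
    robust_se: pd.Series
    family: str
    corr: str
    alpha: float | None   # estimated AR(1) parameter, if applicable
    qic: float
    n_clusters: int
    result: object        # underlying statsmodels GEEResults

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats
        z = stats.norm.ppf(0.5 + level / 2)
        lo = self.coefficients - z * self.robust_se
        hi = self.coefficients + z * self.robust_se
        return pd.DataFrame({"lower": lo, "upper": hi})

    def exp_coefficients(self) -> pd.Series:
        """HR/RR/OR scale (exponentiated coefficients)."""
        return np.exp(self.coefficients)


def _design(panel: pd.DataFrame, predictors) -> pd.DataFrame:
    """Design matrix with intercept; categorical columns dummy-encoded."""
    X = pd.DataFrame(index=panel.index)
    for p in predictors:
        col = panel[p]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=p, drop_first=True, dtype=float)
            X = pd.concat([X, d], axis=1)
        else:
            X[p] = col.astype(float)
    X.insert(0, "const", 1.0)
    return X


def fit_gee(
    panel: pd.DataFrame,
    response: str,
    predictors,
    family: str = "gaussian",
    corr: str = "ar1",
    cluster: str = "subject_id",
    weights: str | None = None,
    time_index: str = "wave",
) -> GEEFit:
    """Fit a weighted GEE with robust sandwich covariance.

    AR(1) working correlation uses the integer wave index as the distance
    metric (visits closer in time are more correlated); weights are
    normalized to mean 1 and act as frequency weights in the estimating
    equation.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; options: {sorted(_FAMILIES)}")
    if corr not in ("independence", "ar1"):
        raise ValueError(f"unknown working correlation {corr!r}")
    cols = [response, cluster] + list(predictors)
    if weights:
        cols.append(weights)
    if corr == "ar1":
        cols.append(time_index)
    df = panel[list(dict.fromkeys(cols))].dropna().copy()
    if df[cluster].nunique() < 2:
        raise ValueError("GEE requires at least 2 clusters")
    df = df.sort_values([cluster, time_index] if corr == "ar1" else [cluster])

    y = df[response].astype(float)
    X = _design(df, predictors)
    w = None
    if weights:
        w = df[weights].to_numpy(dtype=float)
        w = w / w.mean()
    # grid=True estimates the AR(1) parameter from lag-1 residual moments on
    # the within-cluster visit order (integer wave index), which stays stable
    # when the within-subject correlation approaches 1
    cov_struct = (
        sm.cov_struct.Autoregressive(grid=True)
        if corr == "ar1"
        else sm.cov_struct.Independence()
    )
    kwargs = dict(groups=df[cluster].to_numpy(), family=_FAMILIES[family](),
                  cov_struct=cov_struct, weights=w)
    if corr == "ar1":
        kwargs["time"] = df[time_index].to_numpy(dtype=float)[:, None]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, **kwargs)
        res = model.fit(maxiter=200)
        degenerate = not (np.all(np.isfinite(res.params))
                          and np.all(np.isfinite(res.bse)))
        if degenerate and corr == "ar1":
            # an exact (zero-residual) fit breaks the AR(1) moment estimate;
            # the independence fit is then the GEE solution
            kwargs["cov_struct"] = sm.cov_struct.Independence()
            kwargs.pop("time", None)
            model = sm.GEE(y, X, **kwargs)
            res = model.fit(maxiter=200)
        # scale floor keeps QIC finite for (near-)exact fits; only QIC
        # differences are ever interpreted
        qic = float(res.qic(scale=max(float(res.scale), 1e-12))[0])
    alpha = None
    if corr == "ar1" and isinstance(res.cov_struct, sm.cov_struct.Autoregressive):
        alpha = float(np.atleast_1d(res.cov_struct.dep_params)[0])
    return GEEFit(
        coefficients=res.params,
        robust_se=res.bse,
        family=family,
        corr=corr,
        alpha=alpha,
        qic=qic,
        n_clusters=int(df[cluster].nunique()),
        result=res,
    )


_TIERS = {
    "none": [],
    "demographics": ["sex", "ethnicity", "education"],
    "lifestyle": ["sex", "ethnicity", "education", "smoking", "alcohol"],
    "comorbidities": ["sex", "ethnicity", "education", "smoking", "alcohol",
                      "comorbidity_count"],
}


def aging_trend(
    panel: pd.DataFrame,
    ba_col: str = "anthropoage",
    time_col: str = "years_from_baseline",
    adjustment: str = "none",
    weights: str | None = "survey_weight",
    cluster: str = "subject_id",
) -> dict:
    """Population aging trend: Gaussian GEE of AnthropoAge on follow-up years.

    A slope above 1 means the population accrues more than one year of
    biological age per calendar year ("faster than expected"); below 1,
    slower.  The verdict is read off the robust 95% CI against 1.
    Sequential adjustment tiers: none -> +demographics -> +lifestyle ->
    +comorbidities.
    """
    if adjustment not in _TIERS:
        raise ValueError(f"unknown adjustment tier {adjustment!r}")
    waves_per = panel.groupby(cluster)[time_col].nunique()
    if waves_per.max() < 2:
        raise ValueError("aging trend needs repeated measures (>= 2 waves)")
    predictors = [time_col] + [c for c in _TIERS[adjustment] if c in panel.columns]
    fit = fit_gee(panel, ba_col, predictors, family="gaussian", corr="ar1",
                  cluster=cluster, weights=weights, time_index=time_col)
    beta = float(fit.coefficients[time_col])
    lo, hi = fit.conf_int().loc[time_col]
    if lo > 1.0:
        verdict = "faster"
    elif hi < 1.0:
        verdict = "slower"
    else:
        verdict = "indeterminate"
    return {"fit": fit, "beta": beta, "ci": (float(lo), float(hi)), "verdict": verdict}


def new_onset_model(
    panel: pd.DataFrame,
    outcome: str,
    at_risk_exclusion: bool = True,
    accel_col: str = "accel",
    family: str | None = None,
    adjust=("age", "sex", "ethnicity", "education", "smoking", "alcohol"),
    weights: str | None = "survey_weight",
    cluster: str = "subject_id",
    time_col: str = "years_from_baseline",
) -> dict:
    """New-onset outcome models for age acceleration.

    Fits the three reported contrasts: AnthropoAgeAccel per 1-year increase,
    its interaction with follow-up time, and the binary accelerated-aging
    flag.  Binomial family (odds ratios) for binary outcomes, Poisson (rate
    ratios) for ADL/IADL deficit counts.  With ``at_risk_exclusion`` the
    subjects already reporting the outcome at their baseline wave are
    excluded, so post-baseline reports are new onsets.
    """
    df = panel.copy()
    if family is None:
        family = "poisson" if outcome in ("adl", "iadl") else "binomial"
    baseline_wave = df.groupby(cluster)[time_col].transform("min")
    if at_risk_exclusion:
        base_rows = df[df[time_col] == baseline_wave]
        positive = base_rows.loc[base_rows[outcome] > 0, cluster].unique()
        df = df[~df[cluster].isin(positive)]
        if df.empty:
            raise ValueError("at-risk population is empty")
    # model post-baseline reports only (onset assigned to the reporting wave)
    df = df[df[time_col] > df.groupby(cluster)[time_col].transform("min")]
    if df.empty or df.groupby(cluster).size().max() < 1:
        raise ValueError("outcome must be observed over at least 2 waves")
    adjust = [c for c in adjust if c in df.columns]

    df = df.copy()
    df["_accel_x_time"] = df[accel_col] * df[time_col]
    fits = {}
    fits["per_year"] = fit_gee(df, outcome, [accel_col] + adjust, family=family,
                               corr="ar1", cluster=cluster, weights=weights,
                               time_index=time_col)
    fits["interaction"] = fit_gee(df, outcome, [accel_col, time_col, "_accel_x_time"] + adjust,
                                  family=family, corr="ar1", cluster=cluster,
                                  weights=weights, time_index=time_col)
    df["_accelerated"] = (df[accel_col] > 0).astype(float)
    fits["accelerated"] = fit_gee(df, outcome, ["_accelerated"] + adjust, family=family,
                                  corr="ar1", cluster=cluster, weights=weights,
                                  time_index=time_col)
    # QIC comparison: CA alone vs CA + acceleration
    reduced = fit_gee(df, outcome, ["age"] if "age" in df.columns else adjust,
                      family=family, corr="ar1", cluster=cluster,
                      weights=weights, time_index=time_col)
    full = fit_gee(df, outcome, (["age"] if "age" in df.columns else []) + [accel_col],
                   family=family, corr="ar1", cluster=cluster,
                   weights=weights, time_index=time_col)
    delta_qic = qic_compare(reduced, full)
    n_at_risk = int(df[cluster].nunique())
    return {"fits": fits, "family": family, "delta_qic": delta_qic,
            "n_at_risk": n_at_risk}


def qic_compare(fit_reduced: GEEFit, fit_full: GEEFit) -> float:
    """QIC(full) - QIC(reduced); negative favors the full model.

    For Gaussian fits both QICs are recomputed at the full model's scale so
    the quasi-likelihoods are on one footing.
    """
    if fit_reduced.family != fit_full.family:
        raise ValueError("QIC comparison requires the same variance family")
    if fit_reduced.family == "gaussian":
        scale = fit_full.result.scale
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q_red = float(fit_reduced.result.qic(scale=scale)[0])
            q_full = float(fit_full.result.qic(scale=scale)[0])
        return q_full - q_red
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q_red = float(fit_reduced.result.qic(scale=1.0)[0])
        q_full = float(fit_full.result.qic(scale=1.0)[0])
    return q_full - q_red


def weighted_prevalence_over_time(
    panel: pd.DataFrame,
    flag_col: str = "accelerated",
    time_col: str = "years_from_baseline",
    weight_col: str = "survey_weight",
) -> pd.DataFrame:
    """Survey-weighted prevalence of a flag per wave with a normal-approx CI.

    Horvitz-Thompson-style ratio estimator: p = sum(w*flag)/sum(w); its SE
    uses the linearized variance sum(w^2 (flag-p)^2)/(sum w)^2.  CIs are
    clipped to [0, 1].
    """
    rows = []
    for t, sub in panel.groupby(time_col):
        if len(sub) == 0:
            raise ValueError(f"empty wave at {time_col}={t}")
        w = sub[weight_col].to_numpy(dtype=float)
        f = sub[flag_col].to_numpy(dtype=float)
        p = float(np.sum(w * f) / np.sum(w))
        se = float(np.sqrt(np.sum(w**2 * (f - p) ** 2)) / np.sum(w))
        rows.append((t, p, se, max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se), len(sub)))
    return pd.DataFrame(rows, columns=["time", "prevalence", "se", "ci_low", "ci_high", "n"])
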