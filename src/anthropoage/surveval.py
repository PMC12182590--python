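"""Discrimination and association machinery for right-censored survival data.

Cox models, Kaplan-Meier and the log-rank test are delegated to lifelines;
the censoring-robust discrimination metrics (Uno's IPCW concordance and the
cumulative/dynamic time-dependent AUC) are computed here as explicit
inverse-probability-of-censoring-weighted pair sums, which keeps them
directly comparable with brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

__all__ = [
    "MetricResult",
    "CoxFit",
    "fit_cox",
    "censoring_survival",
    "uno_c",
    "tauc",
    "compare_auc_bootstrap",
    "kaplan_meier",
    "log_rank",
    "ph_test",
]


@dataclass
class MetricResult:
    """Point estimate with optional uncertainty."""

    estimate: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_used: int = 0

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("confidence interval must bracket the estimate")


@dataclass
class CoxFit:
    """Thin wrapper over a fitted lifelines Cox model."""

    model: CoxPHFitter
    terms: list
    strata: list
    robust: bool
    ties: str = "efron"

    @property
    def coefficients(self) -> pd.Series:
        return self.model.params_

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.model.params_)

    @property
    def ses(self) -> pd.Series:
        return self.model.standard_errors_

    def confidence_intervals(self) -> pd.DataFrame:
        return self.model.confidence_intervals_

    @property
    def partial_loglik(self) -> float:
        return float(self.model.log_likelihood_)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.model.predict_partial_hazard(df).pipe(np.log).to_numpy()


def fit_cox(
    panel: pd.DataFrame,
    terms,
    duration_col: str = "time_years",
    event_col: str = "event",
    strata=None,
    weights_col: str | None = None,
    robust: bool = False,
    cluster_col: str | None = None,
    standardize_weights: bool = True,
) -> CoxFit:
    """Weighted, stratified Cox PH fit (Efron ties) via lifelines.

    ``standardize_weights`` divides survey weights by their mean within the
    analysis sample, the convention for standardized survey weights.  A
    covariate that is constant within the sample raises immediately (the
    partial likelihood is flat in it).
    """
    terms = list(terms)
    strata = list(strata) if strata else None
    cols = terms + [duration_col, event_col]
    if strata:
        cols += strata
    if weights_col:
        cols += [weights_col]
    if cluster_col:
        cols += [cluster_col]
    df = panel[cols].dropna().copy()
    if df[event_col].sum() == 0:
        raise ValueError("zero events: Cox partial likelihood undefined")
    for t in terms:
        if df[t].dtype == object:
            raise ValueError(f"term {t!r} is non-numeric; encode it first")
        if np.isclose(df[t].std(ddof=0), 0.0):
            raise ValueError(f"covariate {t!r} is constant; coefficient not identified")
    if weights_col and standardize_weights:
        df[weights_col] = df[weights_col] / df[weights_col].mean()
    import warnings as _warnings

    cph = CoxPHFitter()
    with _warnings.catch_warnings():
        # survey weights are intentionally non-integer; robust/cluster SEs
        # are requested explicitly where inference is reported
        _warnings.filterwarnings("ignore", message=".*weights are not integers.*")
        cph.fit(
            df,
            duration_col=duration_col,
            event_col=event_col,
            strata=strata,
            weights_col=weights_col,
            cluster_col=cluster_col,
            robust=robust or cluster_col is not None,
            formula=" + ".join(terms),
        )
    return CoxFit(model=cph, terms=terms, strata=strata or [],
                  robust=robust or cluster_col is not None)


# ---------------------------------------------------------------------------
# IPCW machinery


def censoring_survival(time, event):
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Computed on the pooled sample, treating censorings as the events.
    Returns a step-function evaluator ``G(t)`` (right-continuous) and a
    left-limit evaluator ``G(t-)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    ts = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def G(t):
        idx = np.searchsorted(ts, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])

    def G_minus(t):
        idx = np.searchsorted(ts, np.asarray(t, dtype=float), side="left") - 1
        return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])

    return G, G_minus


def uno_c(
    linear_predictor,
    time,
    event,
    tau: float | None = None,
    n_boot: int = 0,
    seed: int | None = None,
    g_floor: float | None = None,
) -> MetricResult:
    """Uno's IPCW concordance for right-censored data.

    Comparable pairs are (i, j) with subject i observed to die before
    ``tau`` and ``t_i < t_j``; each pair is weighted by ``1/G(t_i-)^2``
    where G is the censoring-survival KM on the pooled sample.  Ties in the
    predictor count 1/2.  With no censoring and ``tau`` at the maximum
    time this reduces exactly to Harrell's C by pair counting.

    ``n_boot > 0`` adds a nonparametric bootstrap SE and normal CI.
    ``g_floor`` optionally truncates the censoring weights at G >= floor.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if tau is None:
        tau = float(time.max())

    def _estimate(lp, time, event):
        _, G_minus = censoring_survival(time, event)
        g = np.asarray(G_minus(time), dtype=float)
        if g_floor is not None:
            g = np.maximum(g, g_floor)
        is_case = (event == 1) & (time < tau)
        num = 0.0
        den = 0.0
        idx = np.flatnonzero(is_case)
        for i in idx:
            later = time > time[i]
            if not later.any():
                continue
            w = 1.0 / g[i] ** 2
            conc = np.sum(lp[i] > lp[later]) + 0.5 * np.sum(lp[i] == lp[later])
            num += w * conc
            den += w * np.sum(later)
        if den == 0:
            raise ValueError("no comparable pairs before tau")
        return num / den

    est = _estimate(lp, time, event)
    se = ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(time)
        reps = []
        for _ in range(n_boot):
            b = rng.integers(0, n, n)
            try:
                reps.append(_estimate(lp[b], time[b], event[b]))
            except ValueError:
                continue
        se = float(np.std(reps, ddof=1))
        ci = (est - 1.96 * se, est + 1.96 * se)
    return MetricResult(estimate=float(est), se=se,
                        ci_low=None if ci is None else ci[0],
                        ci_high=None if ci is None else ci[1],
                        n_used=len(time))


def tauc(
    linear_predictor,
    time,
    event,
    eval_times,
    g_floor: float | None = None,
) -> pd.DataFrame:
    """Cumulative-case / dynamic-control IPCW AUC at each evaluation time.

    Cases at horizon tau are subjects with an observed event at or before
    tau (weight 1/G(t_i-)); controls are subjects still under observation
    past tau (weight 1/G(tau)).  A time with no cases or no controls is
    returned with AUC = NaN rather than fabricated.

    Returns a DataFrame with columns ``time``, ``auc``, ``n_cases``,
    ``n_controls``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _, G_minus = censoring_survival(time, event)
    g_at = np.asarray(G_minus(time), dtype=float)
    if g_floor is not None:
        g_at = np.maximum(g_at, g_floor)

    rows = []
    for tau in np.atleast_1d(np.asarray(eval_times, dtype=float)):
        cases = (event == 1) & (time <= tau)
        controls = time > tau
        if not cases.any() or not controls.any():
            rows.append((tau, np.nan, int(cases.sum()), int(controls.sum())))
            continue
        w_case = 1.0 / g_at[cases]
        g_tau = float(np.asarray(G_minus(tau + 1e-12)))
        if g_floor is not None:
            g_tau = max(g_tau, g_floor)
        w_ctrl = np.full(controls.sum(), 1.0 / g_tau)
        lc, lk = lp[cases], lp[controls]
        # pairwise comparison, chunked to bound memory
        num = 0.0
        for start in range(0, len(lc), 512):
            sl = slice(start, start + 512)
            gt = (lc[sl, None] > lk[None, :]).astype(float)
            gt += 0.5 * (lc[sl, None] == lk[None, :])
            num += float(np.sum(w_case[sl, None] * w_ctrl[None, :] * gt))
        den = float(w_case.sum() * w_ctrl.sum())
        rows.append((tau, num / den, int(cases.sum()), int(controls.sum())))
    return pd.DataFrame(rows, columns=["time", "auc", "n_cases", "n_controls"])


def delta_tauc(lp_a, lp_b, time, event, eval_times, **kw) -> pd.DataFrame:
    """tAUC(model A) - tAUC(model B) on a shared evaluation grid."""
    a = tauc(lp_a, time, event, eval_times, **kw)
    b = tauc(lp_b, time, event, eval_times, **kw)
    out = a[["time"]].copy()
    out["auc_a"] = a["auc"]
    out["auc_b"] = b["auc"]
    out["delta"] = a["auc"] - b["auc"]
    return out


def compare_auc_bootstrap(
    lp_a,
    lp_b,
    time,
    event,
    horizon: float,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Paired bootstrap test for a difference in IPCW AUC at one horizon.

    Resamples subjects with replacement, recomputes both AUCs on each
    resample, and returns ``(delta, se, p)`` with a two-sided normal
    p-value.  Degenerate resamples (no cases or no controls at the horizon)
    are dropped; more than 10% dropped is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    lp_a = np.asarray(lp_a, dtype=float)
    lp_b = np.asarray(lp_b, dtype=float)
    if lp_a.shape != lp_b.shape:
        raise ValueError("both predictors must cover the same subjects")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    auc_a = float(tauc(lp_a, time, event, [horizon])["auc"].iloc[0])
    auc_b = float(tauc(lp_b, time, event, [horizon])["auc"].iloc[0])
    delta = auc_a - auc_b

    rng = np.random.default_rng(seed)
    n = len(time)
    deltas = []
    dropped = 0
    for _ in range(n_boot):
        b = rng.integers(0, n, n)
        ta = tauc(lp_a[b], time[b], event[b], [horizon])["auc"].iloc[0]
        tb = tauc(lp_b[b], time[b], event[b], [horizon])["auc"].iloc[0]
        if np.isnan(ta) or np.isnan(tb):
            dropped += 1
            continue
        deltas.append(ta - tb)
    if dropped > 0.1 * n_boot:
        raise ValueError(f"{dropped}/{n_boot} bootstrap resamples degenerate")
    deltas = np.asarray(deltas)
    se = float(np.std(deltas, ddof=1))
    if se == 0.0:
        p = 1.0
    else:
        z = delta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"delta": delta, "se": se, "p": p,
            "auc_a": auc_a, "auc_b": auc_b, "n_dropped": dropped}


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / PH diagnostics


def kaplan_meier(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns ``{group_label: step function DataFrame(time, survival)}``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.zeros(len(time), dtype=int) if groups is None else np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(time[m], event_observed=event[m])
        sf = km.survival_function_
        out[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return out


def log_rank(time, event, groups):
    """Log-rank test across any number of groups (e.g. accelerated aging
    crossed with multimorbidity -> 4 groups).  Returns (chi2, p, df)."""
    groups = np.asarray(groups)
    counts = pd.Series(groups).value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), groups,
                                    np.asarray(event, dtype=int))
    return float(res.test_statistic), float(res.p_value), int(res.degrees_of_freedom)


def ph_test(cox_fit: CoxFit, panel: pd.DataFrame, time_transform: str = "identity"):
    """Proportional-hazards diagnostic via scaled Schoenfeld residuals.

    Per-covariate score test of correlation between the scaled Schoenfeld
    residuals and (transformed) event time; the global statistic sums the
    per-covariate chi-squares (df = number of covariates).  Returns a dict
    with per-covariate p-values, the global p, and the residual series for
    plotting.

    Requires at least two events (a single event leaves the residual
    variance undefined).
    """
    df = panel.dropna(subset=cox_fit.terms).copy()
    model = cox_fit.model
    ev_col = model.event_col
    if df[ev_col].sum() < 2:
        raise ValueError("PH test undefined with fewer than 2 events")
    res = proportional_hazard_test(model, df, time_transform=time_transform)
    summary = res.summary  # index: (variable, transform) or variable
    per_cov = {}
    chi2_total = 0.0
    for var in cox_fit.terms:
        row = summary.loc[var]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        per_cov[var] = float(row["p"])
        chi2_total += float(row["test_statistic"])
    k = len(cox_fit.terms)
    global_p = float(stats.chi2.sf(chi2_total, df=k))
    resid = model.compute_residuals(df, "scaled_schoenfeld")
    return {"per_covariate_p": per_cov, "global_p": global_p,
            "global_chi2": chi2_total, "df": k, "residuals": resid}
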