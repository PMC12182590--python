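"""Sex-stratified Gompertz proportional-hazards models and the AnthropoAge
biological-age transform.

Model
-----
The hazard is ``h(t) = exp(xb) * exp(gamma * t)`` with *t* in **months**
since baseline; ``gamma`` is the Gompertz shape and the intercept of ``xb``
the (log) rate.  Two models are fit per sex:

1. chronological age (CA, in years) only:
   ``xb = beta0 + beta1 * CA``, single shape ``gamma0``;
2. CA plus non-linear anthropometry:
   ``xb = rate + b_ca*CA + b1*ln(BMI) + b2*ln(BMI)^2 + b3*WHtR^(1/3)``,
   with a separate shape ``gamma_j`` per race/ethnicity group.

AnthropoAge is the age at which model 1 predicts the same 10-year
(120-month) death probability as model 2 predicts for the individual:
matching the two Gompertz CDFs at horizon *t* and solving for age gives
the closed form

    AnthropoAge = ( ln( -ln(1-M) / ((exp(gamma0*t)-1)/gamma0) ) - beta0 ) / beta1

where ``M`` is the model-2 CDF at the horizon.  AnthropoAgeAccel is the
residual of AnthropoAge regressed on CA within sex; values > 0 define
accelerated aging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GompertzCAFit",
    "GompertzAnthroFit",
    "BAResult",
    "RiskHorizon",
    "ANTHRO_BASIS",
    "fit_gompertz",
    "gompertz_cdf",
    "gompertz_loglik",
    "anthropoage",
    "anthropoage_batch",
    "anthropoage_accel",
    "write_coefficients",
    "read_coefficients",
]

#: covariate basis of the anthropometry model, in column order
ANTHRO_BASIS = ("ca_years", "log_bmi", "log_bmi_sq", "whtr_cbrt")


@dataclass(frozen=True)
class RiskHorizon:
    """Prediction horizon for the CDF matching, in months (default 10 years)."""

    t: float = 120.0

    def __post_init__(self):
        if not (self.t > 0):
            raise ValueError(f"horizon must be positive, got {self.t}")


@dataclass
class GompertzCAFit:
    """Gompertz PH fit with chronological age as the only covariate.

    ``gamma0`` is per month, ``beta1`` per year of age; ``covariance`` is the
    observed-information covariance of (gamma0, beta0, beta1).
    """

    gamma0: float
    beta0: float
    beta1: float
    sex: str
    loglik: float
    covariance: np.ndarray | None = None
    time_unit: str = "months"

    @property
    def param_names(self):
        return ("gamma0", "beta0", "beta1")

    def linear_predictor(self, ca_years):
        return self.beta0 + self.beta1 * np.asarray(ca_years, dtype=float)


@dataclass
class GompertzAnthroFit:
    """Gompertz PH fit on age + anthropometry with per-ethnicity shapes.

    ``gammas`` maps race/ethnicity label -> shape (per month).  ``coefs``
    maps basis-column name -> coefficient; the basis is ``ANTHRO_BASIS``
    (CA in years, ln BMI, (ln BMI)^2, cube-root WHtR) plus ``rate`` for the
    intercept.
    """

    gammas: dict[str, float]
    rate: float
    coefs: dict[str, float]
    sex: str
    loglik: float
    covariance: np.ndarray | None = None
    basis: tuple[str, ...] = ANTHRO_BASIS
    time_unit: str = "months"

    @property
    def param_names(self):
        return tuple(f"gamma[{g}]" for g in self.gammas) + ("rate",) + tuple(self.coefs)

    def linear_predictor(self, ca_years, bmi, whtr):
        ca = np.asarray(ca_years, dtype=float)
        lb = np.log(np.asarray(bmi, dtype=float))
        wc = np.cbrt(np.asarray(whtr, dtype=float))
        return (
            self.rate
            + self.coefs["ca_years"] * ca
            + self.coefs["log_bmi"] * lb
            + self.coefs["log_bmi_sq"] * lb**2
            + self.coefs["whtr_cbrt"] * wc
        )

    def shape_for(self, ethnicity):
        eth = np.asarray(ethnicity, dtype=object)
        unknown = sorted(set(eth.ravel()) - set(self.gammas))
        if unknown:
            raise KeyError(
                f"no fitted shape for ethnicity group(s) {unknown}; "
                f"known groups: {sorted(self.gammas)}"
            )
        return np.vectorize(self.gammas.__getitem__, otypes=[float])(eth)


@dataclass(frozen=True)
class BAResult:
    """Per-row biological age summary."""

    anthropoage: float
    accel: float
    accelerated: bool
    accel_quartile: int | None = None


# ---------------------------------------------------------------------------
# likelihood


def _cum_hazard_factor(gamma, t):
    """(exp(gamma*t) - 1)/gamma, stable as gamma -> 0 (-> t)."""
    gamma = np.asarray(gamma, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.where(
        np.abs(gamma) > 1e-12,
        np.expm1(gamma * t) / np.where(np.abs(gamma) > 1e-12, gamma, 1.0),
        t * (1.0 + gamma * t / 2.0),
    )
    return out


def gompertz_loglik(gamma, xb, time, event, weights=None):
    """Right-censored Gompertz PH log-likelihood.

    ``sum_i w_i * [ d_i*(xb_i + gamma_i*t_i) - exp(xb_i)*(exp(gamma_i*t_i)-1)/gamma_i ]``
    with time in the model's unit (months).  ``gamma`` may be scalar or
    per-observation (group-specific shapes).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    xb = np.asarray(xb, dtype=float)
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), time.shape)
    cum = np.exp(xb) * _cum_hazard_factor(gamma, time)
    return float(np.sum(w * (event * (xb + gamma * time) - cum)))


def _negloglik_and_grad(theta, X, time, event, weights, group_idx, n_groups,
                        log_gamma=False):
    """Negative log-likelihood and gradient; theta = (gamma_1..gamma_G, betas).

    With ``log_gamma`` the shape block of theta is log-transformed, which
    puts all parameters on comparable scales for quasi-Newton methods.
    """
    gammas = np.exp(theta[:n_groups]) if log_gamma else theta[:n_groups]
    betas = theta[n_groups:]
    g = gammas[group_idx]
    xb = X @ betas
    egt = np.exp(g * time)
    cumfac = np.where(np.abs(g) > 1e-12, (egt - 1.0) / g, time)
    A = np.exp(xb)
    ll_terms = event * (xb + g * time) - A * cumfac
    ll = np.sum(weights * ll_terms)

    # d/dbeta_k: sum w * x_k * (d - A*cumfac)
    common = weights * (event - A * cumfac)
    grad_beta = X.T @ common
    # d/dgamma: sum w * (d*t - A * (t*e^{gt}/g - (e^{gt}-1)/g^2))
    dcum = np.where(
        np.abs(g) > 1e-12,
        time * egt / g - (egt - 1.0) / g**2,
        time**2 / 2.0,
    )
    gterm = weights * (event * time - A * dcum)
    grad_gamma = np.bincount(group_idx, weights=gterm, minlength=n_groups)
    if log_gamma:
        grad_gamma = grad_gamma * gammas  # chain rule d/dlog(gamma)
    grad = np.concatenate([grad_gamma, grad_beta])
    return -ll, -grad


def _numerical_hessian(fun, theta, eps=1e-5):
    """Hessian by central differences of the analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for k in range(p):
        step = eps * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tm = theta.copy()
        tp[k] += step
        tm[k] -= step
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, k] = (gp - gm) / (2.0 * step)
    return (H + H.T) / 2.0


def fit_gompertz(
    time,
    event,
    covariates,
    sex: str = "",
    shape_groups=None,
    weights=None,
    covariate_names=None,
    max_iter: int = 500,
    tol: float = 1e-9,
):
    """Maximum-likelihood Gompertz PH fit for one sex stratum.

    Parameters
    ----------
    time
        Follow-up in **months**, > 0.
    event
        1 = died, 0 = right-censored.
    covariates
        (n, p) design matrix *without* intercept; an intercept (the log rate)
        is always included.  For the CA-only model pass a single column of
        age in years; for the anthropometry model pass the ``ANTHRO_BASIS``
        columns.
    shape_groups
        Optional length-n labels (race/ethnicity); one shape parameter is
        fit per group.  ``None`` fits a single shape.
    weights
        Optional positive case weights.

    Returns ``GompertzCAFit`` when covariates has one column and no shape
    groups, else ``GompertzAnthroFit``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    n, p = X.shape
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be positive")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if event.sum() == 0:
        raise ValueError(f"zero events in stratum {sex!r}: Gompertz MLE undefined")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    if shape_groups is None:
        group_labels = ["_all"]
        group_idx = np.zeros(n, dtype=int)
    else:
        sg = np.asarray(shape_groups, dtype=object)
        group_labels = sorted(set(sg.tolist()))
        lab_to_idx = {g: i for i, g in enumerate(group_labels)}
        group_idx = np.array([lab_to_idx[g] for g in sg], dtype=int)
        for gl in group_labels:
            if event[sg == gl].sum() == 0:
                raise ValueError(f"zero events in shape group {gl!r}")
    G = len(group_labels)

    # center covariates (removes the rate/age collinearity) and optimize the
    # shape on the log scale so all parameters are comparably scaled
    means = np.average(X, axis=0, weights=w)
    Xc = X - means
    Xi = np.column_stack([np.ones(n), Xc])  # intercept = log rate (centered)

    # crude exponential-model start: rate ~ events / person-time
    rate0 = math.log(max(event.sum(), 1.0) / np.sum(w * time))

    fun = lambda th: _negloglik_and_grad(
        th, Xi, time, event, w, group_idx, G, log_gamma=True
    )
    lo, hi = math.log(1e-8), math.log(2.0)
    bounds = [(lo, hi)] * G + [(None, None)] * (p + 1)
    res = None
    for g_start in (0.003, 0.01, 0.001, 0.03):
        th0 = np.concatenate([np.full(G, math.log(g_start)), [rate0], np.zeros(p)])
        cand = optimize.minimize(
            fun,
            th0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        if res is None or cand.fun < res.fun:
            res = cand
        at_boundary = np.any(cand.x[:G] <= lo + 0.5) or np.any(cand.x[:G] >= hi - 1e-3)
        if cand.success and not at_boundary and cand.fun <= res.fun + 1e-9:
            res = cand
            break
    if not res.success and "ABNORMAL" not in str(res.message):
        raise RuntimeError(f"Gompertz MLE did not converge: {res.message}")
    for gi in range(G):
        if res.x[gi] <= lo + 0.5 or res.x[gi] >= hi - 1e-3:
            raise RuntimeError(
                f"shape parameter for group {group_labels[gi]!r} driven to the "
                f"boundary ({math.exp(res.x[gi]):.3g}); the Gompertz model is "
                "not identified on these data"
            )
    H = _numerical_hessian(fun, res.x)
    try:
        cov_internal = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_internal = np.full((res.x.size, res.x.size), np.nan)
    loglik = -res.fun

    # back-transform: gamma = exp(loggamma); rate = rate_c - sum(beta*mean)
    theta = res.x.copy()
    theta[:G] = np.exp(theta[:G])
    betas = theta[G + 1:]
    theta[G] = theta[G] - float(betas @ means)
    # delta method: J maps internal (loggamma, rate_c, beta) -> natural
    J = np.eye(theta.size)
    for gi in range(G):
        J[gi, gi] = theta[gi]  # d gamma / d loggamma
    J[G, G + 1:] = -means      # d rate / d beta
    cov = J @ cov_internal @ J.T

    if shape_groups is None and p == 1:
        return GompertzCAFit(
            gamma0=float(theta[0]),
            beta0=float(theta[1]),
            beta1=float(theta[2]),
            sex=sex,
            loglik=loglik,
            covariance=cov,
        )
    names = (
        list(covariate_names)
        if covariate_names is not None
        else list(ANTHRO_BASIS[:p]) if p <= len(ANTHRO_BASIS) else [f"x{i}" for i in range(p)]
    )
    return GompertzAnthroFit(
        gammas={g: float(theta[i]) for i, g in enumerate(group_labels)},
        rate=float(theta[G]),
        coefs={nm: float(theta[G + 1 + i]) for i, nm in enumerate(names)},
        sex=sex,
        loglik=loglik,
        covariance=cov,
        basis=tuple(names),
    )


# ---------------------------------------------------------------------------
# CDF and the biological-age transform


def gompertz_cdf(gamma, xb, horizon: RiskHorizon = RiskHorizon()):
    """Gompertz death probability by the horizon: 1 - exp(-e^xb*(e^(g t)-1)/g).

    ``gamma`` may be scalar or array (per-observation shapes); stable in the
    exponential limit gamma -> 0.
    """
    t = horizon.t if isinstance(horizon, RiskHorizon) else float(horizon)
    if not t > 0:
        raise ValueError("horizon must be positive")
    xb = np.asarray(xb, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> inf -> CDF 1, correct
        cum = np.exp(xb) * _cum_hazard_factor(gamma, t)
    return -np.expm1(-cum)


def anthropoage(
    ca_fit: GompertzCAFit,
    M,
    horizon: RiskHorizon = RiskHorizon(),
    clamp_eps: float | None = None,
):
    """Convert a 10-year death probability to an age-scale biological age.

    Solves ``CDF_CA(t, age) = M`` for age under the CA-only fit; the closed
    form is ``(ln(-ln(1-M) / ((e^(g0 t)-1)/g0)) - beta0) / beta1``.

    ``M`` must lie strictly inside (0, 1).  With ``clamp_eps`` set, values
    outside are clamped into ``[clamp_eps, 1-clamp_eps]`` and the number of
    clamped entries is reported via a ``UserWarning``; by default they raise.
    """
    t = horizon.t if isinstance(horizon, RiskHorizon) else float(horizon)
    M = np.asarray(M, dtype=float)
    scalar = M.ndim == 0
    M = np.atleast_1d(M).astype(float)
    bad = ~((M > 0.0) & (M < 1.0))
    if bad.any():
        if clamp_eps is None:
            raise ValueError(
                f"{int(bad.sum())} probability value(s) outside the open "
                "interval (0, 1); pass clamp_eps to clamp"
            )
        import warnings

        warnings.warn(f"clamped {int(bad.sum())} probability value(s) to "
                      f"[{clamp_eps}, 1-{clamp_eps}]", stacklevel=2)
        M = np.clip(M, clamp_eps, 1.0 - clamp_eps)
    if ca_fit.beta1 == 0:
        raise ValueError("beta1 (age coefficient) must be nonzero")
    denom = _cum_hazard_factor(ca_fit.gamma0, t)
    ba = (np.log(-np.log1p(-M) / denom) - ca_fit.beta0) / ca_fit.beta1
    return float(ba[0]) if scalar else ba


def anthropoage_batch(
    panel: pd.DataFrame,
    ca_fits: dict[str, GompertzCAFit],
    anthro_fits: dict[str, GompertzAnthroFit],
    horizon: RiskHorizon = RiskHorizon(),
    clamp_eps: float | None = None,
) -> np.ndarray:
    """AnthropoAge for every panel row using the sex-matching model pair.

    The panel needs columns ``sex``, ``ethnicity``, ``age``, ``bmi``,
    ``whtr``.  For each row the anthropometry model of the row's sex builds
    the linear predictor with the row's ethnicity shape, the 120-month CDF
    gives the predicted risk, and the CA-only model of the same sex inverts
    it onto the age scale.
    """
    for col in ("sex", "ethnicity", "age", "bmi", "whtr"):
        if col not in panel.columns:
            raise KeyError(f"panel is missing required column {col!r}")
    out = np.full(len(panel), np.nan)
    for sex_label, sub in panel.groupby("sex", sort=False):
        if sex_label not in ca_fits or sex_label not in anthro_fits:
            raise KeyError(f"no fitted models for sex stratum {sex_label!r}")
        afit = anthro_fits[sex_label]
        xb = afit.linear_predictor(sub["age"], sub["bmi"], sub["whtr"])
        gam = afit.shape_for(sub["ethnicity"])
        M = gompertz_cdf(gam, xb, horizon)
        out[panel.index.get_indexer(sub.index)] = anthropoage(
            ca_fits[sex_label], M, horizon, clamp_eps=clamp_eps
        )
    return out


# ---------------------------------------------------------------------------
# age-acceleration residual


def _ols_residuals(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def anthropoage_accel(
    panel: pd.DataFrame,
    mode: str = "study-intercepts",
    ba_col: str = "anthropoage",
    quartiles: bool = True,
) -> pd.DataFrame:
    """AnthropoAgeAccel: the residual of AnthropoAge on chronological age.

    Computed separately per sex.  Modes:

    * ``pooled-ols-by-sex`` — plain OLS of AnthropoAge on CA;
    * ``study-intercepts`` — OLS with fixed study intercepts (default; with
      a handful of studies this is numerically indistinguishable from a
      study random intercept and exactly testable);
    * ``mixed`` — linear mixed model.  With repeated measures: random
      intercept per participant with study as fixed effect; with one row
      per subject: random intercept per study.

    Returns a copy of the panel with ``accel``, ``accelerated`` and (when
    ``quartiles``) per-sex ``accel_quartile`` (1-4, unweighted sample
    quartiles, linear interpolation).
    """
    if mode not in ("pooled-ols-by-sex", "study-intercepts", "mixed"):
        raise ValueError(f"unknown residualization mode {mode!r}")
    for col in ("sex", "age", ba_col):
        if col not in panel.columns:
            raise KeyError(f"panel is missing required column {col!r}")
    if mode != "pooled-ols-by-sex" and "study" not in panel.columns:
        raise KeyError("study column required for study-aware residualization")

    out = panel.copy()
    accel = np.full(len(out), np.nan)
    for sex_label, sub in out.groupby("sex", sort=False):
        if len(sub) < 3:
            raise ValueError(f"sex stratum {sex_label!r} has fewer than 3 rows")
        y = sub[ba_col].to_numpy(dtype=float)
        ca = sub["age"].to_numpy(dtype=float)
        if mode == "pooled-ols-by-sex":
            X = np.column_stack([np.ones(len(sub)), ca])
            res = _ols_residuals(y, X)
        elif mode == "study-intercepts":
            dummies = pd.get_dummies(sub["study"], dtype=float).to_numpy()
            X = np.column_stack([dummies, ca])
            res = _ols_residuals(y, X)
        else:
            res = _mixed_residuals(sub, y, ca)
        accel[out.index.get_indexer(sub.index)] = res
    # a residual below 1e-9 years (~30 ms of age) is numerical noise; snap it
    # to zero so the accelerated flag is stable on exact-identity inputs
    accel[np.abs(accel) < 1e-9] = 0.0
    out["accel"] = accel
    out["accelerated"] = out["accel"] > 0
    if quartiles:
        q = np.full(len(out), 0, dtype=int)
        for _, sub in out.groupby("sex", sort=False):
            edges = np.quantile(sub["accel"], [0.25, 0.5, 0.75])
            q[out.index.get_indexer(sub.index)] = 1 + np.searchsorted(
                edges, sub["accel"], side="left"
            )
        out["accel_quartile"] = q
    return out


def _mixed_residuals(sub: pd.DataFrame, y, ca):
    """Mixed-model residualization (subject or study random intercept)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"ba": y, "ca": ca})
    repeated = (
        "subject_id" in sub.columns
        and sub["subject_id"].duplicated().any()
    )
    if repeated:
        df["study"] = sub["study"].to_numpy()
        df["subject_id"] = sub["subject_id"].to_numpy()
        model = smf.mixedlm("ba ~ ca + C(study)", df, groups=df["subject_id"])
    else:
        df["study"] = sub["study"].to_numpy()
        model = smf.mixedlm("ba ~ ca", df, groups=df["study"])
    fit = model.fit(reml=True, method="lbfgs")
    # remove the fixed trend AND the predicted random intercepts
    fixed = np.asarray(fit.fittedvalues, dtype=float)
    ranef = fit.random_effects
    groups = df["subject_id"] if repeated else df["study"]
    rint = np.array([float(np.asarray(ranef[g]).ravel()[0]) for g in groups])
    return np.asarray(df["ba"], dtype=float) - fixed - rint


# ---------------------------------------------------------------------------
# coefficient file I/O


def write_coefficients(path, ca_fits: dict, anthro_fits: dict) -> None:
    """Serialize fitted models as delimited text (tab-separated).

    Header lines carry sex, time unit, basis and shape groups so a loaded
    model can never be applied with mismatched conventions; name/value pairs
    follow with full float precision, round-tripping bit-exactly.
    """
    lines = []
    for sex, fit in ca_fits.items():
        lines.append(f"#model\tca_only\tsex={sex}\ttime_unit={fit.time_unit}")
        for nm, v in zip(("gamma0", "beta0", "beta1"), (fit.gamma0, fit.beta0, fit.beta1)):
            lines.append(f"{nm}\t{float(v)!r}")
        lines.append(f"loglik\t{float(fit.loglik)!r}")
    for sex, fit in anthro_fits.items():
        groups = ",".join(sorted(fit.gammas))
        lines.append(
            f"#model\tanthro\tsex={sex}\ttime_unit={fit.time_unit}"
            f"\tbasis={','.join(fit.basis)}\tshape_groups={groups}"
        )
        for g in sorted(fit.gammas):
            lines.append(f"gamma[{g}]\t{float(fit.gammas[g])!r}")
        lines.append(f"rate\t{float(fit.rate)!r}")
        for nm in fit.basis:
            lines.append(f"{nm}\t{float(fit.coefs[nm])!r}")
        lines.append(f"loglik\t{float(fit.loglik)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_coefficients(path):
    """Load coefficient files written by :func:`write_coefficients`.

    Returns ``(ca_fits, anthro_fits)`` keyed by sex label.
    """
    ca_fits: dict[str, GompertzCAFit] = {}
    anthro_fits: dict[str, GompertzAnthroFit] = {}
    blocks: list[tuple[dict, dict]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#model"):
                parts = line.split("\t")
                meta = {"kind": parts[1]}
                for p in parts[2:]:
                    k, _, v = p.partition("=")
                    meta[k] = v
                blocks.append((meta, {}))
            else:
                nm, _, val = line.partition("\t")
                blocks[-1][1][nm] = float(val)
    for meta, vals in blocks:
        sex = meta["sex"]
        if meta["kind"] == "ca_only":
            ca_fits[sex] = GompertzCAFit(
                gamma0=vals["gamma0"],
                beta0=vals["beta0"],
                beta1=vals["beta1"],
                sex=sex,
                loglik=vals.get("loglik", float("nan")),
                time_unit=meta.get("time_unit", "months"),
            )
        else:
            basis = tuple(meta["basis"].split(","))
            groups = meta["shape_groups"].split(",")
            anthro_fits[sex] = GompertzAnthroFit(
                gammas={g: vals[f"gamma[{g}]"] for g in groups},
                rate=vals["rate"],
                coefs={nm: vals[nm] for nm in basis},
                sex=sex,
                loglik=vals.get("loglik", float("nan")),
                basis=basis,
                time_unit=meta.get("time_unit", "months"),
            )
    return ca_fits, anthro_fits
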