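"""End-to-end study replica on any compliant participant-visit panel.

Stages: schema validation -> eligibility -> sex-stratified Gompertz fits ->
AnthropoAge / AnthropoAgeAccel -> discrimination (Uno's c, tAUC, bootstrap
AUC comparison) and decision curves -> accelerated-aging Cox and
Kaplan-Meier -> GEE aging trends and accelerated-aging prevalence ->
new-onset outcome grid with delta-QIC.  Every stage writes a tidy delimited
table into the output directory; a manifest records config hash, seeds and
row counts so reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anthropometrics as am
from . import dca, gee, surveval, synth
from . import gompertz as gz

__all__ = ["PipelineConfig", "validate_schema", "run_pipeline"]

log = logging.getLogger("anthropoage.pipeline")

ADJUST_TIERS = {
    "unadjusted": [],
    "age": ["age"],
    "full": ["age", "education", "smoking", "alcohol", "comorbidity_count"],
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; serialized next to the outputs."""

    panel_path: str | None = None          # None -> generate synthetically
    coef_source: str = "self-fit"          # "self-fit" or a coefficient file path
    horizon_months: float = 120.0
    accel_mode: str = "study-intercepts"
    eval_horizon_years: float = 8.0        # tAUC / AUC-comparison horizon
    tauc_grid_years: tuple = (2.0, 4.0, 6.0, 8.0)
    bootstrap_b: int = 200
    seed: int = 1
    truncate_follow_up_years: float | None = None   # sensitivity analysis
    out_dir: str = "pipeline_out"
    synth_n_subjects: int = 1200
    synth_studies: dict | None = None

    def validate(self) -> None:
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.accel_mode not in ("pooled-ols-by-sex", "study-intercepts", "mixed"):
            raise ValueError(f"unknown accel_mode {self.accel_mode!r}")
        if self.bootstrap_b < 100:
            raise ValueError("bootstrap_b must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


SCHEMA = {
    "subject_id": "id",
    "study": "category",
    "wave": "int",
    "age": (0.0, 120.0),
    "sex": "category",
    "ethnicity": "category",
    "height_cm": (50.0, 250.0),
    "weight_kg": (10.0, 350.0),
    "waist_cm": (20.0, 250.0),
    "survey_weight": (0.0, np.inf),
    "time_years": (0.0, 60.0),
    "event": "binary",
}


def validate_schema(panel: pd.DataFrame) -> dict:
    """Column presence / type / plausibility / uniqueness checks.

    Returns ``{"ok": bool, "diagnostics": [...]}``; a duplicated
    (subject_id, wave) pair or a height column whose median is under 3
    (metres instead of centimetres) both fail.
    """
    diags = []
    for col, rule in SCHEMA.items():
        if col not in panel.columns:
            diags.append(f"missing column: {col}")
            continue
        s = panel[col]
        if isinstance(rule, tuple):
            vals = pd.to_numeric(s, errors="coerce").dropna()
            lo, hi = rule
            bad = ((vals < lo) | (vals > hi)).sum()
            if bad:
                diags.append(f"{col}: {bad} value(s) outside plausible range [{lo}, {hi}]")
        elif rule == "binary":
            vals = set(pd.unique(s.dropna()))
            if not vals <= {0, 1, True, False}:
                diags.append(f"{col}: non-binary values {sorted(vals)[:5]}")
    if {"subject_id", "wave"} <= set(panel.columns):
        dup = panel.duplicated(subset=["subject_id", "wave"])
        if dup.any():
            first = panel.loc[dup, ["subject_id", "wave"]].iloc[0]
            diags.append(
                "duplicated (subject_id, wave) pair: "
                f"({first['subject_id']}, {first['wave']})"
            )
    return {"ok": not diags, "diagnostics": diags}


def _encode_for_cox(df: pd.DataFrame, cols):
    """Dummy-encode any categorical adjustment columns, return new term list."""
    out = df.copy()
    terms = []
    for c in cols:
        if c not in out.columns:
            continue
        if out[c].dtype == object:
            d = pd.get_dummies(out[c], prefix=c, drop_first=True, dtype=float)
            # sanitize names for formula use
            d.columns = [cn.replace("/", "_").replace(" ", "_").replace("-", "_")
                         for cn in d.columns]
            out = pd.concat([out, d], axis=1)
            terms += list(d.columns)
        else:
            terms.append(c)
    return out, terms


def run_pipeline(config: PipelineConfig, panel: pd.DataFrame | None = None) -> dict:
    """Run all stages; returns a dict of output tables (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    # ---- stage 0: input ---------------------------------------------------
    if panel is None:
        if config.panel_path:
            panel = synth.read_panel(config.panel_path)
        else:
            scfg = synth.SynthConfig(
                n_subjects=config.synth_n_subjects,
                studies=config.synth_studies or dict(synth.DEFAULT_STUDIES),
                seed=config.seed,
            )
            panel, _ = synth.generate_panel(scfg)
    check = validate_schema(panel)
    if not check["ok"]:
        raise ValueError("panel failed schema validation: " + "; ".join(check["diagnostics"]))
    log.info("stage=input rows=%d subjects=%d", len(panel), panel["subject_id"].nunique())

    if config.truncate_follow_up_years is not None:
        cut = config.truncate_follow_up_years
        panel = panel.copy()
        late_death = (panel["event"] == 1) & (panel["time_years"] > cut)
        panel.loc[late_death, "event"] = 0
        panel["time_years"] = panel["time_years"].clip(upper=cut)

    # ---- stage 1: eligibility --------------------------------------------
    kept, dropped = am.apply_eligibility(panel)
    acct = (
        dropped.groupby(["study", "drop_reason"]).size().rename("n_dropped").reset_index()
        if len(dropped)
        else pd.DataFrame(columns=["study", "drop_reason", "n_dropped"])
    )
    totals = panel.groupby("study").size().rename("n_input").reset_index()
    keptn = kept.groupby("study").size().rename("n_kept").reset_index()
    tables["eligibility"] = totals.merge(keptn, on="study", how="left").fillna({"n_kept": 0})
    tables["eligibility_reasons"] = acct
    log.info("stage=eligibility kept=%d dropped=%d", len(kept), len(dropped))
    if kept.empty:
        raise RuntimeError("eligibility left zero rows")

    kept = kept.copy()
    kept["bmi"] = kept["weight_kg"] / (kept["height_cm"] / 100.0) ** 2
    kept["whtr"] = kept["waist_cm"] / kept["height_cm"]
    baseline = kept.sort_values("wave").groupby("subject_id", as_index=False).first()

    # ---- stage 2: Gompertz fits ------------------------------------------
    horizon = gz.RiskHorizon(config.horizon_months)
    if config.coef_source == "self-fit":
        ca_fits, anthro_fits = {}, {}
        for sex_label, sub in baseline.groupby("sex"):
            t_m = sub["time_years"].to_numpy() * 12.0
            ev = sub["event"].to_numpy()
            ca_fits[sex_label] = gz.fit_gompertz(t_m, ev, sub[["age"]].to_numpy(), sex=sex_label)
            lb = np.log(sub["bmi"].to_numpy())
            X = np.column_stack([sub["age"], lb, lb**2, np.cbrt(sub["whtr"])])
            anthro_fits[sex_label] = gz.fit_gompertz(
                t_m, ev, X, sex=sex_label, shape_groups=sub["ethnicity"].to_numpy()
            )
        gz.write_coefficients(out_dir / "coefficients.tsv", ca_fits, anthro_fits)
    else:
        ca_fits, anthro_fits = gz.read_coefficients(config.coef_source)
    log.info("stage=gompertz strata=%s", sorted(ca_fits))

    # ---- stage 3: biological age -----------------------------------------
    kept["anthropoage"] = gz.anthropoage_batch(kept, ca_fits, anthro_fits, horizon)
    kept = gz.anthropoage_accel(kept, mode=config.accel_mode)
    summ = (
        kept.groupby("study")
        .agg(
            n=("subject_id", "nunique"),
            anthropoage_median=("anthropoage", "median"),
            anthropoage_q1=("anthropoage", lambda s: s.quantile(0.25)),
            anthropoage_q3=("anthropoage", lambda s: s.quantile(0.75)),
            accel_median=("accel", "median"),
            pct_accelerated=("accelerated", lambda s: 100.0 * s.mean()),
        )
        .reset_index()
    )
    tables["ba_summary"] = summ
    base_ba = kept.sort_values("wave").groupby("subject_id", as_index=False).first()
    log.info("stage=ba rows=%d pct_accel=%.1f", len(kept), 100 * kept["accelerated"].mean())

    # ---- stage 4: discrimination + DCA -----------------------------------
    rng_seed = config.seed
    base_ba["bri"] = [
        am.body_roundness_index(w, h) for w, h in zip(base_ba["waist_cm"], base_ba["height_cm"])
    ]
    base_ba["wwi"] = base_ba["waist_cm"] / np.sqrt(base_ba["weight_kg"])
    base_ba["absi"] = (base_ba["waist_cm"] / 100.0) / (
        base_ba["bmi"] ** (2 / 3) * (base_ba["height_cm"] / 100.0) ** 0.5
    )
    model_terms = {
        "ca": ["age"],
        "ca_accel": ["age", "accel"],
        "bri": ["age", "bri"],
        "wwi": ["age", "wwi"],
        "absi": ["age", "absi"],
    }
    t = base_ba["time_years"].to_numpy()
    ev = base_ba["event"].to_numpy()
    lps, disc_rows = {}, []
    for name, terms in model_terms.items():
        cox = surveval.fit_cox(base_ba, terms, weights_col="survey_weight")
        lp = cox.linear_predictor(base_ba)
        lps[name] = lp
        c = surveval.uno_c(lp, t, ev)
        disc_rows.append((name, "uno_c", np.nan, c.estimate, c.n_used))
        tc = surveval.tauc(lp, t, ev, config.tauc_grid_years)
        for _, r in tc.iterrows():
            disc_rows.append((name, "tauc", r["time"], r["auc"], int(r["n_cases"] + r["n_controls"])))
    tables["discrimination"] = pd.DataFrame(
        disc_rows, columns=["model", "metric", "time", "estimate", "n"]
    )
    cmp_res = surveval.compare_auc_bootstrap(
        lps["ca_accel"], lps["ca"], t, ev, horizon=config.eval_horizon_years,
        n_boot=config.bootstrap_b, seed=rng_seed,
    )
    tables["auc_comparison"] = pd.DataFrame([cmp_res])

    horizon_y = config.horizon_months / 12.0
    status, w_ipcw, mask = dca.survival_to_binary(t, ev, horizon_y)
    grid = dca.default_grid()
    curves = {}
    for name in ("ca", "ca_accel", "bri", "wwi", "absi"):
        # risk at the DCA horizon through the sex-matched CDF scale is model
        # specific; rank-preserving logistic calibration of the Cox lp
        risk = _calibrate_risk(lps[name][mask], status[mask], w_ipcw[mask])
        curves[name] = dca.net_benefit(risk, status[mask], grid, weights=w_ipcw[mask])
    dca_rows = []
    ref = curves["ca"]
    for name, cv in curves.items():
        delta = dca.delta_net_benefit(cv, ref)
        df = cv.to_frame()
        df.insert(0, "model", name)
        df["delta_vs_ca"] = delta
        dca_rows.append(df)
    tables["decision_curves"] = pd.concat(dca_rows, ignore_index=True)
    log.info("stage=discrimination models=%d", len(model_terms))

    # ---- stage 5: accelerated aging & mortality ---------------------------
    cox_rows = []
    for tier, adj in ADJUST_TIERS.items():
        enc, terms = _encode_for_cox(base_ba, adj)
        enc["accelerated_f"] = base_ba["accelerated"].astype(float)
        cox = surveval.fit_cox(
            enc, ["accelerated_f"] + terms, strata=["sex", "ethnicity"],
            weights_col="survey_weight", robust=True,
        )
        hr = float(np.exp(cox.coefficients["accelerated_f"]))
        ci = np.exp(cox.confidence_intervals().loc["accelerated_f"]).to_numpy()
        cox_rows.append(("accelerated", tier, hr, ci[0], ci[1], int(len(enc))))
    enc, terms = _encode_for_cox(base_ba, ADJUST_TIERS["full"])
    for q in (2, 3, 4):
        enc[f"q{q}"] = (base_ba["accel_quartile"] == q).astype(float)
    coxq = surveval.fit_cox(enc, ["q2", "q3", "q4"] + terms,
                            strata=["sex", "ethnicity"], weights_col="survey_weight",
                            robust=True)
    for q in (2, 3, 4):
        hr = float(np.exp(coxq.coefficients[f"q{q}"]))
        ci = np.exp(coxq.confidence_intervals().loc[f"q{q}"]).to_numpy()
        cox_rows.append((f"quartile_{q}_vs_1", "full", hr, ci[0], ci[1], int(len(enc))))
    tables["cox_hr"] = pd.DataFrame(
        cox_rows, columns=["contrast", "adjustment", "hr", "ci_low", "ci_high", "n"]
    )

    groups = (base_ba["accelerated"].astype(int).astype(str) + "_"
              + base_ba["multimorbidity"].astype(int).astype(str))
    km = surveval.kaplan_meier(t, ev, groups)
    km_df = pd.concat(
        [df.assign(group=g) for g, df in km.items()], ignore_index=True
    )
    chi2, p, dof = surveval.log_rank(t, ev, groups)
    tables["km_curves"] = km_df
    tables["log_rank"] = pd.DataFrame(
        [{"chi2": chi2, "p": p, "df": dof, "groups": len(km)}]
    )
    log.info("stage=cox contrasts=%d logrank_p=%.3g", len(cox_rows), p)

    # ---- stage 6: aging trends -------------------------------------------
    trend_rows = []
    for study, sub in kept.groupby("study"):
        if sub.groupby("subject_id")["years_from_baseline"].nunique().max() < 2:
            continue
        tr = gee.aging_trend(sub)
        trend_rows.append((study, tr["beta"], tr["ci"][0], tr["ci"][1], tr["verdict"],
                           tr["fit"].n_clusters))
    tr_all = gee.aging_trend(kept)
    trend_rows.append(("pooled", tr_all["beta"], tr_all["ci"][0], tr_all["ci"][1],
                       tr_all["verdict"], tr_all["fit"].n_clusters))
    tables["aging_trend"] = pd.DataFrame(
        trend_rows, columns=["study", "beta", "ci_low", "ci_high", "verdict", "n_clusters"]
    )
    prev = []
    for study, sub in kept.groupby("study"):
        p_ = gee.weighted_prevalence_over_time(sub)
        p_.insert(0, "study", study)
        prev.append(p_)
    tables["accel_prevalence"] = pd.concat(prev, ignore_index=True)
    log.info("stage=trends studies=%d", len(trend_rows))

    # ---- stage 7: new-onset grid -----------------------------------------
    onset_rows = []
    for outcome in ("adl", "iadl", "poor_srh", "diabetes", "hypertension"):
        if outcome not in kept.columns:
            continue
        try:
            res = gee.new_onset_model(kept, outcome)
        except ValueError:
            continue
        f = res["fits"]
        per = f["per_year"]
        acc = f["accelerated"]
        inter = f["interaction"]
        lo, hi = per.conf_int().loc["accel"]
        lo_a, hi_a = acc.conf_int().loc["_accelerated"]
        lo_i, hi_i = inter.conf_int().loc["_accel_x_time"]
        onset_rows.append({
            "outcome": outcome, "family": res["family"], "n_at_risk": res["n_at_risk"],
            "rr_or_per_year": float(np.exp(per.coefficients["accel"])),
            "per_year_ci_low": float(np.exp(lo)), "per_year_ci_high": float(np.exp(hi)),
            "interaction": float(np.exp(inter.coefficients["_accel_x_time"])),
            "interaction_ci_low": float(np.exp(lo_i)),
            "interaction_ci_high": float(np.exp(hi_i)),
            "rr_or_accelerated": float(np.exp(acc.coefficients["_accelerated"])),
            "accelerated_ci_low": float(np.exp(lo_a)),
            "accelerated_ci_high": float(np.exp(hi_a)),
            "delta_qic": res["delta_qic"],
        })
    tables["new_onset"] = pd.DataFrame(onset_rows)
    log.info("stage=new_onset outcomes=%d", len(onset_rows))

    # ---- write ------------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_rows_input": int(len(panel)),
        "n_rows_eligible": int(len(kept)),
        "n_subjects": int(kept["subject_id"].nunique()),
        "tables": sorted(tables),
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    tables["manifest"] = manifest
    return tables


def _calibrate_risk(lp, status, weights):
    """Map a Cox linear predictor to [0,1] risks by weighted logistic
    recalibration (rank-preserving)."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(lp), lp])
    try:
        fit = sm.GLM(status, X, family=sm.families.Binomial(), freq_weights=weights).fit()
        risk = fit.predict(X)
    except Exception:
        # fall back to the empirical-logit linear map
        risk = 1.0 / (1.0 + np.exp(-(lp - lp.mean())))
    return np.clip(risk, 0.0, 1.0)
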