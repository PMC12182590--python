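"""Synthetic multi-study longitudinal aging panels with known ground truth.

The generator emulates the structure of harmonized multinational aging
cohorts: several studies with their own wave schedules (2-3 year spacing),
participants aged 50-94 at baseline, sex- and ethnicity-specific
anthropometry, Gompertz mortality whose hazard depends on both age and body
composition, survey weights, and self-reported outcomes (ADL/IADL deficits,
poor self-rated health, chronic diseases) that accrue over waves and
correlate with a latent per-subject age-acceleration deviate.

Every stochastic ingredient is recorded in a :class:`SynthTruth` sidecar so
downstream estimators can be validated against the generating parameters.
Truth is never consumed by estimation code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "SynthTruth", "generate_panel", "inject_acceleration",
           "write_panel", "read_panel", "DEFAULT_STUDIES", "OUTCOME_NAMES"]

#: default study layout: label -> visit offsets in years from baseline
DEFAULT_STUDIES = {
    "US": (0, 2, 4, 6, 8, 10, 12),
    "ENG": (0, 4, 8),
    "MEX": (0, 2, 11),
    "CR": (0, 2, 5),
    "CHN": (0, 2, 4),
}

#: ethnicity mix of the pooled sample
DEFAULT_ETHNICITY_MIX = {
    "White": 0.45,
    "Other": 0.30,
    "Hispanic/Latino": 0.17,
    "Black": 0.08,
}

DISEASES = (
    "hypertension",
    "diabetes",
    "myocardial_infarction",
    "stroke",
    "cancer",
    "chronic_lung_disease",
    "arthritis",
)
OUTCOME_NAMES = DISEASES + ("poor_srh",)


def _default_anthro_params():
    # medians/IQRs of the pooled multinational sample: BMI ~26.6 (23.3-30.6),
    # WHtR ~0.58 (0.53-0.64); women slightly higher WHtR dispersion.
    return {
        "female": {
            "log_bmi_mean": 3.30, "log_bmi_sd": 0.19, "log_bmi_age_slope": -0.0015,
            "whtr_mean": 0.585, "whtr_sd": 0.075, "whtr_age_slope": 0.0012,
        },
        "male": {
            "log_bmi_mean": 3.27, "log_bmi_sd": 0.16, "log_bmi_age_slope": -0.0015,
            "whtr_mean": 0.575, "whtr_sd": 0.060, "whtr_age_slope": 0.0012,
        },
    }


def _default_mortality_params():
    # gamma* per month; beta1* per year of age; beta0* set so that 12-year
    # mortality at the median age (~61 y) is roughly 20%, matching large
    # aging panels.  Anthropometry enters through deviations of ln BMI,
    # (ln BMI)^2 and cube-root WHtR from their age-expected values.
    return {
        "gamma": 0.0045,          # shape, per month
        "beta0": -12.0,           # log rate intercept
        "beta1": 0.085,           # per year of chronological age
        "coef_log_bmi": 0.0,      # linear ln-BMI deviation effect
        "coef_log_bmi_sq": 2.0,   # quadratic (U-shaped) ln-BMI effect
        "coef_whtr_cbrt": 5.0,    # cube-root WHtR deviation effect
    }


def _default_outcome_params():
    # baseline prevalence at age 60 and per-year-of-latent-acceleration
    # log-odds; per-wave incidence keeps reported diagnoses persistent.
    base = {
        "hypertension": 0.35, "diabetes": 0.15, "myocardial_infarction": 0.06,
        "stroke": 0.04, "cancer": 0.08, "chronic_lung_disease": 0.07,
        "arthritis": 0.30, "poor_srh": 0.08,
    }
    return {
        "baseline_prevalence": base,
        "incidence_per_wave": {k: v * 0.15 for k, v in base.items()},
        "log_or_accel": 0.12,       # per year of latent acceleration
        "age_log_or": 0.03,         # per year of age
        "adl_rate": 0.25,           # Poisson mean deficits at age 60
        "iadl_rate": 0.18,
        "log_rr_accel_adl": 0.10,   # per year of latent acceleration
    }


@dataclass
class SynthConfig:
    """Generating conditions for a synthetic multinational aging panel."""

    n_subjects: int = 2000
    studies: dict = field(default_factory=lambda: dict(DEFAULT_STUDIES))
    age_range: tuple = (50.0, 94.0)
    sex_ratio: float = 0.55  # proportion female
    ethnicity_mix: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_MIX))
    anthro_params: dict = field(default_factory=_default_anthro_params)
    mortality_params: dict = field(default_factory=_default_mortality_params)
    outcome_params: dict = field(default_factory=_default_outcome_params)
    accel_sd: float = 2.5          # SD of latent acceleration, years
    accel_load_log_bmi: float = -0.015  # latent-accel loading on ln BMI
    accel_load_whtr: float = 0.012      # latent-accel loading on WHtR
    censor_time: float = 12.0      # administrative horizon, years
    missing_rate: float = 0.0      # optional MCAR blanking of anthropometry
    seed: int = 12345

    def validate(self) -> None:
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        probs = np.array(list(self.ethnicity_mix.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("ethnicity_mix must be a probability distribution")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.censor_time > 0:
            raise ValueError("censor_time must be positive (no positive follow-up otherwise)")
        mp = self.mortality_params
        for k, v in mp.items():
            if not np.isfinite(v):
                raise ValueError(f"mortality parameter {k} is not finite")
        if mp["gamma"] <= 0:
            raise ValueError("true Gompertz shape gamma must be > 0")
        for label, waves in self.studies.items():
            waves = tuple(waves)
            if len(waves) == 0:
                raise ValueError(f"study {label!r} has an empty wave schedule")
            if waves[0] != 0 or np.any(np.diff(waves) <= 0):
                raise ValueError(
                    f"wave offsets for study {label!r} must start at 0 and be "
                    "strictly increasing"
                )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SynthTruth:
    """Ground truth of one generated panel; never used by estimators."""

    params: dict
    subjects: pd.DataFrame  # per-subject: latent accel, xb, death draws
    hr_accel: float = 1.0

    def save(self, path) -> None:
        payload = {"params": self.params, "hr_accel": self.hr_accel,
                   "subjects": self.subjects.to_dict(orient="list")}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SynthTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(params=payload["params"],
                   subjects=pd.DataFrame(payload["subjects"]),
                   hr_accel=payload["hr_accel"])


def _gompertz_time_months(u, gamma, xb):
    """Invert S(t) = exp(-e^xb (e^(g t)-1)/g) at survival probability u."""
    # t = ln(1 - g*ln(u)/e^xb)/g
    return np.log1p(-gamma * np.log(u) / np.exp(xb)) / gamma


def _death_draw(cfg: SynthConfig, subj: pd.DataFrame, hr_accel: float = 1.0):
    """Continuous death time (months) from the configured Gompertz hazard."""
    mp = cfg.mortality_params
    xb = subj["xb_mort"].to_numpy(dtype=float).copy()
    if hr_accel != 1.0:
        xb = xb + np.log(hr_accel) * (subj["latent_accel"].to_numpy() > 0)
    t = _gompertz_time_months(subj["u_death"].to_numpy(), mp["gamma"], xb)
    # reported rounded to the month, mimicking approximate dates of death
    return np.maximum(np.round(t), 1.0)


def generate_panel(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate a long-format participant-visit panel plus its ground truth.

    Each subject has fixed baseline demographics, anthropometry evolving by
    the configured age slopes plus a latent per-subject deviation, a death
    time drawn from the configured Gompertz hazard (linear predictor
    ``beta0 + beta1*age`` plus effects of ln-BMI / ln^2-BMI / cube-root-WHtR
    deviations), and monotone outcome accrual.  Visits after death are
    dropped; follow-up is min(death, censoring horizon) in person-years.
    One RNG stream per study (split from the master seed) so adding a study
    never perturbs the others.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    study_seeds = master.spawn(len(config.studies))

    frames, truth_frames = [], []
    sid0 = 0
    for (label, waves), sseq in zip(config.studies.items(), study_seeds):
        rng = np.random.default_rng(sseq)
        f, tf = _generate_study(config, label, tuple(waves), rng, sid0)
        frames.append(f)
        truth_frames.append(tf)
        sid0 += config.n_subjects

    panel = pd.concat(frames, ignore_index=True)
    truth = SynthTruth(
        params={
            "mortality": dict(config.mortality_params),
            "outcomes": {k: (dict(v) if isinstance(v, dict) else v)
                         for k, v in config.outcome_params.items()},
            "accel_sd": config.accel_sd,
            "seed": config.seed,
        },
        subjects=pd.concat(truth_frames, ignore_index=True),
    )
    return panel, truth


def _expected_anthro(cfg, sex_labels, age):
    ap = cfg.anthro_params
    lb_mu = np.empty_like(age)
    whtr_mu = np.empty_like(age)
    for sx in ("female", "male"):
        m = sex_labels == sx
        p = ap[sx]
        lb_mu[m] = p["log_bmi_mean"] + p["log_bmi_age_slope"] * (age[m] - 60.0)
        whtr_mu[m] = p["whtr_mean"] + p["whtr_age_slope"] * (age[m] - 60.0)
    return lb_mu, whtr_mu


def _generate_study(cfg: SynthConfig, label: str, waves, rng, sid0):
    n = cfg.n_subjects
    mp = cfg.mortality_params

    age0 = cfg.age_range[0] + (cfg.age_range[1] - cfg.age_range[0]) * rng.beta(1.3, 3.0, n)
    sex = np.where(rng.random(n) < cfg.sex_ratio, "female", "male")
    eth_labels = list(cfg.ethnicity_mix)
    eth = rng.choice(eth_labels, size=n, p=list(cfg.ethnicity_mix.values()))
    latent = rng.normal(0.0, cfg.accel_sd, n)

    # subject-level anthropometry deviations: loading on the latent deviate
    # plus independent noise, on the transformed scales
    lb_mu0, whtr_mu0 = _expected_anthro(cfg, sex, age0)
    sd_lb = np.where(sex == "female", cfg.anthro_params["female"]["log_bmi_sd"],
                     cfg.anthro_params["male"]["log_bmi_sd"])
    sd_wh = np.where(sex == "female", cfg.anthro_params["female"]["whtr_sd"],
                     cfg.anthro_params["male"]["whtr_sd"])
    lb_dev = cfg.accel_load_log_bmi * latent + rng.normal(0, 1, n) * sd_lb
    wh_dev = cfg.accel_load_whtr * latent + rng.normal(0, 1, n) * sd_wh

    # mortality linear predictor: age + deviations of the transformed
    # anthropometry from its age/sex expectation at baseline
    lb0 = lb_mu0 + lb_dev
    wh0 = np.clip(whtr_mu0 + wh_dev, 0.30, 1.05)
    d_lb = lb0 - lb_mu0
    d_wc = np.cbrt(wh0) - np.cbrt(whtr_mu0)
    xb = (mp["beta0"] + mp["beta1"] * age0
          + mp["coef_log_bmi"] * d_lb
          + mp["coef_log_bmi_sq"] * d_lb**2
          + mp["coef_whtr_cbrt"] * d_wc)

    u_death = rng.random(n)
    height = np.clip(np.where(sex == "female",
                              rng.normal(160.0, 6.5, n),
                              rng.normal(172.0, 7.0, n)), 126.0, 199.0)
    weight_sw = np.exp(rng.normal(0.0, 0.5, n))
    weight_sw = weight_sw / weight_sw.mean()

    subj = pd.DataFrame({
        "subject_id": np.arange(sid0, sid0 + n),
        "study": label,
        "sex": sex,
        "ethnicity": eth,
        "age0": age0,
        "latent_accel": latent,
        "lb_dev": lb_dev,
        "wh_dev": wh_dev,
        "xb_mort": xb,
        "u_death": u_death,
        "height_cm": height,
        "survey_weight": weight_sw,
    })

    death_months = _death_draw(cfg, subj)
    subj["death_months"] = death_months
    panel = _assemble_visits(cfg, subj, waves, rng)
    return panel, subj


def _assemble_visits(cfg: SynthConfig, subj: pd.DataFrame, waves, rng):
    """Expand subjects into visit rows; outcome accrual is monotone."""
    op = cfg.outcome_params
    n = len(subj)
    horizon_m = cfg.censor_time * 12.0
    death_m = subj["death_months"].to_numpy()
    follow_m = np.minimum(death_m, horizon_m)
    event = death_m <= horizon_m

    # baseline outcome states
    latent = subj["latent_accel"].to_numpy()
    age0 = subj["age0"].to_numpy()
    states = {}
    for name in OUTCOME_NAMES:
        p0 = op["baseline_prevalence"][name]
        logit = (np.log(p0 / (1 - p0)) + op["age_log_or"] * (age0 - 60.0)
                 + op["log_or_accel"] * latent)
        states[name] = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    adl_mu = op["adl_rate"] * np.exp(0.04 * (age0 - 60.0) + op["log_rr_accel_adl"] * latent)
    iadl_mu = op["iadl_rate"] * np.exp(0.04 * (age0 - 60.0) + op["log_rr_accel_adl"] * latent)
    adl = np.minimum(rng.poisson(adl_mu), 5)
    iadl = np.minimum(rng.poisson(iadl_mu), 4)

    rows = []
    for w_idx, off in enumerate(waves):
        off_m = off * 12.0
        alive = death_m > off_m
        if w_idx > 0:
            # incident outcomes since the previous wave; persistence enforced
            for name in OUTCOME_NAMES:
                pi = op["incidence_per_wave"][name]
                logit = (np.log(pi / (1 - pi)) + op["age_log_or"] * (age0 - 60.0)
                         + op["log_or_accel"] * latent)
                new = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
                states[name] = states[name] | new
            adl = np.minimum(adl + rng.poisson(0.08 * np.exp(op["log_rr_accel_adl"] * latent)), 5)
            iadl = np.minimum(iadl + rng.poisson(0.06 * np.exp(op["log_rr_accel_adl"] * latent)), 4)
        if not alive.any():
            continue
        age_w = age0 + off
        lb_mu, whtr_mu = _expected_anthro(cfg, subj["sex"].to_numpy(), age_w)
        lb = lb_mu + subj["lb_dev"].to_numpy() + rng.normal(0, 0.01, n)
        wh = whtr_mu + subj["wh_dev"].to_numpy() + rng.normal(0, 0.004, n)
        bmi = np.clip(np.exp(lb), 10.5, 59.0)
        wh = np.clip(wh, 0.30, 1.05)
        height = subj["height_cm"].to_numpy()
        rows.append(pd.DataFrame({
            "subject_id": subj["subject_id"],
            "study": subj["study"],
            "wave": w_idx,
            "years_from_baseline": float(off),
            "age": age_w,
            "sex": subj["sex"],
            "ethnicity": subj["ethnicity"],
            "height_cm": height,
            "weight_kg": bmi * (height / 100.0) ** 2,
            "waist_cm": wh * height,
            "survey_weight": subj["survey_weight"],
            "time_years": follow_m / 12.0,
            "event": event.astype(int),
            "adl": adl,
            "iadl": iadl,
            "poor_srh": states["poor_srh"].astype(int),
            **{d: states[d].astype(int) for d in DISEASES},
        })[alive])

    panel = pd.concat(rows, ignore_index=True)
    panel["comorbidity_count"] = panel[list(DISEASES)].sum(axis=1)
    panel["multimorbidity"] = (panel["comorbidity_count"] >= 2).astype(int)
    # simple lifestyle covariates for adjustment tiers (independent of truth)
    lrng = np.random.default_rng(int(subj["subject_id"].iloc[0]) + 7)
    edu = lrng.choice(["primary_or_less", "secondary", "tertiary"],
                      size=len(subj), p=[0.5, 0.3, 0.2])
    smoke = lrng.choice(["never", "former", "lt10_per_day", "ge10_per_day"],
                        size=len(subj), p=[0.5, 0.25, 0.12, 0.13])
    alco = lrng.choice(["never", "lt_weekly", "lt_daily", "daily"],
                       size=len(subj), p=[0.47, 0.25, 0.18, 0.10])
    lookup = pd.DataFrame({"subject_id": subj["subject_id"], "education": edu,
                           "smoking": smoke, "alcohol": alco})
    panel = panel.merge(lookup, on="subject_id", how="left")
    if cfg.missing_rate > 0:
        mrng = np.random.default_rng(int(subj["subject_id"].iloc[0]) + 13)
        blank = mrng.random(len(panel)) < cfg.missing_rate
        panel.loc[blank, ["height_cm", "weight_kg", "waist_cm"]] = np.nan
    return panel


def inject_acceleration(panel: pd.DataFrame, truth: SynthTruth, hr_accel: float,
                        config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Multiply the hazard of latently accelerated subjects by ``hr_accel``.

    Death times are regenerated from the *stored* per-subject uniform draws,
    so ``hr_accel=1`` reproduces the input panel bitwise and any other value
    changes only the death times of accelerated subjects.
    """
    if not hr_accel > 0:
        raise ValueError("hr_accel must be positive")
    subj = truth.subjects.copy()
    death_m = _death_draw(config, subj, hr_accel=hr_accel)
    horizon_m = config.censor_time * 12.0
    follow_y = np.minimum(death_m, horizon_m) / 12.0
    event = (death_m <= horizon_m).astype(int)

    sid = subj["subject_id"].to_numpy()
    dm_map = dict(zip(sid, death_m))
    ty_map = dict(zip(sid, follow_y))
    ev_map = dict(zip(sid, event))
    out = panel.copy()
    out["time_years"] = out["subject_id"].map(ty_map)
    out["event"] = out["subject_id"].map(ev_map).astype(panel["event"].dtype)
    # drop visits at/after the (possibly earlier) new death time
    keep = out["years_from_baseline"] * 12.0 < out["subject_id"].map(dm_map)
    out = out[keep.to_numpy()].reset_index(drop=True)

    new_truth = SynthTruth(params=dict(truth.params), subjects=subj, hr_accel=hr_accel)
    new_truth.subjects["death_months"] = death_m
    return out, new_truth


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write the visit-level panel as CSV (column dictionary in the README)."""
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)
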