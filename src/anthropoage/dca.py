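"""Decision curve analysis: net benefit of mortality-risk models across
threshold probabilities.

Net benefit at threshold ``p_t`` is ``TP/n - (FP/n) * p_t/(1-p_t)`` where a
subject is "treated" when predicted risk >= p_t.  The treat-all curve treats
everyone; treat-none is identically zero.  For survival outcomes, subjects
are converted to horizon-binary status; censoring before the horizon is
handled either by IPCW reweighting or by dropping (naive complete-follower
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surveval import censoring_survival

__all__ = ["NetBenefitCurve", "default_grid", "net_benefit",
           "delta_net_benefit", "survival_to_binary"]


def default_grid(lo: float = 0.01, hi: float = 0.50, step: float = 0.01) -> np.ndarray:
    """Threshold grid for mortality-risk decision curves (default 1%-50%)."""
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass
class NetBenefitCurve:
    """Net benefit per threshold for a model and the two trivial policies."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray = field(default=None)
    delta_vs_reference: np.ndarray | None = None

    def __post_init__(self):
        if self.nb_treat_none is None:
            self.nb_treat_none = np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.nb_model,
            "nb_treat_all": self.nb_treat_all,
            "nb_treat_none": self.nb_treat_none,
        })
        if self.delta_vs_reference is not None:
            df["delta_vs_reference"] = self.delta_vs_reference
        return df


def net_benefit(predicted_risk, observed, thresholds=None, weights=None) -> NetBenefitCurve:
    """Decision curve for one risk model against binary outcomes.

    ``weights`` (e.g. survey or IPCW weights) replace subject counts by
    weight sums; equal weights reduce exactly to the unweighted curve.
    """
    risk = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(observed, dtype=float)
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    thresholds = default_grid() if thresholds is None else np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()

    prevalence = float(np.sum(w * y) / n)
    nb_model = np.empty_like(thresholds)
    nb_all = np.empty_like(thresholds)
    for k, pt in enumerate(thresholds):
        treated = risk >= pt
        tp = np.sum(w * y * treated) / n
        fp = np.sum(w * (1 - y) * treated) / n
        odds = pt / (1.0 - pt)
        nb_model[k] = tp - fp * odds
        nb_all[k] = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(thresholds=thresholds, nb_model=nb_model, nb_treat_all=nb_all)


def delta_net_benefit(curve_a: NetBenefitCurve, curve_b: NetBenefitCurve) -> np.ndarray:
    """Elementwise net-benefit difference A - B on a shared grid."""
    if curve_a.thresholds.shape != curve_b.thresholds.shape or not np.allclose(
        curve_a.thresholds, curve_b.thresholds
    ):
        raise ValueError("curves must share one threshold grid")
    return curve_a.nb_model - curve_b.nb_model


def survival_to_binary(time, event, horizon: float, method: str = "ipcw"):
    """Convert right-censored follow-up into horizon-binary status + weights.

    ``ipcw``: deaths before the horizon get weight 1/G(t-), survivors past
    it 1/G(horizon), and subjects censored before the horizon weight 0 (they
    are uninformative about horizon status).  ``naive`` keeps only complete
    followers with weight 1.

    Returns ``(status, weights, mask)`` aligned with the input.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    died = (event == 1) & (time <= horizon)
    survived = time > horizon
    if method == "naive":
        mask = died | survived
        return died.astype(float), np.ones(len(time)), mask
    if method != "ipcw":
        raise ValueError(f"unknown method {method!r}")
    _, G_minus = censoring_survival(time, event)
    w = np.zeros(len(time))
    w[died] = 1.0 / np.asarray(G_minus(time))[died]
    g_h = float(np.asarray(G_minus(horizon + 1e-12)))
    w[survived] = 1.0 / g_h
    mask = w > 0
    return died.astype(float), w, mask
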