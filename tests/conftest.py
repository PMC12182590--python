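import numpy as np
import pandas as pd
import pytest

from anthropoage import (
    SynthConfig,
    anthropoage_accel,
    anthropoage_batch,
    fit_gompertz,
    generate_panel,
)


def add_derived(panel: pd.DataFrame) -> pd.DataFrame:
    panel = panel.copy()
    panel["bmi"] = panel["weight_kg"] / (panel["height_cm"] / 100.0) ** 2
    panel["whtr"] = panel["waist_cm"] / panel["height_cm"]
    return panel


def fit_models(panel: pd.DataFrame):
    """Sex-stratified CA-only and anthropometry Gompertz fits on baseline rows."""
    base = panel[panel["wave"] == 0]
    ca_fits, anthro_fits = {}, {}
    for sx, sub in base.groupby("sex"):
        t_m = sub["time_years"].to_numpy() * 12.0
        ev = sub["event"].to_numpy()
        ca_fits[sx] = fit_gompertz(t_m, ev, sub[["age"]].to_numpy(), sex=sx)
        lb = np.log(sub["bmi"].to_numpy())
        X = np.column_stack([sub["age"], lb, lb**2, np.cbrt(sub["whtr"])])
        anthro_fits[sx] = fit_gompertz(
            t_m, ev, X, sex=sx, shape_groups=sub["ethnicity"].to_numpy()
        )
    return ca_fits, anthro_fits


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_subjects=500, seed=20240)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = generate_panel(small_config)
    return add_derived(panel), truth


@pytest.fixture(scope="session")
def ba_panel(small_panel):
    """Panel with AnthropoAge and AnthropoAgeAccel computed from self-fits."""
    panel, truth = small_panel
    ca_fits, anthro_fits = fit_models(panel)
    panel = panel.copy()
    panel["anthropoage"] = anthropoage_batch(panel, ca_fits, anthro_fits)
    panel = anthropoage_accel(panel)
    return panel, truth, ca_fits, anthro_fits
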