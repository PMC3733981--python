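"""Shared fixtures: dataset parameterisations and small generated trials."""

import numpy as np
import pytest

import trialsim as ts


@pytest.fixture(scope="session")
def mist2():
    return ts.load_fixture("mist2")


@pytest.fixture(scope="session")
def augib():
    return ts.load_fixture("augib")


@pytest.fixture(scope="session")
def pbc():
    return ts.load_fixture("pbc")


@pytest.fixture(scope="session")
def pbc_calibrated(pbc):
    """PBC generator with censoring calibrated to a 40.4% control event rate."""
    return ts.calibrate_intercept(
        pbc.effect_spec(), pbc.covariate_model(), 0.404, seed=2024
    )


@pytest.fixture(scope="session")
def augib_calibrated(augib):
    """AUGIB generator with intercept calibrated to a 23.6% control event rate."""
    return ts.calibrate_intercept(
        augib.effect_spec(), augib.covariate_model(), 0.236, seed=2024
    )


def make_survival_frame(pbc, effects, n, seed, beta_treat=0.0):
    rng = np.random.default_rng(seed)
    model = pbc.covariate_model()
    X, stratum = ts.sample_covariates(model, n, rng)
    arm = ts.allocate_simple(n, seed + 1)
    eff = effects.with_(beta_treat=beta_treat)
    time, event = ts.gen_survival(ts.linear_predictor(eff, X, arm), eff, rng)
    return ts.TrialFrame(
        X=X, arm=arm, family="survival", time=time, event=event,
        stratum=stratum, names=model.names,
    )


@pytest.fixture(scope="session")
def pbc_frame(pbc, pbc_calibrated):
    """One realised PBC-style trial, n=300, null treatment effect."""
    return make_survival_frame(pbc, pbc_calibrated, 300, seed=42)
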