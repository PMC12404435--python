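"""Shared fixtures: printed-table data, posteriors and synthetic stand-ins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import bycatchsurv as b
from bycatchsurv.avs import AVSFit, ModelSpec, ScalingSpec
from bycatchsurv.mixedlogit import MixedLogit
from bycatchsurv.prs import KnownFatePosterior
from bycatchsurv.simulate import COVARIATES, SimConfig


@pytest.fixture(scope="session")
def table5():
    return b.fixtures.tag_deployments()


@pytest.fixture(scope="session")
def table5_histories(table5):
    return b.build_encounter_histories(table5)


@pytest.fixture(scope="session")
def table5_posterior(table5_histories):
    return b.KnownFateModel(table5_histories).fit_mcmc(seed=123)


def recovery_config(n: int, seed: int, slopes: dict | None = None,
                    year_sd: float = 0.15) -> SimConfig:
    """Single-region generating config with covariate means far from the
    truncation bounds, for clean parameter-recovery checks."""
    mean = np.array([200.0, 60.0, 10.0, 10.0, 40.0, 22.0])
    cov = np.diag(np.array([30.0, 12.0, 3.0, 3.0, 10.0, 3.0]) ** 2)
    return SimConfig(
        regions=("SIM",),
        means={"SIM": mean},
        covs={"SIM": cov},
        slopes=slopes if slopes is not None else
        {"soak_h": -0.35, "sst_c": -0.2, "mainline_km": -0.1,
         "fl_cm": -0.07},
        year_sd=year_sd,
        n_per_region=n,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_records():
    cfg = b.default_config(seed=11, n_per_region=400)
    return b.generate_observer_records(cfg)


def constant_avs_fit(p: float) -> AVSFit:
    """An intercept-only fit predicting a fixed survival probability,
    built from data engineered to reproduce it exactly."""
    beta0 = float(logit(p)) if 0 < p < 1 else (35.0 if p >= 1 else -35.0)
    n = 8
    model = MixedLogit(np.tile([0.0, 1.0], n // 2), np.ones((n, 1)),
                       np.zeros(n), ["intercept"])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=np.array([beta0, 0.0]), maxiter=0,
                        sigma_fixed=0.0)
    res.params[:] = [beta0]
    res.converged = True
    res.aic = 0.0
    empty = pd.Series(dtype=float)
    return AVSFit(spec=ModelSpec(terms=()), results=res,
                  scaling=ScalingSpec(means=empty, sds=empty))


def constant_prs_posterior(prs28: float) -> KnownFatePosterior:
    """A degenerate posterior whose every sample yields PRS = prs28."""
    phi = prs28 ** (1.0 / 28.0)
    beta = float(logit(phi)) if phi < 1 else 35.0
    hist = [b.EncounterHistory("x", (1,) * 28, censored=False)]
    return KnownFatePosterior(
        model=b.KnownFateModel(hist),
        beta0_samples=np.full((3, 200), beta),
        rhat=1.0, acceptance=np.full(3, 0.3),
        settings={"constant": True})


@pytest.fixture(scope="session")
def glmm_recovery_large():
    """One large-sample fit of the four-slope model on synthetic records
    with known negative coefficients (shared by recovery checks)."""
    truth = {"soak_h": -0.35, "sst_c": -0.2, "mainline_km": -0.1,
             "fl_cm": -0.07}
    cfg = recovery_config(20000, seed=42, slopes=truth)
    rec = b.generate_observer_records(cfg)
    spec = ModelSpec.from_formula("FL + ML + SST + ST")
    fits, _, scaling = b.fit_candidate_set(rec, specs=[spec])
    return truth, fits[0], rec


@pytest.fixture(scope="session")
def glmm_coverage():
    """200-replicate 95% CI coverage of the four slopes at n = 5000."""
    from bycatchsurv.avs import fit_mixed_logistic, scale_covariates
    truth = {"soak_h": -0.35, "sst_c": -0.2, "mainline_km": -0.1,
             "fl_cm": -0.07}
    term_of = {"soak_h": "ST", "sst_c": "SST", "mainline_km": "ML",
               "fl_cm": "FL"}
    spec = ModelSpec.from_formula("FL + ML + SST + ST")
    hits = {k: 0 for k in truth}
    n_reps = 200
    for rep in range(n_reps):
        cfg = recovery_config(5000, seed=1000 + rep, slopes=truth)
        rec = b.generate_observer_records(cfg)
        scaled, _ = scale_covariates(rec)
        fit = fit_mixed_logistic(spec, scaled)
        ci = fit.results.conf_int()
        for cov_name, beta in truth.items():
            term = term_of[cov_name]
            if ci.loc[term, "lower"] <= beta <= ci.loc[term, "upper"]:
                hits[cov_name] += 1
    return {k: v / n_reps for k, v in hits.items()}
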