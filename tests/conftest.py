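"""Shared fixtures: small simulated cohorts and reusable fits.

Session-scoped so that expensive MCMC fits are shared across the tests
that only inspect them.
"""

from __future__ import annotations

import numpy as np
import pytest

from driftlearn.hierarchical_fit import MCMCConfig, build_model, fit_hierarchical
from driftlearn.synthetic_data import CohortSpec, GroupGenParams, generate_cohort

UNIT4 = ["alpha_plus", "alpha_minus", "theta", "c_raw"]


@pytest.fixture(scope="session")
def rl2_choice_cohort():
    """Choice data from 12 asymmetric-RL + dynamic-softmax agents."""
    gen = GroupGenParams(
        unit_mean={"alpha_plus": 0.4, "alpha_minus": 0.3, "theta": 0.3, "c_raw": 0.7},
        unit_precision={k: 30.0 for k in UNIT4},
        var_scale={},
    )
    spec = CohortSpec(
        groups={"sim": gen},
        n_per_group={"sim": 12},
        choice_model="rl2",
        choice_decision="dynamic",
        seed=11,
    )
    data, truth = generate_cohort(spec, tasks="choice")
    return data, truth


@pytest.fixture(scope="session")
def kf_estimation_cohort():
    """Estimation data from 10 Kalman-filter learners with moderate drift."""
    gen = GroupGenParams(
        unit_mean={},
        unit_precision={},
        var_scale={"drift_var": 0.05, "init_prior_var": 300.0, "report_var": 20.0},
    )
    spec = CohortSpec(
        groups={"sim": gen}, n_per_group={"sim": 10}, est_model="kf", seed=7
    )
    data, truth = generate_cohort(spec, tasks="estimation")
    return data, truth


@pytest.fixture(scope="session")
def small_mcmc():
    """Short chains for structural tests (not accuracy benchmarks)."""
    return MCMCConfig(n_chains=2, n_samples=1600, burn_in=800, thin=2, seed=5)


@pytest.fixture(scope="session")
def rl2_choice_fit(rl2_choice_cohort, small_mcmc):
    data, _ = rl2_choice_cohort
    spec = build_model("rl2", "dynamic", "choice")
    return spec, fit_hierarchical(data, spec, small_mcmc)


@pytest.fixture(scope="session")
def kf_estimation_fit(kf_estimation_cohort, small_mcmc):
    data, _ = kf_estimation_cohort
    spec = build_model("kf", "none", "estimation")
    return spec, fit_hierarchical(data, spec, small_mcmc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
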