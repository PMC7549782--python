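"""Tests for the hierarchical Bayesian fitting machinery."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftlearn import _kernels
from driftlearn.hierarchical_fit import (
    DECISION_IDS,
    MODEL_IDS,
    TASK_IDS,
    ConvergenceReport,
    MCMCConfig,
    PosteriorSamples,
    build_model,
    check_convergence,
    fit_by_group,
    fit_hierarchical,
    hdi,
    metropolis_sample,
    pack_dataset,
    posterior_summaries,
    split_rhat,
)
from driftlearn.learning_models import (
    AsymRLParams,
    DynamicSoftmaxParams,
    HybridParams,
    KalmanParams,
    RLParams,
    SoftmaxParams,
    dynamic_beta,
    softmax_prob,
    transform_c,
)
from driftlearn.synthetic_data import _UPDATERS, _init_state, make_params


class TestBuildModel:
    @pytest.mark.parametrize(
        "model, decision, task, unit, var",
        [
            ("rl", "constant", "choice", ["alpha", "beta"], []),
            ("kf", "none", "estimation", [], ["drift_var", "init_prior_var", "report_var"]),
            ("ph", "dynamic", "choice", ["assoc_init", "decay", "kappa", "theta", "c_raw"], []),
            ("rl2", "dynamic", "choice", ["alpha_plus", "alpha_minus", "theta", "c_raw"], []),
        ],
    )
    def test_free_parameter_layout(self, model, decision, task, unit, var):
        spec = build_model(model, decision, task)
        assert spec.unit_names == unit
        assert spec.var_names == var

    def test_rl_constant_choice_has_four_group_hyperparameters(self):
        spec = build_model("rl", "constant", "choice")
        group = [r for r in spec.describe() if r["level"] == "group"]
        assert len(group) == 4  # mean + precision for alpha and beta

    def test_kf_fixes_noise_variance(self):
        spec = build_model("kf", "none", "estimation")
        fixed = [r for r in spec.describe() if r["level"] == "fixed"]
        assert len(fixed) == 1 and fixed[0]["name"] == "noise_var"

    def test_inconsistent_task_decision_rejected(self):
        with pytest.raises(ValueError):
            build_model("rl", "constant", "estimation")
        with pytest.raises(ValueError):
            build_model("rl", "none", "choice")
        with pytest.raises(ValueError):
            build_model("qlearn", "none", "estimation")


class TestMCMCConfig:
    def test_default_retained_draw_count(self):
        cfg = MCMCConfig()
        assert cfg.n_chains == 3
        assert cfg.retained_per_chain == 4000  # (40000 - 20000) / 5
        assert cfg.n_chains * cfg.retained_per_chain == 12000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_samples=100, burn_in=200)


def reference_loglik(spec, params_unit, params_var, df, beta_scale=1.0):
    """Pure-Python likelihood via the reference model updates; the
    independent oracle for the jitted likelihood."""
    model, task = spec.model, spec.task
    values = dict(zip(spec.unit_names, params_unit)) | dict(
        zip(spec.var_names, params_var)
    )
    ll = 0.0
    for _, blk in df.sort_values(["block", "trial"]).groupby("block", sort=False):
        if task == "estimation":
            first = float(blk["estimate"].iloc[0])
            p = make_params(model, values) if model != "kf" else KalmanParams(
                values["drift_var"], values["init_prior_var"]
            )
            state = _init_state(model, p, 1, first)
            rv = values["report_var"]
            for _, tr in blk.iterrows():
                resid = float(tr["estimate"]) - state.expectation["0"]
                ll += stats.norm.logpdf(resid, scale=math.sqrt(rv))
                state = _UPDATERS[model](state, "0", float(tr["outcome"]), p)
        else:
            p = make_params(model, values)
            state = _init_state(model, p, 2, 50.0)
            for _, tr in blk.iterrows():
                t = int(tr["trial"])
                if spec.decision == "constant":
                    beta = values["beta"]
                else:
                    beta = dynamic_beta(
                        t, DynamicSoftmaxParams(values["theta"], transform_c(values["c_raw"]))
                    )
                probs = softmax_prob(
                    [state.expectation["0"], state.expectation["1"]], beta * beta_scale
                )
                ch = int(tr["option_chosen"])
                ll += math.log(probs[ch])
                state = _UPDATERS[model](state, str(ch), float(tr["outcome"]), p)
    return ll


@pytest.mark.parametrize(
    "model, decision, task, unit, var",
    [
        ("rl", "constant", "choice", [0.35, 0.4], []),
        ("rl2", "dynamic", "choice", [0.5, 0.25, 0.3, 0.8], []),
        ("kf", "dynamic", "choice", [0.3, 0.6], [0.05, 200.0]),
        ("ph", "constant", "choice", [0.6, 0.4, 0.2, 0.35], []),
        ("rl", "none", "estimation", [0.4], [16.0]),
        ("rl2", "none", "estimation", [0.4, 0.2], [9.0]),
        ("kf", "none", "estimation", [], [0.1, 300.0, 25.0]),
        ("ph", "none", "estimation", [0.5, 0.3, 0.4], [16.0]),
    ],
)
def test_jitted_likelihood_matches_reference(
    model, decision, task, unit, var, rl2_choice_cohort, kf_estimation_cohort
):
    """The numba likelihood agrees with a trial-by-trial pure-Python pass
    through the reference update functions, for every model family."""
    data = rl2_choice_cohort[0] if task == "choice" else kf_estimation_cohort[0]
    pid = data["participant_id"].iloc[0]
    df = data[data["participant_id"] == pid]
    spec = build_model(model, decision, task)
    packed = pack_dataset(df, spec)
    got = _kernels.participant_loglik(
        MODEL_IDS[model],
        DECISION_IDS[decision],
        TASK_IDS[task],
        np.array(unit),
        np.array(var),
        packed.outcome,
        packed.estimate,
        packed.choice,
        packed.tib,
        1.0,
    )
    want = reference_loglik(spec, unit, var, df)
    assert got == pytest.approx(want, rel=1e-10)


class TestMetropolisKernel:
    def test_conjugate_normal_posterior(self):
        """Known-variance Gaussian mean with a flat prior: the sampler
        reproduces the closed-form N(ybar, sigma^2/n) posterior."""
        rng = np.random.default_rng(0)
        y = rng.normal(3.0, 2.0, size=20)
        sigma2 = 4.0

        def logpost(theta):
            return -0.5 * np.sum((y - theta[0]) ** 2) / sigma2

        draws = metropolis_sample(logpost, [0.0], n_samples=40000, burn_in=5000, seed=1)
        post_mean, post_var = y.mean(), sigma2 / y.size
        # ~3 Monte-Carlo SEs with a conservative effective sample size
        ess = 2000
        assert draws.mean() == pytest.approx(post_mean, abs=3 * math.sqrt(post_var / ess))
        assert draws.var() == pytest.approx(post_var, rel=0.15)


class TestFitting:
    def test_retained_draw_shapes(self, rl2_choice_fit, small_mcmc):
        spec, samples = rl2_choice_fit
        c, r = small_mcmc.n_chains, small_mcmc.retained_per_chain
        n = len(samples.participants)
        assert samples.hyper_mean.shape == (c, r, 4)
        assert samples.ind_unit.shape == (c, r, n, 4)
        assert samples.ind_var.shape == (c, r, n, 0)

    def test_draws_respect_supports(self, rl2_choice_fit, kf_estimation_fit):
        for _, samples in (rl2_choice_fit, kf_estimation_fit):
            assert np.all((samples.hyper_mean > 0) & (samples.hyper_mean < 1))
            assert np.all((samples.hyper_prec >= 2) & (samples.hyper_prec <= 600))
            assert np.all((samples.ind_unit > 0) & (samples.ind_unit < 1))
            assert np.all(samples.ind_var > 0)
            assert np.all((samples.hyper_scale > 0) & (samples.hyper_scale <= 1000))

    def test_seed_determinism(self, rl2_choice_cohort, small_mcmc):
        data, _ = rl2_choice_cohort
        spec = build_model("rl2", "dynamic", "choice")
        a = fit_hierarchical(data, spec, small_mcmc)
        b = fit_hierarchical(data, spec, small_mcmc)
        np.testing.assert_array_equal(a.hyper_mean, b.hyper_mean)
        np.testing.assert_array_equal(a.ind_unit, b.ind_unit)

    def test_no_data_reproduces_uniform_hyperprior(self):
        """With zero trials the group-mean posterior is its Uniform(0,1)
        hyperprior (prior-predictive identity)."""
        empty = pd.DataFrame(
            {
                "participant_id": pd.Series(dtype=str),
                "task": pd.Series(dtype=str),
                "block": pd.Series(dtype=int),
                "trial": pd.Series(dtype=int),
                "outcome": pd.Series(dtype=float),
                "option_chosen": pd.Series(dtype=float),
                "estimate": pd.Series(dtype=float),
            }
        )
        spec = build_model("rl", "constant", "choice")
        cfg = MCMCConfig(n_chains=3, n_samples=24000, burn_in=4000, thin=5, seed=2)
        samples = fit_hierarchical(empty, spec, cfg)
        draws = samples.hyper_mean[:, :, 0].ravel()
        assert draws.size == 12000
        ks = stats.ks_1samp(draws, stats.uniform.cdf)
        assert ks.statistic < 0.05

    def test_group_fits_are_separate(self, small_mcmc):
        from driftlearn.synthetic_data import default_cohort_spec, generate_cohort

        spec_c = default_cohort_spec(seed=6, n_adults=4, n_adolescents=3)
        data, _ = generate_cohort(spec_c, tasks="estimation")
        fits = fit_by_group(data, build_model("kf", "none", "estimation"), small_mcmc)
        assert set(fits) == {"adult", "adolescent"}
        assert len(fits["adult"].participants) == 4
        assert len(fits["adolescent"].participants) == 3


class TestConvergence:
    def _fake_samples(self, hyper_mean):
        c, r, k = hyper_mean.shape
        return PosteriorSamples(
            spec=build_model("rl", "constant", "choice"),
            mcmc=MCMCConfig(n_chains=c, n_samples=2 * r, burn_in=r, thin=1, seed=0),
            participants=[],
            unit_names=["alpha", "beta"][:k],
            var_names=[],
            hyper_mean=hyper_mean,
            hyper_prec=np.full_like(hyper_mean, 10.0),
            hyper_scale=np.zeros((c, r, 0)),
            ind_unit=np.zeros((c, r, 0, k)),
            ind_var=np.zeros((c, r, 0, 0)),
        )

    def test_identical_chains_pass(self):
        rng = np.random.default_rng(0)
        one = rng.uniform(0.2, 0.8, size=(1, 4000, 1))
        samples = self._fake_samples(np.repeat(one, 3, axis=0))
        report = check_convergence(samples)
        assert report.passed
        assert report.rhat["m_alpha"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 0.2, size=(1, 2000, 1))
        b = rng.uniform(0.7, 0.8, size=(1, 2000, 1))
        c = rng.uniform(0.4, 0.5, size=(1, 2000, 1))
        samples = self._fake_samples(np.concatenate([a, b, c], axis=0))
        report = check_convergence(samples)
        assert not report.passed
        assert report.rhat["m_alpha"] > 1.1
        assert "m_alpha" in report.failing()

    def test_single_chain_invalid(self):
        rng = np.random.default_rng(0)
        samples = self._fake_samples(rng.uniform(size=(1, 1000, 1)))
        with pytest.raises(ValueError):
            check_convergence(samples)

    def test_split_rhat_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(7)
        draws = np.cumsum(rng.normal(size=(3, 2000)), axis=1) * 0.01 + rng.normal(
            size=(3, 2000)
        )
        ours = split_rhat(draws)
        theirs = float(
            np.asarray(az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"]).ravel()[0]
        )
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSummaries:
    def test_hdi_of_uniform_draws(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi(rng.uniform(size=200_000), prob=0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_hdi_point_mass(self):
        lo, hi = hdi(np.full(1000, 3.3))
        assert lo == hi == 3.3

    def test_hdi_symmetric_unimodal_matches_equal_tails(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=400_000)
        lo, hi = hdi(d)
        qlo, qhi = np.quantile(d, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.03)
        assert hi == pytest.approx(qhi, abs=0.03)

    def test_hdi_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(2)
        d = rng.gamma(2.0, size=50_000)
        lo, hi = hdi(d)
        ref = az.hdi(d, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.05)

    def test_posterior_summaries_table(self, rl2_choice_fit):
        _, samples = rl2_choice_fit
        table = posterior_summaries(samples)
        assert {"parameter", "median", "hdi_lo", "hdi_hi"} <= set(table.columns)
        assert (table["hdi_lo"] <= table["median"]).all()
        assert (table["median"] <= table["hdi_hi"]).all()
        # hyper rows + individual rows
        n = len(samples.participants)
        assert len(table) == 4 * 2 + 4 * n

    def test_individual_medians_include_transformed_c(self, rl2_choice_fit):
        _, samples = rl2_choice_fit
        med = samples.individual_medians()
        assert "c" in med.columns
        np.testing.assert_allclose(med["c"], 4 * med["c_raw"] - 2)


def test_hypermean_recovery_on_fixture_cohort(rl2_choice_cohort):
    """Group-level means recovered within 0.1 on a 12-agent cohort."""
    data, truth = rl2_choice_cohort
    spec = build_model("rl2", "dynamic", "choice")
    samples = fit_hierarchical(data, spec, MCMCConfig.fast(seed=3))
    gen = truth["hyperparameters"]["sim"]["unit_mean"]
    for k, name in enumerate(spec.unit_names):
        rec = float(np.median(samples.hyper_mean[:, :, k]))
        assert rec == pytest.approx(gen[name], abs=0.1)


def test_doubling_does_not_shift_medians(rl2_choice_cohort):
    """Doubling the draws moves hypermean medians by < 0.05 on the
    fixture cohort (stability of the reported point estimates)."""
    data, _ = rl2_choice_cohort
    spec = build_model("rl2", "dynamic", "choice")
    base = MCMCConfig.fast(seed=3)
    a = fit_hierarchical(data, spec, base)
    b = fit_hierarchical(data, spec, base.doubled())
    assert b.mcmc.n_samples == 2 * base.n_samples
    for k in range(4):
        ma = float(np.median(a.hyper_mean[:, :, k]))
        mb = float(np.median(b.hyper_mean[:, :, k]))
        assert ma == pytest.approx(mb, abs=0.05)
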