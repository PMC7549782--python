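"""Tests for task generators, agent simulators and cohort generation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftlearn.behavioural_metrics import clean_estimates, choice_accuracy, learning_rate_table
from driftlearn.learning_models import KalmanParams, RLParams, SoftmaxParams
from driftlearn.synthetic_data import (
    CohortSpec,
    GroupGenParams,
    default_cohort_spec,
    generate_choice_task,
    generate_cohort,
    generate_estimation_task,
    simulate_choice_agent,
    simulate_estimation_agent,
)


class TestEstimationTask:
    def test_default_design_dimensions(self):
        blocks = generate_estimation_task(rng=0)
        assert len(blocks) == 10
        assert all(b.n_trials == 15 for b in blocks)
        assert sum(b.outcomes.size for b in blocks) == 150
        assert sorted(b.outcome_sd for b in blocks) == [4.0] * 5 + [8.0] * 5
        assert all(20.0 <= b.latent_mean <= 80.0 for b in blocks)

    def test_counterbalanced_order(self):
        lo = generate_estimation_task(rng=0, low_noise_first=True)
        hi = generate_estimation_task(rng=0, low_noise_first=False)
        assert [b.outcome_sd for b in lo] == [4.0] * 5 + [8.0] * 5
        assert [b.outcome_sd for b in hi] == [8.0] * 5 + [4.0] * 5

    def test_outcome_sd_matches_schedule(self):
        blocks = generate_estimation_task(
            n_blocks=2, trials_per_block=10_000, sd_schedule=[4.0, 4.0], rng=3
        )
        for b in blocks:
            assert np.std(b.outcomes - b.latent_mean) == pytest.approx(4.0, rel=0.05)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_estimation_task(n_blocks=2, sd_schedule=[4.0, 5.0], rng=0)

    def test_seed_determinism(self):
        a = generate_estimation_task(rng=np.random.default_rng(9))
        b = generate_estimation_task(rng=np.random.default_rng(9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.outcomes, y.outcomes)

    def test_clamp_mode_bounds_outcomes(self):
        blocks = generate_estimation_task(rng=1, clamp=True)
        for b in blocks:
            assert np.all((b.outcomes >= 1) & (b.outcomes <= 100))
            assert np.all(b.outcomes == np.rint(b.outcomes))


class TestChoiceTask:
    def test_default_design(self):
        blocks = generate_choice_task(rng=0)
        assert len(blocks) == 8
        gaps = sorted(b.mean_gap for b in blocks)
        assert gaps == [10.0] * 4 + [20.0] * 4
        for b in blocks:
            assert b.outcome_sd == 8.0
            assert min(b.option_means) in (20.0, 30.0, 40.0, 50.0, 60.0)
            base_ok = any(m in (40.0, 50.0, 60.0) for m in b.option_means)
            assert base_ok

    def test_nonstandard_gap_strict_vs_warning(self):
        with pytest.raises(ValueError):
            generate_choice_task(n_blocks=2, mean_gaps=[0.0, 10.0], rng=0)
        with pytest.warns(UserWarning):
            generate_choice_task(n_blocks=2, mean_gaps=[0.0, 10.0], rng=0, strict=False)

    def test_seed_determinism(self):
        a = generate_choice_task(rng=np.random.default_rng(4))
        b = generate_choice_task(rng=np.random.default_rng(4))
        assert [x.option_means for x in a] == [y.option_means for y in b]


class TestEstimationAgent:
    def test_noiseless_kalman_reports_posterior_means(self):
        """With zero reporting noise and no drift, estimates after trial 1
        are exactly the Bayesian posterior means (running estimates)."""
        blocks = generate_estimation_task(rng=2)
        p = KalmanParams(drift_var=0.0, init_prior_var=1e6)
        df = simulate_estimation_agent("kf", p, blocks, report_noise_sd=0.0, rng=5)
        one = df[df["block"] == 1].reset_index(drop=True)
        # manual Kalman forward pass from the first (guessed) estimate
        mu, s2 = one.loc[0, "estimate"], 1e6
        for t in range(1, len(one)):
            g = s2 / (1 + s2)
            mu = mu + g * (one.loc[t - 1, "outcome"] - mu)
            s2 = s2 / (1 + s2)
            assert one.loc[t, "estimate"] == pytest.approx(mu, abs=1e-9)

    def test_noiseless_kalman_learning_rates_near_one_over_t(self):
        """Empirical learning rates from an undrifting flat-prior Kalman
        agent reproduce the 1/t optimal-gain schedule."""
        blocks = generate_estimation_task(rng=8)
        p = KalmanParams(drift_var=0.0, init_prior_var=1e9)
        df = simulate_estimation_agent("kf", p, blocks, report_noise_sd=0.0, rng=5)
        df.insert(0, "participant_id", "p1")
        lr = learning_rate_table(df)
        ok = lr[lr["valid"]]
        expected = 1.0 / ok["trial"].to_numpy()
        np.testing.assert_allclose(ok["alpha_hat"].to_numpy(), expected, atol=1e-4)

    def test_full_updating_agent_echoes_outcomes(self):
        blocks = generate_estimation_task(rng=3)
        df = simulate_estimation_agent("rl", RLParams(1.0), blocks, report_noise_sd=0.0, rng=4)
        one = df[df["block"] == 3].reset_index(drop=True)
        np.testing.assert_allclose(
            one["estimate"].to_numpy()[1:], one["outcome"].to_numpy()[:-1]
        )

    def test_certainty_within_rating_scale(self):
        blocks = generate_estimation_task(rng=3)
        df = simulate_estimation_agent(
            "kf", KalmanParams(0.1, 100.0), blocks, report_noise_sd=3.0, rng=4
        )
        assert df["certainty"].between(0, 10).all()


class TestChoiceAgent:
    def test_random_agent_chooses_uniformly(self):
        blocks = generate_choice_task(n_blocks=50, trials_per_block=200, rng=1)
        df = simulate_choice_agent(
            "rl", RLParams(0.3), "constant", SoftmaxParams(0.0), blocks, rng=2
        )
        n = len(df)
        se = 0.5 / np.sqrt(n)
        assert df["option_chosen"].mean() == pytest.approx(0.5, abs=3 * se)

    def test_near_greedy_agent_is_accurate_late(self):
        """A high, constant inverse temperature with a clear mean gap
        yields high late-block accuracy.

        The Monte-Carlo reference for this configuration is 0.885: a
        greedy agent permanently locks onto the worse option in the
        (60, 80) block layout whenever its early expectation stays above
        the unsampled option's initial value of 50, which caps mean
        accuracy below the no-lock-in value.
        """
        rng = np.random.default_rng(10)
        accs = []
        for _ in range(100):
            blocks = generate_choice_task(
                n_blocks=5, mean_gaps=[20.0] * 5, rng=rng, strict=True
            )
            df = simulate_choice_agent(
                "rl", RLParams(0.3), "constant", SoftmaxParams(5.0), blocks, rng=rng
            )
            df.insert(0, "participant_id", "p")
            df["mean_chosen"] = np.nan
            df["mean_unchosen"] = np.nan
            k = 0
            for b in blocks:
                ch = df["option_chosen"].iloc[k : k + b.n_trials].astype(int).to_numpy()
                means = np.array(b.option_means)
                df.loc[df.index[k : k + b.n_trials], "mean_chosen"] = means[ch]
                df.loc[df.index[k : k + b.n_trials], "mean_unchosen"] = means[1 - ch]
                k += b.n_trials
            scored, _ = choice_accuracy(df)
            accs.append(scored[scored["trial"] > 10]["accuracy"].mean())
        assert np.mean(accs) > 0.85

    def test_seed_determinism(self):
        blocks = generate_choice_task(rng=3)
        a = simulate_choice_agent("rl", RLParams(0.3), "constant", SoftmaxParams(0.3), blocks, rng=7)
        b = simulate_choice_agent("rl", RLParams(0.3), "constant", SoftmaxParams(0.3), blocks, rng=7)
        pd.testing.assert_frame_equal(a, b)


class TestCohorts:
    def test_study_sized_cohort(self):
        data, truth = generate_cohort(
            default_cohort_spec(seed=1, n_adults=4, n_adolescents=3), tasks="both"
        )
        assert data["participant_id"].nunique() == 7
        assert truth["participants"].shape[0] == 7
        per = data.groupby("participant_id").size()
        assert (per == 150 + 160).all()

    def test_default_spec_sample_sizes(self):
        spec = default_cohort_spec()
        assert spec.n_per_group == {"adult": 35, "adolescent": 25}

    def test_beta_draw_moments(self):
        """Participant-level draws respect the group beta distribution."""
        gen = GroupGenParams(
            unit_mean={"alpha": 0.3}, unit_precision={"alpha": 50.0}, var_scale={}
        )
        rng = np.random.default_rng(0)
        draws = rng.beta(0.3 * 50, 0.7 * 50, size=10_000)
        assert draws.mean() == pytest.approx(0.3, abs=0.01)

    def test_high_precision_collapses_to_group_mean(self):
        gen = GroupGenParams(
            unit_mean={"alpha": 0.4}, unit_precision={"alpha": 600.0}, var_scale={}
        )
        spec = CohortSpec(
            groups={"g": gen},
            n_per_group={"g": 20},
            choice_model="rl",
            choice_decision="constant",
            seed=3,
        )
        # beta for the decision rule is required too
        gen2 = GroupGenParams(
            unit_mean={"alpha": 0.4, "beta": 0.3},
            unit_precision={"alpha": 600.0, "beta": 600.0},
            var_scale={},
        )
        spec = CohortSpec(
            groups={"g": gen2},
            n_per_group={"g": 20},
            choice_model="rl",
            choice_decision="constant",
            seed=3,
        )
        _, truth = generate_cohort(spec, tasks="choice")
        assert truth["participants"]["cho_alpha"].std() < 0.05

    def test_cohort_reproducibility(self):
        spec = default_cohort_spec(seed=5, n_adults=3, n_adolescents=2)
        a, _ = generate_cohort(spec, tasks="both")
        b, _ = generate_cohort(spec, tasks="both")
        pd.testing.assert_frame_equal(a, b)

    def test_hyperparameters_outside_support_rejected(self):
        with pytest.raises(ValueError):
            GroupGenParams(unit_mean={"alpha": 1.2}, unit_precision={}, var_scale={})
        with pytest.raises(ValueError):
            GroupGenParams(
                unit_mean={"alpha": 0.5},
                unit_precision={"alpha": 1.0},
                var_scale={},
            )
        with pytest.raises(ValueError):
            GroupGenParams(unit_mean={}, unit_precision={}, var_scale={"v": 2000.0})

    def test_clamped_outcomes_in_display_range(self):
        spec = default_cohort_spec(seed=2, n_adults=2, n_adolescents=2)
        spec = CohortSpec(
            groups=spec.groups,
            n_per_group=spec.n_per_group,
            seed=2,
            clamp_outcomes=True,
        )
        data, _ = generate_cohort(spec, tasks="estimation")
        assert data["outcome"].between(1, 100).all()


def test_adolescent_like_cohort_higher_lr_lower_accuracy():
    """Directional developmental contrast: a higher-volatility /
    lower-inverse-temperature cohort shows higher late-trial empirical
    learning rates and lower late-trial choice accuracy."""
    spec = default_cohort_spec(
        seed=123, n_adults=30, n_adolescents=30,
        adult_drift_scale=0.01, adolescent_drift_scale=0.1,
    )
    data, _ = generate_cohort(spec, tasks="both")
    cleaned, _ = clean_estimates(data, mode="regression")
    late = cleaned[(cleaned["trial"] >= 8) & (cleaned["trial"] <= 14)]
    lr = late.groupby("group")["alpha_hat"].mean()
    assert lr["adolescent"] > lr["adult"]
    scored, _ = choice_accuracy(data)
    late_acc = scored[(scored["trial"] >= 11) & (scored["trial"] <= 20)]
    acc = late_acc.groupby("group")["accuracy"].mean()
    assert acc["adolescent"] < acc["adult"]
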