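# driftlearn

Computational models of uncertainty-driven learning and exploration,
for researchers studying how people regulate their learning rate and
their exploration as evidence accumulates — for example when comparing
age groups on noisy estimation and bandit tasks.

In a noisy but stable environment, the normative strategy is to learn
quickly at first and then settle down.  `driftlearn` implements the
standard family of trial-level models used to ask whether (and why)
people do this, fits them hierarchically, compares them, validates the
whole pipeline by simulation, and links fitted parameters across tasks.

## Models

All models update a per-option expectation from the prediction error
δₜ = Oₜ − Eₜ:

| Model | Update | Free parameters |
|---|---|---|
| RL (delta rule) | Eₜ₊₁ = Eₜ + α·δₜ | α |
| RL2 (asymmetric) | rate α₊ if δₜ > 0, α₋ if δₜ < 0 | α₊, α₋ |
| KF (Kalman filter) | Eₜ₊₁ = Eₜ + αₜ·δₜ with gain αₜ = s²ₜ/(σ²_ε + s²ₜ) | σ²_η, s²₁ (σ²_ε ≡ 1) |
| PH (RL/Pearce–Hall hybrid) | Eₜ₊₁ = Eₜ + min(1, κ·αₜ)·δₜ, αₜ₊₁ = η·\|δₜ\| + (1−η)·αₜ | α₁, η, κ |

The Kalman filter treats learning as Bayesian inference under an
assumed Gaussian random walk on the latent mean: its drift variance
σ²_η is the learner's representation of environmental volatility, and
it alone determines the asymptotic learning rate — in a truly static
task, any σ²_η > 0 means outcomes are over-weighted forever.

For choice data each learning model is paired with a softmax rule
P(s) = e^{βE_s}/Σ e^{βE_s'}, with either a constant inverse temperature
β or the dynamic form βₜ = θ·(t/10)^c (θ is β on trial 10; c > 0 means
exploration decreases over a block).

Around the models: hierarchical Bayesian estimation (beta group priors
via group mean/precision, half-Cauchy priors for variances, adaptive
MCMC with split-R-hat gating), DIC model comparison with model weights,
model-free behavioural metrics (empirical learning rates, choice
accuracy, exploit/explore classification, cleaning rules),
parameter- and model-recovery suites, rank-based single-level mediation
with bootstrap inference, and simulators for the two task designs
(10 × 15-trial estimation blocks with outcome SD 4/8; 8 × 20-trial
two-armed-bandit blocks with mean gaps 10/20 and SD 8).
See `docs/methods.md` for the full model and prior specification.

## Worked example

Simulate a small two-group cohort on the estimation task, fit the
Kalman filter and the constant-rate delta rule per group on the
low-noise blocks, and compare them:

```python
from driftlearn import (MCMCConfig, build_model, fit_by_group, compute_dic,
                        dic_weights, posterior_group_difference,
                        steady_state_gain, default_cohort_spec, generate_cohort)

spec = default_cohort_spec(seed=7, n_adults=12, n_adolescents=12)
data, truth = generate_cohort(spec, tasks="estimation")
low = data[data["block_sd_or_gap"] == 4.0]

fits = {}
for model in ("kf", "rl"):
    fs = build_model(model, "none", "estimation")
    fits[model] = fit_by_group(low, fs, MCMCConfig.fast(seed=1))

for group in ("adult", "adolescent"):
    dics = [compute_dic(fits[m][group], low[low["group"] == group]).dic
            for m in ("kf", "rl")]
    w = dic_weights(dics)
    print(f"{group:11s}  DIC(KF) = {dics[0]:8.1f}   DIC(RL) = {dics[1]:8.1f}   "
          f"weight(KF) = {w[0]:.3f}")

diff = posterior_group_difference(fits["kf"]["adult"], fits["kf"]["adolescent"],
                                  "drift_var")
print(f"P(drift variance: adult < adolescent) = {diff['frac_below_zero']:.3f}")
for drift in (0.005, 0.1):
    print(f"asymptotic learning rate at drift {drift:5.3f}: "
          f"{steady_state_gain(drift):.3f}")
```

Output:

```
adult        DIC(KF) =   5772.0   DIC(RL) =   6195.5   weight(KF) = 1.000
adolescent   DIC(KF) =   5641.3   DIC(RL) =   5956.0   weight(KF) = 1.000
P(drift variance: adult < adolescent) = 0.956
asymptotic learning rate at drift 0.005: 0.068
asymptotic learning rate at drift 0.100: 0.270
```

Reading it: on data from learners whose rate decays over a block, the
Kalman filter beats the constant-rate model decisively in both groups
(DIC lower by ~300–400, model weight ≈ 1).  The posterior difference
distribution puts 95.6% of its mass on the adult group's volatility
hyperparameter being the smaller one — recovering the generating group
structure (scales 0.005 vs 0.1).  The last two lines show what that
difference means behaviourally: those drift variances pin the
asymptotic learning rate at 0.07 versus 0.27, i.e. the high-volatility
group keeps over-weighting recent outcomes long after the low-volatility
group has settled.

A command-line interface mirrors the library:

```bash
driftlearn simulate --task both --seed 1 --out runs/demo
driftlearn fit --in runs/demo/trials.csv --model kf --task estimation --out kf.json
driftlearn recover --mode parameters --model rl2 --out recovery.json
driftlearn mediate --in params.csv --x group --m drift_var --y theta
```

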