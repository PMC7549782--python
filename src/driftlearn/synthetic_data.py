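"""Task environments and simulated cohorts.

The study data this package is designed for are not publicly deposited,
so every analysis is exercised on synthetic data that emulates the two
published task designs:

* estimation task — 10 blocks x 15 trials; outcomes drawn from a
  Gaussian whose mean is fixed within a block (sampled on [20, 80]) with
  SD 4 in five blocks and SD 8 in the other five;
* choice task (two-armed bandit) — 8 blocks x 20 trials; one option's
  mean is 40, 50 or 60 and the other sits 10 or 20 points higher or
  lower (half the blocks each); outcome SD always 8.

Cohorts mirror the study sample: 35 "adult"-like and 25
"adolescent"-like synthetic participants whose parameters are drawn
from group-level distributions (beta for unit-interval parameters,
half-Cauchy for variance-type parameters).  The adolescent-like group
has a higher drift-variance (assumed volatility) hypermean and a lower
inverse-temperature hypermean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .learning_models import (
    AsymRLParams,
    DynamicSoftmaxParams,
    HybridParams,
    KalmanParams,
    LearnerState,
    RLParams,
    SoftmaxParams,
    asym_rl_update,
    dynamic_beta,
    hybrid_update,
    kalman_update,
    rl_update,
    softmax_prob,
    transform_c,
)

__all__ = [
    "TaskBlock",
    "GroupGenParams",
    "CohortSpec",
    "generate_estimation_task",
    "generate_choice_task",
    "simulate_estimation_agent",
    "simulate_choice_agent",
    "generate_cohort",
    "default_cohort_spec",
    "COLUMNS",
]

COLUMNS = [
    "participant_id",
    "group",
    "task",
    "block",
    "block_sd_or_gap",
    "trial",
    "option_chosen",
    "outcome",
    "estimate",
    "certainty",
]

# canonical free-parameter names per learning model / decision rule
MODEL_UNIT_PARAMS = {
    "rl": ["alpha"],
    "rl2": ["alpha_plus", "alpha_minus"],
    "kf": [],
    "ph": ["assoc_init", "decay", "kappa"],
}
MODEL_VAR_PARAMS = {"rl": [], "rl2": [], "kf": ["drift_var", "init_prior_var"], "ph": []}
DECISION_UNIT_PARAMS = {"none": [], "constant": ["beta"], "dynamic": ["theta", "c_raw"]}


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TaskBlock:
    """One task block: the latent generating process plus, for the
    estimation task, the pre-drawn outcome sequence."""

    block_id: int
    n_trials: int
    outcome_sd: float
    latent_mean: float | None = None  # estimation variant
    outcomes: np.ndarray | None = None  # estimation variant
    option_means: tuple[float, float] | None = None  # choice variant

    @property
    def mean_gap(self) -> float:
        if self.option_means is None:
            raise ValueError("mean_gap is defined only for choice blocks")
        return abs(self.option_means[0] - self.option_means[1])


def _clamp_outcomes(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 1, 100)


def generate_estimation_task(
    n_blocks: int = 10,
    trials_per_block: int = 15,
    sd_schedule: Sequence[float] | None = None,
    rng=None,
    low_noise_first: bool = True,
    clamp: bool = False,
) -> list[TaskBlock]:
    """Generate estimation-task blocks with pre-drawn outcome sequences.

    By default the SD schedule is contiguous halves of SD 4 and SD 8
    (``low_noise_first`` counterbalances the order).  Block means are
    drawn i.i.d. uniform on [20, 80].  With ``clamp`` on, outcomes are
    rounded to integers and clipped to [1, 100] as displayed on screen.
    """
    rng = _rng(rng)
    if sd_schedule is None:
        half = n_blocks // 2
        lows, highs = [4.0] * half, [8.0] * (n_blocks - half)
        sd_schedule = lows + highs if low_noise_first else highs + lows
    sd_schedule = [float(s) for s in sd_schedule]
    if len(sd_schedule) != n_blocks:
        raise ValueError("sd_schedule length must equal n_blocks")
    if any(s not in (4.0, 8.0) for s in sd_schedule):
        raise ValueError("estimation outcome SD must be 4 or 8")
    blocks = []
    for b, sd in enumerate(sd_schedule):
        mean = rng.uniform(20.0, 80.0)
        outcomes = rng.normal(mean, sd, size=trials_per_block)
        if clamp:
            outcomes = _clamp_outcomes(outcomes)
        blocks.append(
            TaskBlock(
                block_id=b + 1,
                n_trials=trials_per_block,
                outcome_sd=sd,
                latent_mean=mean,
                outcomes=outcomes,
            )
        )
    return blocks


def generate_choice_task(
    n_blocks: int = 8,
    trials_per_block: int = 20,
    mean_gaps: Sequence[float] | None = None,
    rng=None,
    strict: bool = True,
) -> list[TaskBlock]:
    """Generate two-armed-bandit blocks (outcomes are drawn on demand).

    Per block, a base mean is drawn from {40, 50, 60} and the partner
    option sits ``gap`` points higher or lower (side randomized);
    ``mean_gaps`` defaults to half the blocks at 10 and half at 20.
    """
    import warnings

    rng = _rng(rng)
    if mean_gaps is None:
        half = n_blocks // 2
        mean_gaps = [10.0] * half + [20.0] * (n_blocks - half)
    mean_gaps = [float(g) for g in mean_gaps]
    if len(mean_gaps) != n_blocks:
        raise ValueError("mean_gaps length must equal n_blocks")
    for g in mean_gaps:
        if g not in (10.0, 20.0):
            if strict:
                raise ValueError(f"mean gap {g} not in {{10, 20}}")
            warnings.warn(f"non-standard mean gap {g}", stacklevel=2)
    order = rng.permutation(n_blocks)
    blocks = []
    for b in range(n_blocks):
        gap = mean_gaps[order[b]]
        base = float(rng.choice([40.0, 50.0, 60.0]))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        other = base + sign * gap
        pair = (base, other) if rng.random() < 0.5 else (other, base)
        blocks.append(
            TaskBlock(
                block_id=b + 1,
                n_trials=trials_per_block,
                outcome_sd=8.0,
                option_means=pair,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# agent simulation


def _init_state(model: str, params, n_options: int, init_expectation) -> LearnerState:
    opts = [str(i) for i in range(n_options)]
    exp = {o: float(init_expectation) for o in opts}
    pv = {}
    assoc = {}
    if model == "kf":
        pv = {o: params.init_prior_var for o in opts}
    if model == "ph":
        assoc = {o: params.assoc_init for o in opts}
    return LearnerState(expectation=exp, posterior_var=pv, associability=assoc)


_UPDATERS = {
    "rl": rl_update,
    "rl2": asym_rl_update,
    "kf": kalman_update,
    "ph": hybrid_update,
}


def make_params(model: str, values: Mapping[str, float]):
    """Build the parameter object for a model id from a name->value map."""
    if model == "rl":
        return RLParams(alpha=values["alpha"])
    if model == "rl2":
        return AsymRLParams(
            alpha_plus=values["alpha_plus"], alpha_minus=values["alpha_minus"]
        )
    if model == "kf":
        return KalmanParams(
            drift_var=values["drift_var"], init_prior_var=values["init_prior_var"]
        )
    if model == "ph":
        return HybridParams(
            assoc_init=values["assoc_init"], decay=values["decay"], kappa=values["kappa"]
        )
    raise ValueError(f"unknown model id {model!r}")


def make_decision_params(decision: str, values: Mapping[str, float]):
    if decision == "constant":
        return SoftmaxParams(beta=values["beta"])
    if decision == "dynamic":
        return DynamicSoftmaxParams(
            theta=values["theta"], c=transform_c(values["c_raw"])
        )
    raise ValueError(f"unknown decision id {decision!r}")


def simulate_estimation_agent(
    model: str,
    params,
    blocks: Sequence[TaskBlock],
    report_noise_sd: float = 0.0,
    certainty_noise_sd: float = 1.0,
    rng=None,
) -> pd.DataFrame:
    """Simulate one agent performing the estimation task.

    On each trial the agent reports its current expectation plus
    Gaussian reporting noise (the first-trial estimate is a uniform
    guess on [20, 80], to which the internal expectation is
    initialized), rates its certainty, then observes the outcome and
    updates.  Certainty is a monotone map of internal uncertainty: for
    the Kalman learner ``10 / (1 + s_t^2)`` (its prior precision
    fraction, scaled to the 0-10 rating scale), and for non-Bayesian
    learners a logistic function of trial number; both plus clipped
    Gaussian rating noise.
    """
    rng = _rng(rng)
    update = _UPDATERS[model]
    rows = []
    for block in blocks:
        if block.outcomes is None:
            raise ValueError("estimation blocks must carry outcome sequences")
        guess = rng.uniform(20.0, 80.0)
        state = _init_state(model, params, 1, guess)
        for t in range(1, block.n_trials + 1):
            exp = state.expectation["0"]
            if t == 1:
                est = guess
            else:
                est = exp + rng.normal(0.0, report_noise_sd) if report_noise_sd > 0 else exp
                # responses are typed on a 0-100 interface; clipping to the
                # boundary mimics the out-of-range entries the cleaning
                # rules are designed to catch
                est = float(np.clip(est, 0.0, 100.0))
            if model == "kf":
                s2 = state.posterior_var["0"]
                cert = 10.0 / (1.0 + s2)
            else:
                cert = 10.0 / (1.0 + np.exp(-(t - 5.0) / 3.0))
            cert = float(np.clip(cert + rng.normal(0.0, certainty_noise_sd), 0.0, 10.0))
            outcome = float(block.outcomes[t - 1])
            rows.append(
                {
                    "task": "estimation",
                    "block": block.block_id,
                    "block_sd_or_gap": block.outcome_sd,
                    "trial": t,
                    "option_chosen": np.nan,
                    "outcome": outcome,
                    "estimate": est,
                    "certainty": cert,
                }
            )
            state = update(state, "0", outcome, params)
    return pd.DataFrame(rows)


def simulate_choice_agent(
    model: str,
    params,
    decision: str,
    decision_params,
    blocks: Sequence[TaskBlock],
    rng=None,
) -> pd.DataFrame:
    """Simulate one agent performing the bandit task.

    Both expectations start at 50 (the centre of the outcome range).
    Each trial: the inverse temperature comes from the constant or
    dynamic softmax rule, a choice is sampled, the chosen option pays
    out, and only the chosen option's state is updated.
    """
    rng = _rng(rng)
    update = _UPDATERS[model]
    rows = []
    for block in blocks:
        if block.option_means is None:
            raise ValueError("choice blocks must carry option means")
        state = _init_state(model, params, 2, 50.0)
        for t in range(1, block.n_trials + 1):
            if decision == "constant":
                beta = decision_params.beta
            else:
                beta = dynamic_beta(t, decision_params)
            e = np.array([state.expectation["0"], state.expectation["1"]])
            p = softmax_prob(e, beta)
            choice = int(rng.random() < p[1])
            outcome = float(
                rng.normal(block.option_means[choice], block.outcome_sd)
            )
            rows.append(
                {
                    "task": "choice",
                    "block": block.block_id,
                    "block_sd_or_gap": block.mean_gap,
                    "trial": t,
                    "option_chosen": choice,
                    "outcome": outcome,
                    "estimate": np.nan,
                    "certainty": np.nan,
                }
            )
            state = update(state, str(choice), outcome, params)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupGenParams:
    """Group-level generating distributions for one cohort group.

    ``unit_mean`` / ``unit_precision`` parameterize beta distributions
    for unit-interval parameters; ``var_scale`` gives half-Cauchy scales
    for variance-type parameters (drift_var, init_prior_var,
    report_var).
    """

    unit_mean: Mapping[str, float]
    unit_precision: Mapping[str, float]
    var_scale: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.unit_mean.items():
            if not (0.0 < v < 1.0):
                raise ValueError(f"unit_mean[{k!r}] must be in (0, 1)")
        for k, v in self.unit_precision.items():
            if not (2.0 <= v <= 600.0):
                raise ValueError(f"unit_precision[{k!r}] must be in [2, 600]")
        for k, v in self.var_scale.items():
            if not (0.0 < v <= 1000.0):
                raise ValueError(f"var_scale[{k!r}] must be in (0, 1000]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and generating hyperparameters.

    Defaults mirror the study sample: 35 adult-like and 25
    adolescent-like participants, Kalman-filter learners in the
    estimation task and Kalman + dynamic-softmax agents in the choice
    task, with a higher drift-variance and lower theta hypermean in the
    adolescent-like group.
    """

    groups: Mapping[str, GroupGenParams]
    n_per_group: Mapping[str, int]
    est_model: str = "kf"
    choice_model: str = "kf"
    choice_decision: str = "dynamic"
    seed: int = 0
    clamp_outcomes: bool = False


def default_cohort_spec(
    seed: int = 0,
    n_adults: int = 35,
    n_adolescents: int = 25,
    adult_drift_scale: float = 0.005,
    adolescent_drift_scale: float = 0.1,
) -> CohortSpec:
    """The packaged study-like cohort.

    Adult-like: near-zero assumed volatility, higher inverse
    temperature; adolescent-like: markedly higher volatility hypermean
    and lower inverse temperature.  Initial prior variance is large
    (>> 100) in both groups, and reporting noise is a few points.
    """
    adult = GroupGenParams(
        unit_mean={"theta": 0.35, "c_raw": 0.75},
        unit_precision={"theta": 30.0, "c_raw": 30.0},
        var_scale={
            "drift_var": adult_drift_scale,
            "init_prior_var": 300.0,
            "report_var": 20.0,
        },
    )
    adolescent = GroupGenParams(
        unit_mean={"theta": 0.15, "c_raw": 0.6},
        unit_precision={"theta": 30.0, "c_raw": 30.0},
        var_scale={
            "drift_var": adolescent_drift_scale,
            "init_prior_var": 300.0,
            "report_var": 20.0,
        },
    )
    return CohortSpec(
        groups={"adult": adult, "adolescent": adolescent},
        n_per_group={"adult": n_adults, "adolescent": n_adolescents},
        seed=seed,
    )


def draw_participant_params(
    gen: GroupGenParams, names_unit, names_var, rng
) -> dict[str, float]:
    """Draw one participant's parameters from the group distributions."""
    out: dict[str, float] = {}
    for name in names_unit:
        m = gen.unit_mean[name]
        n = gen.unit_precision[name]
        out[name] = float(rng.beta(m * n, (1.0 - m) * n))
    for name in names_var:
        # half-Cauchy(scale) = scale * |t_1|
        out[name] = float(gen.var_scale[name] * abs(rng.standard_cauchy()))
    return out


def generate_cohort(
    spec: CohortSpec, tasks: str = "both", rng=None
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort; returns (tidy trial table, ground truth).

    Ground truth holds the per-participant parameter table and the
    generating hyperparameters, for recovery scoring.  Per-participant
    random streams are spawned from the master seed by participant
    index, so cohorts are reproducible and order-independent.
    """
    if tasks not in ("estimation", "choice", "both"):
        raise ValueError("tasks must be 'estimation', 'choice' or 'both'")
    master = spec.seed if rng is None else rng
    if isinstance(master, np.random.Generator):
        # derive a deterministic integer master seed from the generator
        master = int(master.integers(0, 2**31 - 1))

    est_unit = list(MODEL_UNIT_PARAMS[spec.est_model])
    est_var = list(MODEL_VAR_PARAMS[spec.est_model]) + ["report_var"]
    cho_unit = list(MODEL_UNIT_PARAMS[spec.choice_model]) + list(
        DECISION_UNIT_PARAMS[spec.choice_decision]
    )
    cho_var = list(MODEL_VAR_PARAMS[spec.choice_model])

    frames = []
    truth_rows = []
    pidx = 0
    for group in spec.groups:
        gen = spec.groups[group]
        for j in range(spec.n_per_group[group]):
            pid = f"{group[:3]}{j + 1:03d}"
            prng = np.random.default_rng(
                np.random.SeedSequence(entropy=master, spawn_key=(pidx,))
            )
            drawn: dict[str, float] = {}
            if tasks in ("estimation", "both"):
                pvals = draw_participant_params(gen, est_unit, est_var, prng)
                drawn.update({f"est_{k}": v for k, v in pvals.items()})
                blocks = generate_estimation_task(
                    rng=prng, clamp=spec.clamp_outcomes
                )
                df = simulate_estimation_agent(
                    spec.est_model,
                    make_params(spec.est_model, pvals),
                    blocks,
                    report_noise_sd=float(np.sqrt(pvals["report_var"])),
                    rng=prng,
                )
                df.insert(0, "participant_id", pid)
                df.insert(1, "group", group)
                frames.append(df)
            if tasks in ("choice", "both"):
                pvals = draw_participant_params(gen, cho_unit, cho_var, prng)
                drawn.update({f"cho_{k}": v for k, v in pvals.items()})
                blocks = generate_choice_task(rng=prng)
                df = simulate_choice_agent(
                    spec.choice_model,
                    make_params(spec.choice_model, pvals),
                    spec.choice_decision,
                    make_decision_params(spec.choice_decision, pvals),
                    blocks,
                    rng=prng,
                )
                df.insert(0, "participant_id", pid)
                df.insert(1, "group", group)
                # record latent option means for accuracy scoring
                df["mean_chosen"] = np.nan
                df["mean_unchosen"] = np.nan
                k = 0
                for block in blocks:
                    nb = block.n_trials
                    seg = df.iloc[k : k + nb]
                    ch = seg["option_chosen"].to_numpy().astype(int)
                    means = np.array(block.option_means)
                    df.loc[seg.index, "mean_chosen"] = means[ch]
                    df.loc[seg.index, "mean_unchosen"] = means[1 - ch]
                    k += nb
                frames.append(df)
            truth_rows.append({"participant_id": pid, "group": group, **drawn})
            pidx += 1

    data = pd.concat(frames, ignore_index=True)
    front = [c for c in COLUMNS if c in data.columns]
    rest = [c for c in data.columns if c not in front]
    data = data[front + rest]
    truth = {
        "participants": pd.DataFrame(truth_rows),
        "hyperparameters": {
            g: {
                "unit_mean": dict(spec.groups[g].unit_mean),
                "unit_precision": dict(spec.groups[g].unit_precision),
                "var_scale": dict(spec.groups[g].var_scale),
            }
            for g in spec.groups
        },
        "spec": spec,
    }
    return data, truth
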