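"""Hierarchical Bayesian estimation of the learning/decision models.

Every participant has their own parameter vector, drawn from group-level
distributions: beta distributions (reparameterized by a group mean with
a Uniform(0,1) hyperprior and a group precision whose log is uniform on
[log 2, log 600]) for unit-interval parameters, and half-Cauchy
distributions (scale hyperprior uniform on (0, 1000]) for variance-type
parameters (drift variance, initial prior variance, and the
estimation-task reporting variance).  The consistency parameter ``c`` is
estimated on [0, 1] and mapped to [-2, 2] via c = 4c' - 2; the
Kalman-filter noise variance is fixed at 1.

Estimation-task likelihood: reported estimates are Gaussian around the
model's point predictions, with a per-participant reporting variance
under the group half-Cauchy; expectations are initialized to the first
estimate of each block.  Choice-task likelihood: categorical softmax
probabilities; expectations are initialized to 50.

The sampler backend is an adaptive random-walk Metropolis-within-Gibbs
scheme (numba-compiled, see ``_kernels``): participants' parameter
vectors are updated jointly per participant, hyperparameters one at a
time, with proposal scales adapted during burn-in only.  The backend
contract — consume the declarative fit specification, return per-chain
draws, respect the seed — is what downstream code relies on, not the
specific engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .synthetic_data import DECISION_UNIT_PARAMS, MODEL_UNIT_PARAMS, MODEL_VAR_PARAMS

__all__ = [
    "FitSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "build_model",
    "fit_hierarchical",
    "fit_by_group",
    "check_convergence",
    "posterior_summaries",
    "hdi",
    "metropolis_sample",
    "pack_dataset",
    "PackedData",
]

MODEL_IDS = {"rl": _kernels.RL, "rl2": _kernels.RL2, "kf": _kernels.KF, "ph": _kernels.PH}
DECISION_IDS = {
    "none": _kernels.DEC_NONE,
    "constant": _kernels.DEC_CONST,
    "dynamic": _kernels.DEC_DYN,
}
TASK_IDS = {"estimation": _kernels.TASK_EST, "choice": _kernels.TASK_CHOICE}


@dataclass(frozen=True)
class FitSpec:
    """Declarative description of one hierarchical model fit."""

    model: str
    decision: str
    task: str
    beta_scale: float = 1.0

    @property
    def unit_names(self) -> list[str]:
        return list(MODEL_UNIT_PARAMS[self.model]) + list(
            DECISION_UNIT_PARAMS[self.decision]
        )

    @property
    def var_names(self) -> list[str]:
        names = list(MODEL_VAR_PARAMS[self.model])
        if self.task == "estimation":
            names.append("report_var")
        return names

    def describe(self) -> list[dict]:
        """Every free parameter with its level, support, prior, transform."""
        rows = []
        for name in self.unit_names:
            transform = "c = 4*c' - 2" if name == "c_raw" else (
                f"scaled by beta_scale={self.beta_scale}"
                if name in ("beta", "theta") and self.beta_scale != 1.0
                else "identity"
            )
            rows.append(
                {
                    "name": name,
                    "level": "individual",
                    "support": "[0, 1]",
                    "prior": "Beta(m*n, (1-m)*n)",
                    "transform": transform,
                }
            )
            rows.append(
                {
                    "name": f"m_{name}",
                    "level": "group",
                    "support": "(0, 1)",
                    "prior": "Uniform(0, 1)",
                    "transform": "identity",
                }
            )
            rows.append(
                {
                    "name": f"n_{name}",
                    "level": "group",
                    "support": "[2, 600]",
                    "prior": "log n ~ Uniform(log 2, log 600)",
                    "transform": "identity",
                }
            )
        for name in self.var_names:
            rows.append(
                {
                    "name": name,
                    "level": "individual",
                    "support": "(0, inf)",
                    "prior": "HalfCauchy(scale)",
                    "transform": "identity",
                }
            )
            rows.append(
                {
                    "name": f"scale_{name}",
                    "level": "group",
                    "support": "(0, 1000]",
                    "prior": "Uniform(0, 1000)",
                    "transform": "identity",
                }
            )
        if self.model == "kf":
            rows.append(
                {
                    "name": "noise_var",
                    "level": "fixed",
                    "support": "{1}",
                    "prior": "fixed at 1 (only variance ratios matter)",
                    "transform": "identity",
                }
            )
        return rows


def build_model(
    model_id: str,
    decision_id: str,
    task: str,
    group_count: int = 1,
    beta_scale: float = 1.0,
) -> FitSpec:
    """Validate a model/decision/task combination and return its FitSpec.

    Estimation-task fits take no decision rule (and are typically run
    separately per noise condition); choice-task fits require one.
    ``group_count`` is informational: groups are fitted with separate
    group-level distributions by calling :func:`fit_by_group`.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if decision_id not in DECISION_IDS:
        raise ValueError(f"unknown decision rule {decision_id!r}")
    if task not in TASK_IDS:
        raise ValueError(f"unknown task {task!r}")
    if task == "estimation" and decision_id != "none":
        raise ValueError("estimation-task fits take no decision rule")
    if task == "choice" and decision_id == "none":
        raise ValueError("choice-task fits require a decision rule")
    if group_count < 1:
        raise ValueError("group_count must be >= 1")
    return FitSpec(model=model_id, decision=decision_id, task=task, beta_scale=beta_scale)


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC contract: 3 chains x 40,000 samples, 20,000 burn-in, thin 5
    (12,000 retained draws total) by default; ``fast()`` gives the
    reduced profile used by the recovery and comparison suites."""

    n_chains: int = 3
    n_samples: int = 40000
    burn_in: int = 20000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in >= self.n_samples or self.thin < 1:
            raise ValueError("invalid MCMC configuration")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_samples - self.burn_in) // self.thin

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_chains=3, n_samples=4000, burn_in=2000, thin=2, seed=seed)

    def doubled(self) -> "MCMCConfig":
        """The documented non-convergence remedy: twice as many draws."""
        return MCMCConfig(
            n_chains=self.n_chains,
            n_samples=2 * self.n_samples,
            burn_in=2 * self.burn_in,
            thin=self.thin,
            seed=self.seed + 1,
            rhat_threshold=self.rhat_threshold,
        )


@dataclass(frozen=True)
class PackedData:
    """Flat trial arrays for the jitted likelihoods."""

    participants: list[str]
    starts: np.ndarray
    outcome: np.ndarray
    estimate: np.ndarray
    choice: np.ndarray
    tib: np.ndarray


def pack_dataset(dataset: pd.DataFrame, spec: FitSpec) -> PackedData:
    """Sort and flatten a tidy trial table for one task."""
    df = dataset[dataset["task"] == spec.task] if "task" in dataset.columns else dataset
    if "participant_id" not in df.columns:
        raise ValueError("dataset must have a participant_id column")
    df = df.sort_values(["participant_id", "block", "trial"], kind="mergesort")
    participants = list(dict.fromkeys(df["participant_id"]))
    counts = df.groupby("participant_id", sort=False).size()
    starts = np.zeros(len(participants) + 1, dtype=np.int64)
    starts[1:] = np.cumsum([counts[p] for p in participants])
    outcome = df["outcome"].to_numpy(dtype=np.float64)
    if spec.task == "estimation":
        estimate = df["estimate"].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(estimate)):
            raise ValueError("estimation fits require finite estimates on all trials")
        choice = np.zeros(len(df), dtype=np.int64)
    else:
        estimate = np.zeros(len(df), dtype=np.float64)
        ch = df["option_chosen"].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(ch)):
            raise ValueError("choice fits require option_chosen on all trials")
        choice = ch.astype(np.int64)
        if not np.all((choice == 0) | (choice == 1)):
            raise ValueError("option_chosen must be 0 or 1")
    tib = df["trial"].to_numpy(dtype=np.int64)
    if np.any(~np.isfinite(outcome)):
        raise ValueError("outcomes must be finite")
    return PackedData(participants, starts, outcome, estimate, choice, tib)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (chain, draw, ...) on the natural scale."""

    spec: FitSpec
    mcmc: MCMCConfig
    participants: list[str]
    unit_names: list[str]
    var_names: list[str]
    hyper_mean: np.ndarray  # (C, R, Ku)
    hyper_prec: np.ndarray  # (C, R, Ku)
    hyper_scale: np.ndarray  # (C, R, Kv)
    ind_unit: np.ndarray  # (C, R, N, Ku)
    ind_var: np.ndarray  # (C, R, N, Kv)
    doubled: bool = False

    @property
    def n_retained(self) -> int:
        return self.hyper_mean.shape[0] * self.hyper_mean.shape[1]

    def central_tendency_draws(self, name: str) -> np.ndarray:
        """(chain, draw) draws of the hyperparameter governing a
        parameter's group-level central tendency: the beta group mean
        for unit-interval parameters, the half-Cauchy scale for
        variance-type parameters."""
        if name in self.unit_names:
            return self.hyper_mean[:, :, self.unit_names.index(name)]
        if name in self.var_names:
            return self.hyper_scale[:, :, self.var_names.index(name)]
        raise KeyError(f"unknown parameter {name!r}")

    def individual_draws(self, name: str) -> np.ndarray:
        """(chain, draw, participant) draws of an individual parameter."""
        if name in self.unit_names:
            return self.ind_unit[:, :, :, self.unit_names.index(name)]
        if name in self.var_names:
            return self.ind_var[:, :, :, self.var_names.index(name)]
        raise KeyError(f"unknown parameter {name!r}")

    def individual_medians(self) -> pd.DataFrame:
        """Posterior medians of individual-level parameters, one row per
        participant.  ``c_raw`` is also reported transformed (``c``)."""
        out = {"participant_id": self.participants}
        for k, name in enumerate(self.unit_names):
            med = np.median(self.ind_unit[:, :, :, k].reshape(-1, len(self.participants)), axis=0)
            out[name] = med
            if name == "c_raw":
                out["c"] = 4.0 * med - 2.0
        for k, name in enumerate(self.var_names):
            out[name] = np.median(
                self.ind_var[:, :, :, k].reshape(-1, len(self.participants)), axis=0
            )
        return pd.DataFrame(out)

    def scalar_draw_map(self, include_individual: bool = True) -> dict[str, np.ndarray]:
        """Flat name -> (chain, draw) map over every scalar parameter."""
        out: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.unit_names):
            out[f"m_{name}"] = self.hyper_mean[:, :, k]
            out[f"n_{name}"] = self.hyper_prec[:, :, k]
        for k, name in enumerate(self.var_names):
            out[f"scale_{name}"] = self.hyper_scale[:, :, k]
        if include_individual:
            for k, name in enumerate(self.unit_names):
                for i, pid in enumerate(self.participants):
                    out[f"{name}[{pid}]"] = self.ind_unit[:, :, i, k]
            for k, name in enumerate(self.var_names):
                for i, pid in enumerate(self.participants):
                    out[f"{name}[{pid}]"] = self.ind_var[:, :, i, k]
        return out


def _initial_values(spec: FitSpec, n_part: int, rng: np.random.Generator):
    ku, kv = len(spec.unit_names), len(spec.var_names)
    m0 = rng.uniform(0.15, 0.85, size=ku)
    logn0 = rng.uniform(math.log(2.0), math.log(600.0), size=ku)
    scale0 = np.exp(rng.uniform(math.log(0.05), math.log(200.0), size=kv))
    zu0 = rng.normal(0.0, 1.0, size=(n_part, ku))
    zv0 = np.log(scale0)[None, :] + rng.normal(0.0, 0.5, size=(n_part, kv))
    return m0, logn0, scale0, zu0, zv0


def fit_hierarchical(
    dataset: pd.DataFrame,
    fit_spec: FitSpec,
    mcmc: MCMCConfig | None = None,
    auto_double: bool = False,
) -> PosteriorSamples:
    """Fit one hierarchical model to one population of participants.

    Chains start from distinct overdispersed points and are fully
    deterministic given the seed.  With ``auto_double``, a fit whose
    split R-hat exceeds the threshold is re-run once with twice as many
    draws (the documented remedy); the result is flagged ``doubled``.
    """
    mcmc = mcmc or MCMCConfig()
    packed = pack_dataset(dataset, fit_spec)
    n_part = len(packed.participants)
    ku, kv = len(fit_spec.unit_names), len(fit_spec.var_names)

    chains = []
    root = np.random.SeedSequence(entropy=mcmc.seed)
    for c, ss in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(ss)
        m0, logn0, scale0, zu0, zv0 = _initial_values(fit_spec, n_part, rng)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        res = _kernels.run_chain(
            chain_seed,
            mcmc.n_samples,
            mcmc.burn_in,
            mcmc.thin,
            MODEL_IDS[fit_spec.model],
            DECISION_IDS[fit_spec.decision],
            TASK_IDS[fit_spec.task],
            packed.starts,
            packed.outcome,
            packed.estimate,
            packed.choice,
            packed.tib,
            fit_spec.beta_scale,
            m0,
            logn0,
            scale0,
            np.ascontiguousarray(zu0),
            np.ascontiguousarray(zv0),
        )
        chains.append(res)

    samples = PosteriorSamples(
        spec=fit_spec,
        mcmc=mcmc,
        participants=packed.participants,
        unit_names=fit_spec.unit_names,
        var_names=fit_spec.var_names,
        hyper_mean=np.stack([c[0] for c in chains]),
        hyper_prec=np.stack([c[1] for c in chains]),
        hyper_scale=np.stack([c[2] for c in chains]),
        ind_unit=np.stack([c[3] for c in chains]),
        ind_var=np.stack([c[4] for c in chains]),
    )
    if auto_double and not check_convergence(samples).passed:
        redo = fit_hierarchical(dataset, fit_spec, mcmc.doubled(), auto_double=False)
        redo.doubled = True
        return redo
    return samples


def fit_by_group(
    dataset: pd.DataFrame, fit_spec: FitSpec, mcmc: MCMCConfig | None = None, **kw
) -> dict[str, PosteriorSamples]:
    """Separate group-level distributions per group (fitted independently)."""
    if "group" not in dataset.columns:
        raise ValueError("dataset must have a group column")
    out = {}
    for i, (g, df) in enumerate(dataset.groupby("group", sort=False)):
        cfg = mcmc or MCMCConfig()
        cfg = MCMCConfig(
            n_chains=cfg.n_chains,
            n_samples=cfg.n_samples,
            burn_in=cfg.burn_in,
            thin=cfg.thin,
            seed=cfg.seed + 7919 * i,
            rhat_threshold=cfg.rhat_threshold,
        )
        out[g] = fit_hierarchical(df, fit_spec, cfg, **kw)
    return out


# ---------------------------------------------------------------------------
# diagnostics and summaries


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float
    passed: bool

    def failing(self) -> dict[str, float]:
        return {k: v for k, v in self.rhat.items() if np.isfinite(v) and v > self.threshold}


def split_rhat(draws: np.ndarray) -> float:
    """Split R-hat of one scalar parameter; draws shaped (chain, draw)."""
    c, r = draws.shape
    half = r // 2
    if c < 2 and half < 1:
        raise ValueError("need at least 2 chains")
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def check_convergence(samples: PosteriorSamples) -> ConvergenceReport:
    """Split R-hat per scalar parameter; pass iff all <= threshold."""
    if samples.hyper_mean.shape[0] < 2:
        raise ValueError("convergence check needs at least 2 chains")
    rhat = {
        name: split_rhat(d) for name, d in samples.scalar_draw_map().items()
    }
    finite = [v for v in rhat.values() if np.isfinite(v)]
    passed = all(v <= samples.mcmc.rhat_threshold for v in finite)
    return ConvergenceReport(rhat=rhat, threshold=samples.mcmc.rhat_threshold, passed=passed)


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draws")
    k = max(1, int(math.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def posterior_summaries(samples: PosteriorSamples) -> pd.DataFrame:
    """Medians and 95% HDIs for every scalar parameter."""
    rows = []
    for name, d in samples.scalar_draw_map().items():
        lo, hi = hdi(d)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(d)),
                "hdi_lo": lo,
                "hdi_hi": hi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generic Metropolis utility (used for backend validation on conjugate toys)


def metropolis_sample(
    logpost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    n_samples: int = 20000,
    burn_in: int = 5000,
    step: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Adaptive random-walk Metropolis on an arbitrary log density.

    Single chain, joint Gaussian proposals, step size adapted toward an
    acceptance rate of 0.3 during burn-in.  Returns draws of shape
    (n_samples - burn_in, dim).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("logpost must be finite at x0")
    out = np.empty((n_samples - burn_in, x.size))
    for it in range(n_samples):
        prop = x + step * rng.standard_normal(x.size)
        lp_prop = logpost(prop)
        accept = math.log(rng.random() + 1e-300) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        if it < burn_in:
            step *= math.exp(min(0.25, 5.0 / (it + 1.0) ** 0.7) * ((1.0 if accept else 0.0) - 0.3))
        else:
            out[it - burn_in] = x
    return out
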