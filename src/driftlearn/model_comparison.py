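"""DIC model comparison and posterior group contrasts.

DIC = Dbar + pD, where Dbar is the posterior mean deviance (-2 log
likelihood summed over all trials) and pD = Dbar - Dhat is the effective
number of parameters, with Dhat the deviance at posterior point
estimates of the *individual-level* parameters (hyperparameters
integrated out — the conventional focus when sampling hierarchical
models trial-by-trial).  Point estimates are posterior means by default
(canonical DIC); medians are available because downstream diagnostics
use medians.

DIC differences are mapped to a probability scale via model weights
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .hierarchical_fit import (
    DECISION_IDS,
    MODEL_IDS,
    TASK_IDS,
    FitSpec,
    PosteriorSamples,
    pack_dataset,
)
from .learning_models import DynamicSoftmaxParams, SoftmaxParams, dynamic_beta, transform_c
from .synthetic_data import make_params, _UPDATERS, _init_state

__all__ = [
    "FitResult",
    "compute_dic",
    "dic_weights",
    "average_choice_probability",
    "posterior_group_difference",
]


@dataclass(frozen=True)
class FitResult:
    """DIC decomposition for one model on one dataset."""

    model: str
    decision: str
    task: str
    dbar: float
    dhat: float

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "decision": self.decision,
            "task": self.task,
            "Dbar": self.dbar,
            "Dhat": self.dhat,
            "pD": self.pd,
            "DIC": self.dic,
            "focus": "individual-level parameters",
        }


def compute_dic(
    samples: PosteriorSamples,
    dataset: pd.DataFrame,
    fit_spec: FitSpec | None = None,
    point_estimate: str = "mean",
) -> FitResult:
    """DIC of a fitted model, computed from the retained draws.

    All likelihoods are evaluated in log space (no underflow).  The
    deviance at the point estimate uses the posterior mean (or median)
    of each individual-level parameter.
    """
    spec = fit_spec or samples.spec
    packed = pack_dataset(dataset, spec)
    if packed.participants != samples.participants:
        raise ValueError("dataset participants do not match the fitted samples")
    n = len(packed.participants)
    ku, kv = len(samples.unit_names), len(samples.var_names)
    n_draws = samples.ind_unit.shape[0] * samples.ind_unit.shape[1]
    ind_u = samples.ind_unit.reshape(n_draws, n, ku)
    ind_v = samples.ind_var.reshape(n_draws, n, kv)
    args = (
        MODEL_IDS[spec.model],
        DECISION_IDS[spec.decision],
        TASK_IDS[spec.task],
        packed.starts,
        packed.outcome,
        packed.estimate,
        packed.choice,
        packed.tib,
    )
    dev = _kernels.deviance_draws(*args, ind_u, ind_v, spec.beta_scale)
    dbar = float(dev.mean())
    if point_estimate == "mean":
        u_hat, v_hat = ind_u.mean(axis=0), ind_v.mean(axis=0)
    elif point_estimate == "median":
        u_hat = np.median(ind_u, axis=0)
        v_hat = np.median(ind_v, axis=0)
    else:
        raise ValueError("point_estimate must be 'mean' or 'median'")
    dhat = float(
        -2.0 * _kernels.total_loglik(*args, u_hat, v_hat, spec.beta_scale)
    )
    return FitResult(
        model=spec.model, decision=spec.decision, task=spec.task, dbar=dbar, dhat=dhat
    )


def dic_weights(dic_values) -> np.ndarray:
    """Map DIC values to a probability scale (model weights)."""
    d = np.asarray(dic_values, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two models")
    if np.any(~np.isfinite(d)):
        raise ValueError("DIC values must be finite")
    delta = d - d.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def average_choice_probability(
    dataset: pd.DataFrame,
    individual_medians: pd.DataFrame,
    model: str,
    decision: str,
    beta_scale: float = 1.0,
) -> tuple[float, pd.Series]:
    """Mean model probability of the actually-made choices.

    Runs each model forward over each participant's observed sequence at
    the posterior medians of their individual-level parameters, records
    the softmax probability of the choice actually made, then averages
    over trials within participant and over participants.  Implemented
    with the pure-Python reference updates (independent of the jitted
    likelihood path).
    """
    cho = dataset[dataset["task"] == "choice"]
    med = individual_medians.set_index("participant_id")
    per_part = {}
    for pid, g in cho.groupby("participant_id", sort=False):
        if pid not in med.index:
            raise ValueError(f"missing posterior medians for participant {pid!r}")
        row = med.loc[pid]
        params = make_params(model, row)
        if decision == "constant":
            dec = SoftmaxParams(beta=float(row["beta"]))
        else:
            dec = DynamicSoftmaxParams(
                theta=float(row["theta"]), c=transform_c(float(row["c_raw"]))
            )
        update = _UPDATERS[model]
        probs = []
        for _, blk in g.sort_values(["block", "trial"]).groupby("block", sort=False):
            state = _init_state(model, params, 2, 50.0)
            for _, tr in blk.iterrows():
                t = int(tr["trial"])
                beta = dec.beta if decision == "constant" else dynamic_beta(t, dec)
                beta *= beta_scale
                e = np.array([state.expectation["0"], state.expectation["1"]])
                z = beta * e
                z -= z.max()
                p = np.exp(z) / np.exp(z).sum()
                ch = int(tr["option_chosen"])
                probs.append(p[ch])
                state = update(state, str(ch), float(tr["outcome"]), params)
        per_part[pid] = float(np.mean(probs))
    series = pd.Series(per_part, name="avg_choice_prob")
    return float(series.mean()), series


def posterior_group_difference(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    hyperparam: str,
) -> dict:
    """Difference distribution (A - B) of a group-level central tendency.

    Draws are flattened across chains; if the two fits retained unequal
    numbers of draws the longer set is truncated.  Reports the fraction
    of difference draws below and above zero.
    """
    if hyperparam not in samples_a.unit_names + samples_a.var_names:
        raise ValueError(f"parameter {hyperparam!r} not in fit")
    if (samples_a.unit_names, samples_a.var_names) != (
        samples_b.unit_names,
        samples_b.var_names,
    ):
        raise ValueError("fits have mismatched parameter sets")
    a = samples_a.central_tendency_draws(hyperparam).ravel()
    b = samples_b.central_tendency_draws(hyperparam).ravel()
    r = min(a.size, b.size)
    diff = a[:r] - b[:r]
    return {
        "hyperparam": hyperparam,
        "diff_draws": diff,
        "frac_below_zero": float(np.mean(diff < 0)),
        "frac_above_zero": float(np.mean(diff > 0)),
        "median_diff": float(np.median(diff)),
    }
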