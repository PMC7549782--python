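"""Model-free trial metrics and data-cleaning rules.

Empirical (model-free) per-trial quantities for the two tasks:

* estimation task — estimated prediction error ``delta_hat = outcome -
  estimate`` and empirical learning rate ``alpha_hat = (next estimate -
  estimate) / delta_hat``, with the exclusion rules used for the
  regression analyses (typing-error estimates, zero prediction errors,
  extreme learning rates) and the neighbour-average replacement used
  before model fitting;
* choice task — per-trial accuracy (choice of the option with the
  higher generating mean) and the exploit/explore classification based
  on running mean outcomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "empirical_learning_rates",
    "learning_rate_table",
    "clean_estimates",
    "choice_accuracy",
    "classify_exploration",
    "optimal_learning_rate",
]


def empirical_learning_rates(estimates, outcomes) -> pd.DataFrame:
    """Per-trial prediction errors and empirical learning rates for one block.

    ``delta_hat[t] = outcome[t] - estimate[t]`` and ``alpha_hat[t] =
    (estimate[t+1] - estimate[t]) / delta_hat[t]``.  The last trial has
    no learning rate (no further estimate follows the final outcome),
    and trials with a zero prediction error are flagged excluded.
    """
    est = np.asarray(estimates, dtype=float)
    out = np.asarray(outcomes, dtype=float)
    if est.shape != out.shape or est.ndim != 1:
        raise ValueError("estimates and outcomes must be equal-length 1-d sequences")
    n = est.size
    delta = out - est
    alpha = np.full(n, np.nan)
    reason = np.array([""] * n, dtype=object)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        if t == n - 1:
            reason[t] = "last-trial"
            continue
        if delta[t] == 0.0:
            reason[t] = "zero-PE"
            continue
        alpha[t] = (est[t + 1] - est[t]) / delta[t]
        valid[t] = True
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "delta_hat": delta,
            "alpha_hat": alpha,
            "valid": valid,
            "reason": reason,
        }
    )


def learning_rate_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """Empirical learning rates for every (participant, block) in a tidy
    estimation dataset; returns the dataset with delta_hat / alpha_hat /
    valid / reason columns appended."""
    est = dataset[dataset["task"] == "estimation"]
    if est.empty:
        raise ValueError("no estimation-task rows in dataset")
    pieces = []
    for (_, _), g in est.groupby(["participant_id", "block"], sort=False):
        g = g.sort_values("trial")
        m = empirical_learning_rates(g["estimate"].to_numpy(), g["outcome"].to_numpy())
        g = g.copy()
        for col in ("delta_hat", "alpha_hat", "valid", "reason"):
            g[col] = m[col].to_numpy()
        pieces.append(g)
    return pd.concat(pieces, ignore_index=True)


def _replace_invalid_estimates(block: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Neighbour-average replacement of estimates of 0 or above 100.

    Replacements use the nearest valid preceding and following estimate
    within the block; at block edges the single adjacent valid estimate
    is used.
    """
    est = block["estimate"].to_numpy(dtype=float).copy()
    bad = (est == 0.0) | (est > 100.0)
    n_replaced = int(bad.sum())
    if n_replaced:
        good_idx = np.flatnonzero(~bad)
        if good_idx.size == 0:
            est[:] = 50.0  # no usable estimates in the block at all
        else:
            for i in np.flatnonzero(bad):
                prev = good_idx[good_idx < i]
                nxt = good_idx[good_idx > i]
                vals = []
                if prev.size:
                    vals.append(est[prev[-1]])
                if nxt.size:
                    vals.append(est[nxt[0]])
                est[i] = float(np.mean(vals))
        block = block.copy()
        block["estimate"] = est
    return block, n_replaced


def clean_estimates(
    dataset: pd.DataFrame, mode: str
) -> tuple[pd.DataFrame, dict]:
    """Apply the estimation-task cleaning rules.

    mode="regression": drop trials with estimates of 0 or above 100,
    drop the first certainty rating of the session, compute empirical
    learning rates, then drop learning rates outside the per-group
    1st-99th percentile band (linear-interpolation percentiles; values
    exactly on a boundary are retained).  Retained values are never
    altered.

    mode="modelfit": replace estimates of 0 or above 100 with the
    average of the neighbouring estimates (dataset length preserved).

    Returns (cleaned dataset, exclusion report).
    """
    if mode not in ("regression", "modelfit"):
        raise ValueError("mode must be 'regression' or 'modelfit'")
    est = dataset[dataset["task"] == "estimation"]
    if est.empty:
        raise ValueError("no estimation-task rows in dataset")

    if mode == "modelfit":
        pieces = []
        n_replaced = 0
        for (_, _), g in est.groupby(["participant_id", "block"], sort=False):
            g, k = _replace_invalid_estimates(g.sort_values("trial"))
            n_replaced += k
            pieces.append(g)
        out = pd.concat(pieces, ignore_index=True)
        return out, {"mode": mode, "n_replaced": n_replaced}

    report: dict = {"mode": mode}
    bad_est = (est["estimate"] == 0.0) | (est["estimate"] > 100.0)
    report["n_invalid_estimate"] = int(bad_est.sum())
    est = est[~bad_est]

    # first certainty rating of the session was given before any outcome
    est = est.copy()
    first_mask = np.zeros(len(est), dtype=bool)
    for _, g in est.groupby("participant_id", sort=False):
        g = g.sort_values(["block", "trial"])
        first_mask[est.index.get_indexer([g.index[0]])] = True
    est.loc[first_mask, "certainty"] = np.nan
    report["n_certainty_dropped"] = int(first_mask.sum())

    with_lr = learning_rate_table(est)
    valid = with_lr[with_lr["valid"]]
    report["n_no_learning_rate"] = int(len(with_lr) - len(valid))

    kept = []
    n_trimmed = 0
    if "group" in valid.columns:
        group_iter = valid.groupby("group", sort=False)
    else:
        group_iter = [(None, valid)]
    for _, g in group_iter:
        lo, hi = np.percentile(g["alpha_hat"], [1.0, 99.0])
        inside = (g["alpha_hat"] >= lo) & (g["alpha_hat"] <= hi)
        n_trimmed += int((~inside).sum())
        kept.append(g[inside])
    report["n_percentile_trimmed"] = n_trimmed
    return pd.concat(kept, ignore_index=True), report


def choice_accuracy(dataset: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial choice accuracy and its per-trial-index group means.

    Accuracy is 1 iff the chosen option's generating mean is the higher
    one (columns ``mean_chosen`` / ``mean_unchosen``, recorded by the
    simulator or supplied by the caller).  Blocks with equal generating
    means are flagged with NaN accuracy.
    """
    cho = dataset[dataset["task"] == "choice"].copy()
    if cho.empty:
        raise ValueError("no choice-task rows in dataset")
    if "mean_chosen" not in cho.columns or "mean_unchosen" not in cho.columns:
        raise ValueError("dataset must carry mean_chosen / mean_unchosen columns")
    diff = cho["mean_chosen"] - cho["mean_unchosen"]
    acc = np.where(diff > 0, 1.0, 0.0)
    acc = np.where(diff == 0, np.nan, acc)
    cho["accuracy"] = acc
    keys = ["trial"] if "group" not in cho.columns else ["group", "trial"]
    by_trial = (
        cho.groupby(keys, sort=True)["accuracy"].mean().reset_index(name="accuracy")
    )
    return cho, by_trial


def classify_exploration(dataset: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Label each choice exploitative or exploratory.

    The model-free expected value of each option is the mean of the
    outcomes observed for it so far within the block.  Choosing the
    option with the lower running mean is exploratory, the higher
    exploitative.  Trials before both options have been sampled, and
    trials where the running means tie, are excluded.
    """
    cho = dataset[dataset["task"] == "choice"]
    if cho.empty:
        raise ValueError("no choice-task rows in dataset")
    labels = []
    for (_, _), g in cho.groupby(["participant_id", "block"], sort=False):
        g = g.sort_values("trial")
        sums = [0.0, 0.0]
        counts = [0, 0]
        for _, row in g.iterrows():
            ch = int(row["option_chosen"])
            if counts[0] == 0 or counts[1] == 0:
                labels.append("excluded:unsampled")
            else:
                ev = [sums[0] / counts[0], sums[1] / counts[1]]
                if ev[0] == ev[1]:
                    labels.append("excluded:tie")
                elif ev[ch] > ev[1 - ch]:
                    labels.append("exploit")
                else:
                    labels.append("explore")
            sums[ch] += float(row["outcome"])
            counts[ch] += 1
    out = cho.sort_values(["participant_id", "block", "trial"]).copy()
    out["exploration"] = labels
    counts_summary = out["exploration"].value_counts().to_dict()
    n_labelled = sum(
        v for k, v in counts_summary.items() if k in ("exploit", "explore")
    )
    summary = {
        "counts": counts_summary,
        "explore_fraction": (
            counts_summary.get("explore", 0) / n_labelled if n_labelled else np.nan
        ),
    }
    return out, summary


def optimal_learning_rate(t: int) -> float:
    """Optimal learning rate on (1-based) trial t of a static noisy task.

    With no drift and an uninformative prior, the Bayesian gain is 1/t:
    the weight that makes the estimate the running sample mean of the
    outcomes observed so far.
    """
    if t < 1:
        raise ValueError("trial index is 1-based; t must be >= 1")
    return 1.0 / t
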