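"""Trial-table I/O, run configuration and the end-to-end pipeline.

One tidy CSV dialect for all trial data (comma, UTF-8, header):
participant_id, group, task, block, block_sd_or_gap, trial,
option_chosen, outcome, estimate, certainty.  NA is permitted only in
estimate/certainty for choice rows and option_chosen for estimation
rows.  No operation mutates input files; all outputs go to the run
directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavioural_metrics import clean_estimates
from .hierarchical_fit import MCMCConfig, build_model, fit_by_group, posterior_summaries
from .model_comparison import compute_dic, dic_weights
from .synthetic_data import COLUMNS, default_cohort_spec, generate_cohort

__all__ = ["RunConfig", "read_trials", "write_trials", "run_pipeline"]

_KEY = ["participant_id", "task", "block", "trial"]


class SchemaError(ValueError):
    pass


def read_trials(path) -> pd.DataFrame:
    """Read and validate a tidy trial table."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if len(df) == 0:
        return df
    for col in ("outcome", "estimate", "certainty", "block_sd_or_gap"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise SchemaError(f"non-numeric values in {col!r} at rows {list(bad[:10])}")
    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        rows = list(df.index[dup][:20])
        raise SchemaError(f"duplicate (participant, task, block, trial) keys at rows {rows}")
    if df["outcome"].isna().any():
        rows = list(df.index[df["outcome"].isna()][:20])
        raise SchemaError(f"missing outcomes at rows {rows}")
    est = df["task"] == "estimation"
    if df.loc[est, "estimate"].isna().any():
        rows = list(df.index[est & df["estimate"].isna()][:20])
        raise SchemaError(f"missing estimates on estimation rows {rows}")
    if df.loc[~est, "option_chosen"].isna().any():
        rows = list(df.index[~est & df["option_chosen"].isna()][:20])
        raise SchemaError(f"missing option_chosen on choice rows {rows}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    front = [c for c in COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    df[front + rest].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for an end-to-end run."""

    out_dir: str
    seed: int = 0
    data_path: str | None = None  # if None, a cohort is simulated
    tasks: str = "both"
    models: list[dict] = field(
        default_factory=lambda: [
            {"model": "kf", "decision": "none", "task": "estimation"},
            {"model": "rl", "decision": "none", "task": "estimation"},
        ]
    )
    mcmc_profile: str = "fast"
    estimation_per_noise: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        from .hierarchical_fit import DECISION_IDS, MODEL_IDS, TASK_IDS

        if self.mcmc_profile not in ("fast", "paper"):
            raise SchemaError(f"unknown mcmc profile {self.mcmc_profile!r}")
        for m in self.models:
            if m.get("model") not in MODEL_IDS:
                raise SchemaError(f"unknown model id {m.get('model')!r}")
            if m.get("decision", "none") not in DECISION_IDS:
                raise SchemaError(f"unknown decision id {m.get('decision')!r}")
            if m.get("task") not in TASK_IDS:
                raise SchemaError(f"unknown task {m.get('task')!r}")

    def mcmc(self) -> MCMCConfig:
        if self.mcmc_profile == "fast":
            return MCMCConfig.fast(seed=self.seed)
        return MCMCConfig(seed=self.seed)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> clean -> fit -> compare -> summarize.

    Returns the manifest (also written to the run directory) linking
    every output to its inputs; any stage failure raises with a
    stage-tagged message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "config": asdict(config),
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.time()

        def done(**outputs):
            manifest["stages"][name] = {
                "wall_time_s": round(time.time() - t0, 3),
                **outputs,
            }

        return done

    try:
        done = stage("data")
        if config.data_path is None:
            data, truth = generate_cohort(
                default_cohort_spec(seed=config.seed), tasks=config.tasks
            )
            data_path = out / "trials.csv"
            write_trials(data, data_path)
            truth["participants"].to_csv(out / "true_parameters.csv", index=False)
            done(path=str(data_path), simulated=True, n_rows=len(data))
        else:
            data = read_trials(config.data_path)
            done(path=str(config.data_path), simulated=False, n_rows=len(data))
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[stage:data] {e}") from e

    has_est = (data["task"] == "estimation").any()
    if has_est:
        try:
            done = stage("clean")
            est_clean, report = clean_estimates(data, mode="modelfit")
            data = pd.concat(
                [est_clean, data[data["task"] != "estimation"]], ignore_index=True
            )
            done(**report)
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"[stage:clean] {e}") from e

    results = []
    try:
        done = stage("fit")
        for m in config.models:
            spec = build_model(m["model"], m.get("decision", "none"), m["task"])
            subset = data[data["task"] == m["task"]]
            if subset.empty:
                continue
            if m["task"] == "estimation" and config.estimation_per_noise:
                conditions = {
                    f"sd{int(sd)}": subset[subset["block_sd_or_gap"] == sd]
                    for sd in sorted(subset["block_sd_or_gap"].unique())
                }
            else:
                conditions = {"all": subset}
            for cond, cdf in conditions.items():
                fits = fit_by_group(cdf, spec, config.mcmc())
                for group, samples in fits.items():
                    label = f"{m['model']}+{m.get('decision', 'none')}:{m['task']}:{cond}:{group}"
                    summ = posterior_summaries(samples)
                    summ.to_csv(out / f"summary_{label.replace(':', '_')}.csv", index=False)
                    dic = compute_dic(samples, cdf[cdf["group"] == group], spec)
                    results.append({"label": label, "group": group, "cond": cond,
                                    "task": m["task"], **dic.as_dict()})
        done(n_fits=len(results))
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[stage:fit] {e}") from e

    try:
        done = stage("compare")
        table = pd.DataFrame(results)
        if not table.empty:
            weights = np.full(len(table), np.nan)
            for (_, _), idx in table.groupby(["task", "cond"]).groups.items():
                sub = table.loc[idx]
                if len(sub) >= 2:
                    for g, gidx in sub.groupby("group").groups.items():
                        gsub = table.loc[gidx]
                        if len(gsub) >= 2:
                            weights[table.index.get_indexer(gidx)] = dic_weights(
                                gsub["DIC"].to_numpy()
                            )
            table["weight"] = weights
            table.to_csv(out / "model_comparison.csv", index=False)
        done(path=str(out / "model_comparison.csv"), n_models=len(table))
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[stage:compare] {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
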