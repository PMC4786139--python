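"""Reproducible experiment protocol: M runs per optimizer, full report.

Each optimizer (base ALO or CALO with a named chaotic map) is applied M
times to the same three-way-split dataset.  Run i uses seed ``base + i``
so runs are independent yet exactly reproducible.  Every run forces the
all-features solution into the initial antlion population, guaranteeing
that any subset ever promoted to elite is at least as fit as using every
feature.  Metrics are computed on the held-out test third.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chaos import MAP_NAMES, ChaoticMap
from .data import SplitDataset, SynthSpec, load_dataset, synthetic_split, three_way_split
from .engine import Schedule, SearchSpace, run
from .metrics import (
    RunCollection,
    average_accuracy,
    average_fisher,
    average_selection_size,
    run_statistics,
)
from .objective import FitnessConfig, binarize, holdout_accuracy, subset_fitness

logger = logging.getLogger(__name__)

OPTIMIZER_NAMES = ("alo",) + tuple(f"calo-{m}" for m in MAP_NAMES)


def schedule_for(optimizer: str) -> Schedule:
    """Build the exploration schedule for an optimizer name.

    ``alo`` is the base quasi-linear schedule; ``calo-<map>`` modulates it
    with the named chaotic map.
    """
    if optimizer == "alo":
        return Schedule(mode="base")
    if optimizer.startswith("calo-"):
        return Schedule(mode="chaotic", map_spec=ChaoticMap(optimizer[5:]))
    raise ValueError(f"unknown optimizer {optimizer!r}; expected one of {OPTIMIZER_NAMES}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce an experiment bit for bit."""

    dataset: str | None = None              # path to delimited file, or None
    synth: SynthSpec | None = None          # generated dataset when no path
    optimizers: tuple = ("alo", "calo-tent")
    runs: int = 20
    agents: int = 8
    iterations: int = 70
    alpha: float = 0.99
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.dataset is None and self.synth is None:
            raise ValueError("config needs a dataset path or a synthetic spec")
        for name in self.optimizers:
            schedule_for(name)  # validates


def _load(cfg: ExperimentConfig) -> SplitDataset:
    if cfg.dataset is not None:
        X, y = load_dataset(cfg.dataset)
        return three_way_split(X, y, seed=cfg.seed)
    data, _ = synthetic_split(cfg.synth, split_seed=cfg.seed)
    return data


def optimize_subset(
    data: SplitDataset,
    optimizer: str = "calo-tent",
    agents: int = 8,
    iterations: int = 70,
    fitness_cfg: FitnessConfig = FitnessConfig(),
    seed: int | None = None,
):
    """One feature-selection run; returns (mask, fitness, RunResult)."""
    D = data.n_features
    objective = lambda pos: subset_fitness(binarize(pos), data, fitness_cfg)
    result = run(
        SearchSpace.unit(D),
        objective,
        n_agents=agents,
        n_iterations=iterations,
        schedule=schedule_for(optimizer),
        seed=seed,
        forced_positions=[np.ones(D)],  # all-features solution
    )
    return binarize(result.best_position), result.best_fitness, result


def collect_runs(
    data: SplitDataset,
    optimizer: str,
    cfg: ExperimentConfig,
) -> RunCollection:
    """M independent seeded applications of one optimizer on one dataset."""
    fitness_cfg = FitnessConfig(alpha=cfg.alpha, k=cfg.k)
    fitnesses, masks, preds, seeds = [], [], [], []
    for i in range(cfg.runs):
        seed = cfg.seed + i
        mask, fit, res = optimize_subset(
            data, optimizer, cfg.agents, cfg.iterations, fitness_cfg, seed
        )
        if res.trace[-1] != fit:
            raise RuntimeError("trace end does not match reported best fitness")
        pred, _ = holdout_accuracy(mask, data, fitness_cfg)
        fitnesses.append(fit)
        masks.append(mask)
        preds.append(pred)
        seeds.append(seed)
        logger.info(
            "%s run %d (seed %d): fitness %.5f, %d/%d features",
            optimizer, i, seed, fit, int(mask.sum()), data.n_features,
        )
    return RunCollection(
        fitnesses=np.array(fitnesses),
        masks=np.array(masks),
        test_predictions=preds,
        dataset=data,
        seeds=seeds,
    )


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full protocol: per optimizer, M runs and the complete metric suite.

    A failed run is recorded under ``errors`` and the experiment continues
    with the remaining optimizers.
    """
    data = _load(cfg)
    summary_rows, run_rows, errors = [], [], {}
    collections = {}
    for name in cfg.optimizers:
        try:
            rc = collect_runs(data, name, cfg)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("optimizer %s failed: %s", name, exc)
            errors[name] = str(exc)
            continue
        collections[name] = rc
        stats = run_statistics(rc)
        summary_rows.append(
            {
                "optimizer": name,
                "mean_fitness": stats["mean"],
                "best_fitness": stats["best"],
                "worst_fitness": stats["worst"],
                "std_fitness": stats["std"],
                "avg_accuracy": average_accuracy(rc),
                "avg_selection_size": average_selection_size(rc),
                "avg_fisher": average_fisher(rc),
            }
        )
        for i, (seed, fit, mask) in enumerate(zip(rc.seeds, rc.fitnesses, rc.masks)):
            run_rows.append(
                {
                    "optimizer": name,
                    "run": i,
                    "seed": seed,
                    "best_fitness": fit,
                    "mask": "".join(str(int(b)) for b in mask),
                }
            )
    return {
        "summary": pd.DataFrame(summary_rows),
        "runs": pd.DataFrame(run_rows),
        "collections": collections,
        "errors": errors,
        "config": cfg,
        "dataset": data,
    }


def write_report(report: dict, out_dir) -> Path:
    """Write summary + per-run tables as CSV with a YAML provenance sidecar."""
    if report.get("summary") is None or len(report["summary"]) == 0:
        raise ValueError("refusing to write an empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["summary"].to_csv(out / "summary.csv", index=False)
    report["runs"].to_csv(out / "runs.csv", index=False)
    cfg = report["config"]
    provenance = {
        "config": {
            "dataset": cfg.dataset,
            "synth": None if cfg.synth is None else vars(cfg.synth).copy(),
            "optimizers": list(cfg.optimizers),
            "runs": cfg.runs,
            "agents": cfg.agents,
            "iterations": cfg.iterations,
            "alpha": cfg.alpha,
            "k": cfg.k,
            "seed": cfg.seed,
        },
        "errors": report["errors"],
        "versions": {
            "calofs": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    with open(out / "provenance.yml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    return out


def read_report(out_dir):
    """Load a written report back: (summary, runs, provenance)."""
    out = Path(out_dir)
    summary = pd.read_csv(out / "summary.csv")
    runs = pd.read_csv(out / "runs.csv", dtype={"mask": str})
    with open(out / "provenance.yml") as fh:
        provenance = yaml.safe_load(fh)
    return summary, runs, provenance
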