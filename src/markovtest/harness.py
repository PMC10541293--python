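"""Monte-Carlo harness: rejection-rate tables for the benchmark models.

Reproduces the simulation-study layout (per-model, per-length, per-order
rejection percentages) at a configurable number of replications.  Every
(model, T, k, rep) cell draws its seed deterministically from the master
seed, so tables are reproducible, invariant to the degree of parallelism,
and individual cells can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .simulators import SimSpec
from .engine import TestConfig, markov_test
from .order import concat_lags

logger = logging.getLogger("markovtest")

_MODEL_CODES = {"var3": 1, "threshold3": 2, "arch3": 3, "ar1_gauss": 4,
                "iid_gauss3": 5}


@dataclass
class SimStudySpec:
    model_id: str
    T_grid: tuple = (500,)
    k_grid: tuple = (1, 2, 3, 4, 5)
    n_reps: int = 100
    alpha: float = 0.05
    seed: int = 0
    cfg: TestConfig = field(default_factory=TestConfig)
    n_jobs: int = 1
    checkpoint: str | None = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.model_id not in _MODEL_CODES:
            raise ValueError(f"unknown model {self.model_id!r}")


def _cell_seed(master: int, model_id: str, T: int, k: int, rep: int) -> int:
    ss = np.random.SeedSequence(
        master, spawn_key=(_MODEL_CODES[model_id], T, k, rep))
    return int(ss.generate_state(1)[0])


def run_one_replication(model_id: str, T: int, k: int, rep: int,
                        master_seed: int, cfg: TestConfig,
                        alpha: float) -> bool:
    """Simulate one series, test the Markov property of its k-concatenation."""
    seed = _cell_seed(master_seed, model_id, T, k, rep)
    if model_id == "iid_gauss3":
        rng = np.random.default_rng(seed)
        from .simulators import MultiSeries
        series = MultiSeries(rng.normal(0.0, np.sqrt(0.5), size=(T, 3)))
    else:
        series = SimSpec(model_id=model_id, T=T, seed=seed).simulate()
    lag = concat_lags(series, k)
    run_cfg = dataclasses.replace(cfg, alpha=alpha, seed=seed)
    return bool(markov_test(lag.series, run_cfg).reject)


def run_sim_study(spec: SimStudySpec) -> pd.DataFrame:
    """Rejection-rate table over (T, k) cells with binomial standard errors."""
    done: dict[str, bool] = {}
    ckpt = Path(spec.checkpoint) if spec.checkpoint else None
    if ckpt is not None and ckpt.exists():
        with open(ckpt) as fh:
            for line in fh:
                rec = json.loads(line)
                done[rec["key"]] = rec["reject"]

    tasks = []
    for T in spec.T_grid:
        for k in spec.k_grid:
            for rep in range(spec.n_reps):
                key = f"{spec.model_id}:{T}:{k}:{rep}"
                if key not in done:
                    tasks.append((key, T, k, rep))

    if tasks:
        results = Parallel(n_jobs=spec.n_jobs)(
            delayed(run_one_replication)(
                spec.model_id, T, k, rep, spec.seed, spec.cfg, spec.alpha)
            for _, T, k, rep in tasks)
        for (key, *_), reject in zip(tasks, results):
            done[key] = reject
            if ckpt is not None:
                with open(ckpt, "a") as fh:
                    fh.write(json.dumps({"key": key, "reject": reject}) + "\n")

    rows = []
    for T in spec.T_grid:
        for k in spec.k_grid:
            rejects = [done[f"{spec.model_id}:{T}:{k}:{rep}"]
                       for rep in range(spec.n_reps)]
            rate = float(np.mean(rejects))
            se = float(np.sqrt(rate * (1 - rate) / spec.n_reps))
            rows.append({"model": spec.model_id, "T": T, "k": k,
                         "n_reps": spec.n_reps, "reject_rate": rate,
                         "se": se})
            logger.info("cell model=%s T=%d k=%d: reject rate %.3f (se %.3f)",
                        spec.model_id, T, k, rate, se)
    return pd.DataFrame(rows)
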