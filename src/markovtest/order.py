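"""Markov order determination by sequential testing of lag-concatenated series.

A series of order K becomes first-order Markov once each time point is
replaced by the concatenation of k >= K consecutive observations.  The
estimated order is therefore the first k at which the Markov test fails to
reject, each k tested at level alpha with no multiplicity correction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .simulators import MultiSeries
from .engine import TestConfig, TestResult, markov_test


@dataclass(frozen=True)
class LagConcatSeries:
    """Lag-concatenated view: row t is (X_t', ..., X_{t+k-1}')."""

    base: MultiSeries
    k: int
    series: MultiSeries


@dataclass
class OrderResult:
    k_hat: int
    per_k: list[TestResult]
    censored: bool

    @property
    def stopped_at(self) -> int:
        return len(self.per_k)


def concat_lags(series: MultiSeries, k: int) -> LagConcatSeries:
    """Concatenate k consecutive observations per row, oldest block first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    V = series.values
    if series.T < k + 1:
        raise ValueError(f"series of length {series.T} too short for k={k}")
    rows = series.T - k + 1
    blocks = [V[j:j + rows] for j in range(k)]
    return LagConcatSeries(base=series, k=k,
                           series=MultiSeries(np.hstack(blocks)))


def select_order(series: MultiSeries, k_max: int, cfg: TestConfig,
                 ) -> OrderResult:
    """Sequentially test X_t(k) for k = 1..k_max; first non-rejection wins.

    If every k rejects, the estimate is censored at k_max.  Each k uses a
    seed derived from cfg.seed so the runs are independent but reproducible.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    per_k: list[TestResult] = []
    for k in range(1, k_max + 1):
        lag = concat_lags(series, k)
        sub_seed = int(np.random.SeedSequence(
            cfg.seed, spawn_key=(10, k)).generate_state(1)[0])
        sub_cfg = dataclasses.replace(cfg, seed=sub_seed)
        try:
            res = markov_test(lag.series, sub_cfg)
        except Exception as exc:
            raise RuntimeError(f"Markov test failed at order k={k}: {exc}") from exc
        per_k.append(res)
        if not res.reject:
            return OrderResult(k_hat=k, per_k=per_k, censored=False)
    return OrderResult(k_hat=k_max, per_k=per_k, censored=True)
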