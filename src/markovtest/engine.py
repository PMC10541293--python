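"""Doubly robust Markov-property test: chunking, cross-fitted statistics,
multiplier-bootstrap critical value, decision.

The null hypothesis is that the series is first-order Markov.  For each lag
q = 2..Q and each random frequency pair (mu_b, nu_b) the statistic averages
cross-fitted products of a forward residual exp(i mu' X_{t+q}) − φ̂(mu |
X_{t+q-1}) and a backward residual exp(i nu' X_t) − ψ̂(nu | X_{t+1}); under
the null each summand is a martingale difference, and the expectation of the
product vanishes as long as either the forward or the backward conditional
law is correct (double robustness).  The test statistic is the maximum of
the sqrt(count)-scaled absolute real and imaginary parts over all (q, b),
and its critical value is simulated from the Gaussian law with the matched
empirical covariance of the summands (a multiplier bootstrap).

Generators are fitted on expanding prefixes of the series (chunks 1..ℓ) and
residuals evaluated on chunk ℓ+1 only, so estimation error never correlates
with the evaluation data under the null.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .simulators import MultiSeries
from .mdn import TrainOptions, fit_factorized_generator, select_G_cv
from .ccf import FrequencyPairSet, draw_frequency_pairs

logger = logging.getLogger("markovtest")


# -- chunking --------------------------------------------------------------

@dataclass(frozen=True)
class ChunkScheme:
    """L consecutive non-overlapping chunks of length n = floor(T/L).

    When T is not a multiple of L the oldest T − L·n observations are
    dropped, keeping the most recent data; ``offset`` records how many rows
    were dropped from the front.  Index sets refer to rows of the truncated
    series (0-based).
    """

    L: int
    n: int
    offset: int

    @property
    def T_used(self) -> int:
        return self.L * self.n

    def I(self, ell: int) -> np.ndarray:
        if not 1 <= ell <= self.L:
            raise ValueError(f"chunk index {ell} outside 1..{self.L}")
        return np.arange((ell - 1) * self.n, ell * self.n)

    def I_bar(self, ell: int) -> np.ndarray:
        return np.arange(0, ell * self.n)


def make_chunks(T: int, L: int, q_max: int) -> ChunkScheme:
    if L < 2:
        raise ValueError("need at least L=2 chunks")
    t_min = L * (q_max + 2)
    if T < t_min:
        raise ValueError(
            f"series too short: T={T} but the test with L={L}, Q={q_max} "
            f"needs T >= {t_min}")
    n = T // L
    return ChunkScheme(L=L, n=n, offset=T - L * n)


# -- configuration ---------------------------------------------------------

@dataclass
class TestConfig:
    """Hyper-parameters of the Markov test (defaults follow the benchmark
    study: L=3 chunks, M=100 generator samples, Q=10 lags, B=1000 frequency
    pairs, one hidden layer of width 20, level 0.05)."""

    L: int = 3
    B: int = 1000
    M: int = 100
    Q: int = 10
    G: int | None = None            # None => chronological CV over G_grid
    G_grid: tuple = (1, 2, 3)
    alpha: float = 0.05
    H: int = 1
    U: int = 20
    n_boot: int = 2000
    seed: int = 0
    quantile_level: float | None = None   # default alpha/2 (real/imag two-sidedness)
    cv_folds: int = 5
    lr: float = 1e-2
    epochs: int = 600
    patience: int = 60
    sigma_floor: float = 1e-3

    def __post_init__(self):
        if self.Q < 2:
            raise ValueError("Q must be >= 2")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def train_opts(self, seed: int) -> TrainOptions:
        return TrainOptions(lr=self.lr, epochs=self.epochs, seed=seed,
                            patience=self.patience, sigma_floor=self.sigma_floor)


def _derive_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0])


# -- result containers -----------------------------------------------------

@dataclass
class PairStatArray:
    """Cross-fitted statistics S(q, mu_b, nu_b) for q = 2..Q, b = 1..B."""

    S: np.ndarray          # (Q-1, B) complex
    q_values: np.ndarray   # (Q-1,) ints, 2..Q
    counts: np.ndarray     # (Q-1,) summand counts T−n−(q−1)(L−1)

    @property
    def SR(self) -> np.ndarray:
        return self.S.real

    @property
    def SI(self) -> np.ndarray:
        return self.S.imag

    def scale(self, q: int) -> float:
        i = int(np.flatnonzero(self.q_values == q)[0])
        return float(np.sqrt(self.counts[i]))


@dataclass
class TestResult:
    statistic: float
    critical_value: float
    reject: bool
    p_value: float
    alpha: float
    pair_stats: PairStatArray
    per_q_max: np.ndarray
    bootstrap_draws_used: int
    G_used: int
    config: TestConfig
    timings: dict = field(default_factory=dict)


# -- generator fitting -----------------------------------------------------

def fit_chunk_generators(series: MultiSeries, scheme: ChunkScheme,
                         cfg: TestConfig):
    """(forward, backward) generator pairs for ℓ = 1..L−1, pair ℓ trained
    only on the truncated series rows of chunks 1..ℓ."""
    V = series.values[scheme.offset:]
    if cfg.G is None:
        G = select_G_cv(V[:scheme.n], cfg.G_grid, folds=cfg.cv_folds,
                        train_opts=cfg.train_opts(_derive_seed(cfg.seed, 9)),
                        H=cfg.H, U=cfg.U)
        logger.info("selected G=%d by chronological CV", G)
    else:
        G = int(cfg.G)
    gens = []
    for ell in range(1, scheme.L):
        train = V[:ell * scheme.n]
        pair = []
        for direction in ("forward", "backward"):
            try:
                gen = fit_factorized_generator(
                    train, direction, G=G, H=cfg.H, U=cfg.U,
                    train_opts=cfg.train_opts(_derive_seed(cfg.seed, 1, ell)))
            except Exception as exc:
                raise RuntimeError(
                    f"fitting {direction} generator for chunk {ell} failed: {exc}"
                ) from exc
            pair.append(gen)
        logger.info("chunk %d generators fitted on %d rows (G=%d)",
                    ell, train.shape[0] - 1, G)
        gens.append(tuple(pair))
    return gens, G


# -- residual machinery ----------------------------------------------------

def _residual_arrays(V: np.ndarray, scheme: ChunkScheme, gens,
                     pairs: FrequencyPairSet, M: int, seed: int):
    """Per-chunk forward/backward residual matrices.

    For chunk ℓ the conditioning rows are r = ℓn .. ℓn+n−2 (all of chunk
    ℓ+1 except its last row).  Row i of the forward matrix is
    exp(i mu_b' V[r+1]) − φ̂^{(ℓ)}(mu_b | V[r]); row i of the backward
    matrix is exp(i nu_b' V[r−1]) − ψ̂^{(ℓ)}(nu_b | V[r]).  The same M
    generator samples per conditioning row are shared across all B
    frequencies and reused for both the statistic and its covariance.
    """
    n, L = scheme.n, scheme.L
    proj_mu = V @ pairs.mu.T                 # (T_used, B)
    proj_nu = V @ pairs.nu.T
    exp_mu = np.cos(proj_mu) + 1j * np.sin(proj_mu)
    exp_nu = np.cos(proj_nu) + 1j * np.sin(proj_nu)
    out = []
    for ell in range(1, L):
        rows = np.arange(ell * n, ell * n + n - 1)
        fwd, bwd = gens[ell - 1]
        rng_f = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(3, ell, 0)))
        rng_b = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(3, ell, 1)))
        phi = fwd.ccf_matrix(V[rows], pairs.mu, M, rng_f)
        psi = bwd.ccf_matrix(V[rows], pairs.nu, M, rng_b)
        fres = exp_mu[rows + 1] - phi
        bres = exp_nu[rows - 1] - psi
        out.append((fres, bres))
    return out


def _summands(residuals, scheme: ChunkScheme, q: int) -> np.ndarray:
    """Stacked per-(ℓ,t) complex summands of the cross-fitted statistic."""
    n = scheme.n
    parts = []
    for fres, bres in residuals:
        # t = 1..n−q+1: forward local index t+q−3, backward local index t−1
        parts.append(fres[q - 2:n - 1] * bres[:n - q + 1])
    return np.concatenate(parts, axis=0)


def _expected_count(scheme: ChunkScheme, q: int) -> int:
    return scheme.T_used - scheme.n - (q - 1) * (scheme.L - 1)


# -- public statistic operations ------------------------------------------

def pair_statistic(series: MultiSeries, scheme: ChunkScheme, gens,
                   pairs: FrequencyPairSet, q: int, b: int, M: int,
                   rng: np.random.Generator) -> complex:
    """The cross-fitted statistic S(q, mu_b, nu_b) for a single (q, b)."""
    if not 2 <= q <= scheme.n:
        raise ValueError(f"q={q} out of range")
    V = series.values[scheme.offset:]
    sub = FrequencyPairSet(mu=pairs.mu[b:b + 1], nu=pairs.nu[b:b + 1],
                           seed=pairs.seed)
    seed = int(rng.integers(2 ** 31 - 1))
    residuals = _residual_arrays(V, scheme, gens, sub, M, seed)
    s = _summands(residuals, scheme, q)
    assert s.shape[0] == _expected_count(scheme, q), "normaliser/count mismatch"
    return complex(s.mean())


def aggregate_statistic(pair_stats: PairStatArray) -> float:
    """Max over (q, b) of sqrt(count_q) * max(|Re S|, |Im S|)."""
    scales = np.sqrt(pair_stats.counts)[:, None]
    scaled = scales * np.maximum(np.abs(pair_stats.SR), np.abs(pair_stats.SI))
    return float(scaled.max())


def estimate_covariances(series: MultiSeries, scheme: ChunkScheme, gens,
                         pairs: FrequencyPairSet, Q: int, M: int,
                         rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Empirical 2B×2B covariance of the stacked (real, imag) summands for
    each q; the Gram-matrix construction makes each estimate PSD."""
    V = series.values[scheme.offset:]
    seed = int(rng.integers(2 ** 31 - 1))
    residuals = _residual_arrays(V, scheme, gens, pairs, M, seed)
    covs = {}
    for q in range(2, Q + 1):
        s = _summands(residuals, scheme, q)
        count = _expected_count(scheme, q)
        assert s.shape[0] == count, "normaliser/count mismatch"
        lam = np.hstack([s.real, s.imag])       # (count, 2B)
        covs[q] = lam.T @ lam / count
    return covs


def _upper_quantile(draws: np.ndarray, level: float) -> float:
    return float(np.quantile(draws, 1.0 - level, method="higher"))


def bootstrap_critical_value(covs: dict[int, np.ndarray], alpha: float,
                             n_boot: int, rng: np.random.Generator, *,
                             quantile_level: float | None = None) -> float:
    """Upper (alpha/2) empirical quantile of max_q ||Σ̂(q)^{1/2} Z_q||_∞
    over n_boot Monte-Carlo draws, Z_q iid standard normal.

    Matrix square roots come from symmetric eigendecompositions with
    negative eigenvalues clipped at zero; eigenvalues below −1e−8 (relative)
    are treated as an error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    level = alpha / 2 if quantile_level is None else quantile_level
    roots = {}
    for q, cov in covs.items():
        w, v = sla.eigh(cov)
        tol = 1e-8 * max(1.0, abs(w).max())
        if w.min() < -tol:
            raise ValueError(f"covariance for q={q} is not PSD "
                             f"(min eigenvalue {w.min():.3e})")
        roots[q] = v * np.sqrt(np.clip(w, 0.0, None))
    draws = np.full(n_boot, -np.inf)
    for q, root in roots.items():
        z = rng.standard_normal((root.shape[1], n_boot))
        vals = np.abs(root @ z).max(axis=0)
        np.maximum(draws, vals, out=draws)
    return _upper_quantile(draws, level)


def _bootstrap_from_summands(summand_list, counts, alpha, n_boot, rng,
                             quantile_level=None):
    """Multiplier bootstrap directly from the summand factors.

    For each q, Λ_q stacks the real and imaginary parts of the per-(ℓ,t)
    summands; Λ_q' ξ / sqrt(count_q) with ξ ~ N(0, I) has exactly the
    N(0, Σ̂(q)) law used by the eigendecomposition route, without forming
    the 2B×2B matrix.  Returns (critical value, all draws).
    """
    level = alpha / 2 if quantile_level is None else quantile_level
    draws = np.full(n_boot, -np.inf)
    for s, count in zip(summand_list, counts):
        lam = np.hstack([s.real, s.imag])       # (count, 2B)
        xi = rng.standard_normal((lam.shape[0], n_boot))
        vals = np.abs(lam.T @ xi).max(axis=0) / np.sqrt(count)
        np.maximum(draws, vals, out=draws)
    return _upper_quantile(draws, level), draws


# -- the full procedure ----------------------------------------------------

def markov_test(series: MultiSeries, cfg: TestConfig) -> TestResult:
    """Run the complete testing procedure and return the decision.

    Fully deterministic given ``cfg.seed``: generator training, generator
    sampling, frequency pairs and bootstrap multipliers all draw from
    streams derived from it.
    """
    t0 = time.perf_counter()
    timings = {}
    scheme = make_chunks(series.T, cfg.L, cfg.Q)
    if scheme.offset:
        logger.info("T=%d not a multiple of L=%d: dropped %d oldest rows",
                    series.T, cfg.L, scheme.offset)
    V = series.values[scheme.offset:]

    gens, G_used = fit_chunk_generators(series, scheme, cfg)
    timings["fit"] = time.perf_counter() - t0

    pairs = draw_frequency_pairs(cfg.B, series.d, _derive_seed(cfg.seed, 2))
    t1 = time.perf_counter()
    residuals = _residual_arrays(V, scheme, gens, pairs, cfg.M,
                                 _derive_seed(cfg.seed, 3))
    timings["ccf"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    q_values = np.arange(2, cfg.Q + 1)
    S = np.empty((q_values.size, cfg.B), complex)
    counts = np.empty(q_values.size, int)
    summand_list = []
    for i, q in enumerate(q_values):
        s = _summands(residuals, scheme, int(q))
        count = _expected_count(scheme, int(q))
        assert s.shape[0] == count, "normaliser/count mismatch"
        S[i] = s.mean(axis=0)
        counts[i] = count
        summand_list.append(s)
    pair_stats = PairStatArray(S=S, q_values=q_values, counts=counts)
    per_q_max = np.sqrt(counts) * np.maximum(
        np.abs(S.real), np.abs(S.imag)).max(axis=1)
    stat = aggregate_statistic(pair_stats)
    timings["statistic"] = time.perf_counter() - t2
    logger.info("statistic %.4f (argmax q=%d)", stat,
                q_values[int(np.argmax(per_q_max))])

    t3 = time.perf_counter()
    rng_boot = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(4,)))
    crit, draws = _bootstrap_from_summands(
        summand_list, counts, cfg.alpha, cfg.n_boot, rng_boot,
        cfg.quantile_level)
    timings["bootstrap"] = time.perf_counter() - t3
    p_value = min(1.0, 2.0 * float(np.mean(draws >= stat)))
    reject = bool(stat > crit)
    logger.info("critical value %.4f at level %.3f -> %s (p=%.4f)",
                crit, cfg.alpha, "REJECT" if reject else "retain", p_value)
    timings["total"] = time.perf_counter() - t0
    return TestResult(statistic=stat, critical_value=crit, reject=reject,
                      p_value=p_value, alpha=cfg.alpha, pair_stats=pair_stats,
                      per_q_max=per_q_max, bootstrap_draws_used=cfg.n_boot,
                      G_used=G_used, config=dataclasses.replace(cfg),
                      timings=timings)
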