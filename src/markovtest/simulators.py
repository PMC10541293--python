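"""Synthetic multivariate time series used to calibrate and test the Markov test.

Three benchmark data-generating processes of known Markov order K=3 and
dimension d=3 — a linear VAR(3), a threshold AR(3) and a multivariate
ARCH(3) — plus a pedagogical Gaussian AR(1) whose conditional characteristic
function is available in closed form.  All innovations are iid Normal with
mean zero and variance ``noise_var`` (default 0.5).

Every simulator draws its innovations from an explicit ``numpy`` Generator
seeded by the caller, discards a burn-in prefix started from the zero state,
and returns exactly ``T`` rows; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NOISE_VAR = 0.5
DEFAULT_BURN_IN = 500

# VAR / threshold coefficient matrices (shared A regime).
A1 = np.array([[0.5, -0.2, -0.2],
               [-0.2, 0.5, -0.2],
               [-0.2, -0.2, 0.5]])
A2 = np.array([[-0.5, 0.2, 0.2],
               [0.2, -0.5, 0.2],
               [0.2, 0.2, -0.5]])
A3 = np.array([[0.4, -0.1, -0.1],
               [-0.1, 0.4, -0.1],
               [-0.1, -0.1, 0.4]])

# Threshold model, regime "sum of previous components > 0".
# Note: row 3 of B1 is (−0.1, −0.3, 0.3), not symmetric.
B1 = np.array([[0.3, -0.1, -0.1],
               [-0.1, 0.3, -0.1],
               [-0.1, -0.3, 0.3]])
B2 = np.array([[-0.3, 0.1, 0.1],
               [0.1, -0.3, 0.1],
               [0.1, 0.1, -0.3]])
B3 = np.array([[0.25, -0.05, -0.05],
               [-0.05, 0.25, -0.05],
               [-0.05, -0.05, 0.25]])

# ARCH volatility recursions: h_j = omega_j + sum_k alpha_j[k] * xtilde_{t-k,j}^2
ARCH_OMEGA = np.array([0.1, 0.2, 0.1])
ARCH_ALPHA = np.array([[0.6, 0.0, 0.35],
                       [0.8, 0.05, 0.1],
                       [0.3, 0.0, 0.65]])   # columns: lags 1..3
ARCH_MIX = np.array([[1.0, 0.2, 0.2],
                     [0.2, 1.0, 0.2],
                     [0.2, 0.2, 1.0]])


@dataclass(frozen=True)
class MultiSeries:
    """A T×d real-valued time series; rows are time points."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError("values must be a T×d matrix")
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise ValueError("need T >= 2 rows and d >= 1 columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SimSpec:
    """Declarative description of a simulation run (used by the CLI/harness)."""

    model_id: str
    T: int
    seed: int
    burn_in: int = DEFAULT_BURN_IN
    noise_var: float = DEFAULT_NOISE_VAR
    rho: float = 0.5  # only for ar1_gauss
    extra: dict = field(default_factory=dict)

    def simulate(self) -> MultiSeries:
        if self.model_id == "var3":
            return simulate_var3(self.T, self.seed, burn_in=self.burn_in,
                                 noise_var=self.noise_var)
        if self.model_id == "threshold3":
            return simulate_threshold3(self.T, self.seed, burn_in=self.burn_in,
                                       noise_var=self.noise_var)
        if self.model_id == "arch3":
            return simulate_arch3(self.T, self.seed, burn_in=self.burn_in,
                                  noise_var=self.noise_var)
        if self.model_id == "ar1_gauss":
            return simulate_ar1_gauss(self.T, self.rho, self.seed,
                                      burn_in=self.burn_in,
                                      sigma=float(np.sqrt(self.noise_var)))
        raise ValueError(f"unknown model_id {self.model_id!r}")


def _check_T(T: int) -> None:
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")


def simulate_var3(T: int, seed: int, *, burn_in: int = DEFAULT_BURN_IN,
                  noise_var: float = DEFAULT_NOISE_VAR) -> MultiSeries:
    """Linear VAR(3): X_t = A1 X_{t-1} + A2 X_{t-2} + A3 X_{t-3} + eps_t."""
    _check_T(T)
    rng = np.random.default_rng(seed)
    n = burn_in + T
    eps = rng.normal(0.0, np.sqrt(noise_var), size=(n, 3))
    x = np.zeros((n + 3, 3))
    for t in range(n):
        i = t + 3
        x[i] = A1 @ x[i - 1] + A2 @ x[i - 2] + A3 @ x[i - 3] + eps[t]
    return MultiSeries(x[3 + burn_in:])


def simulate_threshold3(T: int, seed: int, *, burn_in: int = DEFAULT_BURN_IN,
                        noise_var: float = DEFAULT_NOISE_VAR) -> MultiSeries:
    """Threshold AR(3): regime A (A1,A2,A3) when sum_j X_{t-1,j} <= 0, else B.

    The boundary (sum exactly 0) belongs to regime A.
    """
    _check_T(T)
    rng = np.random.default_rng(seed)
    n = burn_in + T
    eps = rng.normal(0.0, np.sqrt(noise_var), size=(n, 3))
    x = np.zeros((n + 3, 3))
    for t in range(n):
        i = t + 3
        if x[i - 1].sum() <= 0.0:
            x[i] = A1 @ x[i - 1] + A2 @ x[i - 2] + A3 @ x[i - 3] + eps[t]
        else:
            x[i] = B1 @ x[i - 1] + B2 @ x[i - 2] + B3 @ x[i - 3] + eps[t]
    return MultiSeries(x[3 + burn_in:])


def simulate_arch3(T: int, seed: int, *, burn_in: int = DEFAULT_BURN_IN,
                   noise_var: float = DEFAULT_NOISE_VAR) -> MultiSeries:
    """Multivariate ARCH: latent X~_{t,j} = sqrt(h_{t,j}) eps_{t,j}, X_t = A X~_t.

    Volatilities follow per-coordinate ARCH(3) recursions with intercepts
    (0.1, 0.2, 0.1); the mixing matrix has unit diagonal and 0.2 off-diagonal.
    """
    _check_T(T)
    rng = np.random.default_rng(seed)
    n = burn_in + T
    eps = rng.normal(0.0, np.sqrt(noise_var), size=(n, 3))
    xt = np.zeros((n + 3, 3))   # latent X~ with 3 zero-history rows
    for t in range(n):
        i = t + 3
        past_sq = xt[i - 1::-1][:3] ** 2   # rows: lag 1, 2, 3
        h = ARCH_OMEGA + np.einsum("jk,kj->j", ARCH_ALPHA, past_sq)
        xt[i] = np.sqrt(h) * eps[t]
    latent = xt[3 + burn_in:]
    return MultiSeries(latent @ ARCH_MIX.T)


def simulate_ar1_gauss(T: int, rho: float, seed: int, *,
                       sigma: float = float(np.sqrt(DEFAULT_NOISE_VAR)),
                       burn_in: int = DEFAULT_BURN_IN) -> MultiSeries:
    """Univariate Gaussian AR(1): X_t = rho X_{t-1} + sigma Z_t.

    The stationary law is N(0, sigma^2/(1-rho^2)) and the forward CCF is
    E[exp(i mu X_{t+1}) | X_t = x] = exp(i mu rho x - mu^2 sigma^2 / 2);
    by Gaussian time-reversibility the backward CCF has the same form.
    """
    _check_T(T)
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1 for stationarity, got {rho}")
    rng = np.random.default_rng(seed)
    n = burn_in + T
    z = rng.normal(0.0, sigma, size=n)
    x = np.empty(n + 1)
    x[0] = 0.0
    for t in range(n):
        x[t + 1] = rho * x[t] + z[t]
    return MultiSeries(x[1 + burn_in:][:, None])


def ar1_ccf(mu, x, rho: float, sigma: float) -> np.ndarray:
    """Closed-form AR(1) conditional characteristic function (broadcasting)."""
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(x, dtype=float)
    return np.exp(1j * mu * rho * x - 0.5 * mu ** 2 * sigma ** 2)
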