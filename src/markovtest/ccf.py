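"""Conditional characteristic functions estimated by Monte Carlo.

The forward CCF is φ*(μ|x) = E[exp(iμ'X_{t+1}) | X_t = x] and the backward
CCF conditions the past on the present.  Both are estimated by averaging
exp(iμ's) over M samples s drawn from a fitted conditional generator at the
conditioning point x, so the estimate always has modulus at most 1 and is
conjugate-symmetric in the frequency when the samples are shared.

Any object with a ``ccf_matrix(X, freqs, M, rng) -> (n, B) complex`` method
can stand in for a generator here; ``GaussianAR1CCF`` provides the exact
closed form for the Gaussian AR(1), used as an oracle in the test suite and
for double-robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FrequencyPairSet:
    """B random projection pairs (mu_b, nu_b), each iid N(0, I_d)."""

    mu: np.ndarray   # (B, d)
    nu: np.ndarray   # (B, d)
    seed: int

    @property
    def B(self) -> int:
        return self.mu.shape[0]

    @property
    def d(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class CCFValue:
    value: complex
    at: np.ndarray
    freq: np.ndarray


def draw_frequency_pairs(B: int, d: int, seed: int, *,
                         dist: str = "normal") -> FrequencyPairSet:
    """Draw B iid standard-normal frequency pairs; deterministic given seed.

    ``dist`` is a stub for alternative projection laws (e.g. uniform); only
    the Gaussian option is implemented.
    """
    if B < 1 or d < 1:
        raise ValueError("B and d must be positive")
    if dist != "normal":
        raise NotImplementedError(f"frequency distribution {dist!r} not implemented")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((2 * B, d))
    return FrequencyPairSet(mu=draws[:B], nu=draws[B:], seed=seed)


def estimate_ccf(gen, x, freq, M: int, rng: np.random.Generator) -> CCFValue:
    """Monte-Carlo CCF estimate at one conditioning point and one frequency."""
    if M < 1:
        raise ValueError("M must be >= 1")
    x = np.atleast_1d(np.asarray(x, float))
    freq = np.atleast_1d(np.asarray(freq, float))
    val = gen.ccf_matrix(x[None, :], freq[None, :], M, rng)[0, 0]
    return CCFValue(value=complex(val), at=x, freq=freq)


class GaussianAR1CCF:
    """Exact CCF of a Gaussian AR(1): X_next | X_t = x ~ N(rho x, sigma^2).

    By time-reversibility of the stationary Gaussian AR(1) the same formula
    is the backward CCF, so a single object serves either direction.  An
    optional mean ``shift`` deliberately corrupts the conditional law
    (samples shifted by a constant), which multiplies the CCF by
    exp(i freq' shift) — used to probe double robustness.
    """

    def __init__(self, rho: float, sigma: float, shift: float = 0.0):
        self.rho = float(rho)
        self.sigma = float(sigma)
        self.shift = float(shift)

    def ccf_matrix(self, X, freqs, M=None, rng=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        freqs = np.atleast_2d(np.asarray(freqs, float))
        # univariate: project explicitly to support d=1 inputs of shape (n,1)
        proj = X @ freqs.T * self.rho + self.shift * freqs.T.sum(axis=0)
        var = (self.sigma ** 2) * (freqs ** 2).sum(axis=1)
        return np.exp(1j * proj - 0.5 * var[None, :])


class GaussianAR1Generator:
    """Sampling (not closed-form) Gaussian AR(1) conditional generator.

    Draws X_next ~ N(rho x + shift, sigma^2); its ``ccf_matrix`` therefore
    carries Monte-Carlo error of order 1/sqrt(M), unlike ``GaussianAR1CCF``.
    """

    def __init__(self, rho: float, sigma: float, shift: float = 0.0):
        self.rho = float(rho)
        self.sigma = float(sigma)
        self.shift = float(shift)
        self.dy = 1

    def sample(self, X, M: int, rng: np.random.Generator) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        mean = self.rho * X[:, :1] + self.shift
        z = rng.standard_normal((X.shape[0], M, 1))
        return mean[:, None, :] + self.sigma * z

    def ccf_matrix(self, X, freqs, M: int, rng: np.random.Generator, *,
                   block: int = 256) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        freqs = np.atleast_2d(np.asarray(freqs, float))
        n = X.shape[0]
        out = np.empty((n, freqs.shape[0]), complex)
        for lo in range(0, n, block):
            hi = min(lo + block, n)
            samp = self.sample(X[lo:hi], M, rng)
            proj = samp.reshape(-1, 1) @ freqs.T
            re = np.cos(proj).reshape(hi - lo, M, -1).mean(axis=1)
            im = np.sin(proj).reshape(hi - lo, M, -1).mean(axis=1)
            out[lo:hi] = re + 1j * im
        return out
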