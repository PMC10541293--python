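"""Mixture density networks for conditional density estimation and sampling.

A univariate MDN models f(y|x) as a G-component Gaussian mixture whose
weights, means and standard deviations are produced by a small fully
connected network: H tanh hidden layers of width U, a tanh layer of width G,
and three parallel G×G affine heads passed through softmax (weights),
identity (means) and softplus (standard deviations).

Multivariate conditional laws are modelled by factorising the joint
conditional density into a product of univariate conditionals, one per
response coordinate, each conditioning on the predictor plus the previously
generated response coordinates; sampling is ancestral through the chain.

The networks are small enough that maximum-likelihood training is done here
directly: full-batch Adam on the exact analytic gradient of the mixture
negative log-likelihood, with inputs and response standardised by
training-set moments.  Everything is deterministic given the training seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .simulators import MultiSeries

_LOG_2PI = float(np.log(2.0 * np.pi))
DEFAULT_SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class MixtureHead:
    """Mixture parameters (alpha, mu, sigma) at one conditioning point."""

    alpha: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha, float)
        if a.ndim != 1 or not np.isclose(a.sum(), 1.0, atol=1e-8) or (a < 0).any():
            raise ValueError("alpha must be a probability vector")
        if (np.asarray(self.sigma, float) <= 0).any():
            raise ValueError("sigma must be strictly positive")

    @property
    def mean(self) -> float:
        return float(self.alpha @ self.mu)


@dataclass
class TrainOptions:
    """Adam schedule for MDN maximum likelihood.

    Full-batch gradient steps; ``epochs`` is therefore the number of Adam
    updates.  Training stops early once the best NLL has not improved by
    ``tol`` for ``patience`` consecutive epochs, and the best-seen parameters
    are kept.
    """

    lr: float = 1e-2
    epochs: int = 600
    seed: int = 0
    patience: int = 60
    tol: float = 1e-5
    sigma_floor: float = DEFAULT_SIGMA_FLOOR


def _softplus(s):
    return np.logaddexp(0.0, s)


def _softplus_inv(y):
    y = np.asarray(y, float)
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-12))))


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class MDNUnivariate:
    """A trained (or constructed) univariate mixture density network."""

    def __init__(self, d0: int, G: int, H: int = 1, U: int = 20, *,
                 sigma_floor: float = DEFAULT_SIGMA_FLOOR):
        if G < 1 or H < 1 or U < 1 or d0 < 1:
            raise ValueError("d0, G, H, U must all be positive")
        self.d0, self.G, self.H, self.U = int(d0), int(G), int(H), int(U)
        self.sigma_floor = float(sigma_floor)
        # standardisation (identity until fitted)
        self.x_mean = np.zeros(d0)
        self.x_std = np.ones(d0)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.params: dict[str, np.ndarray] = {}
        self.train_nll_: float | None = None

    # -- construction -----------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> None:
        p = {}
        widths = [self.d0] + [self.U] * self.H
        for i in range(self.H):
            p[f"W{i}"] = _glorot(rng, widths[i], widths[i + 1])
            p[f"b{i}"] = np.zeros(widths[i + 1])
        p["Wg"] = _glorot(rng, self.U, self.G)
        p["bg"] = np.zeros(self.G)
        for name in ("a", "m", "s"):
            p[f"A{name}"] = _glorot(rng, self.G, self.G)
        p["ba"] = np.zeros(self.G)
        # spread component means across the standardised response range
        p["bm"] = (np.linspace(-1.5, 1.5, self.G) if self.G > 1
                   else np.zeros(1))
        p["bs"] = np.full(self.G, float(_softplus_inv(1.0)))
        self.params = p

    @classmethod
    def with_constant_heads(cls, alpha, mu, sigma, d0: int = 1, *,
                            sigma_floor: float = DEFAULT_SIGMA_FLOOR):
        """Build a degenerate model whose heads ignore x (test/diagnostic aid)."""
        alpha = np.asarray(alpha, float)
        mu = np.asarray(mu, float)
        sigma = np.asarray(sigma, float)
        G = alpha.size
        m = cls(d0, G, 1, 1, sigma_floor=sigma_floor)
        m.init_params(np.random.default_rng(0))
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        with np.errstate(divide="ignore"):
            m.params["ba"] = np.log(np.maximum(alpha, 1e-300))
        m.params["bm"] = mu.copy()
        m.params["bs"] = np.asarray(
            _softplus_inv(np.maximum(sigma - sigma_floor, 1e-12)), float)
        return m

    # -- forward pass ------------------------------------------------------

    def _forward(self, xs: np.ndarray, want_cache: bool = False):
        """Heads from standardised input; xs is (N, d0)."""
        p = self.params
        hs = []
        h = xs
        for i in range(self.H):
            h = np.tanh(h @ p[f"W{i}"] + p[f"b{i}"])
            hs.append(h)
        hg = np.tanh(h @ p["Wg"] + p["bg"])
        a = hg @ p["Aa"] + p["ba"]
        mu = hg @ p["Am"] + p["bm"]
        s = hg @ p["As"] + p["bs"]
        a = a - a.max(axis=1, keepdims=True)
        ea = np.exp(a)
        alpha = ea / ea.sum(axis=1, keepdims=True)
        sigma = _softplus(s) + self.sigma_floor
        if want_cache:
            return alpha, mu, sigma, (xs, hs, hg, s)
        return alpha, mu, sigma

    def heads(self, x: np.ndarray) -> MixtureHead:
        """Mixture parameters at one raw conditioning point, original units."""
        x = np.atleast_1d(np.asarray(x, float))
        xs = (x[None, :] - self.x_mean) / self.x_std
        alpha, mu, sigma = self._forward(xs)
        return MixtureHead(alpha[0],
                           mu[0] * self.y_std + self.y_mean,
                           sigma[0] * self.y_std)

    def heads_batch(self, X: np.ndarray):
        """(alpha, mu, sigma) arrays of shape (N, G) in original units."""
        X = np.atleast_2d(np.asarray(X, float))
        xs = (X - self.x_mean) / self.x_std
        alpha, mu, sigma = self._forward(xs)
        return alpha, mu * self.y_std + self.y_mean, sigma * self.y_std

    # -- density / sampling ------------------------------------------------

    def log_density(self, y, X) -> np.ndarray:
        """log f(y|x) in original units; y is (N,), X is (N, d0)."""
        y = np.atleast_1d(np.asarray(y, float))
        alpha, mu, sigma = self.heads_batch(X)
        z = (y[:, None] - mu) / sigma
        comp = np.log(alpha + 1e-300) - np.log(sigma) - 0.5 * z ** 2 \
            - 0.5 * _LOG_2PI
        m = comp.max(axis=1)
        return m + np.log(np.exp(comp - m[:, None]).sum(axis=1))

    def density(self, y, X) -> np.ndarray:
        return np.exp(self.log_density(y, X))

    def sample(self, X: np.ndarray, M: int, rng: np.random.Generator):
        """(N, M) draws from the fitted conditional mixture, original units."""
        alpha, mu, sigma = self.heads_batch(X)
        N = alpha.shape[0]
        u = rng.random((N, M, 1))
        cum = np.cumsum(alpha, axis=1)[:, None, :]
        comp = (u > cum).sum(axis=2)            # (N, M) component indices
        rows = np.arange(N)[:, None]
        z = rng.standard_normal((N, M))
        return mu[rows, comp] + sigma[rows, comp] * z

    # -- training ----------------------------------------------------------

    def _nll_and_grads(self, xs, ys):
        p = self.params
        alpha, mu, sigma, (x0, hs, hg, s) = self._forward(xs, want_cache=True)
        N = xs.shape[0]
        z = (ys[:, None] - mu) / sigma
        comp = np.log(alpha + 1e-300) - np.log(sigma) - 0.5 * z ** 2 \
            - 0.5 * _LOG_2PI
        m = comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(comp - m).sum(axis=1))
        nll = -lse.mean()
        r = np.exp(comp - lse[:, None])          # responsibilities
        ga = (alpha - r) / N                     # d nll / d pre-softmax
        gm = (-r * z / sigma) / N
        gsig = (-r * (z ** 2 - 1.0) / sigma) / N
        gs = gsig / (1.0 + np.exp(-s))           # softplus'
        grads = {
            "Aa": hg.T @ ga, "ba": ga.sum(0),
            "Am": hg.T @ gm, "bm": gm.sum(0),
            "As": hg.T @ gs, "bs": gs.sum(0),
        }
        ghg = ga @ p["Aa"].T + gm @ p["Am"].T + gs @ p["As"].T
        gug = ghg * (1.0 - hg ** 2)
        prev = hs[-1]
        grads["Wg"] = prev.T @ gug
        grads["bg"] = gug.sum(0)
        gh = gug @ p["Wg"].T
        for i in range(self.H - 1, -1, -1):
            gu = gh * (1.0 - hs[i] ** 2)
            below = x0 if i == 0 else hs[i - 1]
            grads[f"W{i}"] = below.T @ gu
            grads[f"b{i}"] = gu.sum(0)
            gh = gu @ p[f"W{i}"].T
        return nll, grads

    def fit(self, X: np.ndarray, y: np.ndarray, opts: TrainOptions):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        N = X.shape[0]
        if N <= self.G:
            raise ValueError(f"need more rows (N={N}) than components (G={self.G})")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")
        self.sigma_floor = float(opts.sigma_floor)
        self.x_mean = X.mean(axis=0)
        self.x_std = np.maximum(X.std(axis=0), 1e-8)
        self.y_mean = float(y.mean())
        self.y_std = float(max(y.std(), 1e-8))
        xs = (X - self.x_mean) / self.x_std
        ys = (y - self.y_mean) / self.y_std
        self.init_params(np.random.default_rng(opts.seed))
        p = self.params
        mom = {k: np.zeros_like(v) for k, v in p.items()}
        vel = {k: np.zeros_like(v) for k, v in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        best_nll, best_p, stall = np.inf, None, 0
        for epoch in range(1, opts.epochs + 1):
            nll, grads = self._nll_and_grads(xs, ys)
            if not np.isfinite(nll):
                raise RuntimeError(
                    f"non-finite NLL at epoch {epoch} (G={self.G}, N={N}); "
                    "consider a larger sigma_floor or smaller lr")
            if nll < best_nll - opts.tol:
                best_nll, stall = nll, 0
                best_p = {k: v.copy() for k, v in p.items()}
            else:
                stall += 1
                if stall >= opts.patience:
                    break
            for k in p:
                g = grads[k]
                mom[k] = b1 * mom[k] + (1 - b1) * g
                vel[k] = b2 * vel[k] + (1 - b2) * g * g
                mh = mom[k] / (1 - b1 ** epoch)
                vh = vel[k] / (1 - b2 ** epoch)
                p[k] -= opts.lr * mh / (np.sqrt(vh) + eps)
        if best_p is not None:
            self.params = best_p
        # training NLL in original units
        self.train_nll_ = float(-self.log_density(y, X).mean())
        return self

    def mean_nll(self, y, X) -> float:
        return float(-self.log_density(y, X).mean())

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "mdn", "d0": self.d0, "G": self.G, "H": self.H,
            "U": self.U, "sigma_floor": self.sigma_floor,
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean, "y_std": self.y_std,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MDNUnivariate":
        m = cls(d["d0"], d["G"], d["H"], d["U"], sigma_floor=d["sigma_floor"])
        m.x_mean = np.asarray(d["x_mean"], float)
        m.x_std = np.asarray(d["x_std"], float)
        m.y_mean, m.y_std = float(d["y_mean"]), float(d["y_std"])
        m.params = {k: np.asarray(v, float) for k, v in d["params"].items()}
        return m


class MultinomialLogit:
    """Multinomial-logistic sub-model for a categorical response coordinate.

    A linear softmax classifier trained by full-batch Adam; used in place of
    an MDN when a coordinate of the series is discrete (mixed-type data).
    """

    def __init__(self, d0: int):
        self.d0 = int(d0)
        self.classes_: np.ndarray | None = None
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.x_mean = np.zeros(d0)
        self.x_std = np.ones(d0)

    def _logits(self, xs):
        return xs @ self.W + self.b

    def fit(self, X, y, opts: TrainOptions):
        X = np.atleast_2d(np.asarray(X, float))
        self.classes_, codes = np.unique(np.asarray(y), return_inverse=True)
        K = self.classes_.size
        self.x_mean = X.mean(axis=0)
        self.x_std = np.maximum(X.std(axis=0), 1e-8)
        xs = (X - self.x_mean) / self.x_std
        N = xs.shape[0]
        self.W = np.zeros((self.d0, K))
        self.b = np.zeros(K)
        onehot = np.eye(K)[codes]
        mW, vW = np.zeros_like(self.W), np.zeros_like(self.W)
        mb, vb = np.zeros_like(self.b), np.zeros_like(self.b)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for epoch in range(1, opts.epochs + 1):
            lg = self._logits(xs)
            lg -= lg.max(axis=1, keepdims=True)
            pr = np.exp(lg)
            pr /= pr.sum(axis=1, keepdims=True)
            gl = (pr - onehot) / N
            gW, gb = xs.T @ gl, gl.sum(0)
            for g, m_, v_, prm in ((gW, mW, vW, self.W), (gb, mb, vb, self.b)):
                m_ *= b1; m_ += (1 - b1) * g
                v_ *= b2; v_ += (1 - b2) * g * g
                prm -= opts.lr * (m_ / (1 - b1 ** epoch)) / (
                    np.sqrt(v_ / (1 - b2 ** epoch)) + eps)
        return self

    def prob(self, X) -> np.ndarray:
        xs = (np.atleast_2d(np.asarray(X, float)) - self.x_mean) / self.x_std
        lg = self._logits(xs)
        lg -= lg.max(axis=1, keepdims=True)
        pr = np.exp(lg)
        return pr / pr.sum(axis=1, keepdims=True)

    def log_density(self, y, X) -> np.ndarray:
        pr = self.prob(X)
        codes = np.searchsorted(self.classes_, np.asarray(y))
        return np.log(pr[np.arange(pr.shape[0]), codes] + 1e-300)

    def sample(self, X, M: int, rng: np.random.Generator):
        pr = self.prob(X)
        cum = np.cumsum(pr, axis=1)[:, None, :]
        u = rng.random((pr.shape[0], M, 1))
        idx = (u > cum).sum(axis=2)
        return self.classes_[idx]


class FactorizedGenerator:
    """Conditional generator for a multivariate response via chained univariate models.

    ``direction`` records whether the model was fitted as a forward
    (X_t | X_{t-1}) or backward (X_{t-1} | X_t) generator; the class itself
    is agnostic — it models an arbitrary dy-dimensional response given a
    d0-dimensional predictor.
    """

    def __init__(self, direction: str, d0: int, dy: int,
                 component_models: Sequence, factorization_order=None):
        if direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if len(component_models) != dy:
            raise ValueError("need one sub-model per response coordinate")
        self.direction = direction
        self.d0, self.dy = int(d0), int(dy)
        self.component_models = list(component_models)
        self.factorization_order = (list(range(dy)) if factorization_order is None
                                    else list(factorization_order))

    def log_density(self, Y, X) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, float))
        X = np.atleast_2d(np.asarray(X, float))
        total = np.zeros(Y.shape[0])
        feats = X
        for j in self.factorization_order:
            total += self.component_models[j].log_density(Y[:, j], feats)
            feats = np.hstack([feats, Y[:, j:j + 1]])
        return total

    def sample(self, X, M: int, rng: np.random.Generator) -> np.ndarray:
        """(n, M, dy) ancestral samples at each of n conditioning points."""
        X = np.atleast_2d(np.asarray(X, float))
        n = X.shape[0]
        out = np.empty((n, M, self.dy))
        feats = np.repeat(X, M, axis=0)        # (n*M, d0 + j)
        for j in self.factorization_order:
            draws = self.component_models[j].sample(feats, 1, rng)[:, 0]
            out[:, :, j] = draws.reshape(n, M)
            feats = np.hstack([feats, draws[:, None]])
        return out

    def ccf_matrix(self, X, freqs, M: int, rng: np.random.Generator, *,
                   block: int = 64) -> np.ndarray:
        """Monte-Carlo CCF estimates: (n, B) complex for n points × B frequencies.

        The same M samples at a conditioning point are reused for every
        frequency; blocks bound peak memory at ~block*M*B complex entries.
        """
        X = np.atleast_2d(np.asarray(X, float))
        freqs = np.atleast_2d(np.asarray(freqs, float))
        n, B = X.shape[0], freqs.shape[0]
        out = np.empty((n, B), complex)
        for lo in range(0, n, block):
            hi = min(lo + block, n)
            samp = self.sample(X[lo:hi], M, rng)          # (nb, M, dy)
            proj = samp.reshape(-1, self.dy) @ freqs.T    # (nb*M, B)
            # cos/sin separately: much cheaper than complex exp
            re = np.cos(proj).reshape(hi - lo, M, B).mean(axis=1)
            im = np.sin(proj).reshape(hi - lo, M, B).mean(axis=1)
            out[lo:hi] = re + 1j * im
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        subs = []
        for m in self.component_models:
            if isinstance(m, MDNUnivariate):
                subs.append(m.to_dict())
            else:
                raise TypeError("only MDN sub-models are serialisable")
        return {"direction": self.direction, "d0": self.d0, "dy": self.dy,
                "factorization_order": self.factorization_order,
                "component_models": subs}

    @classmethod
    def from_dict(cls, d: dict) -> "FactorizedGenerator":
        subs = [MDNUnivariate.from_dict(s) for s in d["component_models"]]
        return cls(d["direction"], d["d0"], d["dy"], subs,
                   d["factorization_order"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FactorizedGenerator":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- module-level operations ----------------------------------------------

def fit_mdn_univariate(x_rows, y, G: int, H: int = 1, U: int = 20,
                       train_opts: TrainOptions | None = None) -> MDNUnivariate:
    """Maximum-likelihood fit of a univariate MDN; deterministic given the seed."""
    opts = train_opts or TrainOptions()
    x_rows = np.atleast_2d(np.asarray(x_rows, float))
    model = MDNUnivariate(x_rows.shape[1], G, H, U, sigma_floor=opts.sigma_floor)
    return model.fit(x_rows, y, opts)


def mdn_density(model: MDNUnivariate, y: float, x) -> float:
    """Conditional density f(y|x) of a fitted univariate MDN."""
    x = np.atleast_1d(np.asarray(x, float))
    return float(model.density(np.array([y]), x[None, :])[0])


def _transition_frames(values: np.ndarray, direction: str):
    if direction == "forward":
        return values[:-1], values[1:]
    if direction == "backward":
        return values[1:], values[:-1]
    raise ValueError("direction must be 'forward' or 'backward'")


def fit_factorized_generator(series, direction: str, *, G: int = 3,
                             H: int = 1, U: int = 20,
                             train_opts: TrainOptions | None = None,
                             categorical_coords: Sequence[int] = (),
                             ) -> FactorizedGenerator:
    """Fit the one-step conditional law of a series in a given direction.

    Forward fits the response X_t on the predictor X_{t-1}; backward swaps
    them.  One univariate sub-model per response coordinate, chained in
    natural coordinate order; coordinates listed in ``categorical_coords``
    get a multinomial-logistic sub-model instead of an MDN.
    """
    opts = train_opts or TrainOptions()
    values = series.values if isinstance(series, MultiSeries) else np.asarray(series, float)
    if values.ndim == 1:
        values = values[:, None]
    X, Y = _transition_frames(values, direction)
    d = values.shape[1]
    if X.shape[0] < G + 2:
        raise ValueError(f"too few transitions ({X.shape[0]}) to fit G={G} components")
    subs = []
    feats = X
    for j in range(d):
        sub_seed = np.random.SeedSequence(opts.seed, spawn_key=(
            0 if direction == "forward" else 1, j)).generate_state(1)[0]
        sub_opts = TrainOptions(lr=opts.lr, epochs=opts.epochs, seed=int(sub_seed),
                                patience=opts.patience, tol=opts.tol,
                                sigma_floor=opts.sigma_floor)
        if j in categorical_coords:
            sub = MultinomialLogit(feats.shape[1]).fit(feats, Y[:, j], sub_opts)
        else:
            sub = MDNUnivariate(feats.shape[1], G, H, U,
                                sigma_floor=opts.sigma_floor).fit(feats, Y[:, j], sub_opts)
        subs.append(sub)
        feats = np.hstack([feats, Y[:, j:j + 1]])
    return FactorizedGenerator(direction, d, d, subs)


def sample_generator(gen: FactorizedGenerator, x, M: int,
                     rng: np.random.Generator) -> np.ndarray:
    """M ancestral samples of the response at a single conditioning point."""
    if M < 1:
        raise ValueError("M must be >= 1")
    x = np.atleast_1d(np.asarray(x, float))
    return gen.sample(x[None, :], M, rng)[0]


def select_G_cv(series, G_grid: Sequence[int], folds: int = 5,
                train_opts: TrainOptions | None = None, *,
                direction: str = "forward", H: int = 1, U: int = 20) -> int:
    """Choose the number of mixture components by chronological cross-validation.

    Rolling-origin evaluation respecting serial dependence: the second half
    of the sample is cut into ``folds`` consecutive validation segments and
    fold j trains on everything before segment j, so the training window is
    never smaller than half the data (tiny windows make the held-out score
    degenerate through extrapolation).  The criterion is the held-out mean
    log-likelihood of the univariate MDN for the last response coordinate
    given the one-step predictor — the response coordinate that is genuinely
    stochastic in both directions for lag-concatenated series — with
    per-point log-densities winsorised below at −20 so a single wild
    extrapolation cannot dominate a fold.  The smallest G within one
    standard error (across folds) of the best mean score is returned: the
    usual parsimony rule.
    """
    if len(G_grid) == 0:
        raise ValueError("G_grid must be nonempty")
    if len(G_grid) == 1:
        return int(G_grid[0])
    opts = train_opts or TrainOptions()
    values = series.values if isinstance(series, MultiSeries) else np.asarray(series, float)
    if values.ndim == 1:
        values = values[:, None]
    X, Y = _transition_frames(values, direction)
    y = Y[:, -1]
    N = X.shape[0]
    edges = np.linspace(N // 2, N, folds + 1).astype(int)
    means, ses = [], []
    for G in G_grid:
        ll = []
        for j in range(folds):
            tr = slice(0, edges[j])
            va = slice(edges[j], edges[j + 1])
            if edges[j] <= G + 1 or edges[j + 1] == edges[j]:
                continue
            m = MDNUnivariate(X.shape[1], int(G), H, U,
                              sigma_floor=opts.sigma_floor).fit(X[tr], y[tr], opts)
            ll.append(np.maximum(m.log_density(y[va], X[va]), -20.0).mean())
        if ll:
            means.append(np.mean(ll))
            ses.append(np.std(ll, ddof=1) / np.sqrt(len(ll)) if len(ll) > 1
                       else 0.0)
        else:
            means.append(-np.inf)
            ses.append(0.0)
    means = np.asarray(means)
    order = np.argsort(np.asarray(G_grid, float), kind="stable")
    best = order[int(np.argmax(means[order]))]
    cutoff = means[best] - ses[best]
    chosen = order[int(np.argmax(means[order] >= cutoff))]
    return int(G_grid[chosen])
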