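"""Test engine: chunk bookkeeping, oracle equivalence of the vectorised
statistics, bootstrap calibration, double robustness, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import markovtest as mt
from markovtest.ccf import GaussianAR1CCF
from markovtest.engine import make_chunks, _expected_count

SIGMA = float(np.sqrt(0.5))


class ZeroCCF:
    """Degenerate oracle: every CCF value is 0 (residual = exp term)."""

    def ccf_matrix(self, X, freqs, M=None, rng=None):
        return np.zeros((np.atleast_2d(X).shape[0],
                         np.atleast_2d(freqs).shape[0]), complex)


class IdentityCCF:
    """Oracle predicting X_next = x exactly: CCF(mu|x) = exp(i mu'x)."""

    def ccf_matrix(self, X, freqs, M=None, rng=None):
        proj = np.atleast_2d(X) @ np.atleast_2d(freqs).T
        return np.exp(1j * proj)


def naive_pair_stat(V, L, n, fwd, bwd, mu, nu, q):
    """Literal double loop over (chunk, t) following the printed index rules."""
    tot, cnt = 0.0 + 0.0j, 0
    for ell in range(1, L):
        for t in range(1, n - q + 2):
            tgt = V[ell * n + t + q - 2]
            cond_f = V[ell * n + t + q - 3]
            obs = V[ell * n + t - 2]
            cond_b = V[ell * n + t - 1]
            phi = fwd.ccf_matrix(cond_f[None, :], mu[None, :])[0, 0]
            psi = bwd.ccf_matrix(cond_b[None, :], nu[None, :])[0, 0]
            a = np.exp(1j * mu @ tgt) - phi
            b = np.exp(1j * nu @ obs) - psi
            tot += a * b
            cnt += 1
    return tot / cnt, cnt


# -- chunking --------------------------------------------------------------

def test_make_chunks_definition_and_truncation():
    s = make_chunks(9, 3, q_max=1)
    assert s.n == 3 and s.offset == 0
    assert np.array_equal(s.I(1), [0, 1, 2])
    assert np.array_equal(s.I(3), [6, 7, 8])
    t = make_chunks(10, 3, q_max=1)
    assert t.n == 3 and t.offset == 1          # oldest row dropped
    assert np.array_equal(t.I_bar(2), np.concatenate([t.I(1), t.I(2)]))


def test_make_chunks_too_short_reports_minimum():
    with pytest.raises(ValueError, match="36"):
        make_chunks(20, 3, q_max=10)
    with pytest.raises(ValueError):
        make_chunks(100, 1, q_max=2)


def test_config_validation():
    with pytest.raises(ValueError):
        mt.TestConfig(Q=1)
    with pytest.raises(ValueError):
        mt.TestConfig(alpha=1.5)
    with pytest.raises(ValueError):
        mt.TestConfig(L=1)


# -- oracle equivalence (vectorised vs naive loops) ------------------------

@pytest.mark.parametrize("T,L,Q", [(30, 2, 2), (40, 2, 3), (36, 3, 3)])
def test_pair_statistic_matches_naive_loop(T, L, Q):
    series = mt.simulate_ar1_gauss(T, 0.5, seed=T + L)
    scheme = make_chunks(T, L, Q)
    oracle = GaussianAR1CCF(0.5, SIGMA)
    gens = [(oracle, oracle)] * (L - 1)
    pairs = mt.draw_frequency_pairs(3, 1, seed=5)
    V = series.values[scheme.offset:]
    for q in range(2, Q + 1):
        for b in range(pairs.B):
            got = mt.pair_statistic(series, scheme, gens, pairs, q, b,
                                    M=10, rng=np.random.default_rng(0))
            want, cnt = naive_pair_stat(V, L, scheme.n, oracle, oracle,
                                        pairs.mu[b], pairs.nu[b], q)
            assert cnt == _expected_count(scheme, q)
            assert abs(got - want) < 1e-12
            assert abs(got) <= 4.0


def test_pair_statistic_zero_for_perfect_residuals():
    series = mt.MultiSeries(np.full((30, 2), 1.3))
    scheme = make_chunks(30, 2, 2)
    oracle = IdentityCCF()
    gens = [(oracle, oracle)]
    pairs = mt.draw_frequency_pairs(2, 2, seed=1)
    val = mt.pair_statistic(series, scheme, gens, pairs, q=2, b=0, M=5,
                            rng=np.random.default_rng(0))
    assert val == 0


def test_covariances_match_naive_and_are_psd():
    T, L, Q = 36, 3, 3
    series = mt.simulate_ar1_gauss(T, 0.4, seed=2)
    scheme = make_chunks(T, L, Q)
    oracle = GaussianAR1CCF(0.4, SIGMA)
    gens = [(oracle, oracle)] * (L - 1)
    pairs = mt.draw_frequency_pairs(2, 1, seed=3)
    covs = mt.estimate_covariances(series, scheme, gens, pairs, Q, M=5,
                                   rng=np.random.default_rng(0))
    V = series.values[scheme.offset:]
    n, B = scheme.n, pairs.B
    for q in range(2, Q + 1):
        lam_rows = []
        for ell in range(1, L):
            for t in range(1, n - q + 2):
                row = []
                for b in range(B):
                    mu, nu = pairs.mu[b], pairs.nu[b]
                    phi = oracle.ccf_matrix(V[ell * n + t + q - 3][None, :],
                                            mu[None, :])[0, 0]
                    psi = oracle.ccf_matrix(V[ell * n + t - 1][None, :],
                                            nu[None, :])[0, 0]
                    s = (np.exp(1j * mu @ V[ell * n + t + q - 2]) - phi) * \
                        (np.exp(1j * nu @ V[ell * n + t - 2]) - psi)
                    row.append(s)
                lam_rows.append(row)
        lam = np.asarray(lam_rows)
        lam_ri = np.hstack([lam.real, lam.imag])
        want = lam_ri.T @ lam_ri / lam.shape[0]
        assert np.allclose(covs[q], want, atol=1e-12)
        assert np.allclose(covs[q], covs[q].T)
        assert np.linalg.eigvalsh(covs[q]).min() >= -1e-8


def test_covariance_rank_one_example():
    series = mt.MultiSeries(np.zeros((20, 1)) + 0.0)
    scheme = make_chunks(20, 2, 2)
    gens = [(ZeroCCF(), ZeroCCF())]
    pairs = mt.draw_frequency_pairs(1, 1, seed=0)
    covs = mt.estimate_covariances(series, scheme, gens, pairs, Q=2, M=5,
                                   rng=np.random.default_rng(0))
    # all summands are exactly 1+0i -> covariance [[1, 0], [0, 0]]
    assert np.allclose(covs[2], [[1.0, 0.0], [0.0, 0.0]], atol=1e-14)


def test_aggregate_statistic_examples_and_naive_max():
    q_values = np.arange(2, 5)
    counts = np.array([10, 9, 8])
    zeros = mt.PairStatArray(S=np.zeros((3, 4), complex), q_values=q_values,
                             counts=counts)
    assert mt.aggregate_statistic(zeros) == 0.0

    S = np.zeros((3, 4), complex)
    S[1, 2] = (3 + 4j) / np.sqrt(counts[1])
    one = mt.PairStatArray(S=S, q_values=q_values, counts=counts)
    assert mt.aggregate_statistic(one) == pytest.approx(4.0, rel=1e-12)

    rng = np.random.default_rng(8)
    R = rng.normal(size=(3, 4)) + 1j * rng.normal(size=(3, 4))
    ps = mt.PairStatArray(S=R, q_values=q_values, counts=counts)
    naive = max(np.sqrt(counts[i]) * max(abs(R[i, b].real), abs(R[i, b].imag))
                for i in range(3) for b in range(4))
    assert mt.aggregate_statistic(ps) == pytest.approx(naive, rel=1e-12)
    assert ps.scale(3) == pytest.approx(3.0)


# -- bootstrap critical value ---------------------------------------------

def test_bootstrap_quantile_matches_closed_form():
    """Q=2, B=1, identity covariance: the upper-(alpha/2) quantile of
    max(|Z1|,|Z2|) solves (2*Phi(c)-1)^2 = 0.975."""
    c_true = stats.norm.ppf((1 + np.sqrt(0.975)) / 2)
    crit = mt.bootstrap_critical_value({2: np.eye(2)}, alpha=0.05,
                                       n_boot=100_000,
                                       rng=np.random.default_rng(1))
    dens = 4 * (2 * stats.norm.cdf(c_true) - 1) * stats.norm.pdf(c_true)
    se = np.sqrt(0.025 * 0.975 / 100_000) / dens
    assert abs(crit - c_true) < 3 * se


def test_bootstrap_zero_cov_and_monotonicity():
    zero = {2: np.zeros((2, 2)), 3: np.zeros((2, 2))}
    assert mt.bootstrap_critical_value(zero, 0.05, 500,
                                       np.random.default_rng(0)) == 0.0
    cov = {2: np.eye(4)}
    c01 = mt.bootstrap_critical_value(cov, 0.01, 2000, np.random.default_rng(3))
    c10 = mt.bootstrap_critical_value(cov, 0.10, 2000, np.random.default_rng(3))
    assert c01 >= c10


def test_bootstrap_rejects_non_psd_naming_q():
    bad = {4: np.array([[1.0, 0.0], [0.0, -0.5]])}
    with pytest.raises(ValueError, match="q=4"):
        mt.bootstrap_critical_value(bad, 0.05, 500, np.random.default_rng(0))
    with pytest.raises(ValueError):
        mt.bootstrap_critical_value({2: np.eye(2)}, 0.05, 10,
                                    np.random.default_rng(0))


def test_factor_and_eigen_bootstrap_agree_in_distribution():
    """The multiplier (factor) route used inside markov_test samples the same
    Gaussian law as the eigendecomposition route of the printed formula."""
    from markovtest.engine import _bootstrap_from_summands
    rng = np.random.default_rng(12)
    s = (rng.normal(size=(60, 3)) + 1j * rng.normal(size=(60, 3))) * 0.5
    count = 60
    lam = np.hstack([s.real, s.imag])
    cov = {2: lam.T @ lam / count}
    c_eig = mt.bootstrap_critical_value(cov, 0.05, 200_000,
                                        np.random.default_rng(1))
    c_fac, draws = _bootstrap_from_summands([s], [count], 0.05, 200_000,
                                            np.random.default_rng(2))
    assert len(draws) == 200_000
    assert c_fac == pytest.approx(c_eig, rel=0.02)


# -- cross-fitting / leakage ----------------------------------------------

def test_chunk_generators_no_leakage_from_later_chunks(fast_opts):
    series = mt.simulate_var3(120, seed=6)
    cfg = mt.TestConfig(L=3, Q=2, B=5, M=5, G=1, U=8, n_boot=200, seed=9,
                        epochs=fast_opts.epochs, lr=fast_opts.lr,
                        patience=fast_opts.patience)
    scheme = make_chunks(series.T, cfg.L, cfg.Q)
    gens_a, _ = mt.fit_chunk_generators(series, scheme, cfg)
    assert len(gens_a) == 2

    perturbed = series.values.copy()
    perturbed[scheme.I(3) + scheme.offset] += 5.0   # later chunk only
    gens_b, _ = mt.fit_chunk_generators(mt.MultiSeries(perturbed), scheme, cfg)
    for (fa, ba), (fb, bb) in zip(gens_a, gens_b):
        for ma, mb in zip(fa.component_models + ba.component_models,
                          fb.component_models + bb.component_models):
            for k in ma.params:
                assert np.array_equal(ma.params[k], mb.params[k])

    two = make_chunks(series.T, 2, cfg.Q)
    gens_two, _ = mt.fit_chunk_generators(
        series, two, dataclasses.replace(cfg, L=2))
    assert len(gens_two) == 1


def test_more_training_data_improves_held_out_fit(fast_opts):
    """The chunk-2 forward generator (trained on chunks 1-2) predicts chunk 3
    at least as well as the chunk-1 generator, on average over seeds."""
    diffs = []
    for seed in range(3):
        series = mt.simulate_var3(300, seed=40 + seed)
        cfg = mt.TestConfig(L=3, Q=2, G=1, U=12, seed=seed,
                            epochs=fast_opts.epochs, lr=fast_opts.lr,
                            patience=fast_opts.patience)
        scheme = make_chunks(series.T, cfg.L, cfg.Q)
        gens, _ = mt.fit_chunk_generators(series, scheme, cfg)
        V = series.values[scheme.offset:]
        chunk3 = V[scheme.I(3)]
        x, y = chunk3[:-1], chunk3[1:]
        nll1 = -gens[0][0].log_density(y, x).mean()
        nll2 = -gens[1][0].log_density(y, x).mean()
        diffs.append(nll1 - nll2)
    assert np.mean(diffs) > 0


# -- double robustness and martingale null --------------------------------

def _dr_mean(forward, backward, n_series=400, T=60, q=2, seed0=0):
    """Mean of the pair statistic over independent short AR(1) series."""
    scheme = make_chunks(T, 2, q)
    pairs = mt.draw_frequency_pairs(1, 1, seed=77)
    gens = [(forward, backward)]
    vals = []
    for s in range(n_series):
        series = mt.simulate_ar1_gauss(T, 0.5, seed=seed0 + s)
        vals.append(mt.pair_statistic(series, scheme, gens, pairs, q, 0,
                                      M=1, rng=np.random.default_rng(0)))
    vals = np.asarray(vals)
    mean = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n_series)
    return mean, se


def test_doubly_robust_statistic_tolerates_one_wrong_nuisance():
    """The estimating equation is unbiased when either conditional law is
    correct, and clearly biased when both are corrupted."""
    good = GaussianAR1CCF(0.5, SIGMA)
    bad = GaussianAR1CCF(0.5, SIGMA, shift=1.0)

    for fwd, bwd in [(good, bad), (bad, good), (good, good)]:
        mean, se = _dr_mean(fwd, bwd)
        assert abs(mean.real) < 3 * se
        assert abs(mean.imag) < 3 * se

    mean, se = _dr_mean(bad, bad)
    assert max(abs(mean.real), abs(mean.imag)) > 5 * se


def test_martingale_null_summands_center_at_zero_for_each_q():
    oracle = GaussianAR1CCF(0.5, SIGMA)
    for q in (2, 3):
        mean, se = _dr_mean(oracle, oracle, n_series=300, T=50, q=q, seed0=900)
        assert abs(mean.real) < 3 * se and abs(mean.imag) < 3 * se


# -- full procedure --------------------------------------------------------

def _tiny_cfg(seed=1):
    return mt.TestConfig(L=3, B=12, M=15, Q=3, G=1, U=8, n_boot=300,
                         seed=seed, epochs=80, lr=1e-2, patience=20)


def test_markov_test_deterministic_and_consistent():
    series = mt.simulate_var3(150, seed=5)
    r1 = mt.markov_test(series, _tiny_cfg())
    r2 = mt.markov_test(series, _tiny_cfg())
    assert r1.statistic == r2.statistic
    assert r1.critical_value == r2.critical_value
    assert r1.reject == r2.reject == (r1.statistic > r1.critical_value)
    assert r1.statistic >= 0
    assert r1.pair_stats.S.shape == (2, 12)
    assert 0 <= r1.p_value <= 1
    r3 = mt.markov_test(series, _tiny_cfg(seed=2))
    assert r3.statistic != r1.statistic  # different internal streams
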