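# markovtest

A nonparametric test of the **Markov property** for multivariate stationary
time series, and a sequential estimator of the **Markov order**, built on
conditional generative learning.

Whether a series is Markov — and of what order — decides how it may be
modelled: Markov decision processes in reinforcement learning and mobile
health (e.g. hourly blood-glucose/insulin dynamics in type-1 diabetes),
state-space models in epidemiology and finance, autoregressions in
environmental monitoring.  Kernel-based tests of this hypothesis degrade
quickly as the dimension d grows; this package instead estimates the
conditional laws with mixture density networks and combines them in a
doubly robust statistic that retains parametric-rate behaviour even though
its ingredients are nonparametric.

## The test

For X_t ∈ R^d strictly stationary, H0 states that the law of X_{t+1} given
the history depends only on X_t.  With forward and backward conditional
characteristic functions

    φ*(μ|x) = E[exp(iμ'X_{t+1}) | X_t = x],
    ψ*(ν|x) = E[exp(iν'X_t) | X_{t+1} = x],

H0 implies, for every lag q ≥ 2 and all μ, ν ∈ R^d,

    E[ {e^{iμ'X_{t+q}} − φ*(μ|X_{t+q−1})} · {e^{iν'X_t} − ψ*(ν|X_{t+1})} ] = 0,

an estimating equation that is **doubly robust**: it still holds if only one
of φ, ψ is correct.  The procedure

1. splits the series into L chunks and fits forward/backward mixture
   density networks on expanding prefixes (cross-fitting),
2. Monte-Carlos φ̂, ψ̂ from M generator samples per conditioning point,
3. averages the residual products over cross-fitted (chunk, t) pairs for
   q = 2..Q and B random N(0, I_d) frequency pairs,
4. takes the max-type statistic Ŝ = max_{q,b} √N_q · max(|Re S|, |Im S|),
   and
5. calibrates it with a multiplier bootstrap at level α (upper α/2
   quantile), rejecting H0 when Ŝ exceeds the critical value.

Run sequentially on lag-concatenated series X_t(k) = (X_t', …, X_{t+k−1}')',
the first non-rejected k estimates the Markov order.  See
`docs/methods.md` for the full write-up.

## Worked example

Estimate the Markov order of the VAR(3) benchmark process (true order 3):

```python
import markovtest as mt

series = mt.simulate_var3(T=500, seed=11)          # d=3, Normal(0, 0.5) noise
cfg = mt.TestConfig(B=500, n_boot=1000, seed=1)
res = mt.select_order(series, k_max=5, cfg=cfg)
for k, r in enumerate(res.per_k, start=1):
    print(f"k={k}: statistic={r.statistic:.3f} critical={r.critical_value:.3f} "
          f"p={r.p_value:.3f} -> {'reject' if r.reject else 'retain'}")
print("estimated Markov order:", res.k_hat)
```

```
k=1: statistic=3.850 critical=3.434 p=0.006 -> reject
k=2: statistic=2.771 critical=3.544 p=1.000 -> retain
estimated Markov order: 2
```

At k=1 the statistic clears the bootstrap critical value decisively: the
raw series is not first-order Markov.  At k=2 the test retains and the
sequential procedure stops.  T=500 is short for detecting the remaining
third-order dependence once two lags are concatenated — the k=2 test has
modest power at this length (the large-replication rejection rate is about
0.26, so stopping at 2 is in fact the most common outcome at T=500); at
T ≥ 1000 the estimate concentrates on the true order 3.  At k ≥ 3 the
concatenated series is genuinely Markov and rejection rates sit at the
nominal 5% level.

The same steps are available from the shell:

```sh
markovtest simulate --model var3 --T 500 --seed 11 --out var3.csv
markovtest order --data var3.csv --kmax 5 --B 500 --n-boot 1000 --seed 1 \
    --out order.json
markovtest simstudy --model var3 --T 500 --kmax 5 --reps 100 --seed 1 \
    --out table.csv        # rejection-rate table (long-running)
```

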