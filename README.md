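# tebench

Benchmarking toolkit for **transfer-entropy (TE) estimation on short
bivariate time series** (~150–330 samples), the regime typical of
minute-scale physiological recordings such as heart-rate variability and
respiration. At these lengths the choice of entropy estimator dominates the
result, and `tebench` exists to make that choice measurable: it implements
five standard estimators behind one interface, simulation models with known
ground truth, quantitative scores for lag specificity and coupling
sensitivity, and surrogate-data tests that separate linear from nonlinear
interactions.

## The statistic

Transfer entropy from a driver process `X` to a target `Y` is the reduction
in uncertainty about the present of `Y` contributed by the past of `X`
beyond the past of `Y` itself:

```
TE(X→Y) = H(Y | Y⁻) − H(Y | X⁻, Y⁻)            [nats]
```

where the past states `X⁻ = (x_{t−τ}, …, x_{t−mτ})` and
`Y⁻ = (y_{t−τ}, …, y_{t−nτ})` come from uniform time-delay embedding with
lag `τ` and dimensions `m`, `n` (default `m = n = 1`). TE is asymmetric,
so it resolves the direction of coupling.

Five estimators of the entropies are provided:

| name | approach | parameter |
|------|----------|-----------|
| `LIN` | linear-Gaussian (OLS residual variances; Granger/2) | model order |
| `KNN` | Kraskov-type k-nearest-neighbor conditional MI | neighbors `k` |
| `FBR` | fixed binning after rank transform (equal-frequency bins) | bins `Q` |
| `KDE` | product-Gaussian kernel density, `h = 1.06·α·σ̂·n^(−1/5)` | multiplier `α` |
| `DVP` | Darbellay–Vajda adaptive partitioning with χ² evenness tests | – |

Benchmark scores: the **Transfer Entropy Excess**
`TEE = Σᵢ TE(τᵢ) / TE(τ_interaction)` (1 = perfect lag specificity; larger =
spurious TE at wrong lags) and the OLS slope `β₁` of median TE on the
coupling strength (sensitivity). Significance uses one-sided tests against
20 IAAFT surrogates — univariate (IRS, destroys all cross-dependence) and
multivariate (IMS, preserves the cross-spectrum and hence linear coupling)
— whose combination classifies an interaction as linear, nonlinear, or
inconclusive.

## Worked example

Estimate TE on one trial of the built-in coupled linear AR model
(`x` drives `y` at lag 1 with strength `a = 0.5`):

```python
from tebench import EmbeddingSpec, SimConfig, estimate_te, simulate

x, y = simulate(SimConfig(model="linear", a=0.5, N=200, seed=42))
spec = EmbeddingSpec(tau=1)
for est, params in [("LIN", {}), ("KNN", {"k": 5}), ("DVP", {})]:
    fwd = estimate_te(x, y, spec, est, params).value
    rev = estimate_te(y, x, spec, est, params).value
    print(est, round(fwd, 4), round(rev, 4))
```

```
LIN 0.2067 0.062
KNN 0.193 0.0419
DVP 0.1625 0.0299
```

Forward TE is positive and several times the reverse TE for every
estimator — the imposed direction of coupling is recovered. A lag sweep on
the nonlinear model (interaction at lag 2) shows what TEE measures:

```
DVP: median TE per lag [ 0.000   0.799   0.000   0.000   0.000]  TEE = 1.00
FBR: median TE per lag [ 0.104   0.848   0.100   0.108   0.103]  TEE = 1.49
```

Both peak at `τ = 2`, but the binning estimator's positive bias puts a
floor under every lag, inflating its excess index. The scripts in
`examples/` walk through each capability (estimation, lag sweeps, coupling
slopes, surrogate classification) and print annotated output.

A thin CLI mirrors the library:

```
tebench simulate --model linear --seed 1 --out trial.csv
tebench estimate --input trial.csv --estimator dvp --tau 1
tebench benchmark --models all --estimators all --trials 50 --seed 1 --out report.json
tebench significance --input trial.csv --estimator dvp --tau 1 --kind both --seed 1 --out sig.json
```

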