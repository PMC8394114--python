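# Methods

This note documents the models, estimator conventions, and numerical
choices in `tebench`, and what the simulation benchmark does and does not
establish.

## Transfer entropy and embedding

All entropies use the natural logarithm (nats). TE is computed as
`H(Y|Y⁻) − H(Y|X⁻,Y⁻)` on uniformly embedded blocks: for lag `τ` and
dimensions `m, n`, the first usable sample is at index `max(m,n)·τ`
(0-based), leaving `R = N − max(m,n)·τ` aligned rows. The default
`m = n = 1` uses a single lagged sample per process; this is the
configuration under which the adaptive-partitioning estimator works in its
native three-dimensional space `(V, U⁻, V⁻)`, and model order 1 is also the
selected setting for the linear estimator in the benchmark. Both remain
configurable. Series shorter than 20 samples are rejected outright: no
estimator's probability-mass approximation is meaningful below that, and
the k-NN preconditions start to fail.

## Estimator conventions

**LIN.** Conditional entropies of a jointly Gaussian model reduce to
`½·log(2πe·var(ε))` with `ε` the OLS residuals, so TE is half the log ratio
of restricted (target past only) to full (both pasts) residual variance.
Regressions include an intercept, making the estimate exactly invariant
under affine transforms of either series. Singular designs (constant or
collinear columns) raise an error.

**KNN.** TE is the conditional mutual information `I(Y; X⁻ | Y⁻)`,
estimated with the Kraskov/Frenzel–Pompe neighbor-counting scheme under the
maximum norm: the k-th-neighbor distance in the full joint space sets a
per-point radius; digamma-weighted strict-interior counts in the marginal
subspaces combine as `ψ(k) − ⟨ψ(n_{YY⁻}+1) + ψ(n_{X⁻Y⁻}+1) − ψ(n_{Y⁻}+1)⟩`.
Sharing one radius across terms cancels the individual entropy biases — a
four-term combination of independent Kozachenko–Leonenko entropy estimates
was tried first and produced a systematic negative offset at uncoupled
lags, which the shared-radius form removes. Single estimates may still be
negative; that is expected behavior, not an error. Exact distance ties
(common on ranked or quantized data) are broken by deterministic jitter of
amplitude `1e-10·σ̂` per column from a fixed-seed generator, keeping the
estimator a pure function of its input; `jitter=False` disables it for
continuous data. The Kozachenko–Leonenko entropy itself is exposed as
`knn_entropy` (max-norm, twice-distance convention, so no volume term).

**FBR.** Each full series is first replaced by its ranks (ordinal
sampling; ties broken by first occurrence), then embedded and quantized
into `Q` equal-width bins per dimension — equal-frequency bins in value
space. Entropies are plug-in sums with the convention `0·log 0 = 0`. A
separate zero-mean/unit-variance normalization would be redundant after
ranking and is not performed. The plug-in bias grows with the number of
occupied cells, which is why this estimator carries a positive TE floor of
roughly `(K₃ − K₂ − K₂' + K₁)/(2R)` at uncoupled lags and why the coarsest
grid `Q = 4` wins the lag-specificity selection.

**KDE.** Joint densities are products of Gaussian kernels with
per-dimension bandwidth `h_j = 1.06·α·σ̂_j·R^(−1/5)` (R = number of embedded
rows; at N = 200 the distinction from N changes h by < 0.1%). Entropies are
resubstitution estimates — the average of `−log` of the leave-in density.
The leave-in self-term inflates the density more strongly in higher
dimensions, and the four-term TE combination inherits a positive bias from
that imbalance; a leave-one-out correction would flip the sign of the bias
and was deliberately not applied, since the positive-bias behavior is the
documented character of this estimator family.

**DVP.** Embedded blocks are ranked per column, then a single
Darbellay–Vajda partition of the joint space is built: a cell is split at
its coordinate midpoints into `2^d` subcells while a χ² test rejects even
occupancy; cells with fewer than `min_points = 8` points (one expected
point per subcell in 3-D) are never split. The printed evenness statistic
is the raw sum `s = Σ(Mᵢ − μ)²`; since `s/μ` is the classical χ² statistic,
the rejection rule compares `s` against `μ · χ²₀.₉₅(2^d − 1)` — the raw sum
against the critical value directly would make the test sample-size
dependent and split every root cell, destroying the estimator's
unbiasedness. All probabilities are read off the final cells and their
axis-aligned projections:
`TE = (1/R)·Σ_cells r·log[(r·r_{V⁻}) / (r_{U⁻V⁻}·r_{VV⁻})]`.
Computing both conditional entropies from the same partition keeps their
resolutions comparable; an earlier variant with separate 2-D and 3-D
partitions made TE strongly negative at the true interaction lag and was
discarded. A single-cell partition gives TE = 0 exactly. Two behaviors are
implementable when the test does not reject: keep the undivided parent
(default) or keep the children (`on_accept="children"`); children-mode
refines everywhere, which measurably inflates TE at uncoupled lags, so the
conservative parent rule is the default. An `initial_split` flag optionally
grants the first 8-cell division unconditionally; it raises sensitivity to
weak coupling at the cost of a small positive floor at all lags, and is off
by default. Because ranking precedes partitioning, DVP is exactly invariant
under strictly increasing transforms of either series.

## Simulation models

Three bivariate models with known interaction lags, all driver→target only
(reverse TE should be ≈ 0). They illustrate dynamics found in real data
without emulating any specific physiological system.

* **linear** — Gaussian AR(2) pair, coupling `a·x_{t−1}` into the target
  (interaction at τ = 1, reference strength a = 0.5). The driver's
  autocorrelation at even lags makes genuine secondary TE peaks at
  τ = 3, 5.
* **nonlinear** — `x = s + ξ_x` with `s ~ N(10, 1)`,
  `y = (b·x_{t−2})² + ξ_y`, Laplace(0, 1) noise (interaction at τ = 2,
  reference b = 0.4). Because the driver sits far from zero the quadratic
  is effectively monotone, so even the linear estimator sees this coupling.
* **linnonlin** — AR(1) pair with linear coupling `c·x_{t−2}` (τ = 2) and a
  weak saturating nonlinear term `d·f(x_{t−4})` (τ = 4),
  `f(u) = 2.4 − 0.9u/(1 + e^{−4u})`, reference c = 0.4, d = 0.6. `f` is a
  soft rectifier with local slope −0.45 at the origin; the grouping of the
  ratio is deliberately isolated in `sigmoid_interaction` because the
  alternative reading `(2.4 − 0.9u)/(1 + e^{−4u})` has a fourfold steeper
  slope and turns the nominally weak nonlinear channel into the dominant
  one, contradicting the benchmark behavior this model is meant to produce
  (small nonlinear slopes, near-unity DVP TEE).

Trials are N = 200 samples after discarding a 100-sample burn-in from zero
initial conditions (the generators are AR processes and need a stationary
start; the burn-in makes the initial conditions irrelevant while keeping
runs reproducible). Noise is redrawn per trial from
`SeedSequence((seed, …, trial))` substreams, so adding trials, lags, or
grid points never perturbs existing trials, and the same trials are reused
across lags and estimators for direct comparability.

What the simulators do *not* emulate: nonstationarity, measurement
artifacts, oscillatory (spectrally peaked) signals, or bidirectional
coupling. Passing the benchmark shows an estimator ranks correctly under
these controlled conditions, not that it is calibrated on clinical data.

## Benchmark indices

The lag sweep computes median and IQR of TE over 50 trials per lag
(1–5). TEE is the ratio of the summed median profile to its value at the
interaction lag, computed on the median profile (matching how profiles are
reported); a per-trial variant is available. TEE is only defined when the
interaction-lag median is positive — a conservative estimator on a weak
coupling can produce a zero median, in which case the index is reported as
undefined rather than extrapolated. Coupling sweeps use 11 equally spaced
points over each model's stated range (a, b ∈ [0, 0.5]; c, d ∈ [0, 0.6];
the mixed model holds the other coupling at d = 0.4 / c = 0.6), with the
slope fitted by OLS on the medians. Parameter selection minimizes
|TEE − 1| over each estimator's grid (LIN order 1–10, KNN k ∈ {5, 10, 15},
FBR Q ∈ {4, 6, 8, 10}, KDE α ∈ {0.5–1.5}), ties toward the smaller value.

Two sensitivity caveats observed at these problem sizes: DVP's χ² gate
makes it the least sensitive estimator to weak coupling (its slope on the
linear model runs below the others', and on the mixed model's weak
nonlinear channel its median profile is often exactly zero away from the
main peak), and near the ideal value TEE differences between unbiased
estimators (LIN/KNN/DVP ≈ 1.00) are within median sampling noise, so
orderings among them at a single seed are not meaningful.

## Surrogate testing

IRS surrogates are standard IAAFT: alternate spectral substitution
(original Fourier magnitudes, current phases) and rank remapping onto the
sorted original values, up to `max_iter = 100` iterations or relative
spectral discrepancy `tol = 1e-6` (the discrepancy plateaus near 1–2% at
N = 200; the distribution match is exact by construction, every run). IMS
surrogates extend this to two channels with one common phase rotation per
frequency, chosen each iteration as the circular mean of the channels'
phase offsets from their originals — the common rotation closest to the
current state — so phase differences, and hence the cross-spectrum and all
linear coupling, are preserved while nonlinear structure is destroyed. DC
(and Nyquist, for even N) rotations are pinned to zero so surrogates are
exactly real.

The one-sided test computes TE on the original and on `n_surr = 20`
surrogate pairs (at least 19 required for a 5% level); for IRS only the
driver is surrogated, preserving the target's self-predictability, which is
the correct null for TE. Significance requires strictly exceeding every
surrogate (ties count against). Under the null the rejection probability is
1/21 ≈ 4.8%; the test suite verifies an empirical rate in [1%, 10%] over
200 repeats. IRS-significant + IMS-not-significant classifies the coupling
as linear; IMS significance indicates a nonlinear component; both
significant leaves the linear part inconclusive. The combination
(IRS not significant, IMS significant) does not occur among the canonical
outcomes but is mapped by the same rule: nonlinear yes, linear no.

## Problem sizes

The shipped benchmark and acceptance script use 50 trials per condition,
N = 200, lags 1–5, and 11-point coupling grids — the study design the
package targets; a full five-estimator, three-model report runs in a few
minutes on one CPU, and the acceptance script in well under a minute.

## Known limitations

Uniform embedding only (no non-uniform embedding), bivariate TE only (no
conditioning on covariates), Gaussian kernels only for KDE, and no
correction for multiple testing across lags in the significance CLI. The
DVP sensitivity caveat above matters for weak couplings at N ≈ 200.
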