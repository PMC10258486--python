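# Methods

## The transform

The thick-pen transform traces a series `X(1..T)` with a pen of thickness τ.
For a square pen the boundaries at time t are the extremes of the window
`k ∈ [−τ/2, τ/2] ∩ Z` padded by `±(τ/2)γ`; a round pen replaces the constant
pad with the semicircular offset `γ√(τ²/4 − k²)` inside the extreme.  The
scaling factor γ converts pen thickness into data units; the conventional
default is γ = 0.1, and all defaults in this package use it.  Small τ tracks
local features; large τ the global trend — the set of thicknesses is a
multiscale summary.

The ensemble variant (square pen only; the round-pen ensemble is undefined
and rejected) averages the τ+1 windowed extremes obtained by shifting the
window's starting point:

    U^E_τ(X(t)) = (τ+1)⁻¹ Σ_{ℓ=0..τ} max{X(t−ℓ), …, X(t+τ−ℓ)} + (τ/2)γ

and symmetrically for the lower boundary.  Averaging smooths the staircase
artifacts of the plain windowed maximum and damps single outliers.  For
nonnegative data with γ > 0 the ensemble upper boundary is bounded below by
(τ/2)γ > 0, which is what makes logarithms of the envelope safe on
zero-inflated data.

Edge handling: windows overrunning `[1, T]` are truncated to the observed
range.  Every window still contains its centre point, so no window is empty
on fully observed data and the output always has length T.  Whether to pad,
reflect or truncate is a genuinely open choice; truncation introduces no
synthetic values and keeps the envelope inside the data's convex hull, at
the price of slightly lower envelopes within τ of the series ends.

Missing data: extremes are taken over the observed points of each window;
a window containing no observed point raises an error rather than imputing.

## Similarity

The thick-pen measure of association between two series at time t is the
ratio of the intersection to the union of their boundary intervals, in
(−1, 1].  On zero-inflated data the lower boundary hugs zero, so the adapted
measure pins it there and reduces to

    η_τ(X(t), Y(t)) = min{U^E(X(t)), U^E(Y(t))} / max{U^E(X(t)), U^E(Y(t))} ∈ (0, 1],

with `log η = −|log U^E(X) − log U^E(Y)|`.  The per-time profile is
aggregated by its geometric mean.  Both measures assume the series are on
roughly a common scale; the package deliberately performs no automatic
rescaling, because rescaling a zero-inflated series is itself a modelling
decision the caller should own.

## Clustering

Maximising the product over series of geometric-mean similarity to cluster
prototypes is equivalent, via the log identity, to minimising

    W(P, M) = Σ_t Σ_i |log U^E(X_i(t)) − μ_{c_i}(t)|,

an L1 problem on the matrix `log U^E(X_i(t))`.  K-medians solves it by
alternating nearest-prototype assignment (cityblock distance, ties to the
lowest cluster index) with coordinate-wise median updates (midpoint
convention for even counts — any point between the central pair is
L1-optimal).  Both steps are non-increasing in W, so the cost trace is
monotone and label stability is a valid stopping rule (cap: 100 iterations).

Choices the objective does not determine:

- **Initialisation**: K distinct data rows drawn uniformly at random;
  best of 10 restarts by final cost.  Deterministic given a seed.
- **Empty clusters** are re-seeded with the row farthest (L1) from the
  cluster's current prototype, keeping K fixed.
- Prototypes live in log-envelope space and are never inverted back to a
  concrete series; the inverse is not unique and nothing downstream needs it.

## Model selection

**Thickness.** With known group labels (the simulation setting), stratified
five-fold cross-validation: cluster the training folds at each candidate τ,
match trained clusters to true groups by maximum-agreement assignment on the
training confusion matrix, assign test series to the nearest prototype, and
score misclassification.  Smallest mean error wins; ties go to the smallest
τ.  Stratification keeps every group represented in every training set,
which the matching step requires.  With unknown labels, an internal index
(Dunn, in the clustering's own L1 log-envelope geometry) is the fallback.

**Number of clusters.** Gap statistic: compare `log W_k` against its mean
under B = 50 reference datasets, with dispersion W_k the same L1 cost the
clustering minimises.  Two departures from the most common textbook recipe,
both standard variants, were needed for reliable behaviour on envelope
features:

- The reference is uniform over the *PCA-aligned* bounding box of the data
  (Tibshirani et al.'s method (b)), not the axis-aligned one.  e-TPT
  envelopes are strongly autocorrelated over time; an axis-aligned uniform
  reference has far higher effective dimension than the data, so the data's
  within-cluster cost keeps falling faster with k than the reference's and
  the gap curve creeps upward forever.
- Selection uses the "globalSEmax" rule (smallest k whose gap is within one
  standard error of the global maximum) rather than the sequential
  first-decrease rule, which stops at k = 1 on well-separated low-noise
  clusters whose gap curve is flat between k = 1 and 2.

All-identical inputs short-circuit to K = 1.

## Benchmark generators

Four labelled generators emulate zero-inflated data with known structure.
Models 1–3 build a real-valued latent process and zero-truncate it
(`max(·, 0)`, exact zeros); Model 4 is a count model, zero-inflated by
construction.  Defaults are N = 100 series per group and T = 500.

1. **Abrupt-change AR(2).**  `Y(t) = φ₁(t) Y(t−1) − 0.81 Y(t−2) + ε(t)`,
   ε iid N(0, 1); φ₁ = 0.8 except in the middle regime t = 54..128, where
   group 1 has φ₁ = −0.9 and group 2 has φ₁ = 1.6 (companion eigenvalue
   modulus 0.9 — locally oscillatory, not explosive).  The latent process is
   mean-zero, so about half the truncated observations are zeros (measured
   ≈ 0.50).
2. **Slowly varying AR(2).**  `Y(t) = −0.8[1 − a cos(πt/T)] Y(t−1) − 0.81
   Y(t−2) + ε(t)`; the groups differ in the modulation depth a: 0.7 vs 0.001
   (case a) or 0.7 vs 0.1 (the harder case b).  Zero fraction ≈ 0.50.
3. **Noisy blocks.**  Five jumps with heights `|h_j| ~ U(0, 20)`, signs
   (−, +, −, +) for j = 1..4 and `h₅ = −Σ_{j≤4} h_j` (sum-to-zero), at
   locations `ξ_j^{(g)} ~ U((g−1)/5, (g+1)/5)` for groups g = 1..4; noise
   sd 3.  The height vector is drawn once per dataset and the locations once
   per group, so each group is one block signal plus noise and groups differ
   in where their activity sits.  (Fully per-series draws were evaluated and
   destroy the group structure any method could recover.)  Zero fraction
   ≈ 0.49, with noticeable between-dataset variance because a single height
   draw governs the whole dataset.
4. **Zero-inflated Poisson.**  Per series: structural-zero probability
   `ω_i ~ U(0.4, 0.7)`, rate `λ_i ~ N(μ_i, σ²)` (floored at 0.01; σ = 0.1 or
   0.5) with `μ_i ~ U(3, 4)` in group 1 and `U(2, 10)` in group 2; emission
   is 0 with probability ω_i, else Poisson(λ_i).  Zero fraction ≈ 0.56.
   The group rate ranges overlap on (3, 4), so part of group 2 is
   irreducibly confusable with group 1 — clustering accuracy plateaus around
   80% by design.

AR burn-in: 200 discarded steps starting from zero, using the t = 1
coefficient, so the reported stretch is free of initial-condition effects.

What the generators do *not* emulate: diurnal/weekly periodicity, missing
observations, reporting artifacts (batching, weekend dips), serial
dependence in the zero process itself, and unequal series lengths.  Passing
benchmarks therefore demonstrates recovery of level- and regime-type group
structure under heavy zero inflation, not robustness to those real-data
features.

## Evaluation

CCR is the best-bijection agreement between predicted and true partitions
(Hungarian assignment on the confusion matrix); adjusted Rand is the
Hubert–Arabie chance-corrected index; the Dunn index is single-linkage
separation over maximum diameter in the clustering's own L1 log-envelope
geometry; variation of information is Meilă's entropy metric (natural log).
VI is a distance — lower means more similar — and is reported as such.

## Problem sizes and determinism

The replicated benchmark runner derives per-replicate seeds from one master
seed, so every table is exactly reproducible.  The packaged acceptance run
uses 30 replicates per benchmark cell and 10 datasets per zero-fraction
estimate; both estimates are unbiased, and their sampling noise (standard
error ≈ sd/√30) is well below the differences that matter between methods.

## Known limitations

- All series must share the same length; there is no alignment or warping.
- The method clusters on envelope *level and shape* at the chosen τ; series
  that differ only in fine temporal phase inside a pen window are not
  distinguished.
- Thickness selection by CV needs labelled data; the unlabelled route
  (internal validity indices) inherits those indices' biases.
- TPMA assumes a shared scale across series; no rescaling is applied.
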