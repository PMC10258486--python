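# etpt — clustering zero-inflated time series with the ensemble thick-pen transform

Zero-inflated time series — daily step counts from wearables, daily confirmed
case counts in disease surveillance, rainfall, transaction counts — defeat
most distance-based clustering methods: half the observations may be exact
zeros, so pointwise distances are dominated by the zeros rather than by the
activity patterns that distinguish the series.

`etpt` implements a model-free clustering pipeline built on the thick-pen
transform (TPT), a multiscale visualisation that traces a series with a pen
of thickness τ and records the upper and lower boundaries of the inked area.
The package provides:

- **Ensemble TPT (e-TPT).** For a square pen, the upper boundary averages
  the τ+1 windowed maxima obtained by shifting the window start:
  `U^E_τ(X(t)) = (τ+1)⁻¹ Σ_{ℓ=0..τ} max{X(t−ℓ),…,X(t+τ−ℓ)} + (τ/2)γ`.
  The envelope is smooth, strictly positive (≥ (τ/2)γ for γ > 0) and free of
  zeros even when the data are mostly zeros.
- **TPMA₀ similarity.** For nonnegative zero-inflated data the lower pen
  boundary barely moves, so the classic thick-pen measure of association is
  adapted by pinning the lower boundary at zero:
  `η_τ(X(t), Y(t)) = min{U^E(X(t)), U^E(Y(t))} / max{U^E(X(t)), U^E(Y(t))} ∈ (0, 1]`,
  aggregated over time by its geometric mean.
- **K-medians clustering.** Maximising the product of geometric-mean TPMA₀
  similarities to cluster prototypes is equivalent to minimising
  `W(P, M) = Σ_t Σ_i |log U^E(X_i(t)) − μ_{c_i}(t)|`, an L1 problem on the log
  upper boundaries solved by alternating nearest-prototype assignment and
  coordinate-wise median updates (monotone cost, best of several restarts).
- **Model selection.** Pen thickness by stratified five-fold cross-validation
  against known labels; number of clusters by the gap statistic with a
  PCA-aligned uniform reference.
- **Benchmarks and metrics.** Four labelled zero-inflated generators
  (abrupt-change AR(2), slowly varying AR(2), noisy blocks, zero-inflated
  Poisson), plus CCR, adjusted Rand, Dunn index and variation of information.

## Worked example

```python
import numpy as np
from etpt import (Model4Spec, simulate_model, log_upper_boundaries,
                  kmedians, ccr, adjusted_rand, zero_ratio)

# 100 series per group, T=500: two groups of zero-inflated Poisson counts
# whose Poisson rates are drawn from overlapping ranges
data, truth = simulate_model(Model4Spec(sigma=0.1), seed=1)
print(f"zero fraction: {zero_ratio(data):.3f}")

logb = log_upper_boundaries(data, thickness=20, gamma=0.1)
fit = kmedians(logb, k=2, n_restarts=10, seed=1)
print(f"final cost: {fit.final_cost:.1f}")
print(f"CCR: {ccr(fit.labels, truth):.3f}  "
      f"aRand: {adjusted_rand(fit.labels, truth):.3f}")
```

```
zero fraction: 0.546
final cost: 14872.6
CCR: 0.835  aRand: 0.446
```

More than half of all observations are exact zeros, yet nearest-prototype
clustering of the log e-TPT envelopes recovers the two rate groups for ~84%
of the series; the remaining errors are mostly series whose rates fall in the
overlap of the two groups' rate ranges, which no envelope can separate.

The same pipeline is available from the shell:

```bash
etpt simulate --model 4 --seed 1 --out data.csv --labels truth.csv
etpt cluster --input data.csv --tau 20 --k 2 --out labels.csv
etpt evaluate --pred labels.csv --truth truth.csv
etpt study --model 2a --tau 20,30,50 --k 2 --replicates 30 --out table.csv
```

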