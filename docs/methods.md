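# Methods

## Model and assumptions

The package treats a DNA sequence as three coupled one-dimensional walks
(the Z-curve components) plus three position-weighted cumulative series
(the combined nucleotide-distance series), and summarizes each family by
how a windowed fluctuation statistic grows with window width. The core
assumption is that intron-bearing status correlates with the strength of
long-range correlation in base arrangement: exponents near the
uncorrelated-walk value characterize one regime, elevated exponents the
other. No gene structure, codon model, or organism-specific signal is
used; the features are functions of the raw base string only.

### Fluctuation estimator

The single-series fluctuation is the *end-increment* form: at width `l`,
F(l) is the standard deviation of `s(i+l) − s(i)` over all `N − l`
overlapping start sites (step 1). This measures the variation of the
series between the two ends of the sliding window. A linearly-detrended
variant (`method="dfa1"`: RMS residual around per-box linear fits,
non-overlapping boxes) is provided behind a configuration switch for
sensitivity analysis; on uncorrelated synthetic sequences both give
exponents near 0.5, and end-increment is the default throughout.

The cross-fluctuation matrix at width `l` is the covariance matrix of the
three combined series' increments, with **population** normalization
(denominator = number of windows). With thousands of windows the
sample/population distinction is negligible, and the population form makes
the rank-1 identities for duplicated series exact. The matrix is
symmetrized as (M + Mᵀ)/2 to cancel float asymmetry; eigenvalues come from
`numpy.linalg.eigvalsh` and are sorted descending.

### Window-width grid

Powers of two `l ∈ {4, 8, …, l_max}` with `l_max` the largest power of two
≤ N/4, capped at 1024 (all configurable). Log-spaced widths weight each
octave equally in the log-log fit; the N/4 ceiling keeps at least 4·l
windows per width so every F(l) is a well-averaged statistic; the 1024 cap
bounds the cost on long sequences. The default minimum sequence length of
256 guarantees at least five grid points.

### Slope fitting and degenerate tracks

Exponents are ordinary least-squares slopes of log F versus log l (natural
logs; the base cancels). Non-positive fluctuation values cannot enter the
log and are dropped per-track with a warning rather than clamped — clamping
would bias the slope. If fewer than three positive points remain the
exponent is *undefined*: for the Z-curve components this is an error (the
sequence cannot be featurized), for eigenvalue tracks the feature is
flagged and σ is computed over the defined subset, with the vector marked
unusable for training — silent imputation would corrupt the classifier.
Eigenvalues below 10⁻¹² × (largest eigenvalue over the grid) are treated
as exact zeros, since degenerate matrices return numerical dust at
relative 1e−15 rather than clean zeros.

A strictly periodic sequence whose period divides every grid width (e.g. a
period-4 repeat against the power-of-two grid) has *exactly zero*
end-increments at every width; this surfaces as the undefined-exponent
error path, not as a spurious slope. Periodic sequences whose period does
not divide the widths give positive, width-independent fluctuations and
exponents near zero, as expected for bounded series.

### Combined distance series

The four position-sum series T_A…T_T are combined into D₁–D₃ with the
purine/pyrimidine, amino/keto and weak/strong pairings — the same axes as
the Z-curve, applied in the distance domain. The pairing is a
configuration hook (`FeatureConfig.combination`) so alternative published
combinations can be substituted without touching the pipeline. Positions
are 1-based: the first nucleotide is the origin and the i-th contributes
distance i, which makes Σ_α T_α(n) = n(n+1)/2 an exact invariant.

Under base complementation (A↔T, C↔G) the purine/pyrimidine and amino/keto
axes negate while the weak/strong axis is invariant — x, y, D₁, D₂ flip
sign and z, D₃ are unchanged. The property suite asserts this exact
symmetry.

### σ and the published feature table

σ is the sample standard deviation (denominator n−1) of the six exponents.
This convention reproduces the σ column of the published twelve-gene
feature table to ±0.0005 for ten of the twelve rows when recomputed from
the printed (4-decimal) exponents; the remaining two rows differ by 0.0016
and 0.0129 respectively, consistent with rounding or transcription effects
in the printed table, and are documented rather than "corrected". The
population convention (denominator n) fails this check broadly (e.g.
0.2494 instead of the printed 0.2732 on one row), which is what fixes the
choice.

## Classifier

RBF-kernel SVM (scikit-learn `SVC`) on the 7-vector, with per-feature
standardization learned from the training split and stored in the model:
the Z-curve exponents (~0.5) and eigen-track exponents (~1.0–1.3) live on
different scales, and an unstandardized RBF kernel would weight them
unevenly. (C, γ) are chosen by grid search over powers of two
(C ∈ 2⁻²…2⁸, γ ∈ 2⁻⁸…2², configurable) minimizing inner-cross-validation
misclassification rate; ties break toward smaller C then smaller γ,
preferring the least complex model. Evaluation is stratified K-fold
cross-validation (default outer K = 5, inner K = 10) reporting per-fold
and average discriminant accuracy (percent correct). The one-by-one
feature-deletion study runs the full model and the seven 6-feature models
on *identical* partitions so accuracy differences are attributable to the
deleted feature alone. When stratification is impossible (fold count
exceeding a class count, e.g. leave-one-out) partitioning falls back to
unstratified folds.

Model-selection metric note: for ±1 labels, mean-square error of the
predicted labels is a monotone transform of the misclassification rate, so
selecting by error rate selects the same (C, γ).

## Synthetic data

The generators define the test conditions:

* **i.i.d. sequences** (uniform base probabilities unless configured):
  uncorrelated regime; Z-curve exponents concentrate near 0.5 and
  eigen-track exponents near 1.0 at N = 32768.
* **Persistent Markov sequences**: with probability p the previous base is
  kept, otherwise a fresh draw from the base distribution (which may repeat
  it, so the observed mean run length is 1/((1−p)(1−π)) ≈ 26.7 at p = 0.95
  uniform, and p = 0 reduces exactly to the i.i.d. mechanism). At p = 0.95
  and N = 32768 every exponent exceeds its i.i.d. counterpart; this is a
  short-memory surrogate for the correlated regime — it lifts the measured
  exponents over the finite width grid through the crossover below the
  correlation length, which is all the tests require. It is not a true
  long-memory (fractional-noise) process, and it does not emulate real
  gene architecture (splice sites, GC isochores, codon structure), so
  passing tests demonstrate that the pipeline *measures correlation
  structure correctly and separates separable regimes*, not that real
  genes achieve any particular accuracy.
* **Two-cluster feature sets**: spherical Gaussians in 7-d feature space
  with configurable means and spread; defaults mimic the observed feature
  ranges of the two gene classes. Used to validate the classifier
  machinery at known separability (including the label-permutation null,
  which must land near 50%).

All generators are pure functions of (configuration, seed).

## Problem sizes

Default verification sizes: sequences of N = 32768 for exponent-regime
checks (grid 4…1024, nine widths); 250+250 points for classifier checks
with tuning grids of 3×3 powers of two; 12+12 sequences of N = 4096 for
the end-to-end sequence→features→classifier comparison of the 7-feature
vs 3-feature models. These sizes give stable Monte-Carlo bands (exponent
spread ≈ ±0.05 at N = 32768) at a few seconds per run.

## Known limitations

* The eigen-track exponents are fitted on covariance-scale (not
  square-root) tracks, so their natural scale is about twice the
  single-series exponents; comparisons across the two families should use
  the features as-is, as the classifier does, not as interchangeable
  Hurst estimates.
* The combined-distance increments grow with absolute position, so the
  fluctuation average is dominated by the downstream part of long
  sequences; this is inherent to the position-weighted definition.
* Published per-gene exponent values for named accessions cannot be
  recomputed here without the corresponding sequence records; only the σ
  column (a pure function of the printed exponents) is reproduced. The
  optional `scripts/external_benchmark.py` runs the full comparison when a
  labeled gene collection is supplied.
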