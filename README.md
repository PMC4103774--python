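# dfa7

Classify gene sequences as **intron-containing** or **intronless** from the
primary DNA sequence alone, using seven feature parameters built on
detrended fluctuation analysis (DFA) and an RBF-kernel support vector
machine.

Intron-containing genes tend to show long-range correlation in their base
arrangement while intronless genes behave closer to uncorrelated random
walks. This package turns that contrast into a fixed-length feature vector
for any sequence, so a standard classifier can separate the two classes
without alignment, organism models, or splice-site prediction.

## The seven features

For a sequence of length *N* over {A, C, G, T}:

1. **Z-curve exponents n₁–n₃.** The Z-curve tracks the cumulative
   purine−pyrimidine, amino−keto and weak−strong base-count imbalances:
   xₙ = (Aₙ+Gₙ)−(Cₙ+Tₙ), yₙ = (Aₙ+Cₙ)−(Gₙ+Tₙ), zₙ = (Aₙ+Tₙ)−(Gₙ+Cₙ).
   For each component, slide a window of width *l* and take
   F(l) = std of the window-end increments over all start sites. Power-law
   growth F(l) ∝ l^β appears as a line on log-log axes; the least-squares
   slopes over a grid of widths l ∈ {4, 8, …, 1024} are n₁, n₂, n₃.
   An uncorrelated sequence gives β ≈ 0.5; persistence pushes β up.

2. **Eigenvalue exponents n₄–n₆.** Let T_α(n) be the sum of the 1-based
   positions at which base α occurs among the first n bases (so
   Σ_α T_α(n) = n(n+1)/2). Combine the four series with the same pairings
   as the Z-curve into D₁, D₂, D₃. At each width *l*, form the 3×3
   covariance matrix of the three series' window-end increments
   F_jk(l) = ⟨Δ_j Δ_k⟩ − ⟨Δ_j⟩⟨Δ_k⟩ — real, symmetric, positive
   semidefinite — and take its ordered eigenvalues λ₁(l) ≥ λ₂(l) ≥ λ₃(l).
   The log-log slopes of the three eigenvalue tracks are n₄, n₅, n₆; they
   capture the *cross*-correlation between the positional distributions of
   the bases, which the Z-curve alone cannot see.

3. **σ**, the sample standard deviation (denominator n−1) of n₁…n₆.

The 7-vector feeds an SVM with Gaussian RBF kernel (features standardized
with training-set statistics; C and γ tuned by grid search under inner
cross-validation), evaluated by K-fold cross-validated discriminant
accuracy, with labels +1 = intronless, −1 = intron-containing.

## Worked example

```sh
dfa7 simulate sim.fa sim_labels.tsv --n-per-class 6 --length 2048 --seed 5
dfa7 features sim.fa features.tsv --labels sim_labels.tsv
dfa7 cv features.tsv --k 3 --k-inner 2 --seed 1
```

The `simulate` step writes six i.i.d. sequences (intronless-like,
uncorrelated regime) and six persistent Markov sequences
(intron-containing-like, correlated regime); `features` computes the seven
parameters per record; `cv` prints:

```
fold accuracies (%): 100.00  100.00  100.00
average accuracy (%): 100.00
```

Every fold classifies perfectly because the two synthetic regimes are well
separated in exponent space: the i.i.d. class sits near n₁–n₃ ≈ 0.5 and
n₄–n₆ ≈ 1.0 while persistence lifts every exponent (n₁–n₃ ≈ 0.7 at
self-transition probability 0.95).

The same works from Python:

```python
import dfa7

seq = dfa7.generate_persistent_sequence(
    dfa7.GeneratorConfig(length=32768, persistence=0.95, seed=7))
fv = dfa7.feature_vector(seq)
print(fv.exponents, fv.sigma)
```

Other subcommands: `dfa7 train` / `dfa7 predict` (fit and apply a model
file), `dfa7 ablate` (cross-validate the full model plus all seven
single-feature deletions on identical partitions).

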