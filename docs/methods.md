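# Methods

## The problem and the model

Specimen-level morphometric tables are rarely complete: some measurements
(e.g. beak-to-nares length, Kipp's distance) are missing in a third to a
half of rows, while others are nearly complete. The package treats the
recovery of one continuous trait at a time as a regression problem on the
natural-log scale. For a focal trait Γ with predictors x (other traits,
optionally sex/species codes), the model is a radial-basis-function (RBF)
network

    ŷ = Σⱼ wⱼ · exp(−γ ‖x − cⱼ‖²),   y = log Γ,   Γ̂ = exp(ŷ),

with k Gaussian hidden units, a single shared width γ, and no bias term.
Log transformation serves three roles: body measurements are strictly
positive and right-skewed; allometric covariation is close to linear on
the log scale; and Euclidean distances inside the kernel become
scale-comparable across traits. No further standardization is applied.

The three stages are:

1. **K-means center placement.** Lloyd's algorithm (k-means++ seeding,
   best of n_init restarts by within-cluster sum of squares) clusters the
   training inputs; the k centroids, in canonical lexicographic order,
   become the RBF centers. Only the output weights are trained.
2. **Weight training.** Full-batch gradient descent on the RMSE loss with
   RMSprop-style squared-gradient scaling. The weights of the best epoch
   seen (lowest training loss) are retained.
3. **Hyperparameter search.** k ∈ [10, 25] (integer) and γ ∈ [0.05, 0.5]
   are tuned by Bayesian optimization of J(k, γ) = −R²_val: 5
   Latin-hypercube points, then 5 expected-improvement proposals under a
   Matérn-5/2 Gaussian-process surrogate on unit-box inputs, 10
   evaluations total per feature combination. Integer k is handled by
   rounding; duplicate proposals are nudged to the nearest unevaluated k.

Around this core, a structured feature search enumerates every size-2 and
size-3 subset of a candidate predictor list (size-1 subsets are excluded;
candidates default to all continuous traits with pairwise-complete
Pearson |r| ≥ 0.1 against the log target), tunes each subset
independently, ranks subsets by validation R² on the log scale, and keeps
the top five. Missing target cells are filled by the best-ranked subset
whose predictors are observed in that row, cascading through the top five;
rows satisfied by none are tagged `unimputable` rather than filled.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| k (hidden units / clusters) | tuned in [10, 25] | also the K-means k |
| γ (kernel width, 1/log-unit²) | tuned in [0.05, 0.5] | shared across units |
| search budget | 10 calls (5 initial) | per feature combination |
| EI exploration ξ | 0.01 | standard |
| learning rate | 3e-4 (precision) / 5e-3 (search) | fixed, no schedule |
| epochs | 12 000 (precision) / 800 (search) | full batch |
| RMSprop decay / ε | 0.9 / 1e-8 | |
| weight init | N(0, 0.1²), seeded | |
| train fraction | 0.7 | one split reused by every method |
| K-means restarts | 10 (4 inside the search) | max_iter 300, tol 1e-6 |
| screening cut | \|r\| ≥ 0.1 | configurable |

Two training presets exist because the trainer serves two roles. With
fixed centers the model is linear in the weights, so the RMSE objective
has an exact least-squares optimum; RMSprop with a fixed learning rate
settles into an oscillation whose amplitude scales with the rate, which
puts a floor under the achievable gap. The precision preset (3e-4 /
12 000 epochs) closes that gap to below 1e-3 RMSE and is the default for
single fits. The search preset (5e-3 / 800 epochs) is used inside the
combination search, where hundreds of fits are ranked and a small common
bias does not change the ranking. For the same reason the search path
runs K-means with 4 restarts and caches centers per k within one
search (the clustering does not depend on γ); `kmeans_fit` itself
defaults to 10 restarts.

A structural limitation worth knowing: with no bias term, a near-linear
relationship over a range much narrower than the kernel width can only be
expressed with very large, delicately cancelling weights, which gradient
training will not reach. On log-morphometric data (spread ≈ 1 log unit,
kernel length scales 1.4–4.5) this is immaterial, but on targets with
little spread the network underfits relative to its closed-form optimum.

## Scale policy

Model selection and ranking use R² on the **log** scale, where the
network is trained; reports also carry original-scale metrics after the
exp back-transform. The two can differ substantially: original-scale R²
weights the largest specimens most, and exponentiation turns symmetric
log-scale errors into right-skewed absolute errors. MAPE excludes rows
with a true value of exactly 0 (counted in the report flags); MSLE is
flagged as undefined when any value is ≤ −1.

## The synthetic generator

Tests and the acceptance script run on generated tables, not downloads.
The generator emulates the structure that makes trait imputation work:
11 traits named after the standard avian measurement set, each with

    log trait = intercept + loading · size + species effect
                + sex effect · sex + noise,

where latent size ~ N(0,1) per individual, species effects
~ N(0, 0.3²) shared across a species' rows and traits, sex is a 0/1
dimorphism shift (0.1 log units), and noise is independent N(0, σ²). The
default σ is derived so that the shared structure explains 95% of each
trait's log variance — a deliberately strong allometric regime typical of
flight-linked measurements. Because the model is linear-Gaussian on the
log scale, the population R² of the best predictor given any trait
subset has a closed form (`oracle_ceiling`), giving every end-to-end
test an exact ceiling: ≈ 0.90 for one predictor, ≈ 0.93 for three.
Missingness is MCAR per trait, or MAR with masking probability logistic
in an always-observed driver trait (intercept calibrated by root-finding
to hit the requested rate). Default rates are heterogeneous (one trait
0.52, one 0.36, the rest 0.05).

What the generator does **not** emulate: phylogenetic covariance beyond
an exchangeable species effect, heteroscedastic measurement error,
trait-specific nonlinear allometries, unit errors, or MNAR mechanisms.
Passing tests therefore demonstrate correct mechanics and recovery under
idealized allometry, not performance on any particular real dataset.

## Study sizes

End-to-end checks use 5,000-row tables (100 species × 50 individuals)
with 30% MCAR on the focal trait and six candidate predictors (35
combinations); the ablation and reproducibility checks use 2,000- and
1,200-row tables. These sizes put sampling error well below the margins
being asserted while keeping the full suite quick to run.

## Numerical choices and edge cases

- Split: seeded permutation; train size = round(N · 0.7); pure function
  of (seed, N), so all methods share one partition.
- K-means empty clusters are re-seeded with the point farthest from its
  centroid, guaranteeing k usable centers; k > N clamps to N with a
  warning. The per-iteration inertia trace is stored and is
  non-increasing.
- Label encoding is first-appearance order on the fitting table and is
  serialized with the model; unseen tokens at predict time map to the
  reserved code −1 with a warning.
- Pearson screening uses pairwise-complete rows; candidates with < 2
  pairs or zero variance are reported as undefined and never screened in.
- A training divergence inside the hyperparameter search is recorded as
  +∞ and the search continues; if every call diverges the search errors.
- Ranking ties break toward fewer features, then lexicographic names.
- All randomness flows from user-supplied integer seeds through
  `numpy.random.default_rng`; repeated runs are bytewise identical in
  their CSV exports.

## Known limitations

- Single-target modeling: each trait is imputed independently; no
  chained multivariate imputation, and imputed values carry no
  uncertainty.
- The mean-imputation, KNN and random-forest baselines use fixed
  conventional settings (5 distance-weighted neighbours; 100 trees);
  they are comparison points, not tuned competitors.
- Categorical variables are predictors only and are never imputed.
- Integer-coded species identity enters the kernel as an arbitrary
  numeric axis; with many species this is a weak predictor and the
  closed-form ceiling does not cover it.
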