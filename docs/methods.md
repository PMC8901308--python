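# Methods

## Swarm variants and their contracts

All optimizers maximize a user-supplied fitness over either R^S
(`continuous`) or {0,1}^S (`standard_binary`, `modified_binary`). One seeded
`numpy` generator per run feeds every stochastic draw in a documented, fixed
order (per particle: the two velocity uniform vectors, or the mutation-count
uniform, the flip positions, the second mutation pair, then one recombination
uniform per dimension), so identical seeds give bit-identical trajectories.
Updates are synchronous: all new positions are generated from the
start-of-iteration bests, evaluated, and only then do pbest/gbest move.
pbest/gbest accept strict improvements only, which makes the recorded best
fitness non-decreasing and keeps ties with the incumbent.

### Inertia weight

w(t) = w_max − (w_max − w_min)·t/T with defaults w_max = 0.9, w_min = 0.4 —
the customary linear exploration-to-exploitation schedule. Acceleration
defaults d1 = d2 = 2.

### The modified binary update

The velocity-free variant evolves each particle by mutating its pbest
(`m1(t)` base) and the gbest (`m2(t)` base) and recombining the two bit
strings. Choices that were genuinely open and how they were fixed:

* **Mutation count.** k = round(m(t)·u) with a single uniform u per particle
  per mutation phase (not per bit), flip positions sampled without
  replacement, k capped at S. The expected count is m(t)/2.
* **Decay horizon.** m(t) = m·(T − t)/T uses the run's own iteration budget
  T; the standalone `decay_schedule` defaults to a 100-iteration horizon and
  clamps at zero beyond it. At T = 100 the two coincide.
* **Recombination.** Agreeing bits are kept. On disagreement the gbest bit
  is taken with probability `combine_threshold`, default 1/3 — biasing
  exploration toward the particle's own history while still pulling toward
  the swarm optimum. The threshold is a config parameter because no single
  canonical value exists.
* **m-base defaults.** m1 = m2 = S/4, so an average particle starts with
  ~S/8 expected flips per parent and anneals to zero. Stated here as the
  package default; any application with structure knowledge should set its
  own.
* **Velocity.** The modified variant uses none — positions evolve by
  mutation/recombination only. The sigmoid-transfer variant clamps |v| ≤ 6
  by default (S(±6) already saturates to within 2.5e-3); pass
  `v_clamp=None` for unclamped velocities.
* **Initialization.** Binary positions i.i.d. Bernoulli(0.5); continuous
  positions uniform in the supplied bounds; velocities zero; pbest = initial
  position.

### Levy baseline

`run_levy_optimizer` adds, after the standard sigmoid-transfer sampling,
`floor(|step|)` extra random bit flips per particle with `step` drawn by the
Mantegna method at stability index α = 1.5. It is a constructed heavy-tailed
baseline — useful as a comparator, not a reference implementation of any
published algorithm — and is flagged experimental.

## Wrapper fitness

Subsets are scored by stratified k-fold (default 5) cross-validated accuracy
of a 1-nearest-neighbour classifier on the selected columns, z-scored per
fold with training-fold statistics, minus α·k/d (default α = 0.01). 1-NN was
chosen because it is hyperparameter-free, deterministic, and sensitive to
noise columns — exactly the signal a wrapper needs; the small α breaks
accuracy ties toward smaller subsets without overriding real accuracy
differences. Fold assignment comes from scikit-learn's `StratifiedKFold`
(shuffled, seeded); given the seed the score is deterministic, so any
reported fitness can be re-verified from its mask.

Implementation note: per fold and feature the squared differences between
test and training samples are precomputed once; a subset's 1-NN distance
matrix is then a sum over selected slices and results are memoized by mask.
This is what makes exhaustive enumeration (2^d − 1 masks at d ≤ 15) and
multi-seed swarm runs affordable on one CPU. The path is tested for exact
agreement with a `StandardScaler` + `KNeighborsClassifier` pipeline scored
by `cross_val_score`. An all-zero candidate mask is repaired by activating
one uniformly random feature before evaluation (keeping the swarm size
constant), and the repaired position is what the particle keeps.

SFFS adds the best-scoring feature greedily and then performs backward
exclusions only while they strictly improve the best score recorded for the
smaller size; strictness prevents add/remove cycles and guarantees
termination. Ties break toward the lowest feature index; the exhaustive
oracle breaks fitness ties toward the lexicographically smallest mask.

## Synthetic data

The feature-table generator draws informative columns N(0,1) vs
N(effect, 1) between classes and noise columns N(0,1) throughout, with
informative columns at seeded random positions and exact class counts.
Defaults — n = 200 samples, 5 informative + 15 noise columns, effect 1.5σ,
balanced classes — define the standard recovery benchmark used by the test
suite. What this emulates is the *selection* problem: a handful of
discriminative measurements hidden among irrelevant ones. It deliberately
omits feature correlation, heteroscedasticity, and label noise, so passing
recovery tests demonstrates the optimizer's search behaviour, not clinical
performance on real radiomic features.

Phantoms are elliptical lesions (default 30×22 px semi-axes in a 128×128
frame) at intensity 0.7 over a 0.2 background. Malignant phantoms get a
lobulated boundary — the ellipse radius perturbed by a seeded Fourier series
of orders 3–7, scaled to a given SD in pixels (default 4) — and smooth
multiplicative speckle inside the mask (Gaussian field, σ = 2 px smoothing,
rescaled to SD 0.2), emulating the "ill-defined, mixed-signal" phenotype;
benign phantoms are generated with both forced to zero, emulating the
"clear boundary, uniform signal" phenotype. Additive pixel noise (default
σ = 0.02) and clipping to [0,1] finish the image. These are geometric
phantoms: no MRI physics (relaxation, chemical shift, k-space artifacts) is
simulated, so segmentation scores on them bound only the thresholding
machinery, not scanner data.

The cohort generator jitters axes (±20%) and center (±10%) per phantom and
enforces exact class counts `round(n·fraction)` — e.g. 36 malignant / 24
benign at n = 60, fraction 0.6, matching the built-in clinical example's
pathology mix.

## Threshold segmentation

Thresholds are gray-coded 8-bit integers mapped to [0,1] (gray coding keeps
single-bit flips local in threshold space); duplicates collapse after
decoding, and the objective — between-class variance Σ w_c(μ_c − μ)² on a
256-bin histogram — simply sees fewer effective levels. The returned
foreground is the intensity class whose mean lies farthest from the
histogram mode, which is the background by construction in any image
dominated by background. Flat images are rejected. For one threshold the
256-point exhaustive scan is the exact oracle (ties to the lowest
threshold); the swarm (20 particles × 30 iterations over 8 bits by default)
is tested to match its optimum.

## Region features

First-order statistics are computed on within-mask intensities (entropy from
a 16-bin histogram, base-2; skewness/kurtosis set to 0 for constant regions
where they are undefined; kurtosis is the excess/Fisher form). Shape uses
the Crofton perimeter estimate (good discrete-circle behaviour: circularity
of a radius-50 disc ≈ 0.99) and convex-hull solidity. Texture uses a
symmetric, mask-restricted co-occurrence matrix on 16-level quantization at
unit horizontal and vertical offsets — pairs with either pixel outside the
mask are discarded, making every feature invariant to anything beyond the
mask. Correlation of a single-level region is reported as 1 (the
scikit-image convention for zero variance).

## Diagnostic statistics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/N, and
Cohen's κ = (Po − Pe)/(1 − Pe) with Pe from the margins; positive =
malignant. A table where both raters are constant has Pe = 1 and κ is
reported as NaN rather than raising. Agreement bands: κ > 0.75 strong,
0.4 ≤ κ ≤ 0.75 general, κ < 0.4 poor.

Location similarity is the mean over tumor types of
min(predicted, reference)/max(predicted, reference) × 100. The formula is a
reverse-engineered inference — it reproduces both printed averages of the
built-in clinical example exactly (65.9 and 89.24) — and is therefore kept
isolated in one documented operation. The printed κ values of that example
(0.45, 0.69) are *not* recoverable from the printed 2×2 tables by the
standard formula (which gives 0.2105, 0.6207); the reproduction report
computes the standard values and flags the discrepancy instead of matching
the print.

## Problem sizes in the test suite

The suite validates search behaviour at sizes where an exact oracle exists:
oracle-equivalence runs use d = 10 tables (3 informative / 7 noise, 1.5σ,
n = 120) against full 1023-mask enumeration over 50 seeds with the default
30-particle × 100-iteration budget; recovery runs use the generator defaults
(d = 20, n = 200) over 20 seeds; threshold-oracle runs use 20 seeded
phantoms. These sizes give stable pass/fail statistics while keeping the
whole suite under half a minute on one CPU.

## Known limitations

* Single-objective, single-swarm only; no neighbourhood topologies,
  constraint handling, or parallel evaluation.
* The wrapper fitness assumes binary labels and needs each class to hold at
  least `cv_folds` samples.
* The "Levy" baseline is a labelled stand-in, not a published algorithm.
* Phantoms and feature tables are idealized; results on them do not certify
  performance on clinical MRI.
* Evaluations/second in the benchmark harness depends on the host and is
  reported for orientation only.
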