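# Methods

## A-SMOTE resampling

The resampler targets binary clinical tables where the "disease present"
class is rare. From a training partition with `z` minority and `r`
majority rows it synthesizes `N = 2(r − z) + z = 2r − z` candidates (for a
balanced input `r = z` this still yields `z` candidates), accepts the
subset that is strictly closer to the minority class than to the majority,
and removes the half of the accepted set closest to the majority class.
The augmented minority count is therefore always
`z + a − ⌊a/2⌋` for `a` accepted candidates, and rejected candidates are
not replaced (`a ≤ N` by construction).

Interpolation follows canonical SMOTE, which the three-step scheme
presupposes but does not pin down: neighbours are the `k = 5` (default)
nearest minority rows by Euclidean distance in the encoded space below,
the gap `u` is uniform on `[0, 1)`, and seeds cycle round-robin so
per-seed candidate counts differ by at most one. `k` is clipped to
`z − 1` when the minority class is smaller than `k + 1`; fewer than two
minority rows is an error, since interpolation needs a pair.

**Distance convention.** All acceptance and rapprochement quantities use
sums of squared coordinate differences with *no square root*, as the
three-step procedure writes them. For the accept/reject comparison this is
harmless — the square root is strictly monotone, so decisions are
identical either way (a property the test suite asserts on random
instances) — but the magnitudes of the logged rapprochement totals `L`
(minority) and `H` (majority) are on the squared scale. `L` and `H` feed
no downstream rule; they are computed and logged purely as an audit trail.

**Mixed-type encoding.** Clinical features mix incomparable units (years,
mg/dl, 0/1 codes). Before any distance computation, continuous columns are
min-max scaled to [0, 1] using the training partition's observed range,
and categorical columns are one-hot expanded, so a one-category mismatch
contributes a squared distance of 2 regardless of coding. Synthesized
categorical values are not interpolated but copied from the nearer parent
along the segment (`u ≤ 0.5` → seed), so candidates always carry valid
category codes.

**Denoising direction.** "Remove the half with the least distance to the
majority" is read as *closest to the majority cloud*: candidates are
ranked by majority rapprochement ascending and the first `⌊a/2⌋` removed,
ties broken toward the earlier candidate index. The opposite reading is
available as `denoise(..., mode="farthest")` but is not the default, since
removing the majority-adjacent candidates is what purges borderline noise.

## Learners

All learners accept per-sample weights so they can serve as AdaBoost
bases, and all ties (equal-gain splits, tied votes, tied posteriors, zero
boosting score) break toward the lower feature index / label 0, making
every fit bit-reproducible given a seed.

* **Decision tree** — greedy CART-style binary splits on midpoint
  thresholds, maximizing weighted impurity decrease (Gini by default,
  entropy available); recursion stops at a depth limit, a pure node, or
  zero achievable gain. Categorical codes are treated ordinally at split
  time (category-subset splits are not implemented); their one-hot
  treatment applies only to resampling distances. `stump` is the depth-1
  tree; `cart` is depth-unlimited with the depth cap as the complexity
  control (no cost-complexity pruning).
* **Naive Bayes** — per-class Gaussians on continuous columns (weighted
  mean/variance, variance floored at 1e-9) and Laplace(+1)-smoothed
  weighted frequencies over the *declared* category codes, so a code
  unseen in training still has mass. Classification is by greatest
  posterior.
* **Random forest** — `n_trees = 25` by default, each tree trained on a
  size-n bootstrap (indices drawn with probability proportional to the
  sample weights; uniform weights recover the plain bootstrap) with
  `⌊√p⌋` features considered per node; majority vote, vote fraction as
  probability.
* **AdaBoost** — discrete AdaBoost on internal ±1 labels,
  `α_t = ½ ln((1 − ε_t)/ε_t)`, multiplicative reweighting normalized each
  round (the stored weight history satisfies the classic identity that
  `h_t` has weighted error exactly ½ under `D_{t+1}`). A round with
  `ε_t ≥ ½` is rejected and boosting halts; `ε_t = 0` stores the round
  with the capped weight from `ε_min = 1/(2M)` and halts. Note that a
  strong base like a full-depth forest typically reaches `ε_1 = 0`, so
  `ab-rf` often reduces to a single forest — the boosted variants
  differentiate most with weak bases (`ab-stump`). Default `T = 50`
  rounds. A model whose first round is rejected fits successfully with
  zero rounds but refuses to predict.
* **Heterogeneous pairs** — two different families fitted on the same
  data, combined by an equal-weight soft vote on class probabilities
  (hard vote optional). For AdaBoost members the additive score is mapped
  through a logistic squashing to obtain a monotone probability surrogate.

## Metrics

Accuracy, precision, recall and F1 come from pooled confusion counts with
label 1 ("disease present") as positive; degenerate denominators yield 0
and are flagged rather than raising. MAE, RMSE, RAE and RRSE are computed
on 0/1 labels by default — matching the convention in which classifier
tables report MAE/RMSE in [0, 1] and making accuracy = 1 − MAE an internal
consistency check — with a probability-based option. RAE uses absolute
differences (per its name and standard definition) and RRSE squared ones;
both are normalized by the predict-the-truth-mean baseline, equal exactly
1 (100%) for that baseline, and are undefined (a named error) when the
ground truth is constant.

## Cross-validation and leakage

Stratified k-fold CV (default k = 10, the community default, with seeded
shuffling) deals each class round-robin into folds, so per-fold class
counts differ by at most one. With `resample="asmote"` the default
`train-only` scope applies A-SMOTE *inside each training fold*, recomputes
`N` from that fold's own `z` and `r`, and evaluates on the untouched test
fold — no synthetic point, interpolated in part from held-out rows, can
reach a test fold. The `global` scope resamples once before splitting,
exists solely to replicate oversample-first pipelines, and both warns at
run time and records the warning in the result and manifest: its scores
are optimistically biased because test folds contain synthetic points
derived from training rows. Pooled (micro-averaged) metrics over the
concatenated out-of-fold predictions are the headline aggregate; per-fold
macro means are also reported, since published tables rarely state which
aggregate they print.

## Synthetic cohorts

The generator emulates the 13-column clinical layout (5 continuous, 8
categorical with the standard cardinalities): continuous features are
class-conditionally Gaussian with plausible clinical location/scale (age
≈ N(54, 9²) years, cholesterol ≈ N(246, 51²) mg/dl, …) and a between-class
shift of `effect · σ`; categorical features are per-class multinomials
with a mildly decreasing baseline and `categorical_skew` total-variation
mass moved onto the last ("risk") category for the disease class. Defaults
are a 303-row cohort with minority fraction 0.35, effect 1.0 and skew 0.1
— a moderately separable, moderately imbalanced screening problem. The
generator deliberately omits feature correlations, nonlinear class
boundaries and missingness, so passing tests demonstrate correct pipeline
behaviour under controllable geometry, not clinical-grade performance on
real cohorts.

Fixtures: `separable` uses an 8σ shift, at which each single continuous
feature separates the classes with per-point overlap ≈ 3·10⁻⁵, so n = 200
draws are linearly separable with probability ≈ 1 (a 4σ shift, sometimes
treated as "separable", still overlaps ≈ 2% per feature and leaves stumps
short of perfect accuracy). `null` is *exactly balanced* with zero effect
and zero skew: with balanced labels independent of the features, the
expected accuracy of any prediction rule whatsoever equals the 50% base
rate, which makes the null control assumption-free rather than dependent
on a model's preference for the majority class. `tiny` is a 12-row
hand-written table for doctests and edge cases.

## Problem sizes used in the built-in checks

The end-to-end checks run at sizes chosen to exercise the statistics they
assert: the count law on the full 1 ≤ z ≤ r ≤ 500 grid; the
acceptance-filter oracle on 200 random instances with up to 50 candidates
and rows; the recall-gain experiment on 20 cohorts of n = 400 at 10%
minority and effect 1.0, with `ab-rf` scaled to 10 boosting rounds over
25-tree forests and 5 folds, compared by a one-sided paired t-test at
α = 0.05; the null control at n = 300 with 10 folds. The acceptance script
mirrors these sizes.

## Known limitations

* Distance-based filtering degrades in very high dimensions (distance
  concentration); the clinical layout here has 13 features, well inside
  the regime the method was designed for.
* Categorical codes are ordinal at tree-split time; trees may therefore
  prefer splits that a category-subset search would not.
* AdaBoost probability outputs are a logistic surrogate, not calibrated
  probabilities.
* The global resampling scope is intentionally leaky and must not be used
  for honest performance claims; it exists for replication only.
* Missing values are rejected, not imputed.
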