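# Methods

This note documents the models and procedures implemented in `wrsvmc`,
the parameter choices and their defaults, what the synthetic generator
does and does not emulate, and the package's known limitations.

## From time series to graph features

Functional connectivity is the Pearson correlation between ROI mean time
series (voxel-to-ROI averaging is assumed to have happened upstream; the
package takes ROI-level matrices). Correlations are clipped to [−1, 1]
and the diagonal forced to 1. A zero-variance series has no defined
correlation and raises an error naming the ROI.

Binarization applies a cut-off c ∈ [0, 1] with a **strict** inequality:
edge (i, j) exists iff r_ij > c. The default mode thresholds the raw
correlation, so negative correlations never form edges; an `absolute`
mode (|r_ij| > c) is provided because treatment of negative correlations
is a genuinely open choice in this literature. Default c = 0.25.

Four metrics are computed on the binary graph:

* **degree** k_i — row sums of the adjacency;
* **shortest path** d(i, j) — hop counts from unweighted all-pairs
  shortest paths (scipy's csgraph). Disconnected pairs receive a finite
  sentinel, default R, one more than the longest achievable path; the
  sentinel is configurable because disconnected graphs appear at high
  cut-offs and a finite value keeps downstream SVMs well-defined;
* **clustering coefficient** — 2·(edges among neighbours)/(k_i(k_i−1)),
  computed from the diagonal of A³; defined as 0 when k_i < 2;
* **local efficiency** — the Latora–Marchiori nodal efficiency: the mean
  of 1/d(u, v) over node pairs of the subgraph induced by node i's
  neighbours (1/∞ = 0), 0 when k_i < 2.

The feature vector concatenates degrees (ROI ascending), shortest paths
(upper-triangle pairs (i, j), i < j, row-major), local efficiencies and
clustering coefficients; length 3R + R(R−1)/2 (4,275 at R = 90). The
`FeatureIndexMap` records metric and ROI(s) for every position so any
feature maps back to one ROI (nodal metrics) or two (paths).

## The weighted ensemble

The cohort is split uniformly at random into a "training and validation"
part and a test part (reference proportions 125/73 of 198; the split is
redrawn, boundedly, until both parts contain both classes). Each of the
n base classifiers draws `n_train_samples` samples and `n_features`
features **without replacement** — sampling with replacement was
rejected so each classifier's validation remainder is disjoint from its
training draw — fits an RBF SVM, and takes its accuracy on the remainder
as its weight W_i ∈ [0, 1]. Prediction maximizes S_a = Σ_i 1[f_i(x)=a]·W_i;
vote mass is conserved (S₊ + S₋ = ΣW_i). Exact ties go to the majority
class of the training-validation part (and to −1 if that is itself tied),
making prediction deterministic.

Parameter conventions and defaults:

| parameter | default | notes |
|---|---|---|
| n (ensemble size) | 500 | size sweep supported over any grid, e.g. 20–600 step 10, with prefix reuse |
| n_train_samples | 65 | must leave a non-empty validation remainder |
| n_features | 65 | drawn from all features, or from a restricted pool during selection |
| kernel | exp(−‖u−v‖²/2σ²), σ = 3 | "bandwidth" is stated without a formula in much of the literature; this convention is fixed here, giving gamma = 1/(2σ²) = 1/18 |
| cost | ∞, capped at 10⁸ | a hard margin may not terminate on non-separable draws, so "infinite" cost maps to a large finite value; configurable |
| standardization | off | voting and feature scoring consume raw feature values; optional z-scoring uses each classifier's own training draw only |

Per-classifier randomness derives from `SeedSequence(base_seed,
spawn_key=(i,))`, so ensembles are reproducible and a size-k ensemble is
exactly the first k classifiers of any larger ensemble from the same
seed. The size sweep exploits this: it trains once at the largest size
and evaluates prefixes; the optimal size is the accuracy argmax, smallest
on ties.

Evaluation reports P_true = T_true/T, sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) with +1 the positive (patient) class.

## Feature selection and region ranking

Classifiers with evaluation accuracy **strictly** above 0.5 are
effective. Feature j of effective classifier i scores
Score_{i,j} = (Σ_k H_{k,j})·W_i, where H are the raw feature values of
the evaluation samples; Score_j sums over the effective classifiers
holding j, and features held by none score 0. The score is therefore
linear in the weights and sensitive to feature scale and sign; an
`absolute-values` variant (Σ|H|) is available. By default the evaluation
set is the *test* set, reproducing the reference procedure's reuse of
the unseen samples — this leaks test information into feature selection
and is deliberately preserved rather than silently fixed; `eval_set=
"validation"` gives the leakage-free alternative.

The top 400 features by score (ties to the smaller index) are the
important features. For each p in the grid, a fresh ensemble whose
feature draws come only from the top-p important features is trained and
evaluated; because each grid point is stochastic, accuracy is averaged
over `repeats` seeds (default 5). The optimal p is the argmax, smallest
on ties, and its top-p list is the optimal subset. Region frequencies
count ROI appearances over that subset (pair features count both
endpoints once each, so totals conserve: #nodal + 2·#pair); ranking ties
break by ascending atlas index. A 90-entry AAL label table ships with
the package; other sizes get generic `ROI_<k>` labels.

The demographic utility is a Pearson chi-square test of independence on
a 2 × 2 table, 1 df, **without** continuity correction (the convention
that reproduces standard reported values such as χ² = 2.683, p = 0.101
for a 93/105 sex-by-group table).

## Synthetic study conditions

The generator emulates a two-class cohort whose connectivity differs
only on a planted set of ROI pairs.

* **Desk-scale profile (defaults):** R = 30 ROIs, 60 subjects per class
  (so the reference 125/73 split scales to 76/44), 20 planted pairs
  concentrated on ROIs 0–9 (so the "abnormal" regions are unambiguous),
  graph mode with base edge probability 0.2 and planted probabilities
  0.9 (patients) vs 0.1 (controls). Base-classifier draws are 40 samples
  and 65 features at this scale. Full R = 90 runs work but are slower.
* **Graph mode** draws each upper-triangle edge independently
  (Bernoulli), symmetrizes, and never creates self-loops.
* **Timeseries mode** samples T (default 130 timepoints, the scale of a
  resting-state acquisition after discarding initial volumes) draws of a
  zero-mean Gaussian whose correlation target is identity plus the
  planted entries (base correlation elsewhere). The target is
  eigenvalue-floored at 10⁻³ and renormalized to unit diagonal, so
  achieved correlations can differ slightly from the request; additive
  white noise of standard deviation `noise_sd` (default 0.5) further
  attenuates empirical correlations by 1/(1+noise_sd²). The manifest
  reports the achieved values.
* The generator is deterministic under its seed, classes are exactly
  balanced, and `SyntheticConfig.null()` removes the class difference
  while keeping everything else fixed.

What the generator does **not** emulate: temporal autocorrelation,
physiological and motion noise, site effects, hemispheric structure,
degree heterogeneity of real cortical networks, or class imbalance.
Passing recovery tests on these cohorts shows the pipeline's machinery
is correct under its own assumptions, not that comparable accuracy is
achievable on real imaging data.

Problem sizes used by the test suite and `scripts/acceptance.py` (200
base classifiers for the main ensembles, 100 for the top-p sweep with a
coarse p grid of 70:400:30 and 2 repeats, 50 for the weighted-vs-single
comparison) are the package's desk-scale choices; they keep a complete
end-to-end run in the tens of seconds while leaving every stage
statistically meaningful.

## Numerical choices

* Correlations are symmetrized ((r + rᵀ)/2) and clipped before use.
* "Infinite" SVM cost is capped at 10⁸; sklearn's SVC handles the rest.
* All ties break deterministically: vote ties to the train-val majority
  class, score ties to the smaller feature index, accuracy ties to the
  smaller p or ensemble size, frequency ties to the smaller atlas index.
* Degree-0/1 nodes have clustering and local efficiency 0 by definition.
* Serialized models store the fitted kernel expansion (support vectors,
  dual coefficients, intercept) as JSON; reloaded models reproduce
  predictions exactly through an explicit RBF decision function.

## Known limitations

* **The feature score localizes poorly.** Score_j factorizes into a pure
  magnitude term (the column sum of raw feature values over the
  evaluation set) times an accumulated-weight term. With non-negative
  graph features the magnitude term dominates the ranking: degrees (≈ k̄
  per sample) outrank path lengths (≈ 2–3), which outrank clustering and
  efficiency (≤ 1). A planted connectivity difference makes the planted
  pairs' distances *small* (a direct edge is the minimum possible hop
  count) in at least one class, so planted pair features sit below the
  background magnitude and cannot reach the top of the importance
  ranking, whichever evaluation set or sign variant is used. In
  consequence the region-frequency ranking recovers planted ROIs at
  roughly chance level on the synthetic cohorts even when test accuracy
  exceeds 95% — the ensemble classifies, the score does not localize.
  The acceptance suite measures this honestly rather than masking it; users who need localization should treat the frequency ranking
  with corresponding caution.
* **Test-set reuse.** The default selection procedure evaluates
  effectiveness and scores on the test set, so the selected subset and
  its accuracy are optimistically biased; use `eval_set="validation"`
  for unbiased selection.
* **Null runs sit slightly below chance.** Under a no-effect cohort the
  mean test accuracy is a few points below 0.5: a uniformly drawn
  train-validation part that is rich in one class leaves a test part
  poor in it, and majority-leaning base classifiers then score below
  chance on the complement. Individual runs stay well inside the
  per-run binomial ±3 SD band around 0.5, and there is no upward bias —
  the direction that would indicate leakage.
* Hard-margin behaviour is approximated by a large finite cost; on
  pathologically scaled data the approximation, not the margin, can
  bind.
* The pipeline is O(n) in the number of base classifiers and is not
  parallelized; reference-scale runs (500 classifiers, 166 grid points,
  5 repeats) are minutes, not seconds.
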