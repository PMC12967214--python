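# Methods

This note records the statistical conventions, defaults and design
decisions behind sigscore, and what the test suite does and does not
establish.

## Scoring model

All scorers map a feature × sample matrix *X* and a signature *S* (size
*k*, optional per-feature weights *w*) to one real score per sample.
Transforms are applied to the **full** matrix before signature subsetting,
because rank-based (quantile) and variance-based (z) statistics need the
complete feature background; subsetting first would change them.

### Column scorers

Operate on the signature's values within one sample. Conventions that the
literature leaves open, fixed here and used consistently by both the
implementation and the test oracles:

* **Quartiles** are type-7 (linear interpolation between order statistics,
  the numpy/R default). All quartile-derived scorers (median, midhinge,
  trimean, iqr, iqm, boxplot fences) share it.
* **trimmedMean** drops ⌊g·n⌋ observations from each end (no fractional
  trimming); default trim fraction g = 0.1.
* **iqm** (interquartile mean) by contrast *is* the fractional trimmed
  mean at g = 0.25: the two observations straddling each quartile cut
  receive weight 1 − frac, so the weights always total n/2. For n
  divisible by 4 this reduces to "drop n/4 from each end and average".
* **mode** is the most frequent exact value, ties resolved to the smallest;
  on continuous data where all values are distinct this degenerates to the
  minimum and a warning is emitted.
* **mad** omits the 1.4826 normal-consistency constant by default (it is a
  pure data summary); `ScorerParams(mad_constant=True)` restores it.
* **Missing values**: with `na_rm` (default) NaNs are dropped per sample
  and the effective feature count adjusted; a sample with no usable values
  gets a missing score, never an exception.

### Matrix scorers

* **combinedZ**: rows are standardized with the sample SD (ddof = 1);
  score_j = Σ_{i∈S} z_ij / √k_j, where k_j counts the non-missing entries.
  Constant rows standardize to zero and still count toward k, which keeps
  the exact identity `mean ∘ zscore = combinedZ / √k` (tested
  cross-module). If *every* signature row is constant the scores are
  missing, with a warning.
* **pca1**: signature rows are centered across samples; scores are the
  sample coordinates on the first principal axis (equivalently s₁·v₁ from
  the SVD of the centered submatrix). Principal axes have arbitrary sign,
  so the vector is oriented to correlate non-negatively with the
  per-sample mean of the submatrix; an exactly zero correlation leaves the
  computed sign.
* **plage**: rows standardized, SVD, scores = first right singular vector
  (unit Euclidean norm), same sign rule.
* **ssgsea**: within each sample, features are ranked ascending by
  expression (top feature gets rank N); walking the descending-ordered
  list, the score is Σ_i [P_in(i) − P_out(i)], with P_in the cumulative
  rank^α-weighted fraction of in-signature features (α = 0.25) and P_out
  the cumulative count fraction of the rest. Expression ties break by
  ascending feature-id order, making the statistic fully deterministic.
  No cross-sample normalization by default; `ssgsea_normalize` divides by
  the score range across samples.
* **gsva**: three stages. (1) Per feature, a Gaussian-kernel CDF estimate
  ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) with bandwidth h_i = s_i/4, floored
  at 1e−12·max(1, |mean|); constant features get ẑ = 0.5 with a warning.
  (2) Per sample, ẑ is ranked descending (ties again by ascending feature
  id) and converted to the symmetric statistic t = |N/2 − r|. (3) A
  KS-like walk down the ranked list adds t^τ (τ = 1, normalized by the
  in-signature total) at signature features and subtracts 1/(N−k)
  elsewhere; the score is max(0, max walk) + min(0, min walk). Degenerate
  corner: if the in-signature rank statistics sum to zero (a singleton set
  whose feature sits exactly at rank N/2), the in-signature increments are
  defined as 0 and the walk is driven by the decrements alone.
* pca1/plage drop feature rows containing NaNs (with a warning);
  ssgsea/gsva require a complete matrix. The Poisson kernel for count data
  is out of scope.

### Transforms

* **step**: each finite value becomes the count of thresholds ≤ it
  (left-closed intervals), an integer in [0, #thresholds]; monotone by
  construction. The interval convention is this package's own.
* **quantile_norm**: columns are forced onto the per-rank cross-column
  mean distribution; ties within a column receive the mean reference value
  over their tied rank span. Note the tie rule means *tied* columns can
  deviate slightly from the shared reference distribution — exact
  column-sorted equality holds for tie-free data. Missing values are
  rejected with advice to impute first.
* **zscore**: per-feature, sample SD (ddof = 1) over non-missing entries;
  rows with zero SD or fewer than two observations become all zeros with a
  warning. Idempotent on non-degenerate rows.

## Resampling nulls and inference

"Resampling molecular feature values" is implemented as **within-column**
resampling across features: each sample column is independently permuted
(without replacement) or redrawn i.i.d. from its own values (with
replacement). This destroys feature identity while preserving each
sample's value distribution (exactly, for permutation). Which axis the
resampling should use was an open design choice; this one makes the null
"no coordination among signature members given this sample's expression
profile", which matches the question the random-signature strategy asks
from the other direction.

For data strategies the transform is re-applied to every perturbed matrix
— the null must flow through the same pipeline as the observed score.
Random signatures match the size of the *used* feature set (the
signature ∩ matrix intersection) and are drawn from all matrix features by
default; `exclude_signature` removes the signature's own features from the
pool.

Replicate *r* of task (signature i, scorer c) seeds its generator with the
integer list [master_seed, i, c, r] (numpy `SeedSequence` entropy), so
replicate streams are independent of execution order and worker count;
parallel (joblib) and serial runs are byte-identical.

Inference follows standard bootstrap practice: add-one ASL
(1 + #{extreme}) / (1 + B) — a valid p-value, never 0, floor 1/(B+1);
two-sided = doubled smaller tail, capped at 1; SE = sample SD of the
replicates; percentile CIs with type-7 quantiles. BCa intervals and any
multiple-testing adjustment are deliberately out of scope.

## Synthetic data

The generator draws i.i.d. N(μ, σ²) (or log-normal) entries and adds a
constant δ to the k signature features in the positive samples. Defaults
(200 features, 30 samples, k = 20, 15 positives, δ = 1, N(0, 1)) give a
per-sample signature-mean shift of δ with SD σ/√k ≈ 0.22, i.e. a strong
but not trivial signal. Deliberately **not** simulated: within-signature
correlation, library-size and dispersion trends of counts, batch effects.
Consequently, passing calibration and recovery tests demonstrates
correctness of the machinery under exchangeability — not performance on
correlated real transcriptomes, where data-resampling nulls are known to
be anti-conservative.

## Problem sizes and tolerances

The test suite checks the simple scorers against naive oracles on 1000
random vectors (lengths 1–200, ~10% missing) at 1e−12
(absolute-or-relative, since near-cancelling weighted means amplify
round-off); pca1/plage against eigen/SVD oracles on 100 submatrices at
1e−8; ssgsea/gsva against literal staged references on 50 small instances
at 1e−10. Statistical checks run at desk scale chosen to keep the suite
fast while leaving the acceptance bands well above Monte-Carlo noise: 200
repetitions (B = 199) for null-ASL calibration, 1000 simulations (B = 999,
n = 50) for CI coverage, 20 repetitions for signal recovery.

## Known limitations

* Dense in-memory matrices only; no sparse single-cell containers.
* Identifier handling is exact-string; no cross-annotation mapping.
* ssGSEA/GSVA require complete data.
* The GSVA kernel stage is O(N·n²) memory/time; fine for thousands of
  features and hundreds of samples, not for atlas-scale single cell data.
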