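# sigscore

Single-sample summary scores for molecular signatures, with
resampling-based significance assessment.

## The problem

A molecular signature — a named set of genes, proteins or metabolites with
coordinated behaviour — is only useful downstream once the expression of
its members in a sample is condensed into a single number. There are many
reasonable ways to do that condensation, they often disagree, and an
apparently striking score can arise from random variation alone. sigscore
addresses both issues for bulk and single-cell expression matrices: it
computes a broad battery of per-sample summary scores behind one uniform
interface, and it quantifies how far each observed score departs from an
empirical null obtained by resampling.

## What it computes

Given a feature × sample matrix *X* and a signature *S* of size *k*:

**Column scorers** reduce the values *x·j* restricted to *S* in each sample
*j*: `sum`, `weightedSum`, `mean`, `weightedMean`, `trimmedMean`, `median`,
`mode`, `midrange` ((min+max)/2), `midhinge` ((Q1+Q3)/2), `trimean`
((Q1+2Q2+Q3)/4), `iqr` (Q3−Q1), `iqm` (interquartile mean, the fractional
trimmed mean at g=0.25), `mad` (median absolute deviation), `aad` (mean
absolute deviation). Quartiles are type-7 (linear interpolation)
throughout.

**Matrix scorers** need more than one column at a time:

* `combinedZ` — z-standardize every feature row, then score sample *j* as
  Σ_{i∈S} z_ij / √k;
* `pca1` — sample coordinates on the first principal axis of the centered
  signature submatrix;
* `plage` — the first right singular vector (unit norm) of the
  row-standardized signature submatrix;
* `ssgsea` — per sample, a rank-weighted running-sum difference between the
  cumulative distribution of in-signature and out-of-signature features
  (exponent α = 0.25 by default);
* `gsva` — Gaussian-kernel CDF estimates per feature, symmetric rank
  statistics |N/2 − r| per sample, and a Kolmogorov–Smirnov-like random
  walk whose clamped extreme deviations give the score.

**Transforms** (`step`, `quantile_norm`, `zscore`) can be applied to the
full matrix before any scorer; scorers and transforms compose freely.

**Significance**: two resampling strategies build empirical nulls — data
perturbation (per-column feature-value resampling, with or without
replacement) and random same-size signatures drawn from a background pool.
From B replicate scores, `computeSignificance`-style inference gives the
achieved significance level ASL = (1 + #extreme) / (1 + B), the replicate
standard error, and percentile confidence intervals. No multiple-testing
adjustment is applied; that choice is left to the user.

## Worked example

```python
from sigscore import (SimulationSpec, RunConfig, generate,
                      compute_sig_scores, recovery_auc)

# 100 features x 10 samples; features g0001..g0010 form the signature and
# are shifted by delta=1 in the first 5 samples
m, sig, labels = generate(SimulationSpec(
    n_features=100, n_samples=10, k=10, n_positive=5, delta=1.0, seed=7))

cfg = RunConfig(scorer_ids=["mean", "trimean", "combinedZ", "ssgsea"],
                strategy="random_signatures", B=199, seed=42)
res = compute_sig_scores(m, [sig], cfg)
print(res.scores.pivot(index="sample_id", columns="scorer", values="score").round(3))
```

```
scorer     combinedZ   mean  ssgsea  trimean
sample_id
s001           1.579  0.839  32.455    1.051
s002           0.908  0.672  23.516    0.807
s003           1.017  0.611  24.134    0.659
s004           1.316  0.794  31.485    0.784
s005           2.782  1.238  34.527    1.151
s006          -2.013 -0.219   2.526   -0.168
s007          -2.036 -0.377  -8.541   -0.277
s008          -0.049  0.269  15.516    0.218
s009          -2.071 -0.432  -6.826   -0.582
s010          -1.434 -0.124   8.788   -0.245
```

The five shifted samples (s001–s005) score visibly higher under every
metric. The attached significance table compares each observed score with
199 random same-size signatures:

```
sample_id  observed  asl    se  ci_low  ci_high
     s001     0.839 0.01 0.275  -0.511    0.521
     s005     1.238 0.01 0.293  -0.313    0.789
     s006    -0.219 0.85 0.337  -0.720    0.566
     ...
```

Positive samples reach the minimum attainable ASL of 1/(B+1) = 0.005–0.01,
while unshifted samples are compatible with the null. Scores separate the
two groups perfectly here: `recovery_auc(..., labels)` returns `1.0`.

The same pipeline is available from the shell:

```sh
sigscore simulate --n-features 100 --n-samples 10 --k 10 --n-pos 5 \
    --delta 1 --seed 7 --out-data m.tsv --out-gmt s.gmt --out-labels l.tsv
sigscore score --data m.tsv --gmt s.gmt --scorers mean,combinedZ \
    --strategy random-sigs --nperm 199 --seed 42 \
    --out scores.tsv --sig-out significance.tsv
sigscore summarize --scores scores.tsv --what box --out box.tsv
```

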