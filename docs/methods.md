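# Methods

## The model

Sample-level enrichment analysis (SLEA) asks, for one sample and one gene
module, whether the module's genes are expressed higher or lower in that
sample than a random gene set of the same size would be. It is a
*self-contained* test: the null is built from the same sample's own
values, so no phenotype contrast or reference group has to be defined
first.

Given a cohort-normalized expression matrix, for sample *s* and a module
mapping to *m* genes with finite values in *s*:

1. the observed statistic is the median (or mean) of the module genes'
   normalized values in *s*;
2. the null is the distribution of the same statistic over random size-*m*
   gene sets drawn without replacement from all genes with finite values
   in *s*;
3. the score is `z = (observed − null mean) / null SD`, with a two-sided
   p-value from the standard-normal reference;
4. p-values are Benjamini–Hochberg adjusted **within each sample** across
   its testable modules;
5. a (sample, module) pair is called *positive-enriched* when `z > 0` and
   the adjusted p-value is below alpha; every other testable pair is
   *non-enriched*. The call is deliberately one-directional: downstream
   stratification compares enriched samples against "all the rest", so a
   significantly negative z still lands in the rest group.

The normal reference is justified by the central limit theorem for the
mean statistic; the distribution of the subset median is not exactly
normal but is close at the permutation counts used (the mean/median
z-scores correlate at r > 0.99 on structured cohorts, which is also one of
the package's acceptance checks).

### Normalization is part of the measurement

Rows are median-centered and divided by the row sample SD (n−1
denominator), so a value of +1 means "one row-SD above the cohort-typical
expression of this gene". The reference is the cohort itself: the same
tumor profile gets different normalized values in different cohorts, and
a cohort of mixed tumors/normals answers a different question than a
tumors-only cohort. The robustness module exists to quantify exactly this
cohort-composition sensitivity.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `statistic` | `median` | module summary; median is robust to outlier genes, mean has a closed-form null |
| `n_permutations` | 10 000 | random gene sets per null; SD of the z-estimate scales as 1/√(2·n) |
| `alpha` | 0.05 | level applied to the within-sample BH-adjusted p |
| `min_module_size` | 10 | below this many mapped finite genes a pair is `not-testable`; the normal approximation degrades for tiny sets |
| `seed` | 0 | master seed; per-sample substreams are spawned from it so serial and parallel execution agree |

Robustness sweeps default to 1 000 permutations because the protocol
multiplies compute by subsets × sizes; headline enrichment runs use
10 000. The default subsample-size ladder is 11, 21, … capped at the
cohort size and 201, with 100 random datasets per size.

## Numerical and degenerate-input conventions

* **Null sampling.** Random same-size gene sets are materialized by
  shuffling the sample's finite-value vector and slicing consecutive
  non-overlapping blocks of length *m* (⌊N/m⌋ subsets per shuffle,
  repeated until `n_permutations` subsets exist). Each block is marginally
  a uniform without-replacement subset. Blocks within one shuffle are
  weakly negatively dependent, but such pairs are a vanishing fraction of
  all draw pairs at n ≥ 1 000, and the estimated null moments agree with
  the exact finite-population formulas (`analytic_null_mean`, checked in
  the test suite: null mean within Monte-Carlo error, null SD within 5%).
* **Degenerate nulls.** If the null SD is zero (constant sample, or
  m = N), the pair gets z = 0, p = 1 rather than an error, so cohort-level
  outputs keep full shape.
* **Zero-spread genes.** Rows that cannot be scaled become all-zero with a
  warning; the matrix shape is stable.
* **Missing values.** NaN cells pass through normalization untouched and
  are excluded from every statistic; `n_mapped` (module genes with finite
  values in the sample) is always reported.
* **Duplicate gene rows** are collapsed by per-cell median before
  normalization (configurable to mean, or to a hard error). Gene and
  sample identifiers match by exact, case-sensitive string equality.
* **p-value floor.** Two-sided normal p-values are floored at the smallest
  positive double so BH adjustment never sees a zero.

## Survival stratification

The cohort is split into positive-enriched (group 1) versus all the rest
(group 0, including not-testable samples). The group effect is estimated
by a Cox proportional-hazards fit on the single binary covariate with
Efron tie handling, reported as hazard ratio with 95% CI, Wald and
likelihood-ratio p-values (which of the two a given publication reports is
often unstated, so both are emitted), plus a log-rank test and
Kaplan-Meier step curves.

The two-gene comparator (`CDKN2A` and `MKI67` both high) labels a sample
positive when both genes exceed a threshold in normalized units. Two
published phrasings of "high" exist — above one row-SD, or simply
positive — so the threshold is a parameter: 1.0 by default, 0.0 for the
looser reading.

## Subsampling robustness protocol

For each size in a ladder, draw many random sample subsets, re-normalize
each subset **independently** (normalization is cohort-relative, so this
is the point of the exercise), re-run SLEA for one module, then report:

* **pairwise correlations** — Pearson r of z-scores between every pair of
  same-size subsets, computed over the samples present in both (pairs with
  fewer than `min_shared = 3` shared samples are skipped and counted);
  intersection is the only well-defined pairing of two overlapping
  subsets;
* **drift** — per sample, a Welch t-test of its z-scores across the
  subsets of size *s* versus across the subsets of the largest size,
  BH-corrected across samples; the drift proportion is the fraction
  significant at 0.05.

Subsets are kept in parent-cohort order (membership, not order, is the
random quantity), which also makes the full-size subset reproduce the
parent run exactly.

A caveat a user should know: the drift statistic is sensitive to the
parent cohort realization. On a fixed parent, the expected subset median
of module-gene expression can differ slightly between subset sizes
(a second-order effect of the empirical activity distribution near its
median), shifting all z-scores in common; because large subsets of a
finite parent also overlap heavily (violating the t-test's independence
assumption), the test has power against these small common shifts. On
synthetic parents the drift proportion at size 91 vs 201 ranges from
under 0.01 to ~0.25 depending on the realization, while pairwise
correlations stay above 0.99 throughout. Drift numbers from a single
parent should therefore be read qualitatively.

## The synthetic generator

`simulate_expression` emulates what SLEA assumes about real cohorts, and
nothing more: `value(g, s) = μ_g + a_s·1[g ∈ module] + ε`, with per-gene
baselines μ_g ~ U(5, 12) and noise SDs σ_g ~ U(0.5, 1.5) on a log2-like
scale, and per-sample module activity either Gaussian (τ = 1.5 by
default, activity comparable to per-gene noise) or two-group (fraction
π = 0.3 active with shift δ = 2). A 70-gene module in a 5 000 × 200
matrix mirrors a mid-sized cohort scored with a chromosomal-instability
sized signature. `simulate_survival` draws exponential event times with
hazard λ₀·exp(β·enriched) (λ₀ = 0.1, β = log 3) and independent
exponential censoring (rate 0.05, about two thirds of events observed).

What it deliberately does **not** model: gene–gene correlation beyond the
module's shared activity (a shared-factor knob exists but is off by
default), probe effects, batch structure, heavy-tailed noise, or any
specific published cohort. Tests passing on these simulations show the
machinery is correct and calibrated under the stated model; they do not
show that any particular real signature is prognostic.

## Problem sizes used in the checks

The packaged acceptance checks run: mean-vs-median concordance on a
5 000 × 200 cohort at 10 000 permutations; null calibration on a
2 000 × 1 000 pure-null cohort; the subsampling protocol on a 289-sample
parent with 20 subsets of 81 (correlations) and 100 subsets each at
sizes 91 and 201 (drift) at 1 000 permutations; and 200 survival
replicates at n = 300. These sizes are scaled-down but structurally
faithful versions of the cohort sizes the method targets.

## Known limitations

* The two-sided p-value is a documented choice; a one-sided variant would
  halve p for positive z but leave the ordering, and the calls, driven by
  the same z ranking.
* BH within sample treats modules as the family; strongly overlapping
  modules (see the Jaccard diagnostics) violate the independence flavor of
  that correction in the same way they do in any enrichment toolkit.
* The permutation null conditions on the sample's value vector; it does
  not model gene–gene correlation, so real-data calibration depends on
  the module not being dominated by one tightly co-regulated cluster.
* Cox fitting assumes proportional hazards; the generator satisfies it by
  construction, real cohorts may not.
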