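# slea — sample-level enrichment analysis

Tools for scoring the activity of gene modules (pathways, signatures,
curated gene sets) in **each individual sample** of an expression cohort,
and for using those per-sample scores to stratify patients.

Classical enrichment analysis needs a phenotype contrast (tumor vs
normal, responder vs non-responder) before it can say anything. SLEA
instead asks, per sample and per module: *are this module's genes
expressed higher in this sample than a random gene set of the same size
would be?* The per-sample scores can then define patient subgroups — for
example, samples positively enriched for a chromosomal-instability
signature versus all the rest — whose survival can be compared directly.

## The statistic

For a cohort-normalized matrix (each gene row median-centered and divided
by its row SD), sample *s* and a module mapping to *m* genes:

    z(s, M) = (q_obs − μ_null) / σ_null

where `q_obs` is the median (or mean) normalized expression of the module
genes in *s*, and `(μ_null, σ_null)` are the moments of the same
statistic over random size-*m* gene sets drawn without replacement from
the same sample (10 000 draws by default). Two-sided normal p-values are
Benjamini–Hochberg corrected **within each sample** across its modules; a
pair with `z > 0` and adjusted `p < 0.05` is called *positive-enriched*.

The package provides, as a Python library and a `slea` command line:

* `io_formats` — expression TSV / GMT / clinical TSV parsing and the
  cohort-relative row normalization;
* `core` — the permutation z-test, its closed-form oracle for the mean
  statistic, BH adjustment, enrichment calls;
* `overlap` — pairwise Jaccard diagnostics for redundant modules;
* `survival` — enrichment-based (or two-gene-signature) stratification
  with Cox PH, log-rank and Kaplan–Meier outputs;
* `robustness` — the cohort-subsampling stability protocol;
* `synthetic` — cohort generator with known ground truth.

## Worked example

```python
from slea import (EnrichmentConfig, SyntheticConfig, modules_with_decoys,
                  normalize_rows, run_slea, simulate_expression)

config = SyntheticConfig(n_genes=2_000, n_samples=120, module_size=70,
                         activity_sd=1.5, seed=1)
matrix, truth = simulate_expression(config)          # raw cohort + ground truth
modules = modules_with_decoys(truth, config, n_decoys=2)
result = run_slea(normalize_rows(matrix), modules,
                  EnrichmentConfig(statistic="median", n_permutations=2_000, seed=2))
print(result.table.head())
```

```
sample_id      module  n_mapped         z        p    p_adj         call
    S0000 true_module        70 -2.192532 0.028341 0.075022 non-enriched
    S0000     decoy_1        70  0.431075 0.666414 0.666414 non-enriched
    S0000     decoy_2        70  1.959838 0.050015 0.075022 non-enriched
    ...
```

(S0000 happens to carry *negative* activity — its module expression sits
about two null-SDs below random gene sets; the one-directional call rule
still files it under non-enriched.)

On this cohort 40 of 120 samples are called positive-enriched for the
true module, the z-scores correlate with the injected activity at
r = 0.993, and the two inactive decoy modules have positive-call rates of
0.025 and 0.042 — at or below the 0.05 level, as they should be under the
null. Feeding the calls into the survival module
(`examples/survival_stratification.py`, planted hazard ratio 3):

```
hazard ratio (enriched vs rest): 3.17 [95% CI 2.33, 4.30]  (truth: 3.0)
Cox Wald p = 1.59e-13, log-rank p = 8.09e-15
```

Each script in `examples/` is a short, self-contained walk-through of one
capability (enrichment, survival stratification, overlap diagnostics,
the robustness sweep) and prints what its numbers mean.

The same pipeline from the shell:

```sh
slea simulate -o cohort/ --seed 1
slea enrich cohort/expression.tsv cohort/modules.gmt -o enr/ --seed 2
slea survival cohort/clinical.tsv -o surv/ --result enr/slea_long.tsv --module true_module
slea robustness cohort/expression.tsv cohort/modules.gmt -o rob/ --module true_module
```

Every run writes a `manifest.json` (inputs, parameters, seed, version);
two runs with identical manifests produce byte-identical tables.

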