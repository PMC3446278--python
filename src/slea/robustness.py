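"""Cohort-subsampling robustness of per-sample z-scores.

Row normalization is cohort-relative, so a sample's z-score for a module
depends on which other samples happen to be in the dataset.  This module
implements a random-subsampling protocol that quantifies that
dependence: draw populations of random subsets of the cohort at a range
of sizes, re-normalize each subset independently, re-run the enrichment
for one module, then summarize

* the pairwise Pearson correlation of z-scores between subsets of the
  same size (computed over the samples the two subsets share), and
* the fraction of samples whose z-scores differ significantly (Welch
  t-test, BH-corrected) between a given size and the largest size.

High correlations and a small drift fraction mean the score is a stable
property of the sample rather than of the particular cohort draw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import EnrichmentConfig, bh_adjust, run_slea
from .errors import SleaError
from .io_formats import ExpressionMatrix, GeneModuleSet, normalize_rows

__all__ = [
    "RobustnessConfig",
    "RobustnessReport",
    "default_sizes",
    "draw_subsample_populations",
    "population_zscores",
    "pairwise_zscore_correlations",
    "population_drift_ttest",
    "run_robustness",
]


def default_sizes(n_samples: int, start: int = 11, step: int = 10, cap: int = 201) -> list[int]:
    """Subsample-size ladder: start, start+step, ... up to min(cohort, cap)."""
    top = min(n_samples, cap)
    sizes = list(range(start, top + 1, step))
    if not sizes:
        raise SleaError(f"cohort of {n_samples} samples is smaller than the start size {start}")
    return sizes


@dataclass(frozen=True)
class RobustnessConfig:
    """Parameters of one robustness sweep.

    ``sizes=None`` uses the default ladder (11, 21, ... capped at the
    cohort size and 201).  The enrichment sweep defaults to 1 000
    permutations — the protocol multiplies compute by subsets x sizes —
    while headline enrichment runs use 10 000.
    """

    module_name: str
    sizes: tuple[int, ...] | None = None
    n_datasets_per_size: int = 100
    enrichment: EnrichmentConfig = field(
        default_factory=lambda: EnrichmentConfig(n_permutations=1_000)
    )
    min_shared: int = 3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets_per_size < 2:
            raise SleaError("n_datasets_per_size must be >= 2")
        if self.sizes is not None:
            if len(self.sizes) == 0:
                raise SleaError("sizes must be non-empty")
            if min(self.sizes) < 2:
                raise SleaError("subsample sizes must be >= 2")


@dataclass(frozen=True)
class RobustnessReport:
    """Per-size correlation distributions and drift fractions.

    ``correlations[size]`` holds one Pearson r per subset pair with
    enough shared samples; ``skipped_pairs[size]`` counts the pairs
    without.  ``drift_proportion[size]`` is the fraction of samples
    whose z-scores differ significantly from the largest-size
    population.
    """

    sizes: tuple[int, ...]
    correlations: dict[int, np.ndarray]
    skipped_pairs: dict[int, int]
    drift_proportion: dict[int, float]
    config: RobustnessConfig

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for size in self.sizes:
            corr = self.correlations[size]
            q = np.percentile(corr, [0, 25, 50, 75, 100])
            rows.append(
                {
                    "size": size,
                    "n_pairs": corr.size,
                    "n_pairs_skipped": self.skipped_pairs[size],
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                    "drift_proportion": self.drift_proportion[size],
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    def boxplot(self, path) -> None:
        """Box-and-whisker plot of pairwise correlations per size."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(self.sizes), 4))
        ax.boxplot(
            [self.correlations[s] for s in self.sizes],
            tick_labels=[str(s) for s in self.sizes],
        )
        ax.set_xlabel("subsample size")
        ax.set_ylabel("pairwise Pearson r of z-scores")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def draw_subsample_populations(
    matrix: ExpressionMatrix, config: RobustnessConfig
) -> dict[int, list[list[str]]]:
    """For each size, ``n_datasets_per_size`` uniform random sample-id
    subsets drawn without replacement; reproducible from ``config.seed``."""
    sample_ids = matrix.sample_ids
    n = len(sample_ids)
    sizes = config.sizes if config.sizes is not None else tuple(default_sizes(n))
    too_big = [s for s in sizes if s > n]
    if too_big:
        raise SleaError(f"subsample size(s) {too_big} exceed the cohort size {n}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    populations: dict[int, list[list[str]]] = {}
    ids = np.asarray(sample_ids, dtype=object)
    for size in sizes:
        # subsets are kept in parent-cohort order: membership is what matters,
        # and a fixed order makes the full-size subset reproduce the parent run
        populations[size] = [
            list(ids[np.sort(rng.choice(n, size=size, replace=False))])
            for _ in range(config.n_datasets_per_size)
        ]
    return populations


def population_zscores(
    matrix_raw: ExpressionMatrix,
    subsets: list[list[str]],
    modules: GeneModuleSet,
    module_name: str,
    enrichment_config: EnrichmentConfig,
) -> list[pd.Series]:
    """z-scores of one module for every subset, each subset re-normalized
    independently.

    Normalization is cohort-relative, so each random dataset must be
    median-centered and SD-scaled on its own columns before enrichment —
    this is the step whose stability the protocol probes.  The identity
    subset (all samples, original order) therefore reproduces the
    full-cohort run exactly.
    """
    if matrix_raw.normalized:
        raise SleaError("robustness protocol starts from the raw (un-normalized) matrix")
    if module_name not in modules:
        raise SleaError(f"unknown module {module_name!r}")
    single = GeneModuleSet(
        modules={module_name: modules[module_name]},
        descriptions={module_name: modules.descriptions.get(module_name, "")},
    )
    out: list[pd.Series] = []
    for subset in subsets:
        sub = normalize_rows(matrix_raw.subset_samples(subset))
        result = run_slea(sub, single, enrichment_config)
        z = result.z_matrix().loc[module_name]
        z.name = "z"
        out.append(z)
    return out


def pairwise_zscore_correlations(
    zscores: list[pd.Series], min_shared: int = 3
) -> tuple[np.ndarray, int]:
    """Pearson correlation of z-scores over the shared samples of every
    subset pair; returns (correlations, n_skipped_pairs).

    Pairs sharing fewer than ``min_shared`` samples, or whose shared
    z-scores have zero spread, are skipped and counted.
    """
    if len(zscores) < 2:
        raise SleaError("need >= 2 subsets to correlate")
    corrs: list[float] = []
    skipped = 0
    for za, zb in itertools.combinations(zscores, 2):
        shared = za.index.intersection(zb.index)
        a = za.loc[shared].to_numpy(dtype=float)
        b = zb.loc[shared].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < min_shared or np.std(a) == 0 or np.std(b) == 0:
            skipped += 1
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        raise SleaError("every subset pair was skipped; no correlations computable")
    return np.asarray(corrs), skipped


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value with a convention for zero-variance groups."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(np.mean(a), np.mean(b)) else np.finfo(float).tiny
    p = sps.ttest_ind(a, b, equal_var=False).pvalue
    return float(max(p, np.finfo(float).tiny)) if np.isfinite(p) else 1.0


def population_drift_ttest(
    population: list[pd.Series],
    population_max: list[pd.Series],
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of samples whose z-scores differ between two populations.

    Per sample appearing in >= 2 subsets of each population, a Welch
    t-test compares its z-scores across the size-s subsets with those
    across the largest-size subsets; p-values are BH-corrected across
    samples.  Returns (drift_proportion, n_excluded_samples).
    """
    by_sample_s: dict[str, list[float]] = {}
    for z in population:
        for sid, value in z.items():
            if np.isfinite(value):
                by_sample_s.setdefault(sid, []).append(float(value))
    by_sample_max: dict[str, list[float]] = {}
    for z in population_max:
        for sid, value in z.items():
            if np.isfinite(value):
                by_sample_max.setdefault(sid, []).append(float(value))

    all_ids = sorted(set(by_sample_s) | set(by_sample_max))
    p_values: list[float] = []
    excluded = 0
    for sid in all_ids:
        a = np.asarray(by_sample_s.get(sid, []), dtype=float)
        b = np.asarray(by_sample_max.get(sid, []), dtype=float)
        if a.size < 2 or b.size < 2:
            excluded += 1
            continue
        p_values.append(_welch_p(a, b))
    if not p_values:
        raise SleaError("no sample appears in >= 2 subsets of both populations")
    adjusted = bh_adjust(p_values)
    return float(np.mean(adjusted < alpha)), excluded


def run_robustness(
    matrix_raw: ExpressionMatrix,
    modules: GeneModuleSet,
    config: RobustnessConfig,
) -> RobustnessReport:
    """Full sweep: draw populations, score each subset, summarize
    correlations per size and drift versus the largest size."""
    populations = draw_subsample_populations(matrix_raw, config)
    sizes = tuple(sorted(populations))
    zscores = {
        size: population_zscores(
            matrix_raw, subsets, modules, config.module_name, config.enrichment
        )
        for size, subsets in populations.items()
    }
    correlations: dict[int, np.ndarray] = {}
    skipped: dict[int, int] = {}
    drift: dict[int, float] = {}
    max_size = sizes[-1]
    for size in sizes:
        correlations[size], skipped[size] = pairwise_zscore_correlations(
            zscores[size], config.min_shared
        )
        drift[size], _ = population_drift_ttest(zscores[size], zscores[max_size], config.alpha)
    return RobustnessReport(
        sizes=sizes,
        correlations=correlations,
        skipped_pairs=skipped,
        drift_proportion=drift,
        config=replace(config, sizes=sizes),
    )
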