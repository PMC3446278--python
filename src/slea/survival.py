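"""Survival stratification by enrichment status.

A cohort is split into two groups — samples positively enriched for a
module (or positive for a two-gene signature) versus all the rest — and
their survival is compared with a Cox proportional-hazards fit on the
binary group indicator (Efron tie handling), a log-rank test, and
Kaplan-Meier curves per group.

The two-gene comparator labels a sample positive when both genes'
row-normalized values exceed a threshold.  Normalized units are row SDs,
so the default threshold 1.0 means "more than one SD above the cohort
median" for both genes; a threshold of 0.0 corresponds to the looser
"positive normalized expression" reading and is exposed as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .core import POSITIVE_ENRICHED, EnrichmentResult
from .errors import SleaError
from .io_formats import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalComparison",
    "groups_from_enrichment",
    "groups_from_two_gene_signature",
    "compare_survival",
]


@dataclass(frozen=True)
class SurvivalComparison:
    """Cox + log-rank + Kaplan-Meier comparison of group 1 vs group 0.

    ``hazard_ratio`` is exp(beta) for the binary group covariate (group 1
    relative to group 0) with its 95% CI; ``wald_p`` and
    ``likelihood_ratio_p`` are the Cox fit's p-values, ``logrank_p`` the
    non-parametric test's.  ``km_curves`` maps group label -> DataFrame
    with ``time`` and ``survival`` step points starting at (0, 1).
    """

    labels: pd.Series
    n1: int
    n0: int
    n_events: int
    hazard_ratio: float
    hr_ci: tuple[float, float]
    wald_p: float
    likelihood_ratio_p: float
    logrank_p: float
    km_curves: dict[int, pd.DataFrame] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_group1": [self.n1],
                "n_group0": [self.n0],
                "n_events": [self.n_events],
                "hazard_ratio": [self.hazard_ratio],
                "hr_ci_low": [self.hr_ci[0]],
                "hr_ci_high": [self.hr_ci[1]],
                "wald_p": [self.wald_p],
                "likelihood_ratio_p": [self.likelihood_ratio_p],
                "logrank_p": [self.logrank_p],
            }
        )

    def km_frame(self) -> pd.DataFrame:
        frames = []
        for group, curve in sorted(self.km_curves.items()):
            frame = curve.copy()
            frame.insert(0, "group", group)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def groups_from_enrichment(result: EnrichmentResult, module_name: str) -> pd.Series:
    """Binary labels from SLEA calls: 1 = positive-enriched, 0 = all the rest.

    Not-testable samples are part of "the rest" and get label 0.
    """
    calls = result.calls_for(module_name)
    if calls.isna().all():
        raise SleaError(f"module {module_name!r} was not tested in any sample")
    labels = (calls == POSITIVE_ENRICHED).astype(int)
    labels.name = "group"
    return labels


def groups_from_two_gene_signature(
    matrix: ExpressionMatrix,
    gene_a: str = "CDKN2A",
    gene_b: str = "MKI67",
    threshold: float = 1.0,
) -> pd.Series:
    """Label 1 iff both genes' normalized values exceed ``threshold``.

    Requires a row-normalized matrix so the threshold is in row-SD units.
    Samples with a missing value for either gene get label 0 with a
    warning.
    """
    if not matrix.normalized:
        raise SleaError("two-gene signature requires a row-normalized matrix")
    for gene in (gene_a, gene_b):
        if gene not in matrix.data.index:
            raise SleaError(f"gene {gene!r} not present in the expression matrix")
    a = matrix.data.loc[gene_a]
    b = matrix.data.loc[gene_b]
    missing = a.isna() | b.isna()
    if missing.any():
        logger.warning(
            "%d sample(s) with missing %s/%s values labeled 0", int(missing.sum()), gene_a, gene_b
        )
        warnings.warn(
            f"{int(missing.sum())} sample(s) with missing {gene_a}/{gene_b} values labeled 0",
            stacklevel=2,
        )
    labels = ((a > threshold) & (b > threshold) & ~missing).astype(int)
    labels.name = "group"
    labels.index.name = "sample_id"
    return labels


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})
    if curve.empty or curve["time"].iloc[0] > 0:
        curve = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), curve], ignore_index=True
        )
    return curve


def compare_survival(clinical: ClinicalTable, labels: pd.Series) -> SurvivalComparison:
    """Compare survival between label-1 and label-0 samples.

    Samples are matched by id; labeled samples without a clinical row
    (and vice versa) are dropped with a logged count.  Requires >= 2
    samples per group and >= 1 observed event overall.
    """
    labels = pd.Series(labels).astype(int)
    if not labels.isin([0, 1]).all():
        raise SleaError("labels must be binary 0/1")
    shared = clinical.data.index.intersection(labels.index)
    if len(shared) == 0:
        raise SleaError("no overlap between clinical sample ids and labeled sample ids")
    dropped = (len(clinical.data) - len(shared)) + (len(labels) - len(shared))
    if dropped:
        logger.info("dropped %d sample(s) without both clinical data and a label", dropped)
    df = pd.DataFrame(
        {
            "time": clinical.data.loc[shared, "time"].astype(float),
            "event": clinical.data.loc[shared, "event"].astype(int),
            "group": labels.loc[shared].to_numpy(),
        }
    )
    n1 = int((df["group"] == 1).sum())
    n0 = int((df["group"] == 0).sum())
    if n1 < 2 or n0 < 2:
        raise SleaError(f"each group needs >= 2 samples (got n1={n1}, n0={n0})")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise SleaError("no observed events; survival comparison is undefined")

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # Efron ties (lifelines default)
    summary = cph.summary.loc["group"]
    lr = cph.log_likelihood_ratio_test()
    res = logrank_test(
        df.loc[df["group"] == 1, "time"],
        df.loc[df["group"] == 0, "time"],
        event_observed_A=df.loc[df["group"] == 1, "event"],
        event_observed_B=df.loc[df["group"] == 0, "event"],
    )
    km_curves = {
        g: _km_curve(
            df.loc[df["group"] == g, "time"].to_numpy(),
            df.loc[df["group"] == g, "event"].to_numpy(),
        )
        for g in (0, 1)
    }
    return SurvivalComparison(
        labels=df["group"],
        n1=n1,
        n0=n0,
        n_events=n_events,
        hazard_ratio=float(summary["exp(coef)"]),
        hr_ci=(
            float(summary["exp(coef) lower 95%"]),
            float(summary["exp(coef) upper 95%"]),
        ),
        wald_p=float(summary["p"]),
        likelihood_ratio_p=float(lr.p_value),
        logrank_p=float(res.p_value),
        km_curves=km_curves,
    )
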