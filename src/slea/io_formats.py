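"""Input/output and gene-wise normalization.

The pipeline works on three plain-text inputs:

* an expression table (TSV, genes in rows, samples in columns) holding
  already gene-summarized, log-scale expression values;
* gene modules in the Broad/MSigDB GMT dialect (one set per line:
  ``name<TAB>description<TAB>gene1<TAB>gene2...``);
* a clinical table (TSV with ``sample_id``, ``time``, ``event`` columns;
  any extra columns are kept as categorical annotations).

Normalization is cohort-relative: each gene row is median-centered and
divided by its sample standard deviation, so a value of +1 means "one
row-SD above the cohort-typical expression of this gene".  Because the
reference is the cohort itself, the composition of the cohort is part of
the measurement — the robustness module quantifies the consequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, SleaError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneModuleSet",
    "ClinicalTable",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "normalize_rows",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real matrix with id axes and a normalized flag.

    ``data`` is a float DataFrame indexed by gene id with sample ids as
    columns; NaN marks a missing measurement.  ``normalized`` records
    whether rows have been median-centered and SD-scaled — normalizing
    twice is an error, so the flag travels with the data.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SleaError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise SleaError(f"duplicate sample ids: {dups[:5]}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise SleaError("expression matrix must have at least one gene and one sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset preserving the normalized flag."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise SleaError(f"unknown sample ids: {missing[:5]}")
        return replace(self, data=self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class GeneModuleSet:
    """Named, non-empty gene-identifier sets with optional descriptions."""

    modules: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.modules.items():
            if not name:
                raise SleaError("module names must be non-empty")
            if not genes:
                raise SleaError(f"module {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.modules[name]

    def __contains__(self, name: str) -> bool:
        return name in self.modules

    @property
    def names(self) -> list[str]:
        return list(self.modules)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival time, event indicator and extra annotations.

    ``data`` is indexed by sample id with a positive float ``time``
    column, an integer ``event`` column in {0, 1} (1 = event observed,
    0 = censored) and any further columns kept verbatim as annotations.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise SleaError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            raise SleaError("duplicate sample ids in clinical table")
        if (self.data["time"] <= 0).any():
            raise SleaError("clinical times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise SleaError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def annotations(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def __len__(self) -> int:
        return len(self.data)


def read_expression_table(path, duplicate_policy: str = "median") -> ExpressionMatrix:
    """Read a genes x samples TSV into an un-normalized :class:`ExpressionMatrix`.

    Column 1 holds gene identifiers, the header row sample identifiers;
    empty cells become NaN.  Duplicate gene rows are collapsed per
    ``duplicate_policy`` (``median`` | ``mean`` | ``error``); the default
    per-cell median mirrors how multi-probe genes are commonly summarized.
    """
    if duplicate_policy not in ("median", "mean", "error"):
        raise SleaError(f"unknown duplicate_policy {duplicate_policy!r}")
    # pandas de-duplicates repeated header names silently; check the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: line 1: header defines no sample columns")
    sample_header = header[1:]
    seen = set()
    for sid in sample_header:
        if sid in seen:
            raise FormatError(f"{path}: line 1: repeated sample id {sid!r} in header")
        seen.add(sid)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header defines no sample columns")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no gene rows")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: repeated sample id(s) in header: {dups[:5]}")
    if df.index.isna().any() or (df.index == "").any():
        raise FormatError(f"{path}: empty gene identifier")

    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        # locate the first offending cell for the error message
        for i, (gene, row) in enumerate(df.iterrows(), start=2):
            for col, cell in row.items():
                if isinstance(cell, str) and cell.strip() != "":
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {i}: non-numeric cell {cell!r} "
                            f"(gene {gene!r}, sample {col!r})"
                        ) from None
        raise FormatError(f"{path}: non-numeric cell")  # pragma: no cover
    values = values.astype(float)

    if values.index.has_duplicates:
        if duplicate_policy == "error":
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"{path}: duplicate gene row(s): {dups[:5]}")
        agg = "median" if duplicate_policy == "median" else "mean"
        n_before = len(values)
        values = values.groupby(level=0, sort=False).agg(agg)
        logger.info(
            "collapsed %d duplicate gene rows by per-cell %s", n_before - len(values), agg
        )
    return ExpressionMatrix(data=values, normalized=False)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix back to TSV (full float precision, NaN as empty cell)."""
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def read_gmt(path) -> GeneModuleSet:
    """Parse a GMT file into a :class:`GeneModuleSet`.

    Each line needs at least name, description and one gene; duplicate
    genes within a line are de-duplicated, empty gene fields dropped, and
    a repeated module name is an error.
    """
    modules: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} field(s), needs >= 3"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip() != "")
            if not name:
                raise FormatError(f"{path}: line {lineno}: empty module name")
            if name in modules:
                raise FormatError(f"{path}: line {lineno}: duplicate module name {name!r}")
            if not genes:
                raise FormatError(f"{path}: line {lineno}: module {name!r} has no genes")
            modules[name] = genes
            descriptions[name] = desc
    if not modules:
        raise FormatError(f"{path}: no modules found")
    return GeneModuleSet(modules=modules, descriptions=descriptions)


def write_gmt(modules: GeneModuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in modules.modules.items():
            desc = modules.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_clinical_table(path, strict: bool = False) -> ClinicalTable:
    """Read a clinical TSV (sample_id, time, event, extra annotation columns).

    Rows with a missing time or event are dropped with a logged count
    (``strict=True`` turns them into an error); a non-positive time or an
    event outside {0, 1} is always an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample id(s): {dups[:5]}")
    df = df.set_index("sample_id")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    incomplete = df["time"].isna() | df["event"].isna()
    if incomplete.any():
        if strict:
            raise FormatError(f"{path}: {int(incomplete.sum())} row(s) with missing time/event")
        logger.warning("excluding %d row(s) with missing time/event", int(incomplete.sum()))
        warnings.warn(
            f"excluded {int(incomplete.sum())} clinical row(s) with missing time/event",
            stacklevel=2,
        )
        df = df.loc[~incomplete]
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()
        if strict:
            raise FormatError(f"{path}: non-positive survival time for {bad[:5]}")
        logger.warning("excluding %d row(s) with non-positive time", len(bad))
        warnings.warn(f"excluded {len(bad)} clinical row(s) with non-positive time", stacklevel=2)
        df = df.loc[df["time"] > 0]
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])].tolist()
        raise FormatError(f"{path}: event outside {{0,1}} for {bad[:5]}")
    if len(df) == 0:
        raise FormatError(f"{path}: no usable clinical rows")
    df["event"] = df["event"].astype(int)
    return ClinicalTable(data=df)


def normalize_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-center each gene row and divide by its sample SD.

    The transform is ``(x - row median) / row SD`` with the (n-1)
    denominator, computed over finite cells only; missing cells stay
    missing.  Rows with fewer than two finite values or zero spread
    cannot be scaled and become all-zero, with a logged warning, so the
    matrix shape is stable.  Normalizing an already-normalized matrix is
    an error.
    """
    if matrix.normalized:
        raise SleaError("matrix is already normalized; refusing to normalize twice")
    values = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    finite_counts = np.sum(np.isfinite(values), axis=1)
    degenerate = (finite_counts < 2) | ~np.isfinite(sd[:, 0]) | (sd[:, 0] == 0)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("%d gene row(s) with zero spread set to all-zero", n_degenerate)
        warnings.warn(
            f"{n_degenerate} gene row(s) with zero spread were set to all-zero",
            stacklevel=2,
        )
    out = np.empty_like(values)
    ok = ~degenerate
    out[ok] = (values[ok] - med[ok]) / sd[ok]
    # keep NaN pattern but zero every finite cell of a degenerate row
    out[degenerate] = np.where(np.isfinite(values[degenerate]), 0.0, np.nan)
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        normalized=True,
    )
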