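"""Pairwise gene-module overlap.

Modules drawn from different sources (Gene Ontology, MSigDB, publication
supplements) often share many genes, and strongly overlapping modules
produce correlated enrichment patterns that should not be read as
independent evidence.  The Jaccard index |A∩B| / |A∪B| quantifies this;
pairs above a threshold (default 0.25) are flagged as redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SleaError
from .io_formats import ExpressionMatrix, GeneModuleSet

__all__ = ["OverlapMatrix", "jaccard_index", "overlap_matrix"]


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric Jaccard matrix over modules plus the flagged pairs.

    ``jaccard`` is a square DataFrame (modules x modules, unit diagonal);
    ``high_overlap_pairs`` lists (module_a, module_b, index) tuples with
    index strictly above ``threshold``, each unordered pair once.
    """

    jaccard: pd.DataFrame
    threshold: float
    high_overlap_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def module_names(self) -> list[str]:
        return list(self.jaccard.index)

    def to_tsv(self, path) -> None:
        out = self.jaccard.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t", float_format="%.17g")

    def pairs_to_tsv(self, path) -> None:
        pd.DataFrame(
            self.high_overlap_pairs, columns=["module_a", "module_b", "jaccard"]
        ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def jaccard_index(set_a, set_b) -> float:
    """|A∩B| / |A∪B| for two non-empty gene sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise SleaError("Jaccard index is undefined for empty sets")
    return len(a & b) / len(a | b)


def overlap_matrix(
    modules: GeneModuleSet,
    threshold: float = 0.25,
    restrict_to: ExpressionMatrix | None = None,
) -> OverlapMatrix:
    """Full pairwise Jaccard matrix over >= 2 modules.

    By default overlap is computed on the module gene sets as given.
    ``restrict_to`` first intersects every module with the genes of an
    expression matrix, matching how enrichment itself only sees mapped
    genes; modules left empty after restriction are an error.
    """
    names = modules.names
    if len(names) < 2:
        raise SleaError("overlap analysis needs at least 2 modules")
    sets: dict[str, frozenset[str]] = dict(modules.modules)
    if restrict_to is not None:
        universe = frozenset(restrict_to.gene_ids)
        sets = {name: genes & universe for name, genes in sets.items()}
        empty = [name for name, genes in sets.items() if not genes]
        if empty:
            raise SleaError(f"module(s) with no genes in the matrix: {empty[:5]}")
    n = len(names)
    mat = np.ones((n, n), dtype=float)
    pairs: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            jac = jaccard_index(sets[names[i]], sets[names[j]])
            mat[i, j] = mat[j, i] = jac
            if jac > threshold:
                pairs.append((names[i], names[j], jac))
    return OverlapMatrix(
        jaccard=pd.DataFrame(mat, index=names, columns=names),
        threshold=threshold,
        high_overlap_pairs=pairs,
    )
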