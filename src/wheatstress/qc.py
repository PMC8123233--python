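"""Replicate-consistency diagnostics: correlation clustering and PCA.

Both operate on log2(value + 1) of the normalized matrix; without the log
transform a handful of very highly expressed tags dominates both the
Pearson coefficient and the leading principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["CorrelationMatrix", "PcaResult", "replicate_correlation", "pca_variance"]


@dataclass
class CorrelationMatrix:
    """Pairwise library Pearson correlations with a dendrogram leaf order."""

    libraries: list[str]
    matrix: pd.DataFrame  # symmetric, diagonal 1
    leaf_order: list[str]
    linkage: np.ndarray

    def min_within(self, expr_design: pd.DataFrame) -> float:
        """Smallest correlation between replicates of one condition."""
        vals = []
        for (_, _), grp in expr_design.groupby(["variety", "treatment"]):
            libs = list(grp.index)
            for i, a in enumerate(libs):
                for b in libs[i + 1 :]:
                    vals.append(self.matrix.loc[a, b])
        return float(min(vals)) if vals else float("nan")

    def max_between(self, expr_design: pd.DataFrame) -> float:
        """Largest correlation between libraries of different conditions."""
        cond = expr_design["variety"].astype(str) + "|" + expr_design["treatment"].astype(str)
        vals = []
        libs = list(self.matrix.index)
        for i, a in enumerate(libs):
            for b in libs[i + 1 :]:
                if cond[a] != cond[b]:
                    vals.append(self.matrix.loc[a, b])
        return float(max(vals)) if vals else float("nan")


@dataclass
class PcaResult:
    variance_fractions: np.ndarray  # nonincreasing, sums to <= 1
    scores: pd.DataFrame  # libraries x components


def replicate_correlation(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation between libraries on log2(value + 1).

    Libraries are clustered by average linkage on the distance ``1 - r``;
    the returned leaf order is the standard dendrogram ordering.
    """
    if not expr.normalized:
        raise ValueError("expression matrix must be normalized first")
    if len(expr.libraries) < 2:
        raise ValueError("need at least two libraries")
    log = np.log2(expr.values.to_numpy(dtype=float) + 1.0)
    sd = log.std(axis=0)
    flat = [lib for lib, s in zip(expr.libraries, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance library (correlation undefined): {flat[0]!r}")
    r = np.corrcoef(log, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    linkage = hierarchy.average(dist)
    order = hierarchy.leaves_list(linkage)
    matrix = pd.DataFrame(r, index=expr.libraries, columns=expr.libraries)
    return CorrelationMatrix(
        libraries=list(expr.libraries),
        matrix=matrix,
        leaf_order=[expr.libraries[i] for i in order],
        linkage=linkage,
    )


def pca_variance(expr: ExpressionMatrix, k: int) -> PcaResult:
    """Principal components of the library x gene log2(value + 1) matrix.

    Genes are mean-centered but not scaled to unit variance, so highly
    expressed structure is retained; variance fractions are relative to
    the total variance across all components.
    """
    from sklearn.decomposition import PCA

    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(expr.libraries):
        raise ValueError("k exceeds the number of libraries")
    log = np.log2(expr.values.to_numpy(dtype=float).T + 1.0)  # libraries x genes
    pca = PCA(n_components=k)
    scores = pca.fit_transform(log)
    return PcaResult(
        variance_fractions=np.asarray(pca.explained_variance_ratio_, dtype=float),
        scores=pd.DataFrame(
            scores,
            index=expr.libraries,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
    )
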