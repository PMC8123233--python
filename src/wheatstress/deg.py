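"""Staged differential-expression calling with Benjamini-Yekutieli control.

A gene is called differentially expressed for a (variety, treatment) pair
when it survives three stages applied in order:

1. expression floor — the gene's replicate-mean expression reaches 0.5
   per-million units in at least one experimental point;
2. fold-change gate — stress:control ratio of replicate means above 2 or
   below 0.5 (strict, "more than doubled");
3. Welch t-test on log2(x+1) replicate values, adjusted per variety by the
   Benjamini-Yekutieli step-up at FDR q = 0.05.

Benjamini-Yekutieli controls the false-discovery rate under arbitrary
dependence between tests by inflating the Benjamini-Hochberg threshold by
the harmonic number H(m); it is conservative but safe for the strongly
co-regulated genes of a stress transcriptome.

Each variety's tests are corrected separately (expression responses of the
two cultivars are treated as independent families).
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GenomicIntervalSet

__all__ = [
    "DegTable",
    "OverlapSummary",
    "filter_low_expression",
    "fold_change",
    "deg_test",
    "benjamini_yekutieli",
    "call_degs",
    "venn_overlap",
    "degs_in_intervals",
    "round_half_up",
]

DEG_COLUMNS = [
    "gene",
    "variety",
    "treatment",
    "mean_control",
    "mean_stress",
    "fold_change",
    "p_value",
    "p_adjusted",
    "direction",
    "significant",
]

#: a DegTable is a plain DataFrame with the columns above, one row per
#: (gene, variety, stress treatment)
DegTable = pd.DataFrame


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _require_normalized(expr: ExpressionMatrix) -> None:
    if not expr.normalized:
        raise ValueError("expression matrix must be normalized per million first")


def _control_treatment(expr: ExpressionMatrix, control: str | None = None) -> str:
    """The baseline treatment: named 'control' if present, else first in design."""
    if control is not None:
        if control not in expr.treatments:
            raise ValueError(f"control treatment {control!r} not in design")
        return control
    return "control" if "control" in expr.treatments else expr.treatments[0]


def filter_low_expression(
    expr: ExpressionMatrix, floor: float = 0.5, require_all: bool = False
) -> list[str]:
    """Genes passing the expression floor.

    By default a gene is retained when its replicate-mean expression
    reaches ``floor`` in at least one experimental point (variety x
    treatment); genes below the floor everywhere are dropped.  With
    ``require_all`` the stricter reading applies: the mean must reach the
    floor in every experimental point.
    """
    _require_normalized(expr)
    means = expr.condition_means()
    ok = (means >= floor).all(axis=1) if require_all else (means >= floor).any(axis=1)
    return list(means.index[ok])


def fold_change(
    expr: ExpressionMatrix,
    gene: str,
    variety: str,
    treatment: str,
    pseudocount: float = 0.01,
    control: str | None = None,
) -> float:
    """Stress:control ratio of replicate means for one gene and variety.

    A small pseudocount keeps the ratio finite for genes silent in one
    condition.
    """
    _require_normalized(expr)
    control = _control_treatment(expr, control)
    c_libs = expr.libraries_for(variety, control)
    s_libs = expr.libraries_for(variety, treatment)
    if not c_libs:
        raise ValueError(f"no control libraries for variety {variety!r}")
    if not s_libs:
        raise ValueError(f"no libraries for ({variety!r}, {treatment!r})")
    mean_c = float(expr.values.loc[gene, c_libs].mean())
    mean_s = float(expr.values.loc[gene, s_libs].mean())
    return (mean_s + pseudocount) / (mean_c + pseudocount)


def deg_test(control_reps, stress_reps) -> float:
    """Two-sided Welch t-test on log2(x+1) replicate values.

    Welch's unpooled-variance form is used: with three replicates per
    group, variance equality cannot be assessed and assuming it is risky.
    Degenerate zero-variance groups resolve by mean comparison (p = 1 when
    equal, p = 0 otherwise).
    """
    c = np.log2(np.asarray(control_reps, dtype=float) + 1.0)
    s = np.log2(np.asarray(stress_reps, dtype=float) + 1.0)
    if len(c) < 2 or len(s) < 2:
        raise ValueError("need at least two replicates per group")
    if c.var(ddof=1) == 0.0 and s.var(ddof=1) == 0.0:
        return 1.0 if np.isclose(c.mean(), s.mean()) else 0.0
    res = stats.ttest_ind(c, s, equal_var=False)
    return float(res.pvalue)


def benjamini_yekutieli(
    p_values, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up adjustment.

    For sorted p-values p(1) <= ... <= p(m), the adjusted value at rank i
    is ``min_{j >= i} min(1, p(j) * m * H(m) / j)`` with H(m) the m-th
    harmonic number; the hypothesis is rejected when its adjusted value is
    at most ``q``.  Valid under arbitrary dependence.

    Returns ``(adjusted, rejected)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    harmonic = np.sum(1.0 / np.arange(1, m + 1))
    scaled = p[order] * m * harmonic / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def call_degs(
    expr: ExpressionMatrix,
    floor: float = 0.5,
    fc_threshold: float = 2.0,
    q: float = 0.05,
    pseudocount: float = 0.01,
    require_all: bool = False,
    per_treatment: bool = False,
    control: str | None = None,
) -> DegTable:
    """Run the three-stage DEG algorithm over every variety and treatment.

    Rows cover every (gene passing the floor, variety, stress treatment);
    p-values are only computed (and corrected) for rows passing the
    fold-change gate — the gate defines the family of tests the FDR
    correction sees.  By default each variety's tests across all
    treatments form one correction family; ``per_treatment`` corrects each
    (variety, treatment) family separately.
    """
    _require_normalized(expr)
    control = _control_treatment(expr, control)
    stress_treatments = [t for t in expr.treatments if t != control]
    for v in expr.varieties:
        if not expr.libraries_for(v, control):
            raise ValueError(f"variety {v!r} has no control libraries")

    kept = filter_low_expression(expr, floor=floor, require_all=require_all)
    means = expr.condition_means().loc[kept]

    rows = []
    log_values = np.log2(expr.values.loc[kept] + 1.0)
    for v in expr.varieties:
        c_libs = expr.libraries_for(v, control)
        for t in stress_treatments:
            s_libs = expr.libraries_for(v, t)
            if not s_libs:
                continue
            mean_c = means[(v, control)]
            mean_s = means[(v, t)]
            fc = (mean_s + pseudocount) / (mean_c + pseudocount)
            passes = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
            p = np.full(len(kept), np.nan)
            if passes.any() and len(c_libs) >= 2 and len(s_libs) >= 2:
                c = log_values[c_libs].to_numpy()
                s = log_values[s_libs].to_numpy()
                idx = np.flatnonzero(passes.to_numpy())
                with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                    # near-constant groups trip scipy's precision-loss
                    # warning; those rows are resolved explicitly below
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = stats.ttest_ind(c[idx], s[idx], axis=1, equal_var=False)
                pv = np.asarray(res.pvalue, dtype=float)
                # zero-variance-in-both degeneracies: decide by mean equality
                both_const = (c[idx].std(axis=1) == 0) & (s[idx].std(axis=1) == 0)
                if both_const.any():
                    eq = np.isclose(c[idx].mean(axis=1), s[idx].mean(axis=1))
                    pv[both_const] = np.where(eq[both_const], 1.0, 0.0)
                p[idx] = pv
            for g, mc, ms, f, pp in zip(kept, mean_c, mean_s, fc, p):
                rows.append((g, v, t, mc, ms, f, pp))

    table = pd.DataFrame(
        rows,
        columns=["gene", "variety", "treatment", "mean_control", "mean_stress",
                 "fold_change", "p_value"],
    )
    table["p_adjusted"] = np.nan
    table["direction"] = np.where(table["fold_change"] >= 1.0, "up", "down")
    table["significant"] = False

    group_cols = ["variety", "treatment"] if per_treatment else ["variety"]
    for _, idx in table.groupby(group_cols).groups.items():
        sub = table.loc[idx]
        tested = sub.index[sub["p_value"].notna()]
        if len(tested) == 0:
            continue
        adjusted, rejected = benjamini_yekutieli(table.loc[tested, "p_value"], q=q)
        table.loc[tested, "p_adjusted"] = adjusted
        table.loc[tested, "significant"] = rejected
    return table[DEG_COLUMNS]


@dataclass
class OverlapSummary:
    """Venn arithmetic for two gene lists."""

    size_a: int
    size_b: int
    intersection: int
    union: int
    percentage: float | None  # 100 * intersection / union, one decimal

    @classmethod
    def from_sets(cls, a, b) -> "OverlapSummary":
        a, b = set(a), set(b)
        inter = len(a & b)
        union = len(a | b)
        pct = None if union == 0 else round_half_up(100.0 * inter / union, 1)
        return cls(len(a), len(b), inter, union, pct)


def venn_overlap(genes_a, genes_b) -> OverlapSummary:
    """Two-set overlap with the shared percentage relative to the union.

    The percentage is reported to one decimal (round-half-up); it is
    ``None`` when both sets are empty.
    """
    return OverlapSummary.from_sets(genes_a, genes_b)


def degs_in_intervals(
    deg_table: DegTable,
    regions: GenomicIntervalSet,
    gene_positions: pd.DataFrame,
) -> DegTable:
    """Rows of a DEG table whose gene midpoint falls inside any region.

    ``gene_positions`` is indexed by gene with columns ``chrom``,
    ``start``, ``end`` (half-open).  Genes without a position are skipped
    with a warning.
    """
    if len(deg_table) == 0 or len(regions) == 0:
        return deg_table.iloc[0:0]
    known = deg_table["gene"].isin(gene_positions.index)
    missing = sorted(set(deg_table.loc[~known, "gene"]))
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) lack positions and were skipped", stacklevel=2
        )
    sub = deg_table[known]
    pos = gene_positions.loc[sub["gene"]]
    mid = (pos["start"].to_numpy() + pos["end"].to_numpy()) / 2.0
    keep = [
        regions.contains(c, m) for c, m in zip(pos["chrom"].to_numpy(), mid)
    ]
    return sub[np.asarray(keep, dtype=bool)]
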