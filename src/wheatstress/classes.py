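"""Six-class fold-change binning and tuple profiling over conditions.

Each gene's stress:control fold change is binned into one of six ordered
classes:

====== =============================================
label  fold-change interval
====== =============================================
i      fc <= 1/2           (decreased more than 2x)
ii     1/2 < fc < 1/band   (decreased less than 2x)
iii    1/band <= fc <= band ("almost unchanged")
iv     band < fc < 2       (increased less than 2x)
v      2 <= fc <= 5        (increased more than 2x)
vi     fc > 5              (increased more than 5x)
====== =============================================

The bins are mutually exclusive and cover all positive fold changes for
any band in (1, 2); the default "almost unchanged" band is 1.25x
(|log2 fc| < ~0.32).  Across an ordered axis of (variety, treatment)
conditions a gene receives a class tuple; six conditions give 6^6 = 46,656
possible tuples, of which only a few are populated in practice.  Genes of
the most populated tuples whose per-treatment response direction agrees
between the varieties form the conserved-response core set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "ClassTupleProfile",
    "TupleHistogram",
    "CoreGeneSet",
    "assign_class",
    "direction_category",
    "build_tuples",
    "top_populated",
    "core_genes",
    "select_pattern",
    "cross_dataset_concordance",
    "fc_frame_from_deg_table",
]

CLASS_LABELS = ("i", "ii", "iii", "iv", "v", "vi")

_DIRECTION = {"i": "down", "ii": "down", "iii": "unchanged",
              "iv": "up", "v": "up", "vi": "up"}


def assign_class(fc: float, unchanged_band: float = 1.25) -> str:
    """Bin one positive fold change into the six-class scheme."""
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    if not 1.0 < unchanged_band < 2.0:
        raise ValueError("unchanged_band must lie in (1, 2)")
    if fc <= 0.5:
        return "i"
    if fc < 1.0 / unchanged_band:
        return "ii"
    if fc <= unchanged_band:
        return "iii"
    if fc < 2.0:
        return "iv"
    if fc <= 5.0:
        return "v"
    return "vi"


def direction_category(label: str) -> str:
    """Collapse a class label to its response direction (down/unchanged/up)."""
    return _DIRECTION[label]


@dataclass
class ClassTupleProfile:
    """One gene's class tuple over the ordered condition axis."""

    gene: str
    axis: tuple  # ordered (variety, treatment) pairs
    labels: tuple  # class labels, same length as axis
    fold_changes: tuple


@dataclass
class TupleHistogram:
    counts: dict  # tuple of labels -> gene count
    axis: tuple
    n_genes: int

    @property
    def n_possible(self) -> int:
        return len(CLASS_LABELS) ** len(self.axis)


@dataclass
class CoreGeneSet:
    """Genes with a variety-consistent per-treatment response direction."""

    genes: list
    directions: pd.DataFrame  # gene x treatment -> down/unchanged/up


def fc_frame_from_deg_table(deg_table: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Pivot a DEG table into a gene x (variety, treatment) fold-change frame."""
    sub = deg_table if genes is None else deg_table[deg_table["gene"].isin(set(genes))]
    frame = sub.pivot_table(
        index="gene", columns=["variety", "treatment"], values="fold_change"
    )
    return frame


def build_tuples(
    fc_frame: pd.DataFrame, axis=None, unchanged_band: float = 1.25
) -> tuple[list[ClassTupleProfile], TupleHistogram]:
    """Classify every gene over the condition axis and tally the tuples.

    ``fc_frame`` is indexed by gene with (variety, treatment) columns; the
    axis defaults to the frame's column order.  Every gene must carry a
    fold change for every axis condition.
    """
    if axis is None:
        axis = tuple(fc_frame.columns)
    else:
        axis = tuple(tuple(c) for c in axis)
        missing = [c for c in axis if c not in fc_frame.columns]
        if missing:
            raise ValueError(f"axis conditions absent from frame: {missing}")
    sub = fc_frame[list(axis)]
    nulls = sub.isna()
    if nulls.any().any():
        gene = sub.index[nulls.any(axis=1)][0]
        cond = sub.columns[nulls.loc[gene]][0]
        raise ValueError(f"missing fold change for gene {gene!r}, condition {cond}")
    profiles = []
    counts: dict[tuple, int] = {}
    for gene, row in sub.iterrows():
        fcs = tuple(float(x) for x in row)
        labels = tuple(assign_class(fc, unchanged_band) for fc in fcs)
        profiles.append(ClassTupleProfile(gene=gene, axis=axis, labels=labels,
                                          fold_changes=fcs))
        counts[labels] = counts.get(labels, 0) + 1
    return profiles, TupleHistogram(counts=counts, axis=axis, n_genes=len(profiles))


_LABEL_ORDER = {lab: i for i, lab in enumerate(CLASS_LABELS)}


def top_populated(hist: TupleHistogram, n: int = 20) -> list[tuple]:
    """The n most populated class tuples (count desc, ties lexicographic)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    key = lambda item: (-item[1], tuple(_LABEL_ORDER[l] for l in item[0]))
    return [t for t, _ in sorted(hist.counts.items(), key=key)[:n]]


def _axis_by_treatment(axis) -> dict:
    """Group axis positions by treatment; each must appear in >= 2 varieties."""
    by_treatment: dict[str, list[int]] = {}
    for i, (_, treatment) in enumerate(axis):
        by_treatment.setdefault(treatment, []).append(i)
    bad = [t for t, idx in by_treatment.items() if len(idx) < 2]
    if bad:
        raise ValueError(
            f"axis does not pair treatments across varieties: {bad}"
        )
    return by_treatment


def core_genes(
    profiles: list[ClassTupleProfile], selected_tuples
) -> CoreGeneSet:
    """Genes in the selected tuples responding the same way in both varieties.

    A gene qualifies when its tuple is among ``selected_tuples`` and, for
    every treatment, its direction category (down for classes i-ii,
    unchanged for iii, up for iv-vi) is identical across the varieties.
    """
    selected = {tuple(t) for t in selected_tuples}
    genes, rows = [], []
    treatments_order: list[str] = []
    for prof in profiles:
        if prof.labels not in selected:
            continue
        by_treatment = _axis_by_treatment(prof.axis)
        if not treatments_order:
            treatments_order = list(by_treatment)
        dirs = {}
        consistent = True
        for treatment, idx in by_treatment.items():
            cats = {direction_category(prof.labels[i]) for i in idx}
            if len(cats) != 1:
                consistent = False
                break
            dirs[treatment] = cats.pop()
        if consistent:
            genes.append(prof.gene)
            rows.append(dirs)
    directions = pd.DataFrame(rows, index=genes, columns=treatments_order or None)
    return CoreGeneSet(genes=genes, directions=directions)


def select_pattern(profiles: list[ClassTupleProfile], pattern: dict) -> list:
    """Genes matching a per-treatment direction pattern in both varieties.

    ``pattern`` maps treatment -> direction ('up', 'down' or 'unchanged'),
    e.g. ``{"wd": "up", "cold6": "down", "cold24": "down"}`` for the
    drought-induced / cold-repressed signature.
    """
    out = []
    for prof in profiles:
        by_treatment = _axis_by_treatment(prof.axis)
        ok = True
        for treatment, want in pattern.items():
            idx = by_treatment.get(treatment)
            if idx is None:
                raise ValueError(f"treatment {treatment!r} absent from axis")
            if any(direction_category(prof.labels[i]) != want for i in idx):
                ok = False
                break
        if ok:
            out.append(prof.gene)
    return out


def cross_dataset_concordance(
    core: CoreGeneSet,
    external_fc: dict,
    treatment: str,
    unchanged_band: float = 1.25,
) -> tuple[float | None, list]:
    """Direction agreement of core genes with an external fold-change table.

    ``external_fc`` maps gene -> stress:control fold change measured in an
    independent dataset under a comparable treatment.  Returns the
    fraction of covered core genes whose external direction (binned with
    the same class scheme) matches the core direction for ``treatment``,
    plus the list of core genes the external table does not cover.
    """
    if treatment not in core.directions.columns:
        raise ValueError(f"core set has no direction for treatment {treatment!r}")
    covered, matches = 0, 0
    uncovered = []
    for gene in core.genes:
        if gene not in external_fc:
            uncovered.append(gene)
            continue
        covered += 1
        ext_dir = direction_category(assign_class(external_fc[gene], unchanged_band))
        if ext_dir == core.directions.loc[gene, treatment]:
            matches += 1
    if covered == 0:
        warnings.warn("external table covers no core gene", stacklevel=2)
        return None, uncovered
    return matches / covered, uncovered
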