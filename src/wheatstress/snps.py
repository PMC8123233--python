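"""SNP filtering, sharing and genome-wide distribution summaries.

Variants called against the reference cultivar are filtered on call
quality (QUAL strictly above 30 is considered reliable), restricted to
sites homozygous for the alternate allele within a variety, and
summarized: per-variety totals and sharing between varieties, counts and
per-Mb densities per chromosome, position profiles along a normalized
("averaged") chromosome, annotation-category breakdowns, and a three-leaf
distance dendrogram (two varieties plus the reference, distances counted
as differing sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .deg import OverlapSummary, round_half_up
from .io import GT_HOM_ALT, GT_MISSING, SnpRecordSet

__all__ = [
    "filter_snps",
    "select_hom_alt",
    "variety_sharing",
    "chromosome_profile",
    "category_fractions",
    "distance_tree",
    "VarietyDistanceTree",
]


def filter_snps(records: SnpRecordSet, qual_min: float = 30.0) -> SnpRecordSet:
    """Keep records with QUAL strictly above ``qual_min``."""
    df = records.records
    return SnpRecordSet(records=df[df["qual"] > qual_min].reset_index(drop=True))


def select_hom_alt(records: SnpRecordSet) -> SnpRecordSet:
    """Keep records homozygous for the alternate allele in their variety.

    Records with a missing genotype are dropped (they carry no evidence
    either way).
    """
    df = records.records
    n_missing = int((df["genotype"] == GT_MISSING).sum())
    if n_missing:
        import warnings

        warnings.warn(f"{n_missing} record(s) with missing genotype skipped",
                      stacklevel=2)
    return SnpRecordSet(
        records=df[df["genotype"] == GT_HOM_ALT].reset_index(drop=True)
    )


def variety_sharing(sites_a, sites_b) -> OverlapSummary:
    """Site sharing between two varieties, percentage relative to the union.

    Site keys are whatever the caller used to build the sets — by default
    (chromosome, position, alternate allele) via
    :meth:`SnpRecordSet.variety_sites`.
    """
    return OverlapSummary.from_sets(sites_a, sites_b)


def chromosome_profile(
    records: SnpRecordSet, chrom_lengths: dict, n_bins: int = 100
) -> dict:
    """Per-chromosome counts, per-Mb densities and a normalized position profile.

    The position profile bins ``pos / length`` into ``n_bins`` equal bins
    and sums over chromosomes — the distribution along an "averaged"
    chromosome.  Its mass equals the number of records profiled.
    """
    df = records.records
    unknown = sorted(set(df["chrom"]) - set(chrom_lengths))
    if unknown:
        raise ValueError(f"chromosome(s) missing from chrom_lengths: {unknown}")
    counts = df.groupby("chrom").size().reindex(chrom_lengths.keys(), fill_value=0)
    lengths = pd.Series(chrom_lengths, dtype=float)
    density = counts / (lengths / 1e6)
    hist = np.zeros(n_bins, dtype=int)
    if len(df):
        frac = df["pos"].to_numpy(dtype=float) / lengths.loc[df["chrom"]].to_numpy()
        bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
        hist = np.bincount(bins, minlength=n_bins)
    return {
        "counts": counts,
        "per_mb": density,
        "position_profile": hist,
        "n_bins": n_bins,
    }


def category_fractions(records: SnpRecordSet) -> dict:
    """Share of records per annotation category.

    Returns ``{"fractions": {...}, "percent": {...}}``: exact fractions
    plus integer display percentages (round-half-up).
    """
    df = records.records
    if len(df) == 0:
        return {"fractions": {}, "percent": {}}
    counts = df["category"].value_counts()
    fractions = (counts / counts.sum()).to_dict()
    percent = {k: int(round_half_up(100.0 * v, 0)) for k, v in fractions.items()}
    return {"fractions": fractions, "percent": percent}


@dataclass
class VarietyDistanceTree:
    """3-leaf dendrogram over (variety1, variety2, reference).

    Distances count differing sites: a variety differs from the reference
    at every site it carries, and two varieties differ at the symmetric
    difference of their site sets.
    """

    labels: list
    distances: pd.DataFrame  # symmetric, zero diagonal
    linkage: np.ndarray

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({walk(left)}:{ld:g},{walk(right)}:{rd:g})"

        return walk(tree) + ";"


def distance_tree(sites_a, sites_b, labels=("variety1", "variety2", "reference")) -> VarietyDistanceTree:
    """Average-linkage dendrogram of two varieties and the reference.

    The reference carries no alternate alleles, so its distance to a
    variety is that variety's site count; the inter-variety distance is
    the size of the symmetric difference.
    """
    a, b = set(sites_a), set(sites_b)
    d_ab = len(a ^ b)
    mat = np.array(
        [
            [0.0, d_ab, len(a)],
            [d_ab, 0.0, len(b)],
            [len(a), len(b), 0.0],
        ]
    )
    linkage = hierarchy.average(squareform(mat, checks=False))
    return VarietyDistanceTree(
        labels=list(labels),
        distances=pd.DataFrame(mat, index=labels, columns=labels),
        linkage=linkage,
    )
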