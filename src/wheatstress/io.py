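"""Readers, writers and containers for the formats the pipeline consumes.

The pipeline operates downstream of read quantification: its inputs are a
gene x library count table with a sample-design sheet, a BLAST tabular
(outfmt 6) homology hit table, a SnpEff-annotated VCF, and BED intervals
for QTL regions.  All coordinate conventions are centralized here: VCF
positions are 1-based, BED intervals 0-based half-open.

Expression values are normalized per million counted reads per library
(counts-per-million).  The 3'-tag protocol the pipeline targets produces
one tag per transcript, so no gene-length term enters the normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "HomologyHitTable",
    "SnpRecordSet",
    "GenomicIntervalSet",
    "FormatError",
    "read_expression",
    "write_expression",
    "normalize_per_million",
    "read_vcf",
    "read_hits",
    "write_hits",
    "read_intervals",
]

DESIGN_COLUMNS = ("variety", "treatment", "replicate")

#: genotype codes used throughout the SNP layer
GT_HOM_REF = "hom-ref"
GT_HET = "het"
GT_HOM_ALT = "hom-alt"
GT_MISSING = "missing"


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Gene x library expression values with the sample design attached.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per library id.
        Nonnegative; raw counts when ``normalized`` is False, per-million
        units otherwise.
    design
        DataFrame indexed by library id with columns ``variety``,
        ``treatment`` and ``replicate``.  Treatment order as first seen in
        the design defines the condition axis downstream.
    normalized
        Whether values are on the per-million scale.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate library id: {dup!r}")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise FormatError(f"design lacks columns: {missing}")
        absent = self.values.columns.difference(self.design.index)
        if len(absent):
            raise FormatError(
                f"libraries missing from design: {sorted(map(str, absent))}"
            )
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise FormatError("expression values must be numeric")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be nonnegative")
        # keep design restricted and aligned to the matrix columns
        self.design = self.design.loc[self.values.columns, list(DESIGN_COLUMNS)]

    # -- design helpers -----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)

    @property
    def varieties(self) -> list[str]:
        return list(dict.fromkeys(self.design["variety"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.design["treatment"]))

    def libraries_for(self, variety: str, treatment: str) -> list[str]:
        m = (self.design["variety"] == variety) & (
            self.design["treatment"] == treatment
        )
        return list(self.design.index[m])

    def condition_means(self) -> pd.DataFrame:
        """Replicate-mean expression per (variety, treatment).

        Returns a DataFrame indexed by gene with a (variety, treatment)
        MultiIndex over columns, in design order.
        """
        cols = {}
        for v in self.varieties:
            for t in self.treatments:
                libs = self.libraries_for(v, t)
                if libs:
                    cols[(v, t)] = self.values[libs].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(
            out.columns, names=["variety", "treatment"]
        )
        return out


def read_expression(matrix_path, design_path) -> ExpressionMatrix:
    """Read a gene x library TSV and its design sheet.

    The matrix TSV has a header row of library ids and gene ids in the
    first column.  The design TSV has columns ``library``, ``variety``,
    ``treatment``, ``replicate``.  The returned matrix is flagged raw
    (``normalized=False``).
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression cell in {matrix_path}: {exc}")
    design = pd.read_csv(design_path, sep="\t")
    if "library" not in design.columns:
        raise FormatError(f"design {design_path} lacks a 'library' column")
    design = design.set_index("library")
    if design.index.has_duplicates:
        dup = design.index[design.index.duplicated()][0]
        raise FormatError(f"duplicate library in design: {dup!r}")
    return ExpressionMatrix(values=values, design=design, normalized=False)


def write_expression(expr: ExpressionMatrix, matrix_path, design_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    design = expr.design.copy()
    design.index.name = "library"
    design.to_csv(design_path, sep="\t")


def normalize_per_million(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each library to one million counted reads.

    Each value becomes ``raw * 1e6 / library_sum``.  This is the per-million
    arithmetic appropriate for 3'-tag counts, where one tag is produced per
    transcript and gene length plays no role.

    Raises
    ------
    ValueError
        If the matrix is already normalized (the operation is guarded
        against double application) or a library has zero total counts.
    """
    if expr.normalized:
        raise ValueError("matrix is already normalized")
    sums = expr.values.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero library: {zero[0]!r}")
    values = expr.values * (1e6 / sums)
    return replace(expr, values=values, normalized=True)


# ---------------------------------------------------------------------------
# Homology hits (BLAST outfmt 6)

OUTFMT6_COLUMNS = [
    "query",
    "subject",
    "identity",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class HomologyHitTable:
    """Pairwise similarity hits; identity stored as a fraction in [0, 1].

    ``rank`` numbers each query's hits in file order (1 = best), mirroring
    the per-query ordering a similarity search emits.
    """

    hits: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.hits
        required = set(OUTFMT6_COLUMNS)
        if not required.issubset(df.columns):
            raise FormatError(
                f"hit table lacks columns: {sorted(required - set(df.columns))}"
            )
        if len(df):
            if (df["identity"] < 0).any() or (df["identity"] > 1).any():
                raise FormatError("identity must lie in [0, 1]")
            if (df["evalue"] < 0).any():
                raise FormatError("e-value must be nonnegative")
            if "rank" not in df.columns:
                self.hits = df.assign(
                    rank=df.groupby("query", sort=False).cumcount() + 1
                )
        elif "rank" not in df.columns:
            self.hits = df.assign(rank=pd.Series(dtype=int))

    def __len__(self) -> int:
        return len(self.hits)


def read_hits(path) -> HomologyHitTable:
    """Read 12-column BLAST tabular output (outfmt 6).

    Identity percentages are converted to fractions on read.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(12))
    if df.shape[1] != 12:
        raise FormatError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = OUTFMT6_COLUMNS
    df["identity"] = df["identity"].astype(float) / 100.0
    return HomologyHitTable(hits=df)


def write_hits(table: HomologyHitTable, path) -> None:
    df = table.hits[OUTFMT6_COLUMNS].copy()
    df["identity"] = df["identity"] * 100.0
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SNP records


@dataclass
class SnpRecordSet:
    """Per-(site, variety) SNP records from an annotated multi-sample VCF.

    One record is kept per site per sample; columns: ``chrom``, ``pos``
    (1-based), ``ref``, ``alt``, ``qual``, ``variety``, ``genotype`` (one of
    hom-ref / het / hom-alt / missing) and ``category`` (first effect term
    of the ANN annotation, empty string when unannotated).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "qual", "variety", "genotype", "category"]
        )
    )

    def __post_init__(self) -> None:
        df = self.records
        required = {"chrom", "pos", "qual", "variety", "genotype", "category"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"SNP records lack columns: {sorted(required - set(df.columns))}"
            )
        if len(df) and (df["pos"] < 1).any():
            raise FormatError("VCF positions are 1-based; position < 1 found")

    def __len__(self) -> int:
        return len(self.records)

    def variety_sites(self, variety: str, by_allele: bool = True) -> set:
        """Site keys carried by one variety: (chrom, pos, alt) or (chrom, pos)."""
        sub = self.records[self.records["variety"] == variety]
        if by_allele:
            return set(zip(sub["chrom"], sub["pos"], sub["alt"]))
        return set(zip(sub["chrom"], sub["pos"]))


def _ann_category(ann: str | None) -> str:
    """First effect term of a SnpEff ANN string ('allele|effect|...')."""
    if not ann:
        return ""
    first = str(ann).split(",")[0].split("|")
    if len(first) < 2:
        return ""
    return first[1].split("&")[0]


def read_vcf(path) -> SnpRecordSet:
    """Read an annotated VCF into per-(site, variety) records.

    Each sample column is treated as one variety.  Only the first ALT
    allele of multi-allelic sites is considered (others are dropped with a
    warning).  Genotype classes come from the GT field alone; QUAL is a
    site-level score shared by the per-variety records of a site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    n_multi = 0
    for var in vcf:
        alts = var.ALT or []
        if len(alts) > 1:
            n_multi += 1
        alt = alts[0] if alts else ""
        category = _ann_category(var.INFO.get("ANN"))
        qual = float(var.QUAL) if var.QUAL is not None else float("nan")
        gt_types = var.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        for i, sample in enumerate(samples):
            code = int(gt_types[i]) if len(samples) else 2
            genotype = {
                0: GT_HOM_REF,
                1: GT_HET,
                2: GT_MISSING,
                3: GT_HOM_ALT,
            }[code]
            rows.append(
                (var.CHROM, int(var.POS), var.REF, alt, qual, sample, genotype, category)
            )
    vcf.close()
    if n_multi:
        warnings.warn(
            f"{n_multi} multi-allelic site(s): only the first ALT allele was kept",
            stacklevel=2,
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "variety", "genotype", "category"],
    )
    return SnpRecordSet(records=df)


# ---------------------------------------------------------------------------
# Genomic intervals (BED)


@dataclass
class GenomicIntervalSet:
    """0-based half-open intervals, optionally labelled (BED3+)."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label"])
    )

    def __post_init__(self) -> None:
        df = self.intervals
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise FormatError("interval set needs chrom/start/end columns")
        if "label" not in df.columns:
            self.intervals = df.assign(label="")
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(
                f"empty/inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: float) -> bool:
        """Whether a point falls in any interval (half-open comparison)."""
        df = self.intervals
        sub = df[df["chrom"] == chrom]
        return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())


def read_intervals(path) -> GenomicIntervalSet:
    """Read BED3+ intervals (0-based half-open, as in the BED standard)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return GenomicIntervalSet()
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns, found {df.shape[1]}")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["label"] = df.iloc[:, 3] if df.shape[1] > 3 else ""
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return GenomicIntervalSet(intervals=out)
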