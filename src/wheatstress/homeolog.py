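"""Homeolog triplet assembly and expression-balance classification.

Allohexaploid bread wheat carries three corresponding gene copies
(homeologs) on the A, B and D subgenomes.  Triplets are assembled from a
protein-similarity hit table: hits are filtered (e-value < 1e-4, identity
> 0.6, top 3 per query), and three genes on the three subgenomes of one
homoeologous group form a triplet when each retains the other two among
its filtered hits (mutual-hit requirement; prevents promiscuous paralogs
from chaining triplets together).

Per condition, the triplet's expression shares (rA, rB, rD) — replicate
means normalized to sum to one — are classified into seven classes,
dominance checked before suppression:

* ``X-dominant``  — copy X carries more than 66% of the triplet total;
* ``X-suppressed`` — copy X carries less than 16% (smallest ratio wins
  when several fall below);
* ``balanced``    — everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._chrom import SUBGENOMES, parse_chromosome
from .io import ExpressionMatrix, HomologyHitTable

__all__ = [
    "HomeologTriplet",
    "BalanceProfile",
    "assemble_triplets",
    "balance_ratios",
    "classify_balance",
    "class_fractions",
    "BALANCE_CLASS_ORDER",
]

BALANCE_CLASS_ORDER = (
    "A-dominant",
    "B-dominant",
    "D-dominant",
    "A-suppressed",
    "B-suppressed",
    "D-suppressed",
    "balanced",
)


@dataclass(frozen=True)
class HomeologTriplet:
    """One gene per subgenome of a single homoeologous group."""

    gene_A: str
    gene_B: str
    gene_D: str
    group: int

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.gene_A, self.gene_B, self.gene_D)


@dataclass
class BalanceProfile:
    triplet: HomeologTriplet
    condition: tuple  # (variety, treatment)
    ratios: tuple | None  # (rA, rB, rD), None when the triple is silent
    balance_class: str | None
    contains_deg: bool = False


def assemble_triplets(
    hits: HomologyHitTable,
    chrom_of: dict,
    e_max: float = 1e-4,
    id_min: float = 0.6,
    top_k: int = 3,
    mutual: bool = True,
) -> list[HomeologTriplet]:
    """Assemble A/B/D homeolog triplets from a similarity hit table.

    ``chrom_of`` maps gene id -> chromosome name; genes with unplaced or
    unparseable chromosomes are skipped with a warning.  When several
    candidate triplets compete for a gene, the greedy resolution keeps the
    candidate with the larger total bitscore (ties broken by lexicographic
    gene ids); each gene joins at most one triplet.
    """
    df = hits.hits
    keep = (df["evalue"] < e_max) & (df["identity"] > id_min) & (df["rank"] <= top_k)
    df = df[keep]

    placement = {}
    skipped = set()
    for gene in set(df["query"]) | set(df["subject"]):
        chrom = chrom_of.get(gene)
        parsed = parse_chromosome(chrom) if chrom is not None else None
        if parsed is None:
            skipped.add(gene)
        else:
            placement[gene] = parsed
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) with unplaced/unparseable chromosome skipped",
            stacklevel=2,
        )

    retained: dict[str, set] = {}
    score: dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        if row.query in skipped or row.subject in skipped:
            continue
        retained.setdefault(row.query, set()).add(row.subject)
        pair = (row.query, row.subject)
        score[pair] = max(score.get(pair, 0.0), float(row.bitscore))

    def linked(a: str, b: str) -> bool:
        if mutual:
            return b in retained.get(a, ()) and a in retained.get(b, ())
        return b in retained.get(a, ()) or a in retained.get(b, ())

    # candidate triples: one gene per subgenome within one homoeologous group
    by_group: dict[int, dict[str, list]] = {}
    for gene, (group, sub) in placement.items():
        by_group.setdefault(group, {s: [] for s in SUBGENOMES})[sub].append(gene)

    candidates = []
    for group, buckets in by_group.items():
        for a in sorted(buckets["A"]):
            for b in sorted(buckets["B"]):
                if not linked(a, b):
                    continue
                for d in sorted(buckets["D"]):
                    if linked(a, d) and linked(b, d):
                        total = sum(
                            score.get(p, 0.0) + score.get((p[1], p[0]), 0.0)
                            for p in ((a, b), (a, d), (b, d))
                        )
                        candidates.append((total, (a, b, d), group))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    used: set[str] = set()
    out = []
    for _, (a, b, d), group in candidates:
        if used & {a, b, d}:
            continue
        used.update((a, b, d))
        out.append(HomeologTriplet(gene_A=a, gene_B=b, gene_D=d, group=group))
    return out


def balance_ratios(
    triplet: HomeologTriplet, expr: ExpressionMatrix, condition: tuple
) -> tuple | None:
    """Expression shares (rA, rB, rD) of a triplet in one condition.

    Replicate-mean expression of the three copies, normalized to sum to
    one.  Returns ``None`` when all three copies are silent (shares
    undefined).
    """
    variety, treatment = condition
    libs = expr.libraries_for(variety, treatment)
    if not libs:
        raise ValueError(f"no libraries for condition {condition}")
    missing = [g for g in triplet.genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"triplet gene(s) absent from matrix: {missing}")
    means = expr.values.loc[list(triplet.genes), libs].mean(axis=1).to_numpy()
    total = float(means.sum())
    if total == 0.0:
        return None
    return tuple(float(x) for x in means / total)


def classify_balance(
    ratios, dominant_threshold: float = 0.66, suppressed_threshold: float = 0.16
) -> str | None:
    """Classify an (rA, rB, rD) share triple into the seven balance classes.

    Dominance is checked first: any copy above the dominant threshold
    claims its dominant class.  Otherwise any copy below the suppressed
    threshold yields that copy's suppressed class (the smallest share wins
    if several qualify).  Thresholds are strict; exact boundary values
    fall through to ``balanced``.
    """
    if ratios is None:
        return None
    r = np.asarray(ratios, dtype=float)
    if r.shape != (3,) or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be three shares summing to 1")
    if (r > dominant_threshold).any():
        return f"{SUBGENOMES[int(np.argmax(r))]}-dominant"
    if (r < suppressed_threshold).any():
        return f"{SUBGENOMES[int(np.argmin(r))]}-suppressed"
    return "balanced"


def class_fractions(
    triplets: list[HomeologTriplet],
    expr: ExpressionMatrix,
    conditions: list[tuple],
    deg_genes=(),
) -> dict:
    """Balance-class fractions per condition, overall and for DEG triplets.

    Returns ``{"all": frame, "deg_subset": frame, "profiles": [...]}``
    where each frame is condition x class fractions over classifiable
    triplets.  The DEG subset keeps triplets with at least one member in
    ``deg_genes`` — the sets whose expression responds to stress.
    """
    deg_set = set(deg_genes)
    profiles: list[BalanceProfile] = []
    for trip in triplets:
        has_deg = bool(deg_set & set(trip.genes))
        for cond in conditions:
            ratios = balance_ratios(trip, expr, cond)
            profiles.append(
                BalanceProfile(
                    triplet=trip,
                    condition=tuple(cond),
                    ratios=ratios,
                    balance_class=classify_balance(ratios),
                    contains_deg=has_deg,
                )
            )

    def tally(profs) -> pd.DataFrame:
        rows = {}
        for cond in map(tuple, conditions):
            classified = [p for p in profs
                          if p.condition == cond and p.balance_class is not None]
            n = len(classified)
            counts = {c: 0 for c in BALANCE_CLASS_ORDER}
            for p in classified:
                counts[p.balance_class] += 1
            rows[cond] = {c: (counts[c] / n if n else float("nan"))
                          for c in BALANCE_CLASS_ORDER}
        return pd.DataFrame.from_dict(rows, orient="index")

    subset = [p for p in profiles if p.contains_deg]
    if deg_set and not subset:
        warnings.warn("no triplet contains a DEG; subset panel is empty", stacklevel=2)
    return {
        "all": tally(profiles),
        "deg_subset": tally(subset) if subset else pd.DataFrame(columns=BALANCE_CLASS_ORDER),
        "profiles": profiles,
    }
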