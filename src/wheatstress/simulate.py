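"""Synthetic study generator with planted ground truth.

Emulates the study design the pipeline targets: two bread-wheat varieties
(a stress-tolerant and a stress-susceptible cultivar) grown under control,
water-deficiency (wd) and short/long cold treatments, three biological
replicates per group, expression quantified by 3'-tag counting and
normalized per million reads.

Every downstream stage has a planted truth to recover:

* differentially expressed genes with known direction and fold change,
  optionally direction-consistent between the varieties, optionally with a
  forced wd-up / cold-down pattern;
* homeolog triplets (one gene per subgenome of one homoeologous group) with
  known A:B:D expression-share class;
* SNPs with known variety of origin, annotation category, QUAL tier,
  genotype class and chromosomal position.

Replicate noise is multiplicative log-normal with a chosen coefficient of
variation; tag counts are positive and right-skewed, which a log-normal
captures with two parameters.  The noise factor has unit mean, so at
``noise_cv = 0`` planted fold changes are realized exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._chrom import SUBGENOMES, parse_chromosome, wheat_chromosomes
from .io import (
    OUTFMT6_COLUMNS,
    ExpressionMatrix,
    HomologyHitTable,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "BALANCE_CLASSES",
    "generate_expression",
    "generate_hit_table",
    "generate_vcf",
    "rescale_to_counts",
]

#: the seven homeolog expression-balance classes
BALANCE_CLASSES = (
    "A-dominant",
    "B-dominant",
    "D-dominant",
    "A-suppressed",
    "B-suppressed",
    "D-suppressed",
    "balanced",
)

#: representative A:B:D expression shares, safely inside each class region
#: (dominant copy > 0.66, suppressed copy < 0.16, balanced away from both)
_CLASS_RATIOS = {
    "A-dominant": (0.80, 0.12, 0.08),
    "B-dominant": (0.12, 0.80, 0.08),
    "D-dominant": (0.08, 0.12, 0.80),
    "A-suppressed": (0.08, 0.46, 0.46),
    "B-suppressed": (0.46, 0.08, 0.46),
    "D-suppressed": (0.46, 0.46, 0.08),
    "balanced": (0.38, 0.34, 0.28),
}

#: default annotation-category mix: the categories and proportions a
#: transcriptome-derived SNP set typically shows (UTR, flanking, coding)
DEFAULT_SNP_CATEGORIES = {
    "3_prime_UTR_variant": 0.32,
    "downstream_gene_variant": 0.34,
    "synonymous_variant": 0.18,
    "intron_variant": 0.06,
    "missense_variant": 0.04,
    "upstream_gene_variant": 0.04,
    "5_prime_UTR_variant": 0.02,
}

#: default sharing structure between the two varieties: roughly a quarter
#: of the union is carried by both, the rest splits between them
DEFAULT_VARIETY_SET_MIX = {"v1": 0.34, "v2": 0.39, "both": 0.27}


def _default_chrom_lengths() -> dict[str, int]:
    # scaled-down wheat karyotype: 21 chromosomes, mildly varying lengths
    return {name: 8_000_000 + 200_000 * i for i, name in enumerate(wheat_chromosomes())}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Expression defaults mirror the emulated design: 2 varieties x
    4 treatments (control, wd, cold6, cold24) x 3 replicates.  Planted
    fold changes default to 3-8x so that every planted gene clears the
    2-fold calling threshold by a margin.
    """

    n_genes: int = 2000
    varieties: tuple[str, ...] = ("YP", "S29")
    treatments: tuple[str, ...] = ("control", "wd", "cold6", "cold24")
    n_replicates: int = 3
    deg_fraction: float = 0.0
    fc_range: tuple[float, float] = (3.0, 8.0)
    consistent_fraction: float = 0.5
    n_pattern_genes: int = 0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2
    noise_cv: float = 0.1
    variety_effect_sd: float = 0.2
    n_triplets: int = 0
    balance_class_mix: tuple[float, ...] = (0.08, 0.08, 0.08, 0.08, 0.08, 0.08, 0.52)
    n_snps: int = 0
    snp_category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SNP_CATEGORIES)
    )
    snp_variety_set_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIETY_SET_MIX)
    )
    qual_above_fraction: float = 0.6
    hom_alt_fraction: float = 0.97
    telomere_bias: float = 0.0
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    library_total_range: tuple[float, float] = (5e6, 9e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if len(self.varieties) < 1 or len(self.treatments) < 2:
            raise ConfigurationError("need >=1 variety and >=2 treatments")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        for name in ("deg_fraction", "consistent_fraction", "qual_above_fraction",
                     "hom_alt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.fc_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("fc_range must satisfy 1 <= low <= high")
        if lo <= 2:
            warnings.warn(
                "fc_range low <= 2: planted fold changes may fall below the "
                "2-fold calling threshold",
                stacklevel=2,
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be nonnegative")
        if self.variety_effect_sd < 0:
            raise ConfigurationError("variety_effect_sd must be nonnegative")
        if len(self.balance_class_mix) != len(BALANCE_CLASSES):
            raise ConfigurationError("balance_class_mix needs 7 proportions")
        if any(p < 0 for p in self.balance_class_mix):
            raise ConfigurationError("balance_class_mix proportions must be >= 0")
        if abs(sum(self.balance_class_mix) - 1.0) > 1e-9:
            raise ConfigurationError("balance_class_mix must sum to 1")
        if self.n_triplets < 0 or 3 * self.n_triplets > self.n_genes:
            raise ConfigurationError("need n_triplets >= 0 and 3*n_triplets <= n_genes")
        if self.n_snps < 0:
            raise ConfigurationError("n_snps must be nonnegative")
        if self.n_snps and not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must be nonempty to plant SNPs")
        for name in self.chrom_lengths:
            if name != "Un" and parse_chromosome(name) is None:
                raise ConfigurationError(f"unparseable chromosome name: {name!r}")
        for mix_name in ("snp_category_mix", "snp_variety_set_mix"):
            mix = getattr(self, mix_name)
            if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{mix_name} must be nonnegative and sum to 1")

    @property
    def stress_treatments(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if t != self.treatments[0])

    def library_ids(self) -> list[str]:
        return [
            f"{v}_{t}_R{r}"
            for v in self.varieties
            for t in self.treatments
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``deg_flags`` / ``planted_fc`` map (gene, variety, treatment) to the
    planted direction ('up'/'down') and the realized stress:control ratio
    (down-regulated genes carry a ratio below 1).
    """

    deg_flags: dict = field(default_factory=dict)
    planted_fc: dict = field(default_factory=dict)
    deg_genes: list = field(default_factory=list)
    consistent_genes: list = field(default_factory=list)
    pattern_genes: list = field(default_factory=list)
    triplets: list = field(default_factory=list)  # (gene_A, gene_B, gene_D)
    triplet_classes: dict = field(default_factory=dict)  # triplet idx -> class
    triplet_ratios: dict = field(default_factory=dict)  # triplet idx -> (rA, rB, rD)
    gene_chrom: dict = field(default_factory=dict)
    snp_table: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "deg_flags": {"|".join(k): v for k, v in self.deg_flags.items()},
            "planted_fc": {"|".join(k): v for k, v in self.planted_fc.items()},
            "deg_genes": self.deg_genes,
            "consistent_genes": self.consistent_genes,
            "pattern_genes": self.pattern_genes,
            "triplets": self.triplets,
            "triplet_classes": self.triplet_classes,
            "triplet_ratios": self.triplet_ratios,
            "gene_chrom": self.gene_chrom,
            "snp_table": None
            if self.snp_table is None
            else self.snp_table.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _assign_gene_names(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[str], dict]:
    """Gene ids with the chromosome embedded (e.g. 'G00012-2A').

    The first ``3 * n_triplets`` genes form homeolog triplets: members of
    triplet *k* sit on the A, B and D chromosomes of one homoeologous
    group.
    """
    placeable = [c for c in config.chrom_lengths if parse_chromosome(c) is not None]
    if not placeable:
        placeable = wheat_chromosomes()
    groups = sorted({parse_chromosome(c)[0] for c in placeable})
    names: list[str] = []
    chrom_of: dict[str, str] = {}
    idx = 0
    for k in range(config.n_triplets):
        group = groups[k % len(groups)]
        for sub in SUBGENOMES:
            chrom = f"{group}{sub}"
            name = f"G{idx:05d}-{chrom}"
            names.append(name)
            chrom_of[name] = chrom
            idx += 1
    remaining = config.n_genes - idx
    chroms = rng.choice(placeable, size=remaining)
    for chrom in chroms:
        name = f"G{idx:05d}-{chrom}"
        names.append(name)
        chrom_of[name] = str(chrom)
        idx += 1
    return names, chrom_of


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a per-million-scale expression matrix with planted truth.

    Each replicate value is ``baseline x fold_change x noise`` where the
    fold change applies only to planted (gene, variety, stress-treatment)
    combinations; control groups are never perturbed.  Exactly
    ``round(deg_fraction * n_genes)`` genes carry at least one planted
    flag.  The first ``consistent_fraction`` of those share direction and
    fold change between the varieties for every treatment, and the first
    ``n_pattern_genes`` of the consistent ones are forced to the
    wd-up / cold-down pattern.

    Returns a matrix flagged ``normalized=True``: values are per-million-
    scale abundances.  Use :func:`rescale_to_counts` to derive a raw count
    matrix with varying library totals.
    """
    rng = np.random.default_rng(config.seed)
    genes, chrom_of = _assign_gene_names(config, rng)
    truth = PlantedTruth(gene_chrom=chrom_of)

    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    # triplet members share a group total split by their planted A:B:D ratio
    if config.n_triplets:
        classes = rng.choice(
            len(BALANCE_CLASSES), size=config.n_triplets, p=list(config.balance_class_mix)
        )
        for k in range(config.n_triplets):
            cls = BALANCE_CLASSES[classes[k]]
            ratios = _CLASS_RATIOS[cls]
            total = baseline[3 * k] * 3.0
            for j in range(3):
                baseline[3 * k + j] = total * ratios[j]
            members = tuple(genes[3 * k : 3 * k + 3])
            truth.triplets.append(members)
            truth.triplet_classes[k] = cls
            truth.triplet_ratios[k] = tuple(ratios)

    # --- plant DEGs among non-triplet genes ---
    n_deg = int(round(config.deg_fraction * config.n_genes))
    free = genes[3 * config.n_triplets :]
    if n_deg > len(free):
        raise ConfigurationError(
            "deg_fraction too high: not enough genes outside planted triplets"
        )
    deg_genes = list(rng.choice(free, size=n_deg, replace=False))
    n_consistent = int(np.ceil(config.consistent_fraction * n_deg))
    if config.n_pattern_genes > n_consistent:
        raise ConfigurationError("n_pattern_genes exceeds the consistent gene count")
    stress = config.stress_treatments
    # forced pattern: up under water deficiency, down under the other
    # stresses (the first stress plays the wd role if none is named "wd")
    wd_like = "wd" if "wd" in stress else stress[0]
    lo, hi = config.fc_range
    for i, gene in enumerate(deg_genes):
        consistent = i < n_consistent
        patterned = consistent and i < config.n_pattern_genes
        if consistent:
            # one direction and magnitude per treatment, shared by varieties
            dirs = {t: ("up" if rng.random() < 0.5 else "down") for t in stress}
            if patterned:
                dirs = {t: ("up" if t == wd_like else "down") for t in stress}
            mags = {t: rng.uniform(lo, hi) for t in stress}
            for v in config.varieties:
                for t in stress:
                    fc = mags[t] if dirs[t] == "up" else 1.0 / mags[t]
                    truth.deg_flags[(gene, v, t)] = dirs[t]
                    truth.planted_fc[(gene, v, t)] = fc
        else:
            # non-consistent genes respond in a random subset of
            # (variety, treatment) combinations — at least one — so the
            # two cultivars' DEG lists overlap only partially
            combos = [(v, t) for v in config.varieties for t in stress]
            while True:
                chosen = [c for c in combos if rng.random() < 0.5]
                if chosen:
                    break
            for v, t in chosen:
                d = "up" if rng.random() < 0.5 else "down"
                mag = rng.uniform(lo, hi)
                fc = mag if d == "up" else 1.0 / mag
                truth.deg_flags[(gene, v, t)] = d
                truth.planted_fc[(gene, v, t)] = fc
    truth.deg_genes = deg_genes
    truth.consistent_genes = deg_genes[:n_consistent]
    # the pattern set records every gene whose planted directions realize
    # wd-up / otherwise-down in both varieties, forced or incidental
    pattern = {t: ("up" if t == wd_like else "down") for t in stress}
    truth.pattern_genes = [
        g for g in deg_genes
        if all(
            truth.deg_flags.get((g, v, t)) == want
            for v in config.varieties
            for t, want in pattern.items()
        )
    ]

    # --- assemble the matrix ---
    # per-gene multiplicative variety factors give the cultivars distinct
    # baseline transcriptomes; they cancel in within-variety fold changes
    # and are not applied to triplet members (they would skew A:B:D shares)
    variety_factor = {config.varieties[0]: np.ones(config.n_genes)}
    for v in config.varieties[1:]:
        f = np.ones(config.n_genes)
        if config.variety_effect_sd > 0:
            f[3 * config.n_triplets :] = rng.lognormal(
                0.0, config.variety_effect_sd, size=config.n_genes - 3 * config.n_triplets
            )
        variety_factor[v] = f

    gene_pos = {g: i for i, g in enumerate(genes)}
    columns = {}
    for v in config.varieties:
        for t in config.treatments:
            mean = baseline * variety_factor[v]
            for (gene, gv, gt), fc in truth.planted_fc.items():
                if gv == v and gt == t:
                    mean[gene_pos[gene]] *= fc
            for r in range(1, config.n_replicates + 1):
                noise = _lognormal_noise(rng, config.noise_cv, config.n_genes)
                columns[f"{v}_{t}_R{r}"] = mean * noise
    values = pd.DataFrame(columns, index=genes)
    design = pd.DataFrame(
        [
            (f"{v}_{t}_R{r}", v, t, r)
            for v in config.varieties
            for t in config.treatments
            for r in range(1, config.n_replicates + 1)
        ],
        columns=["library", "variety", "treatment", "replicate"],
    ).set_index("library")
    expr = ExpressionMatrix(values=values, design=design, normalized=True)
    return expr, truth


def rescale_to_counts(
    expr: ExpressionMatrix, config: SimulationConfig, seed: int | None = None
) -> ExpressionMatrix:
    """Rescale a per-million-scale matrix to raw pseudo-counts.

    Library totals are drawn uniformly from ``config.library_total_range``
    so the per-million normalization downstream is exercised nontrivially.
    Values stay fractional (pseudo-counts); rounding would distort small
    planted fold changes.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    lo, hi = config.library_total_range
    totals = rng.uniform(lo, hi, size=len(expr.libraries))
    sums = expr.values.sum(axis=0)
    values = expr.values * (totals / sums.to_numpy())
    return ExpressionMatrix(values=values, design=expr.design.copy(), normalized=False)


# ---------------------------------------------------------------------------
# Homology hit table


def generate_hit_table(config: SimulationConfig, truth: PlantedTruth) -> HomologyHitTable:
    """Emit an outfmt-6-style hit table encoding the planted triplets.

    Every planted triplet contributes all six ordered cross-hits at
    qualifying identity (> 0.6) and e-value (< 1e-4).  Decoy hits that fail
    each threshold, plus low-rank paralog hits, are added for negative
    testing.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []

    def hit(q, s, identity, evalue, bitscore):
        length = int(rng.integers(200, 500))
        rows.append(
            (q, s, identity * 100.0, length, int(length * (1 - identity)), 0,
             1, length, 1, length, evalue, bitscore)
        )

    for a, b, d in truth.triplets:
        for q, s in ((a, b), (a, d), (b, a), (b, d), (d, a), (d, b)):
            hit(q, s, rng.uniform(0.75, 0.98), 10.0 ** rng.uniform(-180, -20),
                float(rng.uniform(300, 900)))

    # decoys: sub-threshold identity, sub-threshold e-value, and extra-rank
    # paralog hits chained onto triplet members
    free = [g for g in truth.gene_chrom if all(g not in t for t in truth.triplets)]
    n_decoys = max(4, len(truth.triplets))
    for _ in range(n_decoys):
        if len(free) >= 2:
            q, s = rng.choice(free, size=2, replace=False)
            hit(str(q), str(s), rng.uniform(0.30, 0.55), 1e-30, 200.0)  # low identity
            hit(str(s), str(q), rng.uniform(0.70, 0.90), 1e-2, 60.0)  # weak e-value
    for a, b, d in truth.triplets[: min(3, len(truth.triplets))]:
        if free:
            extra = str(rng.choice(free))
            # rank-4 hit: beyond the target=3 cut once the triplet hits rank 1-3
            hit(a, extra, 0.70, 1e-10, 150.0)

    df = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    df["identity"] = df["identity"] / 100.0
    # order hits per query by bitscore, mirroring similarity-search output
    df = (
        df.sort_values(["query", "bitscore"], ascending=[True, False], kind="stable")
        .reset_index(drop=True)
    )
    return HomologyHitTable(hits=df)


# ---------------------------------------------------------------------------
# VCF


def _draw_positions(
    rng: np.random.Generator, length: int, n: int, telomere_bias: float
) -> np.ndarray:
    """Distinct 1-based positions; bias > 0 enriches chromosome ends."""
    out: set[int] = set()
    while len(out) < n:
        m = n - len(out)
        u = rng.random(m)
        tel = rng.beta(0.3, 0.3, size=m)
        frac = np.where(rng.random(m) < telomere_bias, tel, u)
        pos = np.minimum((frac * length).astype(int) + 1, length)
        out.update(int(p) for p in pos)
    return np.array(sorted(out)[:n])


def generate_vcf(config: SimulationConfig, path) -> PlantedTruth:
    """Write a two-sample VCF with planted per-SNP truth.

    QUAL values straddle the conventional reliability threshold of 30
    (``qual_above_fraction`` of sites strictly above, the rest strictly
    below), genotypes are homozygous-alternate with probability
    ``hom_alt_fraction`` (heterozygous otherwise) in each carrying variety,
    and each site carries a single-effect ANN annotation drawn from
    ``snp_category_mix``.  Returns the truth with a ``snp_table``
    DataFrame: chrom, pos, qual_tier, category, variety set and per-variety
    genotype class.
    """
    rng = np.random.default_rng(config.seed + 3)
    if len(config.varieties) < 2:
        raise ConfigurationError("VCF generation needs two varieties")
    v1, v2 = config.varieties[0], config.varieties[1]
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)

    n = config.n_snps
    counts = rng.multinomial(n, lengths / lengths.sum()) if n else np.zeros(len(chroms), int)
    cats = list(config.snp_category_mix)
    cat_p = np.array([config.snp_category_mix[c] for c in cats])
    set_labels = ["v1", "v2", "both"]
    set_p = np.array([config.snp_variety_set_mix.get(k, 0.0) for k in set_labels])
    set_p = set_p / set_p.sum() if set_p.sum() else np.array([0.5, 0.5, 0.0])

    rows = []
    for ci, chrom in enumerate(chroms):
        m = int(counts[ci])
        if m == 0:
            continue
        positions = _draw_positions(
            rng, int(config.chrom_lengths[chrom]), m, config.telomere_bias
        )
        for pos in positions:
            above = rng.random() < config.qual_above_fraction
            qual = rng.uniform(31.0, 200.0) if above else rng.uniform(1.0, 29.5)
            category = cats[rng.choice(len(cats), p=cat_p)]
            which = set_labels[rng.choice(3, p=set_p)]
            carriers = {"v1": (v1,), "v2": (v2,), "both": (v1, v2)}[which]
            gts = {}
            for v in (v1, v2):
                if v in carriers:
                    hom = rng.random() < config.hom_alt_fraction
                    gts[v] = "1/1" if hom else "0/1"
                else:
                    gts[v] = "0/0"
            ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            rows.append(
                (chrom, int(pos), str(ref), str(alt), float(qual),
                 "above" if above else "below", category, which, gts[v1], gts[v2])
            )

    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "qual_tier", "category",
                 "variety_set", f"gt_{v1}", f"gt_{v2}"],
    )
    if len(table):
        table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={config.chrom_lengths[chrom]}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{v1}\t{v2}\n")
        for r in table.itertuples(index=False):
            ann = f"ANN={r.alt}|{r.category}|MODIFIER|gene|gene|transcript|tx|||||"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\t.\t{ann}\tGT\t"
                f"{getattr(r, f'gt_{v1}')}\t{getattr(r, f'gt_{v2}')}\n"
            )

    truth = PlantedTruth(snp_table=table)
    return truth
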