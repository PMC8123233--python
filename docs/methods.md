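# Methods

`wheatstress` implements the post-quantification stages of a comparative
stress-transcriptomics analysis for allohexaploid bread wheat
(*Triticum aestivum*): two cultivars of contrasting stress tolerance,
four growth conditions (control, water deficiency, 6 h cold, 24 h cold),
three biological replicates per group, expression quantified by 3′-tag
counting.  This note records the models, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not demonstrate.

## Normalization

Values are scaled per million counted reads per library
(`normalize_per_million`).  A 3′-tag protocol produces one tag per
transcript regardless of transcript length, so the length term of
FPKM-style normalization is deliberately absent; what remains is
counts-per-million.  The operation is guarded against double application
and errors on all-zero libraries.  Multiplying a library's raw counts by a
constant leaves its normalized values unchanged, which is what makes the
downstream statistics invariant to sequencing depth.

## Replicate QC

Pearson correlation and PCA both operate on `log2(x + 1)`; tag-count
distributions are heavy-tailed and a handful of very highly expressed
genes would otherwise dominate both statistics.  Libraries are clustered
by average linkage on the distance `1 − r`.  PCA centers genes but does
not scale them to unit variance, preserving high-expression structure
(the regime in which a first component can carry more than half of the
variance).  In the emulated design, control replicates form a tight
cluster while stress libraries spread along the leading components.

## Staged DEG calling

A gene is called differentially expressed for a (variety, treatment) pair
when it survives three stages applied in order:

1. **Expression floor** — replicate-mean expression ≥ 0.5 per-million
   units in at least one experimental point (variety × treatment).  The
   stricter reading — require the floor in *every* point — is available
   as `require_all=True`.
2. **Fold-change gate** — stress:control ratio of replicate means
   strictly above 2 or strictly below 1/2 ("more than doubled").  A
   pseudocount (default 0.01, configurable) keeps ratios finite for genes
   silent in one condition.
3. **Welch t-test with Benjamini–Yekutieli correction** — two-sided
   Welch t-test on `log2(x + 1)` replicate values; adjusted p ≤ q
   (default 0.05) declares significance.

Welch's unpooled-variance form is used because with three replicates
variance equality cannot be assessed, and the log transform brings
multiplicative replicate noise close to the additive-normal regime a
t-test assumes.  The BY step-up — adjusted(i) = min over j ≥ rank(i) of
`p(j)·m·H(m)/j`, capped at 1 — controls the FDR under arbitrary
dependence, which matters for the strongly co-regulated genes of a stress
response; it is verified in the tests against both a brute-force
enumeration and statsmodels.

The family of tests the correction sees is the set of (gene, treatment)
pairs passing the fold-change gate, corrected **per variety** (the two
cultivars' responses are treated as independent families); a
`per_treatment` switch corrects each (variety, treatment) family
separately instead.  Degenerate zero-variance comparisons resolve by mean
equality (p = 1 when equal, p = 0 otherwise).  The control group is found
by treatment name ("control" when present), so results do not depend on
column order.

Venn percentages for DEG-list sharing are reported relative to the union,
to one decimal, rounded half-up.  QTL intersection assigns each gene its
interval membership by midpoint against 0-based half-open regions.

## Six-class tuples and the core set

Each fold change is binned into six exclusive classes with boundaries at
1/2, 1/band, band, 2 and 5 (band = the "almost unchanged" half-width,
default 1.25×, i.e. |log2 fc| ≲ 0.32; no published value exists, so it is
a parameter).  As printed, the class descriptions overlap (">5×" implies
">2×"); the exclusive bins preserve the intended ordering while
partitioning (0, ∞) — a property test checks totality for every band in
(1, 2).  Over the ordered six-condition axis (two varieties × three
stress treatments) a gene receives a class tuple; 6⁶ = 46,656 are
possible.  Classification defaults to the significant-DEG set.

Core genes are members of the top-populated tuples (default 20; ties
broken lexicographically) whose per-treatment direction category (down =
classes i–ii, unchanged = iii, up = iv–vi) is identical between the
varieties.  Requiring identical *classes* rather than directions is a
stricter documented option.  `select_pattern` filters on an explicit
direction signature (e.g. wd-up / cold-down), and
`cross_dataset_concordance` scores direction agreement against an
external fold-change table, reporting uncovered genes separately.

## Homeolog balance

Triplets are assembled from a similarity hit table filtered at
e-value < 1e-4, identity > 0.6 and rank ≤ 3 per query.  Three genes on
the A, B and D chromosomes of one homoeologous group form a triplet when
every pair is **mutually** retained (one-directional linking is a flag);
the mutual requirement stops promiscuous paralogs from chaining unrelated
genes.  Competing candidates are resolved greedily by total bitscore,
then lexicographic gene id; a gene joins at most one triplet.  Genes on
unplaced scaffolds ("Un") are excluded.

Per condition, the triplet's expression shares are the replicate means
normalized to sum to one.  Classification follows a fixed order:
any share > 0.66 → that copy's *dominant* class; else any share < 0.16 →
that copy's *suppressed* class (smallest share wins); else *balanced*.
Dominance is deliberately checked first — (0.70, 0.25, 0.05) is
A-dominant, not D-suppressed — and both thresholds are strict, so exact
boundary values fall to balanced.  Shares are scale-invariant, hence so
is the class.  Fractions are reported per condition for all classifiable
triplets and for the subset containing at least one DEG.

## SNP summaries

Records are per (site, sample): each VCF sample column is one variety.
Sites with QUAL strictly above 30 count as reliable; the homozygous-
alternate subset is selected per variety from the GT field alone.  Only
the first ALT of multi-allelic sites is considered (warned).  Site
identity for sharing is (chromosome, 1-based position, alternate allele);
a position-only mode exists because allele-aware matching is a choice,
not a given.  Summaries: per-chromosome counts and per-Mb densities, a
position histogram over `pos/length` in 100 equal bins summed over
chromosomes (the "averaged chromosome"), single-label annotation-category
shares (first ANN effect term), and a three-leaf average-linkage
dendrogram in which a variety's distance to the reference is its site
count and the inter-variety distance is the symmetric-difference size.

## Synthetic study generator

The generator plants ground truth at the emulated design: 2 varieties ×
4 treatments × 3 replicates.  Each replicate value is
`baseline × fold-change × noise`:

* **Baseline** per gene: log-normal with `baseline_log_mean = 3`,
  `baseline_log_sd = 1.2` — a right-skewed abundance distribution
  spanning ~4 orders of magnitude, as tag counts do.
* **Replicate noise**: multiplicative log-normal with unit mean and a
  chosen coefficient of variation (`noise_cv`, default 0.1 ≈ tight
  greenhouse replicates whose pairwise correlations land in the
  0.96–0.99 range).  At `noise_cv = 0` planted effects are realized
  exactly, which the zero-noise recovery tests exploit.
* **Variety effect** (`variety_effect_sd = 0.2`): per-gene multiplicative
  factors distinguishing the cultivars' baseline transcriptomes.  They
  cancel in within-variety fold changes and are not applied to triplet
  members (they would skew planted A:B:D shares).
* **DEGs**: exactly `round(deg_fraction × n_genes)` genes, fold changes
  uniform in `fc_range` (default 3–8×, clearing the 2× gate with margin),
  direction random.  A configurable fraction responds identically in both
  varieties; the first `n_pattern_genes` of those are forced to
  wd-up / cold-down.  The remaining DEGs respond in a random nonempty
  subset of (variety, treatment) combinations, so the two cultivars' DEG
  lists overlap only partially.  The truth records as "pattern genes"
  every gene whose planted directions realize the signature, forced or
  incidental.
* **Triplets**: the first `3 × n_triplets` genes, one per subgenome of a
  homoeologous group, share a group total split by a class-representative
  share triple drawn from `balance_class_mix` (default mix is
  balanced-majority).  Representative shares sit safely inside their
  class regions so zero-noise classification is exact.  Triplet members
  are excluded from DEG planting to keep shares condition-invariant.
* **SNPs**: multinomial over chromosomes by length; QUAL straddles 30
  (`qual_above_fraction`), genotypes are hom-alt with probability 0.97
  (het otherwise) in each carrying variety, categories follow
  `snp_category_mix` (default: 3′-UTR 32%, downstream 34%, synonymous
  18%, intron 6%, missense 4%, upstream 4%, 5′-UTR 2%), and the
  variety-set mix defaults to ~27% shared.  `telomere_bias` mixes in a
  U-shaped Beta(0.3, 0.3) position component to emulate telomeric
  enrichment; 0 means uniform.
* Chromosome lengths default to a scaled-down 21-chromosome karyotype
  (~8 Mb each) so position-resolution tests stay cheap.

`generate_expression` returns the matrix on the per-million scale;
`rescale_to_counts` converts it to raw pseudo-counts with library totals
drawn uniformly (default 5–9 million), so the normalization step is
exercised nontrivially.  Totals are left fractional — rounding would
perturb small planted fold changes.

**What passing these benchmarks shows — and does not.** The generator
emulates multiplicative noise, planted monotone effects and clean
triplet/SNP structure.  It does not model count discreteness or
overdispersion families, 3′-bias, mapping ambiguity between close
homeologs, or linkage between SNPs.  Recovery results therefore validate
the algorithmic correctness and calibration of the pipeline under its own
assumptions, not its power on any particular real dataset.

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script run at desk scale: 2,000-gene
studies (three seeds) for sensitivity, 5,000 genes × 10–20 seeds for the
null false-positive rate, 500 triplets for homeolog recovery, and
2,000–5,000 planted SNPs.  These sizes give binomial standard errors well
below the asserted margins while keeping a full run under a minute.

## Known limitations

* The t-test with n = 3 has limited power for fold changes near the gate;
  the pipeline reproduces the published procedure rather than a
  negative-binomial GLM, which would be the modern choice.
* Published headline lists (e.g. the 2,159 DEGs or the 21,443 triplets)
  derive from the original sequencing libraries and full proteome and are
  not reproducible from synthetic data; only the arithmetic printed
  alongside them is recomputed.
* The "almost unchanged" band and the pseudocount have no published
  values; results near class boundaries depend on them, and both are
  exposed as parameters.
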