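# wheatstress

Comparative stress-transcriptomics toolkit for allohexaploid bread wheat
(*Triticum aestivum*).  It implements the post-quantification stages of a
two-cultivar stress study — control, water deficiency (WD) and short/long
cold treatments with three biological replicates — starting from a
gene × library count table:

* **Normalization** — counts per million per library (no gene-length
  term: 3′-tag protocols produce one tag per transcript).
* **Replicate QC** — Pearson correlation of libraries on log2(x+1) with
  average-linkage clustering, and PCA variance decomposition.
* **Staged DEG calling** — expression floor (≥ 0.5 CPM in at least one
  experimental point), fold-change gate (FC > 2 or < 1/2), Welch t-test
  on log2(x+1) with Benjamini–Yekutieli FDR control (q = 0.05) applied
  per variety; Venn arithmetic between cultivar DEG lists and
  QTL-interval intersection.
* **Six-class tuple profiling** — each fold change binned into classes
  (i) FC ≤ 1/2, (ii) 1/2 < FC < 1/band, (iii) 1/band ≤ FC ≤ band,
  (iv) band < FC < 2, (v) 2 ≤ FC ≤ 5, (vi) FC > 5 over the six
  (variety, treatment) conditions (6⁶ = 46,656 possible tuples);
  top-populated-tuple selection; extraction of the core set of genes
  responding in the same direction in both cultivars; direction
  concordance against external datasets.
* **Homeolog balance** — assembly of A/B/D subgenome triplets from a
  BLAST-tabular hit table (e-value < 1e-4, identity > 0.6, top 3, mutual
  hits) and per-condition classification of expression shares into seven
  classes: X-dominant (share > 66%), X-suppressed (share < 16%), or
  balanced.
* **SNP summaries** — QUAL > 30 filtering, homozygous-alternate
  selection per cultivar, site sharing, per-chromosome/per-Mb densities,
  averaged-chromosome position profiles, annotation-category shares and
  a cultivar–reference distance dendrogram.
* **Synthetic study generator** — expression matrices, hit tables and
  annotated VCFs with planted ground truth (DEGs with known fold
  changes, triplets with known balance classes, SNPs with known origin),
  so every stage is testable without downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic study (1,000 genes, 10% planted DEGs, 50 homeolog
triplets, 2,000 SNPs) and run the pipeline:

```sh
wheatstress simulate --n-genes 1000 --deg-fraction 0.1 --n-triplets 50 \
    --n-snps 2000 --noise-cv 0.08 --seed 42 --out study
wheatstress deg --matrix study/matrix.tsv --design study/design.tsv --out degs.tsv
```

prints the stage counts and the cultivar Venn summary:

```json
{
  "genes_past_floor": 1000,
  "tests_past_fc_gate": 456,
  "significant_rows": 456,
  "significant_genes": 100,
  "variety_overlap": {
    "YP": 97, "S29": 96, "shared": 93, "union": 100,
    "shared_pct_of_union": 93.0
  }
}
```

All 100 planted DEGs (and nothing else) are recovered: 456 (gene,
variety, treatment) combinations pass the fold-change gate and all
survive the BY-adjusted t-test; 93 genes respond in both cultivars
because half of the planted genes were made variety-consistent and most
of the rest hit both cultivars in some treatment.  Continue with tuple
classification, homeolog balance and the SNP summary:

```sh
wheatstress classes --deg-table degs.tsv --out classes.json
wheatstress homeologs --hits study/hits.tsv --matrix study/matrix.tsv \
    --design study/design.tsv --deg-table degs.tsv --out triplets.tsv
wheatstress snps --vcf study/variants.vcf --out snps.json
```

`classes.json` reports 76 populated tuples out of 46,656 and a 39-gene
core set (planted variety-consistent genes that were called significant
and landed in the 20 most populated tuples); `triplets.tsv` carries all 50 planted triplets with their
per-condition shares and balance classes; `snps.json` ends with the
three-leaf dendrogram, e.g.

```
(S29:825,(YP:696,reference:696):129);
```

meaning 1,485 reliable hom-alt records collapsed to 696 YP and 789 S29
sites of which 312 (26.6% of the union) are shared.

The same functionality is available as a library
(`wheatstress.call_degs`, `wheatstress.build_tuples`,
`wheatstress.assemble_triplets`, ...), which is what the CLI wraps.

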