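# orstrat

Phylostratigraphy, tandem-array detection and tissue-enrichment set logic
for insect odorant-receptor (OR) repertoires.

Ants recognize nestmates by detecting cuticular hydrocarbons with odorant
receptors expressed in the antennae; in ants the OR family is massively
expanded, and a distinctive nine-exon OR subfamily is the prime candidate
for nestmate-recognition signalling. Narrowing hundreds of ORs down to a
testable candidate list combines three analyses, and this package
implements all three as a reusable, tested pipeline:

1. **Node-distance phylostratigraphy.** Each protein of a focal proteome is
   compared against reference proteomes (e-value threshold 1e-5; one best
   hit per species, ranked by lowest e-value). Its age is the *node
   distance* of the most distant species with a retained hit — the number
   of internal nodes on the species-tree path between the focal tip and
   that species' tip (sister species = 1, self = 0). Proteins with no hit
   outside the focal species are *taxonomically restricted proteins*
   (TRPs). Category-vs-category age distributions are compared with a
   Pearson chi-squared test, Benjamini–Hochberg adjusted across the
   comparisons of a run.
2. **Tandem-array detection.** Annotated genes are partitioned by
   (scaffold, strand), sorted by start, and chained into arrays whenever
   the gap `start(next) − end(previous)` is strictly below 20 kbp.
   Array-size histograms and a chi-squared test of category composition
   across array sizes summarize the result.
3. **Tissue-enrichment set logic.** Raw transcript counts are pruned of
   genes detected in at most one sample; a gene is *upregulated in the
   focal tissue* when `log2FC > 0` and `padj < .05` in **every**
   focal-vs-other comparison, and *expression restricted* when its raw
   count stays below 10 in every sample of every other tissue. Exclusive
   (upset-style) intersection counts and two-sided Fisher exact
   enrichment tests summarize the sets. Differential-expression tables
   from an external fit are consumed as first-class input; a built-in
   negative-binomial Wald test lets synthetic end-to-end runs proceed
   without one.

A synthetic-data module generates every input with recorded ground truth
(planted gene ages, planted arrays, planted upregulated genes), so the
whole pipeline is testable with no downloads.

## Worked example

Run the full synthetic pipeline with a fixed seed:

```sh
orstrat run --seed 11 --out run11
```

which prints:

```
config 3d7f3f7858f1, seed 11
upregulated vs all tissues: 120/1980, 6.0%
expression-restricted: 20/1980, 1.0%
OR enrichment in upregulated set: p = 6.67e-196
taxonomically restricted proteins: 6/50, 12.0%
tandem arrays: 30 over 60 genes
recovery stratum_recovery: 1.0
recovery trp_set_exact: True
recovery arrays_exact: True
recovery upregulated_recall: 1.0
recovery upregulated_false_inclusions: 0
recovery restricted_recall: 1.0
```

Reading the output: of the 1980 genes surviving the single-sample prune,
120 (6.0%) are upregulated in the antennae against every other tissue and
20 (1.0%) are expression-restricted to the antennae; the planted OR-like
genes are overwhelmingly enriched in the upregulated set (Fisher p ≈
7e-196); 6 of 50 simulated proteins are taxonomically restricted; and the
60 simulated OR genes fall into 30 tandem arrays. The `recovery` lines
compare every stage's output against the generator's planted truth —
stratum assignments, the TRP set and the array partition are recovered
exactly, and all planted upregulated genes are found with no false
inclusions.

Per-stage commands (`orstrat simulate / phylostrat / arrays / express`)
operate on standard files: Newick trees, FASTA proteomes, 12-column BLAST
tabular hits, GFF3 annotations and TSV count matrices. `orstrat run`
accepts a YAML config whose keys mirror `PipelineConfig` (seed,
e-value thresholds, `max_gap_bp`, `alpha_padj`, stage list, input paths);
every output is stamped with the config hash so reruns are byte-identical.

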