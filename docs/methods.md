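# Methods

This note records the models, conventions and numerical choices behind
`orstrat`, in the order the pipeline runs.

## Similarity search and e-values

The phylostratigraphy stage is agnostic about where its hits come from:
externally computed 12-column BLAST tabular files and the built-in search
produce the same `HitTable` and follow identical code paths downstream.
The built-in search exists so synthetic runs need no external aligner; it
scores all query × subject pairs with Smith–Waterman local alignment under
affine gaps (a gap of length L costs `gap_open + gap_extend·L`, defaults
11 + 1·L, BLOSUM62) and converts scores to expect values with the
Karlin–Altschul form `E = K·m·n·exp(−λS)` using the fixed gapped-BLOSUM62
convention constants K = 0.041, λ = 0.267 (m = query length, n = summed
subject length). These constants are a deliberate simplification:
determinism matters downstream, fidelity to any particular BLAST build
does not, because only threshold crossing (E ≤ 1e-5 by default) feeds the
analysis. Composition-based statistics, masking and word seeding are
intentionally absent — synthetic panels are small enough for exact DP.

Best-hit reduction keeps one record per (query, species): minimal e-value,
ties broken by higher bitscore, then lexicographic subject id (the tie
rule is a determinism choice; ties are measure-zero in real data). An
alternative ranking by percent identity (`rank_by="pident"`) covers the
receptor-to-reference association use case, which gates at E < 1e-40 but
ranks by identity.

## Node-distance phylostratigraphy

The age metric is a pure topology count: the number of internal nodes on
the tip-to-tip path between the focal species and the hit species, MRCA
included, tips excluded. This makes sister species distance 1, the focal
species distance 0 from itself, and the count strictly increasing with
divergence; multifurcations need no special handling. A protein's stratum
is the maximum distance over species with retained hits; focal-species
self-hits are excluded, otherwise every protein would trivially hit
itself and no protein could be taxonomically restricted. The max over
species is unchanged whether it is taken before or after best-hit
reduction.

Stratum-enrichment comparisons use the uncorrected Pearson chi-squared
statistic on the 2 × k (category × stratum-bin) table. Strata may be
binned into clade-style labels (configuration, never hard-coded; the raw
integer table is always retained) because raw integer strata at small
sample sizes produce expected cells below 1, where the chi-squared
approximation fails; the test refuses such tables rather than report an
unreliable p. Multiple comparisons within one run are Benjamini–Hochberg
adjusted — the adjustment family is "the comparisons of one run", recorded
in the output.

## Tandem arrays

Coordinates are 1-based inclusive end to end; the chaining gap is the raw
difference `start(next) − end(previous)` with no off-by-one correction,
and the rule is strictly `< 20 000` bp. Adjacency is coordinate-adjacency
within a (scaffold, strand) group, so an intervening gene on the opposite
strand neither joins nor breaks a chain (strand partitioning comes first).
Overlapping gene models chain with a logged warning rather than error:
dense receptor clusters legitimately contain near-adjacent and overlapping
models. Singletons count as arrays of size 1, so detection is a partition
of the input and the size histogram conserves gene counts.

## Expression filters and tests

Pruning removes genes detected (count > 0) in **at most one** sample —
including all-zero genes. Counts are kept as non-negative reals
(pseudo-alignment emits fractional estimated counts) and never rounded;
the restriction filter compares the raw value (`< 10`) in every sample of
every non-focal tissue by default, with a tissue-mean variant and an
optional focal-tissue minimum behind flags. "Upregulated in the focal
tissue" is `log2FC > 0` and `padj < α` (strict, α = .05) in every
focal-vs-other comparison; a missing adjusted p never passes.

The built-in `nb_de_test` is a simplified two-group negative-binomial Wald
test, present so synthetic end-to-end runs need no external fit — external
DE tables remain the first-class input for real data. Per comparison:
median-of-ratios size factors (reference: gene-wise geometric means over
all-positive genes); group means on normalized counts; gene-wise
method-of-moments dispersion from the pooled within-group variance
(`α̂ = (s² − μ̄)/μ̄²`, floored at 1e-8), smoothed by a parametric trend
`α(μ) = a0 + a1/μ` fitted by least squares across genes. The trend is
what the Wald standard error uses: raw per-gene moment estimates at 3–4
replicates are far too noisy to calibrate, while pooling across genes
recovers near-nominal type-I error (measured ≈ 0.045–0.056 at α = .05 in
the 2000-gene null simulations the suite runs). The Wald statistic is
`log2FC / SE` with the delta-method variance
`[(c_A/μ_A + α)/n_A + (c_B/μ_B + α)/n_B] / ln²2`, where `c_G` is the mean
reciprocal size factor of group G; group means are floored at 0.5 inside
the fold change and variance so genes absent from one group get a large
but finite effect. Adjusted p-values are Benjamini–Hochberg within the
comparison.

Fisher exact tests are two-sided via the hypergeometric distribution
(scipy's implementation; an independent enumeration oracle in the test
suite agrees to < 1e-10). The reported odds ratio is the sample odds ratio
`ad/bc`, infinite when `bc = 0`.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure each stage assumes, at
reduced scale, with the truth recorded beside the data:

- **Species tree**: a ladder (caterpillar) with the focal tip nested
  deepest, chosen so every node distance 1..n−1 is realized — maximal
  stratum coverage at small n (default 12 species, emulating a
  many-ant-plus-outgroups reference set).
- **Gene families**: each gene gets a planted birth distance d (TRPs get
  d = 0, default fraction 0.1); homologs exist in all species at distance
  ≤ d. Direct-hit mode emits the hit records themselves (recovery is exact
  by construction and verified end to end); sequence mode emits homolog
  sequences with per-site substitution probability `1 − exp(−r·distance)`
  (default r = 0.05 per node, no indels — indel-free mutation keeps the
  aligner's gap handling out of the recovery path while leaving difficulty
  tunable), and the search must rediscover the hits.
- **Genome layout**: arrays drawn from a size distribution skewed toward
  small arrays (as in real OR repertoires), within-array gaps in
  [200, 19 999] bp, inter-array gaps ≥ 20 000 bp, one strand per array.
- **Counts**: negative binomial with variance `μ + αμ²` (default
  α = 0.05), gene baselines log-uniform on [20, 2000], per-sample library
  factors log-uniform on [0.7, 1.4]; four tissues (antennae, head, thorax,
  leg) with 3/4/4/3 replicates, mirroring a design that lost one antennae
  and one leg replicate to quality control. Planted antennae-upregulated
  genes (default 5%) get a 4-fold mean shift; planted restricted genes
  have mean zero outside the antennae; planted single-sample genes
  exercise pruning. `fold_change = 1` yields a pure null with nothing
  planted.

What the generators do **not** emulate: sequence evolution with indels or
rate heterogeneity, incomplete or erroneous genome annotation, mapping
ambiguity between paralogs (the force that motivates reannotation in real
OR work), library-preparation batch effects, and gene-length or GC biases
in counts. Passing the recovery suites therefore demonstrates that the
implementations compute their definitions correctly under the assumed
models — not that those models capture every failure mode of real
sequencing data.

## Presentation conventions

Summary ratios print as `k/n, p.p%` with the one-decimal percentage
*truncated* (376/21797 → 1.7%, 125/367 → 34.0%) and whole-percent displays
rounded to nearest (376/4288 → 9%); this pair of rules reproduces the
published presentation exactly. Every pipeline output is stamped with a
hash of the analytic configuration (the output directory is excluded) plus
the seed, and reruns with the same config are byte-identical.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use simulation sizes chosen to
make each check informative while keeping the whole suite quick on one
CPU: 2000-gene count matrices (matching the scale at which the dispersion
trend stabilizes), 1000-replicate null simulations for the chi-squared and
NB calibration bands [0.03, 0.07] at α = .05, 200 random 30-mers against
the reference DP aligner, 25–50 gene families per phylostratigraphy
recovery run, and ten seeds of 60-gene genome layouts. The calibration
bands are Monte-Carlo two-sided bands around the nominal 0.05 at 1000
replicates, not tuned quantities.

## Known limitations

- The built-in NB test is not a substitute for a shrinkage-based DE fit on
  real data: no Cook's-distance outlier handling, no independent
  filtering, no LFC shrinkage. Its role is to make synthetic end-to-end
  runs self-contained.
- Karlin–Altschul constants are fixed rather than estimated per
  scoring-system; absolute e-values from the built-in search are
  approximate even though threshold behaviour is stable.
- Node distances are topology-only; branch lengths are ignored by design,
  so the metric depends on the reference-species sampling density.
- The chi-squared tests require every expected cell ≥ 1 and will refuse
  sparser tables rather than silently report unreliable p-values.
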