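"""Synthetic inputs with recorded ground truth.

Every pipeline stage can be exercised without any external download: this
module generates species trees, gene families with known phylogenetic
birth nodes, genome annotations with planted tandem arrays, and
negative-binomial count matrices with planted tissue-upregulated genes.
Each generator is deterministic given its seed and returns the planted
truth alongside the data, so recovery can be scored exactly.

Default shapes mirror the study design this pipeline emulates at reduced
scale: a focal ant proteome searched against a ladder of reference species
(so every node distance is realized), odorant-receptor genes clustered in
sub-20-kbp tandem arrays, and four tissues (antennae, head, thorax, leg)
with 3-4 biological replicates each.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylostrat import SpeciesTree
from .sequence_io import GeneModel, CountMatrix, SeqRecord
from .similarity import HitRecord, HitTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default tissue design: four tissues, one antennae and one leg replicate
#: lost to quality control.
DEFAULT_TISSUES = ("antennae", "head", "thorax", "leg")
DEFAULT_REPLICATES = (3, 4, 4, 3)


@dataclass
class SyntheticTruth:
    """Ground truth recorded next to each generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_strata: dict[str, int] = field(default_factory=dict)
    planted_trps: set[str] = field(default_factory=set)
    planted_arrays: list[list[str]] = field(default_factory=list)
    planted_upregulated: dict[str, set[str]] = field(default_factory=dict)
    planted_restricted: set[str] = field(default_factory=set)
    planted_single_sample: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, set):
                return sorted(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default, indent=1,
                          sort_keys=True)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_set(seed: int = 0, n_species: int = 12) -> tuple[SpeciesTree, list[str]]:
    """A rooted ladder (caterpillar) tree with the focal species nested
    deepest, so node distances 1..n-1 are all realized.

    Tip k of ``sp1..sp{n-1}`` sits at node distance k from the focal tip.
    The topology is fixed; *seed* is accepted for interface uniformity.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    species = ["focal"] + [f"sp{k}" for k in range(1, n_species)]
    newick = "(focal,sp1)"
    for k in range(2, n_species):
        newick = f"({newick},sp{k})"
    tree = SpeciesTree.from_newick(newick + ";", focal="focal")
    return tree, species


# ---------------------------------------------------------------------------
# Gene families with planted birth nodes
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilyData:
    """Output of :func:`simulate_gene_families`.

    ``hits`` is populated in direct-hits mode; ``queries``/``subjects``/
    ``species_of`` in sequence mode (feed them to
    :func:`orstrat.similarity.search`).
    """

    hits: HitTable | None = None
    queries: list[SeqRecord] = field(default_factory=list)
    subjects: list[SeqRecord] = field(default_factory=list)
    species_of: dict[str, str] = field(default_factory=dict)


def simulate_gene_families(
    tree: SpeciesTree,
    n_genes: int = 50,
    trp_fraction: float = 0.1,
    mode: str = "direct_hits",
    mutation_rate_per_node: float = 0.05,
    seed: int = 0,
    evalue_threshold: float = 1e-5,
    length_range: tuple[int, int] = (120, 240),
) -> tuple[GeneFamilyData, SyntheticTruth]:
    """Plant a birth node distance for each focal gene and emit the evidence
    the phylostratigraphy stage must see.

    A gene born at distance d has homologs in every species at node distance
    1..d; taxonomically restricted genes (fraction *trp_fraction*) get d=0
    and no homolog. ``direct_hits`` mode emits hit records directly with
    e-values below *evalue_threshold*; ``sequences`` mode emits homolog
    protein sequences whose per-site substitution probability is
    ``1 - exp(-mutation_rate_per_node * distance)`` (no indels), so the
    similarity search must recover the hits.
    """
    if not 0.0 <= trp_fraction <= 1.0:
        raise ValueError("trp_fraction must be in [0, 1]")
    if mode not in ("direct_hits", "sequences"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    non_focal = [s for s in tree.species if s != tree.focal]
    distances = {s: tree.node_distance(s) for s in non_focal}
    max_d = max(distances.values())
    truth = SyntheticTruth(seed=seed, params={
        "n_genes": n_genes, "trp_fraction": trp_fraction, "mode": mode,
        "mutation_rate_per_node": mutation_rate_per_node,
        "evalue_threshold": evalue_threshold,
    })
    data = GeneFamilyData(hits=None)
    records: list[HitRecord] = []
    for i in range(n_genes):
        gid = f"g{i:04d}"
        if rng.random() < trp_fraction:
            d = 0
            truth.planted_trps.add(gid)
        else:
            d = int(rng.integers(1, max_d + 1))
        truth.planted_strata[gid] = d
        hit_species = [s for s in non_focal if distances[s] <= d]
        if mode == "direct_hits":
            for s in hit_species:
                evalue = 10.0 ** rng.uniform(-60.0, math.log10(evalue_threshold))
                records.append(HitRecord(
                    query_id=gid, subject_id=f"{s}|{gid}", subject_species=s,
                    evalue=evalue, bitscore=float(np.round(rng.uniform(60, 400), 1)),
                ))
        else:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            data.queries.append(SeqRecord(id=gid, residues=seq))
            for s in hit_species:
                p_sub = 1.0 - math.exp(-mutation_rate_per_node * distances[s])
                residues = _mutate(seq, p_sub, rng)
                sid = f"{s}|{gid}"
                data.subjects.append(SeqRecord(id=sid, residues=residues))
                data.species_of[sid] = s
    if mode == "direct_hits":
        data.hits = HitTable(records, threshold_applied=evalue_threshold).sorted()
    return data, truth


def _mutate(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability *p_sub*; replacements drawn
    uniformly from the other 19 residues."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < p_sub)[0]:
        alternatives = AMINO_ACIDS.replace(seq[i], "")
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome layout with planted tandem arrays
# ---------------------------------------------------------------------------

def simulate_genome_layout(
    n_scaffolds: int = 4,
    n_genes: int = 60,
    array_size_distribution: Mapping[int, float] | None = None,
    within_gap_range: tuple[int, int] = (200, 19_999),
    between_gap_min: int = 20_000,
    nine_exon_fraction: float = 0.4,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (1_000, 3_000),
) -> tuple[list[GeneModel], dict[str, str], SyntheticTruth]:
    """Lay odorant-receptor gene models out in planted tandem arrays.

    Arrays are drawn from *array_size_distribution* (default skewed toward
    small arrays, as in real OR repertoires), placed left to right on
    scaffolds with within-array gaps inside *within_gap_range* and
    inter-array gaps of at least *between_gap_min*, one strand per array.
    Categories (nine-exon vs other OR) are assigned per gene by
    *nine_exon_fraction*. Returns (genes, category map, truth).
    """
    if array_size_distribution is None:
        array_size_distribution = {1: 0.35, 2: 0.25, 3: 0.20, 4: 0.12, 6: 0.08}
    if within_gap_range[1] >= between_gap_min:
        raise ValueError("within-array gaps must stay below the between-array minimum")
    rng = np.random.default_rng(seed)
    sizes = sorted(array_size_distribution)
    probs = np.array([array_size_distribution[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    truth = SyntheticTruth(seed=seed, params={
        "n_scaffolds": n_scaffolds, "n_genes": n_genes,
        "array_size_distribution": {int(k): float(v) for k, v in array_size_distribution.items()},
        "within_gap_range": list(within_gap_range),
        "between_gap_min": between_gap_min,
        "nine_exon_fraction": nine_exon_fraction,
    })
    genes: list[GeneModel] = []
    categories: dict[str, str] = {}
    cursors = {f"scaf{j+1}": 1 for j in range(n_scaffolds)}
    gene_no = 0
    while gene_no < n_genes:
        size = min(int(rng.choice(sizes, p=probs)), n_genes - gene_no)
        scaffold = f"scaf{int(rng.integers(n_scaffolds)) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursors[scaffold]
        members: list[str] = []
        for k in range(size):
            if k > 0:
                pos += int(rng.integers(within_gap_range[0], within_gap_range[1] + 1))
            gid = f"or{gene_no:04d}"
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            genes.append(GeneModel(gene_id=gid, scaffold=scaffold, start=pos,
                                   end=pos + length - 1, strand=strand,
                                   category="nine_exon_or"
                                   if rng.random() < nine_exon_fraction else "other_or"))
            categories[gid] = genes[-1].category
            members.append(gid)
            pos = genes[-1].end
            gene_no += 1
        truth.planted_arrays.append(members)
        cursors[scaffold] = pos + between_gap_min + int(rng.integers(0, 30_000))
    return genes, categories, truth


# ---------------------------------------------------------------------------
# Count matrices with planted upregulation
# ---------------------------------------------------------------------------

def simulate_counts(
    n_genes: int = 2_000,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    replicates: Sequence[int] = DEFAULT_REPLICATES,
    upregulated_fraction: float = 0.05,
    fold_change: float = 4.0,
    nb_dispersion: float = 0.05,
    single_sample_fraction: float = 0.01,
    restricted_fraction: float = 0.01,
    baseline_range: tuple[float, float] = (20.0, 2_000.0),
    focal_tissue: str = "antennae",
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts (variance = mu + alpha * mu^2) with planted
    focal-tissue upregulation.

    Gene baselines are log-uniform over *baseline_range*; per-sample library
    scale factors are log-uniform over [0.7, 1.4]. A fraction of genes gets
    *fold_change* applied in the focal tissue; a fraction is made
    focal-restricted (mean zero elsewhere, so the raw-count < 10 filter must
    keep them); a fraction is detected in a single sample only (so pruning
    must remove them). With ``fold_change == 1`` the matrix is a pure null:
    nothing differential is planted.
    """
    if len(tissues) != len(replicates):
        raise ValueError("tissues and replicates must align")
    if any(r < 2 for r in replicates):
        raise ValueError("need >= 2 replicates per tissue")
    if focal_tissue not in tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} not among tissues")
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    tissue_of: dict[str, str] = {}
    for tissue, n_rep in zip(tissues, replicates):
        for r in range(1, n_rep + 1):
            sid = f"{tissue}_{r}"
            sample_ids.append(sid)
            tissue_of[sid] = tissue
    n_samples = len(sample_ids)
    gene_ids = [f"t{i:05d}" for i in range(n_genes)]
    lo, hi = baseline_range
    baselines = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_genes))
    lib = np.exp(rng.uniform(math.log(0.7), math.log(1.4), size=n_samples))

    null_model = fold_change == 1.0
    perm = rng.permutation(n_genes)
    n_up = 0 if null_model else int(round(upregulated_fraction * n_genes))
    n_restr = 0 if null_model else int(round(restricted_fraction * n_genes))
    n_single = int(round(single_sample_fraction * n_genes))
    up_idx = perm[:n_up]
    restr_idx = perm[n_up:n_up + n_restr]
    single_idx = perm[n_up + n_restr:n_up + n_restr + n_single]

    mu = np.outer(baselines, lib)
    focal_cols = np.array([tissue_of[s] == focal_tissue for s in sample_ids])
    mu[np.ix_(up_idx, focal_cols)] *= fold_change
    mu[np.ix_(restr_idx, ~focal_cols)] = 0.0
    if len(single_idx):
        mu[single_idx, :] = 0.0

    if nb_dispersion > 0:
        r = 1.0 / nb_dispersion
        with np.errstate(invalid="ignore"):
            counts = np.where(mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12))), 0)
    else:
        counts = rng.poisson(mu)
    counts = counts.astype(float)
    for i in single_idx:
        j = int(rng.integers(n_samples))
        counts[i, :] = 0.0
        counts[i, j] = float(rng.poisson(50) + 1)

    import pandas as pd
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), tissue_of)
    truth = SyntheticTruth(seed=seed, params={
        "n_genes": n_genes, "tissues": list(tissues), "replicates": list(replicates),
        "upregulated_fraction": upregulated_fraction, "fold_change": fold_change,
        "nb_dispersion": nb_dispersion, "baseline_range": list(baseline_range),
        "single_sample_fraction": single_sample_fraction,
        "restricted_fraction": restricted_fraction, "focal_tissue": focal_tissue,
    })
    planted_up = {gene_ids[i] for i in up_idx} | {gene_ids[i] for i in restr_idx}
    truth.planted_upregulated = {focal_tissue: planted_up} if planted_up else {}
    truth.planted_restricted = {gene_ids[i] for i in restr_idx}
    truth.planted_single_sample = {gene_ids[i] for i in single_idx}
    return cm, truth
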