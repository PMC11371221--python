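"""End-to-end orchestration: one config, dependency-ordered stages, one report.

Stages are pure dataflow — no stage mutates another stage's inputs — and
every output is stamped with the config hash and seed so a rerun with the
same config and inputs is byte-identical.

The report collects the study's summary quantities: upregulated-set sizes
per comparison and their exclusive intersections, category enrichment
tables, the strata table with TRP counts, and array histograms. Ratios are
presented as ``k/n, p.p%`` with the percentage rounded half-to-even to one
decimal (or to a whole percent via :func:`format_percent_int`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, phylostrat, sequence_io, similarity, synthetic_data, tandem_arrays

logger = logging.getLogger("orstrat")


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run.

    Defaults hold the study's thresholds: similarity e-value cutoffs of
    1e-5 (phylostratigraphy) and 1e-40 (receptor-to-reference association),
    a 20 kbp tandem-array gap, a raw-count restriction threshold of 10, and
    an adjusted-p significance level of .05.
    """

    seed: int = 0
    focal_species: str = "focal"
    focal_tissue: str = "antennae"
    evalue_threshold_phylostrat: float = 1e-5
    evalue_threshold_association: float = 1e-40
    max_gap_bp: int = 20_000
    restriction_count_threshold: float = 10.0
    alpha_padj: float = 0.05
    adjustment_method: str = "benjamini-hochberg"
    stages: tuple[str, ...] = ("phylostrat", "arrays", "expression")
    #: Optional node-distance -> clade-label map used for the enrichment
    #: test (the raw integer-strata table is always kept in the report).
    strata_bins: dict | None = None
    synthetic: bool = True
    synthetic_params: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("evalue_threshold_phylostrat", "evalue_threshold_association",
                     "max_gap_bp", "restriction_count_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.alpha_padj < 1.0:
            raise ValueError("alpha_padj must be in (0, 1)")
        unknown = set(self.stages) - {"phylostrat", "arrays", "expression"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def hash(self) -> str:
        """Stable digest of the analytic configuration (the output location
        does not affect results and is excluded)."""
        record = dataclasses.asdict(self)
        record.pop("out_dir", None)
        blob = json.dumps(record, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def format_ratio(k: int, n: int) -> str:
    """Render ``k/n`` with its percentage to one decimal: ``"376/21797, 1.7%"``.

    The decimal is truncated, not rounded (125/367 = 34.059...% prints as
    34.0%), matching the presentation convention this pipeline reproduces.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = math.floor(1000.0 * k / n) / 10.0
    return f"{k}/{n}, {pct:.1f}%"


def format_percent_int(k: int, n: int) -> str:
    """Whole-percent display, round-half-to-even: ``"9%"`` for 376/4288."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return f"{round(100.0 * k / n):d}%"


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_phylostrat(config: PipelineConfig, tree, hits, protein_ids, categories,
                    strata_bins=None) -> dict:
    best = similarity.best_hit_per_species(hits)
    assignments = phylostrat.assign_strata(best, tree, protein_ids)
    trps = phylostrat.find_trps(assignments)
    table = phylostrat.strata_contingency(assignments, categories)
    test_table = (phylostrat.strata_contingency(assignments, categories,
                                                strata_bins=strata_bins)
                  if strata_bins else table)
    cats = sorted({categories[p] for p in protein_ids})
    comparisons = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1:]
                   if table.loc[a].sum() > 0 and table.loc[b].sum() > 0]
    try:
        enrichment = (phylostrat.stratum_enrichment_tests(test_table, comparisons)
                      if comparisons else pd.DataFrame())
    except ValueError:
        logger.warning("stratum-enrichment test skipped: table too sparse")
        enrichment = pd.DataFrame()
    logger.info("phylostrat: %d proteins in, %d TRPs out", len(protein_ids), len(trps))
    return {
        "assignments": assignments,
        "n_proteins": len(protein_ids),
        "n_trps": len(trps),
        "trps": sorted(trps),
        "strata_table": table,
        "enrichment": enrichment,
    }


def _run_arrays(config: PipelineConfig, genes, categories) -> dict:
    arrays = tandem_arrays.detect_arrays(genes, max_gap=config.max_gap_bp)
    hist = tandem_arrays.array_size_histogram(arrays)
    # coarse size bins (singleton / small / large) keep expected cells viable
    size_bins = {s: ("1" if s == 1 else "2-3" if s <= 3 else "4+") for s in hist}
    if len({categories[g.gene_id] for g in genes}) >= 2:
        try:
            chi2, dof, p = tandem_arrays.category_array_chisq(
                arrays, categories, size_bins=size_bins)
        except ValueError:
            logger.warning("array-composition test skipped: table too sparse")
            chi2, dof, p = math.nan, 0, math.nan
    else:
        chi2, dof, p = 0.0, 0, 1.0
    logger.info("arrays: %d genes in, %d arrays out", len(genes), len(arrays))
    return {
        "arrays": arrays,
        "n_genes": len(genes),
        "n_arrays": len(arrays),
        "size_histogram": hist,
        "chi2": chi2, "df": dof, "p": p,
    }


def _run_expression(config: PipelineConfig, counts, categories, de_tables=None) -> dict:
    pruned = expression.prune_single_sample(counts)
    focal = config.focal_tissue
    others = [t for t in pruned.tissues if t != focal]
    if de_tables is None:
        de_tables = {t: expression.nb_de_test(pruned, focal, t) for t in others}
    per_comparison = {t: expression.upregulated_set(rows, config.alpha_padj)
                      for t, rows in de_tables.items()}
    up_all = expression.upregulated_vs_all(de_tables, config.alpha_padj)
    upset = expression.upset_counts(per_comparison)
    restricted = expression.expression_restricted(
        pruned, focal, threshold=config.restriction_count_threshold)
    universe = set(pruned.gene_ids)
    or_set = {g for g in universe
              if categories.get(g, "non_or") in ("nine_exon_or", "other_or")}
    enrich = (expression.fisher_enrichment(up_all, or_set, universe)
              if or_set else None)
    logger.info("expression: %d genes in, %d pruned, %d upregulated-vs-all",
                len(counts.gene_ids), len(counts.gene_ids) - len(pruned.gene_ids),
                len(up_all))
    return {
        "n_genes_in": len(counts.gene_ids),
        "n_genes_pruned": len(counts.gene_ids) - len(pruned.gene_ids),
        "n_genes_kept": len(pruned.gene_ids),
        "per_comparison_upregulated": per_comparison,
        "upregulated_vs_all": up_all,
        "upset": upset,
        "expression_restricted": restricted,
        "or_enrichment": enrich,
        "de_tables": de_tables,
        "pruned_counts": pruned,
    }


# ---------------------------------------------------------------------------
# Top-level run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    In synthetic mode the generators supply every input (and the report
    carries the planted truth); otherwise inputs are read from
    ``config.paths``. When ``config.out_dir`` is set, per-stage TSVs and the
    JSON report are written there.
    """
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    truth_bundle: dict = {}
    if config.synthetic:
        inputs = _synthesize_inputs(config, truth_bundle)
    else:
        inputs = _load_inputs(config)

    if "phylostrat" in config.stages:
        report["stages"]["phylostrat"] = _run_phylostrat(
            config, inputs["tree"], inputs["hits"], inputs["protein_ids"],
            inputs["protein_categories"],
            strata_bins=config.strata_bins or inputs.get("strata_bins"))
    if "arrays" in config.stages:
        report["stages"]["arrays"] = _run_arrays(
            config, inputs["genes"], inputs["gene_categories"])
    if "expression" in config.stages:
        report["stages"]["expression"] = _run_expression(
            config, inputs["counts"], inputs.get("count_categories", {}),
            inputs.get("de_tables"))
    if truth_bundle:
        report["truth"] = truth_bundle
        report["recovery"] = _score_recovery(report, truth_bundle, config)
    if config.out_dir:
        _write_report(report, config)
    return report


def _synthesize_inputs(config: PipelineConfig, truth_bundle: dict) -> dict:
    p = config.synthetic_params
    inputs: dict = {}
    if "phylostrat" in config.stages:
        tree, _ = synthetic_data.simulate_species_set(
            seed=config.seed, n_species=p.get("n_species", 12))
        fam, truth = synthetic_data.simulate_gene_families(
            tree, n_genes=p.get("n_genes_phylo", 50),
            trp_fraction=p.get("trp_fraction", 0.1),
            mode=p.get("phylo_mode", "direct_hits"), seed=config.seed,
            evalue_threshold=config.evalue_threshold_phylostrat)
        hits = fam.hits
        if hits is None:
            hits = similarity.search(fam.queries, fam.subjects, fam.species_of,
                                     config.evalue_threshold_phylostrat)
        inputs["tree"] = tree
        inputs["hits"] = hits
        inputs["protein_ids"] = sorted(truth.planted_strata)
        # a synthetic OR-like split so enrichment has two categories to compare
        inputs["protein_categories"] = {
            pid: ("nine_exon_or" if i % 5 == 0 else "non_or")
            for i, pid in enumerate(inputs["protein_ids"])}
        # coarse clade-style bins so expected cells stay testable at
        # synthetic scale; thirds of the realized distance range
        max_d = max(tree.node_distance(s) for s in tree.species)
        inputs["strata_bins"] = {
            d: ("near" if d <= max_d // 3 else
                "mid" if d <= 2 * max_d // 3 else "far")
            for d in range(max_d + 1)}
        truth_bundle["phylostrat"] = truth
    if "arrays" in config.stages:
        genes, cats, truth = synthetic_data.simulate_genome_layout(
            seed=config.seed, n_genes=p.get("n_genes_layout", 60))
        inputs["genes"] = genes
        inputs["gene_categories"] = cats
        truth_bundle["arrays"] = truth
    if "expression" in config.stages:
        counts, truth = synthetic_data.simulate_counts(
            seed=config.seed, n_genes=p.get("n_genes_counts", 2000),
            focal_tissue=config.focal_tissue)
        inputs["counts"] = counts
        up = truth.planted_upregulated.get(config.focal_tissue, set())
        inputs["count_categories"] = {g: "other_or" for g in up}
        truth_bundle["expression"] = truth
    return inputs


def _load_inputs(config: PipelineConfig) -> dict:
    paths = config.paths
    inputs: dict = {}
    if "phylostrat" in config.stages:
        inputs["tree"] = phylostrat.SpeciesTree.from_newick(
            paths["tree"], focal=config.focal_species)
        species_of = dict(pd.read_csv(paths["species_map"], sep="\t", header=None,
                                      names=["subject_id", "species"],
                                      dtype=str).itertuples(index=False))
        inputs["hits"] = sequence_io.read_blast_tab(paths["hits"], species_of)
        proteins = sequence_io.read_fasta(paths["proteins"])
        inputs["protein_ids"] = [r.id for r in proteins]
        inputs["protein_categories"] = sequence_io.read_category_map(paths["categories"])
        for pid in inputs["protein_ids"]:
            inputs["protein_categories"].setdefault(pid, "non_or")
    if "arrays" in config.stages:
        cats = sequence_io.read_category_map(paths["categories"])
        inputs["genes"] = sequence_io.read_gff3(paths["gff"], cats)
        inputs["gene_categories"] = {g.gene_id: g.category for g in inputs["genes"]}
    if "expression" in config.stages:
        tissue_of = dict(pd.read_csv(paths["tissue_map"], sep="\t", header=None,
                                     names=["sample_id", "tissue"],
                                     dtype=str).itertuples(index=False))
        inputs["counts"] = sequence_io.read_counts_matrix(paths["counts"], tissue_of)
        inputs["count_categories"] = sequence_io.read_category_map(paths["categories"])
        if "de_tables" in paths:
            inputs["de_tables"] = {
                tissue: expression.read_de_table(p, config.focal_tissue, tissue)
                for tissue, p in paths["de_tables"].items()}
    return inputs


def _score_recovery(report: dict, truth_bundle: dict, config: PipelineConfig) -> dict:
    """Compare each stage's output with the planted truth."""
    rec: dict = {}
    if "phylostrat" in truth_bundle and "phylostrat" in report["stages"]:
        truth = truth_bundle["phylostrat"]
        got = {a.protein_id: a.node_distance
               for a in report["stages"]["phylostrat"]["assignments"]}
        agree = sum(got[g] == d for g, d in truth.planted_strata.items())
        rec["stratum_recovery"] = agree / max(len(truth.planted_strata), 1)
        rec["trp_set_exact"] = set(report["stages"]["phylostrat"]["trps"]) == truth.planted_trps
    if "arrays" in truth_bundle and "arrays" in report["stages"]:
        truth = truth_bundle["arrays"]
        detected = {frozenset(a.members) for a in report["stages"]["arrays"]["arrays"]}
        planted = {frozenset(m) for m in truth.planted_arrays}
        rec["arrays_exact"] = detected == planted
    if "expression" in truth_bundle and "expression" in report["stages"]:
        truth = truth_bundle["expression"]
        planted = truth.planted_upregulated.get(config.focal_tissue, set())
        got = report["stages"]["expression"]["upregulated_vs_all"]
        rec["upregulated_recall"] = (len(got & planted) / len(planted)) if planted else 1.0
        rec["upregulated_false_inclusions"] = len(got - planted)
        rec["restricted_recall"] = (
            len(report["stages"]["expression"]["expression_restricted"]
                & truth.planted_restricted) / len(truth.planted_restricted)
            if truth.planted_restricted else 1.0)
    return rec


def _write_report(report: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report["config_hash"], "seed": report["seed"]}
    if "phylostrat" in report["stages"]:
        st = report["stages"]["phylostrat"]
        pd.DataFrame({
            "protein_id": [a.protein_id for a in st["assignments"]],
            "node_distance": [a.node_distance for a in st["assignments"]],
            "deepest_species": [a.deepest_species or "" for a in st["assignments"]],
            "is_trp": [a.is_trp for a in st["assignments"]],
        }).to_csv(out / "strata_assignments.tsv", sep="\t", index=False)
        st["strata_table"].to_csv(out / "strata_table.tsv", sep="\t")
        if len(st["enrichment"]):
            st["enrichment"].to_csv(out / "strata_enrichment.tsv", sep="\t", index=False)
    if "arrays" in report["stages"]:
        tandem_arrays.arrays_to_frame(report["stages"]["arrays"]["arrays"]).to_csv(
            out / "tandem_arrays.tsv", sep="\t", index=False)
    if "expression" in report["stages"]:
        ex = report["stages"]["expression"]
        for tissue, rows in ex["de_tables"].items():
            expression.write_de_table(rows, out / f"de_{config.focal_tissue}_vs_{tissue}.tsv")
        with open(out / "upregulated_vs_all.txt", "w") as fh:
            fh.write("\n".join(sorted(ex["upregulated_vs_all"])) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump({**stamp, "summary": summarize_report(report)}, fh, indent=1)
    logger.info("report written to %s (config %s)", out, report["config_hash"])


def summarize_report(report: dict) -> str:
    """Human-readable summary in the ``k/n, p.p%`` presentation style."""
    lines = [f"config {report['config_hash']}, seed {report['seed']}"]
    stages = report.get("stages", {})
    if "expression" in stages:
        ex = stages["expression"]
        n = ex["n_genes_kept"]
        k = len(ex["upregulated_vs_all"])
        lines.append(f"upregulated vs all tissues: {format_ratio(k, n)}")
        lines.append(f"expression-restricted: {format_ratio(len(ex['expression_restricted']), n)}")
        if ex["or_enrichment"] is not None:
            lines.append(f"OR enrichment in upregulated set: p = {ex['or_enrichment'].p:.3g}")
    if "phylostrat" in stages:
        st = stages["phylostrat"]
        lines.append(f"taxonomically restricted proteins: "
                     f"{format_ratio(st['n_trps'], st['n_proteins'])}")
    if "arrays" in stages:
        ar = stages["arrays"]
        lines.append(f"tandem arrays: {ar['n_arrays']} over {ar['n_genes']} genes")
    if "recovery" in report:
        for key, val in report["recovery"].items():
            lines.append(f"recovery {key}: {val}")
    return "\n".join(lines)
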