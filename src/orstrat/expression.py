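"""Count filters, tissue-upregulation set logic, and enrichment statistics.

The differential-expression engine of record for real data is an external
fit whose result tables (gene_id, log2fc, pvalue, padj) are consumed via
:func:`read_de_table`. :func:`nb_de_test` is a simplified built-in
negative-binomial Wald test so synthetic end-to-end runs need no external
fit: median-of-ratios size factors, method-of-moments dispersion with a
parametric trend fitted across genes, and a Wald z-test on the log2 fold
change with Benjamini–Hochberg adjustment within the comparison.

Set logic follows the study design: a gene is "upregulated in the focal
tissue" when its log2 fold change is positive and its adjusted p is below
alpha in EVERY focal-vs-other comparison; "expression restricted" when its
raw count stays below a threshold in every sample of every other tissue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequence_io import CountMatrix

logger = logging.getLogger("orstrat")

#: Dispersion floor for the built-in NB test.
DISPERSION_FLOOR = 1e-8

#: Mean floor used inside log-fold-change and Wald-variance formulas so that
#: genes absent from one group get a large but finite effect and variance.
MEAN_FLOOR = 0.5


@dataclass(frozen=True)
class DEResultRow:
    """One gene's differential-expression result for one tissue comparison.

    ``log2fc`` is positive when expression is higher in ``tissue_a``.
    ``padj`` may be NaN (not assigned); a NaN adjusted p never passes a
    significance filter.
    """

    gene_id: str
    tissue_a: str
    tissue_b: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if self.tissue_a == self.tissue_b:
            raise ValueError("comparison tissues must be distinct")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0,1] for {self.gene_id!r}")
        if not math.isnan(self.padj) and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"adjusted p out of [0,1] for {self.gene_id!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 enrichment table with its Fisher exact test.

    Cells: ``a`` = in-category and in-hit-set, ``b`` = in-category only,
    ``c`` = in-hit-set only, ``d`` = neither. The odds ratio is the sample
    odds ratio ``a*d / (b*c)`` (infinite when ``b*c == 0``).
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    sidedness: str = "two-sided"

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# Count filters
# ---------------------------------------------------------------------------

def prune_single_sample(counts: CountMatrix) -> CountMatrix:
    """Drop genes detected (count > 0) in at most one sample.

    This removes all-zero genes as well as genes seen in exactly one
    sample; everything else passes through unchanged.
    """
    detected = (counts.counts.to_numpy() > 0).sum(axis=1)
    keep = [g for g, n in zip(counts.gene_ids, detected) if n >= 2]
    return counts.subset_genes(keep)


def expression_restricted(
    counts: CountMatrix,
    focal_tissue: str,
    threshold: float = 10.0,
    per_sample: bool = True,
    focal_min: float | None = None,
) -> set[str]:
    """Genes whose raw counts stay below *threshold* outside the focal tissue.

    With ``per_sample=True`` (default) the rule is strict ``< threshold`` in
    EVERY sample of every non-focal tissue; ``per_sample=False`` applies it
    to each non-focal tissue's mean instead. No condition is placed on
    focal-tissue expression unless *focal_min* is given, in which case the
    gene must additionally reach ``>= focal_min`` in at least one focal
    sample. Counts are compared un-rounded.
    """
    if focal_tissue not in counts.tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} not present")
    non_focal = [s for s in counts.sample_ids if counts.tissue_of[s] != focal_tissue]
    mat = counts.counts
    if per_sample:
        ok = (mat[non_focal] < threshold).all(axis=1)
    else:
        ok = pd.Series(True, index=mat.index)
        for tissue in counts.tissues:
            if tissue == focal_tissue:
                continue
            ok &= mat[counts.samples_of_tissue(tissue)].mean(axis=1) < threshold
    if focal_min is not None:
        focal_samples = counts.samples_of_tissue(focal_tissue)
        ok &= (mat[focal_samples] >= focal_min).any(axis=1)
    return set(mat.index[ok])


# ---------------------------------------------------------------------------
# Built-in negative-binomial Wald test
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed on
    genes with strictly positive counts everywhere; each sample's factor is
    the median ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def _trended_dispersion(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit the parametric mean-dispersion trend ``alpha = a0 + a1/mu`` to the
    gene-wise method-of-moments estimates and evaluate it at each gene's mean.

    Falls back to the gene-wise estimates when too few genes inform the fit.
    """
    usable = (mu > 0) & (alpha_mom > DISPERSION_FLOOR)
    if usable.sum() < 10:
        return np.maximum(alpha_mom, DISPERSION_FLOOR)
    X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[usable], rcond=None)
    trend = coef[0] + coef[1] / np.maximum(mu, MEAN_FLOOR)
    return np.maximum(trend, DISPERSION_FLOOR)


def nb_de_test(
    counts: CountMatrix, tissue_a: str, tissue_b: str,
) -> list[DEResultRow]:
    """Two-group negative-binomial Wald test on raw counts.

    Size factors are estimated on the samples of the two tissues; group
    means are taken on normalized counts; the NB dispersion (variance =
    mu + alpha * mu^2) comes from pooled within-group method-of-moments
    estimates smoothed by a parametric trend and floored at 1e-8. The Wald
    statistic is the log2 fold change over its delta-method standard error;
    adjusted p-values are Benjamini–Hochberg within the comparison.
    """
    sa = counts.samples_of_tissue(tissue_a)
    sb = counts.samples_of_tissue(tissue_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >= 2 samples per tissue, got {len(sa)} for {tissue_a!r} "
            f"and {len(sb)} for {tissue_b!r}")
    sub = counts.counts[sa + sb]
    sf = size_factors(sub)
    norm = sub / sf
    na, nb = len(sa), len(sb)
    mu_a = norm[sa].mean(axis=1).to_numpy()
    mu_b = norm[sb].mean(axis=1).to_numpy()
    var_a = norm[sa].var(axis=1, ddof=1).to_numpy()
    var_b = norm[sb].var(axis=1, ddof=1).to_numpy()
    mu = (na * mu_a + nb * mu_b) / (na + nb)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mu > 0, (pooled_var - mu) / np.square(mu), 0.0)
    alpha = _trended_dispersion(mu, np.maximum(alpha_mom, 0.0))

    fa = np.maximum(mu_a, MEAN_FLOOR)
    fb = np.maximum(mu_b, MEAN_FLOOR)
    log2fc = np.where((mu_a == 0) & (mu_b == 0), 0.0, np.log2(fa / fb))
    inv_a = float(np.mean(1.0 / sf[sa].to_numpy()))
    inv_b = float(np.mean(1.0 / sf[sb].to_numpy()))
    # Var(log2 mean) by the delta method, NB variance mu/s + alpha*mu^2 per sample
    var_log2 = (inv_a / fa + alpha) / na + (inv_b / fb + alpha) / nb
    se = np.sqrt(var_log2) / math.log(2)
    z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where((mu_a == 0) & (mu_b == 0), 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return [
        DEResultRow(gene_id=g, tissue_a=tissue_a, tissue_b=tissue_b,
                    log2fc=float(l), pvalue=float(p), padj=float(q))
        for g, l, p, q in zip(sub.index, log2fc, pvals, padj)
    ]


# ---------------------------------------------------------------------------
# DE tables and set logic
# ---------------------------------------------------------------------------

def read_de_table(path, tissue_a: str, tissue_b: str) -> list[DEResultRow]:
    """Read an external DE result TSV (gene_id, log2fc, pvalue, padj)."""
    df = pd.read_csv(str(path), sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        DEResultRow(gene_id=str(r.gene_id), tissue_a=tissue_a, tissue_b=tissue_b,
                    log2fc=float(r.log2fc), pvalue=float(r.pvalue),
                    padj=float(r.padj) if pd.notna(r.padj) else math.nan)
        for r in df.itertuples(index=False)
    ]


def write_de_table(rows: Sequence[DEResultRow], path) -> None:
    pd.DataFrame({
        "gene_id": [r.gene_id for r in rows],
        "log2fc": [r.log2fc for r in rows],
        "pvalue": [r.pvalue for r in rows],
        "padj": [r.padj for r in rows],
    }).to_csv(str(path), sep="\t", index=False)


def upregulated_set(rows: Iterable[DEResultRow], alpha: float = 0.05) -> set[str]:
    """Genes upregulated in tissue_a of one comparison: log2fc > 0 and
    padj < alpha (NaN padj never passes)."""
    return {
        r.gene_id for r in rows
        if r.log2fc > 0 and not math.isnan(r.padj) and r.padj < alpha
    }


def upregulated_vs_all(
    results: Mapping[str, Sequence[DEResultRow]],
    alpha: float = 0.05,
) -> set[str]:
    """Genes upregulated in the focal tissue against EVERY other tissue.

    *results* maps each non-focal tissue to its focal-vs-that-tissue DE
    table. The result is the intersection of the per-comparison upregulated
    sets; an empty mapping is an error (no comparisons to conjoin).
    """
    if not results:
        raise ValueError("no comparison tables supplied")
    sets = [upregulated_set(rows, alpha) for rows in results.values()]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


@dataclass(frozen=True)
class UpsetCounts:
    """Exclusive intersection counts plus per-set marginal totals."""

    exclusive: dict[tuple[str, ...], int]
    marginals: dict[str, int]


def upset_counts(per_comparison_sets: Mapping[str, set[str]]) -> UpsetCounts:
    """Exclusive (upset-style) intersection counts.

    Each gene is counted once, under the exact signature of comparisons it
    appears in; every non-empty signature over the input comparisons is
    reported, zeros included. Marginals are the plain per-comparison set
    sizes (the horizontal bars of an upset plot).
    """
    if not per_comparison_sets:
        raise ValueError("need at least one set")
    names = sorted(per_comparison_sets)
    membership: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*per_comparison_sets.values()):
        sig = tuple(n for n in names if gene in per_comparison_sets[n])
        membership[gene] = sig
    exclusive: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            exclusive[combo] = 0
    for sig in membership.values():
        exclusive[sig] += 1
    marginals = {n: len(per_comparison_sets[n]) for n in names}
    return UpsetCounts(exclusive=exclusive, marginals=marginals)


# ---------------------------------------------------------------------------
# Fisher exact enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    hit_set: set[str], category_set: set[str], universe: set[str],
) -> EnrichmentResult:
    """Two-sided Fisher exact test for over-representation of a category in
    a hit set, both subsets of a common universe."""
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe or not category_set <= universe:
        raise ValueError("hit_set and category_set must be subsets of the universe")
    a = len(hit_set & category_set)
    b = len(category_set - hit_set)
    c = len(hit_set - category_set)
    d = len(universe) - a - b - c
    return _fisher_2x2(a, b, c, d)


def proportion_fisher(k1: int, n1: int, k2: int, n2: int) -> EnrichmentResult:
    """Two-sided Fisher exact test comparing two proportions k1/n1 vs k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return _fisher_2x2(k1, n1 - k1, k2, n2 - k2)


def _fisher_2x2(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p=float(p))
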