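"""Tandem-array detection on gene annotations.

Genes are partitioned by (scaffold, strand) and sorted by start coordinate;
coordinate-adjacent genes are chained into one array when the gap
``start(next) - end(previous)`` is strictly less than ``max_gap`` base
pairs (default 20 kbp). Chaining is transitive; unchained genes form
size-1 arrays, so the output is a partition of the input genes.

Coordinates are 1-based inclusive throughout; the gap is the raw
difference with no off-by-one correction, so abutting genes
(start(next) == end(previous) + 1) have gap 1 and overlapping genes a
gap <= 0 (chained, with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .sequence_io import GeneModel

logger = logging.getLogger("orstrat")

DEFAULT_MAX_GAP = 20_000


@dataclass(frozen=True)
class TandemArray:
    """A maximal chain of same-scaffold, same-strand genes under the gap rule."""

    scaffold: str
    strand: str
    members: tuple[str, ...]  # gene ids ordered by start coordinate

    @property
    def size(self) -> int:
        return len(self.members)


def detect_arrays(
    genes: Sequence[GeneModel],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[TandemArray]:
    """Partition *genes* into tandem arrays.

    Adjacency is coordinate-adjacency within the (scaffold, strand) group:
    an intervening gene on the opposite strand does not break a chain. The
    gap rule is strict (< max_gap). Every input gene lands in exactly one
    array; the result is invariant under permutation of the input.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        groups.setdefault((g.scaffold, g.strand), []).append(g)
    arrays: list[TandemArray] = []
    for (scaffold, strand) in sorted(groups):
        members = sorted(groups[(scaffold, strand)], key=lambda g: (g.start, g.end, g.gene_id))
        chain: list[GeneModel] = [members[0]]
        for prev, nxt in zip(members, members[1:]):
            gap = nxt.start - prev.end
            if gap <= 0:
                logger.warning(
                    "overlapping gene models %s and %s (gap %d bp): chained",
                    prev.gene_id, nxt.gene_id, gap)
            if gap < max_gap:
                chain.append(nxt)
            else:
                arrays.append(TandemArray(scaffold, strand, tuple(g.gene_id for g in chain)))
                chain = [nxt]
        arrays.append(TandemArray(scaffold, strand, tuple(g.gene_id for g in chain)))
    return arrays


def array_size_histogram(
    arrays: Sequence[TandemArray],
) -> dict[int, tuple[int, int]]:
    """Map array size -> (number of arrays of that size, number of genes in them).

    The gene count for size s is s times the array count, so summing the
    second components over all sizes recovers the total gene count.
    """
    hist: dict[int, tuple[int, int]] = {}
    for a in arrays:
        n_arrays, n_genes = hist.get(a.size, (0, 0))
        hist[a.size] = (n_arrays + 1, n_genes + a.size)
    return dict(sorted(hist.items()))


def category_array_chisq(
    arrays: Sequence[TandemArray],
    categories: Mapping[str, str],
    size_bins: Mapping[int, str] | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of gene-category composition across array
    sizes.

    Builds the (category x size-bin) gene-count table — each gene counted
    once under its array's size — and tests it against independence
    (expected counts from marginal proportions). *size_bins* maps observed
    sizes to bin labels; unbinned sizes are their own bins.
    """
    rows = []
    for a in arrays:
        label = size_bins[a.size] if size_bins is not None else a.size
        for gid in a.members:
            if gid not in categories:
                raise ValueError(f"gene {gid!r} has no category")
            rows.append((categories[gid], label))
    df = pd.DataFrame(rows, columns=["category", "size_bin"])
    table = pd.crosstab(df["category"], df["size_bin"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 0, 1.0
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 1).any():
        raise ValueError("expected cell count < 1: merge sizes into coarser bins")
    return float(chi2), int(dof), float(p)


def arrays_to_frame(arrays: Sequence[TandemArray]) -> pd.DataFrame:
    """Tabular view for TSV export (array_id, scaffold, strand, size, members)."""
    return pd.DataFrame({
        "array_id": [f"array{i:04d}" for i in range(len(arrays))],
        "scaffold": [a.scaffold for a in arrays],
        "strand": [a.strand for a in arrays],
        "size": [a.size for a in arrays],
        "members": [",".join(a.members) for a in arrays],
    })
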