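"""Node-distance phylostratigraphy and taxonomically-restricted-protein calls.

Each focal-species protein is assigned an age: the *node distance* of the
most distant reference species in which a similarity hit was retained.
Node distance between two tips counts the internal nodes on the unique
tip-to-tip path — the MRCA and every intermediate internal node, excluding
the two tips — so sister species are at distance 1 and the focal species is
at distance 0 from itself. A protein with no retained hit outside the focal
species is a taxonomically restricted protein (TRP): node distance 0,
deepest species none.

Category-vs-category stratum enrichment uses a Pearson chi-squared test on
the 2 x k (category x stratum bin) count table, with Benjamini–Hochberg
adjustment across the comparisons of one run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .similarity import HitTable

logger = logging.getLogger("orstrat")


class SpeciesTree:
    """A rooted species tree with a designated focal tip.

    Wraps a :class:`dendropy.Tree`; tip labels are species names and must be
    unique. Multifurcations are allowed.
    """

    def __init__(self, tree: dendropy.Tree, focal: str):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        if focal not in labels:
            raise ValueError(f"focal species {focal!r} is not a tip of the tree")
        self.focal = focal
        self._leaf_of = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        self._distance_cache: dict[str, int] = {}

    @classmethod
    def from_newick(cls, source: str, focal: str) -> "SpeciesTree":
        """Build from a Newick string or a path to a Newick file."""
        import os
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls(tree, focal)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def species(self) -> list[str]:
        return list(self._leaf_of)

    def node_distance(self, other: str) -> int:
        """Internal-node count on the path between the focal tip and *other*.

        The MRCA and all intermediate internal nodes are counted; the two
        tips are not. ``node_distance(focal) == 0``.
        """
        if other not in self._leaf_of:
            raise ValueError(f"unknown tip {other!r}")
        if other == self.focal:
            return 0
        if other in self._distance_cache:
            return self._distance_cache[other]
        # Path node count = edges(focal->mrca) + edges(other->mrca) - 1
        # internal nodes once the two tips are dropped.
        a_anc = self._ancestors(self._leaf_of[self.focal])
        b_anc = self._ancestors(self._leaf_of[other])
        a_set = {id(n): i for i, n in enumerate(a_anc)}
        for j, node in enumerate(b_anc):
            if id(node) in a_set:
                d = a_set[id(node)] + j + 1
                self._distance_cache[other] = d
                return d
        raise ValueError(f"no common ancestor for {self.focal!r} and {other!r}")

    @staticmethod
    def _ancestors(leaf: dendropy.Node) -> list[dendropy.Node]:
        out = []
        node = leaf.parent_node
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out


def node_distance(tree: SpeciesTree, other: str) -> int:
    """Module-level convenience for :meth:`SpeciesTree.node_distance`."""
    return tree.node_distance(other)


@dataclass(frozen=True)
class StratumAssignment:
    """One protein's phylostratigraphic age.

    ``is_trp`` is true iff no non-focal species retained a hit, in which
    case ``node_distance`` is 0 and ``deepest_species`` is None.
    """

    protein_id: str
    node_distance: int
    deepest_species: str | None
    is_trp: bool

    def __post_init__(self) -> None:
        trp_consistent = self.is_trp == (self.node_distance == 0 and self.deepest_species is None)
        if not trp_consistent:
            raise ValueError(f"inconsistent TRP flag for {self.protein_id!r}")


def assign_strata(
    best_hits: HitTable,
    tree: SpeciesTree,
    protein_ids: Sequence[str],
) -> list[StratumAssignment]:
    """Assign every protein in *protein_ids* its node distance.

    The age is the maximum node distance over the species with retained
    hits; hits on the focal species itself are ignored (every protein hits
    itself). Proteins with no non-focal hit are flagged TRP. Ties on the
    maximal distance resolve to the lexicographically first species name.
    """
    hit_species: dict[str, set[str]] = {}
    for r in best_hits:
        if r.subject_species == tree.focal:
            continue
        if r.subject_species not in tree._leaf_of:
            raise ValueError(f"hit species {r.subject_species!r} is not in the tree")
        hit_species.setdefault(r.query_id, set()).add(r.subject_species)
    out: list[StratumAssignment] = []
    for pid in protein_ids:
        species = hit_species.get(pid, set())
        if not species:
            out.append(StratumAssignment(pid, 0, None, True))
            continue
        deepest = max(sorted(species), key=tree.node_distance)
        out.append(StratumAssignment(pid, tree.node_distance(deepest), deepest, False))
    return out


def find_trps(assignments: Sequence[StratumAssignment]) -> set[str]:
    """The taxonomically restricted proteins: those with no non-focal hit."""
    return {a.protein_id for a in assignments if a.is_trp}


def strata_contingency(
    assignments: Sequence[StratumAssignment],
    categories: Mapping[str, str],
    strata_bins: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Count proteins per (category, stratum) into a table.

    Rows are categories, columns strata (ascending integer node distances),
    cells non-negative counts. *strata_bins* optionally maps each distance
    to a clade label (e.g. Formicidae / Hymenoptera / Insecta); binned
    columns keep the order of the smallest distance they contain.
    """
    missing = [a.protein_id for a in assignments if a.protein_id not in categories]
    if missing:
        raise ValueError(f"proteins without a category: {missing[:5]}")
    rows = []
    for a in assignments:
        stratum: int | str = a.node_distance
        if strata_bins is not None:
            if a.node_distance not in strata_bins:
                raise ValueError(f"node distance {a.node_distance} missing from strata_bins")
            stratum = strata_bins[a.node_distance]
        rows.append((categories[a.protein_id], stratum))
    df = pd.DataFrame(rows, columns=["category", "stratum"])
    table = pd.crosstab(df["category"], df["stratum"])
    if strata_bins is None:
        table = table[sorted(table.columns)]
    else:
        first_distance = {}
        for d in sorted(strata_bins):
            first_distance.setdefault(strata_bins[d], d)
        table = table[sorted(table.columns, key=lambda c: first_distance[c])]
    return table


def stratum_enrichment_test(
    table: pd.DataFrame,
    focal_category: str,
    background_category: str,
) -> tuple[float, int, float, float]:
    """Pearson chi-squared test of one category's stratum distribution
    against another's.

    Returns ``(chi2, df, p, padj)``. For a single comparison the BH-adjusted
    p equals the raw p; use :func:`stratum_enrichment_tests` to adjust
    across several comparisons of one run. All-zero strata columns are
    dropped before testing.
    """
    res = stratum_enrichment_tests(table, [(focal_category, background_category)])
    row = res.iloc[0]
    return float(row["chi2"]), int(row["df"]), float(row["p"]), float(row["padj"])


def stratum_enrichment_tests(
    table: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Run several category-vs-category chi-squared tests and BH-adjust the
    p-values across them (one run = one adjustment family)."""
    results = []
    for focal, background in comparisons:
        for cat in (focal, background):
            if cat not in table.index:
                raise ValueError(f"category {cat!r} not in table")
        sub = table.loc[[focal, background]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if (sub.sum(axis=1) == 0).any():
            raise ValueError("degenerate table: a category with zero total")
        if sub.shape[1] < 2:
            # identical support on one stratum: no departure measurable
            chi2, p, dof = 0.0, 1.0, 0
        else:
            chi2, p, dof, expected = stats.chi2_contingency(
                sub.to_numpy(), correction=False)
            if (expected < 1).any():
                raise ValueError(
                    "expected cell count < 1; merge strata into coarser bins")
        results.append({"focal": focal, "background": background,
                        "chi2": float(chi2), "df": int(dof), "p": float(p)})
    df = pd.DataFrame(results)
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
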