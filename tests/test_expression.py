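"""Count filters, NB test behaviour, set logic, upset counts, Fisher tests."""

import math
from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orstrat import (
    CountMatrix, DEResultRow, expression_restricted, fisher_enrichment,
    nb_de_test, proportion_fisher, prune_single_sample, upregulated_set,
    upregulated_vs_all, upset_counts,
)
from orstrat.synthetic_data import simulate_counts


def matrix(rows, samples=None, tissue_of=None):
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{j}" for j in range(n)]
    tissue_of = tissue_of or {s: "t" for s in samples}
    return CountMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                              columns=samples), tissue_of)


def de_row(g, lfc, padj, a="antennae", b="head"):
    p = 0.0 if math.isnan(padj) else min(padj, 1.0)
    return DEResultRow(gene_id=g, tissue_a=a, tissue_b=b, log2fc=lfc,
                       pvalue=p, padj=padj)


class TestPruneSingleSample:
    def test_one_detected_sample_removed(self):
        cm = matrix({"g1": [5, 0, 0, 0], "g2": [5, 1, 0, 0]})
        assert prune_single_sample(cm).gene_ids == ["g2"]

    def test_all_zero_removed(self):
        cm = matrix({"g1": [0, 0, 0], "g2": [1, 2, 0]})
        assert prune_single_sample(cm).gene_ids == ["g2"]

    def test_matches_nonzero_count_oracle(self, rng):
        counts = rng.poisson(0.7, size=(100, 14)).astype(float)
        cm = CountMatrix(pd.DataFrame(counts,
                                      index=[f"g{i}" for i in range(100)],
                                      columns=[f"s{j}" for j in range(14)]),
                         {f"s{j}": "t" for j in range(14)})
        survivors = set(prune_single_sample(cm).gene_ids)
        expected = {f"g{i}" for i in range(100) if (counts[i] > 0).sum() >= 2}
        assert survivors == expected


class TestExpressionRestricted:
    def build(self, focal_counts, other_counts):
        rows = {}
        for g in focal_counts:
            rows[g] = focal_counts[g] + other_counts[g]
        samples = ["a1", "a2", "h1", "h2", "l1"]
        tissue_of = {"a1": "antennae", "a2": "antennae",
                     "h1": "head", "h2": "head", "l1": "leg"}
        return matrix(rows, samples, tissue_of)

    def test_strictly_below_threshold_included(self):
        cm = self.build({"g1": [100, 90]}, {"g1": [9.9, 9.9, 9.9]})
        assert expression_restricted(cm, "antennae") == {"g1"}

    def test_boundary_value_excluded(self):
        cm = self.build({"g1": [100, 90]}, {"g1": [9, 9, 10]})
        assert expression_restricted(cm, "antennae") == set()

    def test_no_condition_on_focal_tissue(self):
        cm = self.build({"g1": [0, 0]}, {"g1": [0, 0, 0]})
        assert expression_restricted(cm, "antennae") == {"g1"}

    def test_focal_min_flag(self):
        cm = self.build({"g1": [0, 0], "g2": [50, 0]},
                        {"g1": [0, 0, 0], "g2": [0, 0, 0]})
        assert expression_restricted(cm, "antennae", focal_min=10) == {"g2"}

    def test_tissue_mean_semantics(self):
        # per-sample fails (one head sample at 12) but the head mean is 7
        cm = self.build({"g1": [100, 90]}, {"g1": [12, 2, 5]})
        assert expression_restricted(cm, "antennae") == set()
        assert expression_restricted(cm, "antennae", per_sample=False) == {"g1"}

    def test_matches_max_over_nonfocal_oracle(self, rng):
        counts = rng.uniform(0, 20, size=(50, 5))
        samples = ["a1", "a2", "h1", "h2", "l1"]
        tissue_of = {"a1": "antennae", "a2": "antennae",
                     "h1": "head", "h2": "head", "l1": "leg"}
        cm = CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(50)],
                                      columns=samples), tissue_of)
        got = expression_restricted(cm, "antennae")
        expected = {f"g{i}" for i in range(50) if counts[i, 2:].max() < 10}
        assert got == expected

    def test_unknown_focal_tissue_rejected(self):
        cm = matrix({"g1": [1, 2]})
        with pytest.raises(ValueError):
            expression_restricted(cm, "antennae")


class TestNbDeTest:
    def test_identical_groups_give_zero_lfc(self):
        cm = matrix({"g1": [10, 10, 10, 10], "g2": [50, 50, 50, 50],
                     "g3": [7, 7, 7, 7]},
                    ["a1", "a2", "b1", "b2"],
                    {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        for row in nb_de_test(cm, "A", "B"):
            assert row.log2fc == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        cm = matrix({"g1": [1, 2, 3]}, ["a1", "b1", "b2"],
                    {"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="2 samples"):
            nb_de_test(cm, "A", "B")

    def test_null_false_positive_rate(self):
        # all genes from one NB distribution in both groups
        cm, _ = simulate_counts(n_genes=2000, fold_change=1.0,
                                single_sample_fraction=0.0, seed=101)
        rows = nb_de_test(cm, "antennae", "head")
        fpr = np.mean([r.pvalue < 0.05 for r in rows])
        assert 0.03 <= fpr <= 0.07

    def test_power_on_planted_fold_change(self):
        cm, truth = simulate_counts(
            n_genes=1000, tissues=("antennae", "head"), replicates=(4, 4),
            upregulated_fraction=0.1, fold_change=4.0, nb_dispersion=0.05,
            restricted_fraction=0.0, single_sample_fraction=0.0, seed=202)
        rows = nb_de_test(cm, "antennae", "head")
        planted = truth.planted_upregulated["antennae"]
        hits = {r.gene_id for r in rows if r.padj < 0.05 and r.log2fc > 0}
        assert len(hits & planted) / len(planted) >= 0.90

    def test_bh_padj_dominates_p(self):
        cm, _ = simulate_counts(n_genes=300, fold_change=1.0, seed=7)
        rows = nb_de_test(cm, "antennae", "leg")
        assert all(r.padj >= r.pvalue - 1e-12 for r in rows)


class TestUpregulatedSetLogic:
    def test_conjunction_across_all_comparisons(self):
        results = {
            "head": [de_row("g1", 2.0, 0.01), de_row("g2", 2.0, 0.01)],
            "thorax": [de_row("g1", 1.5, 0.02, b="thorax"),
                       de_row("g2", 1.5, 0.3, b="thorax")],
            "leg": [de_row("g1", 0.5, 0.001, b="leg"),
                    de_row("g2", 0.5, 0.001, b="leg")],
        }
        # g2 significant in only 2 of 3 comparisons: excluded
        assert upregulated_vs_all(results) == {"g1"}

    def test_negative_lfc_excluded(self):
        results = {"head": [de_row("g1", -2.0, 0.001)]}
        assert upregulated_vs_all(results) == set()

    def test_nan_padj_never_passes(self):
        results = {"head": [de_row("g1", 2.0, math.nan)]}
        assert upregulated_vs_all(results) == set()

    def test_empty_tables_empty_set(self):
        assert upregulated_vs_all({"head": [], "leg": []}) == set()

    def test_missing_comparisons_rejected(self):
        with pytest.raises(ValueError):
            upregulated_vs_all({})

    def test_monotone_in_alpha(self, rng):
        rows = [de_row(f"g{i}", float(rng.normal()), float(rng.uniform()))
                for i in range(200)]
        results = {"head": rows}
        small = upregulated_vs_all(results, alpha=0.01)
        large = upregulated_vs_all(results, alpha=0.2)
        assert small <= large

    def test_matches_brute_force_intersection(self, rng):
        for _ in range(30):
            tissues = ["head", "thorax", "leg"]
            genes = [f"g{i}" for i in range(40)]
            results = {
                t: [de_row(g, float(rng.normal()), float(rng.uniform()), b=t)
                    for g in genes]
                for t in tissues
            }
            got = upregulated_vs_all(results, alpha=0.3)
            expected = set(genes)
            for t in tissues:
                expected &= {r.gene_id for r in results[t]
                             if r.log2fc > 0 and r.padj < 0.3}
            assert got == expected


class TestUpsetCounts:
    def test_identical_sets_single_full_signature(self):
        sets = {"a": {"g1"}, "b": {"g1"}, "c": {"g1"}}
        out = upset_counts(sets)
        assert out.exclusive[("a", "b", "c")] == 1
        assert sum(out.exclusive.values()) == 1

    def test_disjoint_singletons(self):
        sets = {"a": {"g1"}, "b": {"g2"}, "c": {"g3"}}
        out = upset_counts(sets)
        assert out.exclusive[("a",)] == out.exclusive[("b",)] == out.exclusive[("c",)] == 1
        assert out.exclusive[("a", "b", "c")] == 0

    def test_marginals_are_set_sizes(self):
        sets = {"a": {"g1", "g2"}, "b": {"g2"}}
        out = upset_counts(sets)
        assert out.marginals == {"a": 2, "b": 1}

    def test_signature_sum_equals_union_size(self, rng):
        genes = [f"g{i}" for i in range(60)]
        sets = {t: {g for g in genes if rng.random() < 0.4}
                for t in ("a", "b", "c", "d")}
        out = upset_counts(sets)
        assert sum(out.exclusive.values()) == len(set().union(*sets.values()))

    def test_matches_power_set_enumeration(self, rng):
        for _ in range(20):
            genes = [f"g{i}" for i in range(30)]
            names = ["a", "b", "c"]
            sets = {t: {g for g in genes if rng.random() < 0.5} for t in names}
            out = upset_counts(sets)
            for r in range(1, 4):
                for combo in combinations(names, r):
                    inside = set(genes)
                    for t in combo:
                        inside &= sets[t]
                    for t in set(names) - set(combo):
                        inside -= sets[t]
                    assert out.exclusive[combo] == len(inside)


def fisher_two_sided_oracle(a, b, c, d):
    """Full hypergeometric enumeration of the two-sided Fisher p."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, row1, col1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_tiny_table_two_sided_is_one(self):
        # [[1,0],[0,1]]: both tables have probability 1/2
        res = fisher_enrichment({"g1"}, {"g1"}, {"g1", "g2"})
        assert res.a == 1 and res.d == 1
        assert res.p == pytest.approx(1.0)

    def test_degenerate_everything_equal(self):
        u = {"g1", "g2"}
        res = fisher_enrichment(u, u, u)
        assert res.p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), set(), set())

    def test_cells_partition_universe(self, rng):
        genes = [f"g{i}" for i in range(50)]
        hit = {g for g in genes if rng.random() < 0.3}
        cat = {g for g in genes if rng.random() < 0.4}
        res = fisher_enrichment(hit, cat, set(genes))
        assert res.universe_size == 50

    def test_row_column_swap_symmetry(self):
        from orstrat.expression import _fisher_2x2
        assert _fisher_2x2(3, 7, 5, 11).p == pytest.approx(
            _fisher_2x2(11, 5, 7, 3).p, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            from orstrat.expression import _fisher_2x2
            assert abs(_fisher_2x2(a, b, c, d).p
                       - fisher_two_sided_oracle(a, b, c, d)) < 1e-10

    def test_odds_ratio_infinite_when_bc_zero(self):
        from orstrat.expression import _fisher_2x2
        assert math.isinf(_fisher_2x2(5, 0, 0, 5).odds_ratio)


class TestProportionFisher:
    def test_identical_proportions(self):
        assert proportion_fisher(1, 2, 1, 2).p == pytest.approx(1.0)

    def test_extreme_difference(self):
        res = proportion_fisher(10, 10, 0, 10)
        assert res.p == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10), abs=1e-12)
        assert res.p < 0.001

    def test_similar_proportions_not_significant(self):
        # 72/214 vs 125/358: near-identical shares
        res = proportion_fisher(72, 214, 125, 358)
        assert res.p == pytest.approx(
            fisher_two_sided_oracle(72, 142, 125, 233), abs=1e-10)
        assert res.p > 0.05

    def test_preconditions(self):
        with pytest.raises(ValueError):
            proportion_fisher(5, 3, 0, 1)
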