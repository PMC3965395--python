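from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircnv import (
    CnvRecord,
    MirnaGene,
    count_hits,
    gene_length,
    overlaps,
    summarize,
    union_length,
)
from tests.conftest import random_genes


class TestGeneLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(98511626, 98511727, 102), (98510798, 98510907, 110), (5, 5, 1)],
    )
    def test_inclusive_convention(self, start, end, expected):
        assert gene_length(MirnaGene("g", "1", start, end)) == expected


def brute_force_union(intervals):
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e + 1))
    return len(covered)


class TestUnionLength:
    def test_single_interval(self):
        assert union_length([CnvRecord("1", 100, 199, "Gain")]) == 100

    def test_disjoint_intervals_sum(self):
        cnvs = [CnvRecord("1", 100, 199, "Gain"), CnvRecord("1", 300, 399, "Gain")]
        assert union_length(cnvs) == 200

    def test_matches_per_base_oracle_on_random_intervals(self, rng):
        for _ in range(5):
            intervals = []
            for _ in range(50):
                s = int(rng.integers(1, 9_900))
                e = s + int(rng.integers(0, 400))
                intervals.append((s, min(e, 10_000)))
            cnvs = [CnvRecord("1", s, e, "Loss") for s, e in intervals]
            assert union_length(cnvs) == brute_force_union(intervals)

    def test_mixed_types_rejected(self):
        cnvs = [CnvRecord("1", 1, 5, "Gain"), CnvRecord("1", 2, 6, "Loss")]
        with pytest.raises(ValueError, match="one chromosome and one CNV type"):
            union_length(cnvs)

    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(0, 100)), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_split_invariance(self, raw, pyrandom):
        intervals = [(s, s + d) for s, d in raw]
        cnvs = [CnvRecord("1", s, e, "Gain") for s, e in intervals]
        base = union_length(cnvs)
        shuffled = list(cnvs)
        pyrandom.shuffle(shuffled)
        assert union_length(shuffled) == base
        # split the first interval at an interior point into two touching halves
        s, e = intervals[0]
        if e > s:
            cut = pyrandom.randint(s, e - 1)
            split = [CnvRecord("1", s, cut, "Gain"), CnvRecord("1", cut + 1, e, "Gain")] + cnvs[1:]
            assert union_length(split) == base


class TestOverlaps:
    def test_boundary_intersection(self):
        assert overlaps(CnvRecord("1", 100, 5000, "Loss"), MirnaGene("g", "1", 4990, 5080))

    def test_adjacency_is_not_overlap(self):
        assert not overlaps(CnvRecord("1", 100, 5000, "Loss"), MirnaGene("g", "1", 5001, 5090))

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="different chromosomes"):
            overlaps(CnvRecord("1", 1, 10, "Gain"), MirnaGene("g", "2", 1, 10))

    def test_exhaustive_small_intervals_match_set_oracle(self):
        pairs = [(a, b) for a in range(1, 7) for b in range(a, 7)]
        for (cs, ce) in pairs:
            for (ms, me) in pairs:
                cnv = CnvRecord("1", cs, ce, "Gain")
                gene = MirnaGene("g", "1", ms, me)
                expected_any = bool(set(range(cs, ce + 1)) & set(range(ms, me + 1)))
                expected_cont = set(range(ms, me + 1)) <= set(range(cs, ce + 1))
                assert overlaps(cnv, gene, "any") == expected_any
                assert overlaps(cnv, gene, "containment") == expected_cont


class TestCountHits:
    def test_empty_inputs(self):
        assert count_hits([], []) == (0, 0)

    def test_one_gene_in_two_cnvs_counts_twice(self):
        gene = MirnaGene("g", "1", 1000, 1099)
        cnvs = [CnvRecord("1", 500, 1500, "Loss"), CnvRecord("1", 900, 2000, "Loss")]
        assert count_hits(cnvs, [gene]) == (2, 1)

    def test_matches_nested_loop_oracle_on_random_fixture(self, rng):
        genes = random_genes(rng, 30, 50_000)
        cnvs = []
        for _ in range(20):
            s = int(rng.integers(1, 45_000))
            cnvs.append(CnvRecord("1", s, s + int(rng.integers(100, 5_000)), "Gain"))
        hits, unique = count_hits(cnvs, genes)
        oracle_hits = sum(
            1 for c in cnvs for g in genes if c.start <= g.end and c.end >= g.start
        )
        oracle_unique = len(
            {g.gene_id for g in genes for c in cnvs if c.start <= g.end and c.end >= g.start}
        )
        assert (hits, unique) == (oracle_hits, oracle_unique)
        assert unique <= hits

    def test_hits_additive_unique_subadditive_over_partition(self, rng):
        genes = random_genes(rng, 15, 20_000)
        cnvs = [
            CnvRecord("1", int(s), int(s) + 500, "Gain")
            for s in rng.integers(1, 19_000, size=12)
        ]
        hits_all, unique_all = count_hits(cnvs, genes)
        h1, u1 = count_hits(cnvs[:5], genes)
        h2, u2 = count_hits(cnvs[5:], genes)
        assert hits_all == h1 + h2
        assert unique_all <= u1 + u2

    def test_removing_a_cnv_never_increases_counts(self, rng):
        genes = random_genes(rng, 10, 20_000)
        cnvs = [
            CnvRecord("1", int(s), int(s) + 800, "Gain")
            for s in rng.integers(1, 19_000, size=8)
        ]
        hits_all, unique_all = count_hits(cnvs, genes)
        for excluded in range(len(cnvs)):
            subset = cnvs[:excluded] + cnvs[excluded + 1:]
            hits, unique = count_hits(subset, genes)
            assert hits <= hits_all and unique <= unique_all


class TestSummarize:
    def test_ratio_arithmetic_and_na_propagation(self, toy_genome, toy_genes, toy_cnvs):
        summaries = summarize(toy_genome, toy_genes, toy_cnvs)
        by_cell = {(s.chrom, s.cnv_type): s for s in summaries}
        s1_loss = by_cell[("1", "Loss")]
        # genes on chr1: 100 + 91 + 91 = 282 bp over a 10 kb chromosome
        assert s1_loss.L1 == 282
        assert s1_loss.R1 == pytest.approx(0.0282)
        # the two Loss CNVs [100,5000] and [4800,6000] merge into [100,6000]
        assert s1_loss.L2 == 5_901
        assert s1_loss.n_cnvs == 2
        # chr2 has Gains only: Loss row is N/A
        s2_loss = by_cell[("2", "Loss")]
        assert not s2_loss.has_data
        assert s2_loss.L2 is None and s2_loss.hits is None

    def test_hits_match_independent_recomputation(self, toy_genome, toy_genes, toy_cnvs):
        summaries = summarize(toy_genome, toy_genes, toy_cnvs)
        for s in summaries:
            if not s.has_data:
                continue
            cell = [c for c in toy_cnvs if c.chrom == s.chrom and c.cnv_type == s.cnv_type]
            genes = [g for g in toy_genes if g.chrom == s.chrom]
            assert (s.hits, s.unique) == count_hits(cell, genes)
            assert 0 <= s.R1 <= 1 and 0 <= s.R2 <= 1
            assert s.unique <= s.hits
            assert s.L2 <= sum(c.length for c in cell)

    def test_unknown_chromosome_rejected(self, toy_genome, toy_genes):
        stray = [CnvRecord("7", 1, 100, "Gain")]
        with pytest.raises(ValueError, match="absent from genome"):
            summarize(toy_genome, toy_genes, stray)

    def test_containment_mode_is_stricter(self, toy_genome, toy_genes, toy_cnvs):
        any_hits = sum(s.hits or 0 for s in summarize(toy_genome, toy_genes, toy_cnvs, "any"))
        cont_hits = sum(
            s.hits or 0 for s in summarize(toy_genome, toy_genes, toy_cnvs, "containment")
        )
        assert cont_hits <= any_hits
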