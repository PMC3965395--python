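import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircnv import (
    CnvRecord,
    EnrichmentResult,
    MirnaGene,
    bh_adjust,
    candidate_genes,
    correlate,
    population_filter,
    select_significant,
)
from mircnv.datasets import chromosome_summaries
from mircnv.overlap import ChromTypeSummary


def bh_reference(pvals):
    """Independent step-up reference: sort, scale by m/rank, cumulative min."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    scaled = [pvals[j] * m / (rank + 1) for rank, j in enumerate(order)]
    cummin = np.minimum.accumulate(scaled[::-1])[::-1]
    out = [0.0] * m
    for rank, j in enumerate(order):
        out[j] = min(1.0, cummin[rank])
    return out


class TestBhAdjust:
    def test_closed_form_three_values(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_reference_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 30))).tolist()
            assert bh_adjust(p) == pytest.approx(bh_reference(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        for (pa, aa) in zip(p, adj):
            assert aa >= pa - 1e-12
            assert 0 <= aa <= 1
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] <= p[j]:
                    assert adj[i] <= adj[j] + 1e-12


def result(chrom, cnv_type, p_fdr):
    return EnrichmentResult(chrom, cnv_type, 1, 1, p_fdr / 2, p_fdr, p_fdr < 0.05)


class TestSelectSignificant:
    def test_published_adjusted_pvalues_flag_three_cells(self):
        rows = [
            result("1", "Loss", 0.02309),
            result("2", "Loss", 0.00449),
            result("22", "Gain", 0.04349),
            result("22", "Loss", 0.07785),
        ]
        sig = select_significant(rows, alpha=0.05)
        assert [(r.chrom, r.cnv_type) for r in sig] == [
            ("1", "Loss"), ("2", "Loss"), ("22", "Gain"),
        ]

    def test_all_ones_empty(self):
        assert select_significant([result("1", "Gain", 1.0)]) == []

    def test_alpha_zero_strict_inequality(self):
        assert select_significant([result("1", "Gain", 0.0)], alpha=0.0) == []


def make_summary(chrom, cnv_type, r2, hits, n_cnvs=1):
    return ChromTypeSummary(
        chrom=chrom, cnv_type=cnv_type, chrom_length=1_000_000, n_genes=10,
        n_cnvs=n_cnvs, L1=1_000, R1=0.001,
        L2=int(r2 * 1_000_000) if n_cnvs else None,
        R2=r2 if n_cnvs else None,
        hits=hits if n_cnvs else None,
        unique=hits if n_cnvs else None,
    )


class TestCorrelate:
    def test_published_gain_and_loss_correlations(self):
        summaries = chromosome_summaries()
        gain = correlate(summaries, "Gain")
        loss = correlate(summaries, "Loss")
        assert gain.n_points == 19 and loss.n_points == 22
        assert gain.r == pytest.approx(0.75765, abs=1e-3)
        assert loss.r == pytest.approx(0.32732, abs=1e-3)

    def test_collinear_points_recover_exact_line(self):
        summaries = [make_summary(str(i), "Gain", 0.01 * i, 10 * i + 3) for i in range(1, 6)]
        res = correlate(summaries, "Gain")
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1_000.0)
        assert res.intercept == pytest.approx(3.0)

    def test_invariant_to_row_order_and_separate_affine_maps(self):
        base = [make_summary(str(i), "Loss", x, h) for i, (x, h) in
                enumerate([(0.01, 2), (0.05, 9), (0.02, 1), (0.08, 12), (0.03, 7)])]
        r0 = correlate(base, "Loss").r
        assert correlate(base[::-1], "Loss").r == pytest.approx(r0)
        mapped = [make_summary(s.chrom, "Loss", 3 * s.R2 + 0.5, 7 * s.hits + 11) for s in base]
        assert correlate(mapped, "Loss").r == pytest.approx(r0)

    def test_na_rows_excluded_and_too_few_points_error(self):
        summaries = [make_summary("1", "Gain", 0.1, 5), make_summary("2", "Gain", 0, 0, n_cnvs=0)]
        with pytest.raises(ValueError, match=">= 3"):
            correlate(summaries, "Gain")

    def test_zero_variance_error(self):
        summaries = [make_summary(str(i), "Gain", 0.05, i) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            correlate(summaries, "Gain")


class TestCandidatesAndPopulationFilter:
    def setup_method(self):
        self.genes = [
            MirnaGene("mir-1", "1", 1_000, 1_099),
            MirnaGene("mir-2", "1", 5_000, 5_080),
            MirnaGene("mir-3", "2", 2_000, 2_090),
        ]
        self.cnvs = [
            CnvRecord("1", 900, 1_200, "Loss", ("pA",)),
            CnvRecord("1", 950, 1_500, "Loss", ("pB",)),
            CnvRecord("2", 1_500, 2_500, "Gain", ("pA",)),
        ]
        self.sig = [result("1", "Loss", 0.01), result("2", "Gain", 0.02)]

    def test_candidates_pool_types_and_count_patients(self):
        cands = candidate_genes(self.genes, self.cnvs, self.sig)
        assert [c.gene.gene_id for c in cands] == ["mir-1", "mir-3"]
        mir1 = cands[0]
        assert mir1.cnv_types == ("Loss",)
        assert mir1.n_patients == 2

    def test_empty_population_all_study_specific(self):
        cands = candidate_genes(self.genes, self.cnvs, self.sig)
        flagged = population_filter(cands, [])
        assert all(c.in_population is False for c in flagged)

    def test_candidate_overlapping_population_deletion_flagged(self):
        cands = candidate_genes(self.genes, self.cnvs, self.sig)
        pop = [CnvRecord("1", 1_050, 3_000, "Loss", source="population")]
        flagged = population_filter(cands, pop)
        assert {c.gene.gene_id: c.in_population for c in flagged} == {
            "mir-1": True, "mir-3": False,
        }

    def test_24_candidates_2_study_specific_structure(self, rng):
        # 24 candidates; population CNVs tile all loci except two
        genes = [MirnaGene(f"mir-{i}", "1", 1_000 * i, 1_000 * i + 90) for i in range(1, 25)]
        cnvs = [CnvRecord("1", 500, 25_500, "Loss", (f"p{i}",)) for i in range(2)]
        sig = [result("1", "Loss", 0.001)]
        cands = candidate_genes(genes, cnvs, sig)
        assert len(cands) == 24
        avoid = {"mir-7", "mir-19"}
        pop = [
            CnvRecord("1", g.start - 10, g.end + 10, "Gain", source="population")
            for g in genes if g.gene_id not in avoid
        ]
        flagged = population_filter(cands, pop)
        specific = {c.gene.gene_id for c in flagged if not c.in_population}
        oracle = {
            g.gene_id for g in genes
            if not any(p.start <= g.end and p.end >= g.start for p in pop)
        }
        assert specific == avoid == oracle
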