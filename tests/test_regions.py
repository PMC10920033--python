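import numpy as np
import pytest
from scipy.stats import hypergeom

import conacc as cc
from conacc.intervals import GenomicInterval
from conacc.regions import ContingencyTable2x2
from conacc.scan import ElementCall


def call(start, end, kind="AR", category="intergenic", branch="A_sagrei",
         gene_ids=(), chrom="chr1"):
    return ElementCall(
        ref_interval=GenomicInterval(chrom, start, end),
        window_id=f"{chrom}:{start}-{end}",
        kind=kind, branch=None if kind == "all_branch_CE" else branch,
        q=0.01, category=category, gene_ids=frozenset(gene_ids),
    )


def coding_gene(gene_id, start, end, strand="+"):
    return cc.GeneModel(
        gene_id, gene_id, "protein_coding",
        GenomicInterval("chr1", start, end, strand),
    )


class TestOverlapFilter:
    def test_just_over_the_threshold_is_kept(self):
        w = call(0, 60)
        feats = [GenomicInterval("chr1", 0, 49)]  # 49/60 = 81.7%
        assert cc.overlap_filter([w], feats, 0.8) == [w]

    def test_exactly_at_the_threshold_is_dropped(self):
        w = call(0, 60)
        feats = [GenomicInterval("chr1", 0, 48)]  # 48/60 = 80.0%
        assert cc.overlap_filter([w], feats, 0.8) == []

    def test_zero_overlap_dropped_and_idempotent(self):
        w = call(0, 60)
        feats = [GenomicInterval("chr1", 100, 200)]
        assert cc.overlap_filter([w], feats, 0.8) == []
        kept = cc.overlap_filter([call(100, 160)], feats, 0.8)
        assert cc.overlap_filter(kept, feats, 0.8) == kept

    def test_overlapping_features_count_union_not_sum(self):
        w = call(0, 60)
        feats = [GenomicInterval("chr1", 0, 30), GenomicInterval("chr1", 0, 30)]
        assert cc.overlap_filter([w], feats, 0.8) == []

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            cc.overlap_filter([], [], 0.0)


class TestArCeOverlap:
    ces = [call(100, 160, kind="all_branch_CE")]

    def test_one_base_overlap_keeps_intergenic_ar(self):
        ar = call(41, 101)
        assert cc.ar_ce_overlap([ar], self.ces) == [ar]

    def test_intron_ar_without_ce_overlap_dropped(self):
        ar = call(300, 360, category="intron")
        assert cc.ar_ce_overlap([ar], self.ces) == []

    def test_cds_ar_passes_without_overlap(self):
        ar = call(300, 360, category="CDS")
        assert cc.ar_ce_overlap([ar], self.ces) == [ar]

    def test_idempotent(self):
        ars = [call(41, 101), call(300, 360, category="CDS")]
        once = cc.ar_ce_overlap(ars, self.ces)
        assert cc.ar_ce_overlap(once, self.ces) == once


class TestGeneFlanks:
    def test_plus_strand(self):
        up, down = cc.gene_flanks(coding_gene("g", 10_000, 12_000))
        assert (up.start, up.end) == (5_000, 10_000)
        assert (down.start, down.end) == (12_000, 17_000)

    def test_minus_strand_swaps_orientation(self):
        up, down = cc.gene_flanks(coding_gene("g", 10_000, 12_000, strand="-"))
        assert (up.start, up.end) == (12_000, 17_000)
        assert (down.start, down.end) == (5_000, 10_000)

    def test_clipping_at_chromosome_edges(self):
        up, down = cc.gene_flanks(coding_gene("g", 2_000, 3_000),
                                  chrom_length=4_000)
        assert (up.start, up.end) == (0, 2_000)
        assert (down.start, down.end) == (3_000, 4_000)
        up2, _ = cc.gene_flanks(coding_gene("g2", 1, 100))
        assert (up2.start, up2.end) == (0, 1)
        up3, _ = cc.gene_flanks(coding_gene("g3", 0, 100))
        assert up3 is None


class TestAssociateGenes:
    genes = [coding_gene("geneX", 20_000, 25_000)]

    def test_intergenic_ar_within_upstream_flank(self):
        ar = call(16_000, 16_060)  # 4 kb upstream of geneX
        table = cc.associate_genes([ar], [], self.genes, ce_overlap_required=False)
        assert table.by_category["upstream5kb"] == {"geneX"}

    def test_intron_ar_contributes_annotated_gene(self):
        ar = call(21_000, 21_060, category="intron", gene_ids={"geneX"})
        ces = [call(21_000, 21_060, kind="all_branch_CE")]
        table = cc.associate_genes([ar], ces, self.genes, ce_overlap_required=True)
        assert table.by_category["intron"] == {"geneX"}

    def test_far_intergenic_ar_contributes_nothing(self):
        ar = call(40_000, 40_060)  # 15 kb downstream
        table = cc.associate_genes([ar], [], self.genes, ce_overlap_required=False)
        assert table.all_genes() == set()

    def test_ce_requirement_drops_unsupported_intron_ar(self):
        ar = call(21_000, 21_060, category="intron", gene_ids={"geneX"})
        table = cc.associate_genes([ar], [], self.genes, ce_overlap_required=True)
        assert table.all_genes() == set()


class TestFisher:
    def test_enumeration_example(self):
        _, p = cc.fisher_enrichment(ContingencyTable2x2(2, 0, 0, 2), "greater")
        assert p == pytest.approx(1 / 6)

    def test_zero_margin_degenerate(self):
        _, p = cc.fisher_enrichment(ContingencyTable2x2(0, 0, 3, 4), "greater")
        assert p == 1.0

    def test_odds_ratio_infinite_when_bc_zero(self):
        orat, _ = cc.fisher_enrichment(ContingencyTable2x2(2, 0, 0, 2))
        assert orat == float("inf")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        _, p = cc.fisher_enrichment(ContingencyTable2x2(a, b, c, d), "greater")
        n = a + b + c + d
        expected = float(hypergeom.sf(a - 1, n, a + b, a + c))
        assert p == pytest.approx(expected, abs=1e-12)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        stat, dof, p = cc.chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0) and dof == 1 and p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        table = ContingencyTable2x2(30, 10, 10, 30)
        stat, dof, _ = cc.chi_square_2x2(table)
        # all expected counts are 20; sum of (O-E)^2/E = 4 * 100/20 = 20
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cc.chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestCommonGenes:
    def _assoc(self, lineage, cat_genes, window_genes):
        table = cc.GeneAssociationTable(lineage=lineage)
        for cat, genes in cat_genes.items():
            table.by_category[cat] |= set(genes)
        table.window_genes = {w: set(g) for w, g in window_genes.items()}
        return table

    def test_cross_category_common_gene(self):
        a = self._assoc("A", {"intron": {"geneX"}}, {"w1": {"geneX"}})
        b = self._assoc("B", {"upstream5kb": {"geneX"}}, {"w2": {"geneX"}})
        assert cc.common_accelerated_genes(a, b) == [("geneX", False)]

    def test_same_window_flag(self):
        a = self._assoc("A", {"CDS": {"geneY"}}, {"w1": {"geneY"}})
        b = self._assoc("B", {"CDS": {"geneY"}}, {"w1": {"geneY"}})
        assert cc.common_accelerated_genes(a, b) == [("geneY", True)]

    def test_single_lineage_gene_not_reported(self):
        a = self._assoc("A", {"CDS": {"geneZ"}}, {})
        b = self._assoc("B", {}, {})
        assert cc.common_accelerated_genes(a, b) == []

    def test_symmetry(self):
        a = self._assoc("A", {"CDS": {"g1", "g2"}}, {"w1": {"g1"}})
        b = self._assoc("B", {"intron": {"g1"}, "CDS": {"g2"}}, {"w1": {"g1"}})
        assert cc.common_accelerated_genes(a, b) == cc.common_accelerated_genes(b, a)


class TestSummaryReport:
    def test_percentages_recompute_from_integers(self):
        assert cc.percent(571_365_933, 1_081_644_591, 1) == 52.8
        assert cc.percent(50_570_632, 571_258_887, 2) == 8.85

    def test_report_on_synthetic_calls(self):
        plan = cc.plan_gene_cassette(n_repeats=2)
        ds = cc.generate_dataset(plan, seed=3)
        segments = cc.assign_annotation(ds.blocks, ds.genes)
        windows = cc.split_windows(segments)
        ces = [call(0, 60, kind="all_branch_CE")]
        report = cc.summary_report(
            aligned_bases=plan.length,
            reference_length=plan.length,
            windows=windows,
            ces=ces,
            ars_by_branch={"A_sagrei": []},
            ncrna_features=[g.span for g in ds.genes if g.is_ncrna],
        )
        assert report["coverage_pct"] == 100.0
        assert report["ce_total_length"] == 60
        assert report["ce_pct_of_alignment"] == cc.percent(60, plan.length, 2)
        assert set(report["category_base_fraction"]) == {
            "CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic"
        }
        assert sum(report["category_base_fraction"].values()) == pytest.approx(
            1.0, abs=0.01
        )
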