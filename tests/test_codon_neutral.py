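import numpy as np
import pytest

import conacc as cc
from conacc.codon_neutral import (
    AA_FAMILIES,
    FOURFOLD_PREFIXES,
    FourfoldSiteSet,
)
from conacc.model import MISSING


def uniform_counts(per_codon=10):
    return {c: per_codon for fam in AA_FAMILIES.values() for c in fam}


class TestRscu:
    def test_uniform_usage_gives_rscu_one_everywhere(self):
        table = cc.compute_rscu({"sp1": uniform_counts()})
        assert all(v == pytest.approx(1.0) for v in table.rscu["sp1"].values())

    def test_family_sums_equal_family_size(self):
        rng = np.random.default_rng(0)
        counts = {c: int(rng.integers(1, 50)) for c in uniform_counts()}
        table = cc.compute_rscu({"sp": counts})
        for fam in AA_FAMILIES.values():
            assert sum(table.rscu["sp"][c] for c in fam) == pytest.approx(len(fam))

    def test_concentrated_family(self):
        counts = uniform_counts()
        counts.update({"GGA": 4, "GGC": 0, "GGG": 0, "GGT": 0})
        table = cc.compute_rscu({"sp": counts})
        assert table.rscu["sp"]["GGA"] == pytest.approx(4.0)
        assert table.rscu["sp"]["GGC"] == 0.0

    def test_single_codon_families_are_always_one(self):
        table = cc.compute_rscu({"sp": {"ATG": 7, "TGG": 3}})
        assert table.rscu["sp"]["ATG"] == 1.0
        assert table.rscu["sp"]["TGG"] == 1.0

    def test_zero_count_family_reported_missing(self):
        table = cc.compute_rscu({"sp": {"ATG": 1}})
        assert "GGA" not in table.rscu["sp"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cc.compute_rscu({"sp": {"ATG": -1}})


class TestBiasFlags:
    def _table(self, rscu_value, codon="CTA"):
        counts = uniform_counts()
        table = cc.compute_rscu({"sp": counts})
        table.rscu["sp"][codon] = rscu_value
        return cc.flag_biased_codons(table)

    def test_boundaries_are_strict(self):
        assert self._table(0.6).biased["sp"]["CTA"] == "none"
        assert self._table(1.6).biased["sp"]["CTA"] == "none"

    def test_under_and_over(self):
        assert self._table(0.4).biased["sp"]["CTA"] == "under"
        assert self._table(1.7).biased["sp"]["CTA"] == "over"

    def test_study_bias_scenario_flags_exactly_five_codons(self):
        data = cc.generate_biased_codon_data(n_genes=200, seed=1)
        table = cc.flag_biased_codons(cc.compute_rscu(data.species_counts()))
        for sp in table.species:
            under = {c for c, f in table.biased[sp].items() if f == "under"}
            over = {c for c, f in table.biased[sp].items() if f == "over"}
            assert under == {"CTA", "TCG", "CCG", "ACG", "GCG"}
            assert over == set()


class TestFamilySelection:
    def test_study_scenario_retains_gt_cg_gg(self):
        data = cc.generate_biased_codon_data(n_genes=200, seed=1)
        table = cc.flag_biased_codons(cc.compute_rscu(data.species_counts()))
        assert cc.select_unbiased_4d_families(table) == {"GT", "CG", "GG"}

    def test_no_flags_keeps_all_eight_families(self):
        table = cc.flag_biased_codons(cc.compute_rscu({"sp": uniform_counts()}))
        assert cc.select_unbiased_4d_families(table) == set(FOURFOLD_PREFIXES)
        assert len(FOURFOLD_PREFIXES) == 8

    def test_single_over_flag_drops_its_family(self):
        table = cc.flag_biased_codons(cc.compute_rscu({"sp": uniform_counts()}))
        table.biased["sp"]["GGG"] = "over"
        assert "GG" not in cc.select_unbiased_4d_families(table)

    def test_adding_flags_never_grows_the_retained_set(self):
        table = cc.flag_biased_codons(cc.compute_rscu({"sp": uniform_counts()}))
        before = cc.select_unbiased_4d_families(table)
        table.biased["sp"]["ACG"] = "under"
        after = cc.select_unbiased_4d_families(table)
        assert after <= before

    def test_everything_biased_is_an_explicit_error(self):
        table = cc.flag_biased_codons(cc.compute_rscu({"sp": uniform_counts()}))
        for prefix in FOURFOLD_PREFIXES:
            table.biased["sp"][prefix + "A"] = "under"
        with pytest.raises(ValueError, match="threshold"):
            cc.select_unbiased_4d_families(table)


class TestExtract4d:
    taxa = ["s1", "s2", "s3"]

    def test_consistent_family_column_is_extracted(self):
        aln = [("g1", {"s1": "GGA", "s2": "GGC", "s3": "GGT"})]
        sites = cc.extract_4d_sites(aln, {"GG"}, taxa=self.taxa)
        assert sites.n_sites == 1
        assert sites.columns.tolist() == [[0, 1, 3]]  # A, C, T
        assert sites.source == [("g1", 0)]

    def test_prefix_mismatch_is_rejected(self):
        aln = [("g1", {"s1": "GTA", "s2": "GCA", "s3": "GTA"})]
        sites = cc.extract_4d_sites(aln, {"GT", "GC"}, taxa=self.taxa)
        assert sites.n_sites == 0

    def test_gapped_species_contributes_missing(self):
        aln = [("g1", {"s1": "GGA", "s2": "---", "s3": "GGT"})]
        sites = cc.extract_4d_sites(aln, {"GG"}, taxa=self.taxa)
        assert sites.columns.tolist() == [[0, MISSING, 3]]

    def test_non_family_column_is_skipped(self):
        aln = [("g1", {"s1": "ATGGGA", "s2": "ATGGGC", "s3": "ATGGGT"})]
        sites = cc.extract_4d_sites(aln, {"GG"}, taxa=self.taxa)
        assert sites.n_sites == 1 and sites.source == [("g1", 1)]

    def test_out_of_frame_alignment_raises(self):
        with pytest.raises(ValueError, match="frame"):
            cc.extract_4d_sites([("g1", {"s1": "GGAA"})], {"GG"}, taxa=["s1"])


class TestNeutralFit:
    def test_identical_sequences_give_near_zero_branches(self):
        tree = cc.PhyloTree.from_newick("(A:0.1,B:0.1);")
        cols = np.zeros((1000, 2), dtype=np.int8)
        cols[:500, :] = 2
        sites = FourfoldSiteSet(taxa=["A", "B"], columns=cols)
        fit = cc.fit_neutral_model(sites, tree, max_sweeps=5)
        free = [n for n in range(fit.tree.n_nodes) if n != fit.tree.root]
        assert all(fit.tree.lengths[n] <= 1e-6 for n in free)

    def test_fitted_likelihood_dominates_generating_model(self):
        rng = np.random.default_rng(2)
        tree = cc.PhyloTree.from_newick(
            "((A:0.08,B:0.12):0.05,(C:0.2,D:0.07):0.04);"
        )
        model = cc.default_model()
        cols = cc.simulate_columns(tree, model, 3000, 21)
        sites = FourfoldSiteSet(taxa=tree.leaf_labels, columns=cols)
        fit = cc.fit_neutral_model(sites, tree, max_sweeps=8)
        assert fit.log_likelihood >= cc.log_likelihood(tree, model, cols) - 1e-6

    def test_likelihood_invariant_to_taxon_and_column_order(self):
        tree = cc.PhyloTree.from_newick("((A:0.1,B:0.1):0.05,C:0.15);")
        model = cc.default_model()
        cols = cc.simulate_columns(tree, model, 400, 3)
        base = cc.log_likelihood(tree, model, cols)
        rng = np.random.default_rng(0)
        assert cc.log_likelihood(
            tree, model, cols[rng.permutation(len(cols))]
        ) == pytest.approx(base, abs=1e-8)
        # reorder taxa consistently in tree and matrix
        tree2 = cc.PhyloTree.from_newick("(C:0.15,(B:0.1,A:0.1):0.05);")
        idx = [tree.leaf_labels.index(t) for t in tree2.leaf_labels]
        assert cc.log_likelihood(tree2, model, cols[:, idx]) == pytest.approx(
            base, abs=1e-8
        )

    def test_missing_taxon_in_sites_is_an_error(self):
        sites = FourfoldSiteSet(taxa=["A", "B"], columns=np.zeros((5, 2), np.int8))
        tree = cc.PhyloTree.from_newick("((A:0.1,B:0.1):0.05,C:0.15);")
        with pytest.raises(ValueError, match="lacks"):
            cc.fit_neutral_model(sites, tree)
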