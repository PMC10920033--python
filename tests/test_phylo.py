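import numpy as np
import pytest

import conacc as cc
from conacc.model import MISSING, SubstModel, discrete_gamma_rates, encode_sequences
from conacc.phylo import ScaledTree, UninformativeWindowError

from conftest import brute_force_log_likelihood, random_model, random_small_tree


class TestModel:
    def test_rate_matrix_rows_sum_to_zero_and_rate_is_one(self):
        m = cc.default_model()
        q = m.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0)
        assert np.isclose(-np.dot(m.pi, np.diag(q)), 1.0)

    def test_transition_matrices_are_stochastic_and_identity_at_zero(self):
        m = random_model(np.random.default_rng(3))
        p = m.transition_matrices([0.0, 0.1, 2.0])
        assert np.allclose(p.sum(axis=2), 1.0)
        assert np.allclose(p[0], np.eye(4), atol=1e-12)

    def test_detailed_balance(self):
        m = random_model(np.random.default_rng(4))
        p = m.transition_matrices([0.3])[0]
        flux = m.pi[:, None] * p
        assert np.allclose(flux, flux.T)

    def test_discrete_gamma_rates_average_to_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert np.isclose(rates.mean(), 1.0, atol=1e-9)
            assert np.all(np.diff(rates) > 0)

    def test_encode_sequences_round_trip(self):
        cols = encode_sequences(["ACGTN-", "NNACGT"])
        assert cols.shape == (6, 2)
        assert cols[4, 0] == MISSING and cols[5, 0] == MISSING


class TestLogLikelihood:
    def test_single_leaf_closed_form(self):
        t = cc.PhyloTree.from_newick("(A:0.1);")
        m = SubstModel.jukes_cantor()
        cols = np.array([[0]], dtype=np.int8)
        assert cc.log_likelihood(t, m, cols) == pytest.approx(np.log(0.25))

    def test_two_leaf_jc_closed_form(self):
        t_total = 0.37
        tree = cc.PhyloTree.from_newick(f"(A:{t_total / 2},B:{t_total / 2});")
        m = SubstModel.jukes_cantor()
        match = np.array([[2, 2]], dtype=np.int8)
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t_total / 3)))
        assert cc.log_likelihood(tree, m, match) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_small_tree(rng, int(rng.integers(3, 6)))
        model = random_model(rng, gamma=bool(seed % 2))
        cols = rng.integers(0, 5, size=(6, tree.n_leaves)).astype(np.int8)
        got = cc.log_likelihood(tree, model, cols)
        want = brute_force_log_likelihood(tree, model, cols)
        assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_rerooting_for_reversible_model(self):
        m = random_model(np.random.default_rng(9))
        # same unrooted tree: internal edge of 0.12 split differently by the root
        t1 = cc.PhyloTree.from_newick("((A:0.1,B:0.2):0.06,(C:0.3,D:0.1):0.06);")
        t2 = cc.PhyloTree.from_newick("((A:0.1,B:0.2):0.0,(C:0.3,D:0.1):0.12);")
        cols = np.random.default_rng(0).integers(0, 4, (40, 4)).astype(np.int8)
        assert cc.log_likelihood(t1, m, cols) == pytest.approx(
            cc.log_likelihood(t2, m, cols), abs=1e-9
        )

    def test_result_is_negative_and_missing_marginalised(self, tree8, model):
        cols = np.full((5, 8), MISSING, dtype=np.int8)
        cols[:, 0] = 1
        lnl = cc.log_likelihood(tree8, model, cols)
        # only one informative taxon: likelihood is just pi_C per column
        assert lnl == pytest.approx(5 * np.log(model.pi[1]))


class TestScaleFitting:
    def test_global_scale_recovered_at_neutral(self, tree8, model):
        cols = cc.simulate_columns(tree8, model, 5000, 42)
        rho, lnl = cc.fit_global_scale(tree8, model, cols)
        assert 0.9 <= rho <= 1.1
        assert lnl >= cc.log_likelihood(tree8, model, cols) - 1e-9

    def test_invariant_columns_drive_scale_to_lower_bound(self, tree8, model):
        cols = np.zeros((50, 8), dtype=np.int8)
        rho, _ = cc.fit_global_scale(tree8, model, cols)
        assert rho < 1e-4

    def test_branch_scale_recovery(self, tree8, model):
        st = ScaledTree(tree8, branch_scales={"A_sagrei": 5.0})
        cols = cc.simulate_columns(st, model, 2000, 7)
        lam, lnl = cc.fit_branch_scale(tree8, model, cols, "A_sagrei")
        assert 3.0 <= lam <= 8.0
        assert lnl >= cc.log_likelihood(tree8, model, cols) - 1e-9

    def test_branch_scale_near_one_under_neutrality(self, tree8, model):
        cols = cc.simulate_columns(tree8, model, 5000, 8)
        lam, _ = cc.fit_branch_scale(tree8, model, cols, "A_sagrei")
        assert 0.7 <= lam <= 1.4

    def test_internal_branch_can_be_targeted(self, tree8, model):
        st = ScaledTree(tree8, branch_scales={"TC_open": 8.0})
        cols = cc.simulate_columns(st, model, 2000, 13)
        lam, _ = cc.fit_branch_scale(tree8, model, cols, "TC_open")
        assert lam > 3.0

    def test_all_missing_window_raises(self, tree8, model):
        cols = np.full((10, 8), MISSING, dtype=np.int8)
        with pytest.raises(UninformativeWindowError):
            cc.fit_global_scale(tree8, model, cols)

    def test_one_sided_missing_raises_for_branch_test(self, tree8, model):
        cols = cc.simulate_columns(tree8, model, 10, 3)
        cols[:, tree8.leaf_labels.index("A_sagrei")] = MISSING
        with pytest.raises(UninformativeWindowError):
            cc.fit_branch_scale(tree8, model, cols, "A_sagrei")


class TestSimulation:
    def test_zero_branch_lengths_give_identical_columns(self, model):
        t = cc.default_tree(branch_length=0.0)
        cols = cc.simulate_columns(t, model, 100, 1)
        assert (cols == cols[:, :1]).all()

    def test_pairwise_mismatch_matches_closed_form(self):
        t_total = 0.3
        tree = cc.PhyloTree.from_newick(f"(A:{t_total / 2},B:{t_total / 2});")
        m = SubstModel.jukes_cantor()
        n = 100_000
        cols = cc.simulate_columns(tree, m, n, 123)
        mismatch = float((cols[:, 0] != cols[:, 1]).mean())
        expected = 0.75 * (1 - np.exp(-4 * t_total / 3))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(mismatch - expected) < 3 * se

    def test_same_seed_is_deterministic(self, tree8, model):
        a = cc.simulate_columns(tree8, model, 200, 77)
        b = cc.simulate_columns(tree8, model, 200, 77)
        assert (a == b).all()

    def test_gamma_rate_variation_changes_site_pattern_dispersion(self, tree8):
        flat = cc.default_model()
        bursty = SubstModel(pi=flat.pi, exch=flat.exch,
                            gamma_shape=0.2, n_rate_categories=4)
        rng_cols = cc.simulate_columns(tree8, bursty, 3000, 5)
        flat_cols = cc.simulate_columns(tree8, flat, 3000, 5)
        # strongly skewed rates make more columns fully invariant
        inv_bursty = ((rng_cols == rng_cols[:, :1]).all(axis=1)).mean()
        inv_flat = ((flat_cols == flat_cols[:, :1]).all(axis=1)).mean()
        assert inv_bursty > inv_flat
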