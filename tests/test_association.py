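"""Spearman/PGLS association, BKY FDR, and signed-set calling."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from lifecon.association import (
    AssociationRecord,
    AssociationTable,
    DegenerateInputError,
    bky_fdr,
    call_signed_set,
    filter_min_species,
    merge_method_calls,
    pgls_ensemble,
    pgls_fit,
    spearman_association,
)
from lifecon.core_io import ExpressionMatrix, PhyloTreeEnsemble, SignedGeneSet
from lifecon.synthetic import simulate_tree


def spearman_exact_oracle(x, y):
    """Independent enumeration oracle: two-sided permutation p for rho."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total


class TestFilterMinSpecies:
    def _matrix(self, observed_counts, n_species=12):
        values = np.full((len(observed_counts), n_species), np.nan)
        for i, k in enumerate(observed_counts):
            values[i, :k] = float(i + 1)
        return ExpressionMatrix(
            [f"g{i}" for i in range(len(observed_counts))],
            [f"s{j}" for j in range(n_species)],
            values,
        )

    def test_boundary_inclusive_at_ten(self):
        expr = self._matrix([9, 10, 11])
        out = filter_min_species(expr, 10)
        assert out.gene_ids == ["g1", "g2"]

    def test_fully_observed_identity(self):
        expr = self._matrix([12, 12])
        out = filter_min_species(expr, 10)
        assert out.gene_ids == expr.gene_ids
        np.testing.assert_array_equal(out.values, expr.values)

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            filter_min_species(self._matrix([3, 4]), 10)


class TestSpearman:
    def test_perfect_monotone_n5_exact_p(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([10.0, 20, 30, 40, 50])
        rho, p = spearman_association(x, y)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_antisymmetry(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rho, _ = spearman_association(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman_association(np.ones(5), np.arange(5.0))

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([2.0, 4, 6, np.nan, 10, 12])
        rho, _ = spearman_association(x, y)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration(self, n, rng):
        for _ in range(5):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rho, p = spearman_association(x, y)
            rho_o, p_o = spearman_exact_oracle(x, y)
            assert rho == pytest.approx(rho_o)
            assert p == pytest.approx(p_o)

    def test_exact_p_with_ties_matches_enumeration(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 4.0])
        y = rng.standard_normal(6)
        rho, p = spearman_association(x, y)
        rho_o, p_o = spearman_exact_oracle(x, y)
        assert rho == pytest.approx(rho_o)
        assert p == pytest.approx(p_o)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.standard_normal(20)
        y = x + rng.standard_normal(20)
        rho, p = spearman_association(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def whitened_ols_oracle(y, x, V):
    """Independent PGLS oracle: Cholesky-whiten, then plain OLS."""
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, np.column_stack([np.ones_like(x), x]))
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), df=len(y) - 2)
    return beta[1], se, p


class TestPgls:
    def test_identity_covariance_equals_ols(self, rng):
        x = rng.standard_normal(12)
        y = 1.5 * x + rng.standard_normal(12)
        fit = pgls_fit(y, x, np.eye(12))
        ols = sps.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-8)
        assert fit.slope_se == pytest.approx(ols.stderr, abs=1e-8)
        assert fit.p == pytest.approx(ols.pvalue, abs=1e-8)

    def test_perfect_fit(self, three_taxon_tree):
        from lifecon.core_io import phylo_covariance

        V = phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        x = np.array([1.0, 2.0, 3.0])
        fit = pgls_fit(x, x, V)
        assert fit.slope == pytest.approx(1.0)
        assert fit.p == pytest.approx(0.0)

    def test_matches_whitening_oracle(self, rng):
        from lifecon.core_io import phylo_covariance

        for seed in range(10):
            n = int(rng.integers(3, 11))
            tree = simulate_tree(max(n, 3), seed)
            sp = tree.leaf_labels[:n]
            V = phylo_covariance(tree, sp) + 1e-9 * np.eye(n)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            fit = pgls_fit(y, x, V)
            slope_o, se_o, p_o = whitened_ols_oracle(y, x, V)
            assert fit.slope == pytest.approx(slope_o, abs=1e-8)
            assert fit.slope_se == pytest.approx(se_o, abs=1e-8)
            assert fit.p == pytest.approx(p_o, abs=1e-8)

    def test_singular_design_rejected(self):
        with pytest.raises(DegenerateInputError):
            pgls_fit(np.arange(4.0), np.ones(4), np.eye(4))


class TestPglsEnsemble:
    def test_identical_trees_equal_single_fit(self, rng):
        tree = simulate_tree(8, seed=1)
        ens = PhyloTreeEnsemble([tree, tree, tree])
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        from lifecon.core_io import phylo_covariance

        single = pgls_fit(y, x, phylo_covariance(tree, tree.leaf_labels))
        combined = pgls_ensemble(y, x, ens, tree.leaf_labels)
        assert combined.p_max == pytest.approx(single.p)
        assert combined.slope == pytest.approx(single.slope)

    def test_max_p_across_two_trees(self, rng):
        from lifecon.core_io import phylo_covariance
        from lifecon.synthetic import simulate_tree_ensemble

        ens = simulate_tree_ensemble(8, 2, seed=2, jitter_sd=0.5)
        sp = ens.leaf_labels
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        ps = [pgls_fit(y, x, phylo_covariance(t, sp)).p for t in ens]
        combined = pgls_ensemble(y, x, ens, sp)
        assert combined.p_max == pytest.approx(max(ps))

    def test_p_max_monotone_in_ensemble_size(self, rng):
        from lifecon.synthetic import simulate_tree_ensemble

        ens = simulate_tree_ensemble(8, 6, seed=3, jitter_sd=0.3)
        sp = ens.leaf_labels
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        last = 0.0
        for k in range(1, 7):
            sub = PhyloTreeEnsemble(ens.trees[:k])
            p = pgls_ensemble(y, x, sub, sp).p_max
            assert p >= last - 1e-15
            last = p


class TestBkyFdr:
    def test_hand_worked_example(self):
        rejected, q = bky_fdr([0.01, 0.02, 0.5, 0.6], q=0.10)
        assert list(rejected) == [True, True, False, False]

    def test_all_ones_no_rejections(self):
        rejected, q = bky_fdr(np.ones(10), q=0.10)
        assert not rejected.any()
        assert (q == 1.0).all()

    def test_q_values_monotone_in_p(self, rng):
        p = rng.random(50)
        _, q = bky_fdr(p, q=0.10)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejections_superset_of_bh_on_mixed_signal(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = np.concatenate([rng.random(80), rng.random(20) * 1e-4])
            rej_bky, _ = bky_fdr(p, q=0.10)
            rej_bh = multipletests(p, alpha=0.10, method="fdr_bh")[0]
            assert (rej_bky | ~rej_bh).all()

    def test_matches_statsmodels_two_stage(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = np.concatenate([rng.random(60), rng.random(15) * 1e-3])
            rej, _ = bky_fdr(p, q=0.10)
            rej_sm = multipletests(p, alpha=0.10, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(rej, rej_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bky_fdr([0.5, 1.2])


class TestCallAndMerge:
    def _table(self, gene_q_sign):
        records = [
            AssociationRecord(g, "spearman", s * 1.0, q / 2, 12, q_value=q)
            for g, q, s in gene_q_sign
        ]
        return AssociationTable(records)

    def test_threshold_strictly_below(self):
        table = self._table([("g1", 0.05, 1), ("g2", 0.15, -1), ("g3", 0.10, 1)])
        called = call_signed_set(table, 0.10)
        assert called.entries == {"g1": 1}  # q == 0.10 excluded

    def test_empty_table(self):
        assert len(call_signed_set(AssociationTable([]), 0.10)) == 0

    def test_sign_inconsistent_record_excluded(self, caplog):
        rec = AssociationRecord("g1", "pgls", 2.0, 0.001, 12, q_value=0.001,
                                sign_consistent=False)
        with caplog.at_level("WARNING"):
            called = call_signed_set(AssociationTable([rec]), 0.10)
        assert len(called) == 0

    def test_merge_disjoint_union(self):
        a = SignedGeneSet({"g1": 1, "g2": -1, "g3": 1})
        b = SignedGeneSet({"g4": 1, "g5": -1})
        assert len(merge_method_calls(a, b)) == 5

    def test_merge_idempotent_same_sign(self):
        a = SignedGeneSet({"g1": 1})
        b = SignedGeneSet({"g1": 1})
        assert merge_method_calls(a, b).entries == {"g1": 1}

    def test_merge_conflicting_sign_excluded(self, caplog):
        a = SignedGeneSet({"g1": 1, "g2": 1})
        b = SignedGeneSet({"g1": -1})
        with caplog.at_level("WARNING"):
            merged = merge_method_calls(a, b)
        assert merged.entries == {"g2": 1}
        assert "opposite signs" in caplog.text
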