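"""Readers, writers, and the phylogenetic covariance primitives."""

import numpy as np
import pytest

from lifecon.core_io import (
    ConsistencyError,
    FormatError,
    MotifModel,
    PhyloTree,
    SignedGeneSet,
    phylo_covariance,
    prune_tree,
    read_expression_tsv,
    read_fasta_promoters,
    read_jaspar_pfm,
    read_newick_ensemble,
    read_signed_gene_set,
    write_expression_tsv,
    write_fasta_promoters,
    write_signed_gene_set,
)


class TestExpressionTsv:
    def test_parse_with_missing(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text(
            "gene\ts1\ts2\ts3\ts4\n"
            "g1\t1.5\t2.0\tNA\t0.25\n"
            "g2\t-1\t0\t3\t4\n"
            "g3\t\t1\t1\t1\n"
        )
        expr = read_expression_tsv(path)
        assert expr.gene_ids == ["g1", "g2", "g3"]
        assert expr.species_ids == ["s1", "s2", "s3", "s4"]
        assert np.isnan(expr.values[0, 2]) and np.isnan(expr.values[2, 0])
        assert expr.mask.sum() == 10
        assert list(expr.n_observed) == [3, 4, 3]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(FormatError, match="duplicate gene"):
            read_expression_tsv(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ng1\thello\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_expression_tsv(path)

    def test_round_trip_full_precision(self, tmp_path, rng):
        from lifecon.core_io import ExpressionMatrix

        values = rng.standard_normal((5, 4))
        values[1, 2] = np.nan
        expr = ExpressionMatrix([f"g{i}" for i in range(5)], list("wxyz"), values)
        path = tmp_path / "rt.tsv"
        write_expression_tsv(expr, path)
        back = read_expression_tsv(path)
        assert back.gene_ids == expr.gene_ids
        assert back.species_ids == expr.species_ids
        np.testing.assert_array_equal(back.values, expr.values)


class TestNewickEnsemble:
    def test_single_tree_parse(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        ens = read_newick_ensemble(path)
        assert len(ens) == 1
        V = phylo_covariance(ens.trees[0], ["A", "B", "C"])
        np.testing.assert_allclose(np.diag(V), [2, 2, 2])

    def test_differing_leaf_sets_rejected(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:1,B:1):1,D:2);\n")
        with pytest.raises(ConsistencyError):
            read_newick_ensemble(path)

    def test_hundred_identical_lines(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n" * 100)
        assert len(read_newick_ensemble(path)) == 100

    def test_unparsable_newick(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1:1,C;\n")
        with pytest.raises(FormatError):
            read_newick_ensemble(path)


class TestJasparPfm:
    def test_width1_no_pseudocount(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(">M1 test\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        (m,) = read_jaspar_pfm(path, pseudocount=0.0)
        np.testing.assert_allclose(m.frequencies[:, 0], [1, 0, 0, 0])
        assert m.log_odds[0, 0] == pytest.approx(2.0)  # log2(1 / 0.25)

    def test_width1_pseudocount_one(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(">M1 test\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        (m,) = read_jaspar_pfm(path, pseudocount=1.0)
        assert m.frequencies[0, 0] == pytest.approx(11 / 14)

    def test_multi_motif_order_preserved(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">M1 one\nA [ 1 2 ]\nC [ 1 0 ]\nG [ 1 0 ]\nT [ 1 2 ]\n"
            ">M2 two\nA [ 5 ]\nC [ 5 ]\nG [ 0 ]\nT [ 0 ]\n"
        )
        models = read_jaspar_pfm(path)
        assert [m.motif_id for m in models] == ["M1", "M2"]
        assert [m.width for m in models] == [2, 1]

    def test_frequency_columns_normalized(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(">M1 t\nA [ 3 1 ]\nC [ 1 1 ]\nG [ 0 1 ]\nT [ 0 1 ]\n")
        (m,) = read_jaspar_pfm(path, pseudocount=0.5)
        np.testing.assert_allclose(m.frequencies.sum(axis=0), [1.0, 1.0])


class TestFastaPromoters:
    def test_two_records(self, tmp_path):
        path = tmp_path / "p.fa"
        path.write_text(">g1|sp1\nACGT\n>g2|sp1\nacgt\n")
        prom = read_fasta_promoters(path)
        assert prom[("g1", "sp1")] == "ACGT"
        assert prom[("g2", "sp1")] == "ACGT"  # lowercase normalized

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "p.fa"
        path.write_text(">g1|sp1\nACGT\n>g1|sp1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta_promoters(path)

    def test_non_iupac_rejected_and_ambiguity_to_n(self, tmp_path):
        path = tmp_path / "p.fa"
        path.write_text(">g1|sp1\nACRGT\n")
        assert read_fasta_promoters(path)[("g1", "sp1")] == "ACNGT"
        path.write_text(">g1|sp1\nAC9GT\n")
        with pytest.raises(FormatError):
            read_fasta_promoters(path)

    def test_round_trip(self, tmp_path):
        prom = {("g1", "sp1"): "ACGT" * 30, ("g2", "sp2"): "NNNA"}
        path = tmp_path / "p.fa"
        write_fasta_promoters(prom, path)
        assert read_fasta_promoters(path) == prom


class TestSignedGeneSet:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("g1\t+\ng2\t-\n")
        s = read_signed_gene_set(path)
        assert s.entries == {"g1": 1, "g2": -1}

    def test_conflicting_signs_dropped(self, tmp_path, caplog):
        path = tmp_path / "s.tsv"
        path.write_text("g1\t+\ng1\t-1\n")
        with caplog.at_level("WARNING"):
            s = read_signed_gene_set(path)
        assert len(s) == 0
        assert "both signs" in caplog.text

    def test_unknown_token_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("g1\tup\n")
        with pytest.raises(FormatError):
            read_signed_gene_set(path)

    def test_round_trip(self, tmp_path):
        s = SignedGeneSet({"g1": 1, "g2": -1, "g3": 1}, {"trait": "mls"})
        path = tmp_path / "s.tsv"
        write_signed_gene_set(s, path)
        assert read_signed_gene_set(path).entries == s.entries

    def test_empty_set_round_trip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_signed_gene_set(SignedGeneSet({}, {"trait": "mls"}), path)
        assert len(read_signed_gene_set(path)) == 0


class TestTreeOps:
    def test_covariance_hand_example(self, three_taxon_tree):
        V = phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        np.testing.assert_allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_diagonal(self):
        star = PhyloTree.from_newick("(A:1.5,B:1.5,C:1.5,D:1.5);")
        V = phylo_covariance(star, ["A", "B", "C", "D"])
        np.testing.assert_allclose(V, 1.5 * np.eye(4))

    def test_ultrametric_constant_diagonal(self, three_taxon_tree):
        V = phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        assert np.ptp(np.diag(V)) == 0

    def test_unknown_species_rejected(self, three_taxon_tree):
        with pytest.raises(ValueError, match="not in tree"):
            phylo_covariance(three_taxon_tree, ["A", "Z"])

    def test_prune_identity(self, three_taxon_tree):
        pruned = prune_tree(three_taxon_tree, {"A", "B", "C"})
        V0 = phylo_covariance(three_taxon_tree, ["A", "B", "C"])
        V1 = phylo_covariance(pruned, ["A", "B", "C"])
        np.testing.assert_allclose(V0, V1)

    def test_prune_preserves_path_lengths(self, four_taxon_tree):
        # root-to-tip oracle: sum of edge lengths on the leaf's ancestor path
        def depths(tree):
            out = {}
            for leaf in tree.tree.leaf_node_iter():
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length or 0.0
                    node = node.parent_node
                out[leaf.taxon.label] = d
            return out

        before = depths(four_taxon_tree)
        pruned = prune_tree(four_taxon_tree, {"A", "B", "D"})
        after = depths(pruned)
        for sp in ("A", "B", "D"):
            assert after[sp] == pytest.approx(before[sp])
        # shared-branch covariance entries also preserved exactly
        V0 = phylo_covariance(four_taxon_tree, ["A", "B", "D"])
        V1 = phylo_covariance(pruned, ["A", "B", "D"])
        np.testing.assert_allclose(V0, V1)

    def test_prune_too_few_or_not_subset(self, three_taxon_tree):
        with pytest.raises(ValueError):
            prune_tree(three_taxon_tree, {"A", "B"})
        with pytest.raises(ValueError):
            prune_tree(three_taxon_tree, {"A", "B", "Z"})

    def test_covariance_psd_on_random_trees(self):
        from lifecon.synthetic import simulate_tree

        for seed in range(5):
            tree = simulate_tree(10, seed)
            V = phylo_covariance(tree, tree.leaf_labels)
            np.testing.assert_allclose(V, V.T)
            np.linalg.cholesky(V + 1e-10 * np.eye(10))


class TestMotifModelInvariants:
    def test_log_odds_definition(self, rng):
        freqs = rng.dirichlet(np.ones(4), size=5).T
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        m = MotifModel("M", freqs, bg)
        np.testing.assert_allclose(m.log_odds, np.log2(freqs / bg[:, None]))

    def test_reverse_complement_width1(self, width1_A_motif):
        rc = width1_A_motif.reverse_complement()
        np.testing.assert_allclose(rc.frequencies[:, 0], [0, 0, 0, 1])  # T
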