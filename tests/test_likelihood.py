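import numpy as np
import pytest

from phyloconflict.likelihood import (
    TreeLikelihood,
    log_likelihood,
    optimize_branch_lengths,
)
from phyloconflict.models import SubstitutionModel
from phyloconflict.seqio import GeneAlignment
from phyloconflict.synthetic import simulate_alignment
from phyloconflict.trees import PhyloTree

from conftest import brute_force_loglik, random_alignment


class TestPruningOracle:
    def test_single_site_stationary(self):
        aln = GeneAlignment("x", {"A": "C", "B": "C"})
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        result = log_likelihood(aln, tree, SubstitutionModel("JC"))
        assert result.total == pytest.approx(np.log(0.25))

    def test_two_sequence_jc_closed_form(self):
        d = 0.23
        aln = GeneAlignment("x", {"A": "ACGTAC", "B": "ACGTGG"})
        tree = PhyloTree.from_newick(f"(A:{d / 2},B:{d / 2});")
        result = log_likelihood(aln, tree, SubstitutionModel("JC"))
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * d / 3)
        expected = 4 * np.log(0.25 * p_same) + 2 * np.log(0.25 * p_diff)
        assert result.total == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n_taxa,n_sites", [(3, 8), (4, 10), (5, 6)])
    def test_matches_brute_force(self, rng, gtr_gi_model, n_taxa, n_sites):
        species = [chr(65 + i) for i in range(n_taxa)]
        aln = random_alignment(rng, species, n_sites, gap_frac=0.1)
        trees = {
            3: "((A:0.1,B:0.4):0.2,C:0.3);",
            4: "((A:0.12,B:0.3):0.08,(C:0.5,D:0.02):0.21);",
            5: "(((A:0.1,B:0.2):0.1,C:0.3):0.05,(D:0.4,E:0.1):0.2);",
        }
        tree = PhyloTree.from_newick(trees[n_taxa])
        got = log_likelihood(aln, tree, gtr_gi_model).total
        want = brute_force_loglik(aln, tree, gtr_gi_model)
        assert got == pytest.approx(want, rel=1e-10)

    def test_site_vector_sums_to_total(self, rng, quartet_tree, gtr_gi_model):
        aln = random_alignment(rng, list("ABCD"), 40)
        result = log_likelihood(aln, quartet_tree, gtr_gi_model)
        assert result.total == pytest.approx(result.per_site.sum())
        assert len(result) == 40

    def test_missing_leaf_sequence(self, quartet_tree):
        aln = GeneAlignment("x", {"A": "AC", "B": "AC", "C": "AC"})
        with pytest.raises(KeyError, match="D"):
            log_likelihood(aln, quartet_tree, SubstitutionModel("JC"))


class TestModelInvariants:
    def test_pulley_principle(self, rng, quartet_tree, gtr_gi_model):
        aln = random_alignment(rng, list("ABCD"), 30, gap_frac=0.05)
        base = log_likelihood(aln, quartet_tree, gtr_gi_model).total
        for leaf in "ABCD":
            rerooted = quartet_tree.reroot_on_edge(leaf, 0.3)
            alt = log_likelihood(aln, rerooted, gtr_gi_model).total
            assert alt == pytest.approx(base, rel=1e-8)

    def test_gtr_reduces_to_jc(self, rng, quartet_tree):
        aln = random_alignment(rng, list("ABCD"), 25)
        jc = SubstitutionModel("JC", alpha=0.6, pinv=0.1)
        gtr = SubstitutionModel("GTR", alpha=0.6, pinv=0.1)
        a = log_likelihood(aln, quartet_tree, jc).total
        b = log_likelihood(aln, quartet_tree, gtr).total
        assert a == pytest.approx(b, rel=1e-12)

    def test_large_alpha_approaches_homogeneous(self, rng, quartet_tree):
        aln = random_alignment(rng, list("ABCD"), 30)
        hom = log_likelihood(aln, quartet_tree, SubstitutionModel("JC")).total
        het = log_likelihood(
            aln, quartet_tree, SubstitutionModel("JC", alpha=1e6)
        ).total
        assert het == pytest.approx(hom, rel=1e-4)

    def test_pinv_zero_equals_no_invariant_class(self, rng, quartet_tree):
        aln = random_alignment(rng, list("ABCD"), 30)
        a = log_likelihood(
            aln, quartet_tree, SubstitutionModel("JC", alpha=0.8, pinv=0.0)
        ).total
        b = log_likelihood(
            aln, quartet_tree, SubstitutionModel("JC", alpha=0.8)
        ).total
        assert a == pytest.approx(b, rel=1e-12)

    def test_underflow_scaling_deep_tree(self):
        # chain of 30 taxa with long branches: unscaled partials underflow
        n = 30
        newick = "A0:1.0"
        for i in range(1, n):
            newick = f"({newick},A{i}:1.0):1.0"
        tree = PhyloTree.from_newick(newick + ";")
        aln = GeneAlignment("x", {f"A{i}": "ACGT" for i in range(n)})
        result = log_likelihood(aln, tree, SubstitutionModel("JC"))
        assert np.all(np.isfinite(result.per_site))


class TestAminoAcid:
    def test_wag_simulation_fit_and_topology_preference(self):
        wag = SubstitutionModel("WAG", alpha=0.8)
        true = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.05);")
        aln = simulate_alignment(true, wag, 500, seed=17)
        assert aln.alphabet == "amino_acid"
        _, sl_true, _ = optimize_branch_lengths(
            aln, PhyloTree.from_newick("((A,B),(C,D));"), wag, max_cycles=5
        )
        _, sl_wrong, _ = optimize_branch_lengths(
            aln, PhyloTree.from_newick("((A,C),(B,D));"), wag, max_cycles=5
        )
        assert np.isfinite(sl_true.total)
        assert sl_true.total > sl_wrong.total


class TestOptimization:
    def test_identical_sequences_shrink_to_bound(self):
        aln = GeneAlignment("x", {"A": "ACGT" * 25, "B": "ACGT" * 25})
        topo = PhyloTree.from_newick("(A:0.3,B:0.3);")
        tree, sl, _ = optimize_branch_lengths(aln, topo, SubstitutionModel("JC"))
        total_len = sum(n.length for n in tree.postorder() if n.parent is not None)
        assert total_len < 1e-4

    def test_loglik_non_decreasing(self, rng, quartet_tree, gtr_gi_model):
        aln = random_alignment(rng, list("ABCD"), 60)
        engine = TreeLikelihood(aln, quartet_tree.copy(), gtr_gi_model)
        before = engine.total_loglik()
        after = engine.optimize_branch_lengths(max_cycles=3)
        assert after >= before - 1e-9

    def test_parameter_recovery_long_sequences(self, rng):
        true = PhyloTree.from_newick(
            "((A:0.08,B:0.12):0.06,(C:0.15,D:0.05):0.09);"
        )
        model = SubstitutionModel("JC")
        aln = simulate_alignment(true, model, 100_000, seed=99)
        topo = PhyloTree.from_newick("((A,B),(C,D));")
        fitted, _, _ = optimize_branch_lengths(aln, topo, model)
        # root-edge lengths are only identifiable as a sum
        true_lengths = {
            frozenset(n.leaf_names()): n.length
            for n in true.postorder()
            if n.parent is not None and n.parent.parent is not None
        }
        fit_lengths = {
            frozenset(n.leaf_names()): n.length
            for n in fitted.postorder()
            if n.parent is not None and n.parent.parent is not None
        }
        for clade, t in true_lengths.items():
            assert fit_lengths[clade] == pytest.approx(t, rel=0.10)
        true_root = 0.06 + 0.09
        fit_root = sum(c.length for c in fitted.root.children)
        assert fit_root == pytest.approx(true_root, rel=0.10)

    def test_optimize_model_improves_fit(self, rng):
        true = PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
        gen = SubstitutionModel(
            "GTR",
            exchangeabilities=[1, 4, 1, 1, 4, 1],
            frequencies=[0.4, 0.3, 0.2, 0.1],
        )
        aln = simulate_alignment(true, gen, 5000, seed=7)
        topo = PhyloTree.from_newick("((A,B),(C,D));")
        start = SubstitutionModel("GTR")
        _, sl_fixed, _ = optimize_branch_lengths(aln, topo, start)
        _, sl_fit, fitted_model = optimize_branch_lengths(
            aln, topo, start, optimize_model=True
        )
        assert sl_fit.total >= sl_fixed.total
        # transition/transversion signal recovered
        exch = fitted_model.exchangeabilities
        assert exch[0, 2] / exch[0, 1] > 2.0
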