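import math

import numpy as np
import pytest

from phyloconflict.models import SubstitutionModel
from phyloconflict.synthetic import (
    DEFAULT_ORDERS,
    SpeciesTreeSpec,
    SyntheticConfig,
    build_species_tree,
    simulate_alignment,
    simulate_gene_alignments,
    simulate_gene_trees,
    simulate_retro_loci,
)
from phyloconflict.trees import (
    PhyloTree,
    enumerate_rooted_topologies,
    restrict_to_orders,
)


def tree_depths(tree):
    out = []

    def walk(node, depth):
        if node.is_leaf:
            out.append(depth)
        for child in node.children:
            walk(child, depth + (child.length or 0.0))

    walk(tree.root, 0.0)
    return out


class TestBuildSpeciesTree:
    def test_fourteen_leaf_tree_reduces_to_its_topology(self):
        subtrees = {
            "Carnivora": PhyloTree.from_newick("(Dog,(Cat,Panda));"),
            "Cetartiodactyla": PhyloTree.from_newick("(((Cow,Dolphin),Pig),Alpaca);"),
            "Chiroptera": PhyloTree.from_newick("(FlyingFox,Microbat);"),
            "Perissodactyla": PhyloTree.from_newick("(Horse,(Donkey,Rhino));"),
        }
        spec = SpeciesTreeSpec(
            topology_id=14,
            within_order_subtrees=subtrees,
            outgroups=("Human", "Mouse"),
        )
        tree = build_species_tree(spec)
        assert tree.n_leaves == 14
        order_of = {
            name: order for order, sub in subtrees.items() for name in sub.leaf_names()
        }
        reduced = restrict_to_orders(tree, order_of)
        expected = enumerate_rooted_topologies(DEFAULT_ORDERS)[13]
        assert reduced.canonical_newick() == expected.canonical_newick()

    def test_single_tip_orders_no_outgroup(self):
        spec = SpeciesTreeSpec(topology_id=3, outgroups=())
        tree = build_species_tree(spec)
        assert tree.n_leaves == 4
        expected = enumerate_rooted_topologies(DEFAULT_ORDERS)[2]
        assert tree.canonical_newick() == expected.canonical_newick()

    @pytest.mark.parametrize("topology_id", [1, 7, 15])
    def test_internal_node_count(self, topology_id):
        tree = build_species_tree(SpeciesTreeSpec(topology_id=topology_id))
        assert len(tree.internal_nodes()) == tree.n_leaves - 1

    def test_ultrametric(self):
        tree = build_species_tree(SpeciesTreeSpec(topology_id=14))
        depths = tree_depths(tree)
        assert max(depths) - min(depths) < 1e-9

    def test_invalid_topology_id(self):
        with pytest.raises(ValueError):
            SpeciesTreeSpec(topology_id=16)

    def test_duplicate_tip_labels(self):
        subtrees = {o: PhyloTree.from_newick("(x1,x2);") for o in DEFAULT_ORDERS}
        with pytest.raises(ValueError):
            build_species_tree(
                SpeciesTreeSpec(within_order_subtrees=subtrees, outgroups=())
            )


class TestGeneTreeSimulation:
    def test_three_taxon_concordance(self):
        # modest replicate count here; the 1e5-replicate calibration lives
        # in the acceptance suite
        t = 1.0
        sp = PhyloTree.from_newick(f"((A:1.0,B:1.0):{t},C:{1.0 + t});",
                                   units="coalescent")
        trees = simulate_gene_trees(sp, 5000, seed=11)
        frac = sum(
            1 for g in trees if g.canonical_newick() == "((A,B),C);"
        ) / len(trees)
        expected = 1 - (2 / 3) * math.exp(-t)
        assert frac == pytest.approx(expected, abs=0.03)

    def test_long_branch_always_concordant(self):
        sp = PhyloTree.from_newick("((A:1.0,B:1.0):30.0,C:31.0);", units="coalescent")
        trees = simulate_gene_trees(sp, 300, seed=5)
        assert all(g.canonical_newick() == "((A,B),C);" for g in trees)

    def test_determinism(self):
        sp = build_species_tree(SpeciesTreeSpec())
        a = simulate_gene_trees(sp, 10, seed=42)
        b = simulate_gene_trees(sp, 10, seed=42)
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]

    def test_positive_count_required(self):
        sp = build_species_tree(SpeciesTreeSpec())
        with pytest.raises(ValueError):
            simulate_gene_trees(sp, 0)

    def test_leaf_set_preserved(self):
        sp = build_species_tree(SpeciesTreeSpec())
        for g in simulate_gene_trees(sp, 5, seed=3):
            assert g.leaf_names() == sp.leaf_names()


class TestAlignmentSimulation:
    def test_zero_branches_identical(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0,C:0);")
        aln = simulate_alignment(tree, SubstitutionModel("JC"), 100, seed=1)
        rows = list(aln.rows.values())
        assert rows[0] == rows[1] == rows[2]

    def test_pinv_one_everything_invariant(self):
        tree = PhyloTree.from_newick("((A:2,B:2):2,C:2);")
        aln = simulate_alignment(
            tree, SubstitutionModel("JC", pinv=1.0), 50, seed=2
        )
        mat = aln.matrix()
        assert all(len(set(mat[:, j])) == 1 for j in range(50))

    def test_stationary_frequencies(self):
        model = SubstitutionModel(
            "GTR", frequencies=[0.4, 0.3, 0.2, 0.1]
        )
        tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
        aln = simulate_alignment(tree, model, 100_000, seed=3)
        seq = aln.rows["A"]
        freqs = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
        np.testing.assert_allclose(freqs, model.frequencies, atol=0.01)

    def test_determinism(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        a = simulate_alignment(tree, SubstitutionModel("JC"), 500, seed=9)
        b = simulate_alignment(tree, SubstitutionModel("JC"), 500, seed=9)
        assert a.rows == b.rows

    def test_invalid_length(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            simulate_alignment(tree, SubstitutionModel("JC"), 0)


class TestRetroLociSimulation:
    @pytest.fixture
    def no_ils_spec(self):
        return SpeciesTreeSpec(
            topology_id=14, internal_branch=30.0, outgroups=(),
            substitution_scale=0.01,
        )

    def test_zero_rate_no_insertions(self, no_ils_spec):
        cfg = SyntheticConfig(
            species_tree=no_ils_spec, n_introns=10, insertion_rate=0.0, seed=4
        )
        loci = simulate_retro_loci(build_species_tree(no_ils_spec), cfg)
        assert all(not locus.insert_columns for locus in loci)

    def test_dollo_inheritance_no_ils(self, no_ils_spec):
        cfg = SyntheticConfig(
            species_tree=no_ils_spec, n_introns=40, insertion_rate=0.05, seed=8
        )
        tree = build_species_tree(no_ils_spec)
        species_clades = {
            frozenset(n.leaf_names()) for n in tree.postorder()
        }
        loci = simulate_retro_loci(tree, cfg)
        informative = [
            carriers
            for locus in loci
            for carriers in (locus.truth_carriers or [])
            if 2 <= len(carriers) <= 3
        ]
        assert informative, "expected some multi-species insertions"
        # without ILS every carrier set is a species-tree clade
        assert all(c in species_clades for c in informative)

    def test_locus_reproducibility(self, no_ils_spec):
        cfg = SyntheticConfig(
            species_tree=no_ils_spec, n_introns=6, insertion_rate=0.3, seed=21
        )
        tree = build_species_tree(no_ils_spec)
        a = simulate_retro_loci(tree, cfg)
        b = simulate_retro_loci(tree, cfg)
        assert all(x.rows == y.rows for x, y in zip(a, b))
        assert all(x.insert_columns == y.insert_columns for x, y in zip(a, b))

    def test_carriers_are_gene_tree_clades(self):
        # Dollo soundness under heavy ILS: carrier sets are clades of the
        # locus gene tree, so present/absent blocks are never interleaved
        # with point gaps in the emitted alignment interval
        spec = SpeciesTreeSpec(topology_id=14, internal_branch=0.1, outgroups=())
        cfg = SyntheticConfig(species_tree=spec, n_introns=30, insertion_rate=0.3,
                              seed=13)
        loci = simulate_retro_loci(build_species_tree(spec), cfg)
        for locus in loci:
            for (start, end), carriers in zip(
                locus.insert_columns, locus.truth_carriers
            ):
                for sp, row in locus.rows.items():
                    block = row[start:end]
                    if sp in carriers:
                        assert "-" not in block
                    else:
                        assert block == "-" * (end - start)

    def test_flanks_present(self, no_ils_spec):
        cfg = SyntheticConfig(species_tree=no_ils_spec, n_introns=3, seed=2)
        loci = simulate_retro_loci(build_species_tree(no_ils_spec), cfg)
        for locus in loci:
            assert locus.n_columns >= 2 * cfg.flank_length


class TestDatasetAssembly:
    def test_gene_alignment_batch(self):
        cfg = SyntheticConfig(n_genes=4, gene_length=60, seed=5)
        alignments, gene_trees = simulate_gene_alignments(cfg)
        assert len(alignments) == 4 and len(gene_trees) == 4
        assert all(a.n_columns == 60 for a in alignments)

    def test_byte_identical_rerun(self):
        cfg = SyntheticConfig(n_genes=3, gene_length=45, seed=17)
        a, _ = simulate_gene_alignments(cfg)
        b, _ = simulate_gene_alignments(cfg)
        assert [x.rows for x in a] == [y.rows for y in b]

    def test_introgression_pulse(self):
        cfg = SyntheticConfig(
            n_genes=10,
            gene_length=30,
            seed=3,
            introgression_fraction=0.3,
            introgression_topology_id=2,
        )
        alignments, gene_trees = simulate_gene_alignments(cfg)
        assert len(gene_trees) == 10
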