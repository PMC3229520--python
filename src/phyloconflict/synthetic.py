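"""Synthetic-data generation: species trees, multispecies-coalescent gene
trees, sequence alignments, and Dollo retroposon insertion loci.

Species trees live in coalescent units (time measured in units of 2N
generations); a single scalar (``substitution_scale``) maps a coalescent
unit to expected substitutions per site, decoupling the intensity of
incomplete lineage sorting from sequence divergence. Gene genealogies are
drawn with :mod:`msprime`; under the parameterization used here
(haploid lineages, population size 1) msprime's time axis *is* the
coalescent-unit axis, so the classic three-taxon concordance probability
``1 - (2/3) exp(-t)`` holds for an internal branch of ``t`` units.

All randomness flows from a master seed; each locus gets its own child
stream derived from (seed, locus index), so loci are reproducible
individually and outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import msprime
import numpy as np

from .models import SubstitutionModel
from .retro import RetroLocus, RepeatAnnotation
from .seqio import GeneAlignment, write_fasta_alignment
from .trees import (
    PhyloTree,
    Node,
    enumerate_rooted_topologies,
    graft,
    UNIT_COALESCENT,
    UNIT_SUBSTITUTIONS,
)

DEFAULT_ORDERS = ("Carnivora", "Cetartiodactyla", "Chiroptera", "Perissodactyla")

#: Fixed LINE1-like consensus used to seed simulated insertions. The exact
#: sequence is arbitrary; it only needs enough structure for annotation
#: round-trips.
_L1_CONSENSUS_SEED = 20111202
_L1_CONSENSUS_LENGTH = 600


def _l1_consensus() -> str:
    rng = np.random.default_rng(_L1_CONSENSUS_SEED)
    return "".join(rng.choice(list("ACGT"), _L1_CONSENSUS_LENGTH))


@dataclass
class SpeciesTreeSpec:
    """Recipe for an ultrametric species tree in coalescent units.

    ``topology_id`` selects one of the 15 canonical rooted topologies on
    the four order labels (canonical enumeration order of
    :func:`~phyloconflict.trees.enumerate_rooted_topologies`).
    """

    topology_id: int = 14
    orders: tuple[str, ...] = DEFAULT_ORDERS
    #: gap, in coalescent units, between successive inter-order divergences
    internal_branch: float = 2.0
    #: rooted subtrees per order (topology only); None = single tip named
    #: after the order
    within_order_subtrees: Optional[dict[str, PhyloTree]] = None
    #: age of the deepest within-order divergence
    within_order_height: float = 0.5
    outgroups: tuple[str, ...] = ("Outgroup",)
    #: extra coalescent time between the ingroup root and the tree root
    outgroup_gap: float = 4.0
    #: age of the outgroup cherry when there are two outgroups
    outgroup_cherry_age: float = 2.0
    #: expected substitutions/site per coalescent unit
    substitution_scale: float = 0.01

    def __post_init__(self):
        n_topo = len(enumerate_rooted_topologies(self.orders))
        if not 1 <= self.topology_id <= n_topo:
            raise ValueError(
                f"topology_id {self.topology_id} out of range 1..{n_topo}"
            )
        if self.internal_branch < 0:
            raise ValueError("internal branch length must be >= 0")
        if len(self.outgroups) > 2:
            raise ValueError("at most two outgroups supported")


def build_species_tree(spec: SpeciesTreeSpec) -> PhyloTree:
    """Materialize the spec into an ultrametric tree in coalescent units."""
    order_topology = enumerate_rooted_topologies(spec.orders)[spec.topology_id - 1]
    subtrees = dict(spec.within_order_subtrees or {})
    for order in spec.orders:
        if order not in subtrees:
            subtrees[order] = PhyloTree(Node(order))
    full = graft(order_topology, subtrees, outgroups=spec.outgroups)

    order_of = {
        tip.name: order for order, sub in subtrees.items() for tip in sub.leaves()
    }
    outgroup_set = set(spec.outgroups)

    ages: dict[int, float] = {}

    def assign(node: Node) -> float:
        if node.is_leaf:
            ages[id(node)] = 0.0
            return 0.0
        child_ages = [assign(c) for c in node.children]
        tips = node.leaf_names()
        if tips & outgroup_set:
            if tips <= outgroup_set:
                age = spec.outgroup_cherry_age
            else:  # the root joining ingroup and outgroup(s)
                age = max(child_ages) + spec.outgroup_gap
        elif len({order_of[t] for t in tips}) == 1:
            # within-order node: spread evenly below within_order_height
            age = max(child_ages) + spec.within_order_height / max(
                _subtree_depth(node), 1
            )
        else:
            age = max(child_ages) + spec.internal_branch
            if all(len({order_of[t] for t in c.leaf_names()}) == 1 for c in node.children):
                # shallowest inter-order node: add the order stem
                age = max(
                    age, max(child_ages) + spec.internal_branch
                )
        ages[id(node)] = age
        return age

    def _subtree_depth(node: Node) -> int:
        if node.is_leaf:
            return 0
        return 1 + max(_subtree_depth(c) for c in node.children)

    assign(full.root)
    for node in full.postorder():
        if node.parent is not None:
            node.length = ages[id(node.parent)] - ages[id(node)]
    full.root.length = None
    full.units = UNIT_COALESCENT
    return full


@dataclass
class SyntheticConfig:
    """End-to-end synthetic dataset recipe."""

    species_tree: SpeciesTreeSpec = field(default_factory=SpeciesTreeSpec)
    n_genes: int = 50
    gene_length: int = 999
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel("JC"))
    #: fraction of loci following an alternative species tree (single
    #: introgression pulse); 0 disables
    introgression_fraction: float = 0.0
    introgression_topology_id: Optional[int] = None
    n_introns: int = 20
    intron_length_range: tuple[int, int] = (400, 1200)
    flank_length: int = 80
    #: expected LINE1 insertions per intron per coalescent unit of branch
    insertion_rate: float = 0.05
    insert_length_range: tuple[int, int] = (100, 500)
    insert_divergence_range: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_introns < 0 or self.gene_length <= 0:
            raise ValueError("counts must be positive")
        if self.insertion_rate < 0:
            raise ValueError("insertion_rate must be >= 0")
        if not 0.0 <= self.introgression_fraction <= 1.0:
            raise ValueError("introgression_fraction in [0,1]")


# ---------------------------------------------------------------------------
# gene trees


def _demography_from_tree(tree: PhyloTree) -> tuple[msprime.Demography, dict[str, str]]:
    ages: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ages[id(node)] = 0.0
        else:
            child = node.children[0]
            ages[id(node)] = ages[id(child)] + (child.length or 0.0)
    dem = msprime.Demography()
    pop_of: dict[int, str] = {}
    counter = 0
    for node in tree.postorder():
        if node.is_leaf:
            name = node.name
        else:
            counter += 1
            name = f"anc{counter}"
        pop_of[id(node)] = name
        dem.add_population(name=name, initial_size=1.0)
    splits = []
    for node in tree.postorder():
        if node.is_leaf:
            continue
        splits.append(
            (
                ages[id(node)],
                [pop_of[id(c)] for c in node.children],
                pop_of[id(node)],
            )
        )
    for time, derived, ancestral in sorted(splits, key=lambda s: s[0]):
        dem.add_population_split(time=time, derived=derived, ancestral=ancestral)
    samples = {leaf.name: leaf.name for leaf in tree.leaves()}
    return dem, samples


def _tskit_to_phylo(ts_tree, pop_names: dict[int, str]) -> PhyloTree:
    def convert(u: int) -> Node:
        node = Node()
        children = ts_tree.children(u)
        if not children:
            node.name = pop_names[u]
        for c in children:
            child = convert(c)
            child.length = ts_tree.time(u) - ts_tree.time(c)
            node.add_child(child)
        return node

    return PhyloTree(convert(ts_tree.root), units=UNIT_COALESCENT)


def simulate_gene_trees(
    species_tree: PhyloTree, n_genes: int, seed: int = 1
) -> list[PhyloTree]:
    """Independent multispecies-coalescent gene trees, one lineage per
    species, branch lengths in coalescent units."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if species_tree.units not in (None, UNIT_COALESCENT):
        raise ValueError("species tree must be in coalescent units")
    dem, _ = _demography_from_tree(species_tree)
    samples = {leaf.name: 1 for leaf in species_tree.leaves()}
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        random_seed=max(int(seed), 1),
        num_replicates=n_genes,
    )
    out = []
    pop_names: Optional[dict[int, str]] = None
    for ts in reps:
        if pop_names is None:
            # identical demography across replicates -> compute sample
            # labels once
            pop_names = {
                sample: ts.population(ts.node(sample).population).metadata["name"]
                for sample in ts.samples()
            }
        out.append(_tskit_to_phylo(ts.first(), pop_names))
    return out


# ---------------------------------------------------------------------------
# sequence alignments


def _sample_descendant_states(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parent_states))
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(
    gene_tree: PhyloTree,
    model: SubstitutionModel,
    length: int,
    seed: int = 1,
    locus_id: str = "locus",
) -> GeneAlignment:
    """Evolve a gap-free alignment along ``gene_tree`` (branch lengths in
    substitutions/site) under the model's full +G+I rate mixture."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    weights, rates = model.mixture()
    categories = rng.choice(len(rates), size=length, p=weights)
    pi = model.frequencies
    states = {id(gene_tree.root): rng.choice(model.n_states, size=length, p=pi)}
    for node in gene_tree.preorder():
        if node.parent is None:
            continue
        parent = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for k, rate in enumerate(rates):
            mask = categories == k
            if not mask.any():
                continue
            P = model.transition_matrix((node.length or 0.0) * rate)
            child[mask] = _sample_descendant_states(parent[mask], P, rng)
        states[id(node)] = child
    alphabet_chars = np.array(list(model.states))
    rows = {
        leaf.name: "".join(alphabet_chars[states[id(leaf)]])
        for leaf in gene_tree.leaves()
    }
    alphabet = "nucleotide" if model.is_nucleotide else "amino_acid"
    return GeneAlignment(locus_id, rows, alphabet)


# ---------------------------------------------------------------------------
# retroposon loci


def _evolve_jc(
    seq: np.ndarray, distance: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes-Cantor evolution of an integer base array over ``distance``
    substitutions/site (vectorized)."""
    p_diff = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * max(distance, 0.0)))
    hit = rng.random(len(seq)) < p_diff
    out = seq.copy()
    # a substitution picks one of the three other bases uniformly
    out[hit] = (seq[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


_BASE_CHARS = np.array(list("ACGT"))


def _mutate_fraction(seq: str, fraction: float, rng: np.random.Generator) -> str:
    arr = np.array([("ACGT").index(c) for c in seq])
    hit = rng.random(len(arr)) < fraction
    arr[hit] = (arr[hit] + rng.integers(1, 4, hit.sum())) % 4
    return "".join(_BASE_CHARS[arr])


def simulate_retro_loci(
    species_tree: PhyloTree, config: SyntheticConfig
) -> list[RetroLocus]:
    """Simulate intron loci with Dollo LINE1-like insertions.

    Per locus: a gene tree is drawn under the coalescent; insertion events
    are Poisson on gene-tree branches (rate = ``insertion_rate`` per
    coalescent unit) and inherited by all descendant species, never lost.
    The emitted rows are aligned: an insertion occupies a block of columns
    that carriers fill with sequence and non-carriers with gaps.
    """
    species = sorted(species_tree.leaf_names())
    scale = config.species_tree.substitution_scale
    consensus = _l1_consensus()
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_introns)
    loci: list[RetroLocus] = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        msp_seed = int(rng.integers(1, 2**31 - 1))
        gene_tree = simulate_gene_trees(species_tree, 1, seed=msp_seed)[0]

        intron_len = int(rng.integers(*config.intron_length_range))
        flank = config.flank_length
        total_anc = flank + intron_len + flank

        # insertions: Poisson per gene-tree branch
        inserts = []  # (position in intron, sequence, carriers)
        for node in gene_tree.postorder():
            if node.parent is None:
                continue
            n_events = rng.poisson(config.insertion_rate * (node.length or 0.0))
            for _ in range(n_events):
                pos = int(rng.integers(0, intron_len + 1))
                ins_len = int(rng.integers(*config.insert_length_range))
                div = rng.uniform(*config.insert_divergence_range)
                start = int(rng.integers(0, max(len(consensus) - ins_len, 0) + 1))
                template = consensus[start : start + ins_len]
                if len(template) < ins_len:
                    template = (template * (ins_len // len(template) + 1))[:ins_len]
                seq = _mutate_fraction(template, div, rng)
                inserts.append((pos, seq, node.leaf_names()))
        inserts.sort(key=lambda x: x[0])

        # ancestral background, evolved independently per species along
        # root-to-tip JC distances
        anc = rng.integers(0, 4, total_anc)
        depth = {id(species_tree.root): 0.0}
        tip_distance = {}
        for node in species_tree.preorder():
            if node.parent is not None:
                depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
            if node.is_leaf:
                tip_distance[node.name] = depth[id(node)] * scale
        # evolve down the *gene* tree so relatives share mutations
        gstates = {id(gene_tree.root): anc}
        for node in gene_tree.preorder():
            if node.parent is None:
                continue
            gstates[id(node)] = _evolve_jc(
                gstates[id(node.parent)], (node.length or 0.0) * scale, rng
            )
        background = {
            leaf.name: _BASE_CHARS[gstates[id(leaf)]] for leaf in gene_tree.leaves()
        }

        # assemble aligned rows: ancestral columns with insertion blocks
        rows = {sp: [] for sp in species}
        insert_columns = []
        carriers_list = []
        col = 0
        anc_cursor = 0
        for pos, seq, carriers in inserts:
            block_anchor = flank + pos  # position in ancestral coordinates
            for sp in species:
                rows[sp].append("".join(background[sp][anc_cursor:block_anchor]))
            col += block_anchor - anc_cursor
            anc_cursor = block_anchor
            for sp in species:
                if sp in carriers:
                    carrier_seq = _mutate_fraction(seq, 0.01, rng)
                    rows[sp].append(carrier_seq)
                else:
                    rows[sp].append("-" * len(seq))
            insert_columns.append((col, col + len(seq)))
            carriers_list.append(frozenset(carriers))
            col += len(seq)
        for sp in species:
            rows[sp].append("".join(background[sp][anc_cursor:]))

        locus_rows = {sp: "".join(parts) for sp, parts in rows.items()}
        annotations = []
        for (cstart, cend), carriers in zip(insert_columns, carriers_list):
            for sp in sorted(carriers):
                row = locus_rows[sp]
                ungapped_start = len(row[:cstart].replace("-", ""))
                ungapped_end = ungapped_start + len(row[cstart:cend].replace("-", ""))
                annotations.append(
                    RepeatAnnotation(
                        query=f"intron{i:05d}_{sp}",
                        start=ungapped_start,
                        end=ungapped_end,
                        strand="+",
                        repeat_name="L1_synth",
                        family="LINE/L1",
                        score=1000.0,
                    )
                )
        loci.append(
            RetroLocus(
                locus_id=f"intron{i:05d}",
                rows=locus_rows,
                flank_length=flank,
                annotations=annotations,
                insert_columns=insert_columns,
                truth_carriers=carriers_list,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# dataset assembly and writers


def simulate_gene_alignments(
    config: SyntheticConfig,
) -> tuple[list[GeneAlignment], list[PhyloTree]]:
    """Gene trees + alignments for ``config.n_genes`` loci (introgression
    pulse applied when configured)."""
    spec = config.species_tree
    tree = build_species_tree(spec)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11C)))
    n_intro = 0
    if config.introgression_fraction > 0 and config.introgression_topology_id:
        n_intro = int(round(config.introgression_fraction * config.n_genes))
    gene_trees = simulate_gene_trees(
        tree, config.n_genes - n_intro, seed=config.seed + 1
    )
    if n_intro:
        alt_spec = SpeciesTreeSpec(
            **{
                **spec.__dict__,
                "topology_id": config.introgression_topology_id,
            }
        )
        alt_tree = build_species_tree(alt_spec)
        gene_trees += simulate_gene_trees(alt_tree, n_intro, seed=config.seed + 2)
    alignments = []
    for g, gtree in enumerate(gene_trees):
        sub_tree = gtree.scale(spec.substitution_scale)
        sub_tree.units = UNIT_SUBSTITUTIONS
        seed = int(rng.integers(0, 2**63 - 1))
        alignments.append(
            simulate_alignment(
                sub_tree, config.model, config.gene_length, seed=seed,
                locus_id=f"gene{g:04d}",
            )
        )
    return alignments, gene_trees


def write_dataset(
    config: SyntheticConfig,
    out_dir,
    alignments: Optional[list[GeneAlignment]] = None,
    gene_trees: Optional[list[PhyloTree]] = None,
    loci: Optional[list[RetroLocus]] = None,
) -> dict:
    """Write alignments (FASTA), gene trees (newick), retro loci (FASTA +
    RepeatMasker-style .out + truth TSV). Returns a manifest dict."""
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "introns").mkdir(parents=True, exist_ok=True)
    if alignments is None:
        alignments, gene_trees = simulate_gene_alignments(config)
    if loci is None:
        loci = simulate_retro_loci(build_species_tree(config.species_tree), config)
    for aln in alignments:
        write_fasta_alignment(aln, out / "genes" / f"{aln.locus_id}.fasta")
    with open(out / "gene_trees.nwk", "w") as fh:
        for gtree in gene_trees or []:
            fh.write(gtree.to_newick() + "\n")
    with open(out / "introns" / "repeats.out", "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching "
            "repeat         position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat   "
            "class/family   begin end (left) ID\n\n"
        )
        rm_id = 0
        for locus in loci:
            for ann in locus.annotations:
                rm_id += 1
                fh.write(
                    f"{ann.score:6.0f}  10.0  0.0  0.0  {ann.query}  "
                    f"{ann.start + 1} {ann.end} (0) {ann.strand} "
                    f"{ann.repeat_name} {ann.family} 1 {ann.length} (0) {rm_id}\n"
                )
    with open(out / "introns" / "truth.tsv", "w") as fh:
        fh.write("locus\tinsertion\tcol_start\tcol_end\tcarriers\n")
        for locus in loci:
            for j, ((cs, ce), carriers) in enumerate(
                zip(locus.insert_columns, locus.truth_carriers or [])
            ):
                fh.write(
                    f"{locus.locus_id}\t{j}\t{cs}\t{ce}\t"
                    + ",".join(sorted(carriers))
                    + "\n"
                )
    for locus in loci:
        write_fasta_alignment(
            GeneAlignment(locus.locus_id, locus.rows),
            out / "introns" / f"{locus.locus_id}.fasta",
        )
    return {
        "n_genes": len(alignments),
        "n_loci": len(loci),
        "seed": config.seed,
    }
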