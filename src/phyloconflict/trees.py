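"""Rooted binary trees with branch lengths and unit tags.

The tree class here is deliberately small: a mutable node structure that
the likelihood engine, the coalescent simulator and the dating module all
share. Newick parsing is delegated to :mod:`dendropy`; serialization is a
canonical recursive writer so that identical topologies always produce
identical strings.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import dendropy

#: Branch-length unit tags.
UNIT_SUBSTITUTIONS = "substitutions"
UNIT_COALESCENT = "coalescent"
UNIT_MA = "Ma"


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch above this node (``None`` for an
    unset root branch).
    """

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.name, self.length)
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '·'} len={self.length}>"


class PhyloTree:
    """A rooted binary leaf-labeled tree.

    Parameters
    ----------
    root:
        Root :class:`Node`.
    units:
        Unit of the branch lengths: one of ``"substitutions"``,
        ``"coalescent"``, ``"Ma"`` or ``None`` when lengths are absent or
        meaningless (pure topologies).
    """

    def __init__(self, root: Node, units: Optional[str] = None):
        self.root = root
        self.units = units
        names = [n.name for n in root.leaves()]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, units: Optional[str] = None) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip labels in newick: {exc}") from exc

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label, dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node), units=units)

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def find_mrca(self, names: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tip names."""
        want = frozenset(names)
        missing = want - self.leaf_names()
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        for node in self.postorder():
            if want <= node.leaf_names():
                return node
        raise AssertionError("unreachable: root covers all tips")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), units=self.units)

    # -- transforms --------------------------------------------------------

    def scale(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        dup = self.copy()
        for node in dup.postorder():
            if node.length is not None:
                node.length *= factor
        return dup

    def restrict(self, names: Sequence[str]) -> "PhyloTree":
        """Prune to the given tip set, suppressing unary nodes.

        Branch lengths along suppressed paths are summed.
        """
        keep = frozenset(names)

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.name in keep:
                    return Node(node.name, node.length)
                return None
            kept = [c for c in (prune(c) for c in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                return child
            new = Node(node.name, node.length)
            for c in kept:
                new.add_child(c)
            return new

        new_root = prune(self.root)
        if new_root is None:
            raise ValueError("restriction to empty tip set")
        return PhyloTree(new_root, units=self.units)

    def reroot_on_edge(self, leaf_name: str, fraction: float = 0.5) -> "PhyloTree":
        """Reroot on the terminal edge above the named leaf.

        Used by the pulley-principle tests: under a reversible model the
        likelihood must not depend on root placement.
        """
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick")
        leaf = next(
            l for l in dtree.leaf_node_iter() if l.taxon.label == leaf_name
        )
        edge_len = leaf.edge.length or 0.0
        dtree.reroot_at_edge(
            leaf.edge, length1=edge_len * (1 - fraction), length2=edge_len * fraction
        )

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = Node(label, dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return PhyloTree(convert(dtree.seed_node), units=self.units)

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: bool = True, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                core += f":{node.length:.{precision}g}"
            return core

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only newick with children sorted by smallest tip label.

        Two trees have the same rooted topology iff their canonical strings
        are equal.
        """

        def fmt(node: Node) -> tuple[str, str]:
            if node.is_leaf:
                return node.name, node.name
            parts = sorted(fmt(c) for c in node.children)
            key = min(p[0] for p in parts)
            return key, "(" + ",".join(p[1] for p in parts) + ")"

        return fmt(self.root)[1] + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick(lengths=False)}, units={self.units})"


def enumerate_rooted_topologies(labels: Sequence[str]) -> list[PhyloTree]:
    """All distinct rooted binary topologies on the given labels.

    The number of topologies for ``n`` labels is ``(2n-3)!!`` (3 for three
    labels, 15 for four, 105 for five). Trees are returned in a stable
    canonical order — sorted by canonical newick string — so topology
    numbering (index + 1) is reproducible across runs.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")

    def grow(tree: Node, label: str) -> Iterator[Node]:
        # Attach on every existing edge, plus above the current root.
        new_root = Node()
        new_root.add_child(tree.copy())
        new_root.add_child(Node(label))
        yield new_root
        for i, _ in enumerate(list(tree.postorder())):
            dup = tree.copy()
            target = list(dup.postorder())[i]
            if target.parent is None:
                continue
            parent = target.parent
            idx = parent.children.index(target)
            joint = Node()
            joint.add_child(target)
            joint.add_child(Node(label))
            joint.parent = parent
            parent.children[idx] = joint
            yield dup

    first = Node()
    first.add_child(Node(labels[0]))
    first.add_child(Node(labels[1]))
    forest = [first]
    for label in labels[2:]:
        forest = [t for tree in forest for t in grow(tree, label)]
    trees = [PhyloTree(root) for root in forest]
    trees.sort(key=lambda t: t.canonical_newick())
    return trees


def graft(
    order_topology: PhyloTree,
    subtrees: dict[str, PhyloTree],
    outgroups: Sequence[str] = (),
) -> PhyloTree:
    """Expand an order-level topology into a full species tree.

    Every leaf of ``order_topology`` is replaced by the corresponding
    rooted subtree; outgroups (if any) are attached as a sister group of
    the ingroup root (two outgroups form a cherry).
    """
    missing = [l.name for l in order_topology.leaves() if l.name not in subtrees]
    if missing:
        raise KeyError(f"no subtree for orders: {missing}")

    def expand(node: Node) -> Node:
        if node.is_leaf:
            sub = subtrees[node.name].root.copy()
            sub.length = node.length
            return sub
        new = Node(length=node.length)
        for child in node.children:
            new.add_child(expand(child))
        return new

    ingroup = expand(order_topology.root)
    if not outgroups:
        return PhyloTree(ingroup)
    root = Node()
    root.add_child(ingroup)
    if len(outgroups) == 1:
        root.add_child(Node(outgroups[0]))
    else:
        cherry = Node()
        for og in outgroups:
            cherry.add_child(Node(og))
        root.add_child(cherry)
    return PhyloTree(root)


def restrict_to_orders(tree: PhyloTree, order_of: dict[str, str]) -> PhyloTree:
    """Collapse a full species tree back to one tip per order.

    ``order_of`` maps species name to order name. Species not in the map
    (outgroups) are dropped. Each order must be monophyletic in ``tree``.
    """
    reduced = tree.restrict([s for s in tree.leaf_names() if s in order_of])
    orders = set(order_of.values())
    for order in orders:
        members = [s for s, o in order_of.items() if o == order and s in tree.leaf_names()]
        mrca = reduced.find_mrca(members)
        if mrca.leaf_names() != frozenset(members):
            raise ValueError(f"order {order} is not monophyletic")

    def collapse(node: Node) -> Node:
        tips = node.leaf_names()
        its_orders = {order_of[t] for t in tips}
        if len(its_orders) == 1:
            return Node(its_orders.pop(), node.length)
        new = Node(node.name, node.length)
        for child in node.children:
            new.add_child(collapse(child))
        return new

    return PhyloTree(collapse(reduced.root), units=tree.units)
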