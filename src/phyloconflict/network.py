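"""Weighted split systems: threshold consensus networks from gene trees
and marker-count networks from retroposon tallies, exported in the
SplitsTree4 NEXUS dialect.

Splits are canonicalized as the bipartition side *not* containing the
alphabetically first taxon, which prevents duplicate-orientation bugs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .trees import PhyloTree

Split = frozenset


@dataclass
class SplitSystem:
    """Weighted bipartitions of a fixed taxon set.

    Each split is stored as the side excluding the reference taxon
    (alphabetically first). Weights are frequencies in [0, 1] or raw
    counts, positive.
    """

    taxa: list[str]
    weights: dict[Split, float]

    def __post_init__(self):
        self.taxa = sorted(self.taxa)
        universe = frozenset(self.taxa)
        if not self.taxa and self.weights:
            raise ValueError("splits without taxa")
        ref = self.taxa[0] if self.taxa else None
        canon = {}
        for split, w in self.weights.items():
            side = frozenset(split)
            if not side or side >= universe:
                raise ValueError("split sides must be proper non-empty subsets")
            if not side <= universe:
                raise ValueError(f"split mentions unknown taxa: {sorted(side - universe)}")
            if w <= 0:
                raise ValueError("split weights must be positive")
            if ref in side:
                side = universe - side
            if side in canon:
                raise ValueError(f"duplicate split {sorted(side)}")
            canon[side] = float(w)
        self.weights = canon

    @property
    def splits(self) -> set[Split]:
        return set(self.weights)

    def nontrivial_splits(self) -> set[Split]:
        n = len(self.taxa)
        return {s for s in self.weights if 1 < len(s) < n - 1}

    def __len__(self) -> int:
        return len(self.weights)


def canonical_split(side: Iterable[str], taxa: Sequence[str]) -> Split:
    side = frozenset(side)
    ref = sorted(taxa)[0]
    if ref in side:
        side = frozenset(taxa) - side
    return side


def splits_compatible(a: Split, b: Split, taxa: Sequence[str]) -> bool:
    """Two splits are compatible iff some pair of their sides is disjoint."""
    universe = frozenset(taxa)
    for x in (a, universe - a):
        for y in (b, universe - b):
            if not (x & y):
                return True
    return False


def tree_splits(tree: PhyloTree) -> set[Split]:
    """Splits of the unrooted interpretation of ``tree`` (root edge
    merged), one per edge, trivial splits included."""
    taxa = sorted(tree.leaf_names())
    out: set[Split] = set()
    for node in tree.postorder():
        if node.parent is None:
            continue
        side = node.leaf_names()
        if 0 < len(side) < len(taxa):
            out.add(canonical_split(side, taxa))
    return out


def consensus_splits(trees: Sequence[PhyloTree], threshold: float) -> SplitSystem:
    """Threshold consensus: splits occurring in at least ``threshold`` of
    the input trees, weighted by their frequency."""
    if not trees:
        raise ValueError("no trees")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    taxa = sorted(trees[0].leaf_names())
    counts: dict[Split, int] = {}
    for tree in trees:
        if sorted(tree.leaf_names()) != taxa:
            raise ValueError("trees have inconsistent leaf sets")
        for split in tree_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    weights = {s: c / n for s, c in counts.items() if c / n >= threshold and c > 0}
    return SplitSystem(taxa, weights)


def marker_split_network(
    tallies: Mapping[frozenset, float] | Mapping[str, float],
    taxa: Sequence[str],
    hypotheses: Mapping[str, Iterable[str]] | None = None,
) -> SplitSystem:
    """Split system over the order-level taxa weighted by raw marker
    counts; zero-count hypotheses are omitted.

    ``tallies`` maps split sides (frozensets of taxa) or hypothesis names
    to counts; names require ``hypotheses`` to resolve them to sides.
    """
    weights: dict[Split, float] = {}
    for key, count in tallies.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count == 0:
            continue
        if isinstance(key, str):
            if hypotheses is None or key not in hypotheses:
                raise KeyError(f"unresolvable hypothesis name {key!r}")
            side = frozenset(hypotheses[key])
        else:
            side = frozenset(key)
        split = canonical_split(side, taxa)
        weights[split] = weights.get(split, 0.0) + float(count)
    return SplitSystem(list(taxa), weights)


# ---------------------------------------------------------------------------
# NEXUS (SplitsTree4 ST_SPLITS dialect)


def write_splits_nexus(system: SplitSystem, path) -> None:
    """Serialize to a SplitsTree4-readable NEXUS file.

    Weights are printed to 6 decimals; splits are ordered by (size,
    lexicographic member tuple) for byte-stable output.
    """
    if not system.taxa:
        raise ValueError("empty taxon set")
    index = {t: i + 1 for i, t in enumerate(system.taxa)}
    ordered = sorted(
        system.weights.items(), key=lambda kv: (len(kv[0]), tuple(sorted(kv[0])))
    )
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(system.taxa)};\n")
        fh.write("TAXLABELS\n")
        for t in system.taxa:
            fh.write(f"  '{t}'\n")
        fh.write(";\nEND;\n\nBEGIN ST_SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={len(system.taxa)} NSPLITS={len(ordered)};\n")
        fh.write("FORMAT LABELS=NO WEIGHTS=YES;\nMATRIX\n")
        for split, weight in ordered:
            members = " ".join(str(index[t]) for t in sorted(split, key=system.taxa.index))
            fh.write(f"  {weight:.6f}  {members},\n")
        fh.write(";\nEND;\n")


def read_splits_nexus(path) -> SplitSystem:
    """Round-trip reader for files produced by :func:`write_splits_nexus`."""
    text = open(path).read()
    taxa_block = re.search(r"TAXLABELS\s*(.*?);", text, re.S)
    if not taxa_block:
        raise ValueError(f"no TAXLABELS block in {path}")
    taxa = re.findall(r"'([^']*)'", taxa_block.group(1))
    matrix = re.search(r"MATRIX\s*(.*?);", text, re.S)
    if not matrix:
        raise ValueError(f"no MATRIX block in {path}")
    weights: dict[Split, float] = {}
    for line in matrix.group(1).strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        fields = line.split()
        weight = float(fields[0])
        side = frozenset(taxa[int(i) - 1] for i in fields[1:])
        weights[side] = weight
    return SplitSystem(taxa, weights)
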