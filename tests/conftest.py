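"""Shared fixtures and independent oracles."""

import itertools

import numpy as np
import pytest

from phyloconflict.models import SubstitutionModel
from phyloconflict.seqio import GeneAlignment
from phyloconflict.trees import PhyloTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick("((A:0.12,B:0.3):0.08,(C:0.5,D:0.02):0.21);")


@pytest.fixture
def gtr_gi_model():
    return SubstitutionModel(
        "GTR",
        exchangeabilities=[1.2, 2.3, 0.8, 1.1, 3.0, 1.0],
        frequencies=[0.3, 0.2, 0.25, 0.25],
        alpha=0.7,
        pinv=0.15,
    )


def brute_force_loglik(
    alignment: GeneAlignment, tree: PhyloTree, model: SubstitutionModel
) -> float:
    """Exhaustive summation over all ancestral state assignments — the
    independent oracle for the pruning engine. Exponential in the number
    of internal nodes; use only on tiny instances."""
    weights, rates = model.mixture()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    S = model.n_states
    pi = model.frequencies
    total = 0.0
    for site in range(alignment.n_columns):
        site_lik = 0.0
        for wk, rk in zip(weights, rates):
            P = {
                id(n): model.transition_matrix((n.length or 0.0) * rk)
                for n in nodes
                if n.parent is not None
            }
            acc = 0.0
            for assign in itertools.product(range(S), repeat=len(internals)):
                states = {id(n): a for n, a in zip(internals, assign)}
                prob = pi[states[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    parent_state = states[id(n.parent)]
                    if n.is_leaf:
                        partial = model.leaf_partial(alignment.rows[n.name][site])
                        prob *= float((P[id(n)][parent_state] * partial).sum())
                    else:
                        prob *= P[id(n)][parent_state, states[id(n)]]
                acc += prob
            site_lik += wk * acc
        total += np.log(site_lik)
    return float(total)


def random_alignment(rng, species, n_sites, alphabet="ACGT", gap_frac=0.0):
    chars = list(alphabet) + (["-"] if gap_frac else [])
    p = None
    if gap_frac:
        p = [(1 - gap_frac) / len(alphabet)] * len(alphabet) + [gap_frac]
    rows = {s: "".join(rng.choice(chars, n_sites, p=p)) for s in species}
    return GeneAlignment("rand", rows)
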