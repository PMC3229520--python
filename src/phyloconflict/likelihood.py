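"""Tree likelihood by Felsenstein pruning, and branch-length optimization.

The engine works on site patterns (unique alignment columns), mixes
4-category discrete gamma rates with an invariant-sites class, and scales
partial likelihoods per node to avoid underflow. Branch lengths are
optimized by exact coordinate ascent: each edge in turn is optimized by a
bounded one-dimensional search against conditional likelihoods computed
from the subtree below the edge and the rest of the tree above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import SubstitutionModel
from .seqio import GeneAlignment
from .trees import PhyloTree, Node

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0


def _mix_logsumexp(arr: np.ndarray) -> np.ndarray:
    """logsumexp over the leading (rate-category) axis; hot path, so no
    scipy array-api dispatch."""
    if arr.shape[0] == 1:
        return arr[0]
    m = arr.max(axis=0)
    return m + np.log(np.exp(arr - m[None]).sum(axis=0))


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods of one (alignment, tree, model) triple."""

    per_site: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_site.sum())

    def __len__(self) -> int:
        return len(self.per_site)


class TreeLikelihood:
    """Reusable pruning engine bound to one alignment/tree/model triple.

    The tree is referenced, not copied: branch-length edits through
    :meth:`set_length` keep cached conditionals consistent.
    """

    def __init__(
        self, alignment: GeneAlignment, tree: PhyloTree, model: SubstitutionModel
    ):
        self.tree = tree
        self.model = model
        leaves = tree.leaves()
        missing = [l.name for l in leaves if l.name not in alignment.rows]
        if missing:
            raise KeyError(f"tree leaves without sequence: {missing}")

        # Site-pattern compression over the tree's leaf rows.
        mat = np.array([list(alignment.rows[l.name].upper()) for l in leaves])
        patterns, inverse = np.unique(mat, axis=1, return_inverse=True)
        self.pattern_index = inverse
        self.n_patterns = patterns.shape[1]
        self.pattern_counts = np.bincount(inverse, minlength=self.n_patterns)

        self.weights, self.rates = model.mixture()
        K, S, P = len(self.rates), model.n_states, self.n_patterns
        self.K, self.S, self.P = K, S, P

        symbol_partial = {}
        self._leaf_partial: dict[int, np.ndarray] = {}
        for i, leaf in enumerate(leaves):
            arr = np.empty((P, S))
            for p in range(P):
                sym = patterns[i, p]
                if sym not in symbol_partial:
                    symbol_partial[sym] = model.leaf_partial(sym)
                arr[p] = symbol_partial[sym]
            self._leaf_partial[id(leaf)] = arr

        self.nodes = list(tree.postorder())
        # Cached subtree conditionals ("down") and their per-(cat,pattern)
        # log scale factors; populated by _down_pass.
        self._down: dict[int, np.ndarray] = {}
        self._scale: dict[int, np.ndarray] = {}
        self._down_pass()

    # -- core passes -------------------------------------------------------

    def _edge_matrices(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(max(t, 0.0), self.rates)

    def _node_down(self, node: Node) -> None:
        K, P, S = self.K, self.P, self.S
        if node.is_leaf:
            self._down[id(node)] = np.broadcast_to(
                self._leaf_partial[id(node)], (K, P, S)
            )
            self._scale[id(node)] = np.zeros((K, P))
            return
        part = np.ones((K, P, S))
        scale = np.zeros((K, P))
        for child in node.children:
            Pt = self._edge_matrices(child.length or 0.0)
            part = part * np.einsum("kij,kpj->kpi", Pt, self._down[id(child)])
            scale = scale + self._scale[id(child)]
        m = part.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        part = part / m[:, :, None]
        scale = scale + np.log(m)
        self._down[id(node)] = part
        self._scale[id(node)] = scale

    def _down_pass(self) -> None:
        for node in self.nodes:
            self._node_down(node)

    def _update_ancestors(self, node: Node) -> None:
        """Refresh cached conditionals from ``node``'s parent to the root."""
        anc = node.parent
        while anc is not None:
            self._node_down(anc)
            anc = anc.parent

    def pattern_logliks(self) -> np.ndarray:
        root = self.tree.root
        pi = self.model.frequencies
        lk = np.einsum("kps,s->kp", self._down[id(root)], pi)
        logw = np.log(self.weights)
        return _mix_logsumexp(
            np.log(np.maximum(lk, 1e-300)) + self._scale[id(root)] + logw[:, None]
        )

    def site_logliks(self) -> SiteLikelihoods:
        return SiteLikelihoods(self.pattern_logliks()[self.pattern_index])

    def total_loglik(self) -> float:
        return float((self.pattern_logliks() * self.pattern_counts).sum())

    # -- edge-conditional likelihood --------------------------------------

    def _outside(self, target: Node) -> tuple[np.ndarray, np.ndarray]:
        """Conditional likelihood of all data outside ``target``'s subtree,
        as a function of the state at ``target``'s parent (root prior
        included). Returns (values, log-scales)."""
        path = []
        anc = target
        while anc.parent is not None:
            path.append(anc)
            anc = anc.parent
        path.reverse()  # root-side first; last element is target

        K, P, S = self.K, self.P, self.S
        pi = self.model.frequencies
        H = np.broadcast_to(pi, (K, P, S)).copy()  # at the root, above-root prior
        Hscale = np.zeros((K, P))
        for v in path:
            u = v.parent
            G = H.copy()
            Gscale = Hscale.copy()
            for sib in u.children:
                if sib is v:
                    continue
                Pt = self._edge_matrices(sib.length or 0.0)
                G = G * np.einsum("kij,kpj->kpi", Pt, self._down[id(sib)])
                Gscale = Gscale + self._scale[id(sib)]
            m = G.max(axis=2)
            m = np.where(m > 0, m, 1.0)
            G = G / m[:, :, None]
            Gscale = Gscale + np.log(m)
            if v is target:
                return G, Gscale
            Pt = self._edge_matrices(v.length or 0.0)
            H = np.einsum("kpi,kij->kpj", G, Pt)
            Hscale = Gscale
        raise AssertionError("target must not be the root")

    def edge_loglik(
        self, target: Node, t: float, G: np.ndarray, Gscale: np.ndarray
    ) -> float:
        """Total log-likelihood as a function of ``target``'s branch length,
        all other branches fixed."""
        Pt = self._edge_matrices(t)
        lk = np.einsum("kpi,kij,kpj->kp", G, Pt, self._down[id(target)])
        logw = np.log(self.weights)
        pat = _mix_logsumexp(
            np.log(np.maximum(lk, 1e-300))
            + Gscale
            + self._scale[id(target)]
            + logw[:, None]
        )
        return float((pat * self.pattern_counts).sum())

    def set_length(self, node: Node, t: float) -> None:
        node.length = t
        self._update_ancestors(node)

    # -- optimization ------------------------------------------------------

    def optimize_branch_lengths(
        self, tol: float = 1e-4, max_cycles: int = 20, xatol: float = 1e-7
    ) -> float:
        """Coordinate ascent over branch lengths; returns the final logL.

        The total log-likelihood is non-decreasing across accepted moves;
        convergence when a full cycle improves by less than ``tol``.
        """
        edges = [n for n in self.nodes if n.parent is not None]
        # Reversible models see only the sum of the two root-child branch
        # lengths (pulley principle); the redundant coordinate creates a
        # flat ridge that slows coordinate ascent, so fold it away.
        root_children = self.tree.root.children
        if len(root_children) == 2:
            keep, drop = root_children
            keep.length = (keep.length or 0.0) + (drop.length or 0.0)
            drop.length = BRANCH_MIN
            self._node_down(self.tree.root)
            edges = [n for n in edges if n is not drop]
        prev = self.total_loglik()
        for _ in range(max_cycles):
            for node in edges:
                G, Gscale = self._outside(node)
                down = self._down[id(node)]
                const = Gscale + self._scale[id(node)] + np.log(self.weights)[:, None]

                def edge_neg(t):
                    Pt = self._edge_matrices(t)
                    lk = np.einsum("kpi,kij,kpj->kp", G, Pt, down)
                    pat = _mix_logsumexp(np.log(np.maximum(lk, 1e-300)) + const)
                    return -float((pat * self.pattern_counts).sum())

                t0 = node.length if node.length is not None else 0.1
                current = -edge_neg(max(t0, BRANCH_MIN))
                res = minimize_scalar(
                    edge_neg,
                    bounds=(BRANCH_MIN, BRANCH_MAX),
                    method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun >= current:
                    self.set_length(node, float(res.x))
                else:
                    self.set_length(node, max(t0, BRANCH_MIN))
            cur = self.total_loglik()
            if cur - prev < tol:
                break
            prev = cur
        else:
            warnings.warn("branch-length optimization did not converge; "
                          "returning best-so-far", RuntimeWarning)
        return self.total_loglik()


def log_likelihood(
    alignment: GeneAlignment, tree: PhyloTree, model: SubstitutionModel
) -> SiteLikelihoods:
    """Pruning log-likelihood with per-site values.

    Gaps and ambiguity codes contribute partial likelihood 1 for every
    compatible state.
    """
    return TreeLikelihood(alignment, tree, model).site_logliks()


def _model_with(model: SubstitutionModel, theta: np.ndarray) -> SubstitutionModel:
    """Rebuild a model from an unconstrained parameter vector."""
    i = 0
    kwargs: dict = {"kind": model.kind, "ncat": model.ncat}
    if model.kind == "GTR":
        rates = np.exp(theta[i : i + 5])
        kwargs["exchangeabilities"] = np.concatenate([rates, [1.0]])
        i += 5
        logf = np.concatenate([theta[i : i + 3], [0.0]])
        kwargs["frequencies"] = np.exp(logf) / np.exp(logf).sum()
        i += 3
    if model.alpha is not None:
        kwargs["alpha"] = float(np.exp(theta[i]))
        i += 1
    if model.pinv > 0:
        kwargs["pinv"] = float(1.0 / (1.0 + np.exp(-theta[i])))
        i += 1
    return SubstitutionModel(**kwargs)


def _model_theta(model: SubstitutionModel) -> np.ndarray:
    parts = []
    if model.kind == "GTR":
        exch = model.exchangeabilities
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
        ref = exch[2, 3] if exch[2, 3] > 0 else 1.0
        parts.append(np.log([max(exch[i, j], 1e-8) / ref for i, j in idx]))
        f = model.frequencies
        parts.append(np.log(f[:3] / f[3]))
    if model.alpha is not None:
        parts.append([np.log(model.alpha)])
    if model.pinv > 0:
        p = min(max(model.pinv, 1e-6), 1 - 1e-6)
        parts.append([np.log(p / (1 - p))])
    return np.concatenate(parts) if parts else np.zeros(0)


def optimize_branch_lengths(
    alignment: GeneAlignment,
    topology: PhyloTree,
    model: SubstitutionModel,
    optimize_model: bool = False,
    initial_length: float = 0.1,
    tol: float = 1e-4,
    max_cycles: int = 20,
    max_rounds: int = 4,
    xatol: float = 1e-7,
) -> tuple[PhyloTree, SiteLikelihoods, SubstitutionModel]:
    """Fit branch lengths (and optionally model parameters) on a fixed
    topology. Returns (tree with fitted lengths, site log-likelihoods,
    fitted model)."""
    tree = topology.copy()
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            node.length = initial_length
    tree.units = "substitutions"
    engine = TreeLikelihood(alignment, tree, model)
    best = engine.optimize_branch_lengths(tol=tol, max_cycles=max_cycles, xatol=xatol)

    if optimize_model:
        theta = _model_theta(model)
        if theta.size:
            for _ in range(max_rounds):
                lengths = {id(n): n.length for n in tree.postorder()}

                def neg(th):
                    try:
                        m = _model_with(model, th)
                    except ValueError:
                        return 1e12
                    eng = TreeLikelihood(alignment, tree, m)
                    return -eng.total_loglik()

                res = minimize(neg, theta, method="Nelder-Mead",
                               options={"maxiter": 200, "fatol": tol})
                theta = res.x
                model = _model_with(model, theta)
                engine = TreeLikelihood(alignment, tree, model)
                new = engine.optimize_branch_lengths(tol=tol, max_cycles=max_cycles)
                if new - best < tol:
                    best = max(new, best)
                    break
                best = new
                del lengths
    return tree, engine.site_logliks(), model
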