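"""Node-age estimation by nonparametric rate smoothing on a log scale.

Ages minimize the sum of squared differences of log substitution rates
between adjacent branches (with the two root-child branches compared to
their mean log rate), subject to ultrametricity, hard calibration bounds,
and optionally a fixed root age. Ages are parameterized as per-node
proportions of the parent age, which enforces parent > child ordering by
construction; the constrained minimization is restarted with jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .trees import PhyloTree, Node, UNIT_MA

_MIN_BRANCH = 1e-8
_MIN_DURATION = 1e-9


@dataclass
class CalibrationPoint:
    """Age bounds (Ma) on the MRCA of a taxon set."""

    taxa: tuple[str, ...]
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("calibration lower bound exceeds upper bound")
        if self.lower is None and self.upper is None:
            raise ValueError("calibration needs at least one bound")


@dataclass
class Chronogram:
    """Ultrametric tree with node ages (Ma) and implied per-branch rates."""

    tree: PhyloTree
    ages: dict[int, float]      # keyed by id(node)
    rates: dict[int, float]     # substitution rate on the branch above node
    objective: float

    @property
    def root_age(self) -> float:
        return self.ages[id(self.tree.root)]

    def age_of(self, taxa: Sequence[str]) -> float:
        return self.ages[id(self.tree.find_mrca(taxa))]

    def to_newick(self) -> str:
        return self.tree.to_newick()


def read_calibrations_tsv(path) -> list[CalibrationPoint]:
    """TSV columns: comma-separated taxa, lower, upper ('' for absent)."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            taxa, lower, upper = line.rstrip("\n").split("\t")
            out.append(
                CalibrationPoint(
                    tuple(taxa.split(",")),
                    float(lower) if lower else None,
                    float(upper) if upper else None,
                )
            )
    return out


def _smoothness(tree: PhyloTree, ages: dict[int, float]) -> float:
    """NPRS-LOG objective over adjacent branch pairs."""
    log_rate: dict[int, float] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        duration = max(ages[id(node.parent)] - ages[id(node)], _MIN_DURATION)
        log_rate[id(node)] = np.log(max(node.length or 0.0, _MIN_BRANCH) / duration)
    total = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            continue
        if node.parent is None:
            mean = np.mean([log_rate[id(c)] for c in node.children])
            total += sum((log_rate[id(c)] - mean) ** 2 for c in node.children)
        else:
            for child in node.children:
                total += (log_rate[id(child)] - log_rate[id(node)]) ** 2
    return float(total)


def nprs_log_date(
    tree: PhyloTree,
    calibrations: Sequence[CalibrationPoint] = (),
    fixed_root_age: Optional[float] = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> Chronogram:
    """Convert a tree with substitution branch lengths into a chronogram.

    Requires at least one calibration or a fixed root age. Calibration
    bounds are enforced as hard constraints; tips are fixed at age 0.
    """
    if fixed_root_age is None and not calibrations:
        raise ValueError("need a calibration or a fixed root age")
    work = tree.copy()
    floored = 0
    for node in work.postorder():
        if node.parent is not None and (node.length or 0.0) < _MIN_BRANCH:
            node.length = _MIN_BRANCH
            floored += 1
    if floored:
        warnings.warn(
            f"{floored} branch length(s) floored at {_MIN_BRANCH}", RuntimeWarning
        )

    internals = [n for n in work.preorder() if not n.is_leaf]
    index = {id(n): k for k, n in enumerate(internals)}
    cal_nodes = []
    for cal in calibrations:
        node = work.find_mrca(cal.taxa)
        if node.is_leaf:
            raise ValueError(f"calibration MRCA of {cal.taxa} is a tip")
        cal_nodes.append((index[id(node)], cal))

    root_free = fixed_root_age is None
    # parameters: optional root age, then a proportion in (0,1) per
    # non-root internal node (preorder, so parents precede children)
    n_props = len(internals) - 1

    # depth-based feasible start: ages proportional to mean root-to-tip
    # path length below each node
    mean_depth = {}
    for node in work.postorder():
        if node.is_leaf:
            mean_depth[id(node)] = 0.0
        else:
            mean_depth[id(node)] = float(
                np.mean(
                    [mean_depth[id(c)] + max(c.length or 0.0, _MIN_BRANCH)
                     for c in node.children]
                )
            )

    def unpack(x: np.ndarray) -> dict[int, float]:
        ages = {}
        if root_free:
            root_age, props = x[0], x[1:]
        else:
            root_age, props = fixed_root_age, x
        for k, node in enumerate(internals):
            if k == 0:
                ages[id(node)] = float(root_age)
            else:
                ages[id(node)] = float(props[k - 1]) * ages[id(node.parent)]
        for node in work.postorder():
            if node.is_leaf:
                ages[id(node)] = 0.0
        return ages

    def objective(x: np.ndarray) -> float:
        return _smoothness(work, unpack(x))

    lower_root = max(
        (c.lower for _, c in cal_nodes if c.lower is not None), default=1.0
    )
    x0_parts = []
    if root_free:
        x0_parts.append([max(2.0 * lower_root, 1.0)])
    for node in internals[1:]:
        parent_depth = max(mean_depth[id(node.parent)], _MIN_DURATION)
        x0_parts.append([min(max(mean_depth[id(node)] / parent_depth, 0.05), 0.95)])
    x0 = np.concatenate(x0_parts) if x0_parts else np.zeros(0)

    bounds = ([(lower_root, None)] if root_free else []) + [(1e-4, 1 - 1e-4)] * n_props
    constraints = []
    for k, cal in cal_nodes:
        if cal.lower is not None:
            constraints.append(
                {
                    "type": "ineq",
                    "fun": (lambda x, k=k, lo=cal.lower: unpack(x)[id(internals[k])] - lo),
                }
            )
        if cal.upper is not None:
            constraints.append(
                {
                    "type": "ineq",
                    "fun": (lambda x, k=k, hi=cal.upper: hi - unpack(x)[id(internals[k])]),
                }
            )

    rng = np.random.default_rng(seed)
    best_x, best_val = None, np.inf
    for attempt in range(max(n_restarts, 1)):
        if attempt == 0 or x0.size == 0:
            start = x0
        else:
            jitter = rng.normal(0.0, 0.1, size=x0.shape)
            start = np.clip(x0 + jitter, [b[0] if b[0] is not None else -np.inf for b in bounds],
                            [b[1] if b[1] is not None else np.inf for b in bounds])
        res = minimize(
            objective,
            start,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        violated = any(c["fun"](res.x) < -1e-6 for c in constraints)
        if not violated and res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    if best_x is None:
        raise RuntimeError("infeasible calibration set: no restart satisfied bounds")
    if best_val > objective(x0) + 1e-9 and not any(
        c["fun"](x0) < -1e-9 for c in constraints
    ):
        best_x, best_val = x0, float(objective(x0))  # never worse than start

    ages = unpack(best_x)
    rates = {}
    for node in work.postorder():
        if node.parent is None:
            continue
        duration = max(ages[id(node.parent)] - ages[id(node)], _MIN_DURATION)
        rates[id(node)] = max(node.length or 0.0, _MIN_BRANCH) / duration
    chrono = work.copy()
    # rebuild with branch lengths in Ma
    mapping = dict(zip([id(n) for n in work.postorder()], chrono.postorder()))
    for orig in work.postorder():
        dup = mapping[id(orig)]
        if orig.parent is not None:
            dup.length = ages[id(orig.parent)] - ages[id(orig)]
    chrono.units = UNIT_MA
    chrono_ages = {id(mapping[i]): a for i, a in ages.items()}
    chrono_rates = {id(mapping[i]): r for i, r in rates.items()}
    return Chronogram(chrono, chrono_ages, chrono_rates, best_val)
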