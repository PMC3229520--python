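"""Alignment-property influence analysis.

Five per-gene properties (length, longest pairwise distance, sum of
pairwise distances, codon-usage deviation, nucleotide-usage deviation)
are computed, genes are split at the median of each property, sole-best
topology counts are tabulated per group for a fixed set of top trees, and
a 2xK Pearson chi-square of independence quantifies the difference.

Usage deviations are Euclidean distances between a gene's frequency
vector (61 sense codons, or 4 nucleotides) and the mean vector across all
genes; the metric choice is a documented convention, echoed in output
metadata by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .census import GeneScoreMatrix, DEFAULT_MARGINS
from .seqio import GeneAlignment, pairwise_distance_matrix

_STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in _STOP_CODONS
)

PROPERTY_NAMES = (
    "alignment_length",
    "longest_pairwise_distance",
    "sum_pairwise_distances",
    "codon_usage_deviation",
    "nucleotide_usage_deviation",
)


@dataclass
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _codon_frequencies(alignment: GeneAlignment) -> np.ndarray:
    if alignment.n_columns % 3 != 0:
        raise ValueError(
            f"{alignment.locus_id}: column count {alignment.n_columns} not a "
            "multiple of 3 (codon metric needs coding structure)"
        )
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for seq in alignment.rows.values():
        seq = seq.upper()
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    vec = np.array([counts[c] for c in SENSE_CODONS], dtype=float)
    total = vec.sum()
    return vec / total if total else vec


def _nucleotide_frequencies(alignment: GeneAlignment) -> np.ndarray:
    vec = np.zeros(4)
    for seq in alignment.rows.values():
        s = seq.upper()
        for i, b in enumerate("ACGT"):
            vec[i] += s.count(b)
    total = vec.sum()
    return vec / total if total else vec


def compute_properties(alignments: Sequence[GeneAlignment]) -> pd.DataFrame:
    """Per-gene property table (rows indexed by locus id).

    Distances are uncorrected p-distances with pairwise deletion; usage
    deviations are Euclidean distances from the across-gene mean
    frequency vector.
    """
    if not alignments:
        raise ValueError("no alignments")
    codon_freqs = np.stack([_codon_frequencies(a) for a in alignments])
    nuc_freqs = np.stack([_nucleotide_frequencies(a) for a in alignments])
    codon_mean = codon_freqs.mean(axis=0)
    nuc_mean = nuc_freqs.mean(axis=0)
    rows = []
    for i, aln in enumerate(alignments):
        if len(aln.rows) < 2:
            dists = []
        else:
            dists = [
                d for d in pairwise_distance_matrix(aln).values() if not np.isnan(d)
            ]
        rows.append(
            {
                "alignment_length": aln.n_columns,
                "longest_pairwise_distance": max(dists) if dists else 0.0,
                "sum_pairwise_distances": float(np.sum(dists)),
                "codon_usage_deviation": float(
                    np.linalg.norm(codon_freqs[i] - codon_mean)
                ),
                "nucleotide_usage_deviation": float(
                    np.linalg.norm(nuc_freqs[i] - nuc_mean)
                ),
            }
        )
    return pd.DataFrame(rows, index=[a.locus_id for a in alignments])


def median_split(values: pd.Series) -> tuple[list[str], list[str]]:
    """Split gene ids into a low and a high group of near-equal size.

    Ties at the median are resolved deterministically by stable sort on
    (value, gene id); with an odd count the low group gets the extra
    gene. Every low-group value <= every high-group value.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 genes")
    order = values.to_frame("v").reset_index(names="g")
    order = order.sort_values(["v", "g"], kind="stable")
    n_low = (len(order) + 1) // 2
    low = order["g"].iloc[:n_low].tolist()
    high = order["g"].iloc[n_low:].tolist()
    return low, high


def sole_best_counts(
    matrix: GeneScoreMatrix,
    group: Sequence[str],
    top_trees: Sequence[int],
    equal_tol: Optional[float] = None,
) -> dict[int, int]:
    """How often each of ``top_trees`` is the *unique* best topology
    (over ALL topologies, uniqueness within ``equal_tol``) among the
    genes of ``group``. Tied genes contribute to no tree."""
    if not group:
        raise ValueError("empty group")
    unknown = set(top_trees) - set(matrix.topologies)
    if unknown:
        raise KeyError(f"top_trees not in matrix: {sorted(unknown)}")
    if equal_tol is None:
        equal_tol = DEFAULT_MARGINS[matrix.mode][0]
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    counts = {t: 0 for t in top_trees}
    for gene in group:
        row = matrix.scores[gene_index[gene]]
        near_best = np.flatnonzero(row >= row.max() - equal_tol)
        if len(near_best) != 1:
            continue
        tree = matrix.topologies[near_best[0]]
        if tree in counts:
            counts[tree] += 1
    return counts


def chi_square_2xk(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson's chi-square of independence on a 2xK contingency table
    (no continuity correction), df = K - 1."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margins (zero row or column sum)")
    res = chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


def influence_analysis(
    alignments: Sequence[GeneAlignment],
    matrix: GeneScoreMatrix,
    top_trees: Sequence[int],
    equal_tol: Optional[float] = None,
) -> pd.DataFrame:
    """Full five-property table: per property, the two groups' sole-best
    counts over ``top_trees`` plus the chi-square statistic and p."""
    props = compute_properties(alignments)
    props = props.loc[[g for g in props.index if g in set(matrix.genes)]]
    rows = []
    for prop in PROPERTY_NAMES:
        low, high = median_split(props[prop])
        low_counts = sole_best_counts(matrix, low, top_trees, equal_tol)
        high_counts = sole_best_counts(matrix, high, top_trees, equal_tol)
        table = [
            [low_counts[t] for t in top_trees],
            [high_counts[t] for t in top_trees],
        ]
        try:
            chi = chi_square_2xk(table)
            stat, p = chi.statistic, chi.p_value
        except ValueError:
            stat, p = float("nan"), float("nan")
        for label, counts in (("low", low_counts), ("high", high_counts)):
            rows.append(
                {"property": prop, "group": label, "chi2": stat, "p": p}
                | {f"tree_{t}": counts[t] for t in top_trees}
            )
    return pd.DataFrame(rows)
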