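"""Per-gene topology scoring, best/rejected census, and the SH test.

The census follows the "separate"-analysis rules: a topology is *among
the best* for a gene when its score is within ``equal_tol`` of that
gene's maximum, and *rejected* when it falls more than ``reject_margin``
units below the maximum. Default margins depend on the score mode:
maximized log-likelihoods use (tie tolerance ~0, rejection 2 units);
marginal log-likelihoods use (0.5, 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import optimize_branch_lengths
from .models import SubstitutionModel
from .seqio import GeneAlignment
from .trees import PhyloTree

MODE_ML = "ML"
MODE_MARGINAL = "mLogL"

#: Default (equal_tol, reject_margin) per score mode. The ML tie tolerance
#: is 1e-2 rather than exactly 0 to absorb optimizer round-off; pass
#: ``equal_tol=0.0`` for the strict behavior.
DEFAULT_MARGINS = {MODE_ML: (1e-2, 2.0), MODE_MARGINAL: (0.5, 10.0)}


@dataclass
class GeneScoreMatrix:
    """Genes x topologies matrix of (marginal) log-likelihoods."""

    genes: list[str]
    topologies: list[int]
    scores: np.ndarray
    mode: str = MODE_ML
    site_logliks: Optional[dict[tuple[str, int], np.ndarray]] = None
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.topologies)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite (exclude failed genes)")
        if self.mode not in DEFAULT_MARGINS:
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.topologies)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, mode: str = MODE_ML) -> "GeneScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            topologies=[int(t) for t in df.columns],
            scores=df.to_numpy(),
            mode=mode,
        )


@dataclass
class CensusTable:
    """Per-topology best counts, rejection counts, and summed-logL deficits."""

    topologies: list[int]
    best_count: np.ndarray
    rejected_count: np.ndarray
    delta_sum_logL: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "best": self.best_count,
                "rejected": self.rejected_count,
                "delta_sum_logL": self.delta_sum_logL,
            },
            index=pd.Index(self.topologies, name="tree"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.1f")


@dataclass
class ShResult:
    """SH-test p-values per topology; the best topology has pSH = 1."""

    topologies: list[int]
    p_values: np.ndarray
    alpha: float = 0.05

    @property
    def rejected(self) -> np.ndarray:
        return self.p_values < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pSH": self.p_values, "rejected": self.rejected},
            index=pd.Index(self.topologies, name="tree"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.5f")


def score_genes(
    alignments: Iterable[GeneAlignment],
    topology_set: Sequence[PhyloTree],
    model: SubstitutionModel,
    optimize_model: bool = False,
    keep_site_logliks: bool = False,
    **fit_kwargs,
) -> GeneScoreMatrix:
    """Optimize every candidate topology against every gene.

    Genes whose optimization fails for any topology are excluded from the
    matrix; the reason is recorded in ``excluded``.
    """
    topology_ids = list(range(1, len(topology_set) + 1))
    genes, rows = [], []
    site_logliks: dict[tuple[str, int], np.ndarray] = {}
    excluded: dict[str, str] = {}
    for aln in alignments:
        row = np.empty(len(topology_set))
        try:
            for t, topo in enumerate(topology_set):
                _, sl, _ = optimize_branch_lengths(
                    aln, topo, model, optimize_model=optimize_model, **fit_kwargs
                )
                row[t] = sl.total
                if keep_site_logliks:
                    site_logliks[(aln.locus_id, topology_ids[t])] = sl.per_site
        except Exception as exc:  # noqa: BLE001 - per-gene failures are logged
            excluded[aln.locus_id] = f"{type(exc).__name__}: {exc}"
            for tid in topology_ids:
                site_logliks.pop((aln.locus_id, tid), None)
            continue
        genes.append(aln.locus_id)
        rows.append(row)
    if excluded:
        warnings.warn(f"{len(excluded)} gene(s) excluded from scoring", RuntimeWarning)
    return GeneScoreMatrix(
        genes=genes,
        topologies=topology_ids,
        scores=np.array(rows).reshape(len(genes), len(topology_set)),
        mode=MODE_ML,
        site_logliks=site_logliks if keep_site_logliks else None,
        excluded=excluded,
    )


def tally(
    matrix: GeneScoreMatrix,
    equal_tol: Optional[float] = None,
    reject_margin: Optional[float] = None,
) -> CensusTable:
    """Best/rejected census and summed-likelihood comparison.

    best_count[t]  = #genes with score >= gene max - equal_tol (ties count
    for every tied topology); rejected_count[t] = #genes with score <
    gene max - reject_margin; delta_sum_logL[t] = column sum minus the
    best column sum (0 for the best topology).
    """
    if matrix.scores.size == 0:
        raise ValueError("empty score matrix")
    default_tol, default_margin = DEFAULT_MARGINS[matrix.mode]
    equal_tol = default_tol if equal_tol is None else equal_tol
    reject_margin = default_margin if reject_margin is None else reject_margin
    scores = matrix.scores
    gene_max = scores.max(axis=1, keepdims=True)
    best = (scores >= gene_max - equal_tol).sum(axis=0)
    rejected = (scores < gene_max - reject_margin).sum(axis=0)
    sums = scores.sum(axis=0)
    return CensusTable(
        topologies=list(matrix.topologies),
        best_count=best,
        rejected_count=rejected,
        delta_sum_logL=sums - sums.max(),
        n_genes=scores.shape[0],
    )


def sh_test(
    site_logliks: Mapping[int, np.ndarray],
    n_replicates: int = 10_000,
    seed: int = 1,
    alpha: float = 0.05,
) -> ShResult:
    """Shimodaira-Hasegawa test with RELL bootstrap.

    For each topology the observed deficit d_t = max L - L_t is compared
    to the null distribution of centered replicate deficits: resampled
    per-site log-likelihood sums are centered per topology, and the
    replicate deficit is max_t' S_t' - S_t. p_t = fraction of replicates
    with a deficit at least d_t; the maximum-likelihood topology gets
    p = 1 by construction.
    """
    topologies = list(site_logliks)
    if len(topologies) < 2:
        raise ValueError("need at least 2 topologies")
    vectors = [np.asarray(site_logliks[t], dtype=float) for t in topologies]
    n_sites = len(vectors[0])
    if any(len(v) != n_sites for v in vectors):
        raise ValueError("per-site vectors must have equal length")
    mat = np.stack(vectors)  # (T, n_sites)
    totals = mat.sum(axis=1)
    observed_deficit = totals.max() - totals

    rng = np.random.default_rng(seed)
    # RELL: resampling sites with replacement == multinomial site weights;
    # computed in chunks to bound memory at large site counts.
    chunks = []
    done = 0
    while done < n_replicates:
        b = min(500, n_replicates - done)
        weights = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=b)
        chunks.append(weights.astype(float) @ mat.T)  # (b, T)
        done += b
    rep = np.concatenate(chunks).T  # (T, B)
    centered = rep - rep.mean(axis=1, keepdims=True)
    rep_deficit = centered.max(axis=0, keepdims=True) - centered
    p = (rep_deficit >= observed_deficit[:, None]).mean(axis=1)
    p[np.argmax(totals)] = 1.0
    return ShResult(topologies=topologies, p_values=p, alpha=alpha)
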