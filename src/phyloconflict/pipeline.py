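"""End-to-end orchestration: synthetic data -> filters -> per-gene scoring
-> census -> SH test -> networks -> property influence -> retro markers
-> dating, with a machine-readable run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .census import GeneScoreMatrix, score_genes, sh_test, tally
from .dating import nprs_log_date
from .likelihood import optimize_branch_lengths
from .models import SubstitutionModel
from .network import consensus_splits, marker_split_network, write_splits_nexus
from .properties import influence_analysis
from .retro import call_presence_absence, tally_support
from .seqio import concatenate, divergence_filter
from .synthetic import (
    SpeciesTreeSpec,
    SyntheticConfig,
    build_species_tree,
    simulate_gene_alignments,
    simulate_retro_loci,
)
from .trees import enumerate_rooted_topologies, graft, PhyloTree, Node

ALL_STAGES = (
    "simulate",
    "filter",
    "score",
    "census",
    "shtest",
    "network",
    "properties",
    "retro",
    "date",
)


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and the synthetic recipe for one run."""

    seed: int = 1
    n_genes: int = 12
    gene_length: int = 300
    n_introns: int = 30
    topology_id: int = 14
    internal_branch: float = 0.5
    substitution_scale: float = 0.02
    insertion_rate: float = 0.3
    divergence_threshold: float = 0.30
    equal_tol: float = 1e-2
    reject_margin: float = 2.0
    sh_replicates: int = 1000
    network_threshold: float = 0.08
    marker_min_overlap: int = 60
    marker_max_gap: int = 10
    marker_significance_count: int = 3
    root_age: float = 92.0
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})

    def __post_init__(self):
        if not 0 <= self.divergence_threshold <= 1:
            raise ValueError("divergence_threshold in [0,1]")
        if not 0 <= self.network_threshold <= 1:
            raise ValueError("network_threshold in [0,1]")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        stages = {s: True for s in ALL_STAGES}
        stages.update(self.stages)
        self.stages = stages

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            species_tree=SpeciesTreeSpec(
                topology_id=self.topology_id,
                internal_branch=self.internal_branch,
                substitution_scale=self.substitution_scale,
            ),
            n_genes=self.n_genes,
            gene_length=self.gene_length,
            n_introns=self.n_introns,
            insertion_rate=self.insertion_rate,
            seed=self.seed,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "divergence": config.divergence_threshold,
            "equal_tol": config.equal_tol,
            "reject_margin": config.reject_margin,
            "network_threshold": config.network_threshold,
            "marker_min_overlap": config.marker_min_overlap,
            "marker_max_gap": config.marker_max_gap,
            "marker_significance_count": config.marker_significance_count,
            "usage_deviation_metric": "euclidean",
        },
        "stages": {},
        "exclusions": {},
    }
    syn = config.synthetic_config()
    species_tree = build_species_tree(syn.species_tree)
    orders = list(syn.species_tree.orders)
    outgroups = list(syn.species_tree.outgroups)
    model = SubstitutionModel("JC")
    alignments = None
    matrix: Optional[GeneScoreMatrix] = None
    loci = None

    current_stage = "simulate"

    def stage_on(name):
        nonlocal current_stage
        current_stage = name
        enabled = config.stages.get(name, True)
        manifest["stages"][name] = {"enabled": enabled}
        return enabled

    def done(name, **info):
        manifest["stages"][name].update(info, status="ok")

    try:
        if stage_on("simulate"):
            t0 = time.time()
            alignments, gene_trees = simulate_gene_alignments(syn)
            loci = simulate_retro_loci(species_tree, syn)
            done("simulate", n_genes=len(alignments), n_loci=len(loci),
                 seconds=round(time.time() - t0, 2))
        if alignments is None:
            raise StageError("simulate", "pipeline currently requires the "
                             "simulate stage as its data source")

        if stage_on("filter"):
            kept, log_lines = [], []
            for aln in alignments:
                decision = divergence_filter(aln, config.divergence_threshold)
                if decision.keep:
                    kept.append(aln)
                else:
                    log_lines.append(
                        f"{aln.locus_id}\tmax_difference={decision.max_difference:.4f}"
                        f"\tpair={decision.worst_pair}"
                    )
                    manifest["exclusions"][aln.locus_id] = "divergence_filter"
            (out / "filter.log").write_text("\n".join(log_lines) + "\n" if log_lines else "")
            done("filter", kept=len(kept), discarded=len(log_lines))
            alignments = kept

        topologies = enumerate_rooted_topologies(orders)
        subtrees = {o: PhyloTree(Node(o)) for o in orders}
        candidate_trees = [graft(t, subtrees, outgroups) for t in topologies]

        if stage_on("score"):
            if not alignments:
                raise StageError("score", "no alignments left after filtering")
            t0 = time.time()
            matrix = score_genes(alignments, candidate_trees, model)
            matrix.to_tsv(out / "gene_scores.tsv")
            for gene, reason in matrix.excluded.items():
                manifest["exclusions"][gene] = f"score: {reason}"
            done("score", n_genes=len(matrix.genes),
                 n_topologies=len(matrix.topologies),
                 seconds=round(time.time() - t0, 2))

        if stage_on("census"):
            if matrix is None:
                raise StageError("census", "requires the score stage")
            table = tally(matrix, config.equal_tol, config.reject_margin)
            table.to_tsv(out / "census.tsv")
            done("census", best_tree=int(table.topologies[
                int(np.argmax(table.best_count))]))

        if stage_on("shtest"):
            concat, coverage = concatenate(alignments)
            coverage.to_tsv(out / "coverage.tsv")
            site_ll = {}
            for tid, tree in enumerate(candidate_trees, start=1):
                _, sl, _ = optimize_branch_lengths(concat, tree, model)
                site_ll[tid] = sl.per_site
            sh = sh_test(site_ll, n_replicates=config.sh_replicates,
                         seed=config.seed)
            sh.to_tsv(out / "sh_test.tsv")
            done("shtest", best_tree=int(sh.topologies[int(np.argmax(sh.p_values))]),
                 n_not_rejected=int((~sh.rejected).sum()))

        if stage_on("network"):
            if matrix is None:
                raise StageError("network", "requires the score stage")
            gene_best_trees = []
            for row in matrix.scores:
                best = int(np.argmax(row))
                gene_best_trees.append(candidate_trees[best])
            system = consensus_splits(gene_best_trees, config.network_threshold)
            write_splits_nexus(system, out / "consensus_network.nex")
            done("network", n_splits=len(system))

        if stage_on("properties"):
            if matrix is None:
                raise StageError("properties", "requires the score stage")
            census_table = tally(matrix, config.equal_tol, config.reject_margin)
            order_ids = np.argsort(census_table.best_count)[::-1][:5]
            top5 = sorted(int(census_table.topologies[i]) for i in order_ids)
            table = influence_analysis(alignments, matrix, top5, config.equal_tol)
            table.to_csv(out / "property_influence.tsv", sep="\t", index=False)
            done("properties", top_trees=top5)

        if stage_on("retro"):
            if loci is None:
                raise StageError("retro", "requires the simulate stage")
            patterns = []
            for locus in loci:
                for interval in locus.insert_columns:
                    patterns.append(
                        call_presence_absence(
                            locus, interval,
                            min_overlap=config.marker_min_overlap,
                            max_gap=config.marker_max_gap,
                        )
                    )
            informative = [p for p in patterns if p.informative]
            hypotheses = {}
            for p in informative:
                name = "+".join(sorted(p.present_set))
                hypotheses[name] = p.present_set
            tallies = tally_support(
                informative, hypotheses,
                min_markers=config.marker_significance_count,
            )
            tallies.to_tsv(out / "retro_tally.tsv")
            taxa = sorted(species_tree.leaf_names())
            sides = {name: frozenset(side) for name, side in hypotheses.items()}
            nonzero = {name: c for name, c in tallies.counts.items() if c > 0}
            if nonzero:
                system = marker_split_network(nonzero, taxa, hypotheses=sides)
                write_splits_nexus(system, out / "retro_network.nex")
            done("retro", n_patterns=len(patterns),
                 n_informative=len(informative))

        if stage_on("date"):
            concat, _ = concatenate(alignments)
            true_tree = candidate_trees[config.topology_id - 1]
            fitted, _, _ = optimize_branch_lengths(concat, true_tree, model)
            chrono = nprs_log_date(fitted, fixed_root_age=config.root_age,
                                   seed=config.seed)
            (out / "chronogram.nwk").write_text(chrono.to_newick() + "\n")
            done("date", root_age=chrono.root_age,
                 objective=round(chrono.objective, 6))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(current_stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
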