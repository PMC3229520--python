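# phyloconflict

A toolkit for analyzing conflicting phylogenomic signal among a small set
of clades, built around an end-to-end synthetic study of four focal
groups plus outgroups. It covers:

- **Synthetic data** (`phyloconflict.synthetic`): ultrametric species
  trees in coalescent units, multispecies-coalescent gene trees
  (via msprime), sequence alignments under GTR/JC/WAG +Γ+I, and intron
  loci carrying Dollo (never-lost) LINE1-like insertions with exon
  flanks, RepeatMasker-style annotations, and per-locus truth tables.
- **Alignment I/O and filters** (`phyloconflict.seqio`): FASTA
  alignments, back-translation of amino acid alignments to nucleotides,
  the 30% maximum-pairwise-difference discard rule, and locus
  concatenation with coverage reporting.
- **Likelihood engine** (`phyloconflict.likelihood`, `.models`,
  `.trees`): Felsenstein pruning with 4-category discrete gamma plus
  invariant sites, per-node scaling, exact coordinate-ascent
  branch-length optimization, exhaustive rooted-topology enumeration
  ((2n−3)!! trees in a stable canonical order), and grafting of
  order-level topologies onto full species trees.
- **Topology census and SH test** (`phyloconflict.census`): per-gene
  scores for all candidate topologies, best/rejected tallies with
  configurable tie and rejection margins (ML: ~0 / 2 logL units;
  marginal-likelihood mode: 0.5 / 10 units), summed-likelihood
  comparison, and the Shimodaira–Hasegawa test with RELL bootstrap.
- **Split networks** (`phyloconflict.network`): threshold consensus
  split systems from gene-tree sets, marker-count networks from
  retroposon tallies, and SplitsTree4-compatible NEXUS export.
- **Property influence** (`phyloconflict.properties`): five per-gene
  alignment properties, median splits, sole-best topology counts, and
  2×K Pearson chi-square tests.
- **Retroposon screen** (`phyloconflict.retro`): intron harvesting
  (300 < length < 3000, 80 bp exon flanks), RepeatMasker `.out` intake
  filtered to LINE1, orthologous-intron anchoring by local flank
  alignment, presence/absence calling, and hypothesis tallies with the
  ≥3-insertion significance rule.
- **Dating** (`phyloconflict.dating`): nonparametric rate smoothing on a
  log scale (squared differences of log rates between adjacent branches)
  with hard calibration bounds and an optional fixed root age.

## CLI

```bash
# write the default configuration (all thresholds at full precision)
phyloconflict write-config --out config.yaml

# generate a synthetic dataset (FASTA genes, newick gene trees,
# RepeatMasker-style repeat table, truth TSV)
phyloconflict simulate --config config.yaml --out data/ --seed 1

# run the full pipeline: filter -> score -> census -> SH test ->
# consensus network -> property influence -> retro markers -> dating
phyloconflict run --config config.yaml --out run/ --seed 1
# optionally disable stages:
phyloconflict run --out run/ --skip date --skip retro
```

Pipeline outputs are TSV tables (gene scores, census, SH test, property
influence, marker tallies), NEXUS split networks, a newick chronogram,
and `manifest.json` recording versions, thresholds, the seed, and every
excluded locus with a machine-readable reason. Exit codes: 0 success,
2 configuration error, 3 data error.

## Notes on conventions

- Branch-length units are tagged (`coalescent`, `substitutions`, `Ma`);
  a single scalar maps coalescent units to substitutions/site so that
  incomplete-lineage-sorting intensity and sequence divergence can be
  tuned independently.
- Topology numbering 1–15 (four labels) follows the canonical
  enumeration order: topologies sorted by their canonical newick string
  (children ordered by smallest tip label). The numbering is stable
  across runs and documented by `enumerate_rooted_topologies`.
- p-distances use pairwise deletion by default (complete deletion is
  available); coverage counts ambiguity codes as covered.
- All randomness flows from explicit seeds; per-locus streams are
  derived from (master seed, locus index), so any locus can be
  regenerated in isolation.
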