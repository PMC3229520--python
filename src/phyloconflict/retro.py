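"""In-silico retroposon presence/absence screening.

Pipeline stages: harvest introns of suitable length with exon flanks,
ingest RepeatMasker annotations restricted to LINE1 elements, locate
orthologous introns in other species by local alignment of the 80-bp exon
flanks, call per-species presence/absence of the element across a four-way
alignment, and tally the phylogenetic hypotheses supported by informative
patterns.

The paper-era manual screening step is replaced by explicit, configurable
thresholds (minimum filled overlap for a presence call, maximum residual
gap for an absence call, flank-anchoring identity). These defaults are an
operationalization, not a reconstruction of any manual protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Seq import Seq

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"

_BASES = set("ACGT")


@dataclass
class RepeatAnnotation:
    """One repeat interval, 0-based half-open, on a named query sequence."""

    query: str
    start: int
    end: int
    strand: str
    repeat_name: str
    family: str
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RetroLocus:
    """One candidate marker locus: an aligned intron (plus exon flanks)
    across species, with repeat annotations and optional simulation truth.
    """

    locus_id: str
    rows: dict[str, str]                       # aligned, gapped
    flank_length: int = 80
    annotations: list[RepeatAnnotation] = field(default_factory=list)
    #: column intervals (0-based half-open, alignment coordinates) of each
    #: annotated insertion
    insert_columns: list[tuple[int, int]] = field(default_factory=list)
    #: simulation truth: carrier leaf set per insertion (None for real data)
    truth_carriers: Optional[list[frozenset[str]]] = None

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"locus {self.locus_id}: rows not aligned")
        for start, end in self.insert_columns:
            if not (0 <= start <= end <= next(iter(lengths), 0)):
                raise ValueError(f"locus {self.locus_id}: interval outside alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class PresencePattern:
    """Per-species present/absent/ambiguous call for one insertion."""

    locus_id: str
    calls: dict[str, str]

    @property
    def present_set(self) -> frozenset[str]:
        return frozenset(s for s, c in self.calls.items() if c == PRESENT)

    @property
    def absent_set(self) -> frozenset[str]:
        return frozenset(s for s, c in self.calls.items() if c == ABSENT)

    @property
    def informative(self) -> bool:
        """Informative for inter-group splits: the element is present in
        two or three species and cleanly absent in all the rest."""
        n_present = len(self.present_set)
        return (
            n_present in (2, 3)
            and len(self.absent_set) == len(self.calls) - n_present
        )


@dataclass
class HypothesisTally:
    counts: dict[str, int]
    significant: dict[str, bool]
    min_markers: int = 3

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hypothesis\tmarkers\tsignificant\n")
            for name, n in self.counts.items():
                fh.write(f"{name}\t{n}\t{'yes' if self.significant[name] else 'no'}\n")


# ---------------------------------------------------------------------------
# intron harvesting


@dataclass
class Intron:
    gene_id: str
    index: int
    sequence: str
    upstream_flank: str
    downstream_flank: str
    start: int          # 0-based, gene-forward orientation
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def flanked_sequence(self) -> str:
        return self.upstream_flank + self.sequence + self.downstream_flank


def harvest_introns(
    exons: Sequence[tuple[int, int]],
    sequence: str,
    gene_id: str = "gene",
    strand: str = "+",
    min_len: int = 300,
    max_len: int = 3000,
    flank_len: int = 80,
) -> tuple[list[Intron], list[str]]:
    """Introns with ``min_len < length < max_len`` (strict) and full exon
    flanks. Returns (introns, drop log). Coordinates are 0-based half-open
    on the given sequence; minus-strand genes are reverse-complemented
    first so output is in gene orientation.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    exons = sorted(exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 > s2:
            raise ValueError(f"{gene_id}: exons out of order or overlapping")
    if strand == "-":
        n = len(sequence)
        sequence = str(Seq(sequence).reverse_complement())
        exons = sorted((n - e, n - s) for s, e in exons)
    sequence = sequence.upper()

    introns: list[Intron] = []
    dropped: list[str] = []
    for i, ((_, up_end), (down_start, _)) in enumerate(zip(exons, exons[1:])):
        length = down_start - up_end
        if not (min_len < length < max_len):
            continue
        up_exon = sequence[exons[i][0] : up_end]
        down_exon = sequence[down_start : exons[i + 1][1]]
        if len(up_exon) < flank_len or len(down_exon) < flank_len:
            dropped.append(f"{gene_id}.intron{i + 1}: flank truncated at gene boundary")
            continue
        introns.append(
            Intron(
                gene_id=gene_id,
                index=i + 1,
                sequence=sequence[up_end:down_start],
                upstream_flank=up_exon[-flank_len:],
                downstream_flank=down_exon[:flank_len],
                start=up_end,
                end=down_start,
            )
        )
    return introns, dropped


def read_gene_models_gff3(path) -> dict[str, dict]:
    """Optional GFF3 intake for intron harvesting.

    Returns, per gene id, ``{"seqid", "strand", "exons"}`` with exon
    intervals converted to 0-based half-open and sorted; suitable to feed
    straight into :func:`harvest_introns` together with the gene's
    sequence. Exons are grouped by their ``Parent`` (transcript) falling
    back to ``gene_id``/``ID`` attributes; for multi-transcript genes the
    transcript with the most exons is kept.
    """
    by_parent: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2].lower() != "exon":
                continue
            seqid, _, _, start, end, _, strand, _, attrs = fields[:9]
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attributes.get("Parent") or attributes.get("gene_id") \
                or attributes.get("ID") or seqid
            rec = by_parent.setdefault(
                parent, {"seqid": seqid, "strand": strand, "exons": []}
            )
            rec["exons"].append((int(start) - 1, int(end)))
    for rec in by_parent.values():
        rec["exons"].sort()
    return by_parent


# ---------------------------------------------------------------------------
# RepeatMasker intake


def parse_repeat_annotations(
    path, families: tuple[str, ...] = ("LINE/L1",)
) -> tuple[list[RepeatAnnotation], int]:
    """Parse a RepeatMasker ``.out`` table, keeping only the given repeat
    classes (prefix match on the class/family column, default LINE1).

    RepeatMasker coordinates are 1-based inclusive and are converted to
    0-based half-open. Malformed lines are skipped; their count is
    returned alongside the annotations.
    """
    kept: list[RepeatAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("SW", "score") or fields[0].startswith("#"):
                continue  # header
            try:
                score = float(fields[0])
                query = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                name = fields[9]
                family = fields[10]
                if end <= start:
                    raise ValueError
            except (ValueError, IndexError):
                skipped += 1
                continue
            if any(family.startswith(f) for f in families):
                kept.append(
                    RepeatAnnotation(query, start, end, strand, name, family, score)
                )
    return kept, skipped


# ---------------------------------------------------------------------------
# orthologous intron anchoring


def _flank_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def _best_local(aligner, flank: str, target: str, min_identity: float, min_len: int):
    """Best local placement of ``flank`` in ``target``; None when below the
    identity/length threshold or ambiguous (two co-optimal placements)."""
    alignments = aligner.align(flank, target)
    try:
        best = alignments[0]
    except IndexError:
        return None
    matched = sum(
        1
        for (qs, qe), (ts, te) in zip(*best.aligned)
        for a, b in zip(flank[qs:qe], target[ts:te])
        if a == b
    )
    span = sum(qe - qs for qs, qe in best.aligned[0])
    if span < min_len or matched / max(span, 1) < min_identity:
        return None
    if len(alignments) > 1:
        second = alignments[1]
        if (
            second.score == best.score
            and second.aligned[1][0][0] != best.aligned[1][0][0]
        ):
            return "ambiguous"
    t_start = best.aligned[1][0][0]
    t_end = best.aligned[1][-1][1]
    return t_start, t_end, best.score


def anchor_orthologous_intron(
    intron: Intron,
    target_sequence: str,
    min_identity: float = 0.70,
    min_len: int = 60,
) -> Optional[tuple[int, int]]:
    """Locate the orthologous intron span in ``target_sequence`` by local
    alignment of the two exon flanks.

    The intron is the span between the end of the best upstream-flank hit
    and the start of the best downstream-flank hit. Both strands are
    tried; returns coordinates on the forward strand of the given target,
    or ``None`` when a flank cannot be placed (below threshold, ambiguous,
    or inconsistent order).
    """
    aligner = _flank_aligner()
    target_sequence = target_sequence.upper()
    candidates = []
    for strand, target in (
        ("+", target_sequence),
        ("-", str(Seq(target_sequence).reverse_complement())),
    ):
        up = _best_local(aligner, intron.upstream_flank, target, min_identity, min_len)
        down = _best_local(
            aligner, intron.downstream_flank, target, min_identity, min_len
        )
        if up in (None, "ambiguous") or down in (None, "ambiguous"):
            continue
        intron_start, intron_end = up[1], down[0]
        if intron_end <= intron_start:
            continue
        candidates.append((up[2] + down[2], strand, intron_start, intron_end))
    if not candidates:
        return None
    candidates.sort(reverse=True)
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return None  # ambiguous across strands
    _, strand, start, end = candidates[0]
    if strand == "-":
        n = len(target_sequence)
        start, end = n - end, n - start
    return start, end


# ---------------------------------------------------------------------------
# presence/absence calling


def call_presence_absence(
    locus: RetroLocus,
    interval: Optional[tuple[int, int]] = None,
    min_overlap: int = 60,
    max_gap: int = 10,
) -> PresencePattern:
    """Call each species present/absent/ambiguous for one annotated
    insertion interval of the aligned locus.

    A species is *present* when at least ``min_overlap`` unambiguous bases
    fall inside the interval columns; *absent* when fewer than ``max_gap``
    non-gap characters interrupt the span (contiguous flanking alignment
    across the insertion point); anything else — including carriers whose
    interval is filled with Ns — is *ambiguous*.
    """
    if interval is None:
        if not locus.insert_columns:
            raise ValueError(f"locus {locus.locus_id}: no insertion interval")
        interval = locus.insert_columns[0]
    start, end = interval
    if not (0 <= start <= end <= locus.n_columns):
        raise ValueError(f"locus {locus.locus_id}: interval outside alignment")
    calls: dict[str, str] = {}
    for species, row in locus.rows.items():
        window = row[start:end].upper()
        real = sum(1 for c in window if c in _BASES)
        filled = sum(1 for c in window if c != "-")
        if real >= min_overlap:
            calls[species] = PRESENT
        elif filled < max_gap:
            calls[species] = ABSENT
        else:
            calls[species] = AMBIGUOUS
    return PresencePattern(locus.locus_id, calls)


def tally_support(
    patterns: Iterable[PresencePattern],
    hypotheses: Mapping[str, Iterable[str]],
    min_markers: int = 3,
    taxa: Optional[Iterable[str]] = None,
) -> HypothesisTally:
    """Count informative patterns supporting each named hypothesis.

    A hypothesis is a named split side (set of taxa); a pattern supports
    it when its present-species set equals that side exactly. The
    significance flag requires at least ``min_markers`` insertions
    (default three). When ``taxa`` is given, patterns mentioning species
    outside it are rejected.
    """
    sides = {name: frozenset(t) for name, t in hypotheses.items()}
    universe = frozenset(taxa) if taxa is not None else None
    counts = {name: 0 for name in sides}
    for pattern in patterns:
        if universe is not None:
            unknown = set(pattern.calls) - universe
            if unknown:
                raise KeyError(f"pattern on unknown taxa: {sorted(unknown)}")
        if not pattern.informative:
            continue
        for name, side in sides.items():
            if pattern.present_set == side:
                counts[name] += 1
    significant = {name: n >= min_markers for name, n in counts.items()}
    return HypothesisTally(counts, significant, min_markers)
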