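"""Alignment container, FASTA I/O, and alignment-level filters.

Filters implemented here: the 30% maximum-pairwise-difference discard rule
and locus concatenation with per-species coverage reporting. Distances are
uncorrected p-distances; gap handling is pairwise deletion by default
(only columns where both rows are unambiguous residues count), switchable
to complete deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

_NUC_UNAMBIGUOUS = set("ACGTU")
_AA_UNAMBIGUOUS = set("ARNDCQEGHILKMFPSTWYV")


@dataclass
class GeneAlignment:
    """One locus: gapped sequences keyed by species."""

    locus_id: str
    rows: dict[str, str]
    alphabet: str = NUCLEOTIDE

    def __post_init__(self):
        if self.alphabet not in (NUCLEOTIDE, AMINO_ACID):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        lengths = {sp: len(seq) for sp, seq in self.rows.items()}
        if len(set(lengths.values())) > 1:
            detail = ", ".join(f"{sp}={n}" for sp, n in sorted(lengths.items()))
            raise ValueError(f"ragged alignment {self.locus_id!r}: {detail}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def matrix(self) -> np.ndarray:
        """Rows as a (n_species, n_columns) array of single characters."""
        return np.array([list(seq.upper()) for seq in self.rows.values()])

    def __len__(self) -> int:
        return self.n_columns


@dataclass
class CoverageReport:
    """Percent non-gap columns per species plus the overall mean."""

    per_species: dict[str, float]
    overall_mean: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tcoverage_percent\n")
            for sp, cov in self.per_species.items():
                fh.write(f"{sp}\t{cov:.1f}\n")
            fh.write(f"#overall_mean\t{self.overall_mean:.1f}\n")


def read_fasta_alignment(
    path, alphabet: str = NUCLEOTIDE, locus_id: Optional[str] = None
) -> GeneAlignment:
    """Read an aligned FASTA file.

    Raises ``ValueError`` naming the offending record when sequence lengths
    are unequal, and on empty files.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    for rec in records[1:]:
        if len(rec.seq) != length:
            raise ValueError(
                f"ragged alignment in {path}: record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
    rows = {rec.id: str(rec.seq).upper() for rec in records}
    if len(rows) != len(records):
        raise ValueError(f"duplicate record ids in {path}")
    return GeneAlignment(locus_id or Path(str(path)).stem, rows, alphabet)


def write_fasta_alignment(alignment: GeneAlignment, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in alignment.rows.items()
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def back_translate(
    aa_alignment: GeneAlignment, cds: Mapping[str, str]
) -> GeneAlignment:
    """Expand an amino acid alignment to nucleotides using ungapped CDS.

    Each AA column becomes three nucleotide columns; AA gaps become
    ``---``. The CDS must translate exactly to the ungapped AA row under
    the standard code.
    """
    if aa_alignment.alphabet != AMINO_ACID:
        raise ValueError("back_translate expects an amino acid alignment")
    table = standard_dna_table.forward_table
    out: dict[str, str] = {}
    for sp, aa_row in aa_alignment.rows.items():
        if sp not in cds:
            raise KeyError(f"no CDS for species {sp!r}")
        coding = cds[sp].upper().replace("U", "T")
        n_aa = sum(1 for c in aa_row if c != "-")
        if len(coding) != 3 * n_aa:
            raise ValueError(
                f"{sp}: CDS length {len(coding)} != 3 x {n_aa} non-gap residues"
            )
        codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
        nt_row = []
        k = 0
        for pos, aa in enumerate(aa_row):
            if aa == "-":
                nt_row.append("---")
                continue
            codon = codons[k]
            translated = table.get(codon, "X")
            if aa not in ("X", translated):
                raise ValueError(
                    f"{sp}: codon {codon} at AA position {pos + 1} translates to "
                    f"{translated}, alignment has {aa}"
                )
            nt_row.append(codon)
            k += 1
        out[sp] = "".join(nt_row)
    return GeneAlignment(aa_alignment.locus_id, out, NUCLEOTIDE)


def _unambiguous_mask(mat: np.ndarray, alphabet: str) -> np.ndarray:
    good = _NUC_UNAMBIGUOUS if alphabet == NUCLEOTIDE else _AA_UNAMBIGUOUS
    return np.isin(mat, sorted(good))


def p_distance(
    seq_a: str, seq_b: str, alphabet: str = NUCLEOTIDE, deletion: str = "pairwise"
) -> float:
    """Uncorrected proportion of differing sites between two aligned rows.

    ``deletion="pairwise"`` compares columns where both rows are
    unambiguous; ``"complete"`` is handled by the caller (columns already
    restricted). Returns NaN when no comparable columns exist.
    """
    a = np.array(list(seq_a.upper()))
    b = np.array(list(seq_b.upper()))
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    mask = _unambiguous_mask(a, alphabet) & _unambiguous_mask(b, alphabet)
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    return float((a[mask] != b[mask]).sum() / n)


def pairwise_distance_matrix(
    alignment: GeneAlignment, deletion: str = "pairwise"
) -> dict[tuple[str, str], float]:
    """p-distance for every unordered species pair."""
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    mat = alignment.matrix()
    species = alignment.species
    good = _unambiguous_mask(mat, alignment.alphabet)
    if deletion == "complete":
        keep = good.all(axis=0)
        mat = mat[:, keep]
        good = good[:, keep]
    out: dict[tuple[str, str], float] = {}
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            mask = good[i] & good[j]
            n = int(mask.sum())
            if n == 0:
                out[(species[i], species[j])] = float("nan")
            else:
                out[(species[i], species[j])] = float(
                    (mat[i, mask] != mat[j, mask]).sum() / n
                )
    return out


@dataclass
class FilterDecision:
    keep: bool
    max_difference: float
    worst_pair: Optional[tuple[str, str]]


def divergence_filter(
    alignment: GeneAlignment,
    threshold: float = 0.30,
    deletion: str = "pairwise",
) -> FilterDecision:
    """Discard rule: drop a locus whose largest pairwise difference exceeds
    ``threshold``. Pairs with no comparable columns are ignored.
    """
    dists = pairwise_distance_matrix(alignment, deletion=deletion)
    finite = {p: d for p, d in dists.items() if not np.isnan(d)}
    if not finite:
        return FilterDecision(keep=True, max_difference=float("nan"), worst_pair=None)
    worst = max(finite, key=finite.get)
    dmax = finite[worst]
    return FilterDecision(keep=dmax <= threshold, max_difference=dmax, worst_pair=worst)


def concatenate(
    alignments: Iterable[GeneAlignment], locus_id: str = "concatenated"
) -> tuple[GeneAlignment, CoverageReport]:
    """Concatenate loci over the union of species, padding absences with gaps.

    Coverage counts ambiguity codes (N/X) as covered; only gap characters
    reduce coverage.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("empty alignment list")
    alphabets = {a.alphabet for a in alignments}
    if len(alphabets) > 1:
        raise ValueError(f"mixed alphabets: {sorted(alphabets)}")
    species: list[str] = []
    for a in alignments:
        for sp in a.species:
            if sp not in species:
                species.append(sp)
    parts = {sp: [] for sp in species}
    for a in alignments:
        for sp in species:
            parts[sp].append(a.rows.get(sp, "-" * a.n_columns))
    rows = {sp: "".join(chunks) for sp, chunks in parts.items()}
    merged = GeneAlignment(locus_id, rows, alphabets.pop())
    total = merged.n_columns
    per_species = {
        sp: 100.0 * (total - seq.count("-")) / total for sp, seq in rows.items()
    }
    report = CoverageReport(per_species, float(np.mean(list(per_species.values()))))
    return merged, report
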