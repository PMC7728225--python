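"""Genome-level annotation of linear dsDNA (poxvirus-like) genomes.

This module covers the sequence-facing half of the pipeline: reading FASTA
genomes, six-frame ORF calling under a deterministic first-ATG-per-stop-segment
policy, filtering of low-complexity (repetitive) translations, detection of
inverted terminal repeats (ITRs) by anchored seed-and-extend, whole-genome
summary metrics, and scanning ORF upstream regions for the conserved
entomopoxvirus early-promoter motif TGAAANNNNA.

Coordinate conventions: all features are reported in 0-based, half-open
intervals on the forward strand; minus-strand ORFs carry ``strand='-'`` but
their ``start``/``end`` are forward-strand positions.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Genome",
    "OrfRecord",
    "ItrResult",
    "MotifHit",
    "GenomeMetrics",
    "read_fasta",
    "reverse_complement",
    "call_orfs",
    "filter_repetitive",
    "detect_itrs",
    "compute_genome_metrics",
    "scan_early_promoters",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: Early-promoter motif: positions 1-5 fixed TGAAA, 6-9 free, 10 fixed A.
#: Lookahead so overlapping occurrences are all reported.
_MOTIF_RE = re.compile(r"(?=(TGAAA[ACGTN]{4}A))")


@dataclass
class Genome:
    """A named linear DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r}: non-DNA character(s) {sorted(bad)!r} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A called open reading frame.

    ``start``/``end`` are forward-strand, 0-based half-open and include the
    stop codon; ``protein`` excludes the stop and begins with the initiator M.
    """

    orf_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"ORF {self.orf_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"ORF {self.orf_id!r}: bad interval [{self.start}, {self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF {self.orf_id!r}: span not divisible by 3")
        if not self.protein.startswith("M"):
            raise ValueError(f"ORF {self.orf_id!r}: protein does not start with M")
        if "*" in self.protein:
            raise ValueError(f"ORF {self.orf_id!r}: internal stop in protein")

    @property
    def protein_length(self) -> int:
        return len(self.protein)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ItrResult:
    """An inverted terminal repeat: identical-length terminal spans whose
    reverse complements match at ``identity``."""

    left_span: tuple[int, int]
    right_span: tuple[int, int]
    length: int
    identity: float


@dataclass(frozen=True)
class MotifHit:
    """One early-promoter motif occurrence upstream of an ORF.

    ``offset`` is the distance in bp from the motif's last base to the ORF
    start codon on the ORF's strand (1 = immediately adjacent).
    """

    orf_id: str
    offset: int
    matched_seq: str


@dataclass(frozen=True)
class GenomeMetrics:
    genome_id: str
    length_bp: int
    gc_percent: float
    coding_density_percent: float
    orf_count: int
    itr_length_bp: int


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a FASTA file into a list of :class:`Genome` (file order kept).

    Sequences are uppercased and must be DNA over {A, C, G, T, N}; an empty
    file or a record with other characters (including U) is an error naming
    the record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        genomes.append(Genome(id=rec.id, sequence=str(rec.seq)))
    return genomes


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_frame(seq: str, frame: int):
    """Yield (start, end) codon-run ORFs for one forward frame of ``seq``.

    Segments run stop-to-stop; within a segment the ORF goes from the first
    ATG to the stop codon (stop included in the interval).  A codon containing
    N terminates the current segment without emitting, so no ORF ever spans an
    ambiguous codon; a segment running off the sequence end emits nothing.
    """
    first_atg = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            first_atg = None
            continue
        if codon in _STOP_CODONS:
            if first_atg is not None:
                yield first_atg, pos + 3
            first_atg = None
        elif first_atg is None and codon == "ATG":
            first_atg = pos


def _translate(seq: str, start: int, end: int) -> str:
    aas = []
    for pos in range(start, end - 3, 3):
        aas.append(_CODON_TO_AA[seq[pos : pos + 3]])
    return "".join(aas)


def call_orfs(genome: Genome, min_aa: int = 50) -> list[OrfRecord]:
    """Call ORFs in all six reading frames.

    Policy: one ORF per stop-to-stop segment, from the segment's first ATG to
    its stop codon (the longest ATG-initiated frame per stop); only ORFs whose
    translated length (initiator M included, stop excluded) is >= ``min_aa``
    are kept.  Coordinates are forward-strand regardless of ORF strand.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = genome.sequence
    n = len(seq)
    rc = reverse_complement(seq)

    raw: list[tuple[int, int, str, str]] = []
    for frame in range(3):
        for s, e in _scan_frame(seq, frame):
            if (e - s) // 3 - 1 >= min_aa:
                raw.append((s, e, "+", _translate(seq, s, e)))
        for s, e in _scan_frame(rc, frame):
            if (e - s) // 3 - 1 >= min_aa:
                # [s, e) on the reverse-complement maps to [n-e, n-s) forward.
                raw.append((n - e, n - s, "-", _translate(rc, s, e)))

    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    width = max(3, len(str(len(raw))))
    return [
        OrfRecord(
            orf_id=f"{genome.id}_ORF{i + 1:0{width}d}",
            start=s,
            end=e,
            strand=strand,
            protein=protein,
        )
        for i, (s, e, strand, protein) in enumerate(raw)
    ]


def _dipeptide_entropy(protein: str) -> float:
    pairs = Counter(protein[i : i + 2] for i in range(len(protein) - 1))
    total = sum(pairs.values())
    return -sum((c / total) * math.log2(c / total) for c in pairs.values())


def filter_repetitive(
    orfs: list[OrfRecord],
    max_single_aa_frac: float = 0.5,
    min_dipeptide_entropy: float = 2.0,
) -> tuple[list[OrfRecord], list[OrfRecord]]:
    """Split ORFs into (kept, discarded) by a two-rule low-complexity filter.

    An ORF is discarded iff its most frequent amino acid makes up
    >= ``max_single_aa_frac`` of the protein, OR the Shannon entropy of its
    overlapping-dipeptide distribution is < ``min_dipeptide_entropy`` bits.
    Proteins shorter than 2 aa are kept (dipeptide entropy undefined).
    """
    kept, discarded = [], []
    for orf in orfs:
        p = orf.protein
        if len(p) < 2:
            kept.append(orf)
            continue
        top_frac = Counter(p).most_common(1)[0][1] / len(p)
        if top_frac >= max_single_aa_frac or _dipeptide_entropy(p) < min_dipeptide_entropy:
            discarded.append(orf)
        else:
            kept.append(orf)
    return kept, discarded


def detect_itrs(
    genome: Genome, min_seed: int = 25, max_mismatch_frac: float = 0.02
) -> ItrResult | None:
    """Detect inverted terminal repeats by anchored seed-and-extend.

    The genome prefix is compared position-by-position against the reverse
    complement of the genome suffix (equivalently, against the prefix of the
    reverse-complemented genome).  The first ``min_seed`` positions must match
    exactly; the repeat is then extended base-by-base up to floor(G/2),
    permitting mismatches while the cumulative mismatch fraction stays
    <= ``max_mismatch_frac``.  The longest such extension that ends on a
    matching base is reported (a repeat never ends in a mismatch run), or
    ``None`` if the seed fails.
    """
    seq = genome.sequence
    g = len(seq)
    if g < 2 * min_seed:
        raise ValueError(f"genome {genome.id!r}: length {g} < 2*min_seed ({2 * min_seed})")
    rc = reverse_complement(seq)
    if seq[:min_seed] != rc[:min_seed]:
        return None
    limit = g // 2
    best_len, best_mism = min_seed, 0
    mism = 0
    for i in range(min_seed, limit):
        if seq[i] != rc[i]:
            mism += 1
        elif mism / (i + 1) <= max_mismatch_frac:
            best_len, best_mism = i + 1, mism
    return ItrResult(
        left_span=(0, best_len),
        right_span=(g - best_len, g),
        length=best_len,
        identity=1.0 - best_mism / best_len,
    )


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_start, cur_end = None, None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def compute_genome_metrics(
    genome: Genome, orfs: list[OrfRecord], itr: ItrResult | None
) -> GenomeMetrics:
    """Summary metrics: GC% (N excluded from the denominator), coding density
    as the strand-pooled interval union of ORF spans over genome length, ORF
    count, and ITR length (0 if none)."""
    seq = genome.sequence
    n_count = seq.count("N")
    denom = genome.length - n_count
    if denom == 0:
        raise ValueError(f"genome {genome.id!r}: all-N sequence, GC undefined")
    for orf in orfs:
        if orf.end > genome.length:
            raise ValueError(f"ORF {orf.orf_id!r} extends past genome end")
    gc = 100.0 * (seq.count("G") + seq.count("C")) / denom
    coding = 100.0 * _interval_union_length([(o.start, o.end) for o in orfs]) / genome.length
    return GenomeMetrics(
        genome_id=genome.id,
        length_bp=genome.length,
        gc_percent=gc,
        coding_density_percent=coding,
        orf_count=len(orfs),
        itr_length_bp=itr.length if itr is not None else 0,
    )


def upstream_window(genome: Genome, orf: OrfRecord, window: int = 100) -> str:
    """The <=``window`` bp immediately 5' of an ORF's start codon, on the
    ORF's strand (truncated at genome ends)."""
    seq = genome.sequence
    if orf.strand == "+":
        return seq[max(0, orf.start - window) : orf.start]
    return reverse_complement(seq[orf.end : orf.end + window])


def scan_early_promoters(
    genome: Genome, orfs: list[OrfRecord], window: int = 100
) -> list[MotifHit]:
    """Scan each ORF's upstream window for TGAAANNNNA occurrences.

    Overlapping matches are all reported; a match must lie entirely inside the
    window.  ``offset`` 1 means the motif's final A abuts the start codon.
    """
    hits: list[MotifHit] = []
    for orf in orfs:
        win = upstream_window(genome, orf, window)
        for m in _MOTIF_RE.finditer(win):
            i = m.start()
            hits.append(
                MotifHit(
                    orf_id=orf.orf_id,
                    offset=len(win) - (i + 10) + 1,
                    matched_seq=m.group(1),
                )
            )
    return hits


def motif_genomic_span(orf: OrfRecord, hit: MotifHit) -> tuple[int, int]:
    """Forward-strand, 0-based half-open genomic interval of a motif hit."""
    if orf.strand == "+":
        end = orf.start - hit.offset + 1
        return end - 10, end
    start = orf.end + hit.offset - 1
    return start, start + 10
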