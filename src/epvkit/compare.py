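"""Comparative genomics: core-gene synteny dot plots, collinear block
detection, and protein-alignment preparation for phylogenetics.

Synteny between two genomes is summarised as an ortholog point set (shared
gene midpoints in each genome) from which collinear blocks are extracted as
maximal strictly-monotone chains — increasing in both genomes ("same"
orientation) or increasing in one and decreasing in the other ("inverted",
the signature of a segmental inversion).  Alignment utilities implement the
standard supermatrix preparation steps: gap-fraction column trimming and
taxon-checked concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "OrthologPointSet",
    "CollinearBlock",
    "ProteinAlignment",
    "build_dotplot",
    "find_collinear_blocks",
    "trim_alignment",
    "concatenate_alignments",
    "build_metrics_frame",
    "comparison_table",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_alignment_phylip",
]


@dataclass(frozen=True)
class OrthologPointSet:
    """Paired genomic positions of genes shared by two genomes.

    ``points`` are (gene_name, pos_a, pos_b) tuples ordered by ``pos_a``.
    """

    genome_a_id: str
    genome_b_id: str
    points: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        names = [p[0] for p in self.points]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in ortholog point set")

    def swapped(self) -> "OrthologPointSet":
        """The same point set with the two genome axes exchanged."""
        pts = sorted(((g, b, a) for g, a, b in self.points), key=lambda p: p[1])
        return OrthologPointSet(self.genome_b_id, self.genome_a_id, tuple(pts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["gene", f"pos_{self.genome_a_id}", f"pos_{self.genome_b_id}"]
        )


@dataclass(frozen=True)
class CollinearBlock:
    """A chain of orthologs collinear in both genomes."""

    genes: tuple[str, ...]
    orientation: str  # "same" or "inverted"
    span_a: tuple[float, float]
    span_b: tuple[float, float]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ProteinAlignment:
    """A multiple protein alignment: equal-length rows over residues + '-'."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs >= 2 taxa")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])


def build_dotplot(
    map_a: dict[str, float],
    map_b: dict[str, float],
    genome_a_id: str = "A",
    genome_b_id: str = "B",
) -> OrthologPointSet:
    """Intersect two gene->position maps into a dot-plot point set.

    Positions are whatever anchor the caller uses (interval midpoints by
    convention); points are ordered by position in genome A.
    """
    shared = sorted(set(map_a) & set(map_b), key=lambda g: (map_a[g], g))
    if not shared:
        raise ValueError(
            f"no shared genes between {genome_a_id!r} and {genome_b_id!r}"
        )
    points = tuple((g, float(map_a[g]), float(map_b[g])) for g in shared)
    return OrthologPointSet(genome_a_id, genome_b_id, points)


def _longest_chain(points: list[tuple[str, float, float]], inverted: bool) -> list[int]:
    """Indices of one maximum-length strictly-monotone chain.

    Points must be sorted by pos_a.  Chains are strictly increasing in pos_a
    and strictly increasing (same) or strictly decreasing (inverted) in pos_b.
    Among maximum chains the lexicographically smallest index sequence is
    returned, making the result order-deterministic.
    """
    n = len(points)
    best = [1] * n  # longest chain starting at i
    nxt = [-1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if points[j][1] <= points[i][1]:
                continue
            if inverted:
                ok = points[j][2] < points[i][2]
            else:
                ok = points[j][2] > points[i][2]
            if ok and 1 + best[j] > best[i]:
                best[i] = 1 + best[j]
                nxt[i] = j
    if n == 0:
        return []
    top = max(best)
    start = min(i for i in range(n) if best[i] == top)
    chain = []
    i = start
    while i != -1:
        chain.append(i)
        i = nxt[i]
    return chain


def find_collinear_blocks(
    points: OrthologPointSet, min_genes: int = 4
) -> list[CollinearBlock]:
    """Extract collinear blocks as maximal strictly-monotone chains.

    Each orientation is processed independently on the full point set by
    iterative peeling: the longest chain is extracted, its points removed,
    and the search repeated while chains of >= ``min_genes`` remain.  Blocks
    are returned longest first, ties broken by smaller span_a start.
    """
    if len(points.points) < min_genes:
        raise ValueError(
            f"need >= {min_genes} points, got {len(points.points)}"
        )
    blocks: list[CollinearBlock] = []
    for orientation, inverted in (("same", False), ("inverted", True)):
        remaining = list(points.points)
        while len(remaining) >= min_genes:
            chain = _longest_chain(remaining, inverted)
            if len(chain) < min_genes:
                break
            chosen = [remaining[i] for i in chain]
            pos_a = [p[1] for p in chosen]
            pos_b = [p[2] for p in chosen]
            blocks.append(
                CollinearBlock(
                    genes=tuple(p[0] for p in chosen),
                    orientation=orientation,
                    span_a=(min(pos_a), max(pos_a)),
                    span_b=(min(pos_b), max(pos_b)),
                )
            )
            taken = set(chain)
            remaining = [p for i, p in enumerate(remaining) if i not in taken]
    blocks.sort(key=lambda b: (-b.size, b.span_a[0], b.orientation))
    return blocks


def trim_alignment(aln: ProteinAlignment, max_gap_frac: float = 0.5) -> ProteinAlignment:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_frac``.

    The rule is strict: a column with gap fraction exactly ``max_gap_frac``
    is retained.  Removing every column is an error (degenerate alignment).
    """
    n_taxa = len(aln.taxa)
    keep = [
        c
        for c in range(aln.width)
        if sum(1 for r in aln.rows if r[c] == "-") / n_taxa <= max_gap_frac
    ]
    if not keep:
        raise ValueError("trimming removed every column (degenerate alignment)")
    rows = tuple("".join(r[c] for c in keep) for r in aln.rows)
    return ProteinAlignment(taxa=aln.taxa, rows=rows)


def concatenate_alignments(alns: list[ProteinAlignment]) -> ProteinAlignment:
    """Column-wise concatenation of alignments sharing one taxon set.

    Rows follow the taxon order of the first alignment; a taxon-set mismatch
    is an error naming the difference.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    taxa = alns[0].taxa
    taxon_set = set(taxa)
    for k, aln in enumerate(alns[1:], start=2):
        other = set(aln.taxa)
        if other != taxon_set:
            missing = sorted(taxon_set - other)
            extra = sorted(other - taxon_set)
            raise ValueError(
                f"alignment {k}: taxon set mismatch (missing {missing}, extra {extra})"
            )
    parts = {t: [] for t in taxa}
    for aln in alns:
        row_of = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            parts[t].append(row_of[t])
    return ProteinAlignment(taxa=taxa, rows=tuple("".join(parts[t]) for t in taxa))


def build_metrics_frame(metrics, bro_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """One row per genome from :class:`~epvkit.annotate.GenomeMetrics`, with an
    optional ``bro_genes`` count column (gene-family copy number per genome)."""
    df = pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "length_bp": m.length_bp,
                "gc_percent": m.gc_percent,
                "coding_density_percent": m.coding_density_percent,
                "orf_count": m.orf_count,
                "itr_length_bp": m.itr_length_bp,
            }
            for m in metrics
        ]
    )
    if bro_counts is not None:
        df["bro_genes"] = df["genome_id"].map(bro_counts)
    return df


def comparison_table(
    metrics_frame: pd.DataFrame, focal_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-genome metric summary with the focal genome held out.

    ``metrics_frame`` has one row per genome (a ``genome_id`` column plus
    numeric metric columns, e.g. coding density, GC%, gene-family counts).
    Returns the table plus a summary frame of mean and sample SD (n-1
    denominator) per numeric column over the non-focal genomes; with a single
    non-focal genome the SD is reported as NaN (undefined).
    """
    if "genome_id" not in metrics_frame.columns:
        raise ValueError("metrics_frame needs a genome_id column")
    others = metrics_frame[metrics_frame["genome_id"] != focal_id]
    if others.empty:
        raise ValueError("no non-focal genomes to summarize")
    numeric = others.select_dtypes(include=[np.number])
    summary = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": numeric.std(ddof=1) if len(others) > 1 else np.nan,
        }
    )
    return metrics_frame.copy(), summary


def read_alignment_fasta(path: str | Path) -> ProteinAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return ProteinAlignment(
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def write_alignment_fasta(aln: ProteinAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


def write_alignment_phylip(aln: ProteinAlignment, path: str | Path) -> None:
    """Relaxed PHYLIP (full names, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.taxa)} {aln.width}\n")
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f"{taxon}  {row}\n")
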