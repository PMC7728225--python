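"""Writers/readers for the pipeline's on-disk artifacts.

Internal coordinates are 0-based half-open; GFF3 output converts to the
format's 1-based inclusive convention.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import Genome, GenomeMetrics, MotifHit, OrfRecord, motif_genomic_span

__all__ = [
    "write_genome_fasta",
    "write_gff3",
    "read_orfs_gff3",
    "write_metrics_tsv",
    "write_motifs_tsv",
    "read_motifs_tsv",
]

_SOURCE = "epvkit"


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_gff3(
    genome: Genome,
    orfs: list[OrfRecord],
    path: str | Path,
    motif_hits: list[MotifHit] | None = None,
) -> None:
    """ORFs as CDS features and motif hits as regulatory_region features."""
    orf_by_id = {o.orf_id: o for o in orfs}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for o in orfs:
            fh.write(
                "\t".join(
                    [
                        genome.id, _SOURCE, "CDS",
                        str(o.start + 1), str(o.end), ".", o.strand, "0",
                        f"ID={o.orf_id};protein_length={o.protein_length}",
                    ]
                )
                + "\n"
            )
        for i, h in enumerate(motif_hits or []):
            s, e = motif_genomic_span(orf_by_id[h.orf_id], h)
            strand = orf_by_id[h.orf_id].strand
            fh.write(
                "\t".join(
                    [
                        genome.id, _SOURCE, "regulatory_region",
                        str(s + 1), str(e), ".", strand, ".",
                        f"ID=motif{i + 1:04d};Parent={h.orf_id};offset={h.offset};"
                        f"matched_seq={h.matched_seq}",
                    ]
                )
                + "\n"
            )


def read_orfs_gff3(path: str | Path, genome: Genome) -> list[OrfRecord]:
    """Read CDS features written by :func:`write_gff3` back into ORF records.

    Protein sequences are re-derived from the genome so records round-trip.
    """
    import gffutils

    from .annotate import reverse_complement as _rc

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
    orfs = []
    for feat in db.features_of_type("CDS", order_by="start"):
        start, end = feat.start - 1, feat.end
        seq = genome.sequence[start:end]
        if feat.strand == "-":
            seq = _rc(seq)
        from .annotate import _translate  # same codon table as the caller

        orfs.append(
            OrfRecord(
                orf_id=feat.id,
                start=start,
                end=end,
                strand=feat.strand,
                protein=_translate(seq, 0, len(seq)),
            )
        )
    return orfs


def write_metrics_tsv(metrics: list[GenomeMetrics], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "length_bp": m.length_bp,
                "gc_percent": round(m.gc_percent, 3),
                "coding_density_percent": round(m.coding_density_percent, 3),
                "orf_count": m.orf_count,
                "itr_length_bp": m.itr_length_bp,
            }
            for m in metrics
        ]
    ).to_csv(path, sep="\t", index=False)


def write_motifs_tsv(hits: list[MotifHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"orf_id": h.orf_id, "offset": h.offset, "matched_seq": h.matched_seq}
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def read_motifs_tsv(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(orf_id=r.orf_id, offset=int(r.offset), matched_seq=r.matched_seq)
        for r in df.itertuples(index=False)
    ]
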