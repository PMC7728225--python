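"""Functional classification of annotated ORFs.

Homology and domain evidence enters as a table (one row per ORF recording the
conclusions of sequence-similarity and domain searches: a conserved core-gene
name, a Bro-N domain flag, a virulence-homolog flag, an other-function flag).
Each ORF is assigned exactly one functional category by a fixed priority:

    core_replication > virulence_bro > virulence_homology > other_function
    > virulence_promoter (early-promoter motif, no other evidence) > unknown

The module also censuses the conserved poxvirus core-gene set against a
49-name reference and totals the virulence subcategories.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import MotifHit, OrfRecord

__all__ = [
    "CATEGORIES",
    "EvidenceRow",
    "GeneAnnotation",
    "CoreGeneCensus",
    "read_evidence",
    "write_evidence",
    "assign_categories",
    "census_core_genes",
    "summarize_virulence",
]

logger = logging.getLogger(__name__)

#: The recognised functional categories, in priority order (unknown last).
CATEGORIES = (
    "core_replication",
    "virulence_bro",
    "virulence_homology",
    "other_function",
    "virulence_promoter",
    "unknown",
)

#: Categories counted as putative virulence genes.
VIRULENCE_CATEGORIES = ("virulence_bro", "virulence_homology", "virulence_promoter")


@dataclass(frozen=True)
class EvidenceRow:
    """External evidence for one ORF (conclusions of homology/domain searches)."""

    orf_id: str
    core_gene_name: str = ""
    bro_domain: bool = False
    virulence_homolog: bool = False
    other_function: bool = False


@dataclass(frozen=True)
class GeneAnnotation:
    """An ORF joined with its assigned category and motif evidence."""

    orf: OrfRecord
    category: str
    motif_hit_count: int = 0
    core_gene_name: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "virulence_promoter" and self.motif_hit_count < 1:
            raise ValueError(
                f"ORF {self.orf.orf_id!r}: virulence_promoter requires >=1 motif hit"
            )

    @property
    def orf_id(self) -> str:
        return self.orf.orf_id


@dataclass(frozen=True)
class CoreGeneCensus:
    """Presence/absence of the conserved core genes against a reference list."""

    reference_total: int
    identified: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def n_identified(self) -> int:
        return len(self.identified)


def read_evidence(path: str | Path) -> list[EvidenceRow]:
    """Read a TSV evidence table (orf_id, core_gene_name, bro_domain,
    virulence_homolog, other_function)."""
    df = pd.read_csv(path, sep="\t", dtype={"orf_id": str, "core_gene_name": str})
    df["core_gene_name"] = df["core_gene_name"].fillna("")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            EvidenceRow(
                orf_id=rec.orf_id,
                core_gene_name=str(rec.core_gene_name),
                bro_domain=bool(rec.bro_domain),
                virulence_homolog=bool(rec.virulence_homolog),
                other_function=bool(rec.other_function),
            )
        )
    return rows


def write_evidence(rows: list[EvidenceRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "orf_id": r.orf_id,
                "core_gene_name": r.core_gene_name,
                "bro_domain": r.bro_domain,
                "virulence_homolog": r.virulence_homolog,
                "other_function": r.other_function,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def assign_categories(
    orfs: list[OrfRecord],
    evidence: list[EvidenceRow],
    motif_hits: list[MotifHit],
) -> list[GeneAnnotation]:
    """Assign exactly one functional category per ORF by evidence priority.

    Motif hits only matter for ORFs with no other evidence: such ORFs with at
    least one early-promoter hit become ``virulence_promoter``; evidence rows
    naming an ORF absent from ``orfs`` are an error.
    """
    orf_ids = {o.orf_id for o in orfs}
    by_id: dict[str, EvidenceRow] = {}
    for row in evidence:
        if row.orf_id not in orf_ids:
            raise ValueError(f"evidence row for unknown ORF {row.orf_id!r}")
        if row.orf_id in by_id:
            raise ValueError(f"duplicate evidence row for ORF {row.orf_id!r}")
        by_id[row.orf_id] = row

    hit_counts = Counter(h.orf_id for h in motif_hits)

    annotations = []
    for orf in orfs:
        ev = by_id.get(orf.orf_id)
        n_hits = hit_counts.get(orf.orf_id, 0)
        if ev is not None and ev.core_gene_name:
            category = "core_replication"
        elif ev is not None and ev.bro_domain:
            category = "virulence_bro"
        elif ev is not None and ev.virulence_homolog:
            category = "virulence_homology"
        elif ev is not None and ev.other_function:
            category = "other_function"
        elif n_hits >= 1:
            category = "virulence_promoter"
        else:
            category = "unknown"
        annotations.append(
            GeneAnnotation(
                orf=orf,
                category=category,
                motif_hit_count=n_hits,
                core_gene_name=ev.core_gene_name if ev is not None else "",
            )
        )
    return annotations


def census_core_genes(
    annotations: list[GeneAnnotation], reference_list: list[str]
) -> CoreGeneCensus:
    """Census core-replication assignments against a reference name list.

    A reference name assigned to more than one ORF is counted once (with a
    logged warning); names never assigned are reported missing.
    """
    if len(set(reference_list)) != len(reference_list):
        raise ValueError("reference_list contains duplicate names")
    assigned = Counter(
        a.core_gene_name
        for a in annotations
        if a.category == "core_replication" and a.core_gene_name
    )
    for name, count in assigned.items():
        if count > 1:
            logger.warning("core gene %s assigned to %d ORFs; counted once", name, count)
    identified = tuple(n for n in reference_list if n in assigned)
    missing = tuple(n for n in reference_list if n not in assigned)
    return CoreGeneCensus(
        reference_total=len(reference_list), identified=identified, missing=missing
    )


def summarize_virulence(annotations: list[GeneAnnotation]) -> dict[str, int]:
    """Count the virulence subcategories and their total."""
    counts = Counter(a.category for a in annotations)
    bro = counts.get("virulence_bro", 0)
    homology = counts.get("virulence_homology", 0)
    promoter = counts.get("virulence_promoter", 0)
    return {
        "bro": bro,
        "homology": homology,
        "promoter": promoter,
        "total": bro + homology + promoter,
    }


def annotations_to_frame(annotations: list[GeneAnnotation]) -> pd.DataFrame:
    """Tabular view of annotations (one row per ORF)."""
    return pd.DataFrame(
        [
            {
                "orf_id": a.orf_id,
                "start": a.orf.start,
                "end": a.orf.end,
                "strand": a.orf.strand,
                "protein_length": a.orf.protein_length,
                "category": a.category,
                "core_gene_name": a.core_gene_name,
                "motif_hit_count": a.motif_hit_count,
            }
            for a in annotations
        ]
    )
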