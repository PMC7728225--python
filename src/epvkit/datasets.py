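"""Small reference inputs bundled with the package.

These are input tables, not computed results: the 49-name conserved poxvirus
core-gene reference used for the census, and the published annotation/DE
contingency counts for the DlEPV study, expanded into per-gene records so the
summary operations can reproduce the reported partition arithmetic from a
concrete fixture.
"""

from __future__ import annotations

from .annotate import OrfRecord
from .classify import GeneAnnotation
from .expression import DEResult

__all__ = [
    "poxvirus_core_reference",
    "MISSING_CORE_GENES",
    "dlepv_partition_fixture",
]

#: Core genes not detected in the DlEPV annotation (VACV gene names).
MISSING_CORE_GENES = ("H3L", "E6R", "G6R", "A29L")

#: VACV-style names for the conserved poxvirus core-gene set.  The names
#: printed in the source annotation are used where available; the remainder
#: are synthetic placeholders (census arithmetic only needs name identity).
_NAMED_CORE = (
    "E9L", "I8R", "J6R", "D1R", "D5R", "D6R", "A7L", "D11R", "A24R", "A32L",
    "L5R", "H3L", "E6R", "G6R", "A29L",
)


def poxvirus_core_reference() -> list[str]:
    """The 49-name core-gene reference list."""
    placeholders = [f"CORE_X{i:02d}" for i in range(1, 49 - len(_NAMED_CORE) + 1)]
    return list(_NAMED_CORE) + placeholders


# Published contingency for the 193-gene DlEPV study: category sizes and how
# each category splits across the up-in-wasp / down-in-wasp / not-DE cells.
# Category totals and the core/virulence cluster memberships are as reported
# (45 core with 37 up; 27/6/34 virulence with 22/5/26 down; 176 DE with an
# 86/90 up/down split); the remaining cells are the implied complements.
_CONTINGENCY = {
    #                up  down  not_de
    "core_replication": (37, 6, 2),
    "virulence_bro": (3, 22, 2),
    "virulence_homology": (1, 5, 0),
    "virulence_promoter": (5, 26, 3),
    "unknown": (40, 31, 10),
}


def _stub_orf(orf_id: str, index: int) -> OrfRecord:
    start = index * 400
    return OrfRecord(
        orf_id=orf_id, start=start, end=start + 303, strand="+", protein="M" * 100
    )


def dlepv_partition_fixture(
    log2fc_up: float = 2.3, log2fc_down: float = -3.4
) -> tuple[list[GeneAnnotation], list[DEResult]]:
    """Per-gene annotation + DE fixture realizing the published contingency.

    Returns 193 annotated genes and matching clustered DE results; running
    :func:`epvkit.expression.partition_summary` over them reproduces the
    reported partition percentages.  Cluster members carry the reported mean
    cluster effect sizes as their log2 fold changes.
    """
    annotations: list[GeneAnnotation] = []
    results: list[DEResult] = []
    idx = 0
    for category, (n_up, n_down, n_not) in _CONTINGENCY.items():
        for cell, n in (("up", n_up), ("down", n_down), ("not_de", n_not)):
            for _ in range(n):
                idx += 1
                orf_id = f"DLEV{idx:03d}"
                orf = _stub_orf(orf_id, idx)
                annotations.append(
                    GeneAnnotation(
                        orf=orf,
                        category=category,
                        motif_hit_count=1 if category == "virulence_promoter" else 0,
                    )
                )
                if cell == "up":
                    results.append(
                        DEResult(orf_id, 100.0, 10.0, log2fc_up, 1e-6, 1e-5,
                                 True, "up_in_wasp")
                    )
                elif cell == "down":
                    results.append(
                        DEResult(orf_id, 10.0, 100.0, log2fc_down, 1e-6, 1e-5,
                                 True, "down_in_wasp")
                    )
                else:
                    results.append(
                        DEResult(orf_id, 50.0, 50.0, 0.0, 0.8, 0.9, False, None)
                    )
    return annotations, results
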