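"""Synthetic genomes and count matrices with known ground truth.

Every pipeline stage is testable without external data: the genome generator
plants inverted terminal repeats, non-overlapping ORFs with functional
categories, and early-promoter motifs at known positions; the count simulator
draws negative-binomial replicate counts with per-category planted log2 fold
changes between the two hosts.  Both are deterministic given their seeds.

Modeling notes
--------------
* Each planted ORF cassette carries an in-frame TAA immediately before its
  ATG, so the first-ATG-per-stop-segment caller recovers the planted
  coordinates exactly (chance ORFs elsewhere in the sequence are expected and
  harmless).
* A homopolymer separator just inside each repeat boundary guarantees the
  prefix/suffix comparison breaks down exactly at the planted repeat length,
  so seed-and-extend detection is unambiguous even with a mismatch allowance.
* Planted fold changes live on the scale the FPKM assay measures: because
  FPKM is a relative measure, the simulator balances total expected viral
  output between hosts by scaling the fly-side baseline of down-regulated
  genes (a single scalar solved from the planted effect map).  Virulence
  genes consequently have a higher baseline in the fly — the host in which
  they act.
* Per-gene log2 jitter (SD ``jitter_sd``) is applied only to genes whose
  category effect is non-zero, so an all-zero planted map is an exact null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotate import Genome, OrfRecord, reverse_complement
from .classify import EvidenceRow
from .expression import DEResult, ExpressionStudy

__all__ = [
    "DEFAULT_CATEGORY_COUNTS",
    "DEFAULT_PLANTED_LOG2FC",
    "SyntheticGenomeConfig",
    "SyntheticExpressionConfig",
    "PlantedOrf",
    "GroundTruth",
    "generate_genome",
    "make_expression_truth",
    "simulate_counts",
    "evaluate_recovery",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: Default category mix for a 40-gene genome, proportioned like a small
#: entomopoxvirus annotation (core replication, a BRO-family expansion,
#: a few homology-identified virulence genes, promoter-only virulence calls,
#: and unannotated ORFs).
DEFAULT_CATEGORY_COUNTS = {
    "core_replication": 9,
    "virulence_bro": 6,
    "virulence_homology": 1,
    "virulence_promoter": 7,
    "unknown": 17,
}

#: Planted per-category effects (wasp over fly, log2): replication genes up
#: in the wasp venom gland, virulence genes up in the parasitized fly.
DEFAULT_PLANTED_LOG2FC = {
    "core_replication": 2.3,
    "virulence_bro": -3.4,
    "virulence_homology": -3.4,
    "virulence_promoter": -3.4,
    "other_function": 0.0,
    "unknown": 0.0,
}


@dataclass
class SyntheticGenomeConfig:
    genome_length: int = 50_000
    itr_length: int = 2_000
    n_orfs: int = 40
    orf_length_range: tuple[int, int] = (60, 300)  # aa
    category_counts: dict[str, int] | None = None
    gc_target: float = 0.30
    seed: int = 0

    def resolved_category_counts(self) -> dict[str, int]:
        counts = dict(self.category_counts or DEFAULT_CATEGORY_COUNTS)
        if sum(counts.values()) != self.n_orfs:
            raise ValueError(
                f"category counts sum to {sum(counts.values())}, expected n_orfs={self.n_orfs}"
            )
        return counts


@dataclass
class SyntheticExpressionConfig:
    replicates_per_group: int = 6
    base_mean_range: tuple[float, float] = (100.0, 1000.0)
    dispersion: float = 0.05  # NB: variance = mu + dispersion * mu^2
    planted_log2fc: dict[str, float] | None = None
    jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")

    def resolved_log2fc(self) -> dict[str, float]:
        return dict(self.planted_log2fc or DEFAULT_PLANTED_LOG2FC)


@dataclass(frozen=True)
class PlantedOrf:
    orf_id: str
    start: int
    end: int
    strand: str
    category: str
    core_gene_name: str = ""

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """What was planted: ITR spans, ORFs with categories, motif positions,
    and (after count simulation) per-gene planted log2 fold changes."""

    genome_id: str
    itr_spans: tuple[tuple[int, int], tuple[int, int]] | None
    orfs: list[PlantedOrf]
    motif_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)

    def category_of(self) -> dict[str, str]:
        return {o.orf_id: o.category for o in self.orfs}

    def evidence(self, id_map: dict[str, str] | None = None) -> list[EvidenceRow]:
        """Evidence rows encoding the planted truth.

        ``id_map`` translates planted ids to caller-assigned ids (see
        :meth:`match_called`).  Promoter-category and unknown genes get no
        evidence row: their classification rests on the motif scan alone.
        """
        rows = []
        for o in self.orfs:
            oid = id_map.get(o.orf_id, o.orf_id) if id_map else o.orf_id
            if o.category == "core_replication":
                rows.append(EvidenceRow(orf_id=oid, core_gene_name=o.core_gene_name))
            elif o.category == "virulence_bro":
                rows.append(EvidenceRow(orf_id=oid, bro_domain=True))
            elif o.category == "virulence_homology":
                rows.append(EvidenceRow(orf_id=oid, virulence_homolog=True))
            elif o.category == "other_function":
                rows.append(EvidenceRow(orf_id=oid, other_function=True))
        return rows

    def match_called(self, called: list[OrfRecord]) -> dict[str, str]:
        """Map planted ids to called ORF ids by exact coordinate match."""
        by_coords = {(c.start, c.end, c.strand): c.orf_id for c in called}
        mapping = {}
        for o in self.orfs:
            key = (o.start, o.end, o.strand)
            if key not in by_coords:
                raise ValueError(f"planted ORF {o.orf_id!r} not recovered at {key}")
            mapping[o.orf_id] = by_coords[key]
        return mapping


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p)) if n > 0 else []

def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n random non-stop codons with the target base composition."""
    out = []
    while len(out) < n:
        codon = "".join(_random_bases(rng, 3, gc))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


_MOTIF_FIXED = {0: "T", 1: "G", 2: "A", 3: "A", 4: "A", 9: "A"}


def _find_motifs(window: str) -> list[int]:
    hits = []
    for i in range(len(window) - 9):
        if all(window[i + k] == b for k, b in _MOTIF_FIXED.items()):
            hits.append(i)
    return hits


def generate_genome(config: SyntheticGenomeConfig) -> tuple[Genome, GroundTruth]:
    """Build ``ITR + interior + revcomp(ITR)`` with planted, recoverable features.

    Interior layout is a homopolymer boundary separator, then spacer-separated
    ORF cassettes (each ``[filler | motif | filler | TAA | ATG..stop]`` on a
    random strand), then the mirrored separator.  Upstream windows of
    non-promoter genes are scrubbed of chance early-promoter motifs so that
    classification against the planted evidence recovers every label.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.resolved_category_counts()
    lo, hi = config.orf_length_range
    if lo < 2 or hi < lo:
        raise ValueError("bad orf_length_range")
    gc = config.gc_target

    categories: list[str] = []
    for cat, k in counts.items():
        categories.extend([cat] * k)
    rng.shuffle(categories)

    pre_len = 110  # upstream cassette bases; covers the 100 bp promoter window
    guard = max(32, math.ceil(0.03 * config.itr_length))

    # Build cassettes in local (ORF-strand) orientation.
    cassettes = []  # (local_seq, orf_local_span, motif_local_span | None, category, strand, aa)
    for cat in categories:
        aa = int(rng.integers(lo, hi + 1))
        orf_seq = "ATG" + _random_codons(rng, aa - 1, gc) + "TAA"
        if cat == "virulence_promoter":
            offset = int(rng.integers(4, 91))  # motif end, bp upstream of ATG
            motif = "TGAAA" + "".join(_random_bases(rng, 4, gc)) + "A"
            head = "".join(_random_bases(rng, pre_len - 10 - (offset - 1), gc))
            pre = head + motif + "".join(_random_bases(rng, offset - 4, gc)) + "TAA"
            motif_local = (len(head), len(head) + 10)
        else:
            pre = "".join(_random_bases(rng, pre_len - 3, gc)) + "TAA"
            motif_local = None
        strand = str(rng.choice(["+", "-"]))
        cassettes.append((pre + orf_seq, (len(pre), len(pre) + len(orf_seq)), motif_local, cat, strand, aa))

    spacer = 120
    itr = "".join(_random_bases(rng, config.itr_length, gc))
    fixed = 2 * config.itr_length + 2 * guard + (len(cassettes) + 1) * spacer
    needed = fixed + sum(len(c[0]) for c in cassettes)
    if needed > config.genome_length:
        raise ValueError(
            f"cannot pack {config.n_orfs} ORFs into {config.genome_length} bp "
            f"(need {needed})"
        )

    parts: list[str] = [itr, "A" * guard]
    pos = config.itr_length + guard
    orfs: list[PlantedOrf] = []
    motif_spans: dict[str, tuple[int, int]] = {}
    core_idx = 0
    for i, (local, orf_span, motif_local, cat, strand, aa) in enumerate(cassettes):
        parts.append("".join(_random_bases(rng, spacer, gc)))
        pos += spacer
        lc = len(local)
        if strand == "+":
            placed = local
            orf_start, orf_end = pos + orf_span[0], pos + orf_span[1]
            if motif_local:
                mspan = (pos + motif_local[0], pos + motif_local[1])
        else:
            placed = reverse_complement(local)
            orf_start, orf_end = pos + lc - orf_span[1], pos + lc - orf_span[0]
            if motif_local:
                mspan = (pos + lc - motif_local[1], pos + lc - motif_local[0])
        oid = f"planted{i + 1:03d}"
        name = ""
        if cat == "core_replication":
            core_idx += 1
            name = f"CORE_{core_idx:02d}"
        orfs.append(
            PlantedOrf(orf_id=oid, start=orf_start, end=orf_end, strand=strand,
                       category=cat, core_gene_name=name)
        )
        if motif_local:
            motif_spans[oid] = mspan
        parts.append(placed)
        pos += lc

    tail = config.genome_length - pos - guard - config.itr_length
    parts.append("".join(_random_bases(rng, tail, gc)))
    parts.append("A" * guard)
    parts.append(reverse_complement(itr))
    seq = list("".join(parts))
    assert len(seq) == config.genome_length

    # Positions that scrubbing must never touch.
    protected = np.zeros(config.genome_length, dtype=bool)
    protected[: config.itr_length] = True
    protected[config.genome_length - config.itr_length :] = True
    for o in orfs:
        protected[o.start : o.end] = True
        if o.strand == "+":  # the in-frame TAA guard before the ATG
            protected[o.start - 3 : o.start] = True
        else:
            protected[o.end : o.end + 3] = True
    for s, e in motif_spans.values():
        protected[s:e] = True

    # Scrub chance motifs from upstream windows of non-promoter genes.
    window = 100
    for o in orfs:
        if o.category == "virulence_promoter":
            continue
        for _ in range(20):
            if o.strand == "+":
                w_start = o.start - window
                win = "".join(seq[w_start : o.start])
            else:
                win = reverse_complement("".join(seq[o.end : o.end + window]))
            hits = _find_motifs(win)
            if not hits:
                break
            changed = False
            for h in hits:
                for k in (1, 0, 2, 3, 4, 9):  # fixed motif positions
                    if o.strand == "+":
                        gpos = w_start + h + k
                        cur = seq[gpos]
                    else:
                        gpos = o.end + window - 1 - (h + k)
                        cur = reverse_complement(seq[gpos])
                    if protected[gpos]:
                        continue
                    new = "C" if cur != "C" else "T"
                    seq[gpos] = new if o.strand == "+" else reverse_complement(new)
                    changed = True
                    break
            if not changed:
                break

    genome = Genome(id=f"synthetic_epv_{config.seed}", sequence="".join(seq))
    truth = GroundTruth(
        genome_id=genome.id,
        itr_spans=((0, config.itr_length),
                   (config.genome_length - config.itr_length, config.genome_length)),
        orfs=sorted(orfs, key=lambda o: o.start),
        motif_spans=motif_spans,
    )
    return genome, truth


def make_expression_truth(
    n_genes: int = 500,
    category_counts: dict[str, int] | None = None,
    gene_length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> GroundTruth:
    """Ground truth for an expression-only study (no genome sequence).

    The default 500-gene mix keeps the annotated genome's category counts
    (45 core, 27 BRO, 6 homology, 34 promoter) and fills the rest with
    unknown-category genes.
    """
    if category_counts is None:
        category_counts = {
            "core_replication": 45,
            "virulence_bro": 27,
            "virulence_homology": 6,
            "virulence_promoter": 34,
        }
        category_counts["unknown"] = n_genes - sum(category_counts.values())
    if sum(category_counts.values()) != n_genes:
        raise ValueError("category counts must sum to n_genes")
    rng = np.random.default_rng(seed)
    categories = [c for c, k in category_counts.items() for _ in range(k)]
    rng.shuffle(categories)
    orfs = []
    pos = 0
    core_idx = 0
    for i, cat in enumerate(categories):
        length = int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3 + 1)) * 3
        name = ""
        if cat == "core_replication":
            core_idx += 1
            name = f"CORE_{core_idx:02d}"
        orfs.append(
            PlantedOrf(orf_id=f"gene{i + 1:04d}", start=pos, end=pos + length,
                       strand="+", category=cat, core_gene_name=name)
        )
        pos += length + 100
    return GroundTruth(genome_id="expression_truth", itr_spans=None, orfs=orfs)


def simulate_counts(
    truth: GroundTruth, config: SyntheticExpressionConfig
) -> ExpressionStudy:
    """Negative-binomial counts for the two-host design.

    Per gene: a fly-side baseline mean drawn log-uniformly from
    ``base_mean_range``; wasp-side mean = baseline * 2^(planted log2fc), with
    the planted effect = category effect + per-gene jitter (non-null genes
    only).  Baselines of down-regulated genes are scaled so the expected
    totals of the two hosts match (see module notes).  Variance follows
    var = mu + dispersion * mu^2; dispersion 0 is the Poisson limit.
    The realized per-gene effects are recorded in ``truth.log2fc``.
    """
    rng = np.random.default_rng(config.seed)
    effects_map = config.resolved_log2fc()
    n = len(truth.orfs)
    if n == 0:
        raise ValueError("ground truth has no genes")

    base_cat = np.array([effects_map.get(o.category, 0.0) for o in truth.orfs])
    jitter = rng.normal(0.0, config.jitter_sd, size=n)
    lfc = np.where(base_cat != 0.0, base_cat + jitter, 0.0)

    lo, hi = config.base_mean_range
    mu_fly = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    # Mass balance: scale fly-side baselines of down-regulated genes so the
    # expected library composition shift is zero and planted effects are
    # recoverable on the FPKM scale.
    up = lfc > 0
    down = lfc < 0
    if up.any() and down.any():
        k = (mu_fly[up] * (2.0 ** lfc[up] - 1.0)).sum() / (
            mu_fly[down] * (1.0 - 2.0 ** lfc[down])
        ).sum()
        mu_fly = mu_fly.copy()
        mu_fly[down] *= k
    mu_wasp = mu_fly * 2.0 ** lfc

    reps = config.replicates_per_group

    def _draw(mu: np.ndarray) -> np.ndarray:
        m = np.tile(mu[:, None], (1, reps))
        if config.dispersion == 0:
            return rng.poisson(m)
        nb_n = 1.0 / config.dispersion
        nb_p = nb_n / (nb_n + m)
        return rng.negative_binomial(nb_n, nb_p)

    counts = np.hstack([_draw(mu_fly), _draw(mu_wasp)])
    sample_ids = [f"AS{i + 1}" for i in range(reps)] + [f"DL{i + 1}" for i in range(reps)]
    groups = ["fly"] * reps + ["wasp"] * reps

    truth.log2fc = {o.orf_id: float(l) for o, l in zip(truth.orfs, lfc)}
    return ExpressionStudy(
        gene_ids=[o.orf_id for o in truth.orfs],
        gene_lengths=np.array([o.length_bp for o in truth.orfs]),
        counts=counts,
        sample_ids=sample_ids,
        sample_group=groups,
    )


def evaluate_recovery(truth: GroundTruth, de: list[DEResult]) -> dict:
    """Compare estimated effects, clusters and calls against the planted truth.

    Returns mean estimated and planted log2fc per category, the adjusted Rand
    index between recovered clusters and planted effect directions (over DE
    genes with a non-zero planted effect), DE sensitivity over planted
    non-null genes, and the realized false discovery rate.
    """
    from sklearn.metrics import adjusted_rand_score

    if not truth.log2fc:
        raise ValueError("truth has no planted log2fc (run simulate_counts first)")
    cat = truth.category_of()
    planted = truth.log2fc

    est_by_cat: dict[str, list[float]] = {}
    planted_by_cat: dict[str, list[float]] = {}
    for r in de:
        c = cat[r.gene_id]
        est_by_cat.setdefault(c, []).append(r.log2fc)
        planted_by_cat.setdefault(c, []).append(planted[r.gene_id])

    truth_labels, pred_labels = [], []
    for r in de:
        if r.significant and r.cluster is not None and planted[r.gene_id] != 0.0:
            truth_labels.append("up" if planted[r.gene_id] > 0 else "down")
            pred_labels.append(r.cluster)

    n_nonnull = sum(1 for g, l in planted.items() if l != 0.0)
    detected_nonnull = sum(
        1 for r in de if r.significant and planted[r.gene_id] != 0.0
    )
    n_sig = sum(1 for r in de if r.significant)
    false_pos = sum(1 for r in de if r.significant and planted[r.gene_id] == 0.0)

    return {
        "mean_est_log2fc_by_category": {
            c: float(np.mean(v)) for c, v in est_by_cat.items()
        },
        "mean_planted_log2fc_by_category": {
            c: float(np.mean(v)) for c, v in planted_by_cat.items()
        },
        "log2fc_error_by_category": {
            c: float(np.mean(np.array(est_by_cat[c]) - np.array(planted_by_cat[c])))
            for c in est_by_cat
        },
        "ari": float(adjusted_rand_score(truth_labels, pred_labels))
        if truth_labels
        else float("nan"),
        "sensitivity": detected_nonnull / n_nonnull if n_nonnull else float("nan"),
        "fdr": false_pos / n_sig if n_sig else 0.0,
    }
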