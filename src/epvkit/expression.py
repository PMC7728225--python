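"""Dual-host expression partitioning from a gene x sample count matrix.

The experimental design is two groups of bulk RNA-seq libraries over the same
viral gene set: virus replicating in the wasp venom gland versus in the
parasitized fly host (six biological replicates each by default).  The module
computes FPKM, tests each gene for differential expression between hosts
(Welch's t on log2(FPKM + pseudocount), Benjamini-Hochberg FDR), cuts a Ward
dendrogram of the differentially expressed genes into an up-in-wasp and a
down-in-wasp cluster, and summarises how functional categories partition
between the clusters — the replication-vs-virulence split that is the
pipeline's headline output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .classify import VIRULENCE_CATEGORIES, GeneAnnotation

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "PartitionSummary",
    "compute_fpkm",
    "bh_fdr",
    "de_test",
    "cluster_genes",
    "attach_clusters",
    "partition_summary",
    "fold_change",
    "read_counts",
    "read_samples",
    "results_to_frame",
]

GROUPS = ("wasp", "fly")


@dataclass
class ExpressionStudy:
    """Counts plus design: gene ids/lengths, integer counts, sample groups."""

    gene_ids: list[str]
    gene_lengths: np.ndarray  # bp, one per gene
    counts: np.ndarray  # genes x samples, non-negative integers
    sample_ids: list[str]
    sample_group: list[str]  # each in {"wasp", "fly"}

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths)
        self.counts = np.asarray(self.counts)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_lengths) != n_genes:
            raise ValueError("gene dimension mismatch")
        if len(self.sample_ids) != n_samples or len(self.sample_group) != n_samples:
            raise ValueError("sample dimension mismatch")
        bad = set(self.sample_group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown sample group(s) {sorted(bad)}")
        for g in GROUPS:
            if self.sample_group.count(g) < 2:
                raise ValueError(f"group {g!r} needs >= 2 replicates")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.sample_group])


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression outcome (wasp over fly)."""

    gene_id: str
    mean_fpkm_wasp: float
    mean_fpkm_fly: float
    log2fc: float
    p: float
    q: float
    significant: bool
    cluster: str | None = None  # "up_in_wasp" / "down_in_wasp" for DE genes


@dataclass(frozen=True)
class PartitionSummary:
    """Category x cluster bookkeeping for a differential-expression study."""

    n_genes: int
    n_de: int
    pct_de: float
    n_up: int
    n_down: int
    contingency: pd.DataFrame  # rows = categories, cols = up / down / not_de
    pct_core_in_up: float
    pct_virulence_in_down: float
    mean_log2fc_up: float
    mean_log2fc_down: float
    mean_abs_log2fc_up: float
    mean_abs_log2fc_down: float


def compute_fpkm(
    counts: np.ndarray,
    gene_lengths: np.ndarray,
    sample_ids: list[str] | None = None,
) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm[g, s] = counts[g, s] / ((length_g / 1e3) * (total_s / 1e6)) with
    total_s the column sum.  A zero-total sample is an error naming it.
    """
    counts = np.asarray(counts, dtype=float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        idx = int(np.flatnonzero(totals == 0)[0])
        name = sample_ids[idx] if sample_ids else f"column {idx}"
        raise ValueError(f"sample {name} has zero total counts")
    return counts / (gene_lengths[:, None] / 1e3) / (totals[None, :] / 1e6)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped to <= 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t-test p-value with a zero-variance guard."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def de_test(
    study: ExpressionStudy, alpha: float = 0.05, pseudocount: float = 1.0
) -> list[DEResult]:
    """Two-group differential expression per gene.

    y = log2(FPKM + pseudocount); Welch's t between wasp and fly replicates
    gives p; log2fc = mean(y_wasp) - mean(y_fly); q = BH over all genes;
    significant iff q < alpha.  Cluster labels are attached afterwards by
    :func:`attach_clusters`.
    """
    fpkm = compute_fpkm(study.counts, study.gene_lengths, study.sample_ids)
    y = np.log2(fpkm + pseudocount)
    wasp = study.group_mask("wasp")
    fly = study.group_mask("fly")
    pvals = np.array([_welch(y[g, wasp], y[g, fly]) for g in range(len(study.gene_ids))])
    qvals = bh_fdr(pvals)
    results = []
    for g, gene in enumerate(study.gene_ids):
        results.append(
            DEResult(
                gene_id=gene,
                mean_fpkm_wasp=float(fpkm[g, wasp].mean()),
                mean_fpkm_fly=float(fpkm[g, fly].mean()),
                log2fc=float(y[g, wasp].mean() - y[g, fly].mean()),
                p=float(pvals[g]),
                q=float(qvals[g]),
                significant=bool(qvals[g] < alpha),
            )
        )
    return results


def cluster_genes(
    fpkm: np.ndarray,
    log2fc: np.ndarray,
    k: int = 2,
    pseudocount: float = 1.0,
    gene_ids: list[str] | None = None,
) -> list[str]:
    """Ward-linkage hierarchical clustering of (DE) genes into ``k`` groups.

    Rows are log10(FPKM + pseudocount) expression vectors across all samples;
    the dendrogram is cut at ``k`` clusters, which are then NAMED by effect
    direction: the cluster with the higher mean log2fc is ``up_in_wasp``.
    A mean tie is broken toward the cluster holding the lexicographically
    first gene id (first row if ids are not given).
    """
    fpkm = np.asarray(fpkm, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    n = fpkm.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    x = np.log10(fpkm + pseudocount)
    raw = fcluster(linkage(x, method="ward"), t=k, criterion="maxclust")
    means = {c: float(log2fc[raw == c].mean()) for c in np.unique(raw)}
    order = sorted(means)
    if k == 2 and len(order) == 2 and means[order[0]] == means[order[1]]:
        if gene_ids is not None:
            first = min(range(n), key=lambda i: gene_ids[i])
        else:
            first = 0
        up = raw[first]
    else:
        up = max(means, key=lambda c: (means[c], -c))
    return ["up_in_wasp" if c == up else "down_in_wasp" for c in raw]


def attach_clusters(
    study: ExpressionStudy,
    results: list[DEResult],
    k: int = 2,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Cluster the significant genes and return results with labels attached."""
    de_idx = [i for i, r in enumerate(results) if r.significant]
    if len(de_idx) < k:
        return list(results)
    fpkm = compute_fpkm(study.counts, study.gene_lengths, study.sample_ids)
    labels = cluster_genes(
        fpkm[de_idx, :],
        np.array([results[i].log2fc for i in de_idx]),
        k=k,
        pseudocount=pseudocount,
        gene_ids=[results[i].gene_id for i in de_idx],
    )
    out = list(results)
    for i, lab in zip(de_idx, labels):
        out[i] = replace(out[i], cluster=lab)
    return out


def run_expression_analysis(
    study: ExpressionStudy, alpha: float = 0.05, pseudocount: float = 1.0, k: int = 2
) -> list[DEResult]:
    """de_test followed by cluster attachment — the usual entry point."""
    return attach_clusters(study, de_test(study, alpha, pseudocount), k, pseudocount)


def _pct(numerator: int, denominator: int, dp: int) -> float:
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, dp)


def partition_summary(
    annotations: list[GeneAnnotation],
    de: list[DEResult],
    round_dp: int = 1,
) -> PartitionSummary:
    """Category x cluster contingency and the headline percentages.

    pct_de is over all genes; pct_core_in_up over all core-replication genes
    (DE or not); pct_virulence_in_down over all virulence-category genes.
    Percentages are rounded to ``round_dp`` decimals.
    """
    cat_by_gene = {a.orf_id: a.category for a in annotations}
    missing = [r.gene_id for r in de if r.gene_id not in cat_by_gene]
    if missing:
        raise ValueError(f"DE results for unannotated gene(s): {missing[:5]}")

    categories = sorted({a.category for a in annotations})
    cols = ["up", "down", "not_de"]
    table = pd.DataFrame(0, index=categories, columns=cols)
    up_fc, down_fc = [], []
    for r in de:
        cat = cat_by_gene[r.gene_id]
        if r.significant and r.cluster == "up_in_wasp":
            table.loc[cat, "up"] += 1
            up_fc.append(r.log2fc)
        elif r.significant and r.cluster == "down_in_wasp":
            table.loc[cat, "down"] += 1
            down_fc.append(r.log2fc)
        else:
            table.loc[cat, "not_de"] += 1

    n_genes = len(de)
    n_up, n_down = len(up_fc), len(down_fc)
    n_de = n_up + n_down
    core_total = sum(1 for r in de if cat_by_gene[r.gene_id] == "core_replication")
    vir_total = sum(1 for r in de if cat_by_gene[r.gene_id] in VIRULENCE_CATEGORIES)
    core_up = int(table.loc["core_replication", "up"]) if "core_replication" in table.index else 0
    vir_down = int(
        sum(table.loc[c, "down"] for c in VIRULENCE_CATEGORIES if c in table.index)
    )
    return PartitionSummary(
        n_genes=n_genes,
        n_de=n_de,
        pct_de=_pct(n_de, n_genes, round_dp),
        n_up=n_up,
        n_down=n_down,
        contingency=table,
        pct_core_in_up=_pct(core_up, core_total, round_dp),
        pct_virulence_in_down=_pct(vir_down, vir_total, round_dp),
        mean_log2fc_up=float(np.mean(up_fc)) if up_fc else float("nan"),
        mean_log2fc_down=float(np.mean(down_fc)) if down_fc else float("nan"),
        mean_abs_log2fc_up=float(np.mean(np.abs(up_fc))) if up_fc else float("nan"),
        mean_abs_log2fc_down=float(np.mean(np.abs(down_fc))) if down_fc else float("nan"),
    )


def fold_change(log2fc: float) -> float:
    """Linear-scale fold change for a log2 fold change magnitude."""
    return float(2.0 ** log2fc)


def read_counts(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Read a counts TSV (gene_id, length, then one column per sample).

    Returns (gene_ids, gene_lengths, counts, sample_ids).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ValueError(f"{path}: counts table needs gene_id and length columns")
    sample_ids = [c for c in df.columns if c not in ("gene_id", "length")]
    counts = df[sample_ids].to_numpy()
    return list(df["gene_id"]), df["length"].to_numpy(), counts, sample_ids


def read_samples(path: str | Path) -> dict[str, str]:
    """Read a sample sheet TSV (sample_id, group) into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: sample sheet needs sample_id and group columns")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def load_study(counts_path: str | Path, samples_path: str | Path) -> ExpressionStudy:
    gene_ids, lengths, counts, sample_ids = read_counts(counts_path)
    groups = read_samples(samples_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing}")
    return ExpressionStudy(
        gene_ids=gene_ids,
        gene_lengths=lengths,
        counts=counts,
        sample_ids=sample_ids,
        sample_group=[groups[s] for s in sample_ids],
    )


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_fpkm_wasp": r.mean_fpkm_wasp,
                "mean_fpkm_fly": r.mean_fpkm_fly,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "cluster": r.cluster if r.cluster is not None else "",
            }
            for r in results
        ]
    )
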