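"""End-to-end orchestration with config, logging and a run manifest.

Stages run in dependency order (annotate -> classify -> synteny -> express ->
summarize); inputs for every enabled stage are validated before any stage
runs, and a manifest records input digests, effective parameters and the
package version so a run can be reproduced byte-for-byte (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import yaml

from . import annotate as ann
from . import classify as cls
from . import compare as cmp
from . import expression as expr
from . import io as eio

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("annotate", "classify", "synteny", "express")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str
    stages: list[str] = field(default_factory=lambda: ["annotate", "classify", "express"])
    # inputs
    fasta: str | None = None
    evidence: str | None = None
    counts: str | None = None
    samples: str | None = None
    map_a: str | None = None
    map_b: str | None = None
    # parameters
    min_aa: int = 50
    window: int = 100
    min_seed: int = 25
    max_mismatch_frac: float = 0.02
    min_genes: int = 4
    max_gap_frac: float = 0.5
    alpha: float = 0.05
    pseudocount: float = 1.0
    k: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in _STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        required = {
            "annotate": ["fasta"],
            "classify": ["fasta", "evidence"],
            "synteny": ["map_a", "map_b"],
            "express": ["counts", "samples"],
        }
        for stage in self.stages:
            for key in required[stage]:
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"stage {stage!r} requires {key!r}")
                if not Path(value).exists():
                    raise FileNotFoundError(f"stage {stage!r}: missing input {value}")
        if "classify" in self.stages and "annotate" not in self.stages:
            raise ValueError("classify requires the annotate stage")
        if "express" in self.stages and "classify" not in self.stages:
            raise ValueError("express requires the classify stage")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _version() -> str:
    try:
        return _pkg_version("epvkit")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stages_run: list[str] = []

    genomes = orfs = motif_hits = annotations = None

    def _artifact(path: Path) -> None:
        artifacts.append(str(path))

    for stage in (s for s in _STAGE_ORDER if s in config.stages):
        logger.info("stage %s: start", stage)
        try:
            if stage == "annotate":
                genomes = ann.read_fasta(config.fasta)
                metrics = []
                all_orfs, all_hits = {}, {}
                for genome in genomes:
                    called = ann.call_orfs(genome, min_aa=config.min_aa)
                    kept, _ = ann.filter_repetitive(called)
                    itr = ann.detect_itrs(
                        genome,
                        min_seed=config.min_seed,
                        max_mismatch_frac=config.max_mismatch_frac,
                    )
                    hits = ann.scan_early_promoters(genome, kept, window=config.window)
                    metrics.append(ann.compute_genome_metrics(genome, kept, itr))
                    all_orfs[genome.id] = kept
                    all_hits[genome.id] = hits
                    gff = out / f"{genome.id}.gff3"
                    eio.write_gff3(genome, kept, gff, hits)
                    _artifact(gff)
                mpath = out / "metrics.tsv"
                eio.write_metrics_tsv(metrics, mpath)
                _artifact(mpath)
                for gid, hits in all_hits.items():
                    hpath = out / f"{gid}.motifs.tsv"
                    eio.write_motifs_tsv(hits, hpath)
                    _artifact(hpath)
                genome = genomes[0]
                orfs = all_orfs[genome.id]
                motif_hits = all_hits[genome.id]
            elif stage == "classify":
                evidence = cls.read_evidence(config.evidence)
                annotations = cls.assign_categories(orfs, evidence, motif_hits)
                apath = out / "annotations.tsv"
                cls.annotations_to_frame(annotations).to_csv(apath, sep="\t", index=False)
                _artifact(apath)
                report = {
                    "category_counts": cls.annotations_to_frame(annotations)[
                        "category"
                    ].value_counts().to_dict(),
                    "virulence": cls.summarize_virulence(annotations),
                }
                rpath = out / "classification.json"
                rpath.write_text(json.dumps(report, indent=2, sort_keys=True))
                _artifact(rpath)
            elif stage == "synteny":
                import pandas as pd

                ma = pd.read_csv(config.map_a, sep="\t")
                mb = pd.read_csv(config.map_b, sep="\t")
                pts = cmp.build_dotplot(
                    dict(zip(ma["gene"], ma["position"])),
                    dict(zip(mb["gene"], mb["position"])),
                )
                blocks = cmp.find_collinear_blocks(pts, min_genes=config.min_genes)
                ppath = out / "dotplot.tsv"
                pts.to_frame().to_csv(ppath, sep="\t", index=False)
                _artifact(ppath)
                bpath = out / "blocks.tsv"
                pd.DataFrame(
                    [
                        {
                            "orientation": b.orientation,
                            "size": b.size,
                            "genes": ",".join(b.genes),
                            "span_a_start": b.span_a[0],
                            "span_a_end": b.span_a[1],
                            "span_b_start": b.span_b[0],
                            "span_b_end": b.span_b[1],
                        }
                        for b in blocks
                    ]
                ).to_csv(bpath, sep="\t", index=False)
                _artifact(bpath)
            elif stage == "express":
                study = expr.load_study(config.counts, config.samples)
                results = expr.run_expression_analysis(
                    study, alpha=config.alpha, pseudocount=config.pseudocount, k=config.k
                )
                dpath = out / "de_results.tsv"
                expr.results_to_frame(results).to_csv(dpath, sep="\t", index=False)
                _artifact(dpath)
                id_set = set(study.gene_ids)
                relevant = [a for a in annotations if a.orf_id in id_set]
                summary = expr.partition_summary(relevant, results)
                spath = out / "partition_summary.json"
                spath.write_text(
                    json.dumps(
                        {
                            "n_genes": summary.n_genes,
                            "n_de": summary.n_de,
                            "pct_de": summary.pct_de,
                            "n_up": summary.n_up,
                            "n_down": summary.n_down,
                            "pct_core_in_up": summary.pct_core_in_up,
                            "pct_virulence_in_down": summary.pct_virulence_in_down,
                            "mean_abs_log2fc_up": summary.mean_abs_log2fc_up,
                            "mean_abs_log2fc_down": summary.mean_abs_log2fc_down,
                            "contingency": summary.contingency.to_dict(),
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
                _artifact(spath)
        except Exception as exc:
            logger.error("stage %s: failed (%s)", stage, exc)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        stages_run.append(stage)
        logger.info("stage %s: done", stage)

    inputs = {
        key: {"path": str(getattr(config, key)), "sha256": _sha256(getattr(config, key))}
        for key in ("fasta", "evidence", "counts", "samples", "map_a", "map_b")
        if getattr(config, key) is not None
    }
    manifest = {
        "version": _version(),
        "stages": stages_run,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("out_dir", "stages")
        },
        "inputs": inputs,
        "artifacts": sorted(artifacts),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
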