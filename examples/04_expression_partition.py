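"""The dual-host expression split: replication genes up in the wasp venom
gland, virulence genes up in the parasitized fly.

Simulates a 500-gene, 6-vs-6 replicate count study with planted effects
(+2.3 log2 for core replication genes, -3.4 for virulence genes), runs the
differential-expression test, Ward clustering, and prints the partition
summary with the recovery diagnostics.
"""

from epvkit import (
    SyntheticExpressionConfig,
    evaluate_recovery,
    make_expression_truth,
    partition_summary,
    run_expression_analysis,
    simulate_counts,
)
from epvkit.annotate import OrfRecord
from epvkit.classify import GeneAnnotation

truth = make_expression_truth(n_genes=500, seed=7)
study = simulate_counts(truth, SyntheticExpressionConfig(seed=8))
print(
    f"study: {len(study.gene_ids)} genes x {len(study.sample_ids)} samples "
    f"({study.sample_group.count('wasp')} wasp, {study.sample_group.count('fly')} fly)"
)

results = run_expression_analysis(study, alpha=0.05)

annotations = [
    GeneAnnotation(
        orf=OrfRecord(o.orf_id, o.start, o.end, o.strand, "M" * 60),
        category=o.category,
        motif_hit_count=1 if o.category == "virulence_promoter" else 0,
    )
    for o in truth.orfs
]
summary = partition_summary(annotations, results)
print(
    f"differential expression: {summary.n_de}/{summary.n_genes} genes "
    f"({summary.pct_de}%) at q < 0.05; clusters {summary.n_up} up / "
    f"{summary.n_down} down in wasp"
)
print(
    f"partition: {summary.pct_core_in_up}% of core genes in the up-in-wasp "
    f"cluster; {summary.pct_virulence_in_down}% of virulence genes in the "
    f"down-in-wasp cluster"
)
print(
    f"cluster effect sizes: mean |log2FC| {summary.mean_abs_log2fc_up:.2f} (up) "
    f"and {summary.mean_abs_log2fc_down:.2f} (down)"
)

rec = evaluate_recovery(truth, results)
est = rec["mean_est_log2fc_by_category"]
print(
    f"recovery: core log2FC estimate {est['core_replication']:.2f} (planted +2.3), "
    f"BRO estimate {est['virulence_bro']:.2f} (planted -3.4), ARI {rec['ari']:.2f}"
)
print(
    "-> the split mirrors the biology: replication machinery is amplified in"
    " the symbiotic (wasp) host while virulence genes act in the fly."
)
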