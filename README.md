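# epvkit

Annotation and dual-host expression partitioning for entomopoxvirus-like
genomes.

Parasitoid wasps carry heritable viruses that help their offspring survive
inside parasitized host insects.  Most such viruses are endogenized into the
wasp genome; a mutualistic entomopoxvirus of *Diachasmimorpha longicaudata*
wasps instead keeps an exogenous, poxvirus-style genome — a linear dsDNA
molecule with inverted terminal repeats (ITRs) — and achieves its dual role by
*expression* partitioning: replication machinery is transcribed mainly during
virus amplification in the wasp venom gland, while virulence genes are
transcribed mainly in the parasitized fly.  `epvkit` is a tested, reusable
pipeline for exactly this kind of analysis:

* **Genome annotation** — six-frame ORF calling (first-ATG-per-stop policy,
  >= 50 aa), low-complexity filtering, seed-and-extend ITR detection, genome
  metrics (GC%, strand-pooled coding density), and scanning of 100 bp upstream
  windows for the conserved entomopoxvirus early-promoter motif `TGAAANNNNA`.
* **Functional classification** — joins ORFs with homology/domain evidence
  tables and motif hits; assigns one category per gene by fixed priority
  (core replication > BRO-domain virulence > virulence homolog > other
  function > promoter-only virulence > unknown); censuses a 49-name conserved
  core-gene reference and totals the virulence classes.
* **Comparative genomics** — ortholog dot plots, collinear-block detection as
  maximal monotone chains (inversions appear as negative-slope blocks),
  gap-fraction alignment trimming and taxon-checked concatenation for
  phylogenetic supermatrices, and cross-genome metric summaries (mean ± SD,
  focal genome excluded).
* **Expression partitioning** — FPKM from a gene×sample count matrix, Welch's
  t on log2(FPKM+1) with Benjamini–Hochberg FDR (q < 0.05), Ward clustering of
  the differentially expressed genes into up-in-wasp / down-in-wasp groups,
  and the category×cluster partition summary.
* **Synthetic data** — genomes with planted ITRs/ORFs/motifs and
  negative-binomial counts with planted per-category log2 fold changes, so
  every stage is testable against known ground truth.

The statistic at the pipeline's core: per gene *g*,
`FPKM_gs = c_gs / ((L_g/10^3)(N_s/10^6))`, `y = log2(FPKM+1)`,
`log2FC_g = mean(y_g,wasp) − mean(y_g,fly)`, Welch t → p, BH → q; significant
genes are Ward-clustered (Euclidean, log10(FPKM+1)) at k = 2, clusters named by
mean log2FC sign; the partition summary then reports the percentage of core
replication genes in the up-in-wasp cluster and of virulence genes in the
down-in-wasp cluster.  See `docs/methods.md` for every convention and its
rationale.

## Worked example

`examples/04_expression_partition.py` simulates a 500-gene, 6-vs-6 replicate
two-host study with planted effects (+2.3 log2 for core genes, −3.4 for
virulence genes) and runs the full analysis:

```
study: 500 genes x 12 samples (6 wasp, 6 fly)
differential expression: 115/500 genes (23.0%) at q < 0.05; clusters 48 up / 67 down in wasp
partition: 100.0% of core genes in the up-in-wasp cluster; 100.0% of virulence genes in the down-in-wasp cluster
cluster effect sizes: mean |log2FC| 2.25 (up) and 3.33 (down)
recovery: core log2FC estimate 2.37 (planted +2.3), BRO estimate -3.46 (planted -3.4), ARI 1.00
```

Reading: of the 500 simulated genes, the 112 with planted effects (plus a few
false positives) reach significance; every core replication gene lands in the
up-in-wasp cluster and every virulence gene in the down-in-wasp cluster; the
estimated cluster effect sizes (|log2FC| ≈ 2.3 and 3.4, i.e. ~5× up and >10×
down in the wasp) recover the planted values, and the adjusted Rand index of
1.0 says the recovered clusters coincide with the planted directions.  The
other examples (`01`–`03`) walk through annotation of a synthetic genome
(ITR recovered at exactly 2,000 bp, GC 30.1%), classification with a core-gene
census, and synteny-block detection across an inversion.

A thin CLI mirrors the library for shell use:

```bash
epvkit simulate --seed 5 --out-dir sim/
epvkit annotate --fasta sim/genome.fasta --out-dir ann/
epvkit classify --fasta sim/genome.fasta --gff ann/*.gff3 \
    --evidence sim/evidence.tsv --motifs ann/*.motifs.tsv --out report.json
epvkit express --counts sim/counts.tsv --samples sim/samples.tsv \
    --annotations ann/annotations.tsv --out-dir de/
epvkit run-all --config pipeline.yaml
```

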