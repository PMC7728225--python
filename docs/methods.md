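# Methods

`epvkit` implements a desk-scale analysis pipeline for linear dsDNA poxvirus-like
genomes carried by parasitoid wasps: sequence annotation, evidence-based functional
classification, cross-genome synteny, and the two-host differential-expression
partition that quantifies how replication and virulence functions split between a
wasp (symbiont-amplifying) host and a fly (parasitized) host.  This note records
the models, conventions and numerical choices, and what the synthetic data do and
do not establish.

## Coordinates

All features use 0-based, half-open intervals on the forward strand; GFF3 output
converts to 1-based inclusive.  Minus-strand ORFs keep forward-strand `start/end`
with `strand='-'`.  This makes interval arithmetic (unions, overlaps, window
clipping) unambiguous and export to BED/GFF direct.

## ORF calling

Six reading frames are scanned; stop codons partition each frame into segments,
and each segment yields at most one ORF: from its **first** ATG to the stop codon
(stop included in the interval, excluded from the protein).  This is the longest
ATG-initiated frame per stop — a single deterministic rule in place of the manual
curation used in practice by annotation tools.  The length threshold (`min_aa`,
default 50) applies to the translated length counting the initiator methionine
and excluding the stop.  Segments that run off either genome end without a stop
emit nothing.  A codon containing N terminates its segment without emitting, so
no ORF ever spans an ambiguous codon and no residues are fabricated.  The caller
is tested for exact equality against a brute-force enumerator of every
ATG-to-stop candidate in all six frames.

## Repetitive-ORF filter

Low-complexity translations are removed by two rules: discard if the most common
amino acid makes up >= 50% of the protein, or if the Shannon entropy of the
overlapping-dipeptide distribution is below 2.0 bits.  Both thresholds are
configurable.  Proteins shorter than two residues are kept (dipeptide entropy is
undefined).  The 2-bit default separates homopolymer and short-period repeats
(entropy <= log2 of the repeat period, e.g. 1 bit for a 2-residue repeat) from
typical globular sequences, which sit far above it.

## Inverted terminal repeats

Detection is anchored seed-and-extend: the genome prefix is compared base-by-base
against the prefix of the reverse-complemented genome (equivalently, the reverse
complement of the suffix).  The first `min_seed` (25) positions must match
exactly; extension proceeds to floor(G/2), tolerating mismatches while the
cumulative mismatch fraction stays <= `max_mismatch_frac` (0.02).  The reported
repeat is the longest extension that **ends on a matching base**: without that
rule any positive mismatch allowance lets the extension coast tens of bases past
a true repeat boundary on chance matches (after 1,000 clean bases, a 2% budget
absorbs roughly 27 random bases), which would make a planted repeat length
unrecoverable.  Identity is 1 − mismatches/length at the reported length.  Exact
boundary recovery is only guaranteed when the flanking sequence actually
mismatches at the boundary; the synthetic generator enforces this (below).

## Genome metrics

GC% excludes N from the denominator (N is absence of information, not AT).
Coding density is the interval union of ORF spans, strands pooled, divided by
genome length — overlapping ORFs are not double-counted.  The union convention is
a choice; summed-length or per-strand definitions would give different numbers on
overlapping annotations.

## Early-promoter scan

The entomopoxvirus early promoter TGAAANNNNA (positions 1–5 and 10 fixed) is
searched in the `window` (100) bp immediately 5' of each start codon **on the
ORF's strand**; for minus-strand ORFs this is the reverse complement of the
forward-strand bases 3' of the ORF's forward-coordinate end.  Offset 1 means the
motif's final A abuts the ATG; matches must lie entirely inside the window, which
is truncated at genome ends; overlapping occurrences are all reported.  Matches
are permitted to overlap neighbouring coding sequence — poxvirus promoters
frequently do in compact genomes.

## Functional classification

Homology and domain evidence enters as a per-ORF table (the conclusions of
BLAST/Pfam-style searches, not the searches themselves): an optional conserved
core-gene name, a Bro-N domain flag, a virulence-homolog flag, an other-function
flag.  Exactly one category is assigned by fixed priority:
core_replication > virulence_bro > virulence_homology > other_function >
virulence_promoter (>=1 motif hit and no other evidence) > unknown.
The promoter category is last because it is the weakest evidence class — a
conserved regulatory signal rather than sequence similarity.  The core-gene
census reports presence/absence against a 49-name reference; a name assigned to
two ORFs counts once (with a logged warning).  Virulence totals sum the three
virulence subcategories.

## Synteny and alignment preparation

Gene positions are interval midpoints on the forward strand.  A dot plot is the
intersection of two gene→position maps, ordered by position in genome A.
Collinear blocks are maximal strictly-monotone chains: increasing in both
genomes (same orientation) or increasing in A and decreasing in B (inverted —
the negative-slope signature of a segmental inversion).  Each orientation is
processed independently on the full point set by iterative peeling (extract the
longest chain, remove its points, repeat while chains reach `min_genes`,
default 4).  Chains are found by an O(n²) longest-chain dynamic program that
returns the lexicographically smallest index sequence among maxima, so results
are order-deterministic; block lists are sorted longest first, ties by smaller
span start in A.  Monotonicity is strict, so equal coordinates never join a
chain.  This is a parameter-free formalization (no gap penalty, no distance
cap) of what is usually judged visually on a dot plot.

Alignment trimming removes columns whose gap fraction strictly exceeds the
threshold (default 0.5: a column at exactly 50% gaps is retained), and is
idempotent.  Concatenation requires identical taxon sets and preserves the row
order of the first alignment.  Cross-genome metric summaries report mean and
sample SD (n−1) over the non-focal genomes; with one non-focal genome the SD is
undefined (NaN).

## Differential expression and partitioning

FPKM is computed from the count matrix itself:
`fpkm = count / ((length/1e3) * (column_total/1e6))`.  Per gene, the test
statistic is Welch's two-sample t on `y = log2(FPKM + 1)` between the wasp and
fly replicate groups; the pseudocount stabilizes low-expression genes and the
log2 scale makes the group-mean difference directly interpretable as a log2
fold change (`log2fc = mean(y_wasp) − mean(y_fly)`, a difference of mean logs,
not a log of mean ratio).  Genes with zero variance in both groups get p = 1
when means are equal.  Benjamini–Hochberg step-up q-values control the FDR;
significance is q < alpha (0.05).  This defined, auditable two-group test
replaces an RNA-seq-suite internal model on the grounds that the partition
statistics, not the test internals, are the quantity of interest; the test is
isolated behind `de_test` and swappable.

Significant genes are clustered by Ward-linkage agglomerative hierarchical
clustering (Lance–Williams update, Euclidean distance) on `log10(FPKM + 1)` row
vectors across all samples, with the tree cut at k = 2.  Clusters are then
*named* by direction: the cluster with the higher mean log2fc is `up_in_wasp`;
a tie goes to the cluster holding the lexicographically first gene id.  Naming
is therefore deterministic and seed-free.

The partition summary reports: pct_de = 100·n_DE/n_genes; the category×cluster
contingency; pct of core-replication genes in the up-in-wasp cluster and pct of
virulence-category genes in the down-in-wasp cluster (denominators are the full
category sizes, DE or not); and per-cluster mean signed and mean absolute
log2fc (reported separately because "average fold change of a cluster" admits
both readings).  Percentages are rounded to one decimal.

## Synthetic data

**Genome generator.**  The sequence is `ITR + interior + revcomp(ITR)`.  The
interior holds spacer-separated ORF cassettes on random strands; each cassette
is `[filler | optional motif | filler | TAA | ATG…stop]` in its own strand
orientation.  The in-frame TAA immediately before each planted ATG guarantees
the first-ATG-per-stop caller reports exactly the planted coordinates.  Every
promoter-category gene gets one TGAAANNNNA planted at a random offset (4–90 bp)
inside its 100 bp window; upstream windows of all other genes are scrubbed of
chance motifs (mutating only unprotected filler bases) so classification
against the planted evidence recovers every label.  A homopolymer separator
(length max(32, 3% of the ITR length)) just inside each repeat boundary
guarantees the prefix/suffix comparison fails at the boundary, making the
planted ITR length exactly recoverable under the 2% mismatch allowance.
Background bases are drawn with the target GC (default 30%, the AT-rich regime
of insect poxviruses).  Defaults: 50 kb genome, 2 kb ITRs, 40 ORFs of 60–300 aa
in proportions echoing a small entomopoxvirus annotation (9 core, 6 BRO,
1 homology, 7 promoter, 17 unknown).  Chance ORFs in spacers and ITRs are
expected (random sequence contains them) and harmless: planted ORFs are a
subset of the calls, and chance calls classify as unknown.

**Count simulator.**  Per gene, the fly-side baseline mean is log-uniform on
`base_mean_range` (default 100–1,000 — about one order of magnitude of
baseline spread, so the planted direction structure rather than baseline
abundance dominates the clustering distances, as in the observed expression
heatmaps).  The planted effect is the category effect (defaults +2.3 for core
replication, −3.4 for all virulence categories, 0 otherwise) plus per-gene
N(0, 0.5) jitter on the log2 scale; jitter applies only to non-null categories
so an all-zero map is an exact null.  Counts are negative binomial with
variance = mu + phi·mu² (dispersion phi, default 0.05); phi = 0 gives the
Poisson limit.  Six replicates per group by default.

Because FPKM is a relative (compositional) measure, a fold-change pattern that
moves more mass up than down shifts every gene's apparent FPKM ratio by the
library-composition factor; with the default category mix that bias is
log2(1.23) ≈ 0.30.  The simulator therefore balances total expected viral
output between the two hosts by scaling the fly-side baselines of
down-regulated genes with a single scalar solved from the planted map.  The
planted fold changes then live on the scale the FPKM assay actually measures,
and they are recoverable; biologically this amounts to assuming comparable
total viral transcriptional output in the two hosts, with virulence genes
expressed from a higher baseline in the fly — the host in which they act.

**Recovery metrics.**  `evaluate_recovery` reports mean estimated vs planted
log2fc per category, the adjusted Rand index between recovered clusters and
planted effect directions over DE genes with non-zero planted effects, DE
sensitivity over planted non-null genes, and the realized FDR.

**What the synthetic data do not show.**  Genes are non-overlapping with clean
ATG…stop structure; real poxvirus genomes contain overlapping and nested ORFs,
promoter sharing between divergent neighbours, and repeat-driven assembly
ambiguity, none of which are emulated.  Counts are NB with a single global
dispersion and no sample-level batch effects, GC bias or mapping ambiguity.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under its own model, not the adequacy of a Welch-on-FPKM test
for arbitrary real libraries.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale inputs chosen to
exercise every code path well inside a single CPU: 1–10 kb random genomes for
ORF-caller/oracle equivalence (100 genomes), 10–50 kb synthetic genomes for
ITR/classification recovery, 500-gene 6-vs-6 studies for effect recovery and
the null control, and <=15-point permutations for block/LIS equivalence (100
permutations).  All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical seeds give byte-identical genomes and
count matrices.  Property-based tests run derandomized.

## Known limitations

* The ORF rule has no ribosome-binding or codon-usage model; it will call
  spurious ORFs in random or repetitive sequence by design.
* ITR detection assumes the repeat begins at position 0 (true of intact
  poxvirus assemblies); eroded or offset termini are out of scope.
* The comparison-table SD is the sample SD; with two non-focal genomes it is
  defined but weakly informative.
* Ward clustering is performed on absolute log10 expression, so a study whose
  baseline-abundance spread greatly exceeds its effect sizes can cluster by
  abundance instead of direction; row-standardizing is a caller-side option.
* Ortholog inference, tree building, read alignment and quantification are
  external to the package: orthologs enter as position maps, expression as a
  count matrix.
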