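# Methods

This note documents the models, parameter choices and numerical
decisions behind `allosilence`: a pipeline that flags parental-subgenome
genes not expressed in an allopolyploid transcriptome and characterizes
them by their sequence divergence from the partner subgenomes.  The
pipeline is validated end to end on synthetic data with known truth;
this note also states what that validation does and does not show.

## 1. The detection model

A gene's reads in a library are modeled as Poisson sampling at the
gene's expression rate.  For a parental contig with `C_parent` uniquely
mapped reads across parent libraries of pooled depth `D_parent`, the
hypothesis "the gene is still expressed in the polyploid at a fraction
`f` of its parent level" predicts

    lambda = f * (C_parent / D_parent) * D_polyploid

reads in the pooled polyploid libraries, and the probability of
nonetheless observing zero is `P0 = exp(-lambda)`.  `f` is a stated
hypothesis, not an estimate; its default 1/3 reflects the conservative
expectation that a retained gene in a hexaploid background may be
expressed at a third of its diploid-parent level.  At the library
depths of the motivating study (1,999,453 parent / 6,674,733 polyploid
reads) a gene with 10 parent reads gives `P0 ≈ 1.5e-5`, below the
3-in-1000 bound that motivates the 10-read filter.  The Poisson form is
used because the binomial it approximates, `(1-p)^D` with
`p = f*C/D_parent`, agrees with it to better than 1e-6 at these depths
(a unit test asserts this).

Pooling: the zero-count condition is over *all* polyploid libraries, so
`D_polyploid` pools them; parent counts and depths are pooled likewise
by default.  A `per_library` flag instead uses the maximal single
parent-library rate, which is the more aggressive reading; both modes
are provided because the choice is not dictated by the model.

Two call levels mirror the two set sizes a study of this kind reports:
*all-undetected* (any parent evidence, zero polyploid reads) and
*high-confidence* (additionally ≥ `min_parent_reads` = 10 in a single
parent library, where P0 is small enough that sampling cannot explain
the zero).

## 2. Alignment and unique mapping

Both the read mapper and the homology search are built on exact
affine-gap Smith–Waterman semantics (match +1; gap open −5, extend −2;
a length-L gap costs −5 − 2L).  The published pipeline used BWA-SW with
its mismatch penalty raised to 10 and a z-best heuristic of 100; at
desk scale we do not reproduce the heuristic but instead guarantee the
quantity it approximates, the exact best local score.  Secondary blocks
(multi-exon hits) are extracted Waterman–Eggert style: the best local
alignment is reported, its query and subject intervals are masked, and
the DP is repeated, which also guarantees blocks never overlap — so the
block-aggregated identity cannot double-count columns.

Two scoring presets:

* **mapping** (mismatch −10, seed word 16): a read is assigned to a
  contig only if its best score reaches a floor of 0.6 × read length ×
  match and exceeds the best score on any other contig by ≥ 1.  The −10
  penalty makes cross-subgenome reads (≲ 96% identity) fail the floor,
  which is what "uniquely mapped" must mean in a polyploid; ties
  (e.g. identical duplicated genes) are unassigned.
* **homology** (mismatch −2, seed word 12): BLASTN-like, so 70–100%
  identical homeologs align over their full length.

The bulk mapper seeds exact 16-mers at stride 8 (both strands) into a
sorted k-mer index of the reference, clusters seed diagonals per
contig, and scores each cluster with a banded (±8 diagonals) version of
the same DP; a test asserts that its decisions equal the full-DP
single-read path on simulated libraries.  N (masked) bases score 0 in
all alignments — neither match nor mismatch — so QC masking reduces
evidence without destroying mappability; the uniqueness floor is
computed on the full post-QC read length, making heavily masked reads
fail it, which is intended.

Coordinates are 0-based half-open internally and 1-based inclusive in
TSV reports.  Determinism: references are indexed in lexicographic id
order and all ties resolve to the smallest index.

## 3. Quality control

Two rules, applied in order: (1) trim the maximal run of bases with
Phred < 15 from each read end; (2) mask remaining bases with Phred < 20
to N, preserving their qualities.  Both ends are trimmed by default
(a flag restricts to 3′), and reads shorter than 50 nt after trimming
are rejected — the 50 nt minimum is this package's addition, to avoid
unmappable stubs.  The operation is idempotent (tested), and masking
never changes the post-trim length.

## 4. Quantification

RPKM = C / (D/1e6) / (L/1e3).  `D` is the QC-passed read count of the
library — "depth" could also mean raw or uniquely-mapped reads, and the
choice matters for absolute RPKM values; QC-passed was chosen because
it is the denominator under which the mapper actually operated, and the
matrix carries the per-library unassigned counts so any other
convention can be recomputed.

## 5. Divergence analysis

For each query against one comparator collection, blocks shorter than
100 nt are discarded; a subject qualifies if at least one block
survives; the best subject maximizes the total score of qualifying
blocks (ties: higher aggregated identity, then lexicographic id).
Aggregated identity is Σ matches / Σ block columns × 100, gap columns
included — the multi-exon "total alignment-block length" rule.

Identity classes default to 5-point bins 70→100 plus one catch-all
class below 70; the histogram bins of the motivating figures are not
printed numerically, so the edges are configurable.  Two χ² modes are
provided because figure legends of this kind underdetermine the test:
per class (2×2: set membership × in-class) with Bonferroni-adjusted
p-values reported alongside raw ones, and global (one 2×k table).
Genes without a qualifying hit form their own "unmatched" class and are
excluded from the identity-class tests by default (flag to include).
The χ² statistic is Pearson's without continuity correction; a
simulation utility measures its type-I error at the study's set sizes
(112 vs 200), which comes out at 5.0% for α = 0.05 under a realistic
class distribution.

Reciprocal classification: each initial hit's subject is searched back
against the full parental reference; a strictly higher reciprocal
identity marks the initial pair as non-homeologous (the subject is some
other gene's ortholog).  Strictness matters: a subject whose best
reciprocal match is the original query at the same identity is not
"reciprocal-higher".

## 6. The synthetic-data generator

The generator emulates the study design, not the sequencing platform:

* **Genes**: i.i.d. uniform ACGT contigs, lengths uniform on
  500–1500 nt; 2,000 genes at study scale.
* **Expression**: per-gene weights log-uniform over three decades,
  normalized to library rates.  This puts genes on both sides of the
  10-read filter at the configured depths, exercising the
  all-undetected / high-confidence distinction in both directions.
* **Loss**: exactly round(n × 5%) genes deleted and round(n × 3%)
  silenced (statuses partition the gene set).  Deleted genes are absent
  from the polyploid genome; silenced genes are present but transcribed
  at rate 0.
* **Libraries**: 3 parent + 4 polyploid libraries of unequal depth
  (100k–480k reads; the study's libraries ranged from ~120k to >1.2M),
  454-style single-end reads, lengths Normal(400, 80) truncated to
  [50, gene length], uniform substitutions at 0.5%, 1-nt indels at
  0.02%, and Phred scores declining from ~33 by ~14 toward the 3′ end
  with sd 5.  Homopolymer-specific 454 errors are deliberately not
  modeled: no downstream stage depends on the error type, only on reads
  being mappable or not.
* **The polyploid transcriptome honors f exactly.**  Retained genes are
  sampled at `f ×` their parent rate; the partner-subgenome comparators
  absorb the complementary read mass (in proportion to their parent
  counterparts' rates).  This keeps the f = 1/3 hypothesis of the
  absence caller exactly true at fixed library depth, and it means most
  polyploid reads come from the partner subgenomes — which is also what
  makes unique mapping worth testing.  Comparator transcription can be
  disabled, in which case f is only nominal.
* **Comparators**: one per parent gene, a mutated copy landing in a
  percent-identity class drawn from configurable weights (defaults
  giving a control-set mean of ~91%).  With `divergence_bias` on (the
  default, reflecting the empirical coupling between subgenome gene
  loss and homeolog divergence), deleted/silenced genes draw from
  weights concentrated on 70–80%.  Substitutions are placed stratified
  (near-uniform local density) outside a few 18-nt conserved islands —
  the islands mimic conserved motifs and guarantee exact seed words
  survive at 70% identity; both termini are islands so terminal
  trimming cannot inflate identity.  Because the +1/−2 scheme is near
  its break-even at ~70% identity, the best local blocks still favor
  cleaner stretches there, so the generator runs a 1-D model of the
  block extraction (Kadane segments on the known column scores) and
  adds compensating substitutions inside surviving segments until the
  modeled aggregated identity meets the drawn target.  The realized
  aggregated identity, measured by the actual aligner, lands within
  ±1 percentage point of the drawn bin (tested over many seeds).

Everything derives from a single integer seed through spawned
`numpy` `SeedSequence` streams (plus per-library seeds for the numba
read-synthesis kernel); identical configurations give byte-identical
FASTA/FASTQ/TSV outputs.

### What the synthetic validation does not show

Genes are independent random sequences: there are no gene families,
repeats, paralogs or shared domains, so the unique-mapping tie rule and
the reciprocal classification face only easy negatives here (the
reciprocal-higher fraction on synthetic data is 0% by construction,
whereas real EST collections produce substantial fractions).  Error and
quality models are schematic, and comparator divergence is uniform
along the gene except for the modeled islands.  Passing recovery tests
therefore demonstrates the pipeline's logic and calibration, not its
performance on real 454 libraries.

## 7. The in-silico presence check

The wet-lab genomic PCR assay of the motivating study is replaced by a
sequence search of each flagged gene against the polyploid genome
sequence set: present (silenced candidate) requires a qualifying hit
with ≥ 100 nt block and ≥ 98% aggregated identity; absent means
deletion candidate.  98% leaves room for sequencing-level divergence
while excluding any cross-subgenome homeolog the generator can produce
(caps at 100% of a 95–100 bin are possible, which is why deleted genes'
comparators draw from low-identity bins under `divergence_bias`; with
the bias disabled, a deleted gene whose homeolog exceeds 98% identity
would be misread as present — a limitation real studies share).

## 8. Problem sizes and runtime

Study-scale defaults (2,000 genes, 1.6 M reads over 7 libraries) run
the full pipeline in ~6 minutes on one CPU: read synthesis and QC are
numba kernels over packed uint8 arrays, mapping runs at ~15–20k reads/s,
and the homology stages search ~330 query genes against 2,000
comparators via seed shortlisting.  The small demo configuration
(80 genes, 23k reads) runs in seconds and exercises every stage.
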