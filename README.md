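# allosilence

Detection and characterization of parental-subgenome genes that are
**silenced or lost in an allopolyploid transcriptome**, from RNA-seq
read libraries of the parent and the polyploid.

The motivating setting is a young hexaploid such as triticale (wheat
A + B genomes plus the rye R genome): after allopolyploidization, some
genes contributed by one parent stop being expressed, either because
the gene was physically deleted from the hybrid genome or because it is
still present but transcriptionally silenced.  `allosilence` implements
the complete in-silico workflow for finding such genes and asking what
distinguishes them — with a synthetic-data generator that produces
allopolyploid read sets with *known* deletion/silencing truth, so every
stage of the pipeline is verifiable end to end.

## The method

1. **Read QC.**  Maximal runs of bases with Phred < 15 are trimmed from
   both read ends and remaining bases with Phred < 20 are masked to N.
2. **Unique mapping.**  Reads are locally aligned to the parental cDNA
   contigs (match +1, mismatch −10, affine gaps −5/−2).  The heavy
   mismatch penalty makes reads from the partner subgenomes (~70–97%
   identical homeologs) fall below the score floor (0.6 × read length),
   so that counted reads are subgenome-of-origin specific.  A read is
   counted only if exactly one contig attains the best score.
3. **Quantification.**  Unique counts per contig × library, normalized
   as RPKM = C / (D/10⁶) / (L/10³), with D the QC-passed depth.
4. **Absence calling.**  A contig is *all-undetected* if it has parent
   reads but zero polyploid reads in every polyploid library, and
   *high-confidence* if some single parent library holds ≥ 10 reads.
   Each call carries a Poisson non-detection probability: under the
   hypothesis that the gene is still expressed in the polyploid at a
   fraction f (default 1/3) of its parent rate,

       λ = f · (C_parent / D_parent) · D_polyploid ,   P₀ = e^(−λ).

   At the depths of the motivating study (1,999,453 parent and
   6,674,733 polyploid reads), a gene with 10 parent reads gives
   P₀ ≈ 1.5 × 10⁻⁵ ≤ 0.003 — a zero count is then evidence of loss,
   not of sampling.
5. **Divergence analysis.**  Flagged genes and a random control set
   (default n = 200) are searched against comparator collections
   (partner-subgenome assemblies, progenitor genomes, ESTs).  A hit
   qualifies if it has an alignment block ≥ 100 nt; percent identity is
   aggregated over all qualifying blocks (Σ matches / Σ block length).
   Identity-class distributions are compared with Pearson χ²
   contingency tests (per 5-point class, and globally), reciprocal
   best hits back into the parent reference distinguish orthologs from
   missing homeologs, and an in-silico genome search separates
   *deletion candidates* from *silenced candidates*.

## Worked example

```python
from allosilence import RunConfig, run_pipeline
from allosilence.simulate import small_config

result = run_pipeline(RunConfig(simulation=small_config(), n_control=30,
                                output_dir="results/demo"))
print(result.confusion)
```

prints the recovery confusion matrix of the small demo experiment
(80 genes, 4 libraries, 10% deleted, 5% silenced):

```
called    flagged  not_flagged
status
deleted         5            3
retained        0           68
silenced        3            1
```

All eight flagged genes are truth-lost (the three deleted and one
silenced gene that were *not* flagged simply never reached 10 reads in
a parent library — the same reason the motivating study distinguishes
its high-confidence subset), and the in-silico presence check then
classifies the flagged genes into 5 deletion candidates and 3 silenced
candidates with no cross-assignment.

At study scale (`RunConfig()` defaults: 2,000 genes, 7 libraries,
~1.6 M reads, ~6 min on one CPU) the pipeline flags 107 genes —
every deleted/silenced gene with ≥ 10 observed parent reads and zero
false flags — and reproduces the divergence contrast: flagged genes
average 77% identity to their best partner-subgenome match vs 91% for
the random control, with the 70–75% class enriched at p < 10⁻¹⁹.

The numbered scripts under `analysis/` run these stages as a narrative
(design → expression/absence → divergence profile → statistical
calibration) and write their tables under `results/`.

## Command line

Every stage is also exposed as a subcommand:

```bash
allosilence simulate --outdir sim --seed 1
allosilence qc --reads sim/parent_anther.fastq --out clean.fastq
allosilence map --reads clean.fastq --reference sim/reference.fasta --out map.tsv
allosilence run-all --outdir results/run1    # everything, with a manifest
```

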