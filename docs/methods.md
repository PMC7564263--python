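# Methods

This note documents the models, conventions and numerical choices behind
circleaf, and what the synthetic data do and do not establish about real
libraries.

## Coordinates and identifiers

All genomic coordinates are 1-based and fully closed.  A back-splice
junction is identified as `chrom:start-end`, where `start` and `end` are
the first and last base **inside** the circle; that string is the key for
every downstream table.  Exon indices are counted 5'→3' in the host
transcript's orientation, so exon 1 of a minus-strand gene is its
rightmost genomic exon.

## Back-splice detection

**Evidence unit.** SAM records are grouped per read end (mates are
separate groups; secondary and unmapped records are skipped but counted).
Each aligned segment is reduced to its reference interval, strand and its
query interval *in original read orientation* (reverse-strand alignments
are flipped back using the full read length inferred from the CIGAR,
including hard clips).

**Chiastic test.** A group evidences a junction iff two segments share
chromosome and strand, their query intervals abut within a slack
(default 5 bases, covering micro-overlaps and small gaps at the
breakpoint), and the segment *earlier in the read* maps downstream of the
later one.  On the plus strand the junction is then
(`suffix.ref_start`, `prefix.ref_end`); on the minus strand the roles
mirror.  Groups with more than two usable segments use the pair with the
largest total aligned length; ties are discarded as ambiguous (counted).
Both mates of one template supporting the same junction count once —
`n_junction_reads` is the number of distinct templates.

**Canonical signal.** A junction passes the splice-signal filter iff, in
host-strand orientation, the two bases upstream of `start` are AG
(acceptor) and the two bases downstream of `end` are GT (donor);
equivalently AC/CT on the plus strand for minus-strand junctions.
Junctions within two bases of a chromosome edge fail with a logged
reason.  Defaults: `min_reads=2`, signal filter on; both are flags
(permissive mode exists for diagnostics).  Chiastic reads on the
organelle chromosome are never turned into circRNA calls; they only enter
library accounting.

**Anchor detector.** The independent second detector starts from raw
reads: the terminal k-mers (k = 20) of each read (and of its reverse
complement) are placed on the genome via an exact-match 2-bit-packed
k-mer index; a chiastic placement (left anchor downstream of the right
one, same chromosome) is extended inward base by base, and every
breakpoint consistent with both extensions is tested for the GT/AG
flanks.  Exactly one signal-consistent breakpoint → a junction; several,
or multiply-placed anchors → the read is dropped as ambiguous (counted).
Because breakpoints are required to carry the canonical signal, this
detector cannot confirm non-canonical junctions — an intentional
asymmetry that mirrors how independent callers disagree on real data.

## Normalization

A read end is **organelle** if its primary segment lies on an
organelle-class chromosome, else **rRNA** if any segment overlaps an
annotated rRNA interval by ≥ 50% of the segment span (threshold
configurable); the categories are disjoint with organelle precedence.
The effective library size is total mapped read ends minus both
categories, and abundances are reported as counts per million effective
reads (CPM).  The per-million factor is presentational: every statistic
downstream is scale-free.  Absent feature/sample combinations are
explicit zeros.

**Linear counterparts** of a circRNA are counted in two ways, both
normalized identically: (i) *boundary* — templates with a contiguous or
forward-spliced segment whose aligned blocks reach both inside the circle
and outside past the start or end coordinate (back-spliced templates of
that junction are excluded); (ii) *host gene* — templates with any
segment overlapping the gene's exon union.  The boundary counter is the
primary definition: gene-level counts absorb reads from inside the circle
and are therefore partially confounded with circular abundance, which is
visible in the pipeline's secondary host-gene correlation.

## Consensus and correlations

The reproducibility spectrum is the fraction of circRNAs (union over a
genotype's replicates) detected in exactly 1..n replicates.  The
consensus set requires detection in all n replicates by default
(k configurable; n is taken per genotype from the sample sheet).
Mutant-specific circRNAs are computed in two modes: *consensus* (absent
from the reference consensus) and *strict* (absent from every reference
replicate, even once).

Replicate correlations are Pearson r on normalized values, computed
identically for circular and linear matrices.  For each replicate pair,
features zero in both members are dropped (shared absence is not
informative); features present in only one member are kept as zeros,
because presence/absence variability is exactly the stochastic
back-splicing signal the contrast is meant to expose.  No log transform
by default (a flag exists): the raw-scale r is what makes the
circular-vs-linear contrast interpretable as biological noise rather than
dynamic-range compression.

## Differential analysis

Per circRNA: Welch two-sample t-test on log2(CPM + c), pseudocount
c = 0.5, across replicates (n ≥ 2 per group enforced).  The reported
fold change is log2((mean_mut + c)/(mean_wt + c)) on the normalized
scale.  The significance flag follows the conventional raw-p rule
(p ≤ 0.05 and |log2FC| ≥ 1); Benjamini–Hochberg adjusted p-values are
always reported alongside but do not gate the flag.  Features all-zero in
both groups are excluded (logged), never reported significant.  Identical
zero-variance groups yield p = 1.

Genotype-level shifts use a two-sided Mann–Whitney U on pooled
per-circRNA-per-replicate CPM values, each genotype restricted to its own
consensus universe by default (an all-detected mode exists); stars follow
the usual coding (* ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001).  Circular–linear
coupling is a Pearson r over per-feature abundances averaged across the
genotype's replicates; it requires ≥ 3 pairs and variance on both sides,
returning an explicit not-a-value otherwise.

## Annotation

Host gene: the gene whose span contains the junction on its strand;
among several candidates the one with maximal exonic overlap wins, ties
going to the smaller span; if no same-strand candidate exists the search
is repeated strand-agnostically and flagged.  The start-exon index is the
transcript-orientation exon containing the circle's transcript-5'
endpoint; intronic endpoints are assigned to the next exon downstream
with an intronic flag, so distribution tables keep every circRNA.
Boundary classes match the appropriate splice boundary exactly by
default (a ±2-base tolerance flag exists for noisy alignments).  Because
"starts or ends in a known exon" admits two readings, the distribution
table reports both the at-boundary and the within-exon-body fraction.
The representative gene model is the longest annotated transcript.

## The synthetic study

The generator encodes a replicated knockout study: one wild type plus
mutant genotypes, four biological replicates each.  Defaults (the demo):
two 1-Mb nuclear chromosomes, 200 genes of 3–6 exons (exons 100–300 bp,
introns 80–200 bp), one 150-kb organelle chromosome, four rRNA loci,
100-bp paired-end reads, 40 true circRNAs.

- **Genes and signals.** Every intron begins GT and ends AG in transcript
  orientation; an AG is additionally planted immediately upstream of each
  gene's first exon and a GT downstream of its last, so circles bounded
  by *any* exon pair — including first-exon circles — carry the canonical
  signal.  A configurable minority (15%) of circRNAs use shifted,
  exon-internal breakpoints; the AG/GT dinucleotides are planted at the
  shifted positions, emulating cryptic but canonical alternative splice
  sites.  Every simulated circRNA therefore carries a canonical signal,
  matching the behaviour of signal-requiring callers.
- **Pool structure.** 75% of circRNAs are *sporadic*: included per
  replicate as independent Bernoulli draws (p = 0.2) with 1–3 junction
  reads — the stochastic back-splicing class that dominates real
  replicated libraries.  25% are *reproducible* with mean 6 junction
  reads per replicate; their counts are drawn as 2 + NB(mean − 2), i.e.
  the class is defined by reliably passing the 2-read detection threshold
  in every replicate.  Genotype-private circRNAs are reproducible circles
  expressed only in their genotype; privates of the first mutant start at
  exon 1 (the structural signature the mutant comparison looks for).
- **Abundance effects.** Per-circRNA fold changes multiply circRNA means
  only; a genotype-wide scale factor (2.5× / 2.0× for the two demo
  mutants) models mutant-wide increased back-splicing.  Linear gene
  abundances are lognormal (σ = 1.5, a realistic RNA-seq dynamic range)
  and identical across genotypes — circular accumulation changes while
  linear abundance does not, by construction.
- **Noise.** Counts are negative-binomial.  `noise_dispersion` is the
  biological coefficient of variation (BCV), var = μ + (BCV·μ)²,
  default 0.3 — the edgeR-style parametrization; BCV 0.3 corresponds to
  fairly noisy biological replicates.
- **Reads.** Junction reads are emitted as chiastic primary +
  soft-clipped supplementary records with the breakpoint uniformly placed
  ≥ 20 bases from either read end; the mate is a linear read inside the
  circle.  Circles are modelled as their unspliced genomic span (reads
  from the circle come from contiguous genomic sequence, wrapping only at
  the back-splice junction), which keeps every junction read a clean
  two-segment split; intron-retaining circles exist in the literature and
  nothing downstream depends on spliced circles.  Linear mRNA fragments
  produce forward-spliced (M/N) paired records; organelle and rRNA
  contamination reads (12% / 8% of mapped reads) are single-end and
  placed inside their compartments.  Identical seeds give byte-identical
  FASTA/GFF3/SAM/FASTQ/manifest output.

**What passing on this data shows — and does not.**  The simulation
contains no sequencing errors, no mismatched alignments, no multimapping
ambiguity, no isoform diversity and no adapter artifacts.  Perfect
detection recall and near-perfect detector concordance on it demonstrate
the correctness of the geometry, accounting and statistics, not the
robustness of detection under real alignment noise — on real libraries
independent callers agree far less, and thresholds carry real
sensitivity/specificity trade-offs.

## Calibration choices and problem sizes

The statistical calibration of the differential test uses a count-level
simulation (2,000 features, base mean lognormal around 50, BCV 0.3,
n = 4 vs 4; 300 features spiked 4-fold up or down): type-I error at
nominal 0.05 lands near 0.04, power for 4-fold spikes at base mean ≥ 20
is above 0.9, and the median |log2FC| estimation error is ≈ 0.22.  With
the alternative reading of "dispersion 0.3" as the raw NB overdispersion
α (var = μ + 0.3μ²), power against 4-fold at n = 4 plateaus near 0.72 at
any mean — a design-stage power analysis fixed the BCV convention before
implementation, and the convention is exposed in `SimConfig` rather than
hidden.

The replicate-correlation contrast is evaluated over 20 independently
seeded studies at a reduced scale (one 400-kb chromosome, 60 genes, 20
circRNAs, two genotypes); the study-level mean circRNA r falls below the
linear-gene r in ≥ 95% of seeds.  The reduced scale keeps the whole
check inside a few minutes while preserving the pool structure that
drives the contrast.  The circular–linear independence check uses 100
independent feature pairs; note that the null width of Pearson r at
n = 100 is ≈ 0.1, so |r| < 0.2 is a two-sigma statement expected to hold
in roughly 95% of seeds, not a deterministic bound.

## Known limitations

- The anchor detector requires exact anchor matches and a canonical
  signal; it is a cross-validation instrument at synthetic scale, not a
  production aligner.
- Gene-level linear counts include circle-derived reads; use the
  boundary counter when independence from circular abundance matters.
- One representative transcript per gene; no isoform-aware assignment.
- The per-circRNA test is a t-test on log counts at n = 4, not a
  dispersion-shrinkage model; with thousands of features and very small
  counts a dedicated count model would gain power.
- Intronic-lariat circles, intergenic fusions and sequencing-error
  models are out of scope.
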