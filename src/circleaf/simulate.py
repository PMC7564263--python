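"""Synthetic circRNA study generator with a machine-readable ground truth.

Builds a small multi-chromosome genome (nuclear chromosomes + one organelle
chromosome + annotated rRNA loci), multi-exon genes with canonical GT..AG
introns, per-genotype/per-replicate circRNA pools and alignment-level read
evidence.  The back-spliced junction reads are emitted as chiastic split
alignments (primary + soft-clipped supplementary record), i.e. the
representation a split-read circRNA caller faces downstream of a real
aligner.

Study design encoded by the defaults: one wild-type plus mutant genotypes,
four biological replicates each, a circRNA pool dominated by sporadic
(single-replicate) species with a reproducible minority present in every
replicate, genotype-specific fold changes on circRNA abundance with
unchanged linear abundance, and organelle/rRNA contamination that the
effective-library-size normalization has to discount.

Counts are negative-binomial; ``noise_dispersion`` is the biological
coefficient of variation (BCV), i.e. var = m + (BCV*m)^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeBundle, GeneModel, revcomp, NUCLEAR, ORGANELLE

__all__ = [
    "SimConfig",
    "CircTruth",
    "GroundTruthManifest",
    "generate_genome",
    "assign_transcript_pools",
    "emit_alignments",
    "simulate_study",
    "simulate_count_matrix",
    "nb_counts",
    "SimSizingError",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimSizingError(ValueError):
    """Requested content does not fit the configured sequence sizes."""


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


def nb_counts(rng: np.random.Generator, mean, bcv: float, size=None):
    """Negative-binomial counts with var = mean + (bcv*mean)^2.

    ``bcv`` is the biological coefficient of variation (edgeR's sqrt of the
    NB overdispersion); bcv = 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if bcv <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / (bcv * bcv)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults define the standard demo: ~2 Mb of nuclear genome, 200
    genes, 40 true circRNAs, wild-type + two mutants x 4 replicates.
    """

    seed: int = 0
    n_nuclear_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (80, 200)
    organelle_length: int = 150_000
    n_rrna_loci: int = 4
    rrna_locus_length: tuple[int, int] = (600, 1200)
    genotypes: tuple[str, ...] = ("Col-0", "cbp80", "c2h2")
    n_replicates: int = 4
    read_length: int = 100
    fragment_length: tuple[int, int] = (180, 320)
    depth: float = 20.0  # mean linear fragments per gene at relative abundance 1
    n_circ: int = 40
    frac_sporadic_circ: float = 0.75
    frac_reproducible_circ: float = 0.25
    frac_internal_site_circ: float = 0.15
    private_circ: dict = field(default_factory=lambda: {"cbp80": 4, "c2h2": 2})
    sporadic_inclusion_p: float = 0.2
    sporadic_count_range: tuple[int, int] = (1, 3)
    reproducible_mean_count: float = 6.0
    circ_internal_read_factor: float = 1.5
    abundance_sigma: float = 1.5  # lognormal sigma of gene expression levels
    # genotype -> {index into the shared reproducible pool -> fold change}
    circ_fold_changes: dict = field(
        default_factory=lambda: {"cbp80": {0: 4.0, 1: 0.25},
                                 "c2h2": {0: 4.0}}
    )
    # genotype-wide scale on reproducible circRNA means (mutant-wide
    # increase of back-splicing); linear abundances stay untouched
    circ_mean_scale: dict = field(
        default_factory=lambda: {"cbp80": 2.5, "c2h2": 2.0})
    contamination: tuple[float, float] = (0.12, 0.08)  # organelle, rRNA read fractions
    noise_dispersion: float = 0.3  # BCV

    def validate(self) -> None:
        fracs = [self.frac_sporadic_circ, self.frac_reproducible_circ,
                 self.frac_internal_site_circ, self.sporadic_inclusion_p,
                 *self.contamination]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise SimConfigError("all fractions must lie in [0, 1]")
        if self.frac_sporadic_circ + self.frac_reproducible_circ > 1.0 + 1e-9:
            raise SimConfigError(
                "frac_sporadic_circ + frac_reproducible_circ must be <= 1")
        if sum(self.contamination) >= 0.9:
            raise SimConfigError("contamination fractions too close to 1")
        for lo, hi in (self.exon_length, self.intron_length,
                       self.exons_per_gene, self.fragment_length):
            if lo <= 0 or hi < lo:
                raise SimConfigError("length/count ranges must be positive, lo <= hi")
        if self.read_length < 50:
            raise SimConfigError("read_length must be >= 50")
        if len(self.genotypes) < 1 or self.n_replicates < 1:
            raise SimConfigError("need at least one genotype and one replicate")
        for g in self.private_circ:
            if g not in self.genotypes:
                raise SimConfigError(f"private_circ references unknown genotype {g!r}")
        for g in self.circ_fold_changes:
            if g not in self.genotypes:
                raise SimConfigError(
                    f"circ_fold_changes references unknown genotype {g!r}")
        for g in self.circ_mean_scale:
            if g not in self.genotypes:
                raise SimConfigError(
                    f"circ_mean_scale references unknown genotype {g!r}")

    @property
    def wild_type(self) -> str:
        return self.genotypes[0]

    def sample_ids(self) -> list[str]:
        return [f"{g}_rep{r}" for g in self.genotypes
                for r in range(1, self.n_replicates + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_rep{r}", "genotype": g, "replicate": r}
            for g in self.genotypes for r in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class CircTruth:
    """One simulated circRNA: coordinates, host structure, class."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    start_exon_index: int  # transcript orientation, 1-based
    end_exon_index: int
    internal_site: bool  # back-splice shifted into exon bodies
    canonical_signal: bool
    circ_class: str  # 'reproducible' | 'sporadic'
    private_to: str | None = None


@dataclass
class GroundTruthManifest:
    """Everything the simulator decided, for oracle-style verification."""

    circs: dict[str, CircTruth]
    junction_counts: dict[str, dict[str, int]]  # sample -> circ -> reads
    internal_counts: dict[str, dict[str, int]]  # sample -> circ -> fragments
    gene_abundance: dict[str, float]
    linear_fragments: dict[str, dict[str, int]]  # sample -> gene -> fragments
    contamination_reads: dict[str, tuple[int, int]]  # sample -> (organelle, rRNA)
    samples: pd.DataFrame  # sample_id, genotype, replicate
    genotype_mean_counts: dict[str, dict[str, float]]  # genotype -> circ -> mean

    # -- bookkeeping -----------------------------------------------------

    def nuclear_read_ends(self, sample: str) -> int:
        frags = (sum(self.linear_fragments[sample].values())
                 + sum(self.junction_counts[sample].values())
                 + sum(self.internal_counts[sample].values()))
        return 2 * frags

    def total_read_count(self, sample: str) -> int:
        org, rrna = self.contamination_reads[sample]
        return self.nuclear_read_ends(sample) + org + rrna

    def replicates_of(self, genotype: str) -> list[str]:
        sel = self.samples[self.samples.genotype == genotype]
        return list(sel.sample_id)

    # -- oracle views ----------------------------------------------------

    def expected_detected(self, sample: str, min_reads: int = 2) -> set[str]:
        """circRNAs whose emitted junction reads reach the calling threshold."""
        return {c for c, n in self.junction_counts[sample].items()
                if n >= min_reads}

    def expected_consensus(self, genotype: str, k: int | None = None,
                           min_reads: int = 2) -> set[str]:
        reps = self.replicates_of(genotype)
        if k is None:
            k = len(reps)
        detected = [self.expected_detected(s, min_reads) for s in reps]
        union = set().union(*detected) if detected else set()
        return {c for c in union
                if sum(c in d for d in detected) >= k}

    def expected_strict_unique(self, genotype: str, reference: str,
                               min_reads: int = 2) -> set[str]:
        cons = self.expected_consensus(genotype, min_reads=min_reads)
        ref_any = set().union(
            *[self.expected_detected(s, min_reads)
              for s in self.replicates_of(reference)])
        return cons - ref_any

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "circs": {k: asdict(v) for k, v in self.circs.items()},
            "junction_counts": self.junction_counts,
            "internal_counts": self.internal_counts,
            "gene_abundance": self.gene_abundance,
            "linear_fragments": self.linear_fragments,
            "contamination_reads": {k: list(v) for k, v in
                                    self.contamination_reads.items()},
            "samples": self.samples.to_dict(orient="records"),
            "genotype_mean_counts": self.genotype_mean_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            circs={k: CircTruth(**v) for k, v in d["circs"].items()},
            junction_counts=d["junction_counts"],
            internal_counts=d["internal_counts"],
            gene_abundance=d["gene_abundance"],
            linear_fragments=d["linear_fragments"],
            contamination_reads={k: tuple(v) for k, v in
                                 d["contamination_reads"].items()},
            samples=pd.DataFrame(d["samples"]),
            genotype_mean_counts=d["genotype_mean_counts"],
        )


# ---------------------------------------------------------------------------
# genome generation


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Generate nuclear chromosomes with GT..AG multi-exon genes, one
    organelle chromosome and annotated rRNA loci.

    Every intron begins with GT and ends with AG in transcript
    orientation; in addition an AG is planted immediately upstream of each
    gene's first exon and a GT downstream of its last (transcript
    orientation), so that back-splice junctions at any exon boundary carry
    the canonical signal.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    chrom_names = [str(i + 1) for i in range(config.n_nuclear_chroms)]
    chroms = {name: _random_seq(rng, config.chrom_length) for name in chrom_names}

    # reserve a tail on each chromosome for rRNA loci
    per_chrom_rrna = [0] * config.n_nuclear_chroms
    for i in range(config.n_rrna_loci):
        per_chrom_rrna[i % config.n_nuclear_chroms] += 1
    reserve = [n * (config.rrna_locus_length[1] + 500) + 500
               for n in per_chrom_rrna]

    genes: dict[str, GeneModel] = {}
    cursors = {name: 1000 for name in chrom_names}
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_nuclear_chroms]
        n_ex = int(rng.integers(config.exons_per_gene[0],
                                config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0],
                                 config.exon_length[1] + 1, n_ex)
        intron_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1, n_ex - 1)
        strand = "+" if rng.random() < 0.5 else "-"

        parts = []
        for i in range(n_ex):
            parts.append(_random_seq(rng, int(exon_lens[i])))
            if i < n_ex - 1:
                intron = _random_seq(rng, int(intron_lens[i]))
                intron[:2] = b"GT"
                intron[-2:] = b"AG"
                parts.append(intron)
        seq_t = bytearray().join(parts)
        flanked = bytearray(b"AG") + seq_t + bytearray(b"GT")
        gene_len = len(seq_t)

        g_start = cursors[chrom] + 2
        g_end = g_start + gene_len - 1
        ci = chrom_names.index(chrom)
        limit = config.chrom_length - reserve[ci] - 500
        if g_end + 2 > limit:
            raise SimSizingError(
                f"gene content exceeds chromosome capacity on chromosome "
                f"{chrom}: gene {gi} would end at {g_end + 2} but only "
                f"{limit} bases are available (chrom_length={config.chrom_length}"
                f" minus rRNA reserve {reserve[ci]}); reduce n_genes or "
                f"enlarge chrom_length")
        if strand == "-":
            flanked = bytearray(revcomp(flanked.decode()).encode())
        chroms[chrom][g_start - 3: g_end + 2] = flanked

        # exon genomic coordinates
        exons: list[tuple[int, int]] = []
        if strand == "+":
            pos = g_start
            for i in range(n_ex):
                exons.append((pos, pos + int(exon_lens[i]) - 1))
                pos += int(exon_lens[i])
                if i < n_ex - 1:
                    pos += int(intron_lens[i])
        else:
            pos = g_end
            for i in range(n_ex):
                exons.append((pos - int(exon_lens[i]) + 1, pos))
                pos -= int(exon_lens[i])
                if i < n_ex - 1:
                    pos -= int(intron_lens[i])
            exons.sort()

        gene_id = f"AT{chrom}G{(gi + 1) * 10:05d}"
        genes[gene_id] = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand,
            start=g_start, end=g_end, exons=tuple(exons))
        cursors[chrom] = g_end + 2 + int(rng.integers(300, 1500))

    # rRNA loci in the reserved tails
    rrna_loci: list[tuple[str, int, int]] = []
    for ci, name in enumerate(chrom_names):
        pos = config.chrom_length - reserve[ci] + 250
        for _ in range(per_chrom_rrna[ci]):
            length = int(rng.integers(config.rrna_locus_length[0],
                                      config.rrna_locus_length[1] + 1))
            rrna_loci.append((name, pos, pos + length - 1))
            pos += length + 500

    sequences = {name: seq.decode() for name, seq in chroms.items()}
    sequences["Pt"] = _random_seq(rng, config.organelle_length).decode()
    chrom_class = {name: NUCLEAR for name in chrom_names}
    chrom_class["Pt"] = ORGANELLE
    return GenomeBundle(sequences=sequences, genes=genes,
                        chrom_class=chrom_class, rrna_loci=rrna_loci)


# ---------------------------------------------------------------------------
# transcript pools / ground truth


def _plant(genome: GenomeBundle, chrom: str, pos: int, bases: str) -> None:
    """Overwrite genome bases at 1-based position ``pos`` (length of bases)."""
    seq = genome.sequences[chrom]
    genome.sequences[chrom] = seq[: pos - 1] + bases + seq[pos - 1 + len(bases):]


def assign_transcript_pools(config: SimConfig,
                            genome: GenomeBundle) -> GroundTruthManifest:
    """Draw the per-genotype/per-replicate circRNA pools and linear
    abundances, and fix every circRNA's coordinates on the genome.

    Reproducible-class circRNAs (including genotype-private ones) are
    present in every replicate with at least 2 junction reads; sporadic
    circRNAs are included per replicate as independent Bernoulli draws
    with low counts.  Fold changes multiply circRNA means only; linear
    gene abundances are identical across genotypes.  For the exon-internal
    minority the canonical AG/GT dinucleotides are planted at the shifted
    breakpoints (cryptic but canonical back-splice sites), so every
    manifest circRNA carries a canonical signal.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    min_span = config.read_length + 40

    gene_ids = sorted(genome.genes)
    abundance = {g: float(np.exp(rng.normal(0.0, config.abundance_sigma)))
                 for g in gene_ids}

    eligible = [g for g in gene_ids if genome.genes[g].n_exons >= 3]
    if config.n_circ > len(eligible):
        raise SimSizingError(
            f"n_circ={config.n_circ} exceeds the {len(eligible)} genes with "
            f">=3 exons; raise n_genes or exons_per_gene")
    host_ids = list(rng.choice(eligible, size=config.n_circ, replace=False))

    n_repro = int(round(config.frac_reproducible_circ * config.n_circ))
    n_private = sum(config.private_circ.values())
    if n_private > n_repro:
        raise SimConfigError(
            f"private_circ total {n_private} exceeds the reproducible pool "
            f"size {n_repro}")

    # class labels in host order: reproducible first (privates at the head)
    private_labels: list[str | None] = []
    for g, k in config.private_circ.items():
        private_labels.extend([g] * k)
    private_labels.extend([None] * (n_repro - n_private))
    classes = (["reproducible"] * n_repro
               + ["sporadic"] * (config.n_circ - n_repro))

    shared_indices: dict[int, int] = {}  # circ position -> shared-pool index
    n_shared = 0
    for i in range(config.n_circ):
        if classes[i] == "reproducible" and private_labels[i] is None:
            shared_indices[i] = n_shared
            n_shared += 1
    for g, m in config.circ_fold_changes.items():
        for idx in m:
            if int(idx) >= n_shared:
                raise SimConfigError(
                    f"circ_fold_changes[{g!r}] references shared index {idx} "
                    f"but only {n_shared} shared reproducible circRNAs exist")

    mutant_like = config.genotypes[1] if len(config.genotypes) > 1 else None
    circs: dict[str, CircTruth] = {}
    order: list[str] = []
    for i, gene_id in enumerate(host_ids):
        gene = genome.genes[gene_id]
        exons_t = gene.exons_transcript_order()
        n_ex = gene.n_exons
        private_to = private_labels[i] if i < n_repro else None
        first_exon = private_to is not None and private_to == mutant_like
        if first_exon:
            j = 1
            k = int(rng.integers(2, n_ex + 1))
        else:
            j = int(rng.integers(2, n_ex))  # start from exon >= 2
            k = int(rng.integers(j + 1, n_ex + 1))
        if gene.strand == "+":
            s = exons_t[j - 1][0]
            e = exons_t[k - 1][1]
        else:
            s = exons_t[k - 1][0]
            e = exons_t[j - 1][1]
        internal = (not first_exon) and rng.random() < config.frac_internal_site_circ
        if internal and e - s + 1 >= min_span + 40:
            ds = int(rng.integers(4, 20))
            de = int(rng.integers(4, 20))
            s, e = s + ds, e - de
            if gene.strand == "+":
                _plant(genome, gene.chrom, s - 2, "AG")
                _plant(genome, gene.chrom, e + 1, "GT")
            else:
                _plant(genome, gene.chrom, s - 2, "AC")
                _plant(genome, gene.chrom, e + 1, "CT")
        else:
            internal = False
        circ_id = f"{gene.chrom}:{s}-{e}"
        circs[circ_id] = CircTruth(
            circ_id=circ_id, chrom=gene.chrom, start=s, end=e,
            strand=gene.strand, gene_id=gene_id,
            start_exon_index=j, end_exon_index=k,
            internal_site=internal, canonical_signal=True,
            circ_class=classes[i], private_to=private_to)
        order.append(circ_id)

    # expected mean junction counts per genotype
    genotype_means: dict[str, dict[str, float]] = {}
    for g in config.genotypes:
        means: dict[str, float] = {}
        folds = config.circ_fold_changes.get(g, {})
        scale = float(config.circ_mean_scale.get(g, 1.0))
        for i, cid in enumerate(order):
            c = circs[cid]
            if c.circ_class == "reproducible":
                if c.private_to is not None and c.private_to != g:
                    means[cid] = 0.0
                else:
                    fold = float(folds.get(shared_indices[i], 1.0)) \
                        if i in shared_indices else 1.0
                    means[cid] = config.reproducible_mean_count * fold * scale
            else:
                lo, hi = config.sporadic_count_range
                means[cid] = config.sporadic_inclusion_p * (lo + hi) / 2.0
        genotype_means[g] = means

    samples = config.sample_sheet()
    bcv = config.noise_dispersion
    junction_counts: dict[str, dict[str, int]] = {}
    internal_counts: dict[str, dict[str, int]] = {}
    linear_fragments: dict[str, dict[str, int]] = {}
    contamination_reads: dict[str, tuple[int, int]] = {}

    for _, row in samples.iterrows():
        sid, g = row.sample_id, row.genotype
        jc: dict[str, int] = {}
        ic: dict[str, int] = {}
        for i, cid in enumerate(order):
            c = circs[cid]
            if c.circ_class == "reproducible":
                mean = genotype_means[g][cid]
                if mean <= 0:
                    n = 0
                else:
                    # guarantee the detection threshold in every replicate:
                    # the class is defined by reproducible detectability
                    n = 2 + int(nb_counts(rng, max(mean - 2.0, 0.01), bcv))
            else:
                if rng.random() < config.sporadic_inclusion_p:
                    lo, hi = config.sporadic_count_range
                    n = int(rng.integers(lo, hi + 1))
                else:
                    n = 0
            if n > 0:
                jc[cid] = n
                m = int(round(config.circ_internal_read_factor * n))
                if m > 0:
                    ic[cid] = m
        junction_counts[sid] = jc
        internal_counts[sid] = ic

        lf = {
            gid: int(nb_counts(rng, config.depth * abundance[gid], bcv))
            for gid in gene_ids
        }
        linear_fragments[sid] = lf

        n_nuc = 2 * (sum(lf.values()) + sum(jc.values()) + sum(ic.values()))
        fo, fr = config.contamination
        denom = 1.0 - fo - fr
        n_org = int(round(n_nuc * fo / denom))
        n_rrna = int(round(n_nuc * fr / denom))
        contamination_reads[sid] = (n_org, n_rrna)

    return GroundTruthManifest(
        circs=circs, junction_counts=junction_counts,
        internal_counts=internal_counts, gene_abundance=abundance,
        linear_fragments=linear_fragments,
        contamination_reads=contamination_reads, samples=samples,
        genotype_mean_counts=genotype_means)


# ---------------------------------------------------------------------------
# alignment emission


def _sam_header(genome: GenomeBundle) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in genome.sequences.items()],
    })


def _make_rec(header, name, flag, chrom, pos1, cigar, seq,
              mate_chrom=None, mate_pos1=None):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_name = chrom
    rec.reference_start = pos1 - 1
    rec.cigarstring = cigar
    rec.query_sequence = seq
    rec.mapping_quality = 60
    if mate_chrom is not None:
        rec.next_reference_name = mate_chrom
        rec.next_reference_start = mate_pos1 - 1
    return rec


_PAIRED = 0x1
_PROPER = 0x2
_REVERSE = 0x10
_MREVERSE = 0x20
_READ1 = 0x40
_READ2 = 0x80
_SUPPLEMENTARY = 0x800


def _blocks_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (a, b) in enumerate(blocks):
        if i > 0:
            gap = a - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{b - a + 1}M")
    return "".join(parts)


def _pair_flags(read1_reverse: bool, read2_reverse: bool) -> tuple[int, int]:
    f1 = _PAIRED | _PROPER | _READ1
    f2 = _PAIRED | _PROPER | _READ2
    if read1_reverse:
        f1 |= _REVERSE
        f2 |= _MREVERSE
    if read2_reverse:
        f2 |= _REVERSE
        f1 |= _MREVERSE
    return f1, f2


def emit_alignments(manifest: GroundTruthManifest, genome: GenomeBundle,
                    config: SimConfig, outdir: str | Path,
                    write_fastq: bool = False) -> dict[str, dict[str, Path]]:
    """Write one SAM file per sample (optionally FASTQ of the same reads).

    Junction-spanning reads are emitted as a primary plus a supplementary
    record in chiastic order: the read prefix aligns to a downstream
    segment ending at the circRNA end, the read suffix to an upstream
    segment starting at the circRNA start (mirrored on the minus strand).
    Returns ``{sample: {"sam": path, "fastq": path?}}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _sam_header(genome)
    L = config.read_length
    paths: dict[str, dict[str, Path]] = {}

    sample_list = list(manifest.samples.sample_id)
    for si, sid in enumerate(sample_list):
        rng = np.random.default_rng([config.seed, 2, si])
        sam_path = outdir / f"{sid}.sam"
        fq_lines: list[str] = []
        records: list[pysam.AlignedSegment] = []

        def add_pair(name, rec1, rec2, seq1_readorient, seq2_readorient):
            records.append(rec1)
            records.append(rec2)
            if write_fastq:
                qual = "I" * len(seq1_readorient)
                fq_lines.extend([f"@{name}/1", seq1_readorient, "+", qual])
                qual = "I" * len(seq2_readorient)
                fq_lines.extend([f"@{name}/2", seq2_readorient, "+", qual])

        # ---- linear gene fragments (spliced transcripts) ----
        for gid in sorted(manifest.linear_fragments[sid]):
            n = manifest.linear_fragments[sid][gid]
            if n == 0:
                continue
            gene = genome.genes[gid]
            T = gene.transcript_length
            if T < L:
                raise SimSizingError(
                    f"read_length {L} exceeds the spliced transcript length "
                    f"{T} of {gid}; shrink read_length or enlarge exons")
            for i in range(n):
                flen = int(rng.integers(*config.fragment_length))
                flen = max(L, min(flen, T))
                t0 = int(rng.integers(0, T - flen + 1))
                name = f"{sid}:lin:{gid}:{i}"
                b1 = gene.transcript_to_genomic_blocks(t0, L)
                b2 = gene.transcript_to_genomic_blocks(t0 + flen - L, L)
                seq1 = "".join(genome.fetch(gene.chrom, a, b) for a, b in b1)
                seq2 = "".join(genome.fetch(gene.chrom, a, b) for a, b in b2)
                r1_rev = gene.strand == "-"
                f1, f2 = _pair_flags(r1_rev, not r1_rev)
                rec1 = _make_rec(header, name, f1, gene.chrom, b1[0][0],
                                 _blocks_cigar(b1), seq1,
                                 gene.chrom, b2[0][0])
                rec2 = _make_rec(header, name, f2, gene.chrom, b2[0][0],
                                 _blocks_cigar(b2), seq2,
                                 gene.chrom, b1[0][0])
                s1_read = revcomp(seq1) if r1_rev else seq1
                s2_read = seq2 if r1_rev else revcomp(seq2)
                add_pair(name, rec1, rec2, s1_read, s2_read)

        # ---- circRNA junction fragments ----
        for cid in sorted(manifest.junction_counts[sid]):
            n = manifest.junction_counts[sid][cid]
            c = manifest.circs[cid]
            s, e = c.start, c.end
            circ_len = e - s + 1
            if circ_len < L:
                raise SimSizingError(
                    f"read_length {L} exceeds the circumference {circ_len} "
                    f"of {cid}; shrink read_length or enlarge circRNA spans")
            for i in range(n):
                b = int(rng.integers(20, L - 20 + 1))
                name = f"{sid}:bsj:{cid.replace(':', '_')}:{i}"
                if c.strand == "+":
                    # prefix -> [e-b+1, e]; suffix -> [s, s+L-b-1]
                    seq = (genome.fetch(c.chrom, e - b + 1, e)
                           + genome.fetch(c.chrom, s, s + L - b - 1))
                    prim_is_prefix = b >= L - b
                    f_main = _PAIRED | _PROPER | _READ1
                    recP = _make_rec(header, name, f_main, c.chrom, e - b + 1,
                                     f"{b}M{L - b}S", seq)
                    recS = _make_rec(header, name, f_main, c.chrom, s,
                                     f"{b}S{L - b}M", seq)
                    jr_rev = False
                else:
                    # minus strand: stored SEQ is the plus-strand sequence
                    seq = (genome.fetch(c.chrom, e - (L - b) + 1, e)
                           + genome.fetch(c.chrom, s, s + b - 1))
                    prim_is_prefix = b >= L - b
                    f_main = _PAIRED | _PROPER | _READ1 | _REVERSE
                    recP = _make_rec(header, name, f_main, c.chrom, s,
                                     f"{L - b}S{b}M", seq)
                    recS = _make_rec(header, name, f_main, c.chrom,
                                     e - (L - b) + 1, f"{L - b}M{b}S", seq)
                    jr_rev = True
                if prim_is_prefix:
                    primary, suppl = recP, recS
                else:
                    primary, suppl = recS, recP
                suppl.flag |= _SUPPLEMENTARY
                # mate 2: linear read inside the circle, opposite strand
                m2_rev = not jr_rev
                g0 = int(rng.integers(s, e - L + 2))
                seq2 = genome.fetch(c.chrom, g0, g0 + L - 1)
                f2 = _PAIRED | _PROPER | _READ2
                if m2_rev:
                    f2 |= _REVERSE
                if jr_rev:
                    f2 |= _MREVERSE
                for rec in (primary, suppl):
                    if m2_rev:
                        rec.flag |= _MREVERSE
                    rec.next_reference_name = c.chrom
                    rec.next_reference_start = g0 - 1
                rec2 = _make_rec(header, name, f2, c.chrom, g0, f"{L}M", seq2,
                                 c.chrom, primary.reference_start + 1)
                records.extend([primary, suppl, rec2])
                if write_fastq:
                    read1 = revcomp(seq) if jr_rev else seq
                    read2 = revcomp(seq2) if m2_rev else seq2
                    q = "I" * L
                    fq_lines.extend([f"@{name}/1", read1, "+", q,
                                     f"@{name}/2", read2, "+", q])

        # ---- circRNA internal (non-junction) fragments ----
        for cid in sorted(manifest.internal_counts[sid]):
            m = manifest.internal_counts[sid][cid]
            c = manifest.circs[cid]
            s, e = c.start, c.end
            circ_len = e - s + 1
            for i in range(m):
                flen = int(rng.integers(*config.fragment_length))
                flen = max(L, min(flen, circ_len))
                g0 = int(rng.integers(s, e - flen + 2))
                name = f"{sid}:cin:{cid.replace(':', '_')}:{i}"
                seq1 = genome.fetch(c.chrom, g0, g0 + L - 1)
                seq2 = genome.fetch(c.chrom, g0 + flen - L, g0 + flen - 1)
                r1_rev = c.strand == "-"
                f1, f2 = _pair_flags(r1_rev, not r1_rev)
                rec1 = _make_rec(header, name, f1, c.chrom, g0, f"{L}M", seq1,
                                 c.chrom, g0 + flen - L)
                rec2 = _make_rec(header, name, f2, c.chrom, g0 + flen - L,
                                 f"{L}M", seq2, c.chrom, g0)
                s1_read = revcomp(seq1) if r1_rev else seq1
                s2_read = seq2 if r1_rev else revcomp(seq2)
                add_pair(name, rec1, rec2, s1_read, s2_read)

        # ---- contamination: organelle and rRNA single-end reads ----
        n_org, n_rrna = manifest.contamination_reads[sid]
        pt_len = genome.chrom_length("Pt")
        for i in range(n_org):
            g0 = int(rng.integers(1, pt_len - L + 2))
            rev = bool(rng.integers(0, 2))
            seq = genome.fetch("Pt", g0, g0 + L - 1)
            rec = _make_rec(header, f"{sid}:org:{i}",
                            _REVERSE if rev else 0, "Pt", g0, f"{L}M", seq)
            records.append(rec)
            if write_fastq:
                fq_lines.extend([f"@{sid}:org:{i}",
                                 revcomp(seq) if rev else seq, "+", "I" * L])
        loci = genome.rrna_loci
        for i in range(n_rrna):
            chrom, a, bnd = loci[i % len(loci)]
            g0 = int(rng.integers(a, bnd - L + 2))
            rev = bool(rng.integers(0, 2))
            seq = genome.fetch(chrom, g0, g0 + L - 1)
            rec = _make_rec(header, f"{sid}:rrna:{i}",
                            _REVERSE if rev else 0, chrom, g0, f"{L}M", seq)
            records.append(rec)
            if write_fastq:
                fq_lines.extend([f"@{sid}:rrna:{i}",
                                 revcomp(seq) if rev else seq, "+", "I" * L])

        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            for rec in records:
                out.write(rec)
        entry = {"sam": sam_path}
        if write_fastq:
            fq_path = outdir / f"{sid}.fastq"
            fq_path.write_text("\n".join(fq_lines) + ("\n" if fq_lines else ""))
            entry["fastq"] = fq_path
        paths[sid] = entry
    return paths


def simulate_study(config: SimConfig, outdir: str | Path,
                   write_fastq: bool = False):
    """Full synthetic study: genome + pools + alignments + on-disk bundle.

    Writes genome.fa, annotation.gff3, samples.tsv, manifest.json and one
    SAM (and optionally FASTQ) per sample under ``outdir``.  Returns
    (genome, manifest, paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    manifest = assign_transcript_pools(config, genome)
    paths = emit_alignments(manifest, genome, config, outdir,
                            write_fastq=write_fastq)
    genome.write_fasta(outdir / "genome.fa")
    genome.write_gff3(outdir / "annotation.gff3")
    manifest.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    manifest.to_json(outdir / "manifest.json")
    return genome, manifest, paths


# ---------------------------------------------------------------------------
# count-level simulator for statistical calibration


def simulate_count_matrix(n_features: int, n_per_group: tuple[int, int] = (4, 4),
                          base_mean: float = 50.0, mean_sigma: float = 0.6,
                          bcv: float = 0.3,
                          fold_changes: Mapping[int, float] | None = None,
                          seed: int = 0):
    """Two-group NB count matrix with known per-feature fold changes.

    Per-feature base means are lognormal around ``base_mean``; group B
    means are multiplied by the given fold changes.  Returns
    ``(values, samples, truth)`` where ``values`` is a features x samples
    DataFrame of counts, ``samples`` a sample sheet with genotypes ``A``
    (reference) and ``B``, and ``truth`` a DataFrame with the base mean
    and true log2 fold change of every feature.
    """
    rng = np.random.default_rng(seed)
    fold_changes = dict(fold_changes or {})
    means = base_mean * np.exp(rng.normal(0.0, mean_sigma, n_features))
    folds = np.ones(n_features)
    for idx, f in fold_changes.items():
        folds[int(idx)] = float(f)
    na, nb = n_per_group
    a = np.column_stack([nb_counts(rng, means, bcv) for _ in range(na)])
    b = np.column_stack([nb_counts(rng, means * folds, bcv) for _ in range(nb)])
    features = [f"f{i:05d}" for i in range(n_features)]
    cols = [f"A_rep{i+1}" for i in range(na)] + [f"B_rep{i+1}" for i in range(nb)]
    values = pd.DataFrame(np.hstack([a, b]), index=features, columns=cols,
                          dtype=float)
    samples = pd.DataFrame({
        "sample_id": cols,
        "genotype": ["A"] * na + ["B"] * nb,
        "replicate": list(range(1, na + 1)) + list(range(1, nb + 1)),
    })
    truth = pd.DataFrame({"feature": features, "base_mean": means,
                          "true_log2_fc": np.log2(folds)}).set_index("feature")
    return values, samples, truth
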