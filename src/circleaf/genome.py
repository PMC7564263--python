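"""Reference genome, gene models and chromosome classes.

:class:`GenomeBundle` is the coordinate authority for the whole pipeline:
it holds chromosome sequences, one representative (longest) transcript per
gene, the nuclear/organelle class of each chromosome and the annotated rRNA
intervals.  All coordinates are 1-based and fully closed, matching the
``chrom:start-end`` circRNA identifiers used throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["GeneModel", "GenomeBundle", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NUCLEAR = "nuclear"
ORGANELLE = "organelle"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene with the exon chain of its representative transcript.

    ``exons`` are (start, end) pairs, 1-based closed, in *genomic* order.
    On the minus strand exon 1 of the transcript is therefore the last
    tuple of ``exons``; :meth:`exons_transcript_order` resolves that.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"illegal strand {self.strand!r} for {self.gene_id}")
        if any(a > b for a, b in self.exons):
            raise ValueError(f"inverted exon interval in {self.gene_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in 5'->3' transcript orientation (reversed on '-')."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def transcript_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def exonic_overlap(self, start: int, end: int) -> int:
        """Total bases of [start, end] covered by this gene's exons."""
        return sum(
            max(0, min(b, end) - max(a, start) + 1) for a, b in self.exons
        )

    def transcript_to_genomic_blocks(
        self, t_start: int, length: int
    ) -> list[tuple[int, int]]:
        """Map a transcript interval to genomic blocks.

        ``t_start`` is 0-based in transcript orientation; the result is a
        list of 1-based closed genomic intervals in genomic order, one per
        exon touched (the N-gapped blocks of a spliced alignment).
        """
        if t_start < 0 or t_start + length > self.transcript_length:
            raise ValueError(
                f"transcript interval [{t_start}, {t_start + length}) outside "
                f"{self.gene_id} (length {self.transcript_length})"
            )
        blocks: list[tuple[int, int]] = []
        offset = 0
        remaining = length
        pos = t_start
        for a, b in self.exons_transcript_order():
            exon_len = b - a + 1
            if pos >= offset + exon_len:
                offset += exon_len
                continue
            within = pos - offset  # 0-based offset into this exon (transcript sense)
            take = min(exon_len - within, remaining)
            if self.strand == "+":
                g0 = a + within
                blocks.append((g0, g0 + take - 1))
            else:
                g1 = b - within
                blocks.append((g1 - take + 1, g1))
            remaining -= take
            pos += take
            offset += exon_len
            if remaining == 0:
                break
        if self.strand == "-":
            blocks.reverse()
        return blocks


@dataclass
class GenomeBundle:
    """Sequences + gene models + chromosome classes + rRNA loci."""

    sequences: dict[str, str]
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_class: dict[str, str] = field(default_factory=dict)
    rrna_loci: list[tuple[str, int, int]] = field(default_factory=list)

    # -- queries ---------------------------------------------------------

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based closed slice of a chromosome."""
        if start < 1 or end > self.chrom_length(chrom):
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return self.sequences[chrom][start - 1 : end]

    def is_organelle(self, chrom: str) -> bool:
        if chrom not in self.chrom_class:
            raise KeyError(
                f"chromosome {chrom!r} has no chromosome_class annotation"
            )
        return self.chrom_class[chrom] == ORGANELLE

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    # -- serialization ---------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path, source: str = "circleaf") -> None:
        """Emit genes (one mRNA each), exons, rRNA loci and per-chromosome
        ``region`` features carrying a ``chromosome_class`` attribute."""
        lines = ["##gff-version 3"]
        for name, seq in self.sequences.items():
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
        for name, seq in self.sequences.items():
            cls = self.chrom_class.get(name, NUCLEAR)
            lines.append(
                "\t".join(
                    [name, source, "region", "1", str(len(seq)), ".", ".", ".",
                     f"ID=region-{name};chromosome_class={cls}"]
                )
            )
        for gene in self.genes.values():
            gid = gene.gene_id
            lines.append("\t".join(
                [gene.chrom, source, "gene", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", f"ID={gid}"]))
            lines.append("\t".join(
                [gene.chrom, source, "mRNA", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", f"ID={gid}.1;Parent={gid}"]))
            for i, (a, b) in enumerate(gene.exons, start=1):
                lines.append("\t".join(
                    [gene.chrom, source, "exon", str(a), str(b), ".",
                     gene.strand, ".", f"ID={gid}.1.exon{i};Parent={gid}.1"]))
        for i, (chrom, a, b) in enumerate(self.rrna_loci, start=1):
            lines.append("\t".join(
                [chrom, source, "rRNA", str(a), str(b), ".", "+", ".",
                 f"ID=rrna{i:02d}"]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "GenomeBundle":
        """Load a bundle from FASTA + GFF3.

        Genes may carry several mRNAs; the longest one becomes the
        representative transcript whose exon chain is stored.
        """
        import gffutils

        sequences = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta), "fasta")
        }
        db = gffutils.create_db(
            str(gff3), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        chrom_class: dict[str, str] = {}
        for region in db.features_of_type("region"):
            cls_attr = region.attributes.get("chromosome_class", [NUCLEAR])[0]
            chrom_class[region.seqid] = cls_attr
        for name in sequences:
            chrom_class.setdefault(name, NUCLEAR)

        genes: dict[str, GeneModel] = {}
        for gene in db.features_of_type("gene"):
            best_exons: list[tuple[int, int]] | None = None
            best_len = -1
            for mrna in db.children(gene, featuretype="mRNA"):
                exons = sorted(
                    (e.start, e.end) for e in db.children(mrna, featuretype="exon")
                )
                tlen = sum(b - a + 1 for a, b in exons)
                if tlen > best_len:
                    best_len, best_exons = tlen, exons
            if not best_exons:  # gene without mRNA children: exons directly
                best_exons = sorted(
                    (e.start, e.end) for e in db.children(gene, featuretype="exon")
                )
            if not best_exons:
                continue
            genes[gene.id] = GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                start=gene.start, end=gene.end, exons=tuple(best_exons),
            )
        rrna = [(f.seqid, f.start, f.end) for f in db.features_of_type("rRNA")]
        return cls(sequences=sequences, genes=genes,
                   chrom_class=chrom_class, rrna_loci=rrna)
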