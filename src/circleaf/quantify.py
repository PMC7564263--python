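"""Library accounting and abundance matrices.

Back-spliced read counts are normalized to an *effective* library size:
total mapped reads minus reads mapped to the organelle chromosome and to
annotated rRNA loci.  Normalized values are counts per million effective
reads; every statistic downstream is scale-free, so the per-million factor
is presentational only.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .detect import (BackspliceJunction, CircCall, ParsedAlignments,
                     SplitReadGroup, call_backsplice_reads)
from .genome import GenomeBundle, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SampleLibrary",
    "CountMatrix",
    "count_library_components",
    "build_circ_matrix",
    "quantify_linear",
    "coverage_profile",
    "CoverageProfile",
]

SCALE = 1e6


@dataclass
class SampleLibrary:
    """Per-sample read accounting for effective-library-size normalization."""

    sample_id: str
    total_mapped: int
    organelle_mapped: int
    rrna_mapped: int
    genotype: str = ""
    replicate: int = 0

    def __post_init__(self):
        if self.organelle_mapped + self.rrna_mapped > self.total_mapped:
            raise ValueError(
                f"{self.sample_id}: organelle + rRNA reads exceed total mapped")
        if self.effective_size <= 0:
            raise ValueError(f"{self.sample_id}: effective library size is 0")

    @property
    def effective_size(self) -> int:
        return self.total_mapped - self.organelle_mapped - self.rrna_mapped


def _segment_overlaps_rrna(seg, rrna_by_chrom, min_frac: float) -> bool:
    loci = rrna_by_chrom.get(seg.chrom)
    if not loci:
        return False
    span = seg.ref_end - seg.ref_start + 1
    for a, b in loci:
        ov = min(b, seg.ref_end) - max(a, seg.ref_start) + 1
        if ov >= min_frac * span:
            return True
    return False


def count_library_components(groups: ParsedAlignments | Iterable[SplitReadGroup],
                             genome: GenomeBundle,
                             rrna_overlap_frac: float = 0.5,
                             sample_id: str = "", genotype: str = "",
                             replicate: int = 0) -> SampleLibrary:
    """Classify mapped read ends into organelle / rRNA / remaining.

    A read is organelle-mapped if its primary segment lies on an
    organelle-class chromosome, else rRNA-mapped if any segment overlaps
    an annotated rRNA locus by at least ``rrna_overlap_frac`` of the
    segment (categories are disjoint, organelle takes precedence).
    Requires chromosome classes on the annotation; raises otherwise.
    """
    if not genome.chrom_class:
        raise ValueError(
            "annotation lacks the chromosome_class attribute required for "
            "organelle accounting")
    rrna_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, a, b in genome.rrna_loci:
        rrna_by_chrom[chrom].append((a, b))

    total = organelle = rrna = 0
    for group in groups:
        primary = group.primary_segment()
        if primary is None:
            continue
        total += 1
        if genome.is_organelle(primary.chrom):
            organelle += 1
        elif any(_segment_overlaps_rrna(s, rrna_by_chrom, rrna_overlap_frac)
                 for s in group.segments):
            rrna += 1
    return SampleLibrary(sample_id=sample_id, total_mapped=total,
                         organelle_mapped=organelle, rrna_mapped=rrna,
                         genotype=genotype, replicate=replicate)


@dataclass
class CountMatrix:
    """Features x samples abundance matrix, raw and normalized.

    ``normalized[f, s] = raw[f, s] / effective_size(s) * 1e6``; absent
    feature/sample combinations are explicit zeros.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    kind: str  # 'circular' | 'linear_boundary' | 'linear_gene'

    @classmethod
    def build(cls, counts: Mapping[str, Mapping[str, int]],
              libraries: Mapping[str, SampleLibrary], kind: str) -> "CountMatrix":
        """Assemble from per-sample count dicts ``{sample: {feature: n}}``."""
        for sid in counts:
            if sid not in libraries:
                raise KeyError(
                    f"sample {sid!r} has calls but no library accounting")
        features = sorted({f for d in counts.values() for f in d})
        samples = list(counts)
        raw = pd.DataFrame(0, index=features, columns=samples, dtype=float)
        for sid, d in counts.items():
            for f, n in d.items():
                raw.loc[f, sid] = n
        eff = pd.Series({s: libraries[s].effective_size for s in samples})
        normalized = raw / eff * SCALE
        return cls(raw=raw, normalized=normalized, kind=kind)

    def write(self, path: str | Path) -> None:
        """TSV with raw and normalized values side by side."""
        raw = self.raw.add_suffix(".raw")
        norm = self.normalized.add_suffix(".cpm")
        pd.concat([raw, norm], axis=1).rename_axis("feature").to_csv(
            path, sep="\t")


def build_circ_matrix(calls_by_sample: Mapping[str, Sequence[CircCall]],
                      libraries: Mapping[str, SampleLibrary]) -> CountMatrix:
    """circRNA junction-read counts across samples, CPM-normalized."""
    counts = {
        sid: {c.id: c.n_junction_reads for c in calls}
        for sid, calls in calls_by_sample.items()
    }
    return CountMatrix.build(counts, libraries, kind="circular")


# ---------------------------------------------------------------------------
# linear counterparts


def _chiastic_templates(groups: Iterable[SplitReadGroup],
                        slack: int = 5) -> dict[str, set[str]]:
    """junction id -> set of template ids with back-splice evidence."""
    out: dict[str, set[str]] = defaultdict(set)
    for g in groups:
        j = call_backsplice_reads(g, slack=slack)
        if j is not None:
            out[j.id].add(g.template_id)
    return out


def quantify_linear(groups: ParsedAlignments | Iterable[SplitReadGroup],
                    junctions: Sequence[BackspliceJunction],
                    genome: GenomeBundle,
                    slack: int = 5) -> tuple[dict[str, int], dict[str, int]]:
    """Count the linear counterparts of called circRNAs in one sample.

    Returns ``(boundary_counts, gene_counts)``:

    * boundary: templates with a contiguous or forward-spliced aligned
      block crossing the circRNA's start or end coordinate (extending
      outside the circle); back-spliced templates of that same junction
      are excluded.
    * gene: templates with any non-chiastic segment overlapping a gene's
      exon union (one count per template per gene).
    """
    group_list = list(groups)
    chiastic = _chiastic_templates(group_list, slack=slack)
    chiastic_ends = {g.read_id for g in group_list
                     if call_backsplice_reads(g, slack=slack) is not None}

    boundary_templates: dict[str, set[str]] = {j.id: set() for j in junctions}
    exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genome.genes.values():
        for a, b in gene.exons:
            exon_trees[gene.chrom].addi(a, b + 1, gene.gene_id)
    gene_templates: dict[str, set[str]] = defaultdict(set)

    for g in group_list:
        if g.read_id in chiastic_ends:
            continue  # back-spliced evidence is never linear evidence
        for seg in g.segments:
            blocks = seg.blocks or ((seg.ref_start, seg.ref_end),)
            for j in junctions:
                if j.chrom != seg.chrom:
                    continue
                # a segment crosses a boundary when its aligned blocks
                # (contiguous or forward-spliced) reach both inside the
                # circle and outside it past that boundary
                inside = any(a <= j.end and b >= j.start for a, b in blocks)
                below = any(a < j.start for a, b in blocks)
                above = any(b > j.end for a, b in blocks)
                if inside and (below or above) \
                        and g.template_id not in chiastic.get(j.id, ()):
                    boundary_templates[j.id].add(g.template_id)
            for block_a, block_b in blocks:
                for iv in exon_trees.get(seg.chrom, IntervalTree()).overlap(
                        block_a, block_b + 1):
                    gene_templates[iv.data].add(g.template_id)

    boundary_counts = {jid: len(t) for jid, t in boundary_templates.items()}
    gene_counts = {gid: len(t) for gid, t in gene_templates.items()}
    return boundary_counts, gene_counts


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageProfile:
    """Per-base read depth over a gene span with the circRNA interval."""

    chrom: str
    start: int  # gene span, 1-based closed
    end: int
    depth: np.ndarray
    circ_start: int
    circ_end: int
    gene_id: str = ""

    def mean_depth(self, start: int | None = None,
                   end: int | None = None) -> float:
        start = self.start if start is None else start
        end = self.end if end is None else end
        a = max(start, self.start) - self.start
        b = min(end, self.end) - self.start + 1
        return float(self.depth[a:b].mean()) if b > a else float("nan")

    def to_bedgraph(self, path: str | Path) -> None:
        lines = [f"track type=bedGraph name={self.gene_id or self.chrom}"]
        d = self.depth
        i = 0
        while i < len(d):
            j = i
            while j < len(d) and d[j] == d[i]:
                j += 1
            # BEDGRAPH is 0-based half-open
            lines.append(f"{self.chrom}\t{self.start - 1 + i}\t"
                         f"{self.start - 1 + j}\t{int(d[i])}")
            i = j
        Path(path).write_text("\n".join(lines) + "\n")


def coverage_profile(groups: ParsedAlignments | Iterable[SplitReadGroup],
                     gene: GeneModel,
                     junction: BackspliceJunction) -> CoverageProfile:
    """Read depth across a gene, linear and circular reads included."""
    if gene.chrom != junction.chrom:
        raise ValueError("gene and junction must share a chromosome")
    depth = np.zeros(gene.end - gene.start + 1, dtype=np.int64)
    for g in groups:
        for seg in g.segments:
            if seg.chrom != gene.chrom:
                continue
            for a, b in (seg.blocks or ((seg.ref_start, seg.ref_end),)):
                lo = max(a, gene.start) - gene.start
                hi = min(b, gene.end) - gene.start + 1
                if hi > lo:
                    depth[lo:hi] += 1
    return CoverageProfile(chrom=gene.chrom, start=gene.start, end=gene.end,
                           depth=depth, circ_start=junction.start,
                           circ_end=junction.end, gene_id=gene.gene_id)
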