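"""Placement of back-splice junctions on gene models.

Exon indices are counted 5'->3' in the host gene's transcript orientation
(exon 1 of a minus-strand gene is its rightmost genomic exon).  The
junction *start* is the circle's transcript-5' boundary — the genomic
start on plus-strand genes, the genomic end on minus-strand genes — and
matches an annotated acceptor boundary when back-splicing used the exon's
own splice site; the *end* side matches a donor boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import BackspliceJunction
from .genome import GeneModel, GenomeBundle

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionStructure",
    "StructuralInconsistencyError",
    "assign_host_gene",
    "start_exon_index",
    "end_exon_index",
    "boundary_class",
    "annotate_junction",
    "exon_start_distribution",
    "structures_to_frame",
]

EXON_BOUNDARY = "exon_boundary"
EXON_INTERNAL = "exon_internal"
INTRON = "intron"
INTERGENIC = "intergenic"


class StructuralInconsistencyError(ValueError):
    """A junction endpoint falls outside its assigned host gene."""


@dataclass
class JunctionStructure:
    """Structural annotation of one circRNA on its host gene."""

    circ_id: str
    host_gene: str | None
    start_exon_index: int | None  # transcript orientation, 1-based
    end_exon_index: int | None
    start_intronic: bool
    end_intronic: bool
    start_class: str
    end_class: str
    strand_mismatch: bool = False

    @property
    def first_exon_flag(self) -> bool:
        return self.start_exon_index == 1


def assign_host_gene(junction: BackspliceJunction, genome: GenomeBundle
                     ) -> tuple[str | None, bool]:
    """Host gene of a junction, with a strand-mismatch flag.

    Candidates are genes whose span contains [start, end] on the
    junction's strand; among several, the one with maximal exonic overlap
    wins, ties going to the smaller gene span.  With no same-strand
    candidate the search is repeated strand-agnostically (flagged);
    with none at all the junction is intergenic (``None``).
    """
    def candidates(strand_specific: bool) -> list[GeneModel]:
        return [
            g for g in genome.genes.values()
            if g.chrom == junction.chrom
            and g.start <= junction.start and junction.end <= g.end
            and (not strand_specific or g.strand == junction.strand)
        ]

    for strict in (True, False):
        cands = candidates(strict)
        if cands:
            best = max(
                cands,
                key=lambda g: (g.exonic_overlap(junction.start, junction.end),
                               -(g.end - g.start)))
            return best.gene_id, not strict
    return None, False


def _exon_index_of(coord: int, gene: GeneModel) -> tuple[int, bool]:
    """(1-based transcript exon index, intronic flag) for a coordinate.

    Intronic coordinates are assigned to the next exon downstream in
    transcript orientation, flagged intronic.
    """
    if not gene.contains(coord):
        raise StructuralInconsistencyError(
            f"coordinate {coord} outside gene {gene.gene_id} span "
            f"[{gene.start}, {gene.end}]")
    exons_t = gene.exons_transcript_order()
    for i, (a, b) in enumerate(exons_t, start=1):
        if a <= coord <= b:
            return i, False
    # intronic: next exon 5'->3'
    for i, (a, b) in enumerate(exons_t, start=1):
        if (gene.strand == "+" and coord < a) or \
           (gene.strand == "-" and coord > b):
            return i, True
    raise StructuralInconsistencyError(
        f"coordinate {coord} not locatable within gene {gene.gene_id}")


def start_exon_index(junction: BackspliceJunction,
                     gene: GeneModel) -> tuple[int, bool]:
    """Exon index containing the circle's transcript-5' endpoint."""
    coord = junction.start if gene.strand == "+" else junction.end
    return _exon_index_of(coord, gene)


def end_exon_index(junction: BackspliceJunction,
                   gene: GeneModel) -> tuple[int, bool]:
    """Exon index containing the circle's transcript-3' endpoint."""
    coord = junction.end if gene.strand == "+" else junction.start
    return _exon_index_of(coord, gene)


def boundary_class(coordinate: int, side: str, gene: GeneModel,
                   tolerance: int = 0) -> str:
    """Classify a junction endpoint against the gene model.

    ``side='start'`` tests the acceptor boundary (an exon's transcript-5'
    edge), ``side='end'`` the donor boundary; matching within
    ``tolerance`` bases (default exact) gives ``exon_boundary``, else
    ``exon_internal`` inside any exon, ``intron`` inside the gene span,
    ``intergenic`` outside.
    """
    if side not in ("start", "end"):
        raise ValueError(f"side must be 'start' or 'end', got {side!r}")
    if not gene.contains(coordinate):
        return INTERGENIC
    acceptor_side = side == "start"
    five_prime_edge = acceptor_side == (gene.strand == "+")
    edges = [a if five_prime_edge else b for a, b in gene.exons]
    if any(abs(coordinate - edge) <= tolerance for edge in edges):
        return EXON_BOUNDARY
    if any(a <= coordinate <= b for a, b in gene.exons):
        return EXON_INTERNAL
    return INTRON


def annotate_junction(junction: BackspliceJunction, genome: GenomeBundle,
                      tolerance: int = 0) -> JunctionStructure:
    """Full structural annotation of one junction."""
    gene_id, mismatch = assign_host_gene(junction, genome)
    if gene_id is None:
        return JunctionStructure(
            circ_id=junction.id, host_gene=None,
            start_exon_index=None, end_exon_index=None,
            start_intronic=False, end_intronic=False,
            start_class=INTERGENIC, end_class=INTERGENIC)
    gene = genome.genes[gene_id]
    s_idx, s_intr = start_exon_index(junction, gene)
    e_idx, e_intr = end_exon_index(junction, gene)
    t5 = junction.start if gene.strand == "+" else junction.end
    t3 = junction.end if gene.strand == "+" else junction.start
    return JunctionStructure(
        circ_id=junction.id, host_gene=gene_id,
        start_exon_index=s_idx, end_exon_index=e_idx,
        start_intronic=s_intr, end_intronic=e_intr,
        start_class=boundary_class(t5, "start", gene, tolerance),
        end_class=boundary_class(t3, "end", gene, tolerance),
        strand_mismatch=mismatch)


def exon_start_distribution(structures: Sequence[JunctionStructure]
                            ) -> dict:
    """Start-exon histogram plus first-exon and exon-boundary fractions.

    Because "started or ended in a known exon" admits two readings, both
    fractions are reported: ``frac_boundary_exact`` (an endpoint at an
    annotated splice boundary) and ``frac_in_exon_body`` (an endpoint
    anywhere within an exon, boundary included).
    """
    nan = float("nan")
    structs = [s for s in structures if s.host_gene is not None]
    if not structs:
        logger.info("empty structure set: empty distribution")
        return {"n": 0, "histogram": {}, "frac_first_exon": nan,
                "frac_boundary_exact": nan, "frac_in_exon_body": nan}
    hist: dict[int, float] = {}
    for s in structs:
        hist[s.start_exon_index] = hist.get(s.start_exon_index, 0) + 1
    n = len(structs)
    hist = {k: v / n for k, v in sorted(hist.items())}
    first = sum(s.first_exon_flag for s in structs) / n
    exact = sum(
        s.start_class == EXON_BOUNDARY or s.end_class == EXON_BOUNDARY
        for s in structs) / n
    body = sum(
        s.start_class in (EXON_BOUNDARY, EXON_INTERNAL)
        or s.end_class in (EXON_BOUNDARY, EXON_INTERNAL)
        for s in structs) / n
    return {"n": n, "histogram": hist, "frac_first_exon": first,
            "frac_boundary_exact": exact, "frac_in_exon_body": body}


def structures_to_frame(structures: Iterable[JunctionStructure]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "circ_id": s.circ_id, "host_gene": s.host_gene,
            "start_exon_index": s.start_exon_index,
            "end_exon_index": s.end_exon_index,
            "start_intronic": s.start_intronic,
            "end_intronic": s.end_intronic,
            "start_class": s.start_class, "end_class": s.end_class,
            "first_exon": s.first_exon_flag,
            "strand_mismatch": s.strand_mismatch,
        }
        for s in structures
    ])
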