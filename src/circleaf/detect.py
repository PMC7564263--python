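"""Back-splice junction calling from split-read alignments.

Two independent detectors are provided:

* :func:`call_circRNAs` — the primary caller.  It groups SAM records by
  read end, tests each multi-segment group for chiastic geometry (the
  segment earlier in read orientation maps downstream of the segment
  later in the read), verifies the canonical GT–AG back-splice signal on
  the genome and aggregates supporting templates per junction.
* :func:`call_circRNAs_anchor` — an anchor-based caller working from raw
  reads (FASTQ): terminal k-mers of each read are placed exactly on the
  genome, extended inward, and a junction is reported when the anchors
  land in reversed genomic order with matching GT/AG breakpoint flanks.

A junction's identifier is ``chrom:start-end`` with 1-based, fully closed
coordinates: start and end are the first and last base inside the circle.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .genome import GenomeBundle, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SplitReadGroup",
    "ParsedAlignments",
    "BackspliceJunction",
    "CircCall",
    "parse_alignments",
    "call_backsplice_reads",
    "check_splice_signal",
    "call_circRNAs",
    "KmerIndex",
    "call_circRNAs_anchor",
    "concordance",
    "ConcordanceResult",
    "calls_to_frame",
]

CIGAR_QUERY_OPS = {0, 1, 7, 8}  # M, I, =, X consume query
CIGAR_CLIP_OPS = {4, 5}  # S, H


@dataclass(frozen=True)
class Segment:
    """One aligned segment of a read, in original read orientation.

    ``q_start``/``q_end`` are 0-based half-open offsets in the read as it
    was sequenced (reverse-strand alignments are flipped back).
    ``blocks`` are the gapless M-intervals (1-based closed) of a spliced
    alignment.
    """

    chrom: str
    strand: str
    ref_start: int  # 1-based closed
    ref_end: int
    q_start: int
    q_end: int
    read_len: int
    is_supplementary: bool
    blocks: tuple[tuple[int, int], ...] = ()

    @property
    def aligned_len(self) -> int:
        return self.q_end - self.q_start


@dataclass
class SplitReadGroup:
    """All segments of one read end (mates are separate groups)."""

    read_id: str  # qname + '/1' | '/2' | '/0' (single-end)
    template_id: str  # qname
    segments: list[Segment] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def primary_segment(self) -> Segment | None:
        for seg in self.segments:
            if not seg.is_supplementary:
                return seg
        return self.segments[0] if self.segments else None


@dataclass
class ParsedAlignments:
    """Grouped alignment records plus parsing counters."""

    groups: list[SplitReadGroup]
    stats: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.groups)


@dataclass(frozen=True)
class BackspliceJunction:
    """A back-splice junction: first/last base inside the circle."""

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"junction start must precede end, got {self.start}>={self.end}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, circ_id: str, strand: str = "+") -> "BackspliceJunction":
        chrom, span = circ_id.rsplit(":", 1)
        s, e = span.split("-")
        return cls(chrom=chrom, strand=strand, start=int(s), end=int(e))


@dataclass
class CircCall:
    """A called circRNA with its supporting-read evidence."""

    junction: BackspliceJunction
    n_junction_reads: int
    canonical_signal: bool
    supporting_read_ids: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.junction.id


# ---------------------------------------------------------------------------
# parsing


def _segment_from_record(rec: pysam.AlignedSegment) -> Segment:
    cig = rec.cigartuples
    if not cig:
        raise ValueError("record without CIGAR")
    read_len = sum(l for op, l in cig if op in CIGAR_QUERY_OPS | CIGAR_CLIP_OPS)
    lead = 0
    for op, l in cig:
        if op in CIGAR_CLIP_OPS:
            lead += l
        else:
            break
    aligned = sum(l for op, l in cig if op in CIGAR_QUERY_OPS)
    qs, qe = lead, lead + aligned
    if rec.is_reverse:
        qs, qe = read_len - qe, read_len - qs
    blocks = tuple((a + 1, b) for a, b in rec.get_blocks())
    return Segment(
        chrom=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        ref_start=rec.reference_start + 1,
        ref_end=rec.reference_end,
        q_start=qs, q_end=qe, read_len=read_len,
        is_supplementary=rec.is_supplementary,
        blocks=blocks,
    )


def parse_alignments(sam: str | Path | Iterable[pysam.AlignedSegment],
                     header_required: bool = True) -> ParsedAlignments:
    """Group a SAM stream into per-read-end :class:`SplitReadGroup` s.

    Unmapped and secondary records are skipped (counted); mates are
    grouped separately.  Malformed records are skipped with a warning and
    counted under ``stats['malformed']``.  A missing header is a hard
    error when reading from a path.
    """
    stats: Counter = Counter()
    groups: dict[tuple[str, int], SplitReadGroup] = {}

    if isinstance(sam, (str, Path)):
        afile = pysam.AlignmentFile(str(sam), "r", check_sq=False)
        if header_required and not afile.header.to_dict().get("SQ"):
            raise ValueError(f"{sam}: SAM header with @SQ lines is required")
        iterator = afile
    else:
        iterator = sam

    for rec in iterator:
        stats["records"] += 1
        try:
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_duplicate:
                stats["secondary_or_duplicate"] += 1
                continue
            mate = 1 if rec.is_read1 else (2 if rec.is_read2 else 0)
            key = (rec.query_name, mate)
            seg = _segment_from_record(rec)
        except Exception as exc:  # malformed record
            stats["malformed"] += 1
            logger.warning("skipping malformed record: %s", exc)
            continue
        if key not in groups:
            groups[key] = SplitReadGroup(
                read_id=f"{rec.query_name}/{mate}",
                template_id=rec.query_name)
        groups[key].segments.append(seg)

    stats["groups"] = len(groups)
    return ParsedAlignments(groups=list(groups.values()), stats=stats)


# ---------------------------------------------------------------------------
# chiastic geometry


def _chiastic_pair(a: Segment, b: Segment,
                   slack: int = 5) -> BackspliceJunction | None:
    """Test an ordered segment pair (a earlier in the read) for back-splice
    geometry; return the junction or None."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    # read intervals must abut within the slack (no large overlap or gap)
    if abs(b.q_start - a.q_end) > slack:
        return None
    if a.strand == "+":
        # prefix ends at the circle end, suffix starts at the circle start
        s, e = b.ref_start, a.ref_end
        chiastic = b.ref_start < a.ref_start
    else:
        s, e = a.ref_start, b.ref_end
        chiastic = b.ref_start > a.ref_start
    if not chiastic or s >= e:
        return None
    return BackspliceJunction(chrom=a.chrom, strand=a.strand, start=s, end=e)


def call_backsplice_reads(group: SplitReadGroup, slack: int = 5,
                          stats: Counter | None = None
                          ) -> BackspliceJunction | None:
    """Return the back-splice junction evidenced by one read end, if any.

    Groups with more than two usable segments are resolved by taking the
    pair with the largest total aligned read length; ties are rejected as
    ambiguous.
    """
    segs = group.segments
    if len(segs) < 2:
        return None
    if len(segs) == 2:
        pair = segs
    else:
        scored = sorted(
            ((x.aligned_len + y.aligned_len, i, j)
             for i, x in enumerate(segs) for j, y in enumerate(segs) if i < j),
            reverse=True)
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            if stats is not None:
                stats["ambiguous_multisplit"] += 1
            return None
        _, i, j = scored[0]
        pair = [segs[i], segs[j]]
    a, b = sorted(pair, key=lambda s: s.q_start)
    return _chiastic_pair(a, b, slack=slack)


def check_splice_signal(junction: BackspliceJunction,
                        genome: GenomeBundle) -> bool:
    """True iff the back-splice site carries the canonical GT–AG signal.

    In host-strand orientation the two bases downstream of the circle end
    must be the donor GT and the two bases upstream of the start the
    acceptor AG.  On the minus strand this corresponds to plus-strand
    AC before the start and CT after the end.  Junctions within two bases
    of a chromosome edge are rejected.
    """
    chrom_len = genome.chrom_length(junction.chrom)
    if junction.start - 2 < 1 or junction.end + 2 > chrom_len:
        logger.info("junction %s within 2 bases of chromosome edge",
                    junction.id)
        return False
    up = genome.fetch(junction.chrom, junction.start - 2, junction.start - 1)
    down = genome.fetch(junction.chrom, junction.end + 1, junction.end + 2)
    if junction.strand == "+":
        return up == "AG" and down == "GT"
    return up == "AC" and down == "CT"


def call_circRNAs(groups: ParsedAlignments | Iterable[SplitReadGroup],
                  genome: GenomeBundle, min_reads: int = 2,
                  require_signal: bool = True, slack: int = 5,
                  exclude_organelle: bool = True,
                  stats: Counter | None = None) -> list[CircCall]:
    """Aggregate chiastic read evidence into circRNA calls for one sample.

    Junctions are keyed by exact (chrom, start, end, strand); a template
    whose two mates both evidence the same junction counts once.  Calls
    with fewer than ``min_reads`` supporting templates, or (with
    ``require_signal``) without the canonical splice signal, are dropped.
    Output is sorted by chromosome and start.
    """
    stats = stats if stats is not None else Counter()
    support: dict[BackspliceJunction, set[str]] = defaultdict(set)
    for group in groups:
        junction = call_backsplice_reads(group, slack=slack, stats=stats)
        if junction is None:
            continue
        if exclude_organelle and genome.is_organelle(junction.chrom):
            stats["organelle_chiastic"] += 1
            continue
        support[junction].add(group.template_id)

    calls: list[CircCall] = []
    for junction, templates in support.items():
        if len(templates) < min_reads:
            stats["below_min_reads"] += 1
            continue
        signal = check_splice_signal(junction, genome)
        if require_signal and not signal:
            stats["no_canonical_signal"] += 1
            continue
        calls.append(CircCall(
            junction=junction, n_junction_reads=len(templates),
            canonical_signal=signal,
            supporting_read_ids=sorted(templates)))
    calls.sort(key=lambda c: (c.junction.chrom, c.junction.start,
                              c.junction.end))
    return calls


# ---------------------------------------------------------------------------
# anchor-based detector


class KmerIndex:
    """Exact-match k-mer index of a genome (plus strand).

    Built once per genome with numpy 2-bit encoding; lookups return the
    unique placement of a k-mer, ``None`` when absent, or the string
    ``'ambiguous'`` when the k-mer occurs more than once.
    """

    AMBIGUOUS = "ambiguous"

    def __init__(self, genome: GenomeBundle, k: int = 20):
        if k > 31:
            raise ValueError("k must be <= 31 for 2-bit packing")
        self.k = k
        self.chroms = list(genome.sequences)
        codes_tab = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            codes_tab[b] = i
        self._codes_tab = codes_tab
        vals_all, chrom_idx_all, pos_all = [], [], []
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        self._powers = powers
        for ci, name in enumerate(self.chroms):
            seq = genome.sequences[name].upper().encode()
            codes = codes_tab[np.frombuffer(seq, dtype=np.uint8)]
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            vals = win.astype(np.int64) @ powers
            vals[np.any(win == 255, axis=1)] = -1  # non-ACGT
            vals_all.append(vals)
            chrom_idx_all.append(np.full(len(vals), ci, dtype=np.int32))
            pos_all.append(np.arange(1, len(vals) + 1, dtype=np.int64))
        vals = np.concatenate(vals_all)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._chrom_idx = np.concatenate(chrom_idx_all)[order]
        self._pos = np.concatenate(pos_all)[order]

    def lookup(self, kmer: str):
        """Unique 1-based placement (chrom, pos) of a k-mer, or sentinel."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        codes = self._codes_tab[np.frombuffer(kmer.upper().encode(),
                                              dtype=np.uint8)]
        if np.any(codes == 255):
            return None
        val = int(codes.astype(np.int64) @ self._powers)
        lo = int(np.searchsorted(self._vals, val, side="left"))
        hi = int(np.searchsorted(self._vals, val, side="right"))
        if hi == lo:
            return None
        if hi - lo > 1:
            return self.AMBIGUOUS
        return self.chroms[self._chrom_idx[lo]], int(self._pos[lo])


def _anchor_scan(seq: str, genome: GenomeBundle, index: KmerIndex,
                 strand: str) -> BackspliceJunction | str | None:
    """Scan one read orientation for a chiastic anchor placement.

    ``seq`` must already be in plus-genome orientation; ``strand`` is the
    junction strand this orientation corresponds to.  Returns a junction,
    ``'ambiguous'``, or None.
    """
    k = index.k
    L = len(seq)
    left = index.lookup(seq[:k])
    right = index.lookup(seq[L - k:])
    if left == KmerIndex.AMBIGUOUS or right == KmerIndex.AMBIGUOUS:
        return "ambiguous"
    if left is None or right is None:
        return None
    (c1, p1), (c2, p2) = left, right
    if c1 != c2 or p1 <= p2:
        return None  # linear or trans placement
    chrom_seq = genome.sequences[c1]
    # extend the left anchor rightwards: imax = longest matching prefix
    imax = k
    while imax < L and p1 - 1 + imax < len(chrom_seq) \
            and seq[imax] == chrom_seq[p1 - 1 + imax]:
        imax += 1
    # extend the right anchor leftwards: jmin = earliest matching suffix start
    jmin = L - k
    while jmin > 0 and p2 - (L - k) + jmin - 2 >= 0 \
            and seq[jmin - 1] == chrom_seq[p2 - (L - k) + jmin - 2]:
        jmin -= 1
    if jmin > imax:
        return None  # extensions do not meet
    hits: set[tuple[int, int]] = set()
    for b in range(max(jmin, 1), min(imax, L - 1) + 1):
        e = p1 + b - 1
        s = p2 - (L - k) + b
        if s >= e or s - 2 < 1 or e + 2 > len(chrom_seq):
            continue
        junction = BackspliceJunction(chrom=c1, strand=strand, start=s, end=e)
        if check_splice_signal(junction, genome):
            hits.add((s, e))
    if len(hits) == 1:
        s, e = hits.pop()
        return BackspliceJunction(chrom=c1, strand=strand, start=s, end=e)
    if len(hits) > 1:
        return "ambiguous"
    return None


def call_circRNAs_anchor(fastq: str | Path, genome: GenomeBundle,
                         anchor_len: int = 20, min_reads: int = 2,
                         stats: Counter | None = None,
                         index: "KmerIndex | None" = None) -> list[CircCall]:
    """Anchor-based circRNA calling straight from reads.

    Takes ``anchor_len``-mers from both ends of every read, places them
    exactly on the genome, and reports a junction when the left anchor
    lands downstream of the right one (chiastic) with canonical GT/AG
    flanks at the breakpoint.  Reads whose anchors have multiple exact
    placements, or with several signal-consistent breakpoints, are dropped
    as ambiguous.  Aggregation mirrors :func:`call_circRNAs` (template-
    level support, ``min_reads`` threshold).
    """
    stats = stats if stats is not None else Counter()
    with pysam.FastxFile(str(fastq)) as peek:
        first = next(iter(peek), None)
    if first is not None and anchor_len > len(first.sequence) // 2:
        raise ValueError(
            f"anchor_len {anchor_len} exceeds half the read length "
            f"{len(first.sequence)}")
    if index is None:
        index = KmerIndex(genome, k=anchor_len)
    elif index.k != anchor_len:
        raise ValueError(
            f"prebuilt index has k={index.k}, anchor_len is {anchor_len}")
    support: dict[BackspliceJunction, set[str]] = defaultdict(set)
    with pysam.FastxFile(str(fastq)) as fh:
        for entry in fh:
            seq = entry.sequence.upper()
            stats["reads"] += 1
            template = entry.name.split("/")[0]
            result = _anchor_scan(seq, genome, index, "+")
            if result is None:
                result = _anchor_scan(revcomp(seq), genome, index, "-")
            if result == "ambiguous":
                stats["ambiguous_anchor"] += 1
                continue
            if result is None:
                continue
            junction = result
            if genome.is_organelle(junction.chrom):
                stats["organelle_chiastic"] += 1
                continue
            support[junction].add(template)

    calls = [
        CircCall(junction=j, n_junction_reads=len(t), canonical_signal=True,
                 supporting_read_ids=sorted(t))
        for j, t in support.items() if len(t) >= min_reads
    ]
    calls.sort(key=lambda c: (c.junction.chrom, c.junction.start,
                              c.junction.end))
    return calls


# ---------------------------------------------------------------------------
# concordance and tabulation


@dataclass
class ConcordanceResult:
    frac_a_in_b: float
    frac_b_in_a: float
    jaccard: float
    n_a: int
    n_b: int
    n_common: int
    message: str = ""


def concordance(calls_a: Sequence[CircCall],
                calls_b: Sequence[CircCall]) -> ConcordanceResult:
    """Fraction of A's junctions found by B, the reciprocal, and Jaccard."""
    ids_a = {c.id for c in calls_a}
    ids_b = {c.id for c in calls_b}
    common = ids_a & ids_b
    union = ids_a | ids_b
    if not ids_a:
        return ConcordanceResult(
            frac_a_in_b=math.nan,
            frac_b_in_a=(len(common) / len(ids_b)) if ids_b else math.nan,
            jaccard=(len(common) / len(union)) if union else math.nan,
            n_a=0, n_b=len(ids_b), n_common=0,
            message="empty reference call set: fraction undefined")
    return ConcordanceResult(
        frac_a_in_b=len(common) / len(ids_a),
        frac_b_in_a=(len(common) / len(ids_b)) if ids_b else math.nan,
        jaccard=len(common) / len(union),
        n_a=len(ids_a), n_b=len(ids_b), n_common=len(common))


def calls_to_frame(calls: Sequence[CircCall]):
    """Tabulate calls: id, chrom, start, end, strand, reads, signal."""
    import pandas as pd

    return pd.DataFrame([
        {
            "id": c.id, "chrom": c.junction.chrom, "start": c.junction.start,
            "end": c.junction.end, "strand": c.junction.strand,
            "n_junction_reads": c.n_junction_reads,
            "canonical_signal": c.canonical_signal,
        }
        for c in calls
    ])
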