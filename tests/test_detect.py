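"""Chiastic-geometry calling, splice-signal checks and the anchor detector."""

import math

import pytest

from circleaf.detect import (BackspliceJunction, KmerIndex, Segment,
                             SplitReadGroup, call_backsplice_reads,
                             call_circRNAs, call_circRNAs_anchor,
                             check_splice_signal, concordance,
                             parse_alignments)
from circleaf.genome import GenomeBundle, revcomp


def seg(chrom="c", strand="+", ref=(1, 60), q=(0, 60), read_len=120,
        suppl=False):
    return Segment(chrom=chrom, strand=strand, ref_start=ref[0],
                   ref_end=ref[1], q_start=q[0], q_end=q[1],
                   read_len=read_len, is_supplementary=suppl)


def group(*segments):
    return SplitReadGroup(read_id="r/1", template_id="r",
                          segments=list(segments))


class TestChiasticGeometry:
    def test_prefix_downstream_of_suffix_yields_junction(self):
        """Read prefix at [981,1040], suffix at [201,260]: the only segment
        ordering that is back-spliced, giving junction 201-1040."""
        g = group(seg(ref=(981, 1040), q=(0, 60)),
                  seg(ref=(201, 260), q=(60, 120)))
        j = call_backsplice_reads(g)
        assert j is not None and (j.start, j.end) == (201, 1040)
        # every other orientation/ordering of the same intervals: no call
        forward = group(seg(ref=(201, 260), q=(0, 60)),
                        seg(ref=(981, 1040), q=(60, 120)))
        assert call_backsplice_reads(forward) is None

    def test_cross_chromosome_and_cross_strand_pairs_rejected(self):
        g = group(seg(chrom="c1", ref=(981, 1040), q=(0, 60)),
                  seg(chrom="c2", ref=(201, 260), q=(60, 120)))
        assert call_backsplice_reads(g) is None
        g = group(seg(strand="+", ref=(981, 1040), q=(0, 60)),
                  seg(strand="-", ref=(201, 260), q=(60, 120)))
        assert call_backsplice_reads(g) is None

    def test_minus_strand_mirror_geometry(self):
        # on '-', the read prefix carries the circle start (genomic low side)
        g = group(seg(strand="-", ref=(201, 260), q=(0, 60)),
                  seg(strand="-", ref=(981, 1040), q=(60, 120)))
        j = call_backsplice_reads(g)
        assert j is not None and (j.start, j.end) == (201, 1040)
        assert j.strand == "-"

    def test_read_interval_overlap_slack(self):
        g = group(seg(ref=(981, 1040), q=(0, 60)),
                  seg(ref=(201, 260), q=(50, 110), read_len=110))
        assert call_backsplice_reads(g, slack=5) is None
        assert call_backsplice_reads(g, slack=10) is not None

    def test_single_segment_never_a_candidate(self):
        assert call_backsplice_reads(group(seg())) is None

    def test_multisplit_takes_longest_pair_and_rejects_ties(self):
        big1 = seg(ref=(981, 1060), q=(0, 80))
        big2 = seg(ref=(201, 240), q=(80, 120))
        small = seg(ref=(501, 510), q=(75, 85))
        assert call_backsplice_reads(group(big1, big2, small)) is not None
        # two identical-length competing pairs: ambiguous
        twin = seg(ref=(301, 340), q=(80, 120))
        assert call_backsplice_reads(group(big1, big2, twin)) is None


class TestSpliceSignal:
    def make_genome(self, s=11, e=20, up="AG", down="GT", n=40):
        seq = list("ACAC" * (n // 4))
        seq[s - 3: s - 1] = up
        seq[e: e + 2] = down
        return GenomeBundle(sequences={"c": "".join(seq)},
                            chrom_class={"c": "nuclear"})

    def test_plus_strand_definition_and_mutation(self):
        j = BackspliceJunction("c", "+", 11, 20)
        assert check_splice_signal(j, self.make_genome()) is True
        assert check_splice_signal(
            j, self.make_genome(down="GA")) is False

    def test_minus_strand_matches_revcomp_oracle(self):
        """On '-', the signal test must equal applying the plus-strand rule
        to the reverse-complemented 30-nt sequence."""
        genome = self.make_genome(up="AC", down="CT")
        j = BackspliceJunction("c", "-", 11, 20)
        assert check_splice_signal(j, genome) is True
        # brute-force oracle: flip the sequence and coordinates, test as '+'
        seq = genome.sequences["c"]
        n = len(seq)
        flipped = GenomeBundle(sequences={"c": revcomp(seq)},
                               chrom_class={"c": "nuclear"})
        j_flipped = BackspliceJunction("c", "+", n - 20 + 1, n - 11 + 1)
        assert check_splice_signal(j_flipped, flipped) is True

    def test_chromosome_edge_is_false(self):
        genome = self.make_genome()
        assert check_splice_signal(
            BackspliceJunction("c", "+", 2, 20), genome) is False
        assert check_splice_signal(
            BackspliceJunction("c", "+", 11, 39), genome) is False


class TestCallThresholds:
    def make(self, n_reads, s=11, e=30):
        genome = TestSpliceSignal().make_genome(s=s, e=e)
        groups = []
        for i in range(n_reads):
            groups.append(SplitReadGroup(
                read_id=f"t{i}/1", template_id=f"t{i}",
                segments=[seg(ref=(e - 9, e), q=(0, 10), read_len=20),
                          seg(ref=(s, s + 9), q=(10, 20), read_len=20)]))
        return genome, groups

    def test_two_reads_called_one_read_not(self):
        genome, groups = self.make(2)
        assert len(call_circRNAs(groups, genome, min_reads=2)) == 1
        genome, groups = self.make(1)
        assert call_circRNAs(groups, genome, min_reads=2) == []

    def test_permissive_mode_reports_every_chiastic_junction(self):
        # genome carries the signal at (11, 30); probe junction (12, 30)
        genome, _ = self.make(0)
        groups = [SplitReadGroup(
            read_id="t0/1", template_id="t0",
            segments=[seg(ref=(21, 30), q=(0, 10), read_len=20),
                      seg(ref=(12, 21), q=(10, 20), read_len=20)])]
        assert call_circRNAs(groups, genome, min_reads=1) == []
        calls = call_circRNAs(groups, genome, min_reads=1,
                              require_signal=False)
        assert len(calls) == 1 and not calls[0].canonical_signal

    def test_both_mates_of_a_template_count_once(self):
        genome, groups = self.make(2)
        mate2 = SplitReadGroup(read_id="t0/2", template_id="t0",
                               segments=list(groups[0].segments))
        calls = call_circRNAs(groups + [mate2], genome, min_reads=2)
        assert calls[0].n_junction_reads == 2


def test_parse_groups_by_read_end(tmp_path, small_study):
    sid = small_study.samples.sample_id.iloc[0]
    parsed = small_study.parsed[sid]
    by_id = {}
    for g in parsed.groups:
        by_id.setdefault(g.template_id, []).append(g)
    bsj = [t for t in by_id if ":bsj:" in t]
    assert bsj, "study should contain junction templates"
    for t in bsj[:20]:
        mates = {g.read_id[-1] for g in by_id[t]}
        assert mates == {"1", "2"}  # mates grouped separately
        seg_counts = sorted(g.n_segments for g in by_id[t])
        assert seg_counts == [1, 2]  # junction mate split, other contiguous


def test_parse_missing_header_is_hard_error(tmp_path):
    sam = tmp_path / "h.sam"
    sam.write_text("r1\t0\tc\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
    with pytest.raises(ValueError, match="header"):
        parse_alignments(sam)


def test_malformed_record_skipped_and_counted(tmp_path):
    import pysam

    # a mapped record without CIGAR is demoted to unmapped and skipped
    sam = tmp_path / "m.sam"
    sam.write_text("@SQ\tSN:c\tLN:100\n"
                   "ok\t0\tc\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
                   "bad\t0\tc\t5\t60\t*\t*\t0\t0\tACGTACGTAC\t*\n")
    parsed = parse_alignments(sam)
    assert parsed.stats["unmapped"] == 1
    assert len(parsed.groups) == 1

    # a record the interpreter cannot make sense of hits the malformed path
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 100}]})
    ok = pysam.AlignedSegment(header)
    ok.query_name, ok.flag, ok.reference_name = "ok", 0, "c"
    ok.reference_start, ok.cigarstring = 0, "10M"
    ok.query_sequence = "ACGTACGTAC"

    class Broken:
        query_name = "bad"

        @property
        def is_unmapped(self):
            raise ValueError("unreadable record")

    parsed = parse_alignments([ok, Broken()])
    assert parsed.stats["malformed"] == 1
    assert len(parsed.groups) == 1


class TestDetectorInvariants:
    def test_monotonicity_in_min_reads_and_signal(self, small_study):
        genome = small_study.genome
        sid = small_study.samples.sample_id.iloc[1]
        parsed = small_study.parsed[sid]
        permissive = {c.id for c in call_circRNAs(
            parsed, genome, min_reads=1, require_signal=False)}
        default = {c.id for c in call_circRNAs(parsed, genome, min_reads=2)}
        stricter = {c.id for c in call_circRNAs(parsed, genome, min_reads=3)}
        assert stricter <= default <= permissive

    def test_no_chiastic_calls_on_purely_linear_library(self, tmp_path):
        from circleaf.simulate import SimConfig, simulate_study

        cfg = SimConfig(seed=6, n_nuclear_chroms=1, chrom_length=120_000,
                        n_genes=15, n_circ=0, private_circ={},
                        circ_fold_changes={}, circ_mean_scale={},
                        genotypes=("Col-0",), n_replicates=2, depth=4.0,
                        organelle_length=30_000, n_rrna_loci=1)
        genome, manifest, paths = simulate_study(cfg, tmp_path)
        for sid in manifest.samples.sample_id:
            parsed = parse_alignments(paths[sid]["sam"])
            calls = call_circRNAs(parsed, genome, min_reads=1,
                                  require_signal=False)
            assert calls == []

    def test_junction_id_round_trip(self, small_study):
        for calls in small_study.calls.values():
            for c in calls:
                back = BackspliceJunction.from_id(c.id, c.junction.strand)
                assert (back.start, back.end, back.chrom) == (
                    c.junction.start, c.junction.end, c.junction.chrom)


class TestAnchorDetector:
    def test_agrees_with_split_read_caller(self, small_study):
        genome = small_study.genome
        index = KmerIndex(genome, k=20)
        for sid in list(small_study.samples.sample_id)[:2]:
            anchor = call_circRNAs_anchor(small_study.paths[sid]["fastq"],
                                          genome, index=index)
            primary = small_study.calls[sid]
            assert {c.id for c in anchor} == {c.id for c in primary}

    def test_anchor_longer_than_half_read_rejected(self, small_study):
        sid = small_study.samples.sample_id.iloc[0]
        with pytest.raises(ValueError, match="anchor_len"):
            call_circRNAs_anchor(small_study.paths[sid]["fastq"],
                                 small_study.genome, anchor_len=60)

    def test_kmer_index_ambiguity_and_absence(self):
        genome = GenomeBundle(sequences={"c": "ACGTACGTAAATTTCCCGGG" * 2},
                              chrom_class={"c": "nuclear"})
        idx = KmerIndex(genome, k=20)
        assert idx.lookup("ACGTACGTAAATTTCCCGGG") == KmerIndex.AMBIGUOUS
        assert idx.lookup("A" * 20) is None
        unique = genome.sequences["c"][5:25]
        assert idx.lookup(unique) == ("c", 6)


class TestConcordance:
    def call(self, name):
        j = BackspliceJunction("c", "+", *{
            "x": (10, 100), "y": (20, 200), "z": (30, 300),
            "w": (40, 400), "v": (50, 500), "q": (60, 600)}[name])
        return type("C", (), {"id": j.id})()

    def test_four_of_five_shared_is_eighty_percent(self):
        a = [self.call(n) for n in "xyzwv"]
        b = [self.call(n) for n in "xyzwq"]
        res = concordance(a, b)
        assert res.frac_a_in_b == pytest.approx(0.8)
        assert res.frac_b_in_a == pytest.approx(0.8)
        assert res.jaccard == pytest.approx(4 / 6)

    def test_identical_and_disjoint_sets(self):
        a = [self.call(n) for n in "xyz"]
        assert concordance(a, a).frac_a_in_b == 1.0
        b = [self.call(n) for n in "wvq"]
        assert concordance(a, b).frac_a_in_b == 0.0

    def test_empty_reference_is_explicit_not_a_value(self):
        res = concordance([], [self.call("x")])
        assert math.isnan(res.frac_a_in_b) and res.message
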