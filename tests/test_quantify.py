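"""Effective-library accounting, CPM matrices, linear counters, coverage."""

import numpy as np
import pandas as pd
import pytest

from circleaf.detect import BackspliceJunction, Segment, SplitReadGroup
from circleaf.genome import GeneModel, GenomeBundle
from circleaf.quantify import (CountMatrix, SampleLibrary, build_circ_matrix,
                               count_library_components, coverage_profile,
                               quantify_linear)


class TestSampleLibrary:
    def test_effective_size_arithmetic(self):
        lib = SampleLibrary("s", total_mapped=2_000_000,
                            organelle_mapped=500_000, rrna_mapped=500_000)
        assert lib.effective_size == 1_000_000

    def test_zero_contamination(self):
        lib = SampleLibrary("s", total_mapped=1234, organelle_mapped=0,
                            rrna_mapped=0)
        assert lib.effective_size == lib.total_mapped

    def test_category_overflow_rejected(self):
        with pytest.raises(ValueError):
            SampleLibrary("s", total_mapped=10, organelle_mapped=8,
                          rrna_mapped=5)


def test_library_components_match_manifest_exactly(small_study):
    """Category counts from alignment parsing equal the generator's truth."""
    m = small_study.manifest
    for sid in small_study.samples.sample_id:
        lib = small_study.libraries[sid]
        org, rrna = m.contamination_reads[sid]
        assert lib.total_mapped == m.total_read_count(sid)
        assert lib.organelle_mapped == org
        assert lib.rrna_mapped == rrna


def test_missing_chromosome_class_is_hard_error(small_study):
    sid = small_study.samples.sample_id.iloc[0]
    genome = GenomeBundle(sequences=dict(small_study.genome.sequences),
                          chrom_class={}, rrna_loci=[])
    with pytest.raises((ValueError, KeyError)):
        count_library_components(small_study.parsed[sid], genome)


class TestCountMatrix:
    LIBS = {
        "s1": SampleLibrary("s1", 1_000_000, 0, 0),
        "s2": SampleLibrary("s2", 2_000_000, 0, 0),
    }

    def test_cpm_arithmetic_and_absent_is_zero(self):
        cm = CountMatrix.build({"s1": {"a": 10}, "s2": {"b": 4}},
                               self.LIBS, kind="circular")
        assert cm.normalized.loc["a", "s1"] == pytest.approx(10.0)
        assert cm.raw.loc["a", "s2"] == 0 and cm.normalized.loc["a", "s2"] == 0
        assert cm.normalized.loc["b", "s2"] == pytest.approx(2.0)

    def test_scale_invariance(self):
        cm = CountMatrix.build({"s1": {"a": 10, "b": 3}}, self.LIBS, "circular")
        doubled_libs = {"s1": SampleLibrary("s1", 2_000_000, 0, 0)}
        cm2 = CountMatrix.build({"s1": {"a": 20, "b": 6}}, doubled_libs,
                                "circular")
        pd.testing.assert_frame_equal(cm.normalized,
                                      cm2.normalized[["s1"]])

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            CountMatrix.build({"nope": {"a": 1}}, self.LIBS, "circular")


class TestNormalizationInvariance:
    """Contamination scaling must never move a normalized circRNA value."""

    def test_rrna_scaling_leaves_cpm_unchanged(self, small_study):
        calls = small_study.calls
        libs = small_study.libraries
        base = build_circ_matrix(calls, libs).normalized
        scaled_libs = {
            sid: SampleLibrary(sid, l.total_mapped + 9 * (l.rrna_mapped
                                                          + l.organelle_mapped),
                               10 * l.organelle_mapped, 10 * l.rrna_mapped)
            for sid, l in libs.items()
        }
        scaled = build_circ_matrix(calls, scaled_libs).normalized
        assert np.allclose(base.values, scaled.values, rtol=1e-12, atol=0)

    def test_joint_retained_read_scaling(self, small_study):
        libs = small_study.libraries
        counts = {sid: {c.id: c.n_junction_reads for c in cl}
                  for sid, cl in small_study.calls.items()}
        base = CountMatrix.build(counts, libs, "circular").normalized
        libs3 = {sid: SampleLibrary(sid, 3 * l.total_mapped
                                    - 2 * l.organelle_mapped
                                    - 2 * l.rrna_mapped,
                                    l.organelle_mapped, l.rrna_mapped)
                 for sid, l in libs.items()}
        counts3 = {sid: {f: 3 * n for f, n in d.items()}
                   for sid, d in counts.items()}
        scaled = CountMatrix.build(counts3, libs3, "circular").normalized
        assert np.allclose(base.values, scaled.values, rtol=1e-12, atol=0)


class TestLinearCounters:
    GENOME = GenomeBundle(
        sequences={"c": "A" * 2000},
        genes={"g": GeneModel("g", "c", "+", 100, 900,
                              exons=((100, 400), (600, 900)))},
        chrom_class={"c": "nuclear"})
    J = BackspliceJunction("c", "+", 600, 900)

    def make_group(self, name, blocks, q=(0, 50), read_len=50):
        segs = [Segment(chrom="c", strand="+", ref_start=blocks[0][0],
                        ref_end=blocks[-1][1], q_start=q[0], q_end=q[1],
                        read_len=read_len, is_supplementary=False,
                        blocks=tuple(blocks))]
        return SplitReadGroup(read_id=f"{name}/1", template_id=name,
                              segments=segs)

    def test_boundary_crossing_definitions(self):
        crossing = self.make_group("t1", [(580, 629)])  # spans start=600
        inside = self.make_group("t2", [(650, 699)])
        spliced = self.make_group("t3", [(380, 400), (600, 629)])
        b, g = quantify_linear([crossing, inside, spliced], [self.J],
                               self.GENOME)
        assert b[self.J.id] == 2  # contiguous + forward-spliced crossers
        assert g["g"] == 3  # all three overlap the exon union

    def test_backspliced_template_excluded_from_linear(self):
        chiastic = SplitReadGroup(
            read_id="bs/1", template_id="bs",
            segments=[
                Segment("c", "+", 851, 900, 0, 50, 100, False,
                        blocks=((851, 900),)),
                Segment("c", "+", 600, 649, 50, 100, 100, True,
                        blocks=((600, 649),)),
            ])
        crossing = self.make_group("lin", [(580, 629)])
        b, g = quantify_linear([chiastic, crossing], [self.J], self.GENOME)
        assert b[self.J.id] == 1  # only the linear template


def test_coverage_profile_flat_and_circular_excess():
    gene = GeneModel("g", "c", "+", 1, 1000, exons=((1, 1000),))
    junction = BackspliceJunction("c", "+", 401, 600)
    groups = []
    # uniform linear coverage: one 50-mer every 10 bases
    for i, start in enumerate(range(1, 951, 10)):
        groups.append(SplitReadGroup(
            read_id=f"l{i}/1", template_id=f"l{i}",
            segments=[Segment("c", "+", start, start + 49, 0, 50, 50, False,
                              blocks=((start, start + 49),))]))
    # circular excess inside [401, 600]
    for i, start in enumerate(list(range(401, 551, 10)) * 3):
        groups.append(SplitReadGroup(
            read_id=f"x{i}/1", template_id=f"x{i}",
            segments=[Segment("c", "+", start, start + 49, 0, 50, 50, False,
                              blocks=((start, start + 49),))]))
    prof = coverage_profile(groups, gene, junction)
    flank = prof.mean_depth(100, 350)
    inside = prof.mean_depth(420, 580)
    assert flank == pytest.approx(5.0, abs=0.5)
    assert inside / flank == pytest.approx(4.0, rel=0.15)
    empty = coverage_profile([], gene, junction)
    assert empty.depth.sum() == 0


def test_bedgraph_round_trip(tmp_path):
    gene = GeneModel("g", "c", "+", 1, 30, exons=((1, 30),))
    junction = BackspliceJunction("c", "+", 5, 25)
    g = SplitReadGroup(read_id="r/1", template_id="r", segments=[
        Segment("c", "+", 11, 20, 0, 10, 10, False, blocks=((11, 20),))])
    prof = coverage_profile([g], gene, junction)
    out = tmp_path / "cov.bedgraph"
    prof.to_bedgraph(out)
    rows = [l.split("\t") for l in out.read_text().splitlines()[1:]]
    covered = [r for r in rows if r[3] == "1"]
    assert covered == [["c", "10", "20", "1"]]
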