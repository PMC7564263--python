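"""Shared fixtures: seeded synthetic studies at two scales.

``demo_study`` is the full-size study (≈2 Mb genome, 200 genes, 40 true
circRNAs, wild-type + two mutants x 4 replicates) used by the end-to-end
checks; ``small_study`` is a fast single-chromosome variant for unit-level
oracle tests.  Both are generated once per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pytest

from circleaf.detect import CircCall, ParsedAlignments, call_circRNAs, \
    parse_alignments
from circleaf.genome import GenomeBundle
from circleaf.quantify import (CountMatrix, SampleLibrary, build_circ_matrix,
                               count_library_components, quantify_linear)
from circleaf.simulate import GroundTruthManifest, SimConfig, simulate_study

SMALL_CONFIG = dict(
    n_nuclear_chroms=1, chrom_length=400_000, n_genes=60,
    organelle_length=60_000, n_rrna_loci=2, n_circ=20,
    genotypes=("Col-0", "cbp80"), private_circ={"cbp80": 2},
    circ_fold_changes={"cbp80": {0: 4.0}}, circ_mean_scale={"cbp80": 2.5},
    depth=10.0,
)


@dataclass
class Study:
    """A simulated study plus everything the analysis derives from it."""

    config: SimConfig
    genome: GenomeBundle
    manifest: GroundTruthManifest
    paths: dict
    parsed: dict[str, ParsedAlignments] = field(default_factory=dict)
    calls: dict[str, list[CircCall]] = field(default_factory=dict)
    libraries: dict[str, SampleLibrary] = field(default_factory=dict)
    circ_matrix: CountMatrix | None = None
    boundary_matrix: CountMatrix | None = None
    gene_matrix: CountMatrix | None = None

    @property
    def samples(self):
        return self.manifest.samples


def build_study(config: SimConfig, outdir: Path,
                write_fastq: bool = False, matrices: bool = True) -> Study:
    genome, manifest, paths = simulate_study(config, outdir,
                                             write_fastq=write_fastq)
    study = Study(config=config, genome=genome, manifest=manifest, paths=paths)
    for _, row in manifest.samples.iterrows():
        sid = row.sample_id
        parsed = parse_alignments(paths[sid]["sam"])
        study.parsed[sid] = parsed
        study.calls[sid] = call_circRNAs(parsed, genome)
        study.libraries[sid] = count_library_components(
            parsed, genome, sample_id=sid, genotype=row.genotype,
            replicate=int(row.replicate))
    if matrices:
        study.circ_matrix = build_circ_matrix(study.calls, study.libraries)
        junctions = sorted(
            {c.id: c.junction for cl in study.calls.values()
             for c in cl}.items())
        junction_list = [j for _, j in junctions]
        boundary, gene = {}, {}
        for sid, parsed in study.parsed.items():
            b, g = quantify_linear(parsed, junction_list, genome)
            boundary[sid] = b
            gene[sid] = g
        study.boundary_matrix = CountMatrix.build(
            boundary, study.libraries, kind="linear_boundary")
        study.gene_matrix = CountMatrix.build(
            gene, study.libraries, kind="linear_gene")
    return study


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory) -> Study:
    """The full-size seeded demo with FASTQ for the anchor detector."""
    outdir = tmp_path_factory.mktemp("demo")
    return build_study(SimConfig(seed=7), outdir, write_fastq=True)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> Study:
    outdir = tmp_path_factory.mktemp("small")
    return build_study(SimConfig(seed=3, **SMALL_CONFIG), outdir,
                       write_fastq=True)
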