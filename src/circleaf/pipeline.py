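"""End-to-end orchestration: simulate -> detect -> quantify -> consensus ->
differential -> annotate, as one reproducible, seeded run.

``run_all`` executes every stage on either a synthetic study (built from a
:class:`~circleaf.simulate.SimConfig`) or user-supplied files, writes every
stage's tables under the output directory together with a file-hash
manifest, and returns a summary dictionary (also written as JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import consensus as cons
from . import differential as diff
from .detect import (BackspliceJunction, call_circRNAs, call_circRNAs_anchor,
                     calls_to_frame, concordance, parse_alignments)
from .genome import GenomeBundle
from .quantify import (CountMatrix, build_circ_matrix,
                       count_library_components, quantify_linear)
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_inputs", "Diagnostics"]


@dataclass
class RunConfig:
    """One run's inputs and thresholds.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or the four real
    input paths must be supplied.  Thresholds default to the conventional
    values: >=2 junction reads, consensus in all replicates, p <= 0.05
    with a two-fold change, 20-nt anchors, exact boundary matching.
    """

    outdir: str | Path = "circleaf_run"
    seed: int = 0
    simulate: SimConfig | None = None
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    sample_sheet: str | None = None
    alignment_dir: str | None = None
    fastq_dir: str | None = None
    min_reads: int = 2
    consensus_k: int | None = None  # None = all replicates
    pseudocount: float = 0.5
    p_cutoff: float = 0.05
    fold_cutoff: float = 2.0
    anchor_len: int = 20
    boundary_tolerance: int = 0
    run_anchor: bool = True

    def validate(self) -> None:
        have_sim = self.simulate is not None
        have_real = all(x is not None for x in (
            self.genome_fasta, self.annotation_gff3, self.sample_sheet,
            self.alignment_dir))
        if have_sim == have_real:
            raise ValueError(
                "supply exactly one of: a simulate config, or all of "
                "genome_fasta/annotation_gff3/sample_sheet/alignment_dir")
        for name in ("min_reads", "pseudocount", "p_cutoff", "fold_cutoff",
                     "anchor_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.boundary_tolerance < 0:
            raise ValueError("boundary_tolerance must be >= 0")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = plain(dataclasses.asdict(self))
        d["outdir"] = str(self.outdir)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulate")
        if isinstance(sim, Mapping):
            sim = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in sim.items()}
            if "circ_fold_changes" in sim:
                sim["circ_fold_changes"] = {
                    g: {int(i): float(f) for i, f in m.items()}
                    for g, m in sim["circ_fold_changes"].items()}
            d["simulate"] = SimConfig(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Diagnostics:
    fatals: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatals


def validate_inputs(config: RunConfig) -> Diagnostics:
    """Consistency checks across FASTA / GFF3 / SAM / sample sheet.

    Fatal: chromosome-name disagreement between SAM headers and FASTA,
    genotypes with fewer than two replicates, features outside chromosome
    bounds, illegal strands.  Simulated inputs are consistent by
    construction, so diagnostics are only computed for file inputs.
    """
    import pysam

    diag = Diagnostics()
    if config.simulate is not None:
        return diag
    genome = GenomeBundle.from_files(config.genome_fasta,
                                     config.annotation_gff3)
    samples = pd.read_csv(config.sample_sheet, sep="\t")
    for col in ("sample_id", "genotype", "replicate"):
        if col not in samples.columns:
            diag.fatals.append(f"sample sheet lacks column {col!r}")
            return diag
    for genotype, grp in samples.groupby("genotype"):
        if len(grp) < 2:
            diag.fatals.append(
                f"genotype {genotype!r} has only {len(grp)} replicate(s); "
                f"need >= 2")
    for gene in genome.genes.values():
        if gene.strand not in "+-":
            diag.fatals.append(f"gene {gene.gene_id}: illegal strand")
        limit = genome.chrom_length(gene.chrom)
        for a, b in gene.exons:
            if a < 1 or b > limit:
                diag.fatals.append(
                    f"gene {gene.gene_id}: exon {a}-{b} outside chromosome "
                    f"{gene.chrom} (length {limit})")
    for sid in samples.sample_id:
        sam = Path(config.alignment_dir) / f"{sid}.sam"
        if not sam.exists():
            diag.fatals.append(f"missing alignment file {sam}")
            continue
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
            refs = set(fh.references or ())
        unknown = refs - set(genome.sequences)
        if unknown:
            diag.fatals.append(
                f"{sam.name}: SAM chromosomes {sorted(unknown)} absent from "
                f"the FASTA")
    return diag


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(v, dict)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- inputs ----------------------------------------------------
        stage = "simulate"
        manifest = None
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            data_dir = outdir / "data"
            genome, manifest, paths = simulate_study(
                sim, data_dir, write_fastq=config.run_anchor)
            samples = manifest.samples
            sam_paths = {s: paths[s]["sam"] for s in paths}
            fq_paths = {s: paths[s].get("fastq") for s in paths}
        else:
            genome = GenomeBundle.from_files(config.genome_fasta,
                                             config.annotation_gff3)
            samples = pd.read_csv(config.sample_sheet, sep="\t")
            sam_paths = {s: Path(config.alignment_dir) / f"{s}.sam"
                         for s in samples.sample_id}
            fq_paths = {
                s: (Path(config.fastq_dir) / f"{s}.fastq"
                    if config.fastq_dir else None)
                for s in samples.sample_id}

        genotypes = list(dict.fromkeys(samples.genotype))
        wild_type = genotypes[0]

        # ---- detection + library accounting ----------------------------
        stage = "detect"
        calls_by_sample = {}
        libraries = {}
        stage_counters: dict[str, dict] = {}
        parsed_by_sample = {}
        for _, row in samples.iterrows():
            sid = row.sample_id
            parsed = parse_alignments(sam_paths[sid])
            parsed_by_sample[sid] = parsed
            det_stats: Counter = Counter()
            calls = call_circRNAs(parsed, genome, min_reads=config.min_reads,
                                  require_signal=True, stats=det_stats)
            calls_by_sample[sid] = calls
            libraries[sid] = count_library_components(
                parsed, genome, sample_id=sid, genotype=row.genotype,
                replicate=int(row.replicate))
            stage_counters[sid] = dict(parsed.stats | det_stats)
            calls_to_frame(calls).to_csv(
                outdir / f"calls_{sid}.tsv", sep="\t", index=False)

        pd.DataFrame([
            {"sample_id": l.sample_id, "genotype": l.genotype,
             "replicate": l.replicate, "total_mapped": l.total_mapped,
             "organelle_mapped": l.organelle_mapped,
             "rrna_mapped": l.rrna_mapped, "effective_size": l.effective_size}
            for l in libraries.values()
        ]).to_csv(outdir / "libraries.tsv", sep="\t", index=False)

        # ---- anchor cross-validation -----------------------------------
        stage = "detect-anchor"
        concord = {}
        if config.run_anchor and any(fq_paths.values()):
            from .detect import KmerIndex

            index = KmerIndex(genome, k=config.anchor_len)
            for sid, fq in fq_paths.items():
                if fq is None:
                    continue
                anchor_calls = call_circRNAs_anchor(
                    fq, genome, anchor_len=config.anchor_len,
                    min_reads=config.min_reads, index=index)
                c = concordance(calls_by_sample[sid], anchor_calls)
                concord[sid] = {"frac_primary_in_anchor": c.frac_a_in_b,
                                "frac_anchor_in_primary": c.frac_b_in_a,
                                "jaccard": c.jaccard, "n_primary": c.n_a,
                                "n_anchor": c.n_b}

        # ---- quantification --------------------------------------------
        stage = "quantify"
        all_junctions = {}
        for calls in calls_by_sample.values():
            for c in calls:
                all_junctions[c.id] = c.junction
        junction_list = [all_junctions[i] for i in sorted(all_junctions)]

        circ_matrix = build_circ_matrix(calls_by_sample, libraries)
        boundary_counts = {}
        gene_counts = {}
        for sid, parsed in parsed_by_sample.items():
            b, g = quantify_linear(parsed, junction_list, genome)
            boundary_counts[sid] = b
            gene_counts[sid] = g
        boundary_matrix = CountMatrix.build(boundary_counts, libraries,
                                            kind="linear_boundary")
        gene_matrix = CountMatrix.build(gene_counts, libraries,
                                        kind="linear_gene")
        circ_matrix.write(outdir / "circ_matrix.tsv")
        boundary_matrix.write(outdir / "linear_boundary_matrix.tsv")
        gene_matrix.write(outdir / "linear_gene_matrix.tsv")

        # ---- consensus --------------------------------------------------
        stage = "consensus"
        consensus_sets = {}
        consensus_records = []
        spectra = {}
        uniqueness = {}
        for genotype in genotypes:
            cset, records = cons.consensus_set(
                calls_by_sample, samples, genotype, k=config.consensus_k)
            consensus_sets[genotype] = cset
            consensus_records.extend(records)
            spectra[genotype] = cons.reproducibility_spectrum(
                calls_by_sample, samples, genotype).to_dict()
        ref_sets = cons.detection_sets(calls_by_sample, samples, wild_type)
        for genotype in genotypes[1:]:
            uniqueness[genotype] = {
                mode: sorted(cons.unique_to_variant(
                    consensus_sets[genotype], ref_sets, mode=mode))
                for mode in ("strict", "consensus")
            }
        pd.DataFrame([
            {"circ_id": r.circ_id, "genotype": r.genotype,
             "n_detected": r.n_detected, "n_replicates": r.n_replicates,
             "in_consensus": r.in_consensus,
             "pattern": "".join("1" if x else "0"
                                for x in r.detection_pattern)}
            for r in consensus_records
        ]).to_csv(outdir / "consensus.tsv", sep="\t", index=False)

        # ---- correlations -----------------------------------------------
        stage = "correlation"
        correlations = {}
        for genotype in genotypes:
            _, r_circ = cons.replicate_correlation(circ_matrix, samples,
                                                   genotype)
            _, r_lin = cons.replicate_correlation(gene_matrix, samples,
                                                  genotype)
            correlations[genotype] = {"circ_mean_r": r_circ,
                                      "linear_mean_r": r_lin}

        # ---- annotation -------------------------------------------------
        stage = "annotate"
        structures = {}
        distributions = {}
        host_of = {}
        for genotype in genotypes:
            structs = []
            for cid in sorted(consensus_sets[genotype]):
                junction = all_junctions[cid]
                st = ann.annotate_junction(junction, genome,
                                           tolerance=config.boundary_tolerance)
                structs.append(st)
                host_of[cid] = st.host_gene
            structures[genotype] = structs
            distributions[genotype] = ann.exon_start_distribution(structs)
            ann.structures_to_frame(structs).to_csv(
                outdir / f"structures_{genotype}.tsv", sep="\t", index=False)

        # ---- differential -----------------------------------------------
        stage = "differential"
        differential = {}
        global_tests = {}
        circ_linear = {}
        for genotype in genotypes[1:]:
            universe = sorted(consensus_sets[wild_type]
                              | consensus_sets[genotype])
            table = diff.circ_fold_change_test(
                circ_matrix, samples, wild_type, genotype,
                pseudocount=config.pseudocount, universe=universe,
                p_cutoff=config.p_cutoff, fold_cutoff=config.fold_cutoff)
            table.to_csv(outdir / f"differential_{genotype}.tsv", sep="\t")
            sig = table[table.significant]
            differential[genotype] = {
                "n_tested": int(len(table)),
                "n_up": int((sig.log2_fc > 0).sum()),
                "n_down": int((sig.log2_fc < 0).sum()),
            }
            gt = diff.global_accumulation_test(
                circ_matrix, samples, genotype, wild_type,
                universe_alt=sorted(consensus_sets[genotype]),
                universe_ref=sorted(consensus_sets[wild_type]))
            global_tests[genotype] = {
                "p_value": gt.p_value, "stars": gt.stars,
                "median_ref": gt.median_ref, "median_alt": gt.median_alt,
                "n_ref": gt.n_ref, "n_alt": gt.n_alt}
            # primary linear counterpart: boundary-crossing reads of the
            # same junction; host-gene counts as a coarser secondary view
            boundary_pairs = {cid: cid for cid in consensus_sets[genotype]}
            gene_pairs = {cid: host_of[cid]
                          for cid in consensus_sets[genotype]
                          if host_of.get(cid)}
            cl = diff.circ_linear_correlation(circ_matrix, boundary_matrix,
                                              boundary_pairs, samples, genotype)
            cl_gene = diff.circ_linear_correlation(circ_matrix, gene_matrix,
                                                   gene_pairs, samples,
                                                   genotype)
            circ_linear[genotype] = {
                "r": cl.r, "p_value": cl.p_value, "n_pairs": cl.n_pairs,
                "r_host_gene": cl_gene.r, "n_pairs_host_gene": cl_gene.n_pairs}
            lt = diff.linear_abundance_test(
                gene_matrix, samples, genotype, wild_type,
                universe=sorted(set(gene_pairs.values())))
            global_tests[genotype]["linear_counterpart_p"] = lt.p_value

        # ---- summary + hashes -------------------------------------------
        stage = "report"
        summary = {
            "genotypes": genotypes,
            "consensus_counts": {g: len(s) for g, s in consensus_sets.items()},
            "uniqueness_counts": {
                g: {m: len(v) for m, v in modes.items()}
                for g, modes in uniqueness.items()},
            "unique_ids": uniqueness,
            "reproducibility_spectra": spectra,
            "replicate_correlations": correlations,
            "detector_concordance": concord,
            "differential": differential,
            "global_tests": global_tests,
            "circ_linear_correlation": circ_linear,
            "exon_start_distributions": distributions,
            "stage_counters": stage_counters,
            "n_junctions_detected": len(all_junctions),
        }
        (outdir / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=1, sort_keys=True))
        effective = dataclasses.replace(
            config, simulate=sim if config.simulate is not None else None)
        effective.to_yaml(outdir / "run_config.yaml")
        hashes = {
            p.name: _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "file_hashes.json"
        }
        (outdir / "file_hashes.json").write_text(
            json.dumps(hashes, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
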