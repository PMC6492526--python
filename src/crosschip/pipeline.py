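"""End-to-end orchestration: metrics -> filter methods -> flank validation ->
cross-assembly intersection -> context extraction -> conservation ->
chromosome assignment -> nearest genes -> summary report.

Everything is driven by one :class:`PipelineConfig`; each stage persists its
output (TSV / BED / JSON) under the configured output directory, and rerunning
with identical inputs reproduces byte-identical artifacts.  ``simulate_inputs``
writes a fully synthetic input set (with ground truth) in the exact dialects
the readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

from . import annotate as _annotate
from . import flanks as _flanks
from . import io as _io
from . import report as _report
from .filters import METHOD_NAMES, compare_methods, cascade_table, method_config
from .qc import compute_snp_metrics
from .simulate import (
    ScaffoldPlan,
    SyntheticTruth,
    simulate_annotation,
    simulate_genomes,
    simulate_genotype_report,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "simulate_inputs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths, method selection and output settings for one run."""

    report: Path
    manifest: Path
    genome_a: Path
    genome_b: Path
    out_dir: Path
    outgroup: Optional[Path] = None
    synteny_map: Optional[Path] = None
    gene_annotation: Optional[Path] = None
    methods: tuple[str, ...] = METHOD_NAMES
    validation_method: str = "VI"
    maf_level: float = 0.01
    required_flank_length: int = 21
    report_config: _report.ReportConfig = field(default_factory=_report.ReportConfig)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty when the config is runnable).

    Pure validation — nothing is read beyond file existence.
    """
    problems: list[str] = []
    for name in ("report", "manifest", "genome_a", "genome_b"):
        path = getattr(config, name)
        if path is None:
            problems.append(f"{name}: required input missing")
        elif not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    for name in ("outgroup", "synteny_map", "gene_annotation"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    for method in config.methods:
        if method not in METHOD_NAMES:
            problems.append(f"unknown method {method!r}")
    if config.validation_method not in config.methods:
        problems.append(
            f"validation method {config.validation_method!r} not among selected methods"
        )
    if config.maf_level not in (0.01, 0.05):
        problems.append(f"maf_level must be 0.01 or 0.05, got {config.maf_level}")
    if config.required_flank_length not in _flanks.DEFAULT_LENGTHS:
        problems.append(
            f"required_flank_length must be one of {_flanks.DEFAULT_LENGTHS}"
        )
    return problems


def _write_json(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and persist its artifacts; returns the summary dict.

    The flank-validation stages run on the survivors of
    ``validation_method`` at ``maf_level`` (the published pairing: the
    strictest method is validated at MAF >= 0.01, the others at >= 0.05).
    HWE is evaluated on the final retained set and reported, never used as a
    filter.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline configuration: " + "; ".join(problems))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    manifest = _io.read_snp_manifest(config.manifest)
    matrix = _io.read_genotype_report(config.report, manifest)
    log("input", f"{matrix.n_snps} SNPs x {matrix.n_samples} samples")

    # --- filter cascade for every selected method -------------------------
    cascades = compare_methods(matrix, manifest, config.methods)
    table = cascade_table(cascades)
    table.to_csv(out / "cascade_counts.tsv", sep="\t")
    _write_json(
        {name: result.counts for name, result in cascades.items()},
        out / "cascade_counts.json",
    )
    for name, result in cascades.items():
        log("filter", f"method {name}: " + ", ".join(
            f"{stage}={count}" for stage, count in result.counts.items()))

    validation_cfg = method_config(config.validation_method)
    metrics = compute_snp_metrics(matrix, manifest, validation_cfg.no_call_threshold)
    metrics.to_frame().to_csv(
        out / f"metrics_threshold_{validation_cfg.no_call_threshold:g}.tsv",
        sep="\t", index=False, float_format="%.6g",
    )
    selected_stage = f"maf_ge_{config.maf_level:g}"
    selected = sorted(cascades[config.validation_method].survivors(selected_stage))
    log("select", f"method {config.validation_method} {selected_stage}: {len(selected)} SNPs")

    # --- flank validation against both assemblies -------------------------
    genome_a = _io.read_genome_fasta(config.genome_a, name="genomeA")
    genome_b = _io.read_genome_fasta(config.genome_b, name="genomeB")
    by_id = {record.snp_id: record for record in manifest}
    genomes = {"genomeA": genome_a, "genomeB": genome_b}
    uniqueness: dict[str, dict[str, _flanks.UniquenessCall]] = {g: {} for g in genomes}
    loci_by_genome: dict[str, list[_flanks.SnpLocus]] = {g: [] for g in genomes}
    for snp_id in selected:
        queries = _flanks.build_flank_queries(by_id[snp_id])
        located = _flanks.locate_snp(genomes, queries, config.required_flank_length)
        for genome_id, loci in located.items():
            uniqueness[genome_id][snp_id] = _flanks.classify_uniqueness(
                snp_id, genome_id, loci
            )
            loci_by_genome[genome_id].extend(loci)

    for genome_id in genomes:
        _flanks.write_loci_bed(loci_by_genome[genome_id], out / f"loci_{genome_id}.bed")
        rows = [
            "\t".join(
                [snp_id, genome_id, call.classification, str(len(call.loci))]
            )
            for snp_id, call in sorted(uniqueness[genome_id].items())
        ]
        (out / f"uniqueness_{genome_id}.tsv").write_text(
            "snp_id\tgenome\tclass\tn_loci\n" + "".join(r + "\n" for r in rows)
        )
        n_unique = sum(c.is_unique for c in uniqueness[genome_id].values())
        log("flankmap", f"{genome_id}: {n_unique} unique of {len(selected)} searched")

    # --- intersection and retained set ------------------------------------
    retained = sorted(
        _flanks.intersect_genomes(uniqueness["genomeA"], uniqueness["genomeB"])
    )
    (out / "retained_snps.txt").write_text("".join(s + "\n" for s in retained))
    log("intersect", f"{len(retained)} SNPs unique in both assemblies")

    # --- 101-nt contexts and conservation ---------------------------------
    contexts: dict[str, _flanks.SnpContext] = {}
    for snp_id in retained:
        locus = uniqueness["genomeA"][snp_id].loci[0]
        contexts[snp_id] = _flanks.extract_context(genome_a, locus)
    conservation: Optional[dict[str, bool]] = None
    if config.outgroup is not None:
        outgroup = _io.read_genome_fasta(config.outgroup, name="outgroup")
        conservation = {}
        for snp_id, context in contexts.items():
            if context.truncated:
                continue  # incomplete evidence: excluded from the check
            conservation[snp_id] = _flanks.conservation_check(
                context, outgroup, alleles=by_id[snp_id].alleles
            )
        log("conserve", f"{sum(conservation.values())} of {len(conservation)} conserved")
    with open(out / "contexts.tsv", "w") as fh:
        fh.write("snp_id\tsequence\tcenter_index\ttruncated\tconserved\n")
        for snp_id in retained:
            context = contexts[snp_id]
            conserved = "" if conservation is None else str(
                conservation.get(snp_id, "")
            )
            fh.write(
                f"{snp_id}\t{context.sequence}\t{context.center_index}"
                f"\t{context.truncated}\t{conserved}\n"
            )

    # --- HWE on the retained set (reported, not filtered) ------------------
    hwe_flags = {snp_id: metrics[snp_id].hwe.in_equilibrium for snp_id in retained}
    with open(out / "hwe_retained.tsv", "w") as fh:
        fh.write("snp_id\tchi2\tp\tin_equilibrium\n")
        for snp_id in retained:
            hwe = metrics[snp_id].hwe
            chi2 = "" if hwe.chi2 is None else f"{hwe.chi2:.6g}"
            p = "" if hwe.p is None else f"{hwe.p:.6g}"
            flag = "" if hwe.in_equilibrium is None else str(hwe.in_equilibrium)
            fh.write(f"{snp_id}\t{chi2}\t{p}\t{flag}\n")
    n_out = sum(1 for flag in hwe_flags.values() if flag is False)
    log("hwe", f"{n_out} retained SNPs out of Hardy-Weinberg equilibrium")

    # --- chromosome assignment and nearest genes ---------------------------
    assignments = None
    if config.synteny_map is not None:
        cmap = _io.read_synteny_map(config.synteny_map)
        assignments = [
            _annotate.assign_chromosome(cmap, uniqueness["genomeA"][snp_id].loci[0])
            for snp_id in retained
        ]
        with open(out / "chromosome_assignments.tsv", "w") as fh:
            fh.write("snp_id\tchromosome\tevidence\n")
            for a in assignments:
                fh.write(f"{a.snp_id}\t{a.chromosome}\t{a.evidence or ''}\n")
        distribution = _annotate.chromosome_distribution(assignments)
        _write_json(distribution, out / "chromosome_distribution.json")
        log("assign", f"{sum(a.assigned for a in assignments)} of "
            f"{len(assignments)} assigned to chromosomes")

    annotations = None
    if config.gene_annotation is not None:
        geneset = _io.read_gene_annotation(config.gene_annotation)
        annotations = [
            _annotate.nearest_gene(geneset, uniqueness["genomeA"][snp_id].loci[0])
            for snp_id in retained
        ]
        with open(out / "gene_annotations.tsv", "w") as fh:
            fh.write("snp_id\tgene_id\tdistance\twithin_gene\n")
            for snp_id, ann in zip(retained, annotations):
                if ann is None:
                    fh.write(f"{snp_id}\t\t\t\n")
                else:
                    fh.write(
                        f"{ann.snp_id}\t{ann.gene_id}\t{ann.distance}\t{ann.within_gene}\n"
                    )
        n_in = sum(1 for a in annotations if a is not None and a.within_gene)
        log("annotate", f"{n_in} retained SNPs within annotated genes")

    # --- summary -----------------------------------------------------------
    summary = _report.build_summary(
        cascades=cascades,
        uniqueness=uniqueness,
        retained=retained,
        assignments=assignments,
        annotations=annotations,
        conservation=conservation,
        hwe_flags=hwe_flags,
        config=config.report_config,
    )
    _write_json(summary, out / "summary.json")
    (out / "pipeline.log").write_text("".join(line + "\n" for line in log_lines))
    return summary


def simulate_inputs(
    out_dir: str | Path,
    seed: int,
    n_snps: int = 500,
    n_samples: int = 40,
    plan: Optional[ScaffoldPlan] = None,
    with_outgroup: bool = True,
    with_annotation: bool = True,
) -> tuple[PipelineConfig, SyntheticTruth]:
    """Write a complete synthetic input set and return a ready-to-run config.

    All files are produced through the package's own writers, so the
    round-trip through :func:`run_pipeline` exercises the real parsers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, manifest, truth = simulate_genotype_report(
        n_snps, n_samples=n_samples, seed=seed
    )
    genome_a, genome_b, outgroup = simulate_genomes(
        manifest, truth, plan=plan, seed=seed + 1
    )
    _io.write_genotype_report(matrix, out / "genotypes.tsv")
    _io.write_snp_manifest(manifest, out / "manifest.csv")
    _io.write_genome_fasta(genome_a, out / "genomeA.fasta")
    _io.write_genome_fasta(genome_b, out / "genomeB.fasta")
    config = PipelineConfig(
        report=out / "genotypes.tsv",
        manifest=out / "manifest.csv",
        genome_a=out / "genomeA.fasta",
        genome_b=out / "genomeB.fasta",
        out_dir=out / "results",
    )
    if with_outgroup:
        _io.write_genome_fasta(outgroup, out / "outgroup.fasta")
        config = replace(config, outgroup=out / "outgroup.fasta")
    if with_annotation:
        cmap, geneset = simulate_annotation(genome_a, seed=seed + 2)
        _io.write_synteny_map(cmap, out / "synteny.tsv")
        _io.write_gene_annotation(geneset, out / "genes.gff3")
        config = replace(
            config,
            synteny_map=out / "synteny.tsv",
            gene_annotation=out / "genes.gff3",
        )
    return config, truth
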