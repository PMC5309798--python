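"""End-to-end orchestration: inputs -> CNVRs -> peaks -> classes ->
conservation -> randomization -> enrichment, with all report tables
written to an output directory alongside a manifest echoing every
tunable (a permutation result is meaningless without its seed on record).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

import dosagescope
from dosagescope.classify import (
    GeneClass,
    assign_classes,
    find_solitary,
    solitary_in_both,
    unique_solitary_genes,
)
from dosagescope.conservation import (
    conservation_by_class,
    conserved_gene_set,
    summarize_profile,
    unchanged_by_class,
)
from dosagescope.core_io import (
    CnvRecord,
    CnvType,
    GeneRecord,
    GenomeBuild,
    Interpretation,
    read_cnv_table,
    read_gene_table,
    read_orthology_table,
    write_bed,
)
from dosagescope.nulls import fraction_with_flagged_gene, permutation_test
from dosagescope.regions import (
    Scope,
    coverage_profile,
    find_peak_regions,
    genome_fraction,
    merge_cnvrs,
    region_overlap,
)
from dosagescope.stats import chi2_with_residuals, class_enrichment_table, fligner_killeen
from dosagescope.synthetic_data import (
    SimulationConfig,
    simulate_cnvs,
    simulate_genome,
    simulate_orthology,
)

log = logging.getLogger("dosagescope")


@dataclass
class RunConfig:
    """Either file inputs (cnvs/genes/orthology/build paths) or a
    simulation config; not both unset."""

    cnv_path: str | None = None
    gene_path: str | None = None
    orthology_path: str | None = None
    build_path: str | None = None      # chrom/length TSV; default GRCh37
    cnv_dialect: str = "dbvar_tsv"
    simulate: SimulationConfig | None = None
    n_reps: int = 1000
    seed: int = 0
    out_dir: str = "dosagescope_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.cnv_path is None:
            raise ValueError("RunConfig needs input paths or a simulation config")


@dataclass
class RunReport:
    build: GenomeBuild
    genes: list[GeneRecord]
    cnvs: list[CnvRecord]
    regions: dict                      # (interpretation, scope) -> list[CnvRegion]
    peaks: dict                        # (interpretation, scope) -> list[PeakRegion]
    assignments: list
    class_counts: dict[str, int]
    solitary: dict
    conservation_table: pd.DataFrame
    randomization: object | None
    enrichment: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunReport:
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    build, genes, profiles, cnvs = _load_inputs(config)
    log.info(
        "inputs: %d genes, %d CNVs, build %s; seed=%d; filters: >=50 bp, "
        "<=10%% of chromosome, autosomes only",
        len(genes), len(cnvs), build.name, config.seed,
    )

    benign = [c for c in cnvs if c.interpretation is Interpretation.BENIGN]
    pathogenic = [c for c in cnvs if c.interpretation is Interpretation.PATHOGENIC]

    regions, peaks = _regions_stage(benign, pathogenic, out_dir)
    assignments, class_counts, solitary = _classify_stage(
        genes, benign, peaks, out_dir
    )
    conservation_table, cons_tests, summaries = _conservation_stage(
        genes, profiles, assignments, out_dir
    )
    randomization = _randomization_stage(config, pathogenic, genes, build)
    enrichment = _enrichment_stage(genes, assignments, out_dir)

    summary = _summary(
        build, genes, benign, pathogenic, regions, peaks, class_counts,
        solitary, conservation_table, cons_tests, randomization, summaries,
    )
    report = RunReport(
        build=build, genes=genes, cnvs=cnvs, regions=regions, peaks=peaks,
        assignments=assignments, class_counts=class_counts, solitary=solitary,
        conservation_table=conservation_table, randomization=randomization,
        enrichment=enrichment, summary=summary,
    )
    _write_manifest(config, report, out_dir)
    return report


@_stage("load_inputs")
def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = config.simulate
        build, genes = simulate_genome(sim)
        profiles = simulate_orthology(genes, sim)
        cnvs = simulate_cnvs(genes, build, sim)
        return build, genes, profiles, cnvs
    from dosagescope.core_io import GRCH37

    if config.build_path is not None:
        df = pd.read_csv(config.build_path, sep="\t", dtype={"chrom": str})
        build = GenomeBuild(
            "custom", dict(zip(df["chrom"], df["length"].astype(int)))
        )
    else:
        build = GRCH37
    cnvs = read_cnv_table(config.cnv_path, dialect=config.cnv_dialect, build=build)
    genes = read_gene_table(config.gene_path) if config.gene_path else []
    profiles = (
        read_orthology_table(config.orthology_path) if config.orthology_path else []
    )
    return build, genes, profiles, cnvs


@_stage("regions")
def _regions_stage(benign, pathogenic, out_dir: Path):
    regions: dict = {}
    peaks: dict = {}
    for interp, cnv_set in (("benign", benign), ("pathogenic", pathogenic)):
        for scope in Scope:
            if not cnv_set:
                regions[(interp, scope.value)] = []
                peaks[(interp, scope.value)] = []
                continue
            regs = merge_cnvrs(cnv_set, scope)
            regions[(interp, scope.value)] = regs
            pks = [
                p for r in regs for p in find_peak_regions(coverage_profile(r))
            ]
            peaks[(interp, scope.value)] = pks
    for (interp, scope), regs in regions.items():
        write_bed(
            [(r.chromosome, r.start, r.end, r.region_id, len(r.members)) for r in regs],
            out_dir / f"cnvr_{interp}_{scope}.bed",
        )
    for (interp, scope), pks in peaks.items():
        write_bed(
            [(p.chromosome, p.start, p.end, p.peak_id, p.depth) for p in pks],
            out_dir / f"peaks_{interp}_{scope}.bed",
        )
    return regions, peaks


@_stage("classify")
def _classify_stage(genes, benign, peaks, out_dir: Path):
    benign_gain = [c for c in benign if c.cnv_type is CnvType.GAIN]
    benign_loss = [c for c in benign if c.cnv_type is CnvType.LOSS]
    gain_peaks = peaks[("pathogenic", "gain_only")]
    loss_peaks = peaks[("pathogenic", "loss_only")]
    assignments = assign_classes(genes, benign_gain, benign_loss, gain_peaks, loss_peaks)
    class_counts = {
        label.value: sum(a.label is label for a in assignments) for label in GeneClass
    }
    gain_calls = find_solitary(gain_peaks, assignments, genes)
    loss_calls = find_solitary(loss_peaks, assignments, genes)
    solitary = {
        "gain_calls": gain_calls,
        "loss_calls": loss_calls,
        "unique_genes": sorted(
            unique_solitary_genes(gain_calls) | unique_solitary_genes(loss_calls)
        ),
        "in_both": sorted(solitary_in_both(gain_calls, loss_calls)),
    }
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id, "label": a.label.value,
                "in_benign_gain": a.in_benign_gain, "in_benign_loss": a.in_benign_loss,
                "in_path_gain_peak": a.in_path_gain_peak,
                "in_path_loss_peak": a.in_path_loss_peak,
            }
            for a in assignments
        ]
    ).to_csv(out_dir / "gene_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"region_id": c.region_id, "n_class_p": len(c.class_p_gene_ids),
             "solitary": c.solitary, "class_p_genes": ",".join(c.class_p_gene_ids)}
            for c in gain_calls + loss_calls
        ]
    ).to_csv(out_dir / "solitary.tsv", sep="\t", index=False)
    return assignments, class_counts, solitary


@_stage("conservation")
def _conservation_stage(genes, profiles, assignments, out_dir: Path):
    ancestral_ids = {g.gene_id for g in genes if g.ancestral}
    scored = [p for p in profiles if p.unit_id in ancestral_ids]
    summaries = [summarize_profile(p) for p in scored]
    table = conservation_by_class(summaries, assignments)
    table.to_csv(out_dir / "conservation_by_class.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"unit_id": s.unit_id, "n_unchanged": s.n_unchanged,
             "n_duplicated": s.n_duplicated, "n_missing": s.n_missing,
             "conserved": s.conserved}
            for s in summaries
        ]
    ).to_csv(out_dir / "conservation_summaries.tsv", sep="\t", index=False)

    tests: dict = {}
    groups = unchanged_by_class(summaries, assignments)
    usable = {k: v for k, v in groups.items() if k in ("B", "P", "X") and v.size >= 2}
    if len(usable) >= 2:
        try:
            stat, p = fligner_killeen(*usable.values())
            tests["fligner"] = {"groups": sorted(usable), "stat": stat, "p": p}
        except ValueError:
            tests["fligner"] = None
        conserved = conserved_gene_set(summaries)
        counts = [
            [int(sum(1 for uid in _class_ids(assignments, k) if uid in conserved)),
             int(sum(1 for uid in _class_ids(assignments, k)
                     if uid in {s.unit_id for s in summaries} and uid not in conserved))]
            for k in sorted(usable)
        ]
        arr = np.array(counts)
        if (arr.sum(axis=1) > 0).all() and (arr.sum(axis=0) > 0).all():
            res = chi2_with_residuals(arr)
            tests["conserved_chi2"] = {"groups": sorted(usable), "chi2": res.chi2, "p": res.p}
    return table, tests, summaries


def _class_ids(assignments, label: str):
    return [a.gene_id for a in assignments if a.label.value == label]


@_stage("randomization")
def _randomization_stage(config: RunConfig, pathogenic, genes, build):
    if config.n_reps < 1:
        log.info("randomization skipped (n_reps=%d)", config.n_reps)
        return None
    if not pathogenic or not genes:
        return None
    stat = fraction_with_flagged_gene(genes, "developmental")
    return permutation_test(
        stat, pathogenic, build, n_reps=config.n_reps, seed=config.seed
    )


@_stage("enrichment")
def _enrichment_stage(genes, assignments, out_dir: Path):
    try:
        table = class_enrichment_table(genes, assignments)
    except ValueError:
        table = pd.DataFrame()
    table.to_csv(out_dir / "class_enrichment.tsv", sep="\t", index=False)
    return table


def _summary(build, genes, benign, pathogenic, regions, peaks, class_counts,
             solitary, conservation_table, cons_tests, randomization, summaries):
    def frac(cnv_set):
        if not cnv_set:
            return 0.0
        return genome_fraction([(c.chromosome, c.start, c.end) for c in cnv_set], build)

    summary = {
        "n_genes": len(genes),
        "n_benign_cnvs": len(benign),
        "n_pathogenic_cnvs": len(pathogenic),
        "genome_fraction_benign": frac(benign),
        "genome_fraction_pathogenic": frac(pathogenic),
        "n_cnvr": {k[0] + "_" + k[1]: len(v) for k, v in regions.items()},
        "n_peaks": {k[0] + "_" + k[1]: len(v) for k, v in peaks.items()},
        "class_counts": class_counts,
        "n_solitary_regions": sum(
            c.solitary for c in solitary["gain_calls"] + solitary["loss_calls"]
        ),
        "n_unique_solitary_genes": len(solitary["unique_genes"]),
        "n_solitary_in_both": len(solitary["in_both"]),
        "n_conserved_genes": int(sum(s.conserved for s in summaries)),
        "conservation_tests": cons_tests,
    }
    if benign and pathogenic:
        bp, fraction = region_overlap(
            [(c.chromosome, c.start, c.end) for c in benign],
            [(c.chromosome, c.start, c.end) for c in pathogenic],
        )
        summary["benign_bp_overlapped_by_pathogenic"] = bp
        summary["fraction_benign_overlapped_by_pathogenic"] = fraction
    if randomization is not None:
        summary["randomization"] = {
            "observed": randomization.observed,
            "null_mean": randomization.null_mean,
            "null_sd": randomization.null_sd,
            "null_max": randomization.null_max,
            "z": randomization.z,
            "p_empirical": randomization.p_empirical,
            "n_reps": randomization.n_reps,
        }
    return summary


def _write_manifest(config: RunConfig, report: RunReport, out_dir: Path) -> None:
    manifest = {
        "dosagescope_version": dosagescope.__version__,
        "seed": config.seed,
        "n_reps": config.n_reps,
        "cnv_dialect": config.cnv_dialect,
        "inputs": {
            "cnv_path": config.cnv_path,
            "gene_path": config.gene_path,
            "orthology_path": config.orthology_path,
        },
        "simulation": (
            {k: v for k, v in vars(config.simulate).items()}
            if config.simulate is not None else None
        ),
        "filters": {"min_cnv_length": 50, "max_chrom_fraction": 0.1},
        "randomization_skipped": report.randomization is None,
        "summary": report.summary,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
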