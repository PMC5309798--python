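"""Synthetic genomes, gene tables, orthology profiles and CNV call sets.

The generator emulates the statistical structure of the real inputs
(dbVar-style clinical CNV calls, Ensembl-style protein-coding annotation,
Compara-style 13-species orthology) so the full pipeline is testable
without downloads. A single latent ``dosage_sensitive`` boolean per gene
drives every enrichment the analysis is meant to recover:

* dosage-sensitive genes carry developmental/complex/ohnologue flags,
  high loss-of-function-intolerance scores and high expression more often;
* their orthology profiles change (duplicate or disappear) in fewer
  species (q_sensitive < q_neutral);
* pathogenic CNVs are anchored onto dosage-sensitive genes with the
  targeting probability, while benign CNVs avoid them with the avoidance
  probability; benign calls outnumber pathogenic calls about 2:1 but
  pathogenic calls are an order of magnitude longer, mirroring the length
  asymmetry of clinical call sets.

Gene intervals are non-overlapping; real-genome gene overlap is not
emulated (irrelevant to the interval logic under test).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from dosagescope.core_io import (
    CnvRecord,
    CnvType,
    GeneRecord,
    GenomeBuild,
    Interpretation,
    MAMMAL_SPECIES,
    OrthologyProfile,
    OrthologyStatus,
)

_STRATA = (
    (Interpretation.BENIGN, CnvType.GAIN),
    (Interpretation.BENIGN, CnvType.LOSS),
    (Interpretation.PATHOGENIC, CnvType.GAIN),
    (Interpretation.PATHOGENIC, CnvType.LOSS),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    Defaults give a 4-autosome, 120 Mb toy genome with 2,000 genes of which
    20% are latently dosage sensitive, per-species copy-number change
    probabilities of 0.02 (sensitive) vs 0.15 (neutral), pathogenic CNVs
    anchored on sensitive genes with probability 0.8, and a 2:1
    benign:pathogenic count ratio with pathogenic calls ~7x longer.
    """

    n_chromosomes: int = 4
    chromosome_length: int = 30_000_000
    n_genes: int = 2000
    gene_length: int = 20_000
    frac_dosage_sensitive: float = 0.2

    # attribute rates, latent-class conditional
    dev_rate_sensitive: float = 0.5
    dev_rate_neutral: float = 0.12
    complex_rate_sensitive: float = 0.45
    complex_rate_neutral: float = 0.20
    ohnologue_rate_sensitive: float = 0.45
    ohnologue_rate_neutral: float = 0.25
    omim_rate_sensitive: float = 0.25
    omim_rate_neutral: float = 0.12
    ancestral_rate: float = 0.9

    # orthology: per-species copy-number change probabilities
    q_sensitive: float = 0.02
    q_neutral: float = 0.15
    dup_fraction: float = 0.5   # changes split between one2many and none

    # CNV strata: counts and lognormal length medians (bp)
    n_benign_gain: int = 200
    n_benign_loss: int = 200
    n_path_gain: int = 100
    n_path_loss: int = 100
    benign_length_median: float = 30_000.0
    benign_length_sigma: float = 1.0
    path_length_median: float = 200_000.0
    path_length_sigma: float = 0.8

    targeting: float = 0.8   # P(pathogenic CNV anchored on a sensitive gene)
    avoidance: float = 0.8   # P(benign CNV placed avoiding sensitive genes)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dosage_sensitive", "q_sensitive", "q_neutral",
                     "dup_fraction", "targeting", "avoidance", "ancestral_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.path_length_median <= self.benign_length_median:
            raise ValueError("pathogenic mean length must exceed benign mean length")

    def null(self) -> "SimulationConfig":
        """Signal-off conditions: conservation independent of the latent
        class and CNV placement blind to it."""
        return replace(self, q_sensitive=self.q_neutral, targeting=0.0, avoidance=0.0)


def simulate_genome(config: SimulationConfig) -> tuple[GenomeBuild, list[GeneRecord]]:
    """Toy genome build plus a gene table with latent dosage sensitivity.

    Genes are placed without overlap, uniformly within each chromosome;
    attributes are drawn conditionally on the latent ``dosage_sensitive``
    flag (stored in ``flags`` so recovery tests can see the truth).
    """
    rng = np.random.default_rng(config.seed)
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    build = GenomeBuild(
        "synthetic", {c: config.chromosome_length for c in chroms}
    )
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes, rng)
    genes: list[GeneRecord] = []
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k * config.gene_length >= config.chromosome_length:
            raise ValueError("infeasible gene density")
        free = config.chromosome_length - k * config.gene_length
        gaps = np.diff(np.concatenate([[0.0], np.sort(rng.uniform(0, free, size=k))]))
        start = 0
        for gap in gaps:
            start += int(gap)
            sensitive = bool(rng.random() < config.frac_dosage_sensitive)
            flags = {
                "dosage_sensitive": sensitive,
                "developmental": bool(
                    rng.random()
                    < (config.dev_rate_sensitive if sensitive else config.dev_rate_neutral)
                ),
                "complex_member": bool(
                    rng.random()
                    < (config.complex_rate_sensitive if sensitive else config.complex_rate_neutral)
                ),
                "ohnologue": bool(
                    rng.random()
                    < (config.ohnologue_rate_sensitive if sensitive else config.ohnologue_rate_neutral)
                ),
                "omim_disease": bool(
                    rng.random()
                    < (config.omim_rate_sensitive if sensitive else config.omim_rate_neutral)
                ),
            }
            hi = float(rng.beta(2.0, 1.2) if sensitive else rng.beta(0.5, 5.0))
            expr = float(rng.lognormal(np.log(20.0) if sensitive else np.log(10.0), 1.2))
            idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"g{idx:05d}", chromosome=chrom,
                    start=start, end=start + config.gene_length,
                    strand="+" if rng.random() < 0.5 else "-",
                    flags=flags, hi_score=hi, max_expression=expr,
                    ancestral=bool(rng.random() < config.ancestral_rate),
                )
            )
            start += config.gene_length
    return build, genes


def simulate_orthology(
    genes: Sequence[GeneRecord], config: SimulationConfig
) -> list[OrthologyProfile]:
    """13-species orthology profiles, conditioned on latent sensitivity.

    Per gene per species an independent change event occurs with the
    class's q; a change is a duplication (one2many) with ``dup_fraction``
    probability, otherwise a loss (none).
    """
    rng = np.random.default_rng(config.seed + 1)
    profiles = []
    for g in genes:
        q = config.q_sensitive if g.flag("dosage_sensitive") else config.q_neutral
        statuses = {}
        for sp in MAMMAL_SPECIES:
            if rng.random() < q:
                statuses[sp] = (
                    OrthologyStatus.ONE2MANY
                    if rng.random() < config.dup_fraction
                    else OrthologyStatus.NONE
                )
            else:
                statuses[sp] = OrthologyStatus.ONE2ONE
        profiles.append(OrthologyProfile(unit_id=g.gene_id, statuses=statuses))
    return profiles


def simulate_cnvs(
    genes: Sequence[GeneRecord],
    build: GenomeBuild,
    config: SimulationConfig,
    max_retries: int = 200,
) -> list[CnvRecord]:
    """Benign/pathogenic gain/loss CNV strata with placement biases.

    Pathogenic CNVs are anchored to overlap a random dosage-sensitive gene
    with probability ``targeting``; benign CNVs are rejection-placed to
    avoid all sensitive genes with probability ``avoidance``. Lengths are
    lognormal, truncated to [50 bp, 0.1 x chromosome length].
    """
    rng = np.random.default_rng(config.seed + 2)
    chroms = sorted(build.chrom_lengths, key=int)
    weights = np.array([build.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    sensitive = [g for g in genes if g.flag("dosage_sensitive")]
    sensitive_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sensitive:
        sensitive_by_chrom.setdefault(g.chromosome, []).append(g)

    counts = {
        (Interpretation.BENIGN, CnvType.GAIN): config.n_benign_gain,
        (Interpretation.BENIGN, CnvType.LOSS): config.n_benign_loss,
        (Interpretation.PATHOGENIC, CnvType.GAIN): config.n_path_gain,
        (Interpretation.PATHOGENIC, CnvType.LOSS): config.n_path_loss,
    }
    out: list[CnvRecord] = []
    for (interp, ctype) in _STRATA:
        n = counts[(interp, ctype)]
        if interp is Interpretation.BENIGN:
            median, sigma = config.benign_length_median, config.benign_length_sigma
        else:
            median, sigma = config.path_length_median, config.path_length_sigma
        for i in range(n):
            cid = f"{interp.value[0]}_{ctype.value}_{i + 1:04d}"
            length_draw = rng.lognormal(np.log(median), sigma)
            if interp is Interpretation.PATHOGENIC and sensitive and rng.random() < config.targeting:
                chrom, start, length = _place_targeted(
                    rng, sensitive, build, length_draw
                )
            elif interp is Interpretation.BENIGN and rng.random() < config.avoidance:
                chrom, start, length = _place_avoiding(
                    rng, chroms, weights, build, length_draw,
                    sensitive_by_chrom, max_retries, cid,
                )
            else:
                chrom = str(rng.choice(chroms, p=weights))
                length = _truncate(length_draw, build.chrom_lengths[chrom])
                start = int(rng.integers(0, build.chrom_lengths[chrom] - length + 1))
            out.append(
                CnvRecord(
                    id=cid, chromosome=chrom, start=start, end=start + length,
                    cnv_type=ctype, interpretation=interp, study="synthetic",
                )
            )
    out.sort(key=lambda c: (int(c.chromosome), c.start, c.end, c.id))
    return out


def _truncate(length: float, chrom_length: int) -> int:
    return int(np.clip(length, 50, 0.1 * chrom_length))


def _place_targeted(rng, sensitive, build, length_draw):
    anchor = sensitive[int(rng.integers(len(sensitive)))]
    chrom_len = build.chrom_lengths[anchor.chromosome]
    length = _truncate(length_draw, chrom_len)
    lo = max(0, anchor.start - length + 1)
    hi = min(chrom_len - length, anchor.end - 1)
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, anchor.start)
    return anchor.chromosome, start, length


def _place_avoiding(rng, chroms, weights, build, length_draw,
                    sensitive_by_chrom, max_retries, cid):
    for _ in range(max_retries):
        chrom = str(rng.choice(chroms, p=weights))
        length = _truncate(length_draw, build.chrom_lengths[chrom])
        start = int(rng.integers(0, build.chrom_lengths[chrom] - length + 1))
        end = start + length
        hit = any(
            g.start < end and g.end > start
            for g in sensitive_by_chrom.get(chrom, [])
        )
        if not hit:
            return chrom, start, length
    raise RuntimeError(
        f"could not place benign CNV {cid} avoiding sensitive genes "
        f"after {max_retries} retries"
    )


def _split_counts(total: int, parts: int, rng) -> list[int]:
    base = total // parts
    counts = [base] * parts
    for i in rng.choice(parts, size=total - base * parts, replace=False):
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Flat-table writers so the simulator can feed the core_io readers


def write_simulated_tables(
    build: GenomeBuild,
    genes: Sequence[GeneRecord],
    profiles: Sequence[OrthologyProfile],
    cnvs: Sequence[CnvRecord],
    out_dir,
) -> dict[str, str]:
    """Write genes.tsv, orthology.tsv and cnvs.tsv (bed_like dialect) plus
    build.tsv into ``out_dir``; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out_dir / "build.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tlength\n")
        for c in sorted(build.chrom_lengths, key=int):
            fh.write(f"{c}\t{build.chrom_lengths[c]}\n")
    paths["build"] = str(p)

    p = out_dir / "genes.tsv"
    with open(p, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\tdevelopmental\tcomplex_member"
            "\tohnologue\tomim_disease\tdosage_sensitive\tancestral"
            "\thi_score\tmax_expression\n"
        )
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{int(g.flag('developmental'))}\t{int(g.flag('complex_member'))}\t"
                f"{int(g.flag('ohnologue'))}\t{int(g.flag('omim_disease'))}\t"
                f"{int(g.flag('dosage_sensitive'))}\t{int(g.ancestral)}\t"
                f"{g.hi_score:.6f}\t{g.max_expression:.4f}\n"
            )
    paths["genes"] = str(p)

    p = out_dir / "orthology.tsv"
    with open(p, "w") as fh:
        fh.write("human_gene\tspecies\tstatus\n")
        for prof in profiles:
            for sp, status in prof.statuses.items():
                if status is not OrthologyStatus.NONE:  # absence = none
                    fh.write(f"{prof.unit_id}\t{sp}\t{status.value}\n")
    paths["orthology"] = str(p)

    p = out_dir / "cnvs.tsv"
    with open(p, "w") as fh:
        fh.write("id\tchrom\tstart\tend\ttype\tinterpretation\tstudy\n")
        for c in cnvs:
            fh.write(
                f"{c.id}\t{c.chromosome}\t{c.start}\t{c.end}\t"
                f"{c.cnv_type.value}\t{c.interpretation.value}\t{c.study}\n"
            )
    paths["cnvs"] = str(p)
    return paths
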