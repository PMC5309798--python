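"""CNV location-randomization null and permutation summary.

The null model keeps every CNV's chromosome, length, type and
interpretation, and redraws its start uniformly from the placements that
fit on its chromosome. Randomization is within-chromosome so that
chromosome-level gene density is not confounded, and placed CNVs may
overlap each other. Assembly gaps and centromeres are not excluded
(documented limitation).

The permutation summary reports the observed statistic against the null
mean/sd/max, the normal-approximation Z score, and an add-one empirical p
value (p is never exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from dosagescope.classify import intersect_genes
from dosagescope.core_io import CnvRecord, GeneRecord, GenomeBuild


@dataclass(frozen=True)
class RandomizationResult:
    observed: float
    null_mean: float
    null_sd: float
    null_max: float
    z: float              # nan when null_sd == 0
    p_empirical: float    # (1 + #{null >= observed}) / (n_reps + 1)
    p_normal: float       # upper tail of the Z approximation
    n_reps: int
    seed: int

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z)


def randomize_cnv_locations(
    cnvs: Sequence[CnvRecord],
    build: GenomeBuild,
    seed: int | np.random.Generator,
) -> list[CnvRecord]:
    """Redraw each CNV's start uniformly on its own chromosome.

    Length, chromosome, type and interpretation are preserved; the new
    start is uniform on [0, L - len] inclusive, so a CNV spanning its whole
    chromosome keeps its original placement.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c in cnvs:
        chrom_len = build.chrom_lengths[c.chromosome]
        if c.length > chrom_len:
            raise ValueError(f"CNV {c.id} longer than chromosome {c.chromosome}")
        start = int(rng.integers(0, chrom_len - c.length + 1))
        out.append(replace(c, start=start, end=start + c.length))
    return out


def permutation_test(
    statistic: Callable[[Sequence[CnvRecord]], float],
    cnvs: Sequence[CnvRecord],
    build: GenomeBuild,
    n_reps: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Upper-tail permutation test of ``statistic`` under location
    randomization.

    ``statistic`` must be a pure function of a CNV set. Reproducible given
    ``seed``; when the null has zero spread Z is NaN and flagged via
    ``degenerate``.
    """
    from scipy import stats as sps

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(statistic(cnvs))
    null = np.empty(n_reps)
    for i in range(n_reps):
        null[i] = statistic(randomize_cnv_locations(cnvs, build, rng))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_reps > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p_emp = (1 + int((null >= observed).sum())) / (n_reps + 1)
    p_norm = float(sps.norm.sf(z)) if np.isfinite(z) else float("nan")
    return RandomizationResult(
        observed=observed, null_mean=null_mean, null_sd=null_sd,
        null_max=float(null.max()), z=float(z), p_empirical=p_emp,
        p_normal=p_norm, n_reps=n_reps, seed=seed if isinstance(seed, int) else -1,
    )


def fraction_with_flagged_gene(
    genes: Sequence[GeneRecord], flag_name: str
) -> Callable[[Sequence[CnvRecord]], float]:
    """Statistic: fraction of CNVs containing at least one flagged gene."""
    from bisect import bisect_right

    from dosagescope.regions import union_intervals

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.flag(flag_name):
            by_chrom.setdefault(g.chromosome, []).append(g.interval)
    merged = {c: union_intervals(ivs) for c, ivs in by_chrom.items()}
    starts = {c: [s for s, _ in ivs] for c, ivs in merged.items()}

    def stat(cnvs: Sequence[CnvRecord]) -> float:
        if not cnvs:
            return 0.0
        n_hit = 0
        for c in cnvs:
            ivs = merged.get(c.chromosome)
            if not ivs:
                continue
            i = bisect_right(starts[c.chromosome], c.end - 1) - 1
            n_hit += i >= 0 and ivs[i][1] > c.start
        return n_hit / len(cnvs)

    return stat


def fraction_flagged_genes_covered(
    genes: Sequence[GeneRecord], flag_name: str
) -> Callable[[Sequence[CnvRecord]], float]:
    """Statistic: fraction of flagged genes overlapped by >=1 CNV."""
    flagged = [g for g in genes if g.flag(flag_name)]

    def stat(cnvs: Sequence[CnvRecord]) -> float:
        if not flagged:
            return 0.0
        hits = intersect_genes(flagged, cnvs)
        return sum(hits.values()) / len(flagged)

    return stat
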