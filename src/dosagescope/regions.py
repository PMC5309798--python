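"""CNVR merging, coverage step-functions and local-maximum peak regions.

A CNV region (CNVR) is the union interval of a maximal set of mutually
overlap-connected CNVs that share a clinical interpretation (and, for typed
scopes, a CNV type). Coverage over a CNVR is the step function counting the
member CNVs overlapping each base. A peak region is a maximal constant-depth
plateau whose two neighbouring depths (zero beyond the CNVR ends) are both
strictly lower — a proxy for the recurrently affected "critical region" of a
pathogenic locus. Where a CNVR has a single member, the whole CNV is its
peak (depth 1).

Abutting (end == start) CNVs are merged into one CNVR, matching the default
of the standard interval-merge tooling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from dosagescope.core_io import CnvRecord, CnvType, GenomeBuild, Interpretation


class Scope(str, enum.Enum):
    """Which CNV types are merged together: gains and losses jointly
    (grouped) or each type separately."""

    GROUPED = "grouped"
    GAIN_ONLY = "gain_only"
    LOSS_ONLY = "loss_only"


@dataclass(frozen=True)
class CnvRegion:
    region_id: str
    chromosome: str
    start: int
    end: int
    members: tuple[CnvRecord, ...]
    scope: Scope
    interpretation: Interpretation

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class CoverageProfile:
    """Step function of CNV coverage tiling one CNVR.

    ``segments`` are contiguous (start, end, depth) runs; adjacent runs have
    different depths, and sum(depth * length) equals the summed member CNV
    lengths.
    """

    region_id: str
    chromosome: str
    segments: tuple[tuple[int, int, int], ...]


@dataclass(frozen=True)
class PeakRegion:
    peak_id: str
    region_id: str
    chromosome: str
    start: int
    end: int
    depth: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Interval primitives


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; abutting intervals are joined."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for start, end in ivs:
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def merge_cnvrs(cnvs: Sequence[CnvRecord], scope: Scope | str = Scope.GROUPED) -> list[CnvRegion]:
    """Group overlap-connected CNVs of one interpretation into CNVRs.

    For ``gain_only``/``loss_only`` scopes only CNVs of that type are merged;
    ``grouped`` merges both types together. Region ids are deterministic,
    ordered by (chromosome, start).
    """
    scope = Scope(scope)
    interpretations = {c.interpretation for c in cnvs}
    if len(interpretations) > 1:
        raise ValueError("merge_cnvrs requires CNVs of a single interpretation")
    if scope is Scope.GAIN_ONLY:
        cnvs = [c for c in cnvs if c.cnv_type is CnvType.GAIN]
    elif scope is Scope.LOSS_ONLY:
        cnvs = [c for c in cnvs if c.cnv_type is CnvType.LOSS]
    if not cnvs:
        return []
    interpretation = cnvs[0].interpretation
    by_chrom: dict[str, list[CnvRecord]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.chromosome, []).append(c)

    regions: list[CnvRegion] = []
    for chrom in sorted(by_chrom, key=lambda c: int(c)):
        chrom_cnvs = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.id))
        component: list[CnvRecord] = []
        comp_end = -1
        for c in chrom_cnvs:
            if component and c.start > comp_end:  # bookended (==) stays merged
                regions.append(_close_region(component, chrom, scope, interpretation))
                component = []
            component.append(c)
            comp_end = max(comp_end, c.end)
        if component:
            regions.append(_close_region(component, chrom, scope, interpretation))

    tag = {Scope.GROUPED: "cnvr", Scope.GAIN_ONLY: "cnvr_gain", Scope.LOSS_ONLY: "cnvr_loss"}[scope]
    prefix = interpretation.value[0]  # b / p
    return [
        CnvRegion(
            region_id=f"{prefix}_{tag}_{i + 1:04d}",
            chromosome=r.chromosome, start=r.start, end=r.end,
            members=r.members, scope=scope, interpretation=interpretation,
        )
        for i, r in enumerate(regions)
    ]


def _close_region(
    component: list[CnvRecord], chrom: str, scope: Scope, interpretation: Interpretation
) -> CnvRegion:
    return CnvRegion(
        region_id="", chromosome=chrom,
        start=min(c.start for c in component),
        end=max(c.end for c in component),
        members=tuple(component), scope=scope, interpretation=interpretation,
    )


def coverage_profile(region: CnvRegion) -> CoverageProfile:
    """Coverage step function over a CNVR from its members' endpoints."""
    if not region.members:
        raise ValueError(f"region {region.region_id} has no members")
    events: dict[int, int] = {}
    for m in region.members:
        events[m.start] = events.get(m.start, 0) + 1
        events[m.end] = events.get(m.end, 0) - 1
    positions = sorted(events)
    segments: list[tuple[int, int, int]] = []
    depth = 0
    for pos, nxt in zip(positions, positions[1:]):
        depth += events[pos]
        if depth > 0:
            if segments and segments[-1][2] == depth and segments[-1][1] == pos:
                segments[-1] = (segments[-1][0], nxt, depth)
            else:
                segments.append((pos, nxt, depth))
    return CoverageProfile(
        region_id=region.region_id, chromosome=region.chromosome,
        segments=tuple(segments),
    )


def find_peak_regions(profile: CoverageProfile) -> list[PeakRegion]:
    """Local maxima of the coverage step function.

    A peak is a maximal constant-depth plateau strictly higher than both
    neighbouring depths; depth beyond the CNVR ends is taken as 0, so the
    single segment of a one-CNV region is always a peak (the entire CNV).
    """
    segs = profile.segments
    peaks: list[PeakRegion] = []
    n = len(segs)
    for i, (start, end, depth) in enumerate(segs):
        left = segs[i - 1][2] if i > 0 else 0
        right = segs[i + 1][2] if i < n - 1 else 0
        if depth > left and depth > right:
            peaks.append(
                PeakRegion(
                    peak_id=f"{profile.region_id}_peak{len(peaks) + 1}",
                    region_id=profile.region_id, chromosome=profile.chromosome,
                    start=start, end=end, depth=depth,
                )
            )
    return peaks


def genome_fraction(
    intervals: Iterable[tuple[str, int, int]], build: GenomeBuild
) -> float:
    """Fraction of the build covered by the union of (chrom, start, end)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if chrom not in build.chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} not in build {build.name}")
        if end > build.chrom_lengths[chrom]:
            raise ValueError(f"interval ({chrom},{start},{end}) beyond chromosome end")
        by_chrom.setdefault(chrom, []).append((start, end))
    covered = sum(
        e - s for ivs in by_chrom.values() for s, e in union_intervals(ivs)
    )
    return covered / build.total_length


def region_overlap(
    a: Iterable[tuple[str, int, int]], b: Iterable[tuple[str, int, int]]
) -> tuple[int, float]:
    """Base-pair overlap between two interval sets and the fraction of
    union(a) overlapped: (bp_overlap, bp_overlap / |union(a)|)."""
    ua = _union_by_chrom(a)
    ub = _union_by_chrom(b)
    total_a = sum(e - s for ivs in ua.values() for s, e in ivs)
    if total_a == 0:
        raise ValueError("union(a) is empty; overlap fraction undefined")
    bp = 0
    for chrom, ivs_a in ua.items():
        ivs_b = ub.get(chrom, [])
        bp += _intersect_length(ivs_a, ivs_b)
    return bp, bp / total_a


def _union_by_chrom(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    return {c: union_intervals(ivs) for c, ivs in by_chrom.items()}


def _intersect_length(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    i = j = bp = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            bp += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return bp
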