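"""Gene-CNV intersection and dosage-class assignment.

Genes are assigned to dosage classes by which CNV strata overlap them:
full benign CNVs (gain and loss separately) and pathogenic *peak regions*
(gain and loss separately). Benign calls are taken whole because the entire
region is presumed benign; pathogenic calls are refined to their coverage
peaks first.

Classes:

* **B** — overlapped only by benign CNVs: presumed dosage tolerant.
* **P** — overlapped only by pathogenic peak regions: candidate
  dosage-sensitive genes.
* **X** — in both a benign and a pathogenic CNV of the same type
  (gain or loss): likely passengers.
* **BL_PG** — exactly benign-loss + pathogenic-gain (and nothing else):
  candidate genes deleterious only at increased dosage.
* **BG_PL** — exactly benign-gain + pathogenic-loss: candidate
  haploinsufficient genes.
* **unclassified** — in no CNV at all.

A gene intersects an interval if one or more bases overlap, on either
strand.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from dosagescope.core_io import GeneRecord
from dosagescope.regions import union_intervals


class GeneClass(str, enum.Enum):
    B = "B"
    P = "P"
    X = "X"
    BL_PG = "BL_PG"
    BG_PL = "BG_PL"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneClassAssignment:
    gene_id: str
    in_benign_gain: bool
    in_benign_loss: bool
    in_path_gain_peak: bool
    in_path_loss_peak: bool
    label: GeneClass

    @property
    def membership(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.in_benign_gain, self.in_benign_loss,
            self.in_path_gain_peak, self.in_path_loss_peak,
        )


@dataclass(frozen=True)
class SolitaryCall:
    """Class P genes overlapping one pathogenic region; solitary when
    exactly one — the prime disease-gene candidate for that region."""

    region_id: str
    class_p_gene_ids: tuple[str, ...]

    @property
    def solitary(self) -> bool:
        return len(self.class_p_gene_ids) == 1


def _as_intervals(intervals: Iterable) -> list[tuple[str, int, int]]:
    """Accept (chrom,start,end[,...]) tuples or objects with
    chromosome/start/end attributes (CnvRecord, CnvRegion, PeakRegion)."""
    out = []
    for iv in intervals:
        if isinstance(iv, tuple):
            out.append((str(iv[0]), int(iv[1]), int(iv[2])))
        else:
            out.append((iv.chromosome, iv.start, iv.end))
    return out


def intersect_genes(
    genes: Sequence[GeneRecord], intervals: Iterable
) -> dict[str, bool]:
    """True per gene iff >=1 bp of the gene overlaps the interval set."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in _as_intervals(intervals):
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {c: union_intervals(ivs) for c, ivs in by_chrom.items()}
    starts = {c: [s for s, _ in ivs] for c, ivs in merged.items()}
    result: dict[str, bool] = {}
    for g in genes:
        ivs = merged.get(g.chromosome)
        if not ivs:
            result[g.gene_id] = False
            continue
        # candidate: last union interval starting before the gene end
        i = bisect_right(starts[g.chromosome], g.end - 1) - 1
        result[g.gene_id] = i >= 0 and ivs[i][1] > g.start
    return result


def classify_membership(
    in_benign_gain: bool, in_benign_loss: bool,
    in_path_gain_peak: bool, in_path_loss_peak: bool,
) -> GeneClass:
    """The membership -> class truth table.

    Same-type benign+pathogenic co-membership dominates (Class X); the
    cross-type combinations require exactly the stated pair and nothing
    else, which follows because any third membership creates a same-type
    pair.
    """
    bg, bl, pg, pl = in_benign_gain, in_benign_loss, in_path_gain_peak, in_path_loss_peak
    benign = bg or bl
    path = pg or pl
    if not benign and not path:
        return GeneClass.UNCLASSIFIED
    if (bg and pg) or (bl and pl):
        return GeneClass.X
    if benign and not path:
        return GeneClass.B
    if path and not benign:
        return GeneClass.P
    # mixed without a same-type pair: exactly one benign + one pathogenic,
    # of opposite types
    if bl and pg:
        return GeneClass.BL_PG
    return GeneClass.BG_PL


def assign_classes(
    genes: Sequence[GeneRecord],
    benign_gain_cnvs: Iterable,
    benign_loss_cnvs: Iterable,
    path_gain_peaks: Iterable,
    path_loss_peaks: Iterable,
) -> list[GeneClassAssignment]:
    """Assign every gene a dosage class from its CNV overlap pattern.

    Benign inputs are full CNVs; pathogenic inputs are peak regions.
    """
    memberships = [
        intersect_genes(genes, stratum)
        for stratum in (benign_gain_cnvs, benign_loss_cnvs, path_gain_peaks, path_loss_peaks)
    ]
    out = []
    for g in genes:
        bg, bl, pg, pl = (m[g.gene_id] for m in memberships)
        out.append(
            GeneClassAssignment(
                gene_id=g.gene_id,
                in_benign_gain=bg, in_benign_loss=bl,
                in_path_gain_peak=pg, in_path_loss_peak=pl,
                label=classify_membership(bg, bl, pg, pl),
            )
        )
    return out


def find_solitary(
    regions: Sequence,
    assignments: Sequence[GeneClassAssignment],
    genes: Sequence[GeneRecord],
) -> list[SolitaryCall]:
    """Per pathogenic region (peak or CNVR), the Class P genes it overlaps.

    A region with exactly one Class P gene is a solitary call: the single
    candidate causative gene for that region.
    """
    p_ids = {a.gene_id for a in assignments if a.label is GeneClass.P}
    p_genes = [g for g in genes if g.gene_id in p_ids]
    calls = []
    for region in regions:
        if isinstance(region, tuple):
            region_id = f"{region[0]}:{region[1]}-{region[2]}"
        else:
            region_id = getattr(region, "peak_id", None) or region.region_id
        hits = intersect_genes(p_genes, [region])
        ids = tuple(sorted(gid for gid, hit in hits.items() if hit))
        calls.append(SolitaryCall(region_id=region_id, class_p_gene_ids=ids))
    return calls


def unique_solitary_genes(calls: Iterable[SolitaryCall]) -> set[str]:
    return {c.class_p_gene_ids[0] for c in calls if c.solitary}


def solitary_in_both(
    gain_calls: Iterable[SolitaryCall], loss_calls: Iterable[SolitaryCall]
) -> set[str]:
    """Genes that are the solitary Class P gene of both a gain region and a
    loss region."""
    return unique_solitary_genes(gain_calls) & unique_solitary_genes(loss_calls)


def annotation_fraction_per_cnv(
    cnv_or_region, genes: Sequence[GeneRecord], flag_name: str
) -> float | None:
    """Fraction of overlapped genes carrying ``flag_name``.

    None when the interval overlaps no gene: a gene-empty CNV has no defined
    proportion and is excluded from downstream medians rather than scored 0.
    """
    _check_flag(genes, flag_name)
    hits = intersect_genes(genes, [cnv_or_region])
    overlapped = [g for g in genes if hits[g.gene_id]]
    if not overlapped:
        return None
    return sum(g.flag(flag_name) for g in overlapped) / len(overlapped)


def distance_to_nearest_flagged(
    gene: GeneRecord, genes: Sequence[GeneRecord], flag_name: str
) -> int | None:
    """Gap in bp to the nearest same-chromosome gene carrying ``flag_name``;
    0 when one overlaps the query; None when none exists on the chromosome."""
    _check_flag(genes, flag_name)
    best: int | None = None
    for other in genes:
        if other.chromosome != gene.chromosome or not other.flag(flag_name):
            continue
        if other.gene_id == gene.gene_id:
            return 0
        gap = max(other.start - gene.end, gene.start - other.end, 0)
        if other.start < gene.end and other.end > gene.start:
            gap = 0
        best = gap if best is None else min(best, gap)
        if best == 0:
            return 0
    return best


def _check_flag(genes: Sequence[GeneRecord], flag_name: str) -> None:
    known = {name for g in genes for name in g.flags}
    if genes and known and flag_name not in known:
        raise KeyError(f"unknown gene flag {flag_name!r}; known flags: {sorted(known)}")
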