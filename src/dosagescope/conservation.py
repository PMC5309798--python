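"""Copy-number conservation of human genes across 13 mammalian genomes.

For each human gene inferred present in the mammalian common ancestor, the
orthology status in each surveyed genome is tallied as unchanged (one2one),
duplicated (one2many) or missing (none). A gene is *conserved* when its copy
number is unchanged in all 13 genomes — the evolutionary signature of
persistent dosage constraint.

Genes duplicated on the human lineage since the mammalian divergence would
otherwise count every non-sharing genome as changed, so recent human
in-paralogues are first grouped into a single unit whose ancestral copy
number of 1 is compared with each other species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dosagescope.classify import GeneClassAssignment
from dosagescope.core_io import OrthologyProfile, OrthologyStatus


@dataclass(frozen=True)
class ConservationSummary:
    unit_id: str
    n_unchanged: int
    n_duplicated: int
    n_missing: int

    def __post_init__(self) -> None:
        total = self.n_unchanged + self.n_duplicated + self.n_missing
        if total != 13:
            raise ValueError(
                f"{self.unit_id}: species tallies sum to {total}, expected 13"
            )

    @property
    def conserved(self) -> bool:
        return self.n_unchanged == 13


def group_recent_paralogues(
    profiles: Sequence[OrthologyProfile],
    human_paralogy: Mapping[str, str],
) -> list[OrthologyProfile]:
    """Collapse recent human in-paralogues into single ancestral units.

    ``human_paralogy`` maps gene ids to paralogue-group ids; genes absent
    from the map remain singleton units (the mapping cannot place a gene in
    two groups, so that error mode is excluded by construction). Statuses
    carry no orthologue identities, so a group's per-species status is
    aggregated by severity: any member one2many -> one2many, else any member
    one2one -> one2one (the shared single orthologue), else none.
    """
    grouped: dict[str, list[OrthologyProfile]] = {}
    singletons: list[OrthologyProfile] = []
    for p in profiles:
        gid = human_paralogy.get(p.unit_id)
        if gid is None:
            singletons.append(p)
        else:
            grouped.setdefault(gid, []).append(p)

    out = list(singletons)
    for gid in sorted(grouped):
        members = grouped[gid]
        species = list(members[0].statuses)
        statuses = {}
        for sp in species:
            member_statuses = {m.statuses[sp] for m in members}
            if OrthologyStatus.ONE2MANY in member_statuses:
                statuses[sp] = OrthologyStatus.ONE2MANY
            elif OrthologyStatus.ONE2ONE in member_statuses:
                statuses[sp] = OrthologyStatus.ONE2ONE
            else:
                statuses[sp] = OrthologyStatus.NONE
        out.append(
            OrthologyProfile(
                unit_id=gid, statuses=statuses,
                group_members=tuple(m.unit_id for m in members),
            )
        )
    out.sort(key=lambda p: p.unit_id)
    return out


def summarize_profile(profile: OrthologyProfile) -> ConservationSummary:
    """Tally the three per-species statuses of one ancestral unit."""
    values = list(profile.statuses.values())
    return ConservationSummary(
        unit_id=profile.unit_id,
        n_unchanged=sum(s is OrthologyStatus.ONE2ONE for s in values),
        n_duplicated=sum(s is OrthologyStatus.ONE2MANY for s in values),
        n_missing=sum(s is OrthologyStatus.NONE for s in values),
    )


def conserved_gene_set(summaries: Iterable[ConservationSummary]) -> set[str]:
    """Units with copy number unchanged in all 13 genomes."""
    return {s.unit_id for s in summaries if s.conserved}


def conservation_by_class(
    summaries: Sequence[ConservationSummary],
    assignments: Sequence[GeneClassAssignment],
) -> pd.DataFrame:
    """Per-dosage-class distribution summaries of the conservation tallies.

    Returns one row per class present, with n, medians and quartiles of
    n_unchanged / n_duplicated / n_missing and the count of fully conserved
    genes — the inputs to the scale-variance (Fligner-Killeen) and
    chi-square comparisons. Classes with no scored gene are omitted.
    """
    by_id = {s.unit_id: s for s in summaries}
    rows = []
    labels = sorted({a.label for a in assignments}, key=lambda l: l.value)
    for label in labels:
        scored = [by_id[a.gene_id] for a in assignments
                  if a.label is label and a.gene_id in by_id]
        if not scored:
            continue
        unchanged = np.array([s.n_unchanged for s in scored])
        rows.append({
            "label": label.value,
            "n": len(scored),
            "n_conserved": int(sum(s.conserved for s in scored)),
            "unchanged_median": float(np.median(unchanged)),
            "unchanged_q1": float(np.percentile(unchanged, 25)),
            "unchanged_q3": float(np.percentile(unchanged, 75)),
            "unchanged_var": float(np.var(unchanged, ddof=1)) if len(scored) > 1 else 0.0,
            "duplicated_median": float(np.median([s.n_duplicated for s in scored])),
            "missing_median": float(np.median([s.n_missing for s in scored])),
        })
    return pd.DataFrame(rows)


def unchanged_by_class(
    summaries: Sequence[ConservationSummary],
    assignments: Sequence[GeneClassAssignment],
) -> dict[str, np.ndarray]:
    """Raw per-class n_unchanged samples, for the scale and rank tests."""
    by_id = {s.unit_id: s for s in summaries}
    out: dict[str, list[int]] = {}
    for a in assignments:
        s = by_id.get(a.gene_id)
        if s is not None:
            out.setdefault(a.label.value, []).append(s.n_unchanged)
    return {k: np.asarray(v) for k, v in out.items()}
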