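"""Enrichment statistics for the dosage-class comparisons.

Pearson chi-square with per-cell adjusted residuals, two-sided
Mann-Whitney U, Fligner-Killeen scale test, Bonferroni correction, and
upper-tail hypergeometric term enrichment against a custom background.

No Yates continuity correction is applied: the +/-2 adjusted-residual
convention presumes the uncorrected Pearson form. Bonferroni family sizes
are echoed in every emitted table so the correction is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from dosagescope.classify import GeneClassAssignment
from dosagescope.core_io import GeneRecord


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int            # query hits
    n: int            # query size
    K: int            # background hits
    N: int            # background size
    p_raw: float
    p_bonferroni: float


def chi2_with_residuals(table) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) with adjusted residuals.

    The adjusted residual of a cell is
    (obs - exp) / sqrt(exp * (1 - row_total/N) * (1 - col_total/N));
    cells with |residual| > 2 are the ones driving a significant table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total")
    total = obs.sum()
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    adj = (obs - expected) / np.sqrt(
        expected * (1 - row / total)[:, None] * (1 - col / total)[None, :]
    )
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p=float(p),
        expected=expected, adjusted_residuals=adj,
    )


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return float(x.size * y.size / 2), 1.0
    u, p = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(u), float(p)


def fligner_killeen(*groups) -> tuple[float, float]:
    """Fligner-Killeen rank-based test for equal scale across groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(np.unique(a).size == 1 for a in arrays):
        raise ValueError("all groups degenerate (zero spread)")
    stat, p = sps.fligner(*arrays)
    return float(stat), float(p)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def hypergeom_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the query,
    against a custom background gene list.

    Term gene sets are intersected with the background first; the Bonferroni
    family size is the number of terms actually tested (those with at least
    one background gene).
    """
    query_set = set(query)
    background_set = set(background)
    missing = query_set - background_set
    if missing:
        raise ValueError(f"query gene(s) absent from background: {sorted(missing)[:5]}")
    N = len(background_set)
    n = len(query_set)
    tested = []
    for term, members in term_map.items():
        hits_bg = set(members) & background_set
        if not hits_bg:
            continue
        K = len(hits_bg)
        k = len(hits_bg & query_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, n, K, N, p))
    m = len(tested)
    return [
        EnrichmentResult(term=t, k=k, n=n_, K=K, N=N_, p_raw=p,
                         p_bonferroni=bonferroni(p, m))
        for t, k, n_, K, N_, p in sorted(tested, key=lambda r: (r[5], r[0]))
    ]


# ---------------------------------------------------------------------------
# The per-class enrichment battery


_FLAG_ROWS = ("developmental", "complex_member", "ohnologue")
_CLASS_ORDER = ("B", "P", "X", "BL_PG", "BG_PL")


def class_enrichment_table(
    genes: Sequence[GeneRecord],
    assignments: Sequence[GeneClassAssignment],
    hi_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-dosage-class enrichment battery.

    One row per attribute: percentage (and count) of genes per class
    carrying each binary flag, with the chi-square p over the class-by-flag
    table and the adjusted residual per class; plus the haploinsufficient
    subset (hi_score > ``hi_threshold``) and the per-class medians of
    hi_score and maximal expression with the Class B vs Class P
    Mann-Whitney p. Chi-square p values are Bonferroni-corrected over the
    number of chi-square rows emitted.
    """
    by_id = {g.gene_id: g for g in genes}
    members: dict[str, list[GeneRecord]] = {}
    for a in assignments:
        if a.label.value in _CLASS_ORDER:
            members.setdefault(a.label.value, []).append(by_id[a.gene_id])
    classes = [c for c in _CLASS_ORDER if members.get(c)]
    if len(classes) < 2:
        raise ValueError("need at least two populated classes")

    rows = []
    chi_rows = []
    for flag in _FLAG_ROWS:
        counts = np.array(
            [[sum(g.flag(flag) for g in members[c]),
              sum(not g.flag(flag) for g in members[c])] for c in classes]
        )
        chi_rows.append((flag, counts))
    hi_counts = np.array(
        [[sum(1 for g in members[c] if (g.hi_score or 0) > hi_threshold),
          sum(1 for g in members[c] if (g.hi_score or 0) <= hi_threshold)]
         for c in classes]
    )
    chi_rows.append(("haploinsufficient", hi_counts))

    m = len(chi_rows)
    for name, counts in chi_rows:
        try:
            res = chi2_with_residuals(counts)
            p_corr = bonferroni(res.p, m)
            residuals = res.adjusted_residuals[:, 0]
        except ValueError:  # zero marginal (e.g. no flagged genes at all)
            p_corr = float("nan")
            residuals = np.full(len(classes), np.nan)
        row = {"attribute": name, "p_chi2_bonferroni": p_corr, "m_bonferroni": m}
        for i, c in enumerate(classes):
            total = counts[i].sum()
            row[f"{c}_pct"] = 100.0 * counts[i, 0] / total if total else float("nan")
            row[f"{c}_count"] = int(counts[i, 0])
            row[f"{c}_adj_residual"] = float(residuals[i])
        rows.append(row)

    for attr, getter in (
        ("hi_score_median", lambda g: g.hi_score),
        ("max_expression_median", lambda g: g.max_expression),
    ):
        row = {"attribute": attr, "m_bonferroni": m}
        samples = {
            c: np.array([getter(g) for g in members[c] if getter(g) is not None])
            for c in classes
        }
        for c in classes:
            row[f"{c}_median"] = (
                float(np.median(samples[c])) if samples[c].size else float("nan")
            )
        if samples.get("B", np.array([])).size and samples.get("P", np.array([])).size:
            _, p = mann_whitney(samples["B"], samples["P"])
            row["p_mwu_B_vs_P"] = p
        rows.append(row)
    return pd.DataFrame(rows)
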