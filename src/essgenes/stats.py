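"""Hypothesis tests and multiple-testing machinery for 2×2 contrasts.

The Fisher exact test here is computed with exact integer arithmetic: the
two-sided p-value is the sum, over all tables with the observed margins, of
hypergeometric probabilities no larger than the observed one, with the
"no larger" comparison made between integer pmf numerators so that ties are
resolved exactly rather than to floating-point noise. Chi-square delegates to
scipy. The Benjamini–Hochberg step-up adjustment is implemented directly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classify import ClassifiedGeneTable, Group
from .io import AnnotationTable

TableLike = Sequence[Sequence[int]]


def _check_2x2(table: TableLike) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    cells = (int(a), int(b), int(c), int(d))
    if any(x != y for x, y in zip(cells, (a, b, c, d))):
        raise ValueError("2x2 table entries must be integers")
    if any(x < 0 for x in cells):
        raise ValueError("2x2 table entries must be non-negative")
    return cells


def odds_ratio_2x2(table: TableLike) -> float:
    """ad/bc; inf when only bc is zero, nan when the ratio is 0/0."""
    a, b, c, d = _check_2x2(table)
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_2x2(table: TableLike) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2×2 table.

    Returns ``(odds_ratio, p)``. The p-value is conditional on both margins:
    p = P(tables at least as unlikely as the observed one), computed by
    enumerating the hypergeometric support with integer binomial
    coefficients, so the result is exact to float rounding of one division.
    """
    a, b, c, d = _check_2x2(table)
    row1, col1 = a + b, a + c
    n = a + b + c + d
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        # a degenerate margin admits a single table
        return odds_ratio_2x2(table), 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    obs = math.comb(row1, a) * math.comb(n - row1, col1 - a)
    tail = 0
    for k in range(lo, hi + 1):
        num = math.comb(row1, k) * math.comb(n - row1, col1 - k)
        if num <= obs:
            tail += num
    p = tail / math.comb(n, col1)
    return odds_ratio_2x2(table), min(1.0, p)


def chi_square_2x2(table: TableLike, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on 1 df, optionally Yates-corrected.

    Large-count contrasts (e.g. genome-wide housekeeping rates) use this;
    expected counts must all be positive, otherwise use :func:`fisher_2x2`.
    """
    a, b, c, d = _check_2x2(table)
    arr = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected count in chi-square; use fisher_2x2 instead")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    return float(stat), float(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q(i) = min_{j >= i} p(j)·m/j over the ascending ordering, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


class Direction(str, enum.Enum):
    OVER = "over"
    UNDER = "under"
    NONE = "none"


@dataclass
class EnrichmentResult:
    """One group-vs-background 2×2 test for a single annotation term."""

    group: str
    term: str
    table: list[list[int]]
    odds_ratio: float
    p_raw: float
    q_bh: float = math.nan
    direction: Direction = Direction.NONE


def _direction(odds: float) -> Direction:
    if math.isnan(odds) or odds == 1.0:
        return Direction.NONE
    return Direction.OVER if odds > 1.0 else Direction.UNDER


def class_term_enrichment(
    classified: ClassifiedGeneTable,
    annotations: AnnotationTable,
    groups: Iterable[Group],
    background: str = "all_disease",
) -> list[EnrichmentResult]:
    """Test every (group, term) pair for over/under-representation.

    For each term, the 2×2 contrasts group members against the background
    minus the group, by term presence. The gene universe is restricted to
    genes carrying at least one annotation in this namespace (annotation
    coverage is partial, and unannotated genes are uninformative about term
    composition). BH adjustment is applied per (namespace × group) family.

    ``background`` is ``all_disease`` (the default: contrasts within the
    disease gene set, as for disease-class and compartment profiles) or
    ``all_genes`` (genome-style contrasts).
    """
    if background == "all_disease":
        bg_genes = classified.disease_genes()
    elif background == "all_genes":
        bg_genes = set(classified.groups)
    else:
        raise ValueError(f"unknown background '{background}'")
    universe = bg_genes & set(annotations.entries)
    if not universe:
        raise ValueError("empty background: no background gene carries annotations in this namespace")

    terms = sorted(annotations.terms())
    results: list[EnrichmentResult] = []
    for group in groups:
        members = classified.members(group) & universe
        rest = universe - members
        if not rest:
            raise ValueError(f"group {group.value} equals the background; no valid contrast")
        group_results: list[EnrichmentResult] = []
        for term in terms:
            with_term = annotations.genes_with(term)
            a = len(members & with_term)
            b = len(members) - a
            c = len(rest & with_term)
            d = len(rest) - c
            odds, p = fisher_2x2([[a, b], [c, d]])
            group_results.append(
                EnrichmentResult(group.value, term, [[a, b], [c, d]], odds, p, direction=_direction(odds))
            )
        qs = bh_adjust([r.p_raw for r in group_results])
        for r, q in zip(group_results, qs):
            r.q_bh = q
        results.extend(group_results)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]):
    """Enrichment results as a DataFrame in the report column order."""
    import pandas as pd

    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "term": [r.term for r in results],
            "a": [r.table[0][0] for r in results],
            "b": [r.table[0][1] for r in results],
            "c": [r.table[1][0] for r in results],
            "d": [r.table[1][1] for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_raw": [r.p_raw for r in results],
            "q_bh": [r.q_bh for r in results],
            "direction": [r.direction.value for r in results],
        }
    )
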