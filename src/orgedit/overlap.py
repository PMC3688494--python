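"""Cross-factor overlap analysis of editing-site classifications.

Once every site is labelled dependent/independent for each editing factor,
this module counts the Venn regions of up to three factors, reports shared
percentages (e.g. "112/127 or 88% of the sites controlled by one factor are
also controlled by another"), and tests whether two factors act
independently with a chi-square on the joint dependent/independent 2x2
table, reporting the observed versus expected-under-independence counts.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import pandas as pd

from .differential import (DEPENDENT, EXCLUDED, INDEPENDENT, ContingencyTest,
                           chisq_2x2, round_half_up)


def classification_matrix(
    classifications: dict[str, dict], sites: Sequence | None = None
) -> pd.DataFrame:
    """Assemble a sites x factors label matrix.

    ``classifications[factor]`` maps site -> label in
    {dependent, independent, excluded}; sites missing for a factor are
    marked excluded for it.
    """
    factors = list(classifications)
    if sites is None:
        sites = sorted({s for by in classifications.values() for s in by},
                       key=str)
    data = {
        f: [classifications[f].get(s, EXCLUDED) for s in sites]
        for f in factors
    }
    return pd.DataFrame(data, index=list(sites))


def _analyzed(matrix: pd.DataFrame, factors: Sequence[str]) -> pd.DataFrame:
    """Listwise-drop sites excluded for any of the requested factors."""
    sub = matrix[list(factors)]
    return sub[(sub != EXCLUDED).all(axis=1)]


def venn_counts(
    matrix: pd.DataFrame, factors: Sequence[str]
) -> dict[frozenset, int]:
    """Counts of the 2^k dependent-membership regions over analyzed sites.

    Region keys are frozensets of the factors a site is dependent for; the
    empty frozenset is the sites dependent for none.  Counts partition the
    analyzed (non-excluded) site set.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 3:
        raise ValueError("venn_counts supports 1 to 3 factors")
    if any(f not in matrix.columns for f in factors):
        raise KeyError("factor missing from classification matrix")
    sub = _analyzed(matrix, factors)
    counts = {frozenset(r): 0
              for k in range(len(factors) + 1)
              for r in _subsets(factors, k)}
    for _, row in sub.iterrows():
        region = frozenset(f for f in factors if row[f] == DEPENDENT)
        counts[region] += 1
    return counts


def _subsets(items: Sequence[str], k: int):
    from itertools import combinations
    return combinations(items, k)


def overlap_percentage(shared: int, total: int) -> int:
    """Integer percentage (round half up) of shared over total sites."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * shared / total)


def factor_independence_test(
    matrix: pd.DataFrame, factor_a: str, factor_b: str
) -> tuple[ContingencyTest, pd.DataFrame]:
    """Chi-square test of independence between two factors' effects.

    Builds the 2x2 table of joint dependent/independent memberships over
    sites classified for both factors and applies the shared Pearson
    statistic.  Returns the test plus a table of observed and
    expected-under-independence counts per cell, which exposes e.g. an
    excess of sites controlled by both factors.
    """
    sub = _analyzed(matrix, [factor_a, factor_b])
    cells = {}
    for la, lb in product((DEPENDENT, INDEPENDENT), repeat=2):
        cells[(la, lb)] = int(
            ((sub[factor_a] == la) & (sub[factor_b] == lb)).sum()
        )
    test = chisq_2x2(
        cells[(DEPENDENT, DEPENDENT)], cells[(DEPENDENT, INDEPENDENT)],
        cells[(INDEPENDENT, DEPENDENT)], cells[(INDEPENDENT, INDEPENDENT)],
    )
    n = len(sub)
    rows = []
    for la, lb in product((DEPENDENT, INDEPENDENT), repeat=2):
        row_total = (sub[factor_a] == la).sum()
        col_total = (sub[factor_b] == lb).sum()
        expected = row_total * col_total / n if n else float("nan")
        rows.append({
            factor_a: la, factor_b: lb,
            "observed": cells[(la, lb)], "expected": expected,
        })
    return test, pd.DataFrame(rows)
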