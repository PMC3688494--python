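"""Differential editing-extent analysis between genotypes.

The effect of losing an editing factor at a site is measured on C/T read
counts.  Biological replicates are pooled by summing counts, extents are
computed from the pooled counts, and the difference in editing proportion
between two genotypes is tested with a Pearson chi-square on the 2x2 table
(1 df, no continuity correction).  Familywise error is controlled with a
Bonferroni correction: a familywise rate of 1e-3 over 619 mitochondrial
sites gives a nominal per-test threshold of 1.6e-6, and over 37 plastid
sites 2.7e-5.

The effect size is the relative drop in editing extent,

    delta_EE = (extent_wt - extent_mut) / extent_wt,

which (unlike the absolute difference) also captures strong proportional
losses at poorly edited sites.  A site is factor-dependent iff the
chi-square p-value is below the nominal threshold AND delta_EE >= 0.1;
otherwise it is factor-independent.  Silenced plants are compared against
both an uninoculated and a GFP-silenced control: a site counts as dependent
only if the rule holds against both, and sites where the GFP control itself
is reduced versus the uninoculated plants are excluded from the silenced
analysis universe altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2

DEFAULT_ALPHA_FAMILY = 1e-3
DEFAULT_DELTA_EE_CUT = 0.1

DEPENDENT = "dependent"
INDEPENDENT = "independent"
EXCLUDED = "excluded"


def round_half_up(x: float) -> int:
    """Integer rounding with ties away from zero toward +inf (88.5 -> 89)."""
    return int(math.floor(x + 0.5))


@dataclass
class ContingencyTest:
    """Pearson chi-square on a 2x2 table of (C, T) counts for two genotypes."""

    c1: int
    t1: int
    c2: int
    t2: int
    chisq: float
    pvalue: float
    df: int = 1
    excluded: bool = False


@dataclass
class DifferentialResult:
    site: tuple | str
    wt_extent: float | None
    mut_extent: float | None
    delta_ee: float | None
    test: ContingencyTest | None
    nominal_threshold: float
    klass: str
    reason: str = ""


def pool_replicates(counts: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Sum (C, T) count pairs over biological replicates."""
    if not counts:
        raise ValueError("no replicates to pool")
    c = sum(p[0] for p in counts)
    t = sum(p[1] for p in counts)
    return (c, t)


def chisq_2x2(c1: int, t1: int, c2: int, t2: int) -> ContingencyTest:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Expected counts come from the row/column marginals under independence;
    the statistic is sum over the four cells of (O - E)^2 / E.  A zero row
    or column marginal leaves the statistic undefined and is returned as an
    excluded marker rather than raising.
    """
    if min(c1, t1, c2, t2) < 0:
        raise ValueError("negative count")
    n1, n2 = c1 + t1, c2 + t2
    nc, nt = c1 + c2, t1 + t2
    n = n1 + n2
    if n1 == 0 or n2 == 0 or nc == 0 or nt == 0:
        return ContingencyTest(c1, t1, c2, t2, math.nan, math.nan,
                               excluded=True)
    stat = 0.0
    for obs, row, col in ((c1, n1, nc), (t1, n1, nt),
                          (c2, n2, nc), (t2, n2, nt)):
        expected = row * col / n
        stat += (obs - expected) ** 2 / expected
    pvalue = float(chi2.sf(stat, df=1))
    return ContingencyTest(c1, t1, c2, t2, stat, pvalue)


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test nominal threshold achieving the familywise rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def delta_ee(wt_extent: float, mut_extent: float) -> float:
    """Relative drop of editing extent, (wt - mut) / wt."""
    if wt_extent <= 0:
        raise ZeroDivisionError("delta_EE undefined for zero wild-type extent")
    return (wt_extent - mut_extent) / wt_extent


def classify_vs_wildtype(
    wt: tuple[int, int],
    mut: tuple[int, int],
    nominal: float,
    delta_cut: float = DEFAULT_DELTA_EE_CUT,
    site=None,
) -> DifferentialResult:
    """Classify one site as factor-dependent or -independent.

    ``wt``/``mut`` are pooled (C, T) counts.  The site is dependent iff the
    chi-square p-value is below ``nominal`` AND delta_EE >= ``delta_cut``;
    otherwise independent.  Sites with no informative reads in either
    genotype or zero wild-type extent are excluded with a reason code
    (delta_EE is undefined there).  Negative delta_EE (an editing increase)
    is reported but can never be classified dependent.
    """
    (wc, wt_t), (mc, mt) = wt, mut
    if wc + wt_t == 0 or mc + mt == 0:
        return DifferentialResult(site, None, None, None, None, nominal,
                                  EXCLUDED, reason="no_coverage")
    wt_extent = wt_t / (wc + wt_t)
    mut_extent = mt / (mc + mt)
    if wt_extent == 0.0:
        return DifferentialResult(site, wt_extent, mut_extent, None, None,
                                  nominal, EXCLUDED,
                                  reason="zero_wildtype_extent")
    test = chisq_2x2(wc, wt_t, mc, mt)
    if test.excluded:
        return DifferentialResult(site, wt_extent, mut_extent, None, test,
                                  nominal, EXCLUDED,
                                  reason="degenerate_table")
    dee = delta_ee(wt_extent, mut_extent)
    if test.pvalue < nominal and dee >= delta_cut:
        klass = DEPENDENT
    else:
        klass = INDEPENDENT
    return DifferentialResult(site, wt_extent, mut_extent, dee, test,
                              nominal, klass)


def classify_silenced(
    sil: tuple[int, int],
    uninoc: tuple[int, int],
    gfp_sil: tuple[int, int],
    nominal: float,
    delta_cut: float = DEFAULT_DELTA_EE_CUT,
    site=None,
) -> DifferentialResult:
    """Classify a site for a silenced genotype against two controls.

    The site is removed from the comparison universe when the GFP-silenced
    control itself shows a significant reduction versus the uninoculated
    plants (virus inoculation can unspecifically depress editing).
    Otherwise the site is dependent only if the significance + delta_EE rule
    holds against *both* controls; the reported extents and test are
    anchored on the uninoculated control.
    """
    gfp_check = classify_vs_wildtype(uninoc, gfp_sil, nominal, delta_cut)
    if gfp_check.klass == DEPENDENT:
        return DifferentialResult(site, None, None, None, None, nominal,
                                  EXCLUDED, reason="gfp_control_reduced")
    vs_uninoc = classify_vs_wildtype(uninoc, sil, nominal, delta_cut,
                                     site=site)
    if vs_uninoc.klass == EXCLUDED:
        return vs_uninoc
    vs_gfp = classify_vs_wildtype(gfp_sil, sil, nominal, delta_cut)
    if vs_uninoc.klass == DEPENDENT and vs_gfp.klass == DEPENDENT:
        return vs_uninoc
    return DifferentialResult(site, vs_uninoc.wt_extent,
                              vs_uninoc.mut_extent, vs_uninoc.delta_ee,
                              vs_uninoc.test, nominal, INDEPENDENT)


def summarize_classification(
    results: Iterable[DifferentialResult], label: str = ""
) -> pd.DataFrame:
    """Dependent/independent counts and integer percentages for one factor.

    Excluded sites are reported separately; percentages are over the
    analyzed universe (dependent + independent) and rounded half up, in the
    style of a per-genotype summary table.
    """
    results = list(results)
    dep = sum(r.klass == DEPENDENT for r in results)
    indep = sum(r.klass == INDEPENDENT for r in results)
    excl = sum(r.klass == EXCLUDED for r in results)
    universe = dep + indep
    return pd.DataFrame([{
        "factor": label,
        "dependent": dep,
        "independent": indep,
        "dependent_pct": round_half_up(100.0 * dep / universe) if universe
        else 0,
        "independent_pct": round_half_up(100.0 * indep / universe) if universe
        else 0,
        "excluded": excl,
        "analyzed": universe,
    }])


# ---------------------------------------------------------------------------
# Count-matrix replay
# ---------------------------------------------------------------------------

def load_count_matrix(path) -> pd.DataFrame:
    """Load a per-site, per-library C/T count matrix.

    Expected TSV layout: one row per site with columns ``site``,
    ``organelle``, then ``<library>_C`` and ``<library>_T`` pairs -- the
    tabular shape of a per-site read-count supplement.
    """
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise ValueError("count matrix must have a 'site' column")
    return df


def matrix_counts(df: pd.DataFrame, libraries: Sequence[str]) -> dict:
    """Extract pooled (C, T) counts per site for a set of libraries."""
    out = {}
    for _, row in df.iterrows():
        c = int(sum(row[f"{lib}_C"] for lib in libraries))
        t = int(sum(row[f"{lib}_T"] for lib in libraries))
        out[row["site"]] = (c, t)
    return out


def replay_count_matrix(
    df: pd.DataFrame,
    comparisons: Iterable[dict],
    alpha_family: float = DEFAULT_ALPHA_FAMILY,
    delta_cut: float = DEFAULT_DELTA_EE_CUT,
    organelle: str | None = None,
) -> dict[str, list[DifferentialResult]]:
    """Re-run the classification pipeline from a bare count matrix.

    ``comparisons`` items follow :meth:`SampleSheet.comparisons` /
    :meth:`SampleSheet.silenced_comparisons` (the latter recognised by the
    ``silenced_libraries`` key).  The Bonferroni threshold uses the number
    of sites actually tested per comparison.
    """
    if organelle is not None and "organelle" in df.columns:
        df = df[df["organelle"] == organelle]
    results: dict[str, list[DifferentialResult]] = {}
    for comp in comparisons:
        nominal = bonferroni_threshold(alpha_family, len(df))
        out = []
        if "silenced_libraries" in comp:
            sil = matrix_counts(df, comp["silenced_libraries"])
            uninoc = matrix_counts(df, comp["uninoculated_libraries"])
            gfp = matrix_counts(df, comp["gfp_libraries"])
            for site in sil:
                out.append(classify_silenced(
                    sil[site], uninoc[site], gfp[site], nominal, delta_cut,
                    site=site))
        else:
            mut = matrix_counts(df, comp["mutant_libraries"])
            wt = matrix_counts(df, comp["wildtype_libraries"])
            for site in mut:
                out.append(classify_vs_wildtype(
                    wt[site], mut[site], nominal, delta_cut, site=site))
        results[comp["genotype"]] = out
    return results
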