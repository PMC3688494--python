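"""Likelihood-ratio calling of C-to-U editing sites.

At a template C the sequencer reports a mixture: a fraction theta of the
molecules carry the edit (template base effectively T) and the rest do not.
With empirical per-read-position error rates P_i(o|r), the log-likelihood of
the observed column under editing fraction theta is

    L(theta) = sum over observations (i, o) of
               log[(1 - theta) * P_i(o|C) + theta * P_i(o|T)]

H0 fixes theta = 0 (errors only); H1 maximises over theta in [0, 1].  The
statistic 2*(L(theta_hat) - L(0)) is referred to the chi-square(1) upper
tail.  theta sits on the boundary of its space under H0, so the proper null
is the mixture 0.5*chi2_0 + 0.5*chi2_1; using the plain chi-square(1) tail
instead is deliberately conservative (p-values roughly doubled).

Candidate sites across libraries must be significant (p < 1e-6) in at least
one library, show a T fraction above 0.05 in at least one library, and have
a mean depth across all libraries above 100 (all strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .error_model import MismatchRateTable
from .formats_io import BASES, Pileup, PileupColumn, Template

DEFAULT_ALPHA_SITE = 1e-6
DEFAULT_MIN_FRACTION = 0.05
DEFAULT_MIN_MEAN_DEPTH = 100.0
THETA_TOL = 1e-8


class UndefinedExtentError(ZeroDivisionError):
    """Editing extent requested with zero informative (C+T) reads."""


@dataclass
class SiteCall:
    """Per-site, per-library editing call."""

    template_id: str
    position: int
    library_id: str
    c_count: int
    t_count: int
    other_count: int
    theta_hat: float
    lrt: float
    pvalue: float
    covered: bool = True

    @property
    def depth(self) -> int:
        return self.c_count + self.t_count + self.other_count

    @property
    def t_fraction(self) -> float | None:
        informative = self.c_count + self.t_count
        if informative == 0:
            return None
        return self.t_count / informative


@dataclass
class CandidateSet:
    """Union of per-library significant sites with the cross-library filters."""

    union: set
    passed_fraction: set
    passed_depth: set

    @property
    def final(self) -> set:
        return self.union & self.passed_fraction & self.passed_depth


def editing_extent(c_count: int, t_count: int) -> float:
    """Editing extent T/(C+T)."""
    denom = c_count + t_count
    if denom <= 0:
        raise UndefinedExtentError("editing extent undefined: C + T == 0")
    return t_count / denom


def site_log_likelihood(
    column: PileupColumn, rates: MismatchRateTable, theta: float
) -> float:
    """Mixture log-likelihood of one C column at editing fraction theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    total = 0.0
    for (i, o), n in column.obs.items():
        if o not in BASES:
            continue
        p = (1.0 - theta) * rates.rate(i, "C", o) + theta * rates.rate(i, "T", o)
        if p <= 0.0:
            # impossible observation under this theta (zero-rate limit)
            return float("-inf")
        total += n * math.log(p)
    return total


def call_editing_site(
    column: PileupColumn, rates: MismatchRateTable, library_id: str = ""
) -> SiteCall:
    """Maximum-likelihood editing fraction and LRT p-value for one column.

    theta_hat maximises the mixture likelihood on [0, 1] (bounded Brent,
    absolute tolerance 1e-8); the statistic is 2*(L(theta_hat) - L(0)) and
    the p-value its chi-square(1) upper tail.  A column with no T
    observations has its MLE at the boundary theta = 0, and an uncovered
    column returns the null call flagged uncovered.
    """
    counts = column.counts
    c_count, t_count = counts["C"], counts["T"]
    other = counts["A"] + counts["G"]
    base = dict(template_id=column.template_id, position=column.position,
                library_id=library_id, c_count=c_count, t_count=t_count,
                other_count=other)
    if column.depth == 0:
        return SiteCall(**base, theta_hat=0.0, lrt=0.0, pvalue=1.0,
                        covered=False)
    if t_count == 0:
        # No evidence for the edited component: the likelihood is maximised
        # on the theta = 0 boundary (P(C|C) dominates P(C|T)).
        return SiteCall(**base, theta_hat=0.0, lrt=0.0, pvalue=1.0)

    def neg_ll(theta: float) -> float:
        return -site_log_likelihood(column, rates, theta)

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": THETA_TOL})
    l0 = site_log_likelihood(column, rates, 0.0)
    candidates = [(l0, 0.0), (-res.fun, float(res.x))]
    lmax, theta_hat = max(candidates, key=lambda c: c[0])
    lrt = max(0.0, 2.0 * (lmax - l0))
    pvalue = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SiteCall(**base, theta_hat=theta_hat, lrt=lrt, pvalue=pvalue)


def call_sample(
    pileup: Pileup,
    rates: MismatchRateTable,
    library_id: str = "",
    alpha_site: float = DEFAULT_ALPHA_SITE,
) -> tuple[list[SiteCall], set]:
    """Call every covered template-C column in one library.

    Returns all calls plus the set of (template_id, position) significant at
    ``pvalue < alpha_site`` (strict).
    """
    calls = []
    significant = set()
    for (tid, pos), col in sorted(pileup.items()):
        if col.ref_base != "C":
            continue
        call = call_editing_site(col, rates, library_id)
        calls.append(call)
        if call.pvalue < alpha_site:
            significant.add((tid, pos))
    return calls, significant


def select_candidates(
    calls_by_site: Mapping[tuple, Mapping[str, SiteCall]],
    libraries: Iterable[str],
    alpha_site: float = DEFAULT_ALPHA_SITE,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
) -> CandidateSet:
    """Apply the cross-library candidate filters.

    A site survives iff (i) its LRT p-value is below ``alpha_site`` in at
    least one library, (ii) its T fraction exceeds ``min_fraction`` in at
    least one library, and (iii) its mean depth over *all* libraries (zero
    for libraries without coverage) exceeds ``min_mean_depth``.  All three
    comparisons are strict.
    """
    libraries = list(libraries)
    if not libraries:
        raise ValueError("empty library set")
    union, frac_ok, depth_ok = set(), set(), set()
    for site, by_lib in calls_by_site.items():
        pvals = [c.pvalue for c in by_lib.values()]
        if any(p < alpha_site for p in pvals):
            union.add(site)
        fracs = [c.t_fraction for c in by_lib.values()
                 if c.t_fraction is not None]
        if fracs and max(fracs) > min_fraction:
            frac_ok.add(site)
        mean_depth = sum(
            by_lib[lib].depth if lib in by_lib else 0 for lib in libraries
        ) / len(libraries)
        if mean_depth > min_mean_depth:
            depth_ok.add(site)
    return CandidateSet(union=union, passed_fraction=frac_ok,
                        passed_depth=depth_ok)


# ---------------------------------------------------------------------------
# Silent / non-silent annotation
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def annotate_silent(template: Template, position: int) -> str:
    """Classify a C->T edit as silent, non_silent or non_coding.

    ``position`` is 1-based on the template.  The template's CDS annotation
    (1-based inclusive, frame starting at ``cds_start``) defines the reading
    frame; sites outside it are non-coding.
    """
    if template.seq[position - 1] != "C":
        raise ValueError(f"position {position} of {template.id} is not a C")
    if template.cds_start is None or template.cds_end is None:
        return "non_coding"
    if (template.cds_end - template.cds_start + 1) % 3 != 0:
        raise ValueError(f"template {template.id}: CDS length not a multiple "
                         "of 3")
    if not template.cds_start <= position <= template.cds_end:
        return "non_coding"
    idx = position - template.cds_start
    codon_start = template.cds_start - 1 + 3 * (idx // 3)
    codon = template.seq[codon_start:codon_start + 3]
    pos_in_codon = idx % 3
    edited = codon[:pos_in_codon] + "T" + codon[pos_in_codon + 1:]
    return "silent" if _CODON_TABLE[codon] == _CODON_TABLE[edited] else \
        "non_silent"


# ---------------------------------------------------------------------------
# Vectorised batch calling for position-uniform rates
# ---------------------------------------------------------------------------

def call_counts_batch(
    counts: np.ndarray, rates: MismatchRateTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised LRT for many C sites with position-uniform rates.

    ``counts`` has shape (n_sites, 4) with columns ordered A, C, G, T; the
    rate table must be position-uniform (pooled rates only), as produced by
    :meth:`MismatchRateTable.uniform` or when all strata fall back to the
    pooled table.  Returns ``(theta_hat, lrt, pvalue)`` arrays.  Used for
    large calibration simulations; agrees with :func:`call_editing_site` on
    collapsed columns to optimiser tolerance.
    """
    counts = np.asarray(counts, dtype=float)
    p_c = np.array([rates.pooled_rate("C", o) for o in BASES])
    p_t = np.array([rates.pooled_rate("T", o) for o in BASES])

    n = counts.shape[0]
    lo = np.zeros(n)
    hi = np.ones(n)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    # ~60 golden-section iterations shrink the bracket below 1e-12; the
    # per-site likelihood is concave in theta so this is exact enough.
    for _ in range(60):
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = _loglik_at(counts, p_c, p_t, x1)
        f2 = _loglik_at(counts, p_c, p_t, x2)
        take_left = f1 >= f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
    theta_hat = (lo + hi) / 2.0
    l0 = _loglik_at(counts, p_c, p_t, np.zeros(n))
    lmax = _loglik_at(counts, p_c, p_t, theta_hat)
    # The boundary theta = 0 may beat the interior point (e.g. no T reads).
    no_t = counts[:, 3] == 0
    theta_hat = np.where(no_t | (lmax < l0), 0.0, theta_hat)
    lmax = np.maximum(lmax, l0)
    lrt = np.maximum(0.0, 2.0 * (lmax - l0))
    lrt = np.where(no_t, 0.0, lrt)
    pvalue = chi2.sf(lrt, df=1)
    pvalue = np.where(lrt <= 0, 1.0, pvalue)
    return theta_hat, lrt, pvalue


def _loglik_at(counts: np.ndarray, p_c: np.ndarray, p_t: np.ndarray,
               theta: np.ndarray) -> np.ndarray:
    mix = np.outer(1.0 - theta, p_c) + np.outer(theta, p_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        logmix = np.log(mix)
    # counts of 0 contribute nothing even if the rate is 0 (0 * -inf -> 0)
    logmix = np.where(counts > 0, logmix, 0.0)
    return (counts * logmix).sum(axis=1)
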