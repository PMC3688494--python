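"""Empirical position-on-read sequencing-error model.

Illumina amplicon sequencing of organelle cDNA shows substitution error rates
that depend on the position along the read and on the template base: roughly
1e-4 per base-pair class for plasmid spikes and up to ~1e-3 for PCR/RT-PCR
material, with some classes (e.g. A->G) systematically elevated.  The editing
caller needs, for every read position i, the probability P_i(o|r) of
*observing* base o when the template base is r.  These rates are estimated
per library directly from the alignments, after masking columns that are
obviously edited (otherwise genuine C->U editing inflates the apparent C->T
error rate, which would only make editing calls more conservative but also
less sensitive).

A small pseudocount keeps every rate strictly positive so downstream
likelihood ratios never degenerate; sparsely covered read-position strata
fall back to position-pooled rates.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import BASES, Pileup, TemplateSet

#: Minimum per-(position, ref) coverage for the stratum estimate to be used.
DEFAULT_MIN_STRATUM = 1000
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MASK_THRESHOLD = 0.02


class EmptyRateError(ValueError):
    """No observations available for a requested reference base."""


MaskSet = set  # of (template_id, position) tuples


@dataclass
class MismatchRateTable:
    """Empirical P_i(o|r) with a position-pooled fallback.

    ``rates[(i, r)]`` maps observed base -> probability, normalised over the
    four unambiguous bases; ``counts`` holds the raw observation counts that
    produced them.  ``pooled_rates[r]`` marginalises over read position and
    serves as the fallback for positions with fewer than ``min_stratum``
    observations of reference base ``r``.
    """

    rates: dict[tuple[int, str], dict[str, float]]
    counts: dict[tuple[int, str], dict[str, int]]
    pooled_rates: dict[str, dict[str, float]]
    pooled_counts: dict[str, dict[str, int]]
    library_id: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    min_stratum: int = DEFAULT_MIN_STRATUM

    def stratum_coverage(self, i: int, r: str) -> int:
        c = self.counts.get((i, r))
        return sum(c.values()) if c else 0

    def rate(self, i: int, r: str, o: str) -> float:
        """P_i(o|r), falling back to the pooled rate for thin strata."""
        if r not in BASES or o not in BASES:
            raise KeyError(f"unknown base symbol {r!r}/{o!r}")
        if self.stratum_coverage(i, r) >= self.min_stratum:
            return self.rates[(i, r)][o]
        pooled = self.pooled_rates.get(r)
        if not pooled:
            raise EmptyRateError(f"no observations for reference base {r}")
        return pooled[o]

    def pooled_rate(self, r: str, o: str) -> float:
        pooled = self.pooled_rates.get(r)
        if not pooled:
            raise EmptyRateError(f"no observations for reference base {r}")
        return pooled[o]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (i, r), by_obs in sorted(self.counts.items()):
            for o in BASES:
                rows.append({
                    "library": self.library_id, "read_position": i,
                    "ref": r, "obs": o, "count": by_obs.get(o, 0),
                    "rate": self.rates[(i, r)][o],
                })
        for r, by_obs in sorted(self.pooled_counts.items()):
            for o in BASES:
                rows.append({
                    "library": self.library_id, "read_position": "pooled",
                    "ref": r, "obs": o, "count": by_obs.get(o, 0),
                    "rate": self.pooled_rates[r][o],
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 min_stratum: int = DEFAULT_MIN_STRATUM) -> "MismatchRateTable":
        df = pd.read_csv(path, sep="\t")
        rates, counts = {}, {}
        pooled_rates, pooled_counts = {}, {}
        for (pos, r), grp in df.groupby(["read_position", "ref"]):
            rmap = dict(zip(grp["obs"], grp["rate"].astype(float)))
            cmap = dict(zip(grp["obs"], grp["count"].astype(int)))
            if str(pos) == "pooled":
                pooled_rates[r], pooled_counts[r] = rmap, cmap
            else:
                rates[(int(pos), r)] = rmap
                counts[(int(pos), r)] = cmap
        lib = str(df["library"].iloc[0]) if len(df) else ""
        return cls(rates, counts, pooled_rates, pooled_counts, lib,
                   pseudocount, min_stratum)

    @classmethod
    def uniform(cls, profile: Mapping[tuple[str, str], float],
                library_id: str = "synthetic") -> "MismatchRateTable":
        """Build a position-uniform table from per-substitution rates.

        ``profile[(r, o)]`` gives the off-diagonal rate; diagonals receive the
        complementary mass.  Intended for simulations and closed-form checks.
        """
        pooled_rates: dict[str, dict[str, float]] = {}
        for r in BASES:
            row = {}
            off = 0.0
            for o in BASES:
                if o != r:
                    row[o] = float(profile.get((r, o), 0.0))
                    off += row[o]
            row[r] = 1.0 - off
            pooled_rates[r] = row
        return cls({}, {}, pooled_rates,
                   {r: {o: 0 for o in BASES} for r in BASES},
                   library_id, pseudocount=0.0, min_stratum=1)


def estimate_mismatch_rates(
    pileups: Pileup,
    templates: TemplateSet,
    mask: MaskSet | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_stratum: int = DEFAULT_MIN_STRATUM,
    library_id: str = "",
) -> MismatchRateTable:
    """Estimate P_i(o|r) from one library's pileup, excluding masked columns.

    For each read position i and reference base r the off-diagonal rate is
    ``(n(i,r,o) + pseudocount) / (N(i,r) + 3*pseudocount)`` and the diagonal
    takes the complementary mass, so rows are exactly normalised and no rate
    is zero when the pseudocount is positive.  Pooled (position-marginal)
    rates are computed the same way from summed counts.  Ambiguous (N)
    observations are ignored.
    """
    mask = mask or set()
    counts: dict[tuple[int, str], Counter] = defaultdict(Counter)
    for (tid, pos), col in pileups.items():
        if (tid, pos) in mask:
            continue
        r = col.ref_base
        if r not in BASES:
            continue
        for (i, o), n in col.obs.items():
            if o in BASES:
                counts[(i, r)][o] += n
    if not counts:
        raise EmptyRateError("no unmasked observations to estimate rates from")

    pooled_counts: dict[str, Counter] = defaultdict(Counter)
    for (i, r), by_obs in counts.items():
        pooled_counts[r].update(by_obs)

    def _normalise(r: str, by_obs: Mapping[str, int]) -> dict[str, float]:
        n_total = sum(by_obs.values())
        denom = n_total + 3.0 * pseudocount
        row = {}
        for o in BASES:
            if o == r:
                continue
            row[o] = (by_obs.get(o, 0) + pseudocount) / denom
        row[r] = 1.0 - sum(row.values())
        return row

    rates = {(i, r): _normalise(r, c) for (i, r), c in counts.items()}
    pooled_rates = {r: _normalise(r, c) for r, c in pooled_counts.items()}
    return MismatchRateTable(
        rates={k: v for k, v in rates.items()},
        counts={k: dict(v) for k, v in counts.items()},
        pooled_rates=pooled_rates,
        pooled_counts={r: dict(c) for r, c in pooled_counts.items()},
        library_id=library_id,
        pseudocount=pseudocount,
        min_stratum=min_stratum,
    )


def auto_mask(
    pileups: Pileup | Iterable[Pileup],
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> MaskSet:
    """Mask obviously edited columns before rate estimation.

    Pools C/T counts at every template-C column over the given pileups (one
    per library, or a single pileup) and masks columns whose pooled T
    fraction T/(C+T) reaches ``threshold``.
    """
    if isinstance(pileups, dict):
        pileups = [pileups]
    pooled: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    for pileup in pileups:
        for key, col in pileup.items():
            if col.ref_base != "C":
                continue
            c = pooled[key]
            counts = col.counts
            c[0] += counts["C"]
            c[1] += counts["T"]
    mask: MaskSet = set()
    for key, (c_count, t_count) in pooled.items():
        total = c_count + t_count
        if total > 0 and t_count / total >= threshold:
            mask.add(key)
    return mask


def rate_lookup(table: MismatchRateTable, i: int, r: str, o: str) -> float:
    """Functional alias for :meth:`MismatchRateTable.rate`."""
    return table.rate(i, r, o)
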