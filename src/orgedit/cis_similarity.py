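"""Cis-element similarity scanning around editing sites.

The sequence recognised by a site-specificity factor lies mostly upstream of
the edited C (roughly -20 to +5).  Low-level "accidental" editing at a new
site can often be explained by similarity of its surrounding sequence to the
cis-element of a known, highly edited site.  This module extracts the
-20..+5 window around a candidate C (in transcript orientation) and scans it
against the windows of known sites with a gapped local alignment, reporting
pairs that share at least 10 identical aligned nucleotides.

The alignment is a Smith-Waterman with match +1, mismatch -1, gap -2; the
reported "identity" is the number of identical aligned positions, maximised
over all score-optimal local alignments (ties in score are broken in favour
of more identities, then deterministically by coordinate), so results are
reproducible — unlike by-eye gap placement.
"""

from __future__ import annotations

from dataclasses import dataclass

MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass
class CisWindow:
    """Sequence window around a candidate C (20 up, the C, 5 down)."""

    site: str
    sequence: str
    target_index: int  # 0-based index of the C within the window
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) > 26:
            raise ValueError("cis window longer than 26 nt")
        if self.sequence[self.target_index] != "C":
            raise ValueError(
                f"window for {self.site}: base at target index is "
                f"{self.sequence[self.target_index]!r}, not C"
            )


@dataclass
class SimilarityHit:
    query: str
    known: str
    identity: int
    score: int
    aligned_query: str
    aligned_known: str


def extract_window(
    seq: str, position: int, site: str = "", up: int = 20, down: int = 5
) -> CisWindow:
    """Extract the window around a 1-based C position on a template.

    Truncated at template boundaries (flagged).  Raises if the base at
    ``position`` is not a C.
    """
    idx = position - 1
    if not 0 <= idx < len(seq):
        raise IndexError(f"position {position} outside template")
    if seq[idx] != "C":
        raise ValueError(f"base at position {position} is {seq[idx]!r}, not C")
    start = max(0, idx - up)
    end = min(len(seq), idx + down + 1)
    return CisWindow(
        site=site or f"site-{position}",
        sequence=seq[start:end],
        target_index=idx - start,
        truncated=(start > idx - up) or (end < idx + down + 1),
    )


def local_alignment_identity(a: str, b: str) -> tuple[int, int, str, str]:
    """Best local alignment of two sequences under (+1, -1, -2) scoring.

    Returns ``(score, identity, aligned_a, aligned_b)`` where ``identity``
    is the maximum number of identical aligned positions over *all*
    score-optimal local alignments.  Co-optimal alignments may carry
    zero-score flanks that add identities (e.g. ``TTT/TAT`` scores the same
    as its last match alone but aligns two identities), so a plain
    Smith-Waterman maximum is not enough: each cell tracks, for every
    achievable running score, the maximum number of matches of a local
    alignment ending there.  Running scores never need to go negative
    (dropping a negative-score prefix always yields a better alignment), so
    the per-cell maps stay small and the DP is exact.  A pair with no
    positive-scoring alignment returns score 0, identity 0.
    """
    n, m = len(a), len(b)
    # cell[(i, j)][s] = max matches over nonempty local alignments ending at
    # (i, j) with running score s >= 0.
    empty: dict[int, int] = {}
    prev_row = [empty] * (m + 1)
    cells: list[list[dict[int, int]]] = [prev_row]
    for i in range(1, n + 1):
        ai = a[i - 1]
        row: list[dict[int, int]] = [empty]
        for j in range(1, m + 1):
            is_match = ai == b[j - 1]
            step = MATCH if is_match else MISMATCH
            add = 1 if is_match else 0
            here: dict[int, int] = {}

            def _consider(score: int, matches: int) -> None:
                if score >= 0 and matches > here.get(score, -1):
                    here[score] = matches

            for s, k in cells[i - 1][j - 1].items():
                _consider(s + step, k + add)
            _consider(step, add)  # alignment starting at this cell
            for s, k in cells[i - 1][j].items():
                _consider(s + GAP, k)
            for s, k in row[j - 1].items():
                _consider(s + GAP, k)
            row.append(here)
        cells.append(row)

    best_score = 0
    identity = 0
    end = None
    for i in range(n + 1):
        for j in range(m + 1):
            for s, k in cells[i][j].items():
                if s > best_score or (s == best_score and k > identity):
                    best_score, identity, end = s, k, (i, j)
    if best_score <= 0:
        return 0, 0, "", ""

    # Traceback one witness alignment consistent with (score, matches).
    out_a, out_b = [], []
    i, j = end
    s, k = best_score, identity
    while True:
        is_match = i > 0 and j > 0 and a[i - 1] == b[j - 1]
        step = MATCH if is_match else MISMATCH
        add = 1 if is_match else 0
        if i > 0 and j > 0 and s - step == 0 and k - add == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            break  # alignment started here
        if (i > 0 and j > 0
                and cells[i - 1][j - 1].get(s - step, -1) >= k - add):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j, s, k = i - 1, j - 1, s - step, k - add
        elif i > 0 and cells[i - 1][j].get(s - GAP, -1) >= k:
            out_a.append(a[i - 1])
            out_b.append("-")
            i, s = i - 1, s - GAP
        elif j > 0 and cells[i][j - 1].get(s - GAP, -1) >= k:
            out_a.append("-")
            out_b.append(b[j - 1])
            j, s = j - 1, s - GAP
        else:  # pragma: no cover - the DP guarantees one branch applies
            raise AssertionError("traceback inconsistency")
    return best_score, identity, "".join(reversed(out_a)), \
        "".join(reversed(out_b))


def best_identity_match(
    query: CisWindow,
    known: list[CisWindow],
    min_identity: int = 10,
) -> list[SimilarityHit]:
    """Scan a query window against known-site windows.

    Reports every known window whose best local alignment with the query
    shares at least ``min_identity`` identical nucleotides, sorted by
    identity descending then known-site id.
    """
    hits = []
    for kw in known:
        score, ident, aq, ak = local_alignment_identity(
            query.sequence, kw.sequence
        )
        if ident >= min_identity:
            hits.append(SimilarityHit(query.site, kw.site, ident, score,
                                      aq, ak))
    hits.sort(key=lambda h: (-h.identity, h.known))
    return hits
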