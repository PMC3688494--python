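"""Truth-known read simulator for organelle amplicon editing studies.

Generates random amplicon templates, places C-to-U editing sites with known
true editing fractions, and emits strand-specific reads carrying both the
editing signal (each molecule is edited at a site with probability theta)
and position-dependent substitution errors.  Reads come with their true
alignments (plain-text SAM), so the statistical modules can be exercised
end-to-end without an external aligner; a FASTQ is emitted alongside for
pipelines that want to re-align.

Defaults mirror the sequencing regime the method was designed for: 97-nt
processed reads, per-site depths of order several thousand (5500 is the
working default, the mean per-site depth of a 24-plex amplicon pool), and
per-substitution error rates between 1e-4 (plasmid-like spike material) and
1e-3 (PCR/RT-PCR material).  A scalar error profile epsilon means every
off-diagonal substitution (r -> o, o != r) occurs at rate epsilon per base.

For calibration studies that need 1e5+ sites, :func:`simulate_site_counts`
draws the per-site base counts directly (identical statistical model, no
per-read bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .formats_io import (AlignmentRecord, BASES, Pileup, PileupColumn,
                         Template, TemplateSet, write_sam)

DEFAULT_READ_LENGTH = 97
DEFAULT_DEPTH = 5500
DEFAULT_ERROR = 1e-3
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

COVERAGE_SHAPES = ("flat", "mid_dip", "end_peak")


@dataclass
class SimConfig:
    seed: int = 0
    n_templates: int = 4
    template_length: int = 400
    gc_fraction: float = 0.5
    read_length: int = DEFAULT_READ_LENGTH
    depth: float = DEFAULT_DEPTH  # target per-position coverage
    error: float | Mapping[tuple[str, str], float] = DEFAULT_ERROR
    editing_sites: dict[tuple[str, int], float] = field(default_factory=dict)
    n_editing_sites: int = 0  # auto-placed if editing_sites is empty
    editing_thetas: tuple[float, ...] = (0.1, 0.5, 0.9)
    coverage_shape: str = "flat"

    def __post_init__(self) -> None:
        if self.coverage_shape not in COVERAGE_SHAPES:
            raise ValueError(f"unknown coverage shape {self.coverage_shape}")
        for theta in self.editing_sites.values():
            if not 0.0 <= theta <= 1.0:
                raise ValueError("editing fraction outside [0, 1]")


@dataclass
class TruthManifest:
    """Ground truth emitted next to the simulated reads."""

    editing_sites: dict[tuple[str, int], float]
    error: float | Mapping[tuple[str, str], float]
    provenance: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (read_id, template_id, start0, strand)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("template\tposition\ttheta\n")
            for (tid, pos), theta in sorted(self.editing_sites.items()):
                fh.write(f"{tid}\t{pos}\t{theta!r}\n")


def _substitution_matrix(
    error: float | Mapping[tuple[str, str], float]
) -> np.ndarray:
    """4x4 row-stochastic matrix P(observe col | template row)."""
    mat = np.zeros((4, 4))
    if isinstance(error, Mapping):
        for (r, o), rate in error.items():
            mat[_BASE_IDX[r], _BASE_IDX[o]] = rate
    else:
        mat[:] = float(error)
        np.fill_diagonal(mat, 0.0)
    np.fill_diagonal(mat, 1.0 - mat.sum(axis=1))
    if (mat < 0).any():
        raise ValueError("error rates sum past 1 for some template base")
    return mat


def simulate_truth_set(config: SimConfig) -> tuple[TemplateSet, TruthManifest]:
    """Random templates plus an editing truth set on C positions only.

    Base composition follows ``gc_fraction`` (G and C equiprobable, likewise
    A and T).  Explicit ``editing_sites`` are validated to sit on template
    Cs; otherwise ``n_editing_sites`` sites are placed on randomly chosen Cs
    cycling through ``editing_thetas``.  Fully deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    g = config.gc_fraction / 2.0
    a = (1.0 - config.gc_fraction) / 2.0
    probs = [a, g, g, a]  # A, C, G, T
    templates = []
    for t in range(config.n_templates):
        seq = "".join(
            rng.choice(list(BASES), size=config.template_length, p=probs)
        )
        templates.append(Template(
            id=f"tpl{t}", seq=seq, gene=f"gene{t}",
            organelle="mitochondrial",
        ))
    tset = TemplateSet(templates)

    sites = dict(config.editing_sites)
    for (tid, pos), _ in sites.items():
        if tid not in tset or tset[tid].seq[pos - 1] != "C":
            raise ValueError(
                f"editing site ({tid}, {pos}) is not a template C"
            )
    if not sites and config.n_editing_sites:
        all_c = list(tset.c_positions())
        if not all_c:
            raise ValueError("no C positions available for editing sites")
        idx = rng.choice(len(all_c), size=min(config.n_editing_sites,
                                              len(all_c)), replace=False)
        for k, i in enumerate(sorted(idx)):
            theta = config.editing_thetas[k % len(config.editing_thetas)]
            sites[all_c[i]] = theta
    return tset, TruthManifest(editing_sites=sites, error=config.error)


def _start_distribution(n_starts: int, shape: str,
                        rng: np.random.Generator, n_reads: int) -> np.ndarray:
    if shape == "flat":
        weights = np.ones(n_starts)
    elif shape == "mid_dip":
        x = np.linspace(-1, 1, n_starts)
        weights = 0.25 + x ** 2
    else:  # end_peak
        x = np.linspace(0, 1, n_starts)
        weights = 0.2 + np.exp(-5 * x)
    weights /= weights.sum()
    return rng.choice(n_starts, size=n_reads, p=weights)


def simulate_reads(
    templates: TemplateSet, manifest: TruthManifest, config: SimConfig
) -> list[AlignmentRecord]:
    """Draw reads with editing and sequencing error; returns true alignments.

    Each read copies a template interval; at every edited site inside the
    interval the base becomes T with probability theta (molecule-level
    editing), then every base is passed through the substitution-error
    channel.  Reads are forward-strand (the protocol is strand-specific) and
    their true coordinates are recorded, so no aligner is needed downstream.
    """
    rng = np.random.default_rng(config.seed + 1)
    sub = _substitution_matrix(config.error)
    records: list[AlignmentRecord] = []
    for tpl in templates:
        L = len(tpl.seq)
        if config.read_length > L:
            raise ValueError(
                f"read length {config.read_length} exceeds template "
                f"{tpl.id} length {L}"
            )
        n_starts = L - config.read_length + 1
        n_reads = int(round(config.depth * L / config.read_length))
        starts = _start_distribution(n_starts, config.coverage_shape, rng,
                                     n_reads)
        tpl_idx = np.array([_BASE_IDX[b] for b in tpl.seq])
        edited_here = {
            pos - 1: theta
            for (tid, pos), theta in manifest.editing_sites.items()
            if tid == tpl.id
        }
        for r, start in enumerate(starts):
            idx = tpl_idx[start:start + config.read_length].copy()
            for pos0, theta in edited_here.items():
                if start <= pos0 < start + config.read_length:
                    if rng.random() < theta:
                        idx[pos0 - start] = _BASE_IDX["T"]
            # substitution errors, drawn per base via the channel matrix
            u = rng.random(config.read_length)
            cum = sub[idx].cumsum(axis=1)
            idx = (u[:, None] < cum).argmax(axis=1)
            bases = "".join(BASES[i] for i in idx)
            read_id = f"{tpl.id}:r{r}"
            records.append(AlignmentRecord(
                read_id=read_id, template_id=tpl.id,
                template_start=int(start), read_offset=0,
                cigar=[("M", config.read_length)],
                is_secondary=False, has_unique_top_hit=True,
                strand="forward", bases=bases,
                read_length=config.read_length,
            ))
            manifest.provenance.append(
                (read_id, tpl.id, int(start), "forward")
            )
    return records


def write_fastq(records: list[AlignmentRecord], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n"
                     f"{quality_char * len(rec.bases)}\n")


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Emit FASTA + FASTQ + SAM + truth TSV for one simulated library."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    templates, manifest = simulate_truth_set(config)
    records = simulate_reads(templates, manifest, config)
    templates.to_fasta(out / "templates.fasta")
    write_fastq(records, out / "reads.fastq")
    write_sam(out / "alignments.sam", templates, records)
    manifest.to_tsv(out / "truth.tsv")
    return {
        "templates": out / "templates.fasta",
        "fastq": out / "reads.fastq",
        "sam": out / "alignments.sam",
        "truth": out / "truth.tsv",
        "n_reads": len(records),
    }


# ---------------------------------------------------------------------------
# Count-level simulation for large calibration studies
# ---------------------------------------------------------------------------

def simulate_site_counts(
    n_sites: int,
    depth: int,
    theta: float,
    error: float | Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site base counts (columns A, C, G, T) at a template C.

    Statistically identical to sequencing ``depth`` independent molecules of
    a C site with editing fraction ``theta`` through the substitution-error
    channel: each read reports base o with probability
    ``(1 - theta) P(o|C) + theta P(o|T)``.
    """
    sub = _substitution_matrix(error)
    p = (1.0 - theta) * sub[_BASE_IDX["C"]] + theta * sub[_BASE_IDX["T"]]
    return rng.multinomial(depth, p, size=n_sites)


def counts_to_column(
    counts, template_id: str = "sim", position: int = 1,
    ref_base: str = "C", read_positions: int = DEFAULT_READ_LENGTH,
    rng: np.random.Generator | None = None,
) -> PileupColumn:
    """Wrap a base-count vector as a pileup column.

    Observations are spread over read positions (uniformly at random when a
    generator is given, else round-robin) so the column is a valid input for
    the position-stratified error model.
    """
    col = PileupColumn(template_id, position, ref_base)
    counts = np.asarray(counts)
    for b_idx, n in enumerate(counts):
        n = int(n)
        if n == 0:
            continue
        if rng is not None:
            pos_counts = np.bincount(
                rng.integers(1, read_positions + 1, size=n),
                minlength=read_positions + 1,
            )
            for pos in np.nonzero(pos_counts)[0]:
                col.add(int(pos), BASES[b_idx], int(pos_counts[pos]))
        else:
            per, extra = divmod(n, read_positions)
            for pos in range(1, read_positions + 1):
                c = per + (1 if pos <= extra else 0)
                if c:
                    col.add(pos, BASES[b_idx], c)
    return col


def simulate_null_pileup(
    n_columns: int,
    depth: int,
    error: float | Mapping[tuple[str, str], float],
    rng: np.random.Generator,
    ref_base: str = "C",
    read_positions: int = DEFAULT_READ_LENGTH,
    template_id: str = "sim",
) -> Pileup:
    """Unedited pileup columns for error-model estimation at scale.

    Each column spreads its depth uniformly over read positions and draws
    observed bases from the substitution channel, per read position, so
    realised position-specific frequencies can be checked against the
    configured profile.
    """
    sub = _substitution_matrix(error)
    p = sub[_BASE_IDX[ref_base]]
    pileup: Pileup = {}
    for c in range(n_columns):
        col = PileupColumn(template_id, c + 1, ref_base)
        per_pos = np.bincount(
            rng.integers(1, read_positions + 1, size=depth),
            minlength=read_positions + 1,
        )
        for pos in range(1, read_positions + 1):
            n = int(per_pos[pos])
            if n == 0:
                continue
            draws = rng.multinomial(n, p)
            for b_idx, k in enumerate(draws):
                if k:
                    col.add(pos, BASES[b_idx], int(k))
        pileup[(template_id, c + 1)] = col
    return pileup
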