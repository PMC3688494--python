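"""Input/output and pileup construction for organelle amplicon sequencing.

This module owns every external format the toolkit touches -- FASTA amplicon
templates, FASTQ reads, SAM alignments, TSV site tables and the sample sheet
describing the genotype comparison graph -- plus the read preprocessing and
alignment-record filters applied before any statistics, and the construction
of per-library pileups over the amplicon templates.

Coordinate conventions
----------------------
Internally everything is 0-based half-open; every *reported* position is
1-based on the amplicon template in transcript orientation.  "Read position"
always means the 1-based index on the processed (quality-clipped) read as it
came off the sequencer, which is the coordinate the empirical error model is
stratified on.  For a reverse-strand alignment the SAM record stores the read
reverse-complemented into template orientation, so the sequenced read position
of aligned index ``q`` is ``read_length - q`` (1-based from the other end).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO

BASES = ("A", "C", "G", "T")

#: CIGAR operation codes that consume both read and template.
_ALIGNED_OPS = frozenset("M=X")
#: CIGAR operation codes that indicate an indel (disqualifying).
_INDEL_OPS = frozenset("IDN")

SAMPLE_ROLES = (
    "mutant",
    "wildtype_sibling",
    "silenced",
    "uninoculated_control",
    "gfp_silenced_control",
    "spike_control",
)


class FormatError(ValueError):
    """Malformed input data (bad CIGAR, inconsistent sheet, ...)."""


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise FormatError(
                f"read {self.id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """A gapless alignment of a processed read to a template.

    ``bases`` are stored in template orientation (as in SAM); ``strand`` tells
    whether the read was sequenced from the opposite strand, which only
    matters for recovering the sequenced read position.
    """

    read_id: str
    template_id: str
    template_start: int  # 0-based template offset of first aligned base
    read_offset: int  # 0-based index of first aligned base on the read
    cigar: list[tuple[str, int]]
    is_secondary: bool
    has_unique_top_hit: bool
    strand: str  # "forward" | "reverse" relative to the template
    bases: str = ""
    read_length: int = 0

    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _ALIGNED_OPS)

    def has_indel(self) -> bool:
        return any(op in _INDEL_OPS for op, _ in self.cigar)


@dataclass
class Template:
    """One amplicon template in transcript orientation."""

    id: str
    seq: str
    gene: str = ""
    offset: int = 0  # genomic offset added to template positions in site names
    organelle: str = ""  # "mitochondrial" | "plastid" | ""
    cds_start: int | None = None  # 1-based, inclusive; None -> non-coding
    cds_end: int | None = None

    def site_name(self, position: int) -> str:
        """Render a 1-based template position as a field-style site name."""
        gene = self.gene or self.id
        return f"{gene}-{self.offset + position}"


class TemplateSet:
    """Mapping of template id to :class:`Template`."""

    def __init__(self, templates: Iterable[Template]):
        self._templates: dict[str, Template] = {}
        for t in templates:
            if not t.seq:
                raise FormatError(f"template {t.id} has an empty sequence")
            if t.id in self._templates:
                raise FormatError(f"duplicate template id {t.id}")
            self._templates[t.id] = t

    def __getitem__(self, template_id: str) -> Template:
        return self._templates[template_id]

    def __contains__(self, template_id: str) -> bool:
        return template_id in self._templates

    def __iter__(self) -> Iterator[Template]:
        return iter(self._templates.values())

    def __len__(self) -> int:
        return len(self._templates)

    def ids(self) -> list[str]:
        return list(self._templates)

    def c_positions(self) -> Iterator[tuple[str, int]]:
        """Yield every (template_id, 1-based position) with a template C."""
        for t in self:
            for i, base in enumerate(t.seq):
                if base == "C":
                    yield t.id, i + 1

    @classmethod
    def from_fasta(
        cls, path: str | Path, metadata: str | Path | None = None
    ) -> "TemplateSet":
        """Load templates from FASTA, optionally joined with a metadata TSV.

        The metadata table may carry columns ``template, gene, offset,
        organelle, cds_start, cds_end`` keyed on the FASTA record id.
        """
        meta: dict[str, dict] = {}
        if metadata is not None:
            df = pd.read_csv(metadata, sep="\t", dtype={"template": str})
            for row in df.to_dict("records"):
                meta[row["template"]] = row
        templates = []
        for rec in SeqIO.parse(str(path), "fasta"):
            m = meta.get(rec.id, {})
            def _opt_int(key):
                v = m.get(key)
                return None if v is None or pd.isna(v) else int(v)
            templates.append(
                Template(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    gene=str(m.get("gene", "") or ""),
                    offset=_opt_int("offset") or 0,
                    organelle=str(m.get("organelle", "") or ""),
                    cds_start=_opt_int("cds_start"),
                    cds_end=_opt_int("cds_end"),
                )
            )
        return cls(templates)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self:
                fh.write(f">{t.id}\n{t.seq}\n")


@dataclass
class PileupColumn:
    """Observed bases at one template position in one library.

    Observations are stored aggregated as ``(read_position, base) -> count``
    so that very deep columns stay compact; ``observations`` expands them
    when a flat list is convenient.  Ambiguous bases (N) are recorded but
    excluded from ``counts`` used by likelihoods and fractions.
    """

    template_id: str
    position: int  # 1-based on template
    ref_base: str
    obs: Counter = field(default_factory=Counter)

    def add(self, read_position: int, base: str, count: int = 1) -> None:
        self.obs[(read_position, base)] += count

    @property
    def counts(self) -> dict[str, int]:
        out = {b: 0 for b in BASES}
        for (_, base), n in self.obs.items():
            if base in out:
                out[base] += n
        return out

    @property
    def depth(self) -> int:
        """Number of unambiguous (A/C/G/T) observations."""
        return sum(n for (_, b), n in self.obs.items() if b in BASES)

    @property
    def n_observations(self) -> int:
        return sum(self.obs.values())

    def observations(self) -> Iterator[tuple[int, str]]:
        for (pos, base), n in sorted(self.obs.items()):
            for _ in range(n):
                yield (pos, base)


Pileup = dict[tuple[str, int], PileupColumn]


# ---------------------------------------------------------------------------
# Read preprocessing and alignment filtering
# ---------------------------------------------------------------------------

def preprocess_read(
    read: ReadRecord, qmin: int = 20, lmin: int = 60, trim5: int = 3
) -> ReadRecord | None:
    """Trim and quality-clip a read; return ``None`` if it is discarded.

    The first ``trim5`` bases are removed from the 5' end, then the read is
    truncated immediately before the first remaining base with quality below
    ``qmin`` (scanning 5'->3').  Reads shorter than ``lmin`` after both
    operations are discarded.  Retained positions are renumbered 1..L, which
    is the coordinate the error model uses.
    """
    bases = read.bases[trim5:]
    quals = list(read.qualities[trim5:])
    cut = len(quals)
    for i, q in enumerate(quals):
        if q < qmin:
            cut = i
            break
    bases, quals = bases[:cut], quals[:cut]
    if len(bases) < lmin:
        return None
    return ReadRecord(read.id, bases, quals)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate FASTQ records (Phred+33) as :class:`ReadRecord`."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
        )


def filter_alignment(rec: AlignmentRecord) -> bool:
    """Keep only unique-top-hit, primary, indel-free alignments."""
    return rec.has_unique_top_hit and not rec.is_secondary and not rec.has_indel()


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Parse a plain-text SAM file into :class:`AlignmentRecord` objects.

    Mapping uniqueness is taken from the aligner's own report: MAPQ 0 or an
    ``X0`` tag greater than 1 (BWA's number of best hits) marks a tie, which
    is rejected downstream.  Unmapped records are skipped.
    """
    _num2op = "MIDNSHP=X"
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            cigar = [(_num2op[op], ln) for op, ln in (aln.cigartuples or [])]
            unique = aln.mapping_quality > 0
            if aln.has_tag("X0"):
                unique = unique and int(aln.get_tag("X0")) == 1
            yield AlignmentRecord(
                read_id=aln.query_name,
                template_id=aln.reference_name,
                template_start=aln.reference_start,
                read_offset=aln.query_alignment_start,
                cigar=cigar,
                is_secondary=aln.is_secondary,
                has_unique_top_hit=unique,
                strand="reverse" if aln.is_reverse else "forward",
                bases=aln.query_sequence.upper(),
                read_length=len(aln.query_sequence),
            )


def build_pileup(
    alignments: Iterable[AlignmentRecord], templates: TemplateSet
) -> Pileup:
    """Construct per-position pileup columns from accepted alignments.

    Each aligned base contributes one ``(read_position, observed_base)``
    observation to the column at its template coordinate.  ``read_position``
    is counted from the sequenced 5' end of the processed read, so for
    reverse-strand records (stored in template orientation) the index runs
    from the far end.  Alignments extending past the template end raise.
    """
    pileup: Pileup = {}
    for rec in alignments:
        if rec.template_id not in templates:
            raise FormatError(f"alignment {rec.read_id}: unknown template "
                              f"{rec.template_id}")
        tpl = templates[rec.template_id]
        span = rec.aligned_length()
        if rec.template_start + span > len(tpl.seq):
            raise FormatError(
                f"alignment {rec.read_id} extends past the end of template "
                f"{rec.template_id}"
            )
        read_len = rec.read_length or len(rec.bases)
        qpos = rec.read_offset
        tpos = rec.template_start
        for op, ln in rec.cigar:
            if op in _ALIGNED_OPS:
                for k in range(ln):
                    base = rec.bases[qpos + k]
                    if rec.strand == "forward":
                        read_position = qpos + k + 1
                    else:
                        read_position = read_len - (qpos + k)
                    key = (rec.template_id, tpos + k + 1)
                    col = pileup.get(key)
                    if col is None:
                        col = PileupColumn(
                            rec.template_id, tpos + k + 1, tpl.seq[tpos + k]
                        )
                        pileup[key] = col
                    col.add(read_position, base)
                qpos += ln
                tpos += ln
            elif op in "SH":
                if op == "S":
                    qpos += ln
            elif op in _INDEL_OPS:
                raise FormatError(
                    f"alignment {rec.read_id} contains an indel; filter first"
                )
    return pileup


def pileup_from_sam(path: str | Path, templates: TemplateSet) -> Pileup:
    """Read a SAM file, apply the record filters, and build the pileup."""
    return build_pileup(
        (rec for rec in read_sam(path) if filter_alignment(rec)), templates
    )


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "template", "gene", "position", "ref", "C_count", "T_count", "depth",
    "T_fraction", "theta_hat", "lrt", "pvalue",
]
DIFF_TABLE_COLUMNS = SITE_TABLE_COLUMNS + [
    "wt_extent", "mut_extent", "delta_EE", "chisq", "chisq_p", "class",
]


def write_site_table(records: Iterable[Mapping], path: str | Path) -> None:
    """Write site calls (or differential results) as a deterministic TSV.

    Rows are sorted by (template, position); floats are written at full
    precision so the table round-trips exactly through
    :func:`read_site_table`.  Columns beyond the base set are kept if present
    on every record.
    """
    rows = [dict(r) for r in records]
    if rows:
        cols = [c for c in DIFF_TABLE_COLUMNS if c in rows[0]]
        extra = [c for c in rows[0] if c not in cols]
        df = pd.DataFrame(rows)[cols + extra]
        df = df.sort_values(["template", "position"], kind="mergesort")
    else:
        df = pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Library metadata and the genotype comparison graph.

    One row per library: ``library_id, genotype, role, replicate_group,
    comparator_group, sam`` (``sam`` optional -- path to that library's
    alignments).  Replicates share a ``replicate_group``; a mutant group's
    ``comparator_group`` names the replicate group of its wild-type sibling.
    Silenced libraries are compared against both the uninoculated and the
    GFP-silenced control groups, which must both be present.
    """

    table: pd.DataFrame

    REQUIRED = ["library_id", "genotype", "role", "replicate_group"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.table.empty:
            raise FormatError("sample sheet is empty")
        bad = set(self.table["role"]) - set(SAMPLE_ROLES)
        if bad:
            raise FormatError(f"unknown roles in sample sheet: {sorted(bad)}")
        if self.table["library_id"].duplicated().any():
            raise FormatError("duplicate library_id in sample sheet")
        self._validate_graph()

    def _validate_graph(self) -> None:
        wt_groups = set(
            self.table.loc[self.table.role == "wildtype_sibling",
                           "replicate_group"]
        )
        for _, row in self.table[self.table.role == "mutant"].iterrows():
            comp = row.get("comparator_group")
            if comp is None or pd.isna(comp):
                raise FormatError(
                    f"mutant library {row.library_id} has no comparator_group"
                )
            if comp not in wt_groups:
                raise FormatError(
                    f"mutant library {row.library_id}: comparator group "
                    f"{comp!r} matches no wild-type sibling group"
                )
        if (self.table.role == "silenced").any():
            for role in ("uninoculated_control", "gfp_silenced_control"):
                if not (self.table.role == role).any():
                    raise FormatError(
                        f"silenced libraries present but no {role} library"
                    )

    @property
    def libraries(self) -> list[str]:
        return list(self.table["library_id"])

    def libraries_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table.role == role, "library_id"])

    def replicate_groups(self, role: str) -> dict[str, list[str]]:
        """Map replicate_group -> library ids, restricted to one role."""
        sub = self.table[self.table.role == role]
        return {
            g: list(d["library_id"]) for g, d in sub.groupby("replicate_group")
        }

    def comparisons(self) -> list[dict]:
        """Enumerate mutant-vs-wild-type comparisons (pooled replicates)."""
        out = []
        wt = self.replicate_groups("wildtype_sibling")
        for group, libs in self.replicate_groups("mutant").items():
            sub = self.table[self.table.replicate_group == group]
            comp = sub["comparator_group"].iloc[0]
            out.append({
                "genotype": sub["genotype"].iloc[0],
                "mutant_group": group,
                "mutant_libraries": libs,
                "wildtype_libraries": wt[comp],
            })
        return out

    def silenced_comparisons(self) -> list[dict]:
        uninoc = self.libraries_with_role("uninoculated_control")
        gfp = self.libraries_with_role("gfp_silenced_control")
        out = []
        for group, libs in self.replicate_groups("silenced").items():
            sub = self.table[self.table.replicate_group == group]
            out.append({
                "genotype": sub["genotype"].iloc[0],
                "silenced_group": group,
                "silenced_libraries": libs,
                "uninoculated_libraries": uninoc,
                "gfp_libraries": gfp,
            })
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleSheet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(pd.DataFrame(data["libraries"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM writing (used by the simulator; plain text, single-end, gapless)
# ---------------------------------------------------------------------------

def write_sam(
    path: str | Path,
    templates: TemplateSet,
    alignments: Iterable[AlignmentRecord],
    qualities_char: str = "I",
) -> None:
    """Emit gapless alignments as plain-text SAM with an @SQ header."""
    buf = io.StringIO()
    buf.write("@HD\tVN:1.6\tSO:unknown\n")
    for t in templates:
        buf.write(f"@SQ\tSN:{t.id}\tLN:{len(t.seq)}\n")
    for rec in alignments:
        flag = 16 if rec.strand == "reverse" else 0
        if rec.is_secondary:
            flag |= 256
        cigar = "".join(f"{n}{op}" for op, n in rec.cigar)
        qual = qualities_char * len(rec.bases)
        buf.write(
            f"{rec.read_id}\t{flag}\t{rec.template_id}\t"
            f"{rec.template_start + 1}\t{60 if rec.has_unique_top_hit else 0}"
            f"\t{cigar}\t*\t0\t0\t{rec.bases}\t{qual}\n"
        )
    Path(path).write_text(buf.getvalue())
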