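"""Reading, validation and cleanup of genome and CDS FASTA inputs.

This module handles the plumbing around the compositional analysis: parsing
assemblies, computing assembly-level GC and scaffold-length statistics, and
applying the standard coding-sequence cleanup rules (annotation-keyword
exclusion, start/stop codon checks, redundancy removal) before any
codon-position analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GenomeAssembly",
    "AssemblyStats",
    "CdsRecord",
    "FastaParseError",
    "DEFAULT_EXCLUSION_KEYWORDS",
    "STANDARD_START_CODONS",
    "STANDARD_STOP_CODONS",
    "read_fasta",
    "write_fasta",
    "read_cds_fasta",
    "gc_percent",
    "scaffold_stats",
    "clean_cds",
    "write_segment_table",
    "read_segment_table",
    "write_segment_bed",
]

# IUPAC nucleotide one-letter codes (unambiguous + ambiguity + gap-as-N).
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
# Deletion table: translating a valid sequence with this yields "".
_NON_IUPAC = str.maketrans("", "", "ACGTUNRYSWKMBDHVacgtunryswkmbdhv")

# Annotation keywords whose presence in a description disqualifies a gene
# from compositional analysis (case-insensitive substring match).
DEFAULT_EXCLUSION_KEYWORDS: tuple[str, ...] = (
    "partial",
    "putative",
    "synthetic construct",
    "predicted",
    "not experimental",
    "hypothetical protein",
    "r-RNA",
    "t-RNA",
    "ribosomal",
    "mitochondrial",
)

STANDARD_START_CODONS: tuple[str, ...] = ("ATG",)
STANDARD_STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed (empty, headerless, empty record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (chromosome, scaffold or contig)."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = self.sequence.translate(_NON_IUPAC)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(set(bad))}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """An ordered collection of sequence records, optionally numbered as chromosomes."""

    records: list[SequenceRecord]
    chromosome_numbers: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in assembly: {dupes}")
        if self.chromosome_numbers is not None:
            nums = list(self.chromosome_numbers.values())
            if any(n < 1 for n in nums) or len(nums) != len(set(nums)):
                raise ValueError("chromosome numbers must be unique positive integers")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class AssemblyStats:
    """Assembly-level GC and scaffold-length partition around a size cutoff.

    Megabase totals are exact (bp / 1e6, unrounded); percentages are on the
    total assembly length. GC is computed over all records with ambiguity
    codes excluded from numerator and denominator.
    """

    gc_percent: float
    n_records: int
    total_mb: float
    mb_below_cutoff: float
    mb_at_or_above_cutoff: float
    pct_below: float
    pct_at_or_above: float
    cutoff: int


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence with an optional reason for rejection by :func:`clean_cds`."""

    id: str
    description: str
    sequence: str
    rejection_reason: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly` (order preserved, bases upcased).

    Raises :class:`FastaParseError` for an empty file, a file not starting
    with a header line, or a header with no sequence.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if not text_head:
        raise FastaParseError(f"{path}: empty FASTA file")
    if not text_head.startswith(">"):
        raise FastaParseError(
            f"{path}: not FASTA-formatted, first non-blank line is {text_head.strip()!r}"
        )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        records.append(
            SequenceRecord(id=rec.id, description=rec.description, sequence=str(rec.seq).upper())
        )
    if not records:
        raise FastaParseError(f"{path}: no records parsed")
    return GenomeAssembly(records=records)


def write_fasta(records: GenomeAssembly | Iterable[SequenceRecord | CdsRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, wrapping sequence lines at `width` columns."""
    if isinstance(records, GenomeAssembly):
        records = records.records
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=_strip_id(r.description, r.id))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _strip_id(description: str, rec_id: str) -> str:
    # Biopython prepends the id to the description on output; avoid doubling it.
    if description == rec_id:
        return ""
    if description.startswith(rec_id + " "):
        return description[len(rec_id) + 1 :]
    return description


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a CDS FASTA into a list of :class:`CdsRecord` (no filtering applied)."""
    assembly = read_fasta(path)
    return [CdsRecord(id=r.id, description=r.description, sequence=r.sequence) for r in assembly]


def gc_percent(sequence: str) -> float:
    """GC percentage over unambiguous bases: 100*(G+C)/(A+C+G+T).

    N and other IUPAC ambiguity codes are excluded from numerator and
    denominator, so assembly gaps do not bias the estimate. Returns ``nan``
    if the sequence has no unambiguous bases.
    """
    gc, at = _gc_at_counts(sequence)
    denom = gc + at
    return 100.0 * gc / denom if denom else float("nan")


def _gc_at_counts(sequence: str) -> tuple[int, int]:
    bases = "GCAT" if sequence.isupper() else "GCATgcat"
    counts = {b: sequence.count(b) for b in bases}
    gc = counts["G"] + counts["C"] + counts.get("g", 0) + counts.get("c", 0)
    at = counts["A"] + counts["T"] + counts.get("a", 0) + counts.get("t", 0)
    return gc, at


def scaffold_stats(assembly: GenomeAssembly, cutoff: int = 100_000) -> AssemblyStats:
    """Partition assembly length by a scaffold-size cutoff and compute overall GC.

    The cutoff is inclusive: a record of exactly `cutoff` bases counts in the
    at-or-above class. Invariant under record reordering.
    """
    if not assembly.records:
        raise ValueError("empty assembly")
    bp_below = sum(r.length for r in assembly if r.length < cutoff)
    bp_above = sum(r.length for r in assembly if r.length >= cutoff)
    total = bp_below + bp_above
    gc_bp = at_bp = 0
    for r in assembly:
        gc, at = _gc_at_counts(r.sequence)
        gc_bp += gc
        at_bp += at
    gc = 100.0 * gc_bp / (gc_bp + at_bp) if (gc_bp + at_bp) else float("nan")
    return AssemblyStats(
        gc_percent=gc,
        n_records=assembly.n_records,
        total_mb=total / 1e6,
        mb_below_cutoff=bp_below / 1e6,
        mb_at_or_above_cutoff=bp_above / 1e6,
        pct_below=100.0 * bp_below / total,
        pct_at_or_above=100.0 * bp_above / total,
        cutoff=cutoff,
    )


def clean_cds(
    records: Sequence[CdsRecord],
    exclusion_keywords: Sequence[str] = DEFAULT_EXCLUSION_KEYWORDS,
    start_codons: Sequence[str] = STANDARD_START_CODONS,
    stop_codons: Sequence[str] = STANDARD_STOP_CODONS,
) -> tuple[list[CdsRecord], list[CdsRecord]]:
    """Apply CDS cleanup rules; return ``(accepted, rejected)``.

    Rules, in order:

    1. Descriptions containing any exclusion keyword (case-insensitive
       substring) are rejected with reason ``keyword-excluded``.
    2. Length must be a multiple of 3 (``length-not-multiple-of-3``).
    3. The first codon must be a start codon (``no-start``), the last a stop
       codon (``no-stop``), with no stop codon at any internal position
       (``internal-stop``).
    4. Exact-duplicate sequences are removed keeping the first occurrence
       (``redundant``).

    Every input record lands in exactly one of the two output lists.
    Non-standard genetic codes (e.g. ciliate stop-codon reassignment) can be
    accommodated by passing different ``start_codons`` / ``stop_codons``.
    """
    kw = [k.lower() for k in exclusion_keywords]
    starts = {c.upper() for c in start_codons}
    stops = {c.upper() for c in stop_codons}
    accepted: list[CdsRecord] = []
    rejected: list[CdsRecord] = []
    seen: set[str] = set()
    for rec in records:
        desc = rec.description.lower()
        seq = rec.sequence.upper()
        reason = None
        if any(k in desc for k in kw):
            reason = "keyword-excluded"
        elif len(seq) % 3 != 0:
            reason = "length-not-multiple-of-3"
        elif seq[:3] not in starts:
            reason = "no-start"
        elif seq[-3:] not in stops:
            reason = "no-stop"
        elif any(seq[i : i + 3] in stops for i in range(3, len(seq) - 3, 3)):
            reason = "internal-stop"
        elif seq in seen:
            reason = "redundant"
        if reason is None:
            seen.add(seq)
            accepted.append(replace(rec, rejection_reason=None))
        else:
            rejected.append(replace(rec, rejection_reason=reason))
    return accepted, rejected


# --- segment tables -------------------------------------------------------

_SEGMENT_COLUMNS = ["name", "chromosome", "start", "end", "size_kb", "gc_percent"]


def write_segment_table(segments: Sequence, path: str | Path) -> None:
    """Write segments as TSV with 1-based inclusive coordinates.

    Columns: name, chromosome, start, end, size_kb, gc_percent. Internally
    segments carry 0-based half-open coordinates; the table reports 1-based
    inclusive, the convention of published coordinate tables.
    """
    rows = [
        {
            "name": s.name,
            "chromosome": s.chrom_id,
            "start": s.start + 1,
            "end": s.end,
            "size_kb": s.size / 1000.0,
            "gc_percent": s.gc_percent,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segment_table(path: str | Path):
    """Read a segment TSV written by :func:`write_segment_table` back into segments."""
    from .segmentation import Segment  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    return [
        Segment(
            chrom_id=str(row["chromosome"]),
            start=int(row["start"]) - 1,
            end=int(row["end"]),
            gc_percent=float(row["gc_percent"]),
            name=str(row["name"]),
        )
        for _, row in df.iterrows()
    ]


def write_segment_bed(segments: Sequence, path: str | Path) -> None:
    """Write segments as BED (0-based half-open; name field = segment name)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom_id}\t{s.start}\t{s.end}\t{s.name}\t{s.gc_percent:.2f}\n")
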