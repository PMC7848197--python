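"""Readers and writers for FASTA, RepeatMasker ``.out``, BED and the TSV
report schemas, plus the shared positional domain types.

Coordinate convention
---------------------
All in-memory coordinates are 0-based, half-open (``[start, end)``), as in
BED.  RepeatMasker ``.out`` files and human-readable reports use 1-based,
inclusive coordinates; the conversion happens only at the file boundary in
this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class HaplotypeSequence:
    """A named haplotype contig.

    The sequence is upper-cased on ingest and restricted to the alphabet
    {A, C, G, T, N}; anything else is mapped to N (assemblies carry IUPAC
    ambiguity codes and alignment artifacts, and every downstream filter
    already treats N as missing).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("haplotype id must be non-empty")
        seq = self.seq.upper()
        if not set(seq) <= _VALID_BASES:
            n_mapped = sum(1 for c in seq if c not in _VALID_BASES)
            seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            logger.info(
                "sequence %s: %d non-ACGTN characters mapped to N", self.id, n_mapped
            )
        self.seq = seq

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker hit: a repeat-family interval on a query sequence."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    pct_div: float = 0.0
    sw_score: int = 0
    rm_id: int = 0

    def __post_init__(self) -> None:
        if self.pct_div < 0:
            raise ValueError("pct_div must be >= 0")


@dataclass
class AnnotationTrack:
    """The ordered repeat annotations of one haplotype.

    Annotations are kept sorted by start; overlapping hits are legal
    (RepeatMasker emits nested and overlapping fragments).
    """

    seq_id: str
    annotations: list[RepeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.interval.seq_id != self.seq_id:
                raise ValueError(
                    f"annotation on {ann.interval.seq_id!r} in track {self.seq_id!r}"
                )
        self.annotations.sort(key=lambda a: (a.interval.start, a.interval.end))

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[HaplotypeSequence]:
    """Read a FASTA file into :class:`HaplotypeSequence` records.

    Sequences are upper-cased; non-ACGTN characters become N (with a logged
    count).  Duplicate ids and empty files are errors.
    """
    records: list[HaplotypeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(HaplotypeSequence(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(
    records: Iterable[HaplotypeSequence], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path) -> dict[str, AnnotationTrack]:
    """Parse the standard 15-column RepeatMasker ``.out`` dialect.

    Returns one :class:`AnnotationTrack` per query sequence.  Query
    coordinates (1-based inclusive in the file) are converted to the internal
    0-based half-open convention; strand ``C`` becomes ``-``.
    """
    tracks: dict[str, list[RepeatAnnotation]] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        # 15 columns, or 16 when RepeatMasker appends a '*' overlap flag
        if len(fields) not in (15, 16):
            raise FormatError(
                f"{path}:{lineno}: expected 15 columns, got {len(fields)}"
            )
        (sw, div, _dele, _ins, qname, qbeg, qend, _qleft, strand,
         rname, rclass, _rbeg, _rend, _rleft, rm_id) = fields[:15]
        qbeg_i, qend_i = int(qbeg), int(qend)
        if qbeg_i > qend_i:
            raise FormatError(
                f"{path}:{lineno}: query begin {qbeg_i} > end {qend_i}"
            )
        if strand == "C":
            strand = "-"
        elif strand != "+":
            raise FormatError(f"{path}:{lineno}: bad strand field {strand!r}")
        ann = RepeatAnnotation(
            interval=GenomicInterval(qname, qbeg_i - 1, qend_i, strand),
            repeat_name=rname,
            repeat_class=rclass,
            pct_div=float(div),
            sw_score=int(sw),
            rm_id=int(rm_id),
        )
        tracks.setdefault(qname, []).append(ann)
    return {sid: AnnotationTrack(sid, anns) for sid, anns in tracks.items()}


def write_repeatmasker_out(
    tracks: dict[str, AnnotationTrack] | Iterable[AnnotationTrack],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Write tracks in the 15-column ``.out`` dialect (1-based inclusive).

    ``seq_lengths`` fills the ``(left)`` column when known; otherwise it is
    written as ``(0)``.
    """
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    seq_lengths = seq_lengths or {}
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for track in tracks:
            for ann in track:
                iv = ann.interval
                length = seq_lengths.get(iv.seq_id)
                qleft = f"({length - iv.end})" if length is not None else "(0)"
                rm_len = len(iv)
                strand = "C" if iv.strand == "-" else "+"
                fh.write(
                    f"{ann.sw_score:>5} {ann.pct_div:4.1f}  0.0  0.0  "
                    f"{iv.seq_id} {iv.start + 1} {iv.end} {qleft} "
                    f"{strand} {ann.repeat_name} {ann.repeat_class} "
                    f"1 {rm_len} (0) {ann.rm_id}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals_with_names: Iterable[tuple[GenomicInterval, str]],
    path: str | Path,
) -> None:
    """Write BED4 directly in the internal 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for interval, name in intervals_with_names:
            fh.write(f"{interval.seq_id}\t{interval.start}\t{interval.end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED4; strand from column 6 when present."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand),
                 name)
            )
    return out
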