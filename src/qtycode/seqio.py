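"""Sequence and topology I/O.

Reads and writes FASTA, segment tables (TSV) and UniProt flat-file TRANSMEM
features, and provides a Kyte–Doolittle sliding-window fallback for
transmembrane-segment inference when no curated annotation is available.

All sequence coordinates are 1-based inclusive, matching the UniProt feature
convention; conversion to 0-based slices happens only inside function bodies.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

SEGMENT_KINDS = ("TM", "ICL", "ECL", "NTERM", "CTERM")

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class SequenceError(ValueError):
    """Raised for malformed sequences or annotations."""


def _validate_sequence(seq: str, record_id: str) -> str:
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise SequenceError(
                f"record {record_id!r}: illegal residue {ch!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``id`` is an accession or label; ``sequence`` holds uppercase one-letter
    codes restricted to the 20 standard amino acids.  Ambiguity codes
    (B/Z/X) and non-standard residues (U/O) are rejected because downstream
    substitution and mass computations require exact identities.
    """

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence, self.id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """A labeled 1-based inclusive interval of a sequence."""

    label: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise SequenceError(
                f"segment {self.label!r}: unknown kind {self.kind!r} "
                f"(expected one of {', '.join(SEGMENT_KINDS)})"
            )
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"segment {self.label!r}: invalid interval {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        """1-based positions covered by this segment."""
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SegmentAnnotation:
    """Ordered, validated segments over one record.

    TM segments must be pairwise non-overlapping; other kinds may overlap
    freely (loop boundaries from different sources are often fuzzy).
    """

    record_id: str
    segments: tuple[Segment, ...]
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: (s.start, s.end)))
        object.__setattr__(self, "segments", segs)
        if self.sequence_length is not None:
            for s in segs:
                if s.end > self.sequence_length:
                    raise SequenceError(
                        f"segment {s.label!r} ({s.start}..{s.end}) exceeds "
                        f"sequence length {self.sequence_length}"
                    )
        tms = self.tm_segments
        for a, b in zip(tms, tms[1:]):
            if b.start <= a.end:
                raise SequenceError(
                    f"TM segments {a.label!r} and {b.label!r} overlap"
                )

    @property
    def tm_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "TM")

    def of_kinds(self, kinds: Iterable[str]) -> tuple[Segment, ...]:
        wanted = set(kinds)
        return tuple(s for s in self.segments if s.kind in wanted)

    def segment_at(self, position: int) -> Segment | None:
        """First segment covering a 1-based position, or None."""
        for s in self.segments:
            if s.start <= position <= s.end:
                return s
        return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(stream) -> list[ProteinRecord]:
    """Parse FASTA text (or a text handle) into ProteinRecords.

    Record ids are the first whitespace-delimited header token; the header
    remainder becomes ``name``.  Sequences are uppercased and validated;
    gap characters are rejected with the offending position.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq)
        name = rec.description[len(rec.id):].strip() if rec.description else ""
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq, name=name))
    if not records:
        raise SequenceError("no records")
    return records


def write_fasta(records: Sequence[ProteinRecord], line_width: int = 60) -> str:
    """Serialize records as FASTA, wrapping sequence lines at ``line_width``."""
    if not records:
        raise SequenceError("no records to write")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    out: list[str] = []
    for rec in records:
        header = f">{rec.id}" + (f" {rec.name}" if rec.name else "")
        out.append(header)
        for i in range(0, len(rec.sequence), line_width):
            out.append(rec.sequence[i : i + line_width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

def load_segments(stream, record: ProteinRecord) -> SegmentAnnotation:
    """Load a tab-separated segment table.

    Lines are ``label<TAB>kind<TAB>start<TAB>end`` with 1-based inclusive
    coordinates; ``#`` starts a comment.  Intervals are validated against the
    record length and TM overlap is rejected naming both segments.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    segments: list[Segment] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SequenceError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
            )
        label, kind, start_s, end_s = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise SequenceError(f"line {lineno}: non-integer coordinate") from None
        if not (1 <= start <= end <= len(record)):
            raise SequenceError(
                f"line {lineno}: interval {start}..{end} out of range for "
                f"sequence of length {len(record)}"
            )
        segments.append(Segment(label=label, start=start, end=end, kind=kind))
    if not segments:
        raise SequenceError("no segments")
    return SegmentAnnotation(
        record_id=record.id, segments=tuple(segments), sequence_length=len(record)
    )


def write_segments(annotation: SegmentAnnotation) -> str:
    lines = [f"# segments for {annotation.record_id}"]
    for s in annotation.segments:
        lines.append(f"{s.label}\t{s.kind}\t{s.start}\t{s.end}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# UniProt flat text
# ---------------------------------------------------------------------------

_FT_NEW = re.compile(r"^FT\s+TRANSMEM\s+(\d+)\.\.(\d+)")
_FT_OLD = re.compile(r"^FT\s+TRANSMEM\s+(\d+)\s+(\d+)")
_SQ = re.compile(r"^SQ\s+SEQUENCE\s+(\d+)\s+AA")


def transmem_from_uniprot_text(stream, record: ProteinRecord) -> SegmentAnnotation:
    """Extract TRANSMEM features from UniProt flat-file text.

    Accepts both the current ``40..63`` and the legacy two-column feature
    coordinate syntax.  Features become TM1..TMn in order of appearance.
    If the flat file carries an ``SQ`` line, its length must match the record.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    intervals: list[tuple[int, int]] = []
    declared_length: int | None = None
    for line in stream:
        m = _FT_NEW.match(line) or _FT_OLD.match(line)
        if m:
            intervals.append((int(m.group(1)), int(m.group(2))))
            continue
        m = _SQ.match(line)
        if m:
            declared_length = int(m.group(1))
    if not intervals:
        raise SequenceError("no transmembrane annotation")
    if declared_length is not None and declared_length != len(record):
        raise SequenceError(
            f"sequence length mismatch: flat file declares {declared_length} aa, "
            f"record {record.id!r} has {len(record)}"
        )
    segments = tuple(
        Segment(label=f"TM{i}", start=a, end=b, kind="TM")
        for i, (a, b) in enumerate(intervals, start=1)
    )
    return SegmentAnnotation(
        record_id=record.id, segments=segments, sequence_length=len(record)
    )


# ---------------------------------------------------------------------------
# Hydropathy fallback
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed-mean hydropathy; score i covers window centred at i+window//2."""

    record_id: str
    window: int
    scores: tuple[float, ...] = field(repr=False)


def hydropathy_profile(
    record: ProteinRecord, window: int = 19, scale: dict[str, float] | None = None
) -> HydropathyProfile:
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > len(record):
        raise SequenceError(
            f"window {window} exceeds sequence length {len(record)}"
        )
    sc = scale or KYTE_DOOLITTLE
    vals = [sc[ch] for ch in record.sequence]
    n = len(vals) - window + 1
    acc = sum(vals[:window])
    scores = [acc / window]
    for i in range(1, n):
        acc += vals[i + window - 1] - vals[i - 1]
        scores.append(acc / window)
    return HydropathyProfile(record_id=record.id, window=window, scores=tuple(scores))


def infer_tm_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> SegmentAnnotation:
    """Infer TM segments as maximal above-threshold hydropathy runs.

    A deterministic, fallback-quality scan: windowed Kyte–Doolittle means are
    assigned to window-centre positions; maximal runs above ``threshold``
    shorter than ``min_len`` are dropped.  Curated tables should be preferred
    whenever available.
    """
    prof = hydropathy_profile(record, window=window)
    half = window // 2
    # centre position (1-based) of score i is i + half + 1
    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(prof.scores):
        if s > threshold:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(prof.scores) - 1))
    segments = []
    n = 0
    for a, b in runs:
        s, e = a + half + 1, b + half + 1
        if e - s + 1 >= min_len:
            n += 1
            segments.append(Segment(label=f"TM{n}", start=s, end=e, kind="TM"))
    return SegmentAnnotation(
        record_id=record.id, segments=tuple(segments), sequence_length=len(record)
    )
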