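"""Residue-substitution engine.

Applies a configurable substitution code inside annotated segments.  The
default map is the QTY code — L→Q, I→T, V→T, F→Y — which removes the four
hydrophobic residues that line the lipid-facing surface of transmembrane
helices.  Alternative alphabets (e.g. Q/T/Y→A, →R, →G back-substitutions)
are plain data and can be loaded from small TSV documents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, NamedTuple, Sequence

from qtycode.seqio import (
    AMINO_ACIDS,
    ProteinRecord,
    SegmentAnnotation,
    SequenceError,
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, used for all reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubstitutionMap:
    """A named source→target residue mapping; no source maps to itself."""

    name: str
    rules: dict[str, str]

    def __post_init__(self) -> None:
        for src, dst in self.rules.items():
            if src not in AMINO_ACIDS or dst not in AMINO_ACIDS:
                raise SequenceError(
                    f"map {self.name!r}: invalid rule {src!r}→{dst!r}"
                )
            if src == dst:
                raise SequenceError(
                    f"map {self.name!r}: source {src!r} maps to itself"
                )

    @classmethod
    def from_tsv(cls, stream) -> "SubstitutionMap":
        """Load ``from<TAB>to`` rows; a ``# name: X`` comment names the map."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        name = "custom"
        rules: dict[str, str] = {}
        for raw in stream:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("name:"):
                    name = body[5:].strip()
                continue
            src, dst = line.split("\t")
            rules[src.strip()] = dst.strip()
        if not rules:
            raise SequenceError("substitution map has no rules")
        return cls(name=name, rules=rules)

    def to_tsv(self) -> str:
        lines = [f"# name: {self.name}"]
        lines += [f"{s}\t{t}" for s, t in self.rules.items()]
        return "\n".join(lines) + "\n"


#: The canonical QTY code (pairing L→Q, I→T, V→T, F→Y).
QTY_MAP = SubstitutionMap(name="QTY", rules={"L": "Q", "I": "T", "V": "T", "F": "Y"})

DEFAULT_SCOPE = frozenset({"TM"})


class SubstitutionEvent(NamedTuple):
    position: int  # 1-based
    source: str
    target: str
    segment_label: str


@dataclass(frozen=True)
class QTYResult:
    """Outcome of a substitution-only transform: native, variant, events."""

    native: ProteinRecord
    variant: ProteinRecord
    events: tuple[SubstitutionEvent, ...]

    def __post_init__(self) -> None:
        if len(self.native) != len(self.variant):
            raise SequenceError("native and variant lengths differ")


@dataclass(frozen=True)
class VariationStats:
    identity_pct: float
    total_variation_pct: float
    membrane_variation_pct: float
    n_events: int
    n_tm_residues: int


def apply_substitution(
    record: ProteinRecord,
    annotation: SegmentAnnotation,
    sub_map: SubstitutionMap = QTY_MAP,
    scope: Iterable[str] = DEFAULT_SCOPE,
    extra_positions: Sequence[int] = (),
    variant_id: str | None = None,
) -> QTYResult:
    """Apply ``sub_map`` to every scoped position of ``record``.

    ``scope`` selects segment kinds (default: TM only).  ``extra_positions``
    is a per-protein override list of additional 1-based positions to treat
    as in scope — the hook for designs that also modify intracellular-loop or
    C-terminal residues.  Positions outside scope are never touched.
    """
    if annotation.record_id != record.id:
        raise SequenceError(
            f"annotation is for {annotation.record_id!r}, record is {record.id!r}"
        )
    if annotation.sequence_length is not None and annotation.sequence_length != len(record):
        raise SequenceError("annotation length does not match record")
    scoped = set()
    label_at: dict[int, str] = {}
    for seg in annotation.of_kinds(scope):
        for p in seg.positions():
            scoped.add(p)
            label_at.setdefault(p, seg.label)
    for p in extra_positions:
        if not (1 <= p <= len(record)):
            raise SequenceError(f"extra position {p} out of range")
        scoped.add(p)
        if p not in label_at:
            seg = annotation.segment_at(p)
            label_at[p] = seg.label if seg else "extra"

    chars = list(record.sequence)
    events: list[SubstitutionEvent] = []
    for p in sorted(scoped):
        src = chars[p - 1]
        dst = sub_map.rules.get(src)
        if dst is not None:
            chars[p - 1] = dst
            events.append(SubstitutionEvent(p, src, dst, label_at[p]))
    variant = ProteinRecord(
        id=variant_id or f"{record.id}_{sub_map.name}",
        sequence="".join(chars),
        name=f"{record.name} [{sub_map.name} variant]".strip(),
    )
    return QTYResult(native=record, variant=variant, events=tuple(events))


def positional_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Percentage of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise SequenceError(
            f"length mismatch: {a.id!r} has {len(a)}, {b.id!r} has {len(b)}"
        )
    matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
    return round_half_up(100.0 * matches / len(a))


def variation_stats(
    result: QTYResult, annotation: SegmentAnnotation
) -> VariationStats:
    """Total and membrane (TM-restricted) variation rates for one pair."""
    if annotation.record_id != result.native.id:
        raise SequenceError("annotation does not belong to the result's record")
    length = len(result.native)
    tm_positions: set[int] = set()
    for seg in annotation.tm_segments:
        tm_positions.update(seg.positions())
    tm_events = sum(1 for e in result.events if e.position in tm_positions)
    if tm_events and not tm_positions:
        raise SequenceError("events inside TM segments but annotation has none")
    total_pct = round_half_up(100.0 * len(result.events) / length)
    membrane_pct = (
        round_half_up(100.0 * tm_events / len(tm_positions)) if tm_positions else 0.0
    )
    return VariationStats(
        identity_pct=round_half_up(100.0 - 100.0 * len(result.events) / length),
        total_variation_pct=total_pct,
        membrane_variation_pct=membrane_pct,
        n_events=len(result.events),
        n_tm_residues=len(tm_positions),
    )


def render_alignment(
    a: ProteinRecord,
    b: ProteinRecord,
    annotation: SegmentAnnotation | None = None,
    block_width: int = 60,
) -> str:
    """Plain-text pairwise view: '|' marks identical columns, '*' differing.

    Blocks of ``block_width`` columns carry an optional ruler line marking TM
    segments with '=' under their extent, and a trailing legend listing the
    differing positions.
    """
    if len(a) != len(b):
        raise SequenceError("cannot render alignment of unequal-length sequences")
    if block_width < 1:
        raise ValueError("block_width must be positive")
    match = "".join(
        "|" if x == y else "*" for x, y in zip(a.sequence, b.sequence)
    )
    ruler = [" "] * len(a)
    if annotation is not None:
        for seg in annotation.tm_segments:
            for p in seg.positions():
                if p <= len(a):
                    ruler[p - 1] = "="
    ruler_s = "".join(ruler)
    width = max(len(a.id), len(b.id), 2)
    out: list[str] = [f"{a.id} vs {b.id} ({len(a)} aa)"]
    for off in range(0, len(a), block_width):
        end = min(off + block_width, len(a))
        if annotation is not None:
            out.append(f"{'':>{width}}  {ruler_s[off:end]}")
        out.append(f"{a.id:>{width}}  {a.sequence[off:end]}  {end}")
        out.append(f"{'':>{width}}  {match[off:end]}")
        out.append(f"{b.id:>{width}}  {b.sequence[off:end]}  {end}")
        out.append("")
    diffs = [str(i + 1) for i, c in enumerate(match) if c == "*"]
    out.append(
        f"differing positions ({len(diffs)}): {', '.join(diffs) if diffs else 'none'}"
    )
    return "\n".join(out) + "\n"
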