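"""Alignment records and CIGAR handling shared across the package.

Alignments are held in a PAF-like record: query/target coordinates are
0-based half-open, target coordinates always refer to the forward strand
of the target, and the CIGAR is an explicit operation list distinguishing
match (``=``) from mismatch (``X``). An ambiguous ``M`` is accepted on
input and flagged, but all internal producers emit ``=``/``X``/``I``/``D``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

OP_MATCH = "match"
OP_MISMATCH = "mismatch"
OP_INS = "ins"
OP_DEL = "del"

_CIGAR_CODE = {"=": OP_MATCH, "X": OP_MISMATCH, "I": OP_INS, "D": OP_DEL, "M": OP_MATCH}
_CODE_CIGAR = {OP_MATCH: "=", OP_MISMATCH: "X", OP_INS: "I", OP_DEL: "D"}
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# query-consuming / target-consuming op sets
QUERY_OPS = {OP_MATCH, OP_MISMATCH, OP_INS}
TARGET_OPS = {OP_MATCH, OP_MISMATCH, OP_DEL}


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a cg-style CIGAR string into ``(op, length)`` pairs.

    ``M`` is accepted and mapped to match (match-or-mismatch is flagged by
    the caller via :func:`cigar_has_ambiguous_m` when it matters).
    """
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR string: {cigar!r}")
        length = int(m.group(1))
        code = m.group(2)
        if code in ("N", "S", "H", "P"):
            raise ValueError(f"unsupported CIGAR op {code!r} in {cigar!r}")
        ops.append((_CIGAR_CODE[code], length))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return ops


def cigar_has_ambiguous_m(cigar: str) -> bool:
    return "M" in cigar


def cigar_to_string(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{_CODE_CIGAR[op]}" for op, n in ops)


def cigar_spans(ops: list[tuple[str, int]]) -> tuple[int, int]:
    """Return (query_span, target_span) consumed by the operation list."""
    q = sum(n for op, n in ops if op in QUERY_OPS)
    t = sum(n for op, n in ops if op in TARGET_OPS)
    return q, t


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment with an explicit CIGAR."""

    read_id: str
    target: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    cigar: list[tuple[str, int]] = field(default_factory=list)
    query_length: int | None = None
    target_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.cigar:
            q, t = cigar_spans(self.cigar)
            if q != self.query_end - self.query_start:
                raise ValueError(
                    f"read {self.read_id}: CIGAR consumes {q} query bases, "
                    f"span is {self.query_end - self.query_start}"
                )
            if t != self.target_end - self.target_start:
                raise ValueError(
                    f"read {self.read_id}: CIGAR consumes {t} target bases, "
                    f"span is {self.target_end - self.target_start}"
                )

    @property
    def aligned_query_length(self) -> int:
        return self.query_end - self.query_start

    def op_counts(self) -> dict[str, int]:
        counts = {OP_MATCH: 0, OP_MISMATCH: 0, OP_INS: 0, OP_DEL: 0}
        for op, n in self.cigar:
            counts[op] += n
        return counts
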