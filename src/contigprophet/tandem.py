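"""Tandem repeat array detection: telomeric (TTAGGG) and multi-kb units.

Arrays are found by rotation-aware unit tiling: for every cyclic rotation
of the unit the sequence is scored +1 per matching base and -q per
mismatching base, with q chosen so the score breaks even exactly at the
minimum purity (q = purity / (1 - purity)). Maximal positive-scoring
segments then delimit arrays with sharp boundaries: random flanking
sequence (~25% match) scores steeply negative while a diverged array above
the purity floor scores positive. Candidates from all rotations are
deduplicated by keeping the best-scoring of any overlapping pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TELOMERE_UNIT = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TandemArrayAnnotation:
    """A detected repeat array on a read or contig."""

    sequence_id: str
    unit: str
    array_start: int
    array_end: int  # 0-based half-open
    copy_count: int  # nearest whole number of unit copies
    copy_count_fractional: float
    purity: float  # percent of array bases matching the best unit tiling

    @property
    def span(self) -> int:
        return self.array_end - self.array_start


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _positive_segments(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal positive-scoring segments (start, end, score) of a score array.

    A segment starts after the running score last hit its minimum and ends
    at the argmax of the running score within its positive stretch; this is
    the linear-scan maximal-subarray decomposition, vectorised.
    """
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    floor = np.minimum.accumulate(prefix[:-1])
    cur = prefix[1:] - floor  # best suffix score ending at i
    positive = cur > 0
    if not positive.any():
        return []
    segments: list[tuple[int, int, float]] = []
    edges = np.flatnonzero(np.diff(positive.astype(np.int8)))
    starts = [0] if positive[0] else []
    starts += [int(e) + 1 for e in edges if positive[e + 1]]
    ends = [int(e) + 1 for e in edges if positive[e]]
    if positive[-1]:
        ends.append(len(cur))
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(cur[s:e]))
        segments.append((s, peak + 1, float(cur[peak])))
    return segments


def annotate_tandem_arrays(
    sequence: str,
    unit: str,
    min_purity: float = 80.0,
    min_copies: int = 3,
    sequence_id: str = "seq",
) -> list[TandemArrayAnnotation]:
    """Detect tandem arrays of ``unit`` (any cyclic rotation) in a sequence."""
    u = len(unit)
    n = len(sequence)
    if not (1 <= u <= n):
        return []
    if not (0.0 < min_purity <= 100.0):
        raise ValueError("min_purity must be in (0, 100]")
    seq_codes = _encode(sequence)
    unit_codes = _encode(unit)
    penalty = (
        min_purity / (100.0 - min_purity) if min_purity < 100.0 else float(n + 1)
    )
    # M[r, i]: does seq[i] match rotation-r tiling (array starting at i ≡ r mod u)?
    idx = (np.arange(n)[None, :] - np.arange(u)[:, None]) % u
    match = unit_codes[idx] == seq_codes[None, :]
    candidates: list[tuple[float, int, int, int]] = []  # (score, start, end, matches)
    for r in range(u):
        scores = np.where(match[r], 1.0, -penalty)
        cummatch = np.concatenate([[0], np.cumsum(match[r])])
        for s, e, score in _positive_segments(scores):
            span = e - s
            n_match = int(cummatch[e] - cummatch[s])
            purity = 100.0 * n_match / span
            if span / u >= min_copies - 0.5 and purity >= min_purity:
                candidates.append((score, s, e, n_match))
    # keep the best-scoring candidate of any overlapping pair (rotations of
    # one array all detect roughly the same interval)
    chosen: list[tuple[float, int, int, int]] = []
    for cand in sorted(candidates, key=lambda c: (-c[0], c[1])):
        if all(cand[2] <= c[1] or c[2] <= cand[1] for c in chosen):
            chosen.append(cand)
    out = []
    for score, s, e, n_match in sorted(chosen, key=lambda c: c[1]):
        span = e - s
        copies = span / u
        out.append(
            TandemArrayAnnotation(
                sequence_id=sequence_id,
                unit=unit,
                array_start=int(s),
                array_end=int(e),
                copy_count=int(round(copies)),
                copy_count_fractional=float(copies),
                purity=100.0 * n_match / span,
            )
        )
    return [a for a in out if a.copy_count >= min_copies]


def telomere_annotation(
    read_sequence: str,
    unit: str = TELOMERE_UNIT,
    min_purity: float = 80.0,
    terminal_slack: int = 100,
) -> tuple[int | None, int]:
    """Locate the terminal telomeric array on a read.

    Both strands are considered (TTAGGG and its reverse complement CCCTAA)
    and both read ends; an array is terminal when it ends within
    ``terminal_slack`` bases of a read end. Returns (junction, span): the
    junction is the array boundary facing the read interior, the span the
    length of the detected array. (None, 0) when no terminal array exists.
    Scanning both the read and its reverse complement makes the reported
    span strand-symmetric by construction.
    """
    n = len(read_sequence)
    candidates: list[tuple[int, int]] = []  # (start, end) in read coordinates
    for seq, flip in ((read_sequence, False), (reverse_complement(read_sequence), True)):
        for probe in (unit, reverse_complement(unit)):
            for ann in annotate_tandem_arrays(seq, probe, min_purity=min_purity):
                s, e = ann.array_start, ann.array_end
                if flip:
                    s, e = n - e, n - s
                candidates.append((s, e))
    terminal = [
        (s, e)
        for s, e in candidates
        if e >= n - terminal_slack or s <= terminal_slack
    ]
    if not terminal:
        return None, 0
    s, e = max(terminal, key=lambda c: (c[1] - c[0], -min(c[0], n - c[1])))
    junction = s if e >= n - terminal_slack else e
    return junction, e - s


def telomere_report(
    spans_by_arm: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Per-chromosome-arm telomere span summary; empty arms are omitted."""
    rows = []
    for arm in sorted(spans_by_arm):
        spans = list(spans_by_arm[arm])
        if not spans:
            continue
        rows.append(
            {
                "arm": arm,
                "n_reads": len(spans),
                "spans": spans,
                "median_span": float(np.median(spans)),
            }
        )
    return pd.DataFrame(rows, columns=["arm", "n_reads", "spans", "median_span"])
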