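"""Homopolymer call-length accuracy from boundary-anchored alignments.

A reference homopolymer (e.g. the AAA in TAAAG) is enclosed by two
non-homopolymer boundary bases. For a read alignment spanning the run plus
both boundaries, the match/mismatch/insertion/deletion operations strictly
between the boundary bases are tabulated; alignments whose boundary
positions are not themselves aligned with a match or mismatch are rejected
as unanchored. The called homopolymer length is the reference run length
plus inserted minus deleted bases within the enclosed region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import OP_DEL, OP_INS, AlignmentRecord


@dataclass(frozen=True)
class HomopolymerRun:
    """Maximal same-base reference run with its two flanking boundary bases."""

    chrom: str
    start: int
    end: int  # 0-based half-open
    base: str
    left_boundary: str
    right_boundary: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomopolymerObservation:
    run: HomopolymerRun
    read_id: str
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int

    @property
    def delta(self) -> int:
        return self.n_ins - self.n_del

    @property
    def observed_length(self) -> int:
        return self.run.length + self.delta


def find_homopolymer_runs(
    sequence: str, min_length: int = 2, chrom: str = "ref"
) -> list[HomopolymerRun]:
    """Maximal runs of length >= min_length with both boundary bases present.

    Runs touching either sequence end lack a boundary and are excluded; N
    never forms a run (and an N boundary is fine — it differs from the run
    base by construction).
    """
    runs: list[HomopolymerRun] = []
    seq = sequence.upper()
    n = len(seq)
    i = 0
    while i < n:
        base = seq[i]
        j = i + 1
        while j < n and seq[j] == base:
            j += 1
        if base in "ACGT" and j - i >= min_length and i > 0 and j < n:
            runs.append(HomopolymerRun(chrom, i, j, base, seq[i - 1], seq[j]))
        i = j
    return runs


class NotSpanned(Exception):
    """Alignment does not cover the run plus both boundary bases."""


class NotAnchored(Exception):
    """A boundary base is not aligned with a match/mismatch operation."""


def homopolymer_call(
    rec: AlignmentRecord, run: HomopolymerRun
) -> HomopolymerObservation:
    """Tabulate alignment operations between the boundary bases of one run.

    Raises :class:`NotSpanned` when the alignment does not reach both
    boundary positions, :class:`NotAnchored` when either boundary is not a
    match/mismatch column. Insertions are attributed to the target position
    of the preceding aligned base, so an insertion adjacent to the left edge
    of the run (an over-called homopolymer) counts as inside it.
    """
    left = run.start - 1  # target position of the left boundary base
    right = run.end  # target position of the right boundary base
    if rec.target_start > left or rec.target_end < right + 1:
        raise NotSpanned(
            f"alignment [{rec.target_start},{rec.target_end}) does not span "
            f"run plus boundaries [{left},{right + 1})"
        )
    n_match = n_mismatch = n_ins = n_del = 0
    anchored_left = anchored_right = False
    t = rec.target_start
    for op, length in rec.cigar:
        if op == OP_INS:
            # preceding aligned target base is t - 1
            if left <= t - 1 <= right - 1:
                n_ins += length
            continue
        t_next = t + length
        if op in ("match", "mismatch"):
            if t <= left < t_next:
                anchored_left = True
            if t <= right < t_next:
                anchored_right = True
            inside = min(t_next, run.end) - max(t, run.start)
            if inside > 0:
                if op == "match":
                    n_match += inside
                else:
                    n_mismatch += inside
        elif op == OP_DEL:
            inside = min(t_next, run.end) - max(t, run.start)
            if inside > 0:
                n_del += inside
        t = t_next
    if not (anchored_left and anchored_right):
        raise NotAnchored(f"read {rec.read_id}: boundary not aligned as match/mismatch")
    return HomopolymerObservation(run, rec.read_id, n_match, n_mismatch, n_ins, n_del)


def collect_observations(
    runs: Iterable[HomopolymerRun],
    alignments: Iterable[AlignmentRecord],
) -> list[HomopolymerObservation]:
    """All anchored observations of the given runs across the alignments."""
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_chrom.setdefault(rec.target, []).append(rec)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.target_start)
    obs: list[HomopolymerObservation] = []
    for run in runs:
        for rec in by_chrom.get(run.chrom, []):
            if rec.target_start > run.start - 1:
                break
            if rec.target_end < run.end + 1:
                continue
            try:
                obs.append(homopolymer_call(rec, run))
            except (NotSpanned, NotAnchored):
                continue
    return obs


def homopolymer_profile(
    genome: Mapping[str, str],
    alignments: Sequence[AlignmentRecord],
    max_per_length: int = 1000,
    seed: int = 0,
    min_length: int = 2,
) -> pd.DataFrame:
    """Median called length per reference homopolymer length.

    At most ``max_per_length`` runs are sampled uniformly without
    replacement (seeded) for each reference run length before observations
    are aggregated. Returns a table with columns ref_length, n,
    median_observed, mean_observed.
    """
    rng = np.random.default_rng(seed)
    runs: list[HomopolymerRun] = []
    for chrom, seq in genome.items():
        runs.extend(find_homopolymer_runs(seq, min_length=min_length, chrom=chrom))
    by_length: dict[int, list[HomopolymerRun]] = {}
    for run in runs:
        by_length.setdefault(run.length, []).append(run)
    sampled: list[HomopolymerRun] = []
    for length in sorted(by_length):
        group = by_length[length]
        if len(group) > max_per_length:
            idx = rng.choice(len(group), size=max_per_length, replace=False)
            group = [group[i] for i in sorted(idx)]
        sampled.extend(group)
    obs = collect_observations(sampled, alignments)
    rows = []
    by_ref: dict[int, list[int]] = {}
    for o in obs:
        by_ref.setdefault(o.run.length, []).append(o.observed_length)
    for length in sorted(by_ref):
        vals = np.array(by_ref[length])
        rows.append(
            {
                "ref_length": length,
                "n": int(vals.size),
                "median_observed": float(np.median(vals)),
                "mean_observed": float(vals.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["ref_length", "n", "median_observed", "mean_observed"])
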