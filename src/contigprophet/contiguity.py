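"""Repeat-bridging model of assembly contiguity.

A repeat of length ``ell`` is *bridged* when at least one read covers the
whole repeat plus at least one base of unique flank on each side. A read of
length ``L`` placed uniformly on a genome of size ``G`` therefore bridges a
given repeat with probability ``w/G`` where ``w = max(0, L - ell - 2)`` is
the number of admissible start positions. Over an empirical read-length
multiset ``{L_j}`` the probability that the repeat is unspanned by every
read is the exact product

    p(ell) = prod_j (1 - w_j / G),

which reduces to the classical fixed-read-length form
``exp(-N (L - ell - 2) / G)`` when all reads share one length. Given a
histogram of merged repeat lengths (``a_i`` repeats in length bin ``i``),
the chance that at least one repeat of that bin goes unbridged is
``P(ell) = 1 - (1 - p(ell))^{a_i}`` under independence. The shortest
``ell`` on a 1-kb grid with ``P > alpha`` (default 0.05) is the spanned
repeat length of a read set, and the expected NG50 when repeats up to a
given length are resolvable follows from cutting each chromosome at the
remaining unresolved repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly import ng_statistic

DEFAULT_IDENTITY_THRESHOLDS = (0.0, 90.0, 95.0, 98.0, 99.0, 99.5)

GAP = "gap"


@dataclass
class ReadLengthDistribution:
    """Multiset of read lengths together with the genome size G.

    ``n_at_least(L)`` and ``coverage_at_least(L)`` are the N and c of the
    classical fixed-length bridging formula.
    """

    lengths: np.ndarray
    genome_size: int

    def __init__(self, lengths: Iterable[int], genome_size: int):
        arr = np.asarray(sorted(int(x) for x in lengths), dtype=np.int64)
        if arr.size and arr.min() <= 0:
            raise ValueError("read lengths must be positive")
        if genome_size <= 0:
            raise ValueError("genome size must be positive")
        self.lengths = arr
        self.genome_size = int(genome_size)

    @property
    def n_reads(self) -> int:
        return int(self.lengths.size)

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def n_at_least(self, length: int) -> int:
        """Number of reads with length >= ``length``."""
        return int(self.lengths.size - np.searchsorted(self.lengths, length, side="left"))

    def coverage_at_least(self, length: int) -> float:
        """Fold coverage contributed by reads of length >= ``length``."""
        i = np.searchsorted(self.lengths, length, side="left")
        return float(self.lengths[i:].sum()) / self.genome_size

    def n50(self) -> int | None:
        """Read length N50: reads of this length or greater sum to half the total bases."""
        return ng_statistic(self.lengths.tolist(), self.total_bases)


@dataclass(frozen=True)
class RepeatInterval:
    """Identity-annotated genomic interval; gaps are always unresolvable."""

    chrom: str
    start: int
    end: int
    identity: float = 0.0
    kind: str = "segdup"  # segdup | selfchain | gap

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatTrack:
    """Disjoint, sorted repeat intervals plus chromosome sizes."""

    intervals: list[RepeatInterval]
    chromosome_sizes: dict[str, int]

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)


def build_repeat_track(
    raw_intervals: Sequence[RepeatInterval],
    identity_threshold: float,
    chromosome_sizes: dict[str, int],
) -> RepeatTrack:
    """Filter repeats below an identity threshold, keep gaps, merge the rest.

    Intervals that overlap or abut are merged into one. A threshold of 0
    keeps everything (the 0% identity class).
    """
    for iv in raw_intervals:
        size = chromosome_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > size:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome size {size}"
            )
    kept = [
        iv for iv in raw_intervals if iv.kind == GAP or iv.identity >= identity_threshold
    ]
    merged: list[RepeatInterval] = []
    for iv in sorted(kept, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = RepeatInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                max(prev.identity, iv.identity),
                GAP if GAP in (prev.kind, iv.kind) else prev.kind,
            )
        else:
            merged.append(iv)
    return RepeatTrack(merged, dict(chromosome_sizes))


@dataclass
class RepeatHistogram:
    """Binned length histogram of merged repeats (a_i counts per 1-kb bin).

    Bin ``i`` (1-based) holds lengths in ``((i-1)*bin_width, i*bin_width]``.
    """

    bin_width: int
    counts: dict[int, int] = field(default_factory=dict)

    def count_for_length(self, length: int, cumulative: bool = False) -> int:
        """a_i for the bin containing ``length``; cumulatively over all
        longer-or-equal bins when ``cumulative`` is set."""
        i = bin_index(length, self.bin_width)
        if cumulative:
            return sum(c for j, c in self.counts.items() if j >= i)
        return self.counts.get(i, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def bin_index(length: int, bin_width: int) -> int:
    return (int(length) + bin_width - 1) // bin_width


def repeat_length_histogram(track: RepeatTrack, bin_width: int = 1000) -> RepeatHistogram:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    for iv in track.intervals:
        i = bin_index(iv.length, bin_width)
        counts[i] = counts.get(i, 0) + 1
    return RepeatHistogram(bin_width, counts)


def prob_repeat_unbridged(
    repeat_length: int,
    dist: ReadLengthDistribution,
    approximate: bool = False,
) -> float:
    """Probability that no read bridges a single repeat of the given length.

    Exact product over reads; ``approximate`` uses the exponential form
    ``exp(-sum_j w_j / G)`` which agrees closely when every ``w_j/G`` is
    small.
    """
    if repeat_length < 1:
        raise ValueError("repeat length must be >= 1")
    G = dist.genome_size
    w = np.maximum(dist.lengths - repeat_length - 2, 0).astype(np.float64)
    if approximate:
        return float(math.exp(-w.sum() / G))
    frac = w / G
    if np.any(frac >= 1.0):
        return 0.0
    return float(np.exp(np.log1p(-frac).sum()))


def prob_any_unbridged(
    repeat_length: int,
    hist: RepeatHistogram,
    dist: ReadLengthDistribution,
    cumulative: bool = False,
) -> float:
    """P(at least one repeat in the length bin is unbridged), repeats independent."""
    a = hist.count_for_length(repeat_length, cumulative=cumulative)
    if a == 0:
        return 0.0
    p = prob_repeat_unbridged(repeat_length, dist)
    return float(-math.expm1(a * math.log1p(-p))) if p < 1.0 else 1.0


def spanned_repeat_length(
    dist: ReadLengthDistribution,
    hist: RepeatHistogram,
    alpha: float = 0.05,
    max_length: int = 100_000,
    step: int = 1000,
    cumulative: bool = False,
) -> int | None:
    """Shortest grid repeat length with P(any unbridged) > alpha, or None."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if step <= 0:
        raise ValueError("step must be positive")
    for ell in range(step, max_length + 1, step):
        if prob_any_unbridged(ell, hist, dist, cumulative=cumulative) > alpha:
            return ell
    return None


def expected_ng50(
    track: RepeatTrack,
    resolvable_length: int,
    genome_size: int,
) -> int:
    """Expected NG50 when repeats of length <= resolvable_length are resolved.

    Unresolved repeats cut each chromosome into inter-repeat segments
    (repeat bases excluded); the NG50 of those segments against
    ``genome_size`` is returned (0 when the segments do not reach half the
    genome).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    segments: list[int] = []
    by_chrom: dict[str, list[RepeatInterval]] = {}
    for iv in track.intervals:
        if iv.length > resolvable_length:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, size in track.chromosome_sizes.items():
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                segments.append(iv.start - pos)
            pos = iv.end
        if size > pos:
            segments.append(size - pos)
    ng = ng_statistic(segments, genome_size)
    return 0 if ng is None else ng


@dataclass
class ContiguityCurve:
    """Per-length-bin unbridged probabilities and expected NG50 for one identity class."""

    identity_threshold: float
    repeat_lengths: np.ndarray
    p_unbridged: np.ndarray
    p_any_unbridged: np.ndarray
    expected_ng50: np.ndarray
    spanned_length: int | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "identity_threshold": self.identity_threshold,
                "repeat_length": self.repeat_lengths,
                "p_unbridged": self.p_unbridged,
                "p_any_unbridged": self.p_any_unbridged,
                "expected_ng50": self.expected_ng50,
            }
        )


def contiguity_curve(
    raw_intervals: Sequence[RepeatInterval],
    identity_thresholds: Sequence[float],
    dist: ReadLengthDistribution,
    genome_size: int,
    chromosome_sizes: dict[str, int],
    alpha: float = 0.05,
    step: int = 1000,
    max_length: int = 100_000,
    cumulative: bool = False,
) -> list[ContiguityCurve]:
    """One contiguity curve per identity class over the 1-kb length grid."""
    curves = []
    grid = np.arange(step, max_length + 1, step, dtype=np.int64)
    p_un = np.array([prob_repeat_unbridged(int(ell), dist) for ell in grid])
    for thr in identity_thresholds:
        track = build_repeat_track(raw_intervals, thr, chromosome_sizes)
        hist = repeat_length_histogram(track, bin_width=step)
        p_any = np.array(
            [prob_any_unbridged(int(ell), hist, dist, cumulative=cumulative) for ell in grid]
        )
        ngs = np.array([expected_ng50(track, int(ell), genome_size) for ell in grid])
        spanned = spanned_repeat_length(
            dist, hist, alpha=alpha, max_length=max_length, step=step, cumulative=cumulative
        )
        curves.append(ContiguityCurve(thr, grid.copy(), p_un.copy(), p_any, ngs, spanned))
    return curves
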