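"""Assembly and read-set summary statistics.

NG/N statistics, Phred-scaled consensus quality from summed variant bases,
CIGAR-derived alignment identity, length-scored alignment chaining, k-mer
representation bias, symmetric-DUST low-complexity filtering, and coverage
summaries against a Poisson reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import OP_MATCH, AlignmentRecord

QV_CAP = 60.0


def ng_statistic(
    lengths: Sequence[int], genome_size: int, fraction: float = 0.5
) -> int | None:
    """NGx: longest length such that lengths >= it sum to ``fraction * genome_size``.

    With ``genome_size`` equal to the total of ``lengths`` this is the plain
    Nx statistic (e.g. the read N50). Returns None when the total never
    reaches the target.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    target = fraction * genome_size
    running = 0
    for length in sorted(lengths, reverse=True):
        if length <= 0:
            raise ValueError("lengths must be positive")
        running += length
        if running >= target:
            return int(length)
    return None


@dataclass(frozen=True)
class QualitySummary:
    """Consensus quality from summed variant bases E over covered bases B."""

    variant_bases: int
    covered_bases: int
    qv: float
    identity: float


def qv_identity(variant_bases: int, covered_bases: int) -> QualitySummary:
    """Phred QV = -10 log10(E/B) (capped at 60 when E = 0); identity = 100 (1 - E/B)."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be positive")
    if not (0 <= variant_bases <= covered_bases):
        raise ValueError("variant_bases must be in [0, covered_bases]")
    if variant_bases == 0:
        qv = QV_CAP
    else:
        qv = min(QV_CAP, -10.0 * math.log10(variant_bases / covered_bases))
    identity = 100.0 * (1.0 - variant_bases / covered_bases)
    return QualitySummary(variant_bases, covered_bases, qv, identity)


def alignment_identity(rec: AlignmentRecord) -> float:
    """Percent identity over all alignment columns including indel bases.

    identity = 100 * matches / (matches + mismatches + ins + del). The
    denominator includes inserted and deleted bases (BLAST-style columns),
    the convention under which high-indel nanopore reads land near 84%.
    """
    counts = rec.op_counts()
    columns = sum(counts.values())
    if columns == 0:
        raise ValueError("zero-column alignment")
    return 100.0 * counts[OP_MATCH] / columns


def chain_alignments(
    records: Iterable[AlignmentRecord],
) -> dict[str, list[AlignmentRecord]]:
    """Select at most one maximal colinear chain per read, scored by aligned length.

    For each read, candidate chains are colinear sets of alignments to a
    single target and strand, non-overlapping in the query, with target
    order matching query order (reversed for the minus strand). The chain
    maximising total aligned query length wins; ties break toward the
    earliest target start.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
    out: dict[str, list[AlignmentRecord]] = {}
    for read_id, recs in by_read.items():
        best: tuple[int, int, list[AlignmentRecord]] | None = None
        groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
        for rec in recs:
            groups.setdefault((rec.target, rec.strand), []).append(rec)
        for (_, strand), group in groups.items():
            chain = _best_chain(group, strand)
            score = sum(r.aligned_query_length for r in chain)
            tstart = min(r.target_start for r in chain)
            if best is None or (score, -tstart) > (best[0], -best[1]):
                best = (score, tstart, chain)
        assert best is not None
        out[read_id] = best[2]
    return out


def _best_chain(group: list[AlignmentRecord], strand: str) -> list[AlignmentRecord]:
    """Max-weight colinear chain by O(n^2) dynamic programming."""
    recs = sorted(group, key=lambda r: (r.query_start, r.query_end))
    n = len(recs)
    score = [r.aligned_query_length for r in recs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if recs[j].query_end > recs[i].query_start:
                continue  # overlap in query
            if strand == "+":
                colinear = recs[j].target_end <= recs[i].target_start
            else:
                colinear = recs[i].target_end <= recs[j].target_start
            if not colinear:
                continue
            cand = score[j] + recs[i].aligned_query_length
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    best_i = max(
        range(n), key=lambda i: (score[i], -min_chain_tstart(recs, prev, i))
    )
    chain = []
    i = best_i
    while i != -1:
        chain.append(recs[i])
        i = prev[i]
    return chain[::-1]


def min_chain_tstart(recs: list[AlignmentRecord], prev: list[int], i: int) -> int:
    t = recs[i].target_start
    while prev[i] != -1:
        i = prev[i]
        t = min(t, recs[i].target_start)
    return t


@dataclass
class KmerSpectrum:
    """k-mer counts over {A,C,G,T} from reads or a reference."""

    k: int
    counts: dict[str, int]
    source: str = "reads"

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], k: int, source: str = "reads") -> "KmerSpectrum":
        counts: dict[str, int] = {}
        for seq in sequences:
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if all(c in "ACGT" for c in kmer):
                    counts[kmer] = counts.get(kmer, 0) + 1
        return cls(k, counts, source)


def kmer_representation(
    read_spectrum: KmerSpectrum, ref_spectrum: KmerSpectrum
) -> pd.DataFrame:
    """Observed vs expected k-mer frequencies with a pseudocount-1 log2 ratio.

    Under-represented k-mers (e.g. A/T homopolymer 5-mers for a base-caller
    that collapses runs) get a negative log2_ratio.
    """
    if read_spectrum.k != ref_spectrum.k:
        raise ValueError("k-mer lengths differ between spectra")
    if not read_spectrum.counts or not ref_spectrum.counts:
        raise ValueError("empty k-mer spectrum")
    k = read_spectrum.k
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    obs_raw = np.array([read_spectrum.counts.get(m, 0) for m in kmers], dtype=float)
    exp_raw = np.array([ref_spectrum.counts.get(m, 0) for m in kmers], dtype=float)
    obs_freq = obs_raw / obs_raw.sum()
    exp_freq = exp_raw / exp_raw.sum()
    obs_p = (obs_raw + 1) / (obs_raw + 1).sum()
    exp_p = (exp_raw + 1) / (exp_raw + 1).sum()
    table = pd.DataFrame(
        {
            "kmer": kmers,
            "observed_frequency": obs_freq,
            "expected_frequency": exp_freq,
            "log2_ratio": np.log2(obs_p / exp_p),
        }
    )
    return table.sort_values("log2_ratio").reset_index(drop=True)


_TRIPLET_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def dust_masked_fraction(
    sequence: str, window: int = 64, score_threshold: float = 20.0
) -> float:
    """Fraction of a sequence masked by a symmetric-DUST low-complexity scan.

    Each length-``window`` window is scored ``10 * sum_t c_t (c_t - 1) / 2``
    over its 3-mer counts ``c_t``, scaled by the number of 3-mer start
    positions; windows scoring above the threshold are merged into the
    masked region.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(sequence)
    if n < 3:
        return 0.0
    codes = np.full(n - 2, -1, dtype=np.int64)
    enc = np.array([_TRIPLET_BASE.get(c, -100) for c in sequence.upper()], dtype=np.int64)
    trip = enc[:-2] * 16 + enc[1:-1] * 4 + enc[2:]
    valid = trip >= 0
    codes[valid] = trip[valid]

    w = min(window, n)
    n_trip = w - 2
    counts = np.zeros(64, dtype=np.int64)
    pair_sum = 0
    masked: list[tuple[int, int]] = []
    for i in range(0, n - w + 1):
        if i == 0:
            for c in codes[:n_trip]:
                if c >= 0:
                    pair_sum += counts[c]
                    counts[c] += 1
        else:
            c_out = codes[i - 1]
            if c_out >= 0:
                counts[c_out] -= 1
                pair_sum -= counts[c_out]
            c_in = codes[i + n_trip - 1]
            if c_in >= 0:
                pair_sum += counts[c_in]
                counts[c_in] += 1
        score = 10.0 * pair_sum / max(n_trip - 1, 1)
        if score > score_threshold:
            if masked and i <= masked[-1][1]:
                masked[-1] = (masked[-1][0], i + w)
            else:
                masked.append((i, i + w))
    return sum(e - s for s, e in masked) / n


def low_complexity_filter(
    reads: Iterable[tuple[str, str]],
    window: int = 64,
    score_threshold: float = 20.0,
    removal_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, float]]:
    """Split reads into (kept, removed) by masked low-complexity fraction.

    A read is removed when its masked fraction strictly exceeds
    ``removal_fraction`` (default: more than half the read is
    low-complexity).
    """
    kept: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    fractions: dict[str, float] = {}
    for read_id, seq in reads:
        frac = dust_masked_fraction(seq, window=window, score_threshold=score_threshold)
        fractions[read_id] = frac
        (removed if frac > removal_fraction else kept).append((read_id, seq))
    return kept, removed, fractions


@dataclass
class CoverageSummary:
    mean: float
    sd: float
    zero_excluded_mean: float  # nan when every position has zero depth
    zero_excluded_sd: float
    histogram: np.ndarray
    poisson_reference: np.ndarray
    lam: float


def coverage_summary(depths: Sequence[int], lam: float) -> CoverageSummary:
    """Depth-of-coverage summary with a Poisson(lambda) reference histogram."""
    arr = np.asarray(depths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty depth vector")
    if arr.min() < 0:
        raise ValueError("depths must be non-negative")
    nz = arr[arr > 0]
    hist = np.bincount(arr)
    ref = stats.poisson.pmf(np.arange(hist.size), lam) * arr.size
    return CoverageSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        zero_excluded_mean=float(nz.mean()) if nz.size else float("nan"),
        zero_excluded_sd=float(nz.std(ddof=0)) if nz.size else float("nan"),
        histogram=hist,
        poisson_reference=ref,
        lam=float(lam),
    )
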