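"""Synthetic genomes, reads, alignments and genotype call sets.

The generator emulates the statistical structure the downstream analyses
assume: a background i.i.d. genome with planted repeat families (copies of
a unit mutated to a target percent identity), reference gaps (N runs),
homopolymer runs with guaranteed boundary bases, and terminal telomeric
arrays; reads with configurable length distributions, uniform placement,
point-error profiles and base-caller-style homopolymer pathologies
(capping runs at 5 bp, or overcalling 5-15 bp runs and undercalling longer
ones); and paired truth/test genotype call sets with per-site
log-likelihood ratios. Every generator is deterministic under a fixed
seed, and every read carries an exact truth CIGAR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contiguity import GAP, ReadLengthDistribution, RepeatInterval, RepeatTrack
from .genotypes import GENOTYPES, HET, HOMALT, GenotypeCall
from .alignments import AlignmentRecord
from .tandem import TandemArrayAnnotation

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class RepeatFamilySpec:
    unit_length: int
    copies: int
    identity: float  # percent
    placement: str = "interleaved"  # interleaved | tandem

    def __post_init__(self) -> None:
        if self.unit_length <= 0 or self.copies <= 0:
            raise ValueError("unit_length and copies must be positive")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percent in [0, 100]")
        if self.placement not in ("interleaved", "tandem"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class HomopolymerSpec:
    base: str
    length: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.base not in "ACGT":
            raise ValueError("homopolymer base must be one of A, C, G, T")
        if self.length <= 0 or self.count <= 0:
            raise ValueError("length and count must be positive")


@dataclass(frozen=True)
class TelomereSpec:
    unit: str = "TTAGGG"
    span: int = 5000

    def __post_init__(self) -> None:
        if self.span <= 0 or not self.unit:
            raise ValueError("telomere unit and span must be non-empty/positive")


@dataclass
class SimGenomeConfig:
    genome_size: int
    n_chromosomes: int = 1
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    gap_runs: list[int] = field(default_factory=list)
    homopolymer_runs: list[HomopolymerSpec] = field(default_factory=list)
    telomere_arrays: list[TelomereSpec] = field(default_factory=list)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_size and n_chromosomes must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition probabilities must sum to 1")
        if any(g <= 0 for g in self.gap_runs):
            raise ValueError("gap lengths must be positive")


@dataclass
class SimGenome:
    sequences: dict[str, str]
    truth_track: RepeatTrack
    homopolymer_truth: list[tuple[str, int, int, str]]
    tandem_truth: list[TandemArrayAnnotation]

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chromosome_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass(frozen=True)
class ErrorProfile:
    """Point-error rates plus a homopolymer base-caller pathology mode.

    ``cap5`` truncates every emitted homopolymer run of 6 bp or more to
    5 bp (a 5-mer base-caller that cannot count through a run). ``distort``
    overcalls runs of 5 bp up to the undercall threshold (15 bp) and
    undercalls longer ones, by 1..distort_overcall_range bases. Indels are
    single-base events geometrically extended with ``extension_prob``.
    """

    substitution_rate: float = 0.0
    transition_fraction: float = 0.5
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    homopolymer_mode: str = "none"  # none | cap5 | distort
    distort_overcall_range: int = 3
    distort_undercall_threshold: int = 15
    extension_prob: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "transition_fraction",
            "insertion_rate",
            "deletion_rate",
            "extension_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.homopolymer_mode not in ("none", "cap5", "distort"):
            raise ValueError(f"unknown homopolymer_mode {self.homopolymer_mode!r}")

    @property
    def error_free(self) -> bool:
        return (
            self.substitution_rate == 0.0
            and self.insertion_rate == 0.0
            and self.deletion_rate == 0.0
            and self.homopolymer_mode == "none"
        )


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    true_chrom: str
    true_start: int
    true_cigar: list[tuple[str, int]]


@dataclass
class SimReadSet:
    reads: list[SimRead]
    length_distribution: ReadLengthDistribution

    def to_alignments(self) -> list[AlignmentRecord]:
        """Truth alignments (forward strand, exact CIGAR) for every read."""
        out = []
        for read in self.reads:
            t_span = sum(n for op, n in read.true_cigar if op in ("match", "mismatch", "del"))
            out.append(
                AlignmentRecord(
                    read_id=read.read_id,
                    target=read.true_chrom,
                    query_start=0,
                    query_end=len(read.sequence),
                    target_start=read.true_start,
                    target_end=read.true_start + t_span,
                    strand="+",
                    cigar=list(read.true_cigar),
                    query_length=len(read.sequence),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Genome simulation


def _random_sequence(rng: np.random.Generator, n: int, composition) -> np.ndarray:
    return rng.choice(BASES, size=n, p=list(composition))


def _mutate_to_identity(
    rng: np.random.Generator, unit: np.ndarray, identity: float
) -> np.ndarray:
    """Copy-paste with per-base substitution at rate (100 - identity)/100."""
    rate = (100.0 - identity) / 100.0
    copy = unit.copy()
    hit = rng.random(copy.size) < rate
    for i in np.flatnonzero(hit):
        others = [b for b in "ACGT" if b != copy[i]]
        copy[i] = others[rng.integers(0, 3)]
    return copy


def simulate_genome(config: SimGenomeConfig) -> SimGenome:
    """Build a genome with planted repeats, gaps, homopolymers and telomeres.

    Features are placed uniformly at random without overlap (uniform cut
    points in the free sequence between them); telomere arrays go to
    chromosome ends. The truth track records one interval per repeat copy
    (kind segdup, the configured identity) and per gap (kind gap).
    """
    rng = np.random.default_rng(config.seed)
    base = config.genome_size // config.n_chromosomes
    sizes = [base] * config.n_chromosomes
    sizes[-1] += config.genome_size - base * config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # build the feature items: (tag, payload); each knows its planted length
    items: list[tuple[str, object, int]] = []
    for fam in config.repeat_families:
        unit = _random_sequence(rng, fam.unit_length, config.base_composition)
        if fam.placement == "tandem":
            items.append(("tandem", (unit, fam), fam.unit_length * fam.copies))
        else:
            for _ in range(fam.copies):
                items.append(("repeat", (unit, fam), fam.unit_length))
    for gap_len in config.gap_runs:
        items.append(("gap", gap_len, gap_len))
    for spec in config.homopolymer_runs:
        for _ in range(spec.count):
            items.append(("homopolymer", spec, spec.length + 2))  # + boundary bases

    # round-robin assignment of interleaved items to chromosomes
    per_chrom: dict[str, list[tuple[str, object, int]]] = {c: [] for c in chroms}
    for i, item in enumerate(items):
        per_chrom[chroms[i % len(chroms)]].append(item)
    telo_by_chrom: dict[str, list[TelomereSpec]] = {c: [] for c in chroms}
    for i, spec in enumerate(config.telomere_arrays):
        telo_by_chrom[chroms[i % len(chroms)]].append(spec)

    sequences: dict[str, str] = {}
    truth_intervals: list[RepeatInterval] = []
    homopolymer_truth: list[tuple[str, int, int, str]] = []
    tandem_truth: list[TandemArrayAnnotation] = []

    for chrom, size in zip(chroms, sizes):
        seq = _random_sequence(rng, size, config.base_composition)
        chrom_items = per_chrom[chrom]
        telo_specs = telo_by_chrom[chrom]
        telo_len = sum(t.span for t in telo_specs[:2])
        feat_len = sum(length for _, _, length in chrom_items)
        if feat_len + telo_len > size:
            raise ValueError(
                f"planted features ({feat_len + telo_len} bases) exceed "
                f"chromosome {chrom} size {size}"
            )
        # terminal telomere arrays: first at the right end, second at the left
        left_reserved = 0
        right_reserved = 0
        for k, spec in enumerate(telo_specs[:2]):
            tiling = (spec.unit * math.ceil(spec.span / len(spec.unit)))[: spec.span]
            if k == 0:
                start = size - spec.span
                right_reserved = spec.span
            else:
                start = 0
                left_reserved = spec.span
            seq[start : start + spec.span] = list(tiling)
            tandem_truth.append(
                TandemArrayAnnotation(
                    sequence_id=chrom,
                    unit=spec.unit,
                    array_start=start,
                    array_end=start + spec.span,
                    copy_count=int(round(spec.span / len(spec.unit))),
                    copy_count_fractional=spec.span / len(spec.unit),
                    purity=100.0,
                )
            )
        # uniform non-overlapping placement of the remaining features
        free = size - left_reserved - right_reserved - feat_len
        order = list(rng.permutation(len(chrom_items)))
        cuts = np.sort(rng.integers(0, free + 1, size=len(chrom_items)))
        cursor_extra = 0
        for cut, idx in zip(cuts, order):
            tag, payload, length = chrom_items[idx]
            start = left_reserved + int(cut) + cursor_extra
            cursor_extra += length
            end = start + length
            if tag == "gap":
                seq[start:end] = "N"
                truth_intervals.append(RepeatInterval(chrom, start, end, 0.0, GAP))
            elif tag == "repeat":
                unit, fam = payload
                seq[start:end] = _mutate_to_identity(rng, unit, fam.identity)
                truth_intervals.append(
                    RepeatInterval(chrom, start, end, fam.identity, "segdup")
                )
            elif tag == "tandem":
                unit, fam = payload
                matches = 0
                for c in range(fam.copies):
                    copy = _mutate_to_identity(rng, unit, fam.identity)
                    matches += int((copy == unit).sum())
                    s = start + c * fam.unit_length
                    seq[s : s + fam.unit_length] = copy
                    truth_intervals.append(
                        RepeatInterval(chrom, s, s + fam.unit_length, fam.identity, "segdup")
                    )
                tandem_truth.append(
                    TandemArrayAnnotation(
                        sequence_id=chrom,
                        unit="".join(unit),
                        array_start=start,
                        array_end=end,
                        copy_count=fam.copies,
                        copy_count_fractional=float(fam.copies),
                        purity=100.0 * matches / (fam.copies * fam.unit_length),
                    )
                )
            elif tag == "homopolymer":
                spec = payload
                others = [b for b in "ACGT" if b != spec.base]
                seq[start] = others[rng.integers(0, 3)]
                seq[start + 1 : end - 1] = spec.base
                seq[end - 1] = others[rng.integers(0, 3)]
                homopolymer_truth.append((chrom, start + 1, end - 1, spec.base))
        sequences[chrom] = "".join(seq)

    track = RepeatTrack(
        sorted(truth_intervals, key=lambda iv: (iv.chrom, iv.start)),
        {c: s for c, s in zip(chroms, sizes)},
    )
    return SimGenome(sequences, track, homopolymer_truth, tandem_truth)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class LognormalLengths:
    """Log-normal read-length model: ln(length) ~ Normal(mu, sigma)."""

    mu: float
    sigma: float
    min_length: int = 50

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lengths = np.exp(rng.normal(self.mu, self.sigma, size=n))
        return np.maximum(lengths.astype(np.int64), self.min_length)


@dataclass(frozen=True)
class EmpiricalLengths:
    """Resample read lengths from an observed multiset."""

    lengths: tuple[int, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        arr = np.asarray(self.lengths, dtype=np.int64)
        return arr[rng.integers(0, arr.size, size=n)]


def _find_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal homopolymer runs (start, end) of length >= 2 over ACGT."""
    runs = []
    n = len(seq)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2 and seq[i] in "ACGT":
            runs.append((i, j))
        i = j
    return runs


def _geometric_extension(rng: np.random.Generator, p_extend: float) -> int:
    length = 1
    while rng.random() < p_extend:
        length += 1
    return length


def _point_errors(
    segment: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[list[str], list[tuple[str, int]]]:
    out: list[str] = []
    ops: list[tuple[str, int]] = []
    n = len(segment)
    i = 0
    while i < n:
        if profile.deletion_rate and rng.random() < profile.deletion_rate:
            dlen = min(_geometric_extension(rng, profile.extension_prob), n - i)
            ops.append(("del", dlen))
            i += dlen
            continue
        base = segment[i]
        if base in "ACGT" and profile.substitution_rate and rng.random() < profile.substitution_rate:
            if rng.random() < profile.transition_fraction:
                out.append(_TRANSITION[base])
            else:
                tv = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
                out.append(tv[rng.integers(0, 2)])
            ops.append(("mismatch", 1))
        else:
            out.append(base)
            ops.append(("match", 1))
        i += 1
        if profile.insertion_rate and rng.random() < profile.insertion_rate:
            ilen = _geometric_extension(rng, profile.extension_prob)
            out.extend(BASES[rng.integers(0, 4, size=ilen)])
            ops.append(("ins", ilen))
    return out, ops


def _compress_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def mutate_sequence(
    ref: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply an error profile to a reference substring; return (read, truth CIGAR).

    Homopolymer pathologies are applied as clean run-length rewrites of the
    affected reference runs (cap5: runs >= 6; distort: runs >= 5),
    overriding point errors there so the emitted run length is exact; point
    errors apply everywhere else.
    """
    if profile.error_free:
        return ref, [("match", len(ref))]
    rewrite_min = {"none": None, "cap5": 6, "distort": 5}[profile.homopolymer_mode]
    boundaries: list[tuple[int, int]] = []
    if rewrite_min is not None:
        boundaries = [(s, e) for s, e in _find_runs(ref) if e - s >= rewrite_min]
    out: list[str] = []
    ops: list[tuple[str, int]] = []
    pos = 0
    for s, e in boundaries:
        if s > pos:
            seg_out, seg_ops = _point_errors(ref[pos:s], profile, rng)
            out.extend(seg_out)
            ops.extend(seg_ops)
        run_len = e - s
        base = ref[s]
        if profile.homopolymer_mode == "cap5":
            emitted = min(run_len, 5)
        else:  # distort
            shift = int(rng.integers(1, profile.distort_overcall_range + 1))
            if run_len > profile.distort_undercall_threshold:
                emitted = max(1, run_len - shift)
            else:
                emitted = run_len + shift
        out.append(base * emitted)
        if emitted >= run_len:
            ops.append(("match", run_len))
            ops.append(("ins", emitted - run_len))
        else:
            ops.append(("match", emitted))
            ops.append(("del", run_len - emitted))
        pos = e
    if pos < len(ref):
        seg_out, seg_ops = _point_errors(ref[pos:], profile, rng)
        out.extend(seg_out)
        ops.extend(seg_ops)
    return "".join(out), _compress_ops(ops)


def simulate_reads(
    genome: SimGenome,
    length_spec: LognormalLengths | EmpiricalLengths,
    coverage: float,
    profile: ErrorProfile | None = None,
    seed: int = 0,
) -> SimReadSet:
    """Sample reads uniformly over the genome to a target fold coverage.

    Start positions are uniform over the concatenated genome; reads running
    off a chromosome end are truncated (linear chromosomes). The final read
    is clipped so total read bases hit the requested coverage exactly
    (within the truncation of that one read). Errors are injected per the
    profile with the truth CIGAR updated alongside.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if genome.total_size == 0 or not genome.sequences:
        raise ValueError("empty genome")
    profile = profile or ErrorProfile()
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    sizes = np.array([len(genome.sequences[c]) for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(sizes.sum())
    target = int(round(coverage * total))

    reads: list[SimRead] = []
    emitted = 0
    batch = max(16, int(target / max(np.exp(getattr(length_spec, "mu", 8.5)), 1000)) + 1)
    while emitted < target:
        for length in length_spec.sample(rng, batch):
            if emitted >= target:
                break
            length = int(min(length, target - emitted)) or 1
            flat = int(rng.integers(0, total))
            ci = int(np.searchsorted(offsets, flat, side="right") - 1)
            chrom = chroms[ci]
            start = flat - int(offsets[ci])
            ref = genome.sequences[chrom][start : start + length]
            seq, cigar = mutate_sequence(ref, profile, rng)
            if not seq:
                continue
            reads.append(
                SimRead(f"read{len(reads):06d}", seq, chrom, start, cigar)
            )
            emitted += len(seq)
    dist = ReadLengthDistribution([len(r.sequence) for r in reads], total)
    return SimReadSet(reads, dist)


# ---------------------------------------------------------------------------
# Genotype call simulation


@dataclass(frozen=True)
class LlrSpec:
    """Shifted-normal LLR model: variant sites mean +60, non-variant -60, sd 20.

    Centred well clear of the 30 threshold so both acceptance and rejection
    branches of the threshold rule are exercised.
    """

    variant_mean: float = 60.0
    nonvariant_mean: float = -60.0
    sd: float = 20.0


def simulate_genotype_calls(
    n_sites: int,
    genotype_frequencies: Sequence[float] = (0.90, 0.07, 0.03),
    miscall_matrix: Sequence[Sequence[float]] | None = None,
    llr_spec: LlrSpec = LlrSpec(),
    seed: int = 0,
    chrom: str = "chr20",
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Paired truth/test genotype call sets with per-site LLRs.

    Truth genotypes are drawn from ``genotype_frequencies`` over
    (homref, het, homalt); each test call is drawn from the miscall-matrix
    row of its truth genotype (identity matrix by default) and carries an
    LLR from the truth-status-conditional normal in ``llr_spec``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    freqs = np.asarray(genotype_frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("genotype frequencies must sum to 1")
    m = np.eye(3) if miscall_matrix is None else np.asarray(miscall_matrix, dtype=float)
    if m.shape != (3, 3) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("miscall matrix rows must each sum to 1")
    rng = np.random.default_rng(seed)
    truth_idx = rng.choice(3, size=n_sites, p=freqs)
    truth, test = [], []
    for i, ti in enumerate(truth_idx):
        site = f"site{i:07d}"
        pos = 100 * (i + 1)
        truth_gt = GENOTYPES[ti]
        test_gt = GENOTYPES[rng.choice(3, p=m[ti])]
        mean = (
            llr_spec.variant_mean if truth_gt in (HET, HOMALT) else llr_spec.nonvariant_mean
        )
        llr = float(rng.normal(mean, llr_spec.sd))
        truth.append(GenotypeCall(site, chrom, pos, truth_gt))
        test.append(GenotypeCall(site, chrom, pos, test_gt, llr=llr))
    return truth, test


# ---------------------------------------------------------------------------
# Ultra-long boost


def boost_ultralong(
    reads: SimReadSet | ReadLengthDistribution, factor: int
):
    """Repeat every read (or length) ``factor`` times, emulating the x6
    replication that turns a 5x ultra-long run into a 30x one."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if isinstance(reads, ReadLengthDistribution):
        return ReadLengthDistribution(
            np.repeat(reads.lengths, factor), reads.genome_size
        )
    boosted = [
        SimRead(f"{r.read_id}_rep{k}", r.sequence, r.true_chrom, r.true_start, r.true_cigar)
        for r in reads.reads
        for k in range(factor)
    ]
    dist = ReadLengthDistribution(
        np.repeat(reads.length_distribution.lengths, factor),
        reads.length_distribution.genome_size,
    )
    return SimReadSet(boosted, dist)
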