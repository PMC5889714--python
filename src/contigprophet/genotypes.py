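"""Genotype concordance, SV genotyping sensitivity and shuffle-based FDR.

Genotypes live on a fixed alphabet {homref, het, homalt, missing}. A
variant call (het or homalt) is accepted only when its log-likelihood ratio
against homozygous reference reaches a threshold (default 30), otherwise
the site reverts to homref. Concordance is reported three ways: over all
compared sites, over sites where either call set is variant, and over sites
the truth set annotates as variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOMREF = "homref"
HET = "het"
HOMALT = "homalt"
MISSING = "missing"
GENOTYPES = (HOMREF, HET, HOMALT)
VARIANT = (HET, HOMALT)


@dataclass(frozen=True)
class GenotypeCall:
    site_id: str
    chrom: str
    pos: int  # 1-based
    genotype: str
    llr: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES + (MISSING,):
            raise ValueError(f"invalid genotype {self.genotype!r}")


def apply_llr_threshold(
    calls: Iterable[GenotypeCall], threshold: float = 30.0
) -> list[GenotypeCall]:
    """Demote variant calls with LLR below the (inclusive) threshold to homref."""
    out = []
    for call in calls:
        if call.genotype in VARIANT:
            if call.llr is None:
                raise ValueError(f"variant call at {call.site_id} lacks an LLR")
            if call.llr < threshold:
                call = replace(call, genotype=HOMREF)
        out.append(call)
    return out


@dataclass
class ConfusionMatrix:
    """Truth-by-test genotype cross-tabulation, with a missing column."""

    counts: pd.DataFrame  # index truth, columns test

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def compared(self) -> pd.DataFrame:
        """Counts restricted to sites present in both sets."""
        return self.counts.loc[list(GENOTYPES), list(GENOTYPES)]


def build_confusion_matrix(
    truth: Sequence[GenotypeCall], test: Sequence[GenotypeCall]
) -> ConfusionMatrix:
    """Join call sets on site_id; truth sites absent from test count as missing."""
    truth_by_site: dict[str, GenotypeCall] = {}
    for call in truth:
        if call.site_id in truth_by_site:
            raise ValueError(f"duplicate site_id {call.site_id!r} in truth set")
        truth_by_site[call.site_id] = call
    test_by_site: dict[str, GenotypeCall] = {}
    for call in test:
        if call.site_id in test_by_site:
            raise ValueError(f"duplicate site_id {call.site_id!r} in test set")
        test_by_site[call.site_id] = call
    labels = list(GENOTYPES) + [MISSING]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=np.int64)
    counts.index.name = "truth"
    counts.columns.name = "test"
    for site_id, t in truth_by_site.items():
        other = test_by_site.get(site_id)
        counts.loc[t.genotype, MISSING if other is None else other.genotype] += 1
    for site_id, s in test_by_site.items():
        if site_id not in truth_by_site:
            counts.loc[MISSING, s.genotype] += 1
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ConcordanceReport:
    overall_pct: float
    variant_site_pct: float  # truth OR test variant in the denominator
    truth_variant_pct: float  # truth variant in the denominator
    n_total: int
    n_concordant: int

    def rounded(self) -> tuple[float, float, float]:
        return (
            round(self.overall_pct, 2),
            round(self.variant_site_pct, 2),
            round(self.truth_variant_pct, 2),
        )


def concordance_rates(matrix: ConfusionMatrix) -> ConcordanceReport:
    """Overall, variant-site and truth-variant concordance percentages.

    Sites missing from either set are excluded from every denominator.
    The variant-site rate counts sites where truth or test is variant; its
    numerator (like the truth-variant numerator) is concordant variant
    sites, since a concordant site in the union denominator is variant in
    both sets.
    """
    m = matrix.compared.to_numpy()
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    concordant = int(np.trace(m))
    variant_diag = int(m[1, 1] + m[2, 2])  # het/het + homalt/homalt
    union_variant = int(m.sum() - m[0, 0])  # all but homref/homref
    truth_variant = int(m[1, :].sum() + m[2, :].sum())
    return ConcordanceReport(
        overall_pct=100.0 * concordant / total,
        variant_site_pct=100.0 * variant_diag / union_variant if union_variant else 100.0,
        truth_variant_pct=100.0 * variant_diag / truth_variant if truth_variant else 100.0,
        n_total=total,
        n_concordant=concordant,
    )


# ---------------------------------------------------------------------------
# Structural variant genotyping


@dataclass(frozen=True)
class SvInterval:
    chrom: str
    start: int
    end: int  # 0-based half-open
    sv_type: str = "DEL"  # DEL | DUP
    genotype: str = HOMREF

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty SV interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap_match(
    a: SvInterval, b: SvInterval, min_fraction: float = 0.5
) -> bool:
    """True iff the overlap covers at least min_fraction of both intervals."""
    if a.chrom != b.chrom:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return overlap / a.length >= min_fraction and overlap / b.length >= min_fraction


def binomial_support_genotyper(
    alt_support: Sequence[bool] | np.ndarray,
    het_threshold: float = 0.25,
    homalt_threshold: float = 0.75,
) -> str:
    """Simple read-support genotyper: alt fraction < 0.25 homref, < 0.75 het, else homalt."""
    support = np.asarray(alt_support, dtype=bool)
    if support.size == 0:
        return HOMREF
    frac = support.mean()
    if frac < het_threshold:
        return HOMREF
    if frac < homalt_threshold:
        return HET
    return HOMALT


def subsampled_sv_sensitivity(
    truth_genotypes: Mapping[str, str],
    read_support_by_site: Mapping[str, Sequence[bool]],
    depths: Sequence[float],
    full_depth: float,
    genotyper: Callable[[np.ndarray], str] = binomial_support_genotyper,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotyping sensitivity as a function of subsampled sequencing depth.

    Per-site read support (one alt/ref flag per read at full depth) is
    thinned to each target depth; sensitivity is the fraction of re-called
    genotypes concordant with truth, with ``replicates`` seeded subsampling
    replicates per depth.
    """
    if not truth_genotypes:
        raise ValueError("empty site set")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > full_depth:
            raise ValueError(f"requested depth {depth} exceeds available {full_depth}")
        frac = depth / full_depth
        values = []
        for _ in range(replicates):
            concordant = 0
            for site_id, truth_gt in truth_genotypes.items():
                support = np.asarray(read_support_by_site[site_id], dtype=bool)
                keep = rng.random(support.size) < frac
                called = genotyper(support[keep])
                concordant += called == truth_gt
            values.append(concordant / len(truth_genotypes))
        rows.append(
            {
                "depth": depth,
                "mean_sensitivity": float(np.mean(values)),
                "replicate_sensitivities": values,
            }
        )
    return pd.DataFrame(rows)


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def shuffle_intervals(
    svs: Sequence[SvInterval],
    chromosome_sizes: Mapping[str, int],
    excluded_regions: Sequence[SvInterval],
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> list[SvInterval]:
    """Place each SV uniformly at random, length preserved, outside excluded regions."""
    excluded_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for region in excluded_regions:
        excluded_by_chrom.setdefault(region.chrom, []).append((region.start, region.end))
    excluded_by_chrom = {c: _merge_intervals(v) for c, v in excluded_by_chrom.items()}
    chroms = sorted(chromosome_sizes)
    sizes = np.array([chromosome_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placed = []
    for sv in svs:
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = chromosome_sizes[chrom] - sv.length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + sv.length
            if any(
                start < e and s < end for s, e in excluded_by_chrom.get(chrom, [])
            ):
                continue
            placed.append(replace(sv, chrom=chrom, start=start, end=end))
            break
        else:
            raise RuntimeError(
                f"could not place SV of length {sv.length} outside excluded regions"
            )
    return placed


def shuffle_fdr(
    svs: Sequence[SvInterval],
    chromosome_sizes: Mapping[str, int],
    excluded_regions: Sequence[SvInterval],
    truth_genotyper: Callable[[SvInterval], str],
    test_genotyper: Callable[[SvInterval], str],
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Mean false-discovery rate over shuffled SV placements.

    Each iteration shuffles every SV to a random allowed location and
    genotypes it with both callers. A false positive is a site where the
    truth caller reports homref but the test caller reports a variant; the
    iteration FDR is FP / (sites with truth homref). Returns the mean FDR
    (percent) and the per-iteration values.
    """
    if not svs:
        raise ValueError("empty SV set")
    rng = np.random.default_rng(seed)
    fdrs = []
    for _ in range(iterations):
        shuffled = shuffle_intervals(svs, chromosome_sizes, excluded_regions, rng)
        fp = 0
        homref_sites = 0
        for sv in shuffled:
            if truth_genotyper(sv) == HOMREF:
                homref_sites += 1
                if test_genotyper(sv) != HOMREF:
                    fp += 1
        fdrs.append(100.0 * fp / homref_sites if homref_sites else 0.0)
    return float(np.mean(fdrs)), fdrs


def allelic_balance_deviation(cov_a: int, cov_b: int) -> float:
    """d = |0.5 - cov_a / (cov_a + cov_b)|, in [0, 0.5]."""
    if cov_a < 0 or cov_b < 0:
        raise ValueError("coverages must be non-negative")
    total = cov_a + cov_b
    if total == 0:
        raise ValueError("both allele coverages are zero")
    return abs(0.5 - cov_a / total)


def allelic_balance_report(pairs: Sequence[tuple[int, int]]) -> dict[str, float]:
    """Mean d and 90th percentile of d over heterozygous sites."""
    d = np.array([allelic_balance_deviation(a, b) for a, b in pairs])
    return {"mean_d": float(d.mean()), "p90_d": float(np.quantile(d, 0.9))}


def classify_read_haplotype(
    marker_calls: Sequence[str], agreement_threshold: float = 0.55
) -> str:
    """Assign a read to haplotype A or B from its phasing-marker alleles.

    Reads with one marker or fewer stay unassigned; otherwise the haplotype
    whose agreement fraction strictly exceeds the threshold (default 55%)
    wins, and a tie at or below it leaves the read unassigned.
    """
    calls = [c for c in marker_calls if c in ("A", "B")]
    if len(calls) <= 1:
        return "unassigned"
    frac_a = calls.count("A") / len(calls)
    if frac_a > agreement_threshold:
        return "A"
    if 1.0 - frac_a > agreement_threshold:
        return "B"
    return "unassigned"
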