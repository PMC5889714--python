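# Methods

## Repeat-bridging contiguity model

**Model.** A repeat of length `ell` is resolved during assembly only if
some read covers the repeat plus at least one base of unique flanking
sequence on each side. A read of length `L` placed uniformly on a genome of
size `G` does so from `w = max(0, L - ell - 2)` start positions, so it
bridges the repeat with probability `w/G`. For an empirical read-length
multiset `{L_j}` the probability the repeat is unspanned by every read is
the exact product `p(ell) = prod_j (1 - w_j/G)`, evaluated in log space
(`log1p`). When all reads share one length this reduces to the classical
`(1 - (L-ell-2)/G)^N ≈ exp(-N (L-ell-2)/G)` with `N` reads; the
exponential form is exposed via `approximate=True` and agrees with the
exact product to better than 1e-3 whenever every `w_j/G ≤ 1e-3`.

**Assumptions.** Reads are placed independently and uniformly; chromosomes
are linear, and a read is never split across chromosomes; repeats do not
overlap after merging; distinct repeats fail to be bridged independently
(so `P(ell) = 1 - (1-p)^{a_ell}` for `a_ell` repeats in a length bin). The
independence assumption is mildly optimistic: two repeats share the same
finite read set, which introduces a small negative correlation between
their bridging events — at desk scale the analytic `P` agrees with a
shared-placement Monte-Carlo simulation to within ~0.5% absolute.

**Repeat tracks.** Intervals carry a percent identity and a kind
(`segdup`, `selfchain`, `gap`). For an identity class, intervals *below*
the threshold are dropped (they are assumed separable by sequence
divergence), gaps are always kept (unresolvable by definition), and the
survivors are merged when they overlap or abut. Coordinates are 0-based
half-open throughout. Merged lengths are binned at 1 kb: bin `i` holds
lengths in `((i-1)·1000, i·1000]`, so a 1,000-base repeat falls in bin 1.

**Aggregation choice.** `P(at least one unbridged)` is evaluated per length
bin against that bin's own count, not cumulatively over all longer
repeats; longer repeats are strictly harder to bridge, so the per-bin curve
is the more conservative reading of a fixed-length sweep. The cumulative
alternative is available via `cumulative=True` on `prob_any_unbridged` and
`spanned_repeat_length`.

**Expected NG50.** Repeats with length ≤ the resolvable length are deleted
from the track; the remainder cut each chromosome into inter-repeat
segments, excluding the repeat bases themselves (a repeat that cannot be
bridged contributes no reliably assembled sequence). The NG50 of the
segments is taken against the full genome size, and is 0 when the segments
sum to less than half of it. Whether repeat bases should count inside
contigs is genuinely open; including them would shift NG50 up by roughly
half a repeat length per junction, well inside the model's other
approximations.

## Synthetic data generator

**Genome.** Background sequence is i.i.d. over A/C/G/T with configurable
composition. Repeat families are planted by copy-paste of a random unit
with per-base substitution at rate `(100 - identity)/100` — substitutions
only, because the downstream identity classes are percent-identity bins.
Features (repeat copies, N-gap runs, homopolymer runs with forced
non-matching boundary bases) are assigned round-robin to chromosomes and
placed uniformly without overlap via sorted uniform cut points; telomere
arrays occupy chromosome ends. Feature sets that cannot fit raise a
configuration error. The truth track, homopolymer truth and tandem-array
truth are emitted alongside the sequence.

**Reads.** Lengths come from a log-normal model (`ln L ~ N(mu, sigma)`) or
an empirical multiset; starts are uniform over the concatenated genome;
reads running off a chromosome end are truncated (no circularity — these
are linear chromosomes). Reads are drawn until total bases reach
`coverage × genome_size`, with the final read clipped to land on the
target exactly. Point errors are per-base: substitutions (transition
fraction 0.5 by default), and single-base insertions/deletions extended
geometrically (extension probability 0.3, mean event length ≈ 1.4 bases).
Each read carries an exact truth CIGAR (`=`/`X`/`I`/`D`).

**Homopolymer pathologies.** Two base-caller-style modes rewrite reference
homopolymer runs as a clean run-length substitution, overriding point
errors inside the run (the rewrite would clobber them anyway, and doing it
at generation time keeps the truth CIGAR exact): `cap5` emits
`min(run, 5)` bases for runs of ≥ 6 (a 5-mer model that cannot count
through a run), and `distort` overcalls runs of 5–15 bases and undercalls
runs longer than 15, each by 1–3 bases by default. The magnitudes of the
distort mode are free parameters — no quantitative over/under-call sizes
are established for the behaviour it emulates — so only their signs should
be treated as meaningful.

**Genotype calls.** Truth genotypes are categorical over
(homref, het, homalt); test calls are drawn per site from the miscall
matrix row of the truth genotype. Log-likelihood ratios are shifted
normals: variant-site mean +60, non-variant mean −60, sd 20, so the
threshold-30 acceptance rule is exercised from both sides with realistic
overlap mass near the threshold.

**What a green test does not establish.** The generator has no coverage
bias, no chimeric reads, no mapping ambiguity, and substitution-only repeat
divergence; reads are placed uniformly rather than with the clustered
start positions of real flow cells. Results on synthetic data validate the
*computations*, not the behaviour of any aligner or base-caller on real
signal.

## Evaluation statistics

**NG/N.** `ng_statistic` sorts lengths descending and returns the first
length at which the running sum reaches `fraction × genome_size`; with the
set's own total as the denominator this is the plain Nx (read N50).

**QV/identity.** From summed variant bases `E` over bases covered at depth
≥ 3 `B`: `QV = -10·log10(E/B)` (capped at 60 when `E = 0`) and
`identity = 100·(1 - E/B)` — the standard Phred convention.

**Alignment identity** is `100 · matches / (matches + mismatches +
inserted + deleted bases)`: indel bases are columns in the denominator,
the convention under which indel-dominated long reads land in the
mid-80s% rather than high-90s%.

**Chaining** selects, per read, the colinear set of alignments to a single
target and strand, non-overlapping in the query and order-consistent on
the target (reversed for minus-strand), maximising total aligned query
length; ties break toward the earlier target start. An O(n²) DP, verified
against exhaustive enumeration.

**k-mer representation** normalises raw counts within each spectrum and
reports `log2(observed/expected)` with a pseudocount of 1 on raw counts to
keep absent k-mers finite.

**Low-complexity filter.** A symmetric-DUST scan: each 64-base window is
scored `10 · Σ_t c_t(c_t-1)/2 / (#3-mers - 1)` over its 3-mer counts and
flagged above 20; flagged windows are merged and a read is removed when
the masked fraction strictly exceeds 0.5. A pure homopolymer scores ~305;
an i.i.d. random window ~5.

**Homopolymer calls.** A reference run (length ≥ 2, enclosed by two
boundary bases that differ from the run base; runs touching sequence ends
are excluded) is evaluated against each spanning alignment: operations on
target positions inside the run are tabulated, the called length is
`run + insertions - deletions`, and the alignment is rejected unless both
boundary positions are aligned as match/mismatch columns. Insertions are
attributed to the target position of the preceding aligned base, so an
insertion adjacent to the run's left edge counts as inside it (an
over-called homopolymer manifests exactly there); insertions before the
left boundary do not. Mismatches inside the run count toward the operation
totals but not the length. Per reference length at most 1,000 runs are
sampled uniformly without replacement under the given seed.

**Genotype concordance.** Variant calls (het/homalt) with LLR below the
threshold (inclusive at 30) revert to homref. Three rates are reported:
overall concordance; variant-site concordance, whose denominator is sites
where truth *or* test is variant; and truth-variant concordance, over
sites the truth set marks variant. Sites missing from either set are
excluded from all three denominators. Both variant denominators share the
concordant-variant numerator, since a concordant site in either
denominator is variant in both sets.

**Shuffle FDR.** Each iteration places every SV (length preserved)
uniformly at random outside the excluded regions (centromere/telomere/gap
style masks), retrying up to 1,000 times per SV before failing; a false
positive is a site the truth genotyper calls homref but the test genotyper
calls variant, and the iteration FDR is FP over truth-homref sites. The
built-in SV genotyper is a simple read-support model (alt fraction < 0.25
homref, < 0.75 het, else homalt); it is a placeholder for any real
caller, which can be plugged in as a function.

**Haplotype classification.** Reads with ≤ 1 phasing marker stay
unassigned; otherwise a read joins the haplotype with which strictly more
than 55% of its markers agree.

## Tandem and telomere arrays

Arrays of a unit `u` are found by rotation-aware tiling: for every cyclic
rotation, bases score +1 on match and `-q` on mismatch with
`q = purity/(1 - purity)` so the score breaks even exactly at the minimum
purity (default 80%). Maximal positive-scoring segments (linear-scan
maximal-subarray decomposition) delimit candidate arrays; random flanks
(~25% match) score steeply negative, so boundaries land within a few bases
of the true array edges. Candidates from different rotations are
deduplicated by score. The integer copy count is `round(span/|u|)` — with
per-base divergence a mutated edge base can shave the detected span by a
few bases, and rounding (rather than flooring) keeps the count at the
planted value; the fractional count is reported alongside. A profile-HMM
would be the heavier-weight alternative for diverged units; the tiling
segmentation is exactly testable on synthetic arrays and parameter-free
apart from the purity floor.

Telomere annotation scans both the read and its reverse complement for
TTAGGG/CCCTAA arrays (so the reported span is strand-symmetric by
construction) and keeps arrays ending within 100 bases of a read end
(adapter/error slack); the junction is the array boundary facing the read
interior. The divergence tolerance for telomeric repeats is not an
established constant; the purity floor defaults to 80%.

## Numerical choices and degenerate inputs

- Probabilities are accumulated in log space; `p = 0` exactly when some
  single read's bridging window reaches `G`.
- Empty read sets give `p = 1`; an empty repeat histogram gives `P = 0`
  everywhere and no spanned length.
- `ng_statistic` returns `None` when the lengths cannot reach the target
  fraction; `expected_ng50` maps that to 0.
- `coverage_summary` returns NaN for the zero-excluded mean of an all-zero
  depth vector.
- All generators and samplers take explicit integer seeds and are
  byte-reproducible; nothing reads global random state.

## Known limitations

- The contiguity model ignores error-driven overlap failure and chimeric
  reads: it predicts the ceiling imposed by read length alone.
- Reproducing published human-scale NG50 predictions requires the real
  UCSC repeat tracks and read sets, which are deliberately out of scope;
  the model is validated by Monte-Carlo equivalence and monotonicity
  properties at desk scale instead.
- The tandem-array detector assumes substitution-style divergence; large
  indels inside an array shift the tiling phase and will split the array.
- The SV genotyper is a deliberately simple binomial support model; FDR
  and sensitivity numbers on synthetic data characterise the evaluation
  machinery, not any particular caller.
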