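# Methods

## Detection model

`paraconv` tests each intra-species paralog alignment against each other
species in the tree. For a paralog pair (A₁, A₂) and an outgroup ortholog B₁
of A₁, informative sites are alignment columns where the three bases are
unambiguous nucleotides and exactly one of {A₂, B₁} equals A₁. A column where
the *paralog* matches is a **down** step (the pattern a conversion creates),
and one where the *ortholog* matches is an **up** step. Columns with gaps,
ambiguity codes, or no ortholog coverage contribute nothing. The walk runs
over the cumulative ±1 score in column order.

The null hypothesis is no conversion with the duplication predating the
outgroup split. Its key property is *exchangeability*: with a homogeneous
substitution process along the sequence, the up/down labels of the
informative sites are an exchangeable sequence given their counts (m, n), so
the null distribution of any order statistic of the walk is the uniform
distribution over the C(m+n, n) orderings — a hypergeometric random walk.
This makes the test robust to unequal rates of evolution between lineages
(rate differences change m and n, not the exchangeability of their order),
though not to rate variation *along* the sequence (see Limitations).

The test statistic is the maximum descent k = max over column pairs i < j of
(score_i − score_j). Its descent interval — from the step after the last
attainment of the running maximum to the first trough reaching depth k — is
the candidate converted tract; reported tract endpoints are the genomic
positions of the first and last informative sites inside the interval, a
deliberately conservative convention. Ties among equally deep descents
resolve to the leftmost.

### Exact P-value

P(max descent ≥ k) is computed exactly by dynamic programming on the
*drawdown* process D_t = (running max − score): D is a walk reflected at 0,
and the survival probability of {D < k throughout} is propagated over a
state (down-steps used d, drawdown w) with the without-replacement step
probability (n−d)/(steps remaining). Memory is O(n·k) and time O((m+n)·n·k);
the inner loops are JIT-compiled (numba) with an equivalent pure-numpy
fallback, and results are memoized. This scales to thousands of informative
sites. Values below ≈1e-15 underflow to 0.0, which only ever makes reported
P-values more conservative-looking than they are. The implementation is
verified against exhaustive enumeration of all orderings for every
(m, n, k) with m + n ≤ 12.

### Quadruplet test

When both paralogs have orthologs (B₁ and B₂), the triplets [A₁, A₂, B₁] and
[A₂, A₁, B₂] are combined per column: a column stepped in only one triplet
keeps a unit step; a column stepped in both — necessarily with the same sign,
because both triplets share the paralog-match condition — carries a
magnitude-2 step marking double support. The maximum-descent interval is read
from this combined walk. For the P-value, however, each combined column
counts as a single ±1 step: the exchangeable items under the null are the
*columns*, and expanding a magnitude-2 step into two glued unit steps would
violate the exchangeability the null computation assumes. This choice was
validated empirically: with magnitude expansion the per-test false-positive
rate was ~21% at nominal 5% in the simulation conditions below; with
per-column counting it is ~3%.

### Direction

Inside the shared descent interval of the two triplets, the recipient's own
ortholog has diverged at paralog-age distance (its tract was overwritten),
so the recipient's triplet shows a higher proportion of down steps. The two
(down, up) count pairs are compared with Fisher's exact test (an exact
conditional two-proportion test); below the significance level
`direction_alpha` (default 0.05) the primary of the higher-down-proportion
triplet is called the recipient, otherwise direction is `unknown`. Triplet
tests (single ortholog) never call direction.

### Whole-paralog criterion

A conversion covering (nearly) an entire paralog pair leaves no flanking
region: the descent test degenerates (with no non-converted flank the
maximum descent is no longer surprising under its own conditioning). When
the descent interval spans strictly more than `coverage_threshold` (default
0.80) of the alignment columns, the descent test is skipped in favour of a
binomial tail on the same counts: p = min(0.5, n/(n+m)) and
P = P(X ≥ n), X ~ Binomial(m+n, p). The p parameter is a plug-in estimate
from the observed counts — under the null the per-site down probability
cannot exceed 0.5, and the min() cap is what gives the test its power (a
fully converted pair has n ≈ m+n ≫ (m+n)/2). This
criterion additionally requires the two paralogs to map to distinct,
non-overlapping ortholog regions in the outgroup: distinct orthologs certify
a duplication older than the speciation, whereas a shared ortholog region
means the duplication may postdate the split and whole-length similarity is
then expected without any conversion. Verified property: under the null the
estimated p makes this tail ≈ 0.5, so criterion 2 contributes essentially no
false calls.

### Multiple testing

All (pair, outgroup) tests executed in a run form the correction family;
the per-test threshold is alpha/num_tests (Bonferroni; default alpha 0.05).
Tests with fewer than `min_informative_sites` (default 10) informative sites
are reported as untested and not counted in the family.

## Redundancy collapsing

One historical event is typically observed several times. Observations are
merged in a fixed order:

* **across outgroups** (same primary, same pair): boundary-similar intervals
  share an event id; the lowest-P observation represents the event.
  Boundary similarity is reciprocal overlap ≥ `boundary_tolerance`
  (default 0.5) — a chosen operationalization of "equal or quite similar".
* **across primary species**: events whose paralog pairs are orthologous,
  detected with a common outgroup, merge when the converted interval of one,
  mapped through the primary–primary ortholog alignment, is
  boundary-similar to the other's. Merging across *different* outgroups is
  deliberately not performed.
* **across post-conversion duplicates**: two events sharing a converted copy
  A₃ (observations A₁→A₃ and A₂→A₃ with similar boundaries on A₃) are
  arbitrated by percent identities inside the conversion region:
  max(Sim(A₁,A₂), Sim(A₁,A₃), Sim(A₂,A₃)) decides whether the conversion
  predates the A₁/A₂ duplication (keep lowest P) or which pairwise
  observation is the real one (keep it, drop the other). Exact ties resolve
  to before-duplication — the fewest distinct events — with a logged
  warning. Percent identity excludes gap and ambiguous columns from the
  denominator.

Event ids are assigned in (primary species, genomic start) order of the
representatives, making output deterministic. Deduplication is idempotent.

## Event dating

Each detecting outgroup bounds an event from above: the conversion postdates
the primary/outgroup split, and the topologically closest detecting outgroup
(fewest edges on the leaf-to-leaf path; branch lengths are ignored since the
tool runs from a topology) gives the tightest bound. The carrying primaries
bound it from below: the event predates their split (single primary: its
terminal edge; all leaves: a virtual root-stem edge). The reported branch is
the edge path from upper to lower bound, or `?` when no upper-bound edge is
ancestral to all carriers — absence of detection in a species is never used
to tighten a bound. Edges are numbered by depth-first post-order (children
in input order), stable across runs.

## Simulator

The simulator evolves a cluster of contiguous *units* down the species tree:

* substitutions: single-rate symmetric (Jukes–Cantor-style) model, applied
  per site per branch with probability 3/4·(1 − e^(−4t/3));
* duplications: copy a unit (or sub-interval) to an adjacent position,
  creating a new unit id;
* conversions: overwrite a tract of one unit with the homologous
  (same ancestral coordinates) tract of another unit in the same genome;
  tract length is geometric (mean `conversion_tract_mean`, default 500 bp)
  and placement uniform unless scripted.

Events arise from per-branch Poisson rates, from an explicit script
(branch, time, participants), or both; scripted events are how the studies
pin "exactly one duplication before speciation, one conversion on branch X".
Units never acquire indels, so true paralog and ortholog alignments are
gap-free, derived exactly from coordinate bookkeeping, and orthology is
positional (same unit id across species). One integer seed fixes every byte
of output.

The default study conditions are a 4-taxon tree
`((((S1:0.04,S2:0.04):0.03,S3:0.07):0.03,S4:0.10):0.05)` (expected
substitutions/site), a 3 kb root sequence, and one whole-cluster duplication
in the stem ancestor — so the duplication strictly predates the first
speciation, giving paralog divergence ≈ 0.2–0.3 and ortholog divergence
≈ 0.08–0.2, a regime comparable to primate gene clusters. These sizes keep a
full simulate-detect-evaluate cycle around 0.1 s, so the calibration (500
replicates), recovery (100), and threshold-sweep (40 × 8 thresholds) studies
run in about a minute total.

What the simulator deliberately does **not** emulate: insertions/deletions
and alignment error (true alignments are exact), inversions and deletions of
units, rate variation along the sequence, biased conversion initiation, and
assembly/sequencing artifacts. Passing tests therefore demonstrate the
statistical machinery under clean alignments; on real data, alignment
quality — especially at local-alignment ends, which is precisely what the
coverage threshold guards against — will dominate boundary accuracy and can
only degrade it.

## Evaluation conventions

A detection matches a true conversion when either of its two row intervals
reciprocally overlaps the true tract (projected onto the matching species)
by ≥ 0.5. A truth is *detectable in principle* when some carrying leaf has
an available outgroup: a species carrying the duplicated pair but not the
conversion. Sensitivity is matched/detectable; FDR is unmatched/total
detections, 0 by convention when there are no detections (and 1 when there
are detections but no true conversions). Boundary error of a matched
observation is the mean absolute offset of its two endpoints; the reported
value is the median over truths of each truth's best observation.

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open internally, 1-based inclusive in tables.
* Minus-strand MAF rows are normalized at read time (row 1 always plus);
  ortholog bases are complemented when projected across strands, making
  detection orientation-invariant (tested).
* Ambiguity codes are non-informative everywhere; percent identity over a
  window with zero usable columns raises a distinct error.
* Empty walks, missing projections, or sub-minimum informative counts yield
  "untested", never a P-value.
* P-values are clipped to [0, 1]; the DP's survival complement cannot go
  negative beyond float error.
* MAF blocks with other than two sequence rows are rejected; each 2-row
  block is one paralog pair (overlapping blocks are tested independently).

## Limitations

* The exchangeability null assumes homogeneous substitution rates along the
  sequence; strong site-rate heterogeneity (e.g. conserved exons inside a
  tested pair) can create spurious descents. The outgroup comparison removes
  shared purifying selection, which is the dominant such effect.
* Bonferroni is conservative for the positively correlated tests a cluster
  scan produces; sensitivity loss grows with the number of species.
* The criterion-2 binomial uses a plug-in p estimated from the same counts
  it tests; it behaves conservatively under the null (tail ≈ 0.5) but is not
  a pivotal quantity.
* Direction calls need informative-site counts rarely available in short
  tracts; `unknown` is common and honest.
* Only intra-species paralog pairs are tested; conversions in the outgroup
  lineage are not called (they surface indirectly as direction ambiguity or
  extra events).
* Events carried by every species cannot be dated more precisely than the
  root stem.
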