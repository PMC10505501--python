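# Methods

## Model and scope

The package implements the (w, s)-minmer winnowing scheme and the machinery
built on it: a rolling bottom-s sketch that emits *minmer intervals*, an
interval index supporting exact per-window sketch queries, a two-stage
mapper that reports local Jaccard/ANI estimates, and closed-form density
results with simulation validators. All coordinates are 0-based and
half-open: window W_j covers k-mer positions [j, j+w), and an interval
(i, a, b) covers window starts [a, b).

A k-mer is a minmer if it ranks among the s smallest (under a seeded random
hash order; ties broken toward the left-most position) in any window of w
consecutive k-mers containing it. The scheme has the (w, s)-window
guarantee — every window with at least s distinct k-mers contributes at
least s sampled k-mers — and is non-forward: a position's sampled window
ranges need not be contiguous, which is why intervals, not positions, are
indexed.

## Hashing

k-mers are packed 2 bits per base and scrambled with a seeded splitmix64
finalizer, a seedable uniform 64-bit mixer (any seedable uniform hash
serves; uniformity on [0,1] after normalization is exercised by a KS test
in the suite). Canonicalization hashes the lexicographically smaller of a
k-mer and its reverse complement, so sketches are strand-invariant; the
winning orientation is kept as a per-position strand bit. k-mers covering
an ambiguous base (N) keep their coordinate but are masked out of windows,
sketches and sampling. Because the canonical sketch of a segment equals
that of its reverse complement, strand is *called*, not searched: the
reported strand is a majority vote of (query strand bit x reference strand
bit) over the sketch members shared at the best offset.

## Rolling index construction

One left-to-right sweep maintains the current window's bottom-s distinct
hashes in a sorted map M (bisect-maintained sorted list plus dict) and the
remaining in-window hashes in a lazy min-heap H. Each slide classifies the
exiting and entering hashes against max(M): sketch exits close their open
interval (end = current window) and append it to the index; entering
hashes either evict max(M) or are pushed to H; vacated slots are refilled
from H, discarding expired entries lazily, and H is rebuilt from the live
window whenever it exceeds 2w entries (amortized O(1); the suite asserts
<= n/w rebuilds). Open intervals are closed at (last window index) + 1.

Duplicate k-mers share one sketch slot per distinct hash with a counter of
active positions (a deque, so the left-most active position is always at
hand as the interval's representative). A hash's in-sketch run can then
exceed w window starts; runs are split into adjacent chunks of length <= w
(a bound the mapper's region sweep relies on), driven by a small heap of
pending split deadlines. With duplicates present, the entering and exiting
hash can be equal, and a value may leave the window entirely while still
in the sketch — two cases beyond the four no-duplicate ones, handled
explicitly. Exactly s intervals stab any window with >= s distinct k-mers.

Ground truth for all of this is `brute_force_index`, which sorts every
window outright and reconstructs per-hash membership runs; the rolling
construction must (and does) reproduce it *exactly*, including interval
splits and representative positions, over randomized and duplicate-heavy
streams. Sequences with fewer than w k-mers are one window of their full
length with sketch size min(s, #distinct).

## Estimator and ANI conversion

The minhash numerator/denominator convention is |union bottom-s shared by
both sketches| / |union bottom-s| (the denominator may be < s for tiny or
low-complexity inputs). Jaccard converts to ANI through the binomial
k-mer survival model: divergence d gives shared-k-mer fraction (1-d)^k,
hence expected Jaccard j = (1-d)^k / (2 - (1-d)^k), inverted exactly as
d = 1 - (2j/(1+j))^(1/k). The familiar log form -(1/k) ln(2j/(1+j)) is
this inversion's Poisson approximation; it overstates divergence by
~d^2/2 (+0.005 at d = 0.10), which is measurable at the suite's replicate
counts, so the exact inversion is used. Ĵ = 0 maps to the ANI sentinel 0.
The conversion is a pair of small pure functions and is trivially
swappable.

`winnowed_minhash_jaccard` keeps the minimizer-era estimator (sketch the
w'-minimizer *subset* of each sequence) purely as the biased baseline; the
suite demonstrates its systematic ANI under-prediction against the minmer
pipeline's unbiased estimates.

## Mapper

Queries are tiled into non-overlapping segments of w k-mers (a trailing
partial segment is kept if >= w/2 k-mers, mapped with its own effective
window; shorter queries are one segment). Per segment:

1. *Stage 1.* The reference intervals whose hashes occur in the segment
   sketch are swept by sorted endpoints; the running overlap count at
   window start j equals |π_s(A) ∩ π_s(B_j)| exactly. Maximal runs
   meeting the numerator implied by the ANI threshold become candidate
   regions with their max overlap ci.
2. *ΔANI pre-filter.* Conditioned on c, the numerator is
   Y ~ Hypergeom(2s−c, c, s). The best candidate's predicted Jaccard is
   E[Y|c_max]/s = c_max/(2s−c_max); κ is the numerator matching
   (best ANI − ΔANI); a region survives iff Pr(Y >= κ | ci) >= 1 −
   filter_confidence (default 0.999, i.e. keep anything with >= 0.1%
   chance). ci < κ is dropped with certainty since Y <= c.
3. *Stage 2.* Regions are processed in decreasing ci; within a region the
   window sketch changes only at interval start/end events, so the
   estimator is recomputed per event by an O(s) sorted merge and held
   constant between events — value-identical to the direct minhash at
   every window start. Processing stops once the next ci < κ for the best
   ANI seen; because Y <= c and ties favor earlier regions, termination
   provably changes nothing (asserted over 50 simulated query sets).

The default report is the best mapping per segment; `all_mappings` keeps
each region's best within ΔANI of the segment best (a deliberate
simplification — no chaining or cross-segment plane-sweep). Mappings below
the ANI threshold are dropped, and each carries the segment's complexity
(distinct k-mers / window length) as a reliability flag; low-complexity
estimates are known to overestimate ANI.

## Theory

`interval_density` is the exact d*(w,s) = 1 − (w−s+1)(w−s)/(w(w+1));
`minmer_density` evaluates the rank-model double sum, with
Rw−1 | r1 ~ BetaBinomial(n = w−1, α = r1, β = w−r1+1) — the focal hash is
the r1-th of w uniforms, so it is Beta(r1, w−r1+1) and the final window
holds w−1 fresh competitors — and, for r1, rw > s,
Pr(C=1 | r1, rw) = Σ_u Pr(U=u) · C(2u+rw−r1, u+rw−s) / C(2u+rw−r1, u)
with U ~ Hypergeom(w−1, r1−1, w−rw), δ = min(r1−1, w−rw); coefficients in
log space. The extracted statement of this inner expression was ambiguous,
so the implementation is certified against `minmer_density_mc`, a direct
simulation (focal hash centered in 2w−1 uniforms, checked against the
bottom-s of all w covering windows): agreement is within ~1 SE at 2×10⁶
replicates and within 3 SE of winnowed-stream densities, so the closed
form is the default. The spread pmf C(w−d, df−2)/C(w, df−1) uses
Gamma-function binomials for real df, support d in {1..w}, normalized
(exactly 1 for integer df by the hockey-stick identity).

Finite-stream interval counts are compared to theory through
E|I| = (n−w)·d* + s — each sketch-changing slide closes exactly one
interval and s remain open at the end — which removes the O(w/n) edge
bias a naive |I|/n comparison would carry.

## Synthetic data and what it does (not) show

Generators draw from explicit seeds only. `mutate` substitutes exactly
round(r·L) distinct positions (targets uniform over the three alternative
bases) and can forbid duplicate k-mers via bounded resampling, making the
true Jaccard an exact function of the disrupted k-mer count — the ideal
regime in which estimator unbiasedness is provable and tested. Real
genomes add repeats (duplicate k-mers), indels (not modeled by the
binomial conversion; known to bias ANI upward at larger divergence),
N-runs, and compositional bias; passing tests here validate the
*estimator and index machinery*, not robustness to those effects (the
complexity flag is the only concession the mapper makes to them).

## Study and test sizes

The ANI-prediction study follows the ideal-sequence design: a 1 Mb random
reference indexed at (w, s, k) = (10000, 78, 19) — empirical density
~0.009 — with 100 segments of 10 kb per rate r ∈ {0.01, 0.05, 0.10},
mutated with the duplicate-free constraint and mapped back; mean predicted
divergence is required within 3 SE of r, and a sign test requires the
minimizer baseline's divergence over-prediction at r = 0.01 (p < 0.01).
Density validations winnow 10⁶-value uniform streams; stochastic
comparisons estimate the SE empirically across independent substreams
because sampled-position indicators are serially correlated within ~w
positions, so an i.i.d. SE would be anti-conservative. The minimizer vs
minmer density comparison at w = 1000 sweeps a grid of s spanning 2..501
that includes the floor(1000/s) discontinuities (s = 334, 501), where the
guarantee-matched minimizer scheme is most wasteful (~90% excess).

## Numerical and design choices

- Hashes are 64-bit unsigned integers for DNA (exact equality, no float
  hazards), floats in [0,1] for synthetic streams; the winnowing core is
  agnostic to which.
- Ordering on duplicated hash values is by (hash, position), left-most
  first; sketch membership is per distinct value (set semantics, matching
  Jaccard on sets).
- `sortedcontainers`-style trees are unnecessary at these sketch sizes:
  M is a bisect-maintained list (O(s) insert, s <= a few hundred here).
- κ = ceil(denominator × jaccard(best ANI − ΔANI)) is the documented
  convention for the early-termination numerator.
- The stage-1 filter keeps a region iff Pr(Y >= κ | ci) >= 1 −
  filter_confidence; the confidence is the probability mass a discarded
  region is allowed to have of actually reaching within ΔANI of the best.
- Degenerate inputs: empty sequences yield empty indexes; n < w collapses
  to a single window; two empty sketches make the estimator undefined
  (error); Ĵ = 0 reports ANI 0.

## Known limitations

No indel or structural-variant modeling; no chaining of segment mappings;
single-reference indexes (no concatenated multi-sequence coordinate
space); the closed-form minmer density is evaluated exactly only up to
w of a few hundred (O(w³) terms) — beyond that use the Monte-Carlo or
empirical paths; winnowing is pure Python (~0.5 μs–2 μs per position),
adequate for megabase-scale studies but not for whole mammalian genomes.
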