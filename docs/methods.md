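# Methods

This note documents the models implemented in `flexiverse`, the
defaults and their rationale, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## Coordinates and the flexible interval

All coordinates are 0-based, half-open (BED). A flexible interval is
four ordered coordinates `start_start ≤ start_end ≤ end_start ≤
end_end`: the region start lies in `[start_start, start_end]`, the end
in `[end_start, end_end]`, and `[start_end, end_start)` is the core.
This parameterization makes the degenerate case
(`start_start = start_end`, `end_start = end_end`) coincide exactly
with the fixed interval `[start_start, end_end)`, so fixed universes
embed into flexible ones with no special cases. An empty core
(`start_end = end_start`) is structurally permitted; builders emit such
regions when the data supports a start immediately followed by an end.
Strand is ignored throughout. Chromosomes are processed independently
and ordered lexicographically in outputs.

## Signal tracks

Each region set is first merged so that one experiment contributes at
most 1 to any position. Merging joins *strictly overlapping* intervals
only: abutting fragments (`[a,b)` + `[b,c)`) are deliberately kept as
two regions, because their shared boundary is real evidence for the
boundary tracks and the decoders can represent back-to-back regions
through the end→start transition.

End events are recorded at the last covered base (`end − 1`), not the
exclusive end coordinate. This keeps all three tracks supported on
covered bases — a position can simultaneously be covered and be an end
— which the likelihood model assumes. The tracks then satisfy the
balance identity `c(i) − c(i−1) = s(i) − e(i−1)` and
`Σ s = Σ e = number of merged regions`, both checked by the test suite
against a per-base counter.

Coverage is stored run-length encoded and start/end tracks as sparse
position/count pairs; dense vectors are materialized per chromosome on
demand. Exactness is contractual, the representation is not.

## Coverage cutoff universes

The CC universe keeps maximal runs with `c(i) ≥ x`. The bound
`x ≥ S_c/g` (mean genome coverage by the collection) admits a range of
cutoffs; the default takes the smallest admissible integer,
`x* = clamp(ceil(S_c/g), 1, n)`, which maximizes recall among
admissible cutoffs. An explicitly supplied cutoff is honored as given
(floored at 1, not capped at `n`): a cutoff above the observed maximum
coverage legitimately produces an empty universe, with a warning.

The CCF universe uses a lower cutoff for outer spans and an upper
cutoff for cores. Default cutoffs place a Poisson-style ±1 sd band
around the optimal cutoff: `(x* − ceil(√x*), x* + ceil(√x*))`, clamped
to `[1, n]`; both are overridable. A `≥ lower` run that never reaches
`upper` has no core and is dropped — a region without a core is
undefined. When one lower run contains several separate upper runs, it
is split between consecutive cores at the leftmost position of minimum
coverage in the gap. Each core therefore yields exactly one flexible
region, outer spans stay disjoint, and the cores reproduce the plain
cutoff universe at `upper` exactly (a tested identity). The
alternative — bridging all cores into one region — would make the
boundary intervals of a multimodal run meaningless.

## Track likelihood model and the LH universe

Per track `t ∈ {start, core, end}`, position `i` gets
`p_t(i) = (t(i) + α)/(n + 2α)` with pseudocount `α = 1` by default
(any `α > 0` keeps every probability strictly inside (0,1) and all
logs finite; `α` trades smoothing against sensitivity for small `n`).
A genome labeling over states B/S/C/E scores, per position,

```
σ(i, ℓ) = Σ_t [ on(ℓ,t)·log p_t(i) + (1 − on(ℓ,t))·log(1 − p_t(i)) ]
```

with on-sets S: {start, core}, C: {core}, E: {end, core}, B: {} —
start and end positions are themselves covered, consistent with the
end-at-last-base convention.

The LH universe is the labeling maximizing `Σᵢ σ(i, Lᵢ)` subject to the
region grammar `B* (S⁺ C* E⁺)* B*` (equivalently the transition
structure B→{B,S}, S→{S,C,E}, C→{C,E}, E→{E,B,S}, opening in {B,S} and
closing in {B,E}). Dynamic programming makes the optimum exact; the
test suite verifies it against exhaustive enumeration of all valid
labelings on short genomes. Ties prefer B, then S, then C, then E (for
the state and for its predecessor), so decoding is deterministic and
biased against spurious regions. Decoded S/C/E runs become the start
interval, core and end interval of one flexible region.

A consequence worth knowing: the S-versus-C score difference at a
position is `logit(p_start(i))`, so the decoder extends an S run only
across positions where more than half the sets register a start. With
dispersed boundary jitter the maximum-likelihood boundary intervals
are therefore narrow (often 1 bp at the majority-vote position) rather
than spanning the full jitter range; they locate the consensus
boundary, they do not enclose every observed one.

## HMM universe

The HMM has the same four states and transition structure, with
row-stochastic transition matrix (defaults: self-transitions 0.9 for B
and C, 0.5 for S and E, remaining mass split evenly among allowed
moves) and per-track Binomial(n, θ) count emissions. The default θ
table encodes the qualitative structure of the states — e.g. the S
state expects half the sets to register a start (`θ_{S,start} = 0.5`)
while background expects 2 % noise on every track — and is
configuration, not a claim; tuning it is the point of the model.
Initial probabilities are 0.9/0.1 over {B, S}; paths must end in
{B, E} so every region closes, and reset to B at chromosome
boundaries. Parameter validation rejects matrices with mass on
forbidden transitions and degenerate ones that make regions
unreachable (`B→S = 0`) or unclosable. Viterbi decoding is checked
against a brute-force path maximum in the tests. An optional
Viterbi-training loop (`em_iterations > 0`) re-estimates θ from the
decoded segmentation; it is off by default — the model is presented as
tunable, not trained.

## Filtering

`filter_universe` drops regions by outer width and/or by their
likelihood contribution (the region's σ gain over an all-background
labeling of its span, flexible-aware). Both filters default to off;
useful thresholds are collection-specific.

## Fit metrics

**F10.** The universe predicts, per base, membership in each query set:
TP/FP/FN per-base counts give precision and recall, combined by Fβ
with β = 10. Flexible regions count their full outer span as covered —
the region asserts it may extend that far; penalizing the uncertainty
band as false positives would double-count it. Conventions: F10 with
`P = R = 0` is 0; recall against an empty query is 1 (vacuous), as is
precision of an empty universe. Collection score: arithmetic mean over
sets.

**RBD.** Start boundaries match only start boundaries and ends only
ends (unmatched pairing would reward universes that merge adjacent
regions). Per direction the summary is the median distance; the two
directions combine as a weighted harmonic mean of the closenesses
`1/(1 + d)` — so `d = 0` maps to 1 with no division by zero — with
default weights 10 (query→universe) : 1 (universe→query), mirroring
the recall-over-precision asymmetry of F10. For flexible universes a
query boundary inside the boundary interval is at distance 0, else at
distance to the interval's nearest edge; this pointwise dominates the
fixed treatment, so the flexible RBD is never below the fixed RBD of
the same universe (a tested direction). Boundaries on chromosomes
where the other side is empty get infinite distance; the medians
absorb a minority of them.

**Likelihood.** A fixed universe labels each region S…C…E (width-1
regions are S only, width-2 are S,E — the grammar requires a start and
an end but no core) and sums σ; the score is reported as natural-log
likelihood and as the delta over the empty (all-background) universe,
which is exactly 0 by construction. The flexible variant replaces each
point boundary term by `log(min(1 − ε, Σ p))` over the boundary
interval (ε = 1e−12 caps the aggregate below 1), drops the per-base
"off" terms inside the interval, and keeps the core track on per-base
across the outer span; the end interval is shifted by one into
last-covered-base space so a degenerate flexible region reproduces the
fixed score exactly (a tested identity). Under this rule the flexible
score is never below the fixed score, and widening a boundary interval
inward is monotone non-decreasing — both tested.

## Synthetic benchmark

The generator plants `k` non-overlapping loci (normal widths, minimum
gap `max(1, 8·jitter_sd)`), observes each locus in every set with
independent Gaussian integer-rounded boundary jitter (truncated to keep
`start < end`), drops each locus per set with probability `dropout_p`,
and adds Poisson-distributed uniform noise regions. Ground truth is a
flexible universe whose boundary intervals span ±2·jitter_sd around
each true boundary. Defaults — 100 kb genome, 50 loci of 300 ± 50 bp,
10 sets, 5 bp jitter, 20 % dropout, 2 noise regions per set — describe
a small ATAC-like benchmark. Everything is deterministic given the
seed.

What it does not emulate: signal-strength variation across loci,
correlated start/end jitter, fragment-level noise, heavy-tailed peak
widths, or mappability gaps. Consequently, passing tests demonstrate
algorithmic correctness and the direction of the claimed effects, not
performance on real ChIP/ATAC heterogeneity.

The recovery test runs at zero jitter, where "every true boundary lies
inside the built boundary interval" is an exact-recovery statement;
as noted above, under the maximum-likelihood scoring model nonzero
dispersed jitter narrows boundary intervals to the consensus position,
so at 1 bp jitter the suite instead asserts the honest weaker property
that built boundary intervals intersect the ground-truth jitter
window.

## Numerical and scale choices

Decoding is exact DP in float64; emission and σ matrices are dense per
chromosome (the sweep itself is event-based, so only the decoders are
O(genome)). Oracle-equivalence tests enumerate all grammar-valid paths
on 8 bp genomes; recovery statistics use 100 replicates of 30 loci on
30 kb; the benchmark pipeline uses the 100 kb defaults. These sizes
were chosen so the full suite exercises every claim at desk scale.

## Known limitations

* Boundary intervals from LH/HMM are consensus-seeking (see above);
  use CCF when you want boundary intervals that span the observed
  coverage slope.
* The likelihood metric shares its model with the LH builder, which
  therefore scores best on it by construction; comparisons between
  *other* universes remain meaningful, and the tests cross-check the
  metric against independent brute-force computations.
* No tabix/bigBed/bigWig support; inputs are plain-text BED and
  chrom-sizes files.
* `assess` recomputes tracks unless given precomputed ones; for many
  universes against one collection, pass `tracks=` once.
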