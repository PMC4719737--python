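# Methods

`mapalign` aligns error-prone genomic maps — ordered fragment-size lists
produced by optical/genome mapping instruments — to in-silico maps derived
from sequence. This note documents the model, the algorithms, the
synthetic-data generator, and the numerical and design choices, in the order
the pipeline applies them.

## Map model and feasibility

An experimental map `o` is the ordered list `o_1..o_m` of fragment sizes in
bp; an in-silico map `r` additionally carries a per-fragment standard
deviation `sigma_j`. The sigma model is `sigma_j = max(sigma_min, rho *
r_j)` with defaults `rho = 0.05`, `sigma_min = 300 bp`: relative sizing
error with an absolute floor, which reproduces the size-range structure of
instrument error tables (small fragments are floor-dominated, large ones
relative-error-dominated). Both parameters are exposed in `SigmaModel`.

A *feasible match* pairs a block of consecutive experimental fragments with
a block of consecutive reference fragments such that

    | sum(o_i) - sum(r_j) | <= C_sigma * sqrt(sum(sigma_j^2)),

with `C_sigma = 3` (appropriate if sizing errors are roughly normal).
Matches at an alignment end are one-sided:

* the terminal *experimental* fragment may be physically truncated, so only
  the positive excess of the experimental sum is capped ("upper" mode);
* a match pinned at an *in-silico* map end (overlap alignment) caps only
  the deficit ("lower" mode), because the reference block understates the
  genomic fragment cut off at the sequence boundary.

The sign convention is that each one-sided test caps the error on the side
that truncation cannot explain. One-sided matches carry no chi^2 term and
are flagged `truncated`; they count toward `#matches`.

## Composite seeds and the sorted index

Discrete k-mer seeding does not transfer to continuous-valued maps, so the
index stores, for every reference position `j`, the order-2 composite seed:
the plain tuple `(r_j, r_j+1)` and the merged variants `(r_j + r_j+1,
r_j+2)` and `(r_j, r_j+1 + r_j+2)`, which pre-absorb one missing cut.
Queries are formed both plain `(o_i, o_i+1)` and merged `(o_i + o_i+1,
o_i+2)`, absorbing one false cut. Entries are sorted by first element; a
lookup binary-searches a conservative window and verifies each candidate
element against the stricter seed bound `C_sigma_seed = 2` using the
reference-side sigma of its constituents (merged constituents use the root
of the sigma^2 sum).

The search window must be a superset of the true acceptance region. The
index derives an affine envelope `sd <= A + B * e` over its entries (split
at the median entry size) and solves `|q - e| <= C_seed * (A + B e)`; every
candidate inside the window is then tested exactly, so the envelope affects
speed only.

**Seed narrowing.** Raw hits are clustered per reference map along
diagonals `r_pos - q_pos` (chain tolerance 2, matching the diagonal drift a
few cut errors cause). Clusters supported by at least two distinct query
positions are extended; up to three representative anchors per cluster are
tried in order (plain variants near the cluster centre first) and the first
successful extension is kept. A true placement of a >= 10-fragment map is
supported by many seeds, so the support filter costs little sensitivity
(measured ~2 % under the easier scenario, ~5 % under the harder) while
removing the bulk of isolated spurious hits; this is this package's
concrete realization of narrowing the seed list before extension.

## Seed extension by banded dynamic programming

Extension minimizes

    Score = C_ce * #cut_errors + sum(chi^2 per match),
    #cut_errors = missing_cuts + false_cuts + missing_fragments,

where per-match `chi^2 = (sum o - sum r)^2 / sum sigma^2`. With `C_ce =
C_sigma^2 * m + 1` the weight exceeds any achievable chi^2 total (each
feasible match contributes at most `C_sigma^2` and there are at most `m`
matches), so score minimization is exactly lexicographic minimization of
(cut errors, chi^2); this is asserted against a two-stage oracle in the
tests. Remaining ties prefer fewer matches, then the leftmost reference
start.

Each side of the anchor is extended independently (the anchor matches are
fixed by the seed variant). The DP state `(s, t)` aligns the end of the
s-th query fragment with the end of the t-th reference fragment, banded per
match to at most 5 consecutive false cuts and 8 consecutive missing cuts.
The extension aborts when no state has been reachable for a full
match-width of query positions — an exact reachability criterion that never
abandons a recoverable extension (the `f_min_feasible` parameter of the
classic early-stop heuristic is retained in `AlignParams` for
compatibility, but the exact rule subsumes it).

**Missing small fragments.** An in-silico fragment at or below the
detection limit (2 kbp) may be skipped inside a match, in runs of at most
three consecutive fragments. A skip trades one missing cut for one missing
fragment, leaving the match's cut-error count unchanged, so skip variants
compete purely on chi^2. A skip variant is admissible when the unskipped
span of the same match is infeasible, or when the skip at least halves that
span's chi^2. (The halving rule is stated against the same match span; the
comparison window is genuinely ambiguous in the field's usage, and the
same-span reading makes the rule a local, order-independent predicate that
both the DP and the brute-force test oracle can apply identically.) Skips
attach to the match on their anchor-facing side, which fixes a canonical
representation. Two exact prunings follow from the algebra: skipping mass
always *raises* the signed deviation, so skips are only explored when the
experimental sum falls short of the reference sum, and upper-mode matches
never benefit from skips.

## Statistical evaluation

All successful extensions of a map's anchors, deduplicated by placement and
match structure, form the candidate population `Pi`. Each candidate is
summarized by three features — `#matches` (higher better), `#cut_errors`
(lower better), and the Wilson–Hilferty transform
`WHT(chi^2, #matches) = ((chi^2/n)^(1/3) - (1 - 2/(9n))) / sqrt(2/(9n))`
of its sizing error (lower better) — which are approximately independent
for false placements. Features are Z-standardized over `Pi`, the signed
sum `-Z(#matches) + Z(#cut_errors) + Z(WHT)` is Z-standardized again, and
the standard-normal CDF of the result is the candidate's p-value; the best
candidate is the argmin.

Because the best p is the minimum over `|Pi|` approximately-exchangeable
scores, the cross-map FDR step uses the selection-corrected value
`1 - (1 - p)^N` (Beta(1,N) null; candidate correlation makes this
conservative). q-values are Benjamini–Hochberg within fragment-count strata
(bins of two fragments, merged until >= 50 maps; a Storey estimator with
lambda = 0.5 is available as an option). A map is reported
`significant_unique` when its q-value passes the threshold (default 0.01)
and the raw p-value of the best candidate is at least `uniqueness_ratio`
(default 5) below the next-best candidate at a different locus (>= 50 %
reciprocal overlap on the same strand defines "same locus"; candidates from
the two strands at the same interval are deduplicated to one).

Populations below two candidates cannot be standardized and are
`non_significant`; populations below 60 candidates are flagged
`low_population` because the normal approximation of the feature means
degrades. A practical consequence, visible in the tests: on very small
references the achievable |Z| is bounded by `sqrt(N-1)`, so even a perfect
alignment cannot reach strong significance without a populated null — the
method is built for genome-scale references.

## Overlap alignment

Overlap mode slides a window of `window_l = 12` fragments (step 1) over the
experimental map, solves each window as a glocal sub-problem (truncated
ends allowed), pools all window solutions of a run for the q-value step
(every window shares the same length, hence one stratum), and then iterates
solutions by ascending p-value: stop at the first false-labeled solution;
skip solutions that duplicate an already-reported overlap, conflict with a
better-ranked pick, or are non-unique against a worse-ranked conflicting
solution. Two window solutions conflict when their windows overlap, or
when they place on the same in-silico map on different strands or at
diagonals more than a window length apart (the diagonal test is what makes
"same location, continuing alignment" precise for non-overlapping
windows).

Each surviving window's seed is re-extended over the full map with the same
DP, allowed to terminate at an end of either map on each side: the side
either consumes the query (possibly truncated, "upper") or reaches the
in-silico end ("lower") leaving unaligned query overhang. Among feasible
terminals lower score wins, ties go to longer alignments. Reported
overlaps are typed `contained`, `left`, `right` or `spanning` by which
sides overhang; overhang fragments are what scaffold extension consumes.
In-silico maps with fewer than four non-end fragments are excluded at
assembly simulation time, since such maps cannot be confidently aligned.

## Synthetic data generator

`synth_reference` draws i.i.d. exponential fragment sizes (floored at 100
bp) — the spacing law of a fixed recognition pattern along random sequence.
The defaults used throughout the benchmarks emulate a human-scale digest:
50,000 fragments of mean 10.8 kbp for seed benchmarks, smaller references
for pipeline-level suites so that complete runs stay within desk-scale
compute (problem sizes are stated in each test).

`simulate_map` applies the error process in the instrument's causal order:

1. molecule extraction at a uniform start with truncated end fragments; the
   fragment count is a shifted negative binomial (r = 8) with mean 17,
   giving molecules near 275 kbp on a ~16–17 kbp digest;
2. missing cuts: each true internal cut retained with probability `d`;
3. false cuts: Poisson with rate `f100` per 100 kbp, placements re-drawn
   (up to 100 times) when they would create a fragment under 1.2 kbp;
4. missing fragments: size-dependent removal (easier scenario: probability
   0.5 below 1.2 kbp, 0.75 below 600 bp, 1 below 350 bp; harder scenario:
   0.5 below 2 kbp, 0.75 below 800 bp, 1 below 350 bp). The removed
   fragment disappears and its flanking cuts collapse into one; neighbours
   are *not* merged — this is the convention the aligner's skip rule models;
5. sizing error: Gaussian relative error by true-size range (SD 15 % below
   2 kbp, 8 % to 10 kbp, 5 % above), truncated at ±3 SD — a parametric
   stand-in for instrument-specific empirical deviation tables, fully
   configurable in `ScenarioParams`;
6. the instrument filter drops maps under 150 kbp or under 10 fragments;
7. a fair-coin strand flip.

The two standard scenarios are `ScenarioParams.easier()` (`d = 0.78`,
`f100 = 0.97`) and `ScenarioParams.harder()` (`d = 0.61`, `f100 = 1.38`).
Every map carries a `TruthRecord` (source interval, orientation, per-cut
provenance, and the reference-fragment range of every emitted fragment) so
error rates can be re-estimated and alignments scored. What the generator
does *not* emulate: chimeric/spurious molecules as a physical process
(spurious maps for FDR testing are drawn i.i.d. instead), instrument
quality scores, and correlated sizing errors along a molecule — so passing
tests bound behavior under the modeled error process, not under every
instrument artifact.

`simulate_assembly` partitions a reference at log-normal scaffold sizes
(the length-weighted median pinned to the target N50, log-SD 0.8) with
boundaries at arbitrary bp, then drops scaffolds with fewer than four
non-end fragments.

## Evaluation conventions

A glocal alignment is correct when it names the truth reference and
orientation and its reference bp interval reciprocally overlaps the source
interval by at least 50 % — a criterion insensitive to end truncation. A
seed is correct when it lies on the truth strand within one fragment of the
true counterpart of its query position. An overlap extension is correct
when the map's source interval genuinely continues past the scaffold end on
the reported overhang side and the aligned part falls on the true region.
Sensitivity divides by all maps with a true placement; precision by all
reported alignments (`NaN` when nothing is reported).

## Numerical notes and limitations

* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; runs are bit-reproducible.
* p-values are floored at 1e-300 before ratio tests; the uniqueness ratio
  is infinite when no second locus exists.
* Population Z-scores use the population SD (`ddof = 0`); a zero-spread
  feature contributes all-zero Z-scores rather than NaNs.
* Reference prefix sums make block statistics O(1); per-extension reference
  windows are capped at the band's maximal reach (9 reference fragments per
  query fragment), which bounds memory without excluding any banded
  alignment.
* Only order-2 composite seeds are implemented; seeds with more than one
  merge per side, multi-enzyme digests and two-colour nicking labels are
  out of scope. Glocal mode reports a single placement per map; only
  overlap mode reports split alignments.
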