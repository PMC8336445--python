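# Methods

This note records the models, parameter conventions, numerical choices and
known limitations behind `cenhor`. It documents how results are computed;
every empirical statement here is one the test suite or the acceptance
script computes itself.

## Distances and consensi

All string comparison is unit-cost Levenshtein edit distance; *divergence*
is edit distance divided by the length of the longer string, so it is
symmetric, zero exactly for equal strings, and bounded by 1. Ambiguity
codes are ordinary symbols and mismatch every base.

Cluster consensi use a deterministic star alignment rather than a full
progressive MSA: the center is the medoid of (the first up to 25 of) the
inputs, every input is globally aligned to the center with edlib, and a
weighted column majority is taken, treating each inserted segment between
center columns as an atomic voting unit. Ties: a gap loses to any
nucleotide, nucleotides resolve A<C<G<T, the empty insertion loses to a
non-empty one, and insertion content ties resolve lexicographically. The
contract is only the consensus string, so the engine is swappable; this one
is reproducible given input order and needs no external binary. With only
two diverged inputs every difference is a tie, which inflates the consensus
length — callers that feed two-string clusters (e.g. a 2-monomer alphabet
consensus used as the initial monomer) should set the expected-length
parameter from the string they actually use.

## Block decomposition

The array is tiled by a dynamic program over sequence positions: each block
is globally aligned to one monomer with match +1, mismatch/indel −1, and
block boundaries are free. The DP state is one alignment column per
monomer; row 0 of a column can open a fresh block at the current boundary
*or* extend an open block with a leading sequence insertion, and a
post-column sweep admits leading monomer deletions, so terminal partial
monomers at array ends are ordinary blocks. The per-position recurrence
runs under numba; a brute-force enumeration over all boundary placements
with identical scoring is the test oracle on ≤ 60 bp instances, where the
two agree exactly on the optimal tiling score. Boundary placements at score
ties can differ by a base or two between equally optimal tilings; tests
treat that as equivalence.

Per block, divergence to every monomer is then recomputed by global
alignment: `div1`/`div2` are the best/second-best values, ties broken by
lexicographic monomer id. Classification: resolved below 5%
(`maxResolvedDivergence`), non-monomeric above 40% (`maxDivergence`),
unresolved between. Coordinates are 0-based half-open internally; reports
print divergences as percentages with two decimals. Reverse-strand monomer
candidates exist behind an off-by-default flag, since satellite annotation
is conventionally done on a fixed strand.

Non-monomeric region handling re-runs the decomposition after extracting
maximal non-monomeric runs, single-linkage clustering them at the resolved
threshold and adding cluster consensi to the alphabet under `nm<k>` ids;
blocks matching such an entry stay non-monomeric regardless of divergence.

## Monomer inference

The generator starts from one initial monomer and iterates: decompose;
stop when the resolved fraction exceeds `FractionResolvedBlocks` (0.95)
with all other blocks non-monomeric; otherwise build the block-graph on
unresolved blocks (edges at divergence < `maxResolvedDivergence`/2), take
the largest connected component (ties: smallest minimum block start), add
its consensus as a new monomer, drop monomers that are no block's best
match, and recompute every monomer as the consensus of its resolved blocks.
On the returned set each monomer is a fixed point of that recomputation,
which the tests assert. A `max_iterations` cap of 100 turns pathological
inputs into an explicit failure carrying the full iteration log; the log
also reports, per iteration, the new monomer's radius and its separation
*to previously generated monomers* — the convention used in published
per-iteration tables, distinct from the final all-monomers separation
statistic.

Pair enumeration for the block-graph uses a k-mer prefilter (k = 7): a pair
at edit distance e preserves all k-mer types outside its ≤ e edited
regions, so sharing fewer than `n_types − e·k` types rules the pair out;
survivors are verified exactly. The filter is a necessary condition, so the
output equals the all-pairs computation, which remains available as
`method="bruteforce"` and is the test oracle.

Statistics: count is the number of blocks (non-monomeric excluded) whose
best monomer is M; radius the maximum consensus-to-block edit distance;
separation the minimum consensus-to-consensus distance to other monomers
(absent for a singleton set); separation ratio their quotient, +inf when
the radius is 0. Frequent means count strictly exceeds
`|Blocks|/FreqCeiling` (40); an infrequent monomer with count ≤
`rareMonomerCount` (5) is rare.

Hybrid detection searches, for each infrequent candidate M and each ordered
pair of distinct frequent parents (X, Y), the concatenation
`X[:i] + Y[−j:]` minimising divergence to M. Rather than bounding the cut
points heuristically, the search is exact within the decision band implied
by the threshold: edit distance is at least the length difference, so only
`i + j` within `|M|·(1 ± MaxHybridDivergence)` can pass, and within that
band forward/backward edit-distance tables give the exact minimum over all
cuts and split points. Candidates at or below `MaxHybridDivergence` (1%)
are annotated `X(i)+Y(j)`. When the junction characters coincide the cut
point is inherently ambiguous; the smallest qualifying `i` is reported.

## Monomer graph and shifting

The monomer-graph counts immediate successions in the monostring; the `?`
token breaks adjacency. An i-shifted monomer-set takes, per edge (M, M′),
the i-suffix of M concatenated with the (|M′|−i)-prefix of M′ — the formula
reading of "shift by i", which for unequal monomer lengths differs from
shifting every start right by i; both readings agree on equal-length
monomers. Candidates are merged by single-linkage at
`maxResolvedDivergence`/2, represented by their source-edge-weighted
consensus, and labelled by the heaviest source edge. Weight-1 edges are
retained (with their weight reported) rather than filtered. The shifted
monomer-graph is built from consecutive triples mapped through the merge.
No "standard" shift is chosen automatically; the 94 nt shift used for the
human reference set is a user-supplied value.

## HOR inference

Substitution machinery follows the leftmost rule: occurrences of h are
accepted greedily left to right without overlap; `S(h)` replaces them by
one new symbol, so `|S(h)| = |S| − count·(|h|−1)`. Run-length encoding
collapses maximal runs `X…X` to `X^n`, counted as one symbol. The greedy
step selects, among substrings with length ≤ `MaxLength` (30), count ≥
`MinCount` (5), weight `|S*| − |S(h)*|` ≥ `MinWeight` (5), at least two
distinct symbols, no `?`, and (for HORs, not superHORs) at least one
original monomer symbol, the candidate minimising `|S(h)*|`; ties go to the
shortest, then lexicographically smallest expansion. Two threshold
conventions deliberately deviate from a strict "exceeds" reading:

* count/weight thresholds are inclusive (≥). The superHOR defaults
  `MinCount = 2`, `MinWeight = 2` are intended to admit a twice-occurring
  weight-2 pattern (the worked chain's `bc`), which strict comparison would
  reject; frequency classes, by contrast, keep the strict reading
  (frequent: count > `|HORDecomposition|/HORFreqCeiling`; rare: count ≤
  `rareHORCount`).
* a recurrence floor of 2 applies regardless of `MinCount`, since a
  substring occurring once is not a repeat (and would otherwise make the
  whole string the best "HOR" at `MinCount ≤ 1`).

The published walkthrough on `CABDEGFABEGFBDEGFABDEGFDABABDD` states
parameters under which its own first pick (EGF, weight 8, stated
`minWeight` 10) fails its own threshold, and the greedy objective on that
string is actually minimised by BDEGF (`|S(h)*|` = 17 vs 21 for EGF); the
chain EGF → AB → Da is therefore treated as an illustration of the
machinery, which the tests verify step by step via explicit substitutions,
not as the greedy trace. `select_hor` implements the stated objective
faithfully.

HOR counts are reported in all three conventions that appear in published
tables: `count` (occurrences in the fully expanded decomposition, including
those nested inside later HOR definitions — the convention of the published
per-HOR cenX table, where e.g. the 12-mer's 1482 = 1444 top-level + 20 via
one containing HOR + 18 via another), `count_top` (top-level only, degrees
expanded) and `n_elements` (run-length elements). The frequency rule uses
`count` against the run-length element total.

Canonical (externally supplied) HORs are substituted first in their given
order, bypass the thresholds, and remain in the output even at count 0,
providing continuity with previously published HOR names. SuperHOR
inference strips degrees (each run `H^n` becomes one `H`) and reruns the
loop with the super thresholds and no monomer-containment requirement;
degrees are not re-attached, the superHOR string is reported alongside the
degree-bearing one. Every decomposition run asserts the score identity per
iteration and verifies lossless expansion at the end; termination is
guaranteed because each accepted substitution strictly shrinks `|S*|`.

The HOR-graph connects HORs sharing at least one monomer after recursive
expansion; each component's primary HOR is its maximal-count member, ties
to the smallest id.

## Simulator

The simulator emulates the nested-tandem-repeat data model: a monomer
alphabet descended from one random ancestor, with all pairwise divergences
forced into `inter_monomer_divergence` ± 20% of itself by incremental
rejection sampling (default 0.25, matching the 65–88% identity range of
human alpha-satellite monomers); a HOR pattern repeated `n_units` times;
per-copy substitutions (default 0.9%) and indels (default 0.1%, insertions
capped at 3 bp, deletions single-base) — together the "1% mutation" study
condition; optional variant units and planted non-monomeric insertions with
recorded intervals. Identical spec + seed gives byte-identical output.

What it does not emulate: sequencing or assembly error, large structural
rearrangements, divergence gradients along the array (old vs young layers),
transposon sequence realism (insertions are uniform random), or
inter-monomer divergence structure (all pairs sit in one window, whereas
real monomer families have hierarchical similarity). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated repeat model, not robustness to assembly artefacts or to divergent
HOR layers.

Truth-aware evaluation matches blocks at ≥ 50% reciprocal overlap, matches
monomer sets by minimum-cost bipartite assignment on divergence, and raises
a phase flag when matched blocks show a systematic (non-zero median) start
offset — full recall with a phase flag is the signature of a prediction
locked to a different monomer rotation.

## Problem sizes used in the automated checks

Recovery checks run on arrays with k ∈ {2, 5, 12} planted monomers,
100–150 HOR units (≈ 34–205 kb) at 1% per-copy mutation and fixed seeds;
the generator recovers exactly k frequent monomers with matched divergence
≤ 1%, and the top inferred HOR equals the planted unit up to rotation.
These sizes keep the whole suite in the minutes range while preserving the
regime the method targets (hundreds of HOR copies, intra-unit divergence
far above copy-to-copy noise). Genome-scale annotation (a full human
centromere complement) requires the external assembly and is out of scope
for the automated checks; what is exercised at desk scale instead is the
per-iteration log format and the published cenX HOR table bundled as a
parsing/graph fixture.

## Known limitations

* The greedy decomposer approximates the score-minimisation problem; it
  carries no optimality guarantee and alternative optimal HOR sets can
  exist (the objective itself admits multiple solutions).
* Monomer clustering can over-merge monomers shared between arrays
  (low separation ratio flags this); submonomer subdivision is not
  implemented.
* The block DP is exact for its scoring but that scoring (unit costs,
  free boundaries) is itself a modelling choice; divergence-based
  classification softens, but does not remove, its influence on boundary
  placement at ties.
* Canonical-HOR seeding substitutes seeds in the given order before the
  greedy loop; interleaving seeds with discovered HORs is not supported.
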