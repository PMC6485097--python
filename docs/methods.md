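# Methods

`morphpars` implements classical maximum parsimony for discrete
morphological characters: given a taxa × characters matrix of small
integer states, find the unrooted binary trees minimizing the total
number of state changes, then quantify homoplasy, clade support, and the
character changes that diagnose each clade. This note records the models,
conventions and numerical choices, and what the simulation-based tests do
and do not establish.

## Character model and scoring

A cell is a set of candidate states. Singletons are ordinary
observations; polymorphic/uncertain codings such as `(0/1)` are treated
as *uncertainty*: any reconstruction may pick whichever member is
cheapest, so an ancestor matching any member adds no cost. Missing (`?`)
and inapplicable (`-`) cells are both treated as missing — the full state
range of their character — which is standard practice for morphological
matrices; the original symbol is preserved for round-tripping. This
uncertainty convention (TNT's default) affects step counts on polymorphic
cells and is applied consistently in tree length, `m`/`g` bounds, and
ancestral states.

Unordered (non-additive) characters are scored with Fitch set operations:
intersect child state sets, or on empty intersection take the union and
add one step. Ordered (additive) characters use the Farris interval
method with cost |i − j|; a polymorphic leaf contributes the interval
[min, max] of its members. Both passes are exact on binary trees and are
property-tested against exhaustive minimization over every ancestral
assignment on all topologies with ≤ 6 leaves. Characters have positive
weights (default 1, the equal-weights configuration typical of these
datasets); tree length is the weighted sum.

For polytomous trees (consensus trees, collapsed trees) pairwise Fitch is
not exact, so exact lengths on arbitrary trees use a Sankoff dynamic
program over per-state cost vectors (cost matrix 1 − I for unordered,
|i − j| for ordered). The same DP powers ancestral states and the branch
collapse rule.

## Homoplasy statistics

Per character: `m` is the minimum conceivable steps on any tree —
unordered: (minimum number of states covering every non-missing cell,
minimized over polymorphic resolutions) − 1; ordered: the smallest
achievable state range. `g` is the maximum conceivable steps — unordered:
n_eff − (largest achievable single-state count), with n_eff the
non-missing cell count; ordered `g` has no comparably simple closed form,
so it is computed by explicit topology enumeration up to 8 effective
cells and reported as unavailable beyond that (ensemble RI is then
undefined and flagged; fully unordered matrices are always exact). Both
formulas are tested against enumeration over all topologies.

Ensemble CI = M/S and RI = (G − S)/(G − M) with M, S, G the sums of m,
s, g. Programs differ on whether parsimony-uninformative characters are
included; both modes are provided (`include_uninformative`, default
True), with "informative" defined as g > m — exactly the characters able
to add steps beyond their minimum. Reported CI/RI are rounded half-even
to 2 decimals, matching the precision of published values; per-character
ci = m/s is defined as 1.0 when s = 0, and ri is NaN when g = m.

## Tree search

* **Exhaustive** enumeration by stepwise insertion yields each of the
  (2n − 5)!! topologies exactly once (guarded to n ≤ 10); it is the
  oracle for everything else.
* **Branch-and-bound** does DFS over the same insertion tree, pruning any
  partial tree longer than the current bound — safe because parsimony
  length is non-decreasing under taxon addition. The bound is initialized
  from a greedy addition tree. Equal-length complete trees are collected,
  so the MPT set is exact.
* **Heuristic search** is random-addition-sequence Wagner building
  (holding `hold_per_step` trees per step, ties broken by canonical
  branch order) followed by tree-bisection-reconnection (TBR) swapping
  with first-improvement acceptance over a canonically ordered
  neighborhood. The optimal set is closed over equal-length TBR
  neighbors (bounded by `max_trees`, default 10,000), which recovers the
  full MPT set whenever each same-length "island" is reached by at least
  one replicate; the oracle-equivalence tests use 40 replicates because
  islands genuinely occur at 6–8 taxa.

All randomness flows from a single integer seed; identical seeds give
byte-identical results. The published analysis this package re-implements
describes exact branch-and-bound together with heuristic replicate
settings; both paths are provided — exact search is the default up to 10
taxa, heuristic beyond — and the report echoes which was used.

After search, any internal branch whose minimum optimized length is zero
is collapsed (the TNT-style rule): a branch is collapsible exactly when
contracting it leaves tree length unchanged, tested with the Sankoff DP.
The rule is configurable (`collapse=False` keeps binary trees), since
MPT counts are only meaningful under a stated collapse convention.

## Clade support

**Bremer decay** of a strict-consensus clade = (best length among trees
not displaying the clade) − (best length overall). Up to
`exact_max_taxa` (default 10) this is computed by converse-constraint
branch-and-bound that rejects clade-containing trees at completion;
beyond that, by a penalized heuristic search whose objective adds a
large constant (10^6) to any tree displaying the clade, so TBR descends
toward the best clade-free tree directly. Heuristic values above `cap`
(default 20) are censored and reported as ">cap". The exact path is
tested against full enumeration of every topology's length at ≤ 7 taxa.

**Bootstrap**: each pseudoreplicate resamples characters with
replacement to the original count and is analyzed with a reduced
heuristic search (default 10 RAS starts, hold 1 — replicate-level search
settings are rarely published, so these defaults are explicit
configuration, echoed in reports). All optimal trees found in a
replicate are summarized by their strict consensus before counting
bipartitions, avoiding arbitrary tie resolution; frequencies are
percentages over replicates, and a majority-rule (> 50%) tree carries
them as node labels.

## Ancestral states and synapomorphies

Trees are rooted on a designated outgroup taxon (default: the first
matrix taxon, with a logged warning, since a functional outgroup is not
always stated). Reconstruction minimizes cost by DP; the root state
prefers, among minimal states, one observed in the outgroup (polarity),
then the smallest. Resolving top-down, ties between keeping the parent
state and changing are broken toward change under ACCTRAN (accelerated:
reversals over parallelisms) and away from change under DELTRAN, then
toward the smallest state. Both conventions are minimum reconstructions,
so per-character changes summed over branches equal the character's steps
(property-tested, including ordered characters where a change i→j counts
|i − j| steps). Reported synapomorphies follow ACCTRAN; the
`unambiguous` flag marks changes DELTRAN places identically. A change
onto a polymorphic terminal appears only when no member matches the
reconstructed parent state. With multiple MPTs, apomorphies are reported
on the first canonical MPT; published node annotations do not always
state their convention, which is why both are computed.

## Synthetic data

The simulator evolves each character along a random (or given) binary
tree by a per-branch Bernoulli jump: with probability `change_prob` the
state jumps to a uniformly chosen different state (ordered variant: ±1,
reflecting at the range ends). All branch lengths are 1. This matches
parsimony's change-counting view and deliberately avoids a rate ×
branch-length model; it is not a likelihood-calibrated Mk simulator, so
passing tests say nothing about model-based inference, only about the
combinatorial machinery. Defaults mirror the shape of a typical published
morphological dataset — 30 taxa × 103 characters, 2–4 states, a few
percent missing (5%) and polymorphic (2%) cells; `change_prob` defaults
to 0.1, which yields moderate homoplasy (ensemble CI roughly 0.6–0.8 at
that shape). Missing cells are masked uniformly at random — real
missingness is structured (whole anatomical regions absent), which is
exactly what the tooth-only degradation mode emulates: for chosen taxa,
all characters outside a 22-of-103 dental subset are masked (~80%
missing), the regime of fossil taxa known only from teeth.

Simulation-based checks use sizes chosen for statistical comfort at desk
scale: oracle equivalence on 100 random 6–8-taxon matrices, support
checks on 200-character congruent matrices with 1000 bootstrap
replicates, and tree recovery over 100 seeded 12-taxon runs (observed
recovery ≈ 99% of true clades at change_prob 0.05, asserted ≥ 95% to
absorb sampling noise).

## Degenerate inputs and edge conventions

Matrices with 2–3 taxa have a unique topology and are handled specially.
Invariant and all-missing characters contribute zero steps and m = g = 0;
an all-missing character changes no statistic. Strict consensus of one
tree is that tree; majority-rule thresholds below 0.5 are rejected
(incompatible splits), and threshold 1.0 reproduces the strict consensus.
Bipartitions are canonicalized as the side not containing the first
taxon. Newick output displays trees rooted on the outgroup edge; labels
with spaces are quoted, and internal labels carry support values when
requested.

## Known limitations

No Sankoff step matrices, implied weighting, ratchet/sectorial search,
jackknife, partitioned Bremer, or likelihood/Bayesian reconstruction.
Exhaustive search is guarded to 10 taxa and exact Bremer to
`exact_max_taxa`; heuristic Bremer values are lower-bounded by
construction and censored at the cap rather than guessed. Ordered-
character g (hence RI) is unavailable past 8 effective cells. TBR
closure can in principle miss an equal-length island never visited by
any replicate; replicate counts are the lever, and the determinism
contract makes any such miss reproducible rather than silent.
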