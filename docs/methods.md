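# Methods

## The comparison problem

Two communities observed as directed consumer–resource networks can differ
in which taxa occur (composition) and in how the taxa that do occur
interact (structure).  `ecoged` measures both at once through a graph edit
distance and then asks, information-theoretically, how much of the joint
measure could have been predicted from composition alone.

## Edit model and cost computation

A web is g = (V, E) with links oriented resource → consumer.  An edit path
between g1 and g2 consists of node deletions/insertions, link
deletions/insertions and link reversals (flips).  Deletion and insertion of
the same element class share one price, which makes the distance symmetric
in its arguments.  Every injective partial correspondence m: V1 → V2
induces a cheapest edit path whose cost decomposes exactly:

* node term — `c_node` per unmatched node on either side;
* links incident to an unmatched node — `c_link` each (counted once);
* for each unordered pair of matched nodes, the two webs' pair states
  (none / forward / backward / both) are compared: each direction mismatch
  is one `c_link`; a pure reversal (forward vs backward) is priced
  `min(c_flip, 2·c_link)`, because deleting and re-inserting the link is
  always an admissible alternative route to a flip — without the cap the
  "distance" would overcharge reversals whenever `c_flip > 2·c_link`,
  which holds in several of the built-in scenarios;
* a self-loop presence mismatch on a matched node is one `c_link`
  (a reversed self-loop is itself, so loops never flip).

GED is the minimum induced cost over correspondences.  The cost of one
correspondence is evaluated in O(k²) with boolean adjacency matrices.

**Normalisation.** Scores are raw cost divided by
`C_max = c_node·(|V1|+|V2|) + c_link·(|E1|+|E2|)`, the cost of the
always-available path that deletes web 1 wholesale and inserts web 2.
This maps identity to 0 and total replacement to 1 for every cost scheme,
and is monotone in the raw cost for a fixed pair.  (The original network
aligner this emulates normalises per node against the highest possible
single-node contribution; that convention is only paraphrased in the
literature we follow, so the global, exactly testable form above is used
instead.  Both agree at the endpoints 0 and 1.)  `C_max = 0` — both costs
zero, or two empty webs — returns score 0.

## Solvers

* **exact** — enumerate every injective partial correspondence (including
  the empty one).  The count grows as Σ_k C(n1,k)·C(n2,k)·k!, so the
  solver is capped at 6 nodes per side (≈13k evaluations); ties are broken
  by enumeration order for determinism.
* **evolutionary** — both node sets are padded with null partners to a
  common length N = |V1|+|V2| and a correspondence is a permutation of
  0..N−1.  Steady-state loop: one offspring per iteration from an
  elite-biased parent pair via assignment crossover (graft parent-2
  pairings, repairing with swaps) and per-position swap mutation, replacing
  the worst member if better.  A run stops after `stall_limit` offspring
  without improvement (default 1,000, the aligner's published stopping
  rule) or `max_iterations` (50,000); `restarts` independent runs are
  pooled.  Defaults: population 128, elite fraction 0.1, mutation rate
  0.05.  The initial population always contains the delete-all/insert-all
  correspondence (so the result never exceeds `C_max`) and, when
  `seed_with_identity` is on (default), the taxon-identity correspondence,
  so shared-composition signal is never missed.  Deterministic given the
  seed.
* **identity** — evaluate only the taxon-identity correspondence.  Cheap,
  label-honouring, and an upper bound on GED; useful when taxon codes are
  trusted across sites.

The search itself is label-free (topology-driven): on tiny instances the
heuristic with 3 restarts recovers the exact optimum in ≈100 % of trials
(validated in the test suite and the acceptance script) and can never fall
below it.

## Compositional similarity and the β-partition

Jaccard dissimilarity is (a+b)/(a+b+c) over taxon occurrences; two empty
webs compare as identical (0) for consistency with the equal-sets limit.
The interaction partition identifies a link by its ordered taxon pair:
B_WN compares full link sets, B_OS the links among shared taxa only, and
B_ST = B_WN − B_OS.  The pairwise dissimilarity family defaults to
Whittaker, (a+b)/(2c+a+b) — the default of the standard β-link R
implementation — with Jaccard form available for sensitivity checks.
B_OS ≤ B_WN holds identically (shared links are common to both
computations and unique-link counts can only shrink), so B_ST ≥ 0.  When
neither web has any link among shared taxa, B_OS is undefined in the
source framework; it is set to 0 here (so B_ST = B_WN) and flagged,
keeping downstream AMI inputs complete.

## Adjusted mutual information

Similarity vectors are discretized into equal-frequency bins (stable-sort
chunking into sizes ⌊n/nbins⌋/⌈n/nbins⌉; adjacent bins holding one
identical repeated value merge, so a constant vector collapses to one bin).
`nbins` defaults to round(n^⅓) — 5 for the survey's 120 pairs — and is a
knob because the discretization used for the published tables is not
recorded.  Entropy and mutual information are plug-in estimates in nats.
The expected MI under the permutation model (all contingency tables with
the observed margins, hypergeometric cell law) is evaluated exactly in
log-factorial space, and

AMI = (I − E{I}) / (max{H(U), H(V)} − E{I}).

When both labelings collapse to a single bin the denominator vanishes; the
convention is AMI = 1 for identical labelings, else 0.  The implementation
is checked to 1e-8 against an independently maintained max-normalised AMI
and to 1e-10 against brute-force enumeration of margin-preserving tables.

## Scenario sweep

The 49 cost scenarios are stored as literal data — scenario 1 prices every
edit at 1; scenarios 2–25 cross flip 0.25 with node × link levels
{0, 0.25, 0.5, 0.75, 1}² minus (0, 0); scenarios 26–49 repeat at flip
0.75 — and a generator regenerates the grid rule in tests to guard the
transcription.  For n webs each scenario yields C(n,2) pairwise rows
(120 for the 16-web survey; the sweep reports its literal row count —
note the survey text's total of 8,820 comparisons does not equal
49 × 120 = 5,880, a discrepancy left as documented).  Per-pair search
seeds are `crc32(master_seed | scenario | pair names)`, so sweeps are
reproducible yet searches independent.  Jaccard and β columns do not
depend on edit costs; they are computed once and joined to every scenario,
and the sweep asserts their invariance.

## Synthetic communities

The generator emulates a multi-site stream survey, not any particular
dataset:

* **Metaweb** — niche model: niche values n_i ~ U(0,1), feeding range
  r_i = x·n_i with x ~ Beta(1, 1/(2C) − 1) centred at c_i ~ U(r_i/2, n_i).
  Realised connectance averages the target C (±0.01 over 50 seeds at
  S = 200, C = 0.05 in the tests).  Chosen because it produces realistic
  directed food-web topology (interval diets, cannibalism, looping) with a
  single interpretable parameter; it is a stand-in behind the `MetaWeb`
  interface and swappable.
* **Local assembly** — a web at gradient position p samples its richness
  (uniform on `richness_range`) with taxon weights
  ∝ exp(−gradient_strength·|n_i − p|); links are the induced metaweb
  subgraph.  Defaults: 16 webs, richness 48–113, pool 160, connectance
  0.06, links filtered to 110–832 — the survey's scale.
  `gradient_strength = 4` makes the default-scale compositional range
  (1−Jaccard ≈ 0.07–0.68) match the field range (0.08–0.67).
* **Rewiring** — each realised link is independently, with probability ρ,
  replaced by a uniformly drawn absent directed pair among the sampled
  taxa (self-loops excluded, link count preserved so GED differences
  reflect structure, not density).  ρ = 0 makes every pair of webs agree
  exactly on shared taxa (B_OS ≡ 0, asserted in tests); ρ = 1 removes all
  co-occurrence signal from interactions.

What the generator does **not** emulate: empirical degree distributions,
body-size or habitat correlates, sampling effort differences between
sites, or abundance.  Passing tests therefore demonstrate the machinery's
correctness and the qualitative composition/interaction decoupling
mechanism, not quantitative agreement with any field system.

## Problem sizes for validation runs

Exact GED limits validation webs to ≤5 nodes; the heuristic-vs-exact
agreement check uses 100 such pairs under 5 sampled scenarios.  The
end-to-end demonstrations use 16 webs of 20–30 taxa from a 50-taxon pool
(so species pools overlap as in the field data) with search budgets of
population 48 / stall 200, and the decoupling experiment uses 8 webs of
20–30 taxa × 10 replicates per ρ with population 32 / stall 150 — sizes
chosen to keep the full suite and the acceptance script in the minutes
range while leaving the AMI estimates their qualitative resolution.  At
these scales the scenario-7 AMI between 1−GED and 1−Jaccard on
half-rewired communities sits near 0 (the published full-scale values
range 0.014–0.134), and mean AMI declines with ρ (negative Spearman trend
across {0, 0.25, 0.5, 0.75, 1}).

## Numerical conventions and edge cases

* Natural logarithms throughout; AMI is base-free.
* 0·log 0 := 0 in entropy/MI; MI clipped at 0 against roundoff.
* Equal-frequency ties: stable sort of (value, original index); only
  whole single-valued bins merge.
* Improvement threshold in the search is 1e-12 to avoid stall-counter
  resets from floating noise.
* Labels are canonicalized (trimmed, case-folded) at every input boundary;
  adjacency orientation has no default and must be stated.
* Empty webs: valid everywhere; empty-vs-empty is similarity 1 / distance
  0 by the equal-sets convention.

## Known limitations

* The evolutionary search is a heuristic: scores for webs beyond the exact
  solver's reach are upper bounds on true GED, with seed-dependent
  variance that propagates into sweep-level AMI values.
* AMI at C(16,2) = 120 pairs with 5 bins has limited resolution; values
  within ±0.05 of each other should not be ranked.
* The β-partition and GED treat links as binary; interaction strengths are
  out of scope.
* The niche-model stand-in means full-scale published AMI values are
  reproduced qualitatively (low, far from 1), not numerically.
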