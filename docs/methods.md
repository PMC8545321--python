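# Methods

## Pair weighting

A reaction with mapped non-hydrogen atoms is split into every
(reactant, product) combination. Atom identity is the atom-map index:
`n_c` is the size of the intersection of the two index sets, `n_r` and
`n_p` the set sizes. Hydrogens carry no indices and are invisible to the
calculation. The Conserved Atom Ratio is

    CAR = (CAR_r + CAR_p)/2 · (1 − |CAR_r − CAR_p|),   CAR_x = n_c / n_x

The second factor corrects for size mismatch: a small fragment fully
conserved inside a much larger partner is penalized even though one of
the one-sided ratios is 1. Two consequences worth knowing:

* the factor lies in [0, 1] always (both one-sided ratios are ratios in
  [0, 1]), so the defensive clip of the CAR at 0 never actually binds;
* the CAR is **not monotone in n_c** when n_r ≠ n_p. Example:
  CAR(1, 2, 40) ≈ 0.138 but CAR(2, 2, 40) ≈ 0.026 — conserving the whole
  2-atom fragment maximizes the imbalance |CAR_r − CAR_p| and the factor
  collapses faster than the mean grows. This is a real property of the
  formula, deliberate in spirit (imbalanced pairs are cofactor-like), and
  the test suite asserts it explicitly rather than a false monotonicity.
  Monotonicity does hold for n_r = n_p, where CAR = n_c/n.

Self-pairs (a compound regenerated on both sides) are dropped — they can
never appear in a loop-less path. Stoichiometric duplicates are expanded
into distinct participant instances and the pair with maximal n_c per
(substrate, product) is kept. Zero-CAR pairs survive decomposition (they
document that a pair was considered) and are filtered at graph build.

### CoA contraction

When a Coenzyme A moiety occurs on both sides of a reaction, each moiety
collapses to a single pseudo-atom before counting, so the acyl groups
dominate the CAR of thioester pairs. The pseudo-atom takes the smallest
mapped index of its moiety: a conserved moiety therefore contributes
exactly one conserved atom to n_c (the pseudo-atom is itself conserved —
it is "a single atom" present on both sides). CoA on one side only is
left as ordinary atoms, with a warning. Moieties are declared explicitly
per participant (`coa_atoms` in the reaction table), via a configured
free-CoA id list (whole compound), or detected from structures by an
RDKit substructure match when reaction SMILES are the input.

## Graph model

Nodes are compounds after stereoisomer merging: compounds sharing the
first 14 InChIKey characters (the connectivity block — skeleton without
stereochemistry, charge, isotopes) become one node named by the
lexicographically smallest member id; compounds without a valid key map
to themselves. Edges are undirected; parallel pairs between the same
node pair collapse to one edge with the maximum CAR (shortest-path
semantics only ever use the best pair) and the union of supporting
reaction ids. Edge distances:

| transform | d(CAR)        | d(1) | intent                                   |
|-----------|---------------|------|------------------------------------------|
| default   | 1/CAR         | 1    | baseline                                 |
| sqrt      | √(1/CAR)      | 1    | softer atom-conservation penalty         |
| exp       | e^(1/CAR − 1) | 1    | harder penalty; best for long pathways   |

The exp form is read as e^(1/CAR)/e, the unique reading that gives
d(1) = 1 for all three transforms and preserves the strict ordering
sqrt < default < exp on (0, 1). Free CoA (C00010) is excluded from the
network by default — CoA-to-CoA pairs carry near-maximal CARs and would
act as a large-hub shortcut that the weighting cannot suppress. Other
hub cofactors are *not* excluded: suppressing them is the job of the
CAR weighting itself; a configurable cofactor list supports benchmark
networks built the traditional cofactor-free way.

The thresholded view keeps edges with CAR **strictly greater** than the
cutoff, sets every distance to 1 and drops isolated nodes; it is the
substrate for network diagnostics and the two-sided unweighted search.

## Pathway search

Yen's k-shortest loop-less path enumeration (networkx's
`shortest_simple_paths`) yields simple paths in non-decreasing score
order; `carpath` layers on top: a `max_length` filter (discarded paths
do not count toward k), deterministic tie-breaking by
(score, length, lexicographic node sequence) with a 1e-9 score
tolerance for tie detection, and full per-step bookkeeping (CARs,
distances, reaction-id sets; reports print the smallest reaction id per
step). The pathway score is the sum of step distances under the active
transform; the average CAR is the arithmetic mean of step CARs.
Queries with source = target are rejected; a source and target in
different components return an empty result plus a structured warning.

The unweighted benchmark mode ranks by hop count on the thresholded
view, using a bidirectional (two-sided) BFS for the reachability check;
loop-less and k semantics are identical. Multi-source searches are
independent per-source runs; a failing source maps to an empty result
without affecting the others.

## Network diagnostics

Statistics are computed on the thresholded view: node/edge counts (plus
the doubled directed-arc count some tools report), number of connected
components, biggest component (ties broken by edge count then smallest
node id) with node/edge percentages relative to the thresholded graph,
and its exact diameter by all-pairs BFS — fixtures are desk-scale, so no
approximation is used. The connectivity check warns when a query's
endpoints fall in different components at the active threshold.

## ROC validation

CAR cutoffs form the grid c_i = i/100 (zero excluded, one included —
cutoff 0 would degenerately predict everything positive); a pair is
predicted "main" when CAR ≥ c (inclusive). Sensitivity, specificity and
Youden's index (sens + spec − 1) are tabulated per cutoff; the AUC is
trapezoidal over the (FPR, TPR) grid points augmented with (0,0) and
(1,1); the optimal cutoff is the smallest cutoff maximizing Youden's
index. Tests cross-check the grid AUC against the rank-based
Mann-Whitney estimator on smooth score distributions (agreement to
5e-3 at the sample sizes used).

## Synthetic study conditions

* **Hub shortcut**: 2 steps at CAR 0.2 vs 5 steps at CAR 0.9. Closed
  forms give hub scores {default 10, sqrt 4.47, exp 109.2} and chain
  scores {5.56, 5.27, 5.59}: exp ranks the chain first, sqrt the hub,
  and the default transform also prefers the chain (5.56 < 10) — route
  preference under the default transform follows the arithmetic, not a
  rule of thumb that "short always wins".
* **Labeled pairs**: 5148 positives / 5599 negatives (the population
  sizes of the curated reference set). Positive CARs ~ Beta(1.4, 1.2),
  negative ~ Beta(1.6, 7.5); these shapes were fixed once, from the
  closed-form population properties (theoretical AUC 0.881,
  Youden-optimal cutoff 0.34, Youden max 0.63), to emulate the empirical
  separation between main and non-main pairs. A smooth two-Beta model
  matching AUC ≈ 0.88 and cutoff ≈ 0.34 tops out at Youden ≈ 0.63,
  slightly below the 0.66 of the empirical (partly discrete) CAR
  distribution — a known, accepted gap of the generative model.
* **CoA case**: a 48-atom CoA moiety shared by thioesters; acyl
  elongation (CAR 0.94 → 0.48 after contraction) and full acyl exchange
  (0.96 → 0.33, i.e. below the 0.34 cutoff) plus a CoA-free analogue
  that the contraction flag must leave untouched.
* **Random graphs**: seeded Erdos-Renyi networks (≤ 25 nodes, uniform
  CARs) for oracle equivalence. Oracles are hand-written DFS path
  enumeration, BFS components/diameters and exact rational CAR
  evaluation — none share code with the implementation.

What the fixtures do **not** emulate: real molecule structures (atom
sets are abstract indices), reaction mechanism constraints, the heavy
tail of hub-metabolite degree distributions in genome-scale networks,
and the discreteness of empirical CAR values. Passing tests therefore
demonstrate algorithmic correctness and the intended ranking behavior,
not chemical validity of any particular route.

## Numerical choices and limitations

* Score ties detected at 1e-9; display rounding is two decimals,
  round-half-even, full precision in machine mode.
* Problem sizes in tests and the acceptance script (≤ 25-node graphs,
  100 + 50 oracle comparisons, 10^4-pair ROC samples) keep the whole
  suite in seconds while exercising every code path; they are
  desk-scale by design.
* The search enumerates simple paths globally; worst-case cost grows
  with k and with dense near-tie score plateaus. For genome-scale
  networks the unweighted two-sided mode on the thresholded graph is
  the fast alternative, at the cost of ignoring within-threshold CAR
  differences.
* Pairs with CAR = 0 never become edges, so routes requiring a
  zero-conservation step are invisible by construction.
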