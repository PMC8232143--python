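# Methods

This note records the model, the algorithmic conventions, and the design
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and score

A structure is a labelled DAG over the dataset's variables.  Fit is
measured by the multinomial BIC with natural logarithms: for each node,
the maximised multinomial log-likelihood of the child given its parent
configurations minus (ln N)/2 · (r − 1) · q, where q is the product of the
parent cardinalities (q = 1 for the empty set).  Conventions: 0·ln 0 = 0;
parent configurations never observed contribute nothing to the likelihood
but still count in q — the penalty prices the full parameter table, which
is the standard BIC reading and keeps the score score-equivalent across
Markov-equivalent DAGs (asserted in the tests).  The log base is a global
rescaling only.  Local scores are cached by (variable, sorted parent
tuple); the cache is unbounded, which is adequate at the problem sizes the
package targets (tens of variables, thousands of rows).

A maximum in-degree k is *not* enforced by default; when configured, the
hill climber refuses moves that would exceed it and random starts,
perturbations and Momentum kicks are projected back into the constrained
space by dropping excess in-edges (lexicographically last parents first —
a deterministic, score-agnostic projection).

## Acyclicity machinery

Whole edge sets are validated with Kahn's topological sort.  The search
loop instead asks "would this one edge close a cycle?" millions of times,
which is answered by an incremental DFS reachability query (path from the
head back to the tail).  Graphs carry both an adjacency view and the
from-list/to-list edge matrix the operators are defined on; the two are
consistent by construction.

## Operators

*Basic moves.*  An Add that would close a cycle inserts the edge in the
opposite orientation instead; a Reverse that would close a cycle is
dropped; Delete needs no repair.

*Leaf / Root.*  Reverse all outgoing (incoming) edges of the target node.
Both preserve acyclicity outright: a new cycle would have to pass through
the target, which has just lost all children (parents).  Applying either
to a node already in the target role is a no-op.

*Swap.*  Exactly one incoming edge of each of X and Y is exchanged
(P→X, Q→Y become P→Y, Q→X): two deletes and two adds, hence a minimum
structural effect of 4 SHD units.  When a node has several parents the
exchanged edge is drawn uniformly.  Candidate pairs are screened before
the move: P = Q (the exchange reproduces the same edges), P = Y or Q = X
(self-loop), an existing opposite edge (bidirectional pair), or an
existing identical edge (duplicate) disqualify a pair.  If the swapped
graph is cyclic, the repair applies Leaf to the from-node of a
cycle-generating new edge, preferring the swap's own additions in random
order, until the graph is acyclic; each Leaf removes every cycle through
its node and can create none (even on a transiently cyclic graph a
reversed edge cannot be left through a now-childless node), so the loop
terminates.  Cycles are repaired with Leaf rather than Root because the
maximum out-degree typically exceeds the maximum in-degree, so Leaf-based
repair explores a wider neighbourhood.

*Momentum.*  m iterations, each drawing a node uniformly with replacement
and an operator uniformly from {Leaf, Root, Swap}.  Draws that are
inapplicable (Leaf of a leaf, Root of a root, Swap with an empty
whitelist) are resampled up to 10 times, then the iteration is skipped;
the schedule needs no fallback beyond that because skips are rare on
non-degenerate graphs.

*Effect trials.*  Each trial applies the operator (or its multi-object
form `op(round(m))`) to a fresh copy of the reference network and measures
SHD against it.  Single-operator draws are resampled (bounded) until the
draw actually changes the structure — otherwise dropped reversals and
no-op Leaf/Root draws would deflate the minimum statistics that
characterise each operator (basic operators: always exactly 1; Swap: at
least 4).

## Search schedule

Hill climbing is best-improvement (steepest ascent) with ties broken
lexicographically by (kind, from, to), which makes every run fully
deterministic given the seed; improvements must exceed 1e-9 to count.

ILSG iterates perturb(pf basic moves) → hill climb → keep the better
graph, tracking the best graph ever seen; after `sr` non-improving
iterations it soft-restarts the working graph from a fresh random DAG
(patience defaults to 20).  Ties keep the incumbent.

ILSM wraps ILSG in an outer schedule with stride array {n/10, n/5, n/2, n}
(rounded, minimum 1): each outer iteration runs ILSG with the current
stride as its perturbation magnitude and a bounded inner budget (default
50 iterations) so the outer scheduling actually engages.  After `rs`
(default 20) non-improving outer iterations the incumbent takes a Momentum
kick of `mo` (default n) operations and the stride advances one position
(capped at the last entry) — the stride step is coupled to the Momentum
trigger, since both respond to the same stall signal and the stride exists
to strengthen the perturbation when the search is stuck.  After `rh`
(default 5) Momentum kicks without a new global best, the search restarts
from a random DAG and the stride and counters reset.  `rh` counts kicks
since the last global-best improvement.

Budgets: an outer-iteration cap (default 1000), an optional wall-clock
ceiling, and an optional cap on total move evaluations (`max_deltas`).
The evaluation cap exists so ILSM and the random-restart hill-climbing
baseline can be compared under *identical* move-evaluation budgets, which
is the only fair footing for a paired comparison; both drivers and plain
hill climbing honour it.  Reported best scores always equal a fresh
rescore of the returned graph.

Random initial graphs draw a uniform random topological order and include
each order-respecting pair independently with probability 2/(n−1)
(expected n edges, a typical benchmark sparsity); the distribution of the
initial graph is otherwise an open choice and this scheme samples only
valid DAGs with one interpretable knob.

## Evaluation metrics

SHD counts unordered pairs adjacent in exactly one graph plus pairs
adjacent in both with opposite orientation (a reversal is one unit).
BSF uses directed edge matching: TP are directed edges present in both
graphs, so a reversed edge contributes one FP and one FN, while TN counts
unordered pairs non-adjacent in both.  The two metrics deliberately differ
on reversals.  Under this convention BSF's exact lower bound is
−1 − a/(2i) rather than −1: a graph that reverses true edges while filling
every independent pair pushes FP above i.  The anchors BSF(truth) = 1 and
BSF(empty) = 0 are unaffected.

## Synthetic data

The simulator performs ancestral sampling in topological order, fully
vectorised over records.  Random CPTs draw each conditional row from a
symmetric Dirichlet whose concentration sets the dependence strength.  Two
refinements keep "low concentration" synonymous with *recoverable*
structure, which is what the knob is for: (1) rows for successive parent
configurations are sorted and rotated so their modal child state cycles
through the states — independently drawn skewed rows would land on the
same modal state about half the time (for binary nodes) and encode almost
no dependence; (2) parentless nodes use max(concentration, 1) so no
exogenous state is vanishingly rare and every parent configuration is
actually observed.  Without these, data generated at concentration 0.1
supports the true edge over the empty graph in well under half of seeds;
with them, essentially always (the property test requires ≥ 95/100).

The chest-clinic fixture ships the classic 8-node structure with this
package's own moderately strong binary CPTs — deliberately *not* the
published parameterization, so no numeric claim rests on values the
package does not contain.  What passing tests on simulated data do not
show: robustness to missing values, continuous or ordinal variables,
deterministic relationships, or the weak-and-conflicting dependencies of
real biological data; the simulator generates complete, faithful,
moderately strong multinomial data only.

BIF files use the bnlearn/JavaBayes grammar; the reader canonicalises
parent axes to sorted label order, validates that every conditional row
sums to one (tolerance 1e-6), rejects cyclic structures with a line
number, and warns about (rather than silently dropping) `property` lines.
Dataset CSVs map state labels to indices lexicographically, so round-trips
are stable.

## Problem sizes in the shipped experiments

The test suite and acceptance script run at desk scale: the 8-variable
fixture with 1000-record samples and move-evaluation budgets of 15,000 for
the paired ILSM vs. restart-HC comparison (10 seeds, identical budgets);
20 seeds on 3-variable data against the exhaustively enumerated global
optimum; operator-effect trials at 5n draws; and the acyclicity theorems
exhaustively on all labelled DAGs with up to 5 nodes at the object level
plus all 3,781,503 six-node DAGs through a vectorised adjacency-matrix
mirror of Leaf/Root that is itself cross-checked against the object
implementation on a random subsample.  These sizes were chosen so the full
suite completes in about a minute on one core while still covering every
structural claim exhaustively where enumeration is feasible.

## Known limitations

* Only complete discrete data; no missing-value handling, no continuous
  variables, and only the BIC score (no BDeu/MDL/AIC).
* Search is over DAG space directly; no equivalence-class (CPDAG) moves,
  no constraint-based pruning, and no exact solver.
* The score cache never evicts; very large parent-set churn on wide
  datasets would grow it without bound.
* SHD/BSF compare DAGs directly and will penalise Markov-equivalent
  reorientations that the score cannot distinguish.
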