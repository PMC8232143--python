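# ilsbn — Bayesian network structure learning by iterated local search

`ilsbn` learns the structure of a discrete Bayesian network — a directed
acyclic graph (DAG) G over categorical variables X₁…Xₙ whose joint
distribution factorises as P(X₁,…,Xₙ) = ∏ᵢ P(Xᵢ | Pa(Xᵢ)) — from complete
data, by score-based search. It is aimed at researchers in systems biology
and probabilistic modelling who want a self-contained, reproducible
score-and-search learner together with the simulation and evaluation
machinery needed to study it.

## The method

Candidate structures are scored with the decomposable BIC
(natural logarithms):

    BIC(G) = Σᵢ [ Σ_π Σ_x N(x,π) ln( N(x,π) / N(π) )
                  − (ln N)/2 · (rᵢ − 1) · qᵢ ]

where N(x,π) counts records with Xᵢ = x under parent configuration π, rᵢ is
the cardinality of Xᵢ and qᵢ the number of parent configurations.  Because
the score is a sum of per-node terms, an edge move is evaluated by rescoring
at most two nodes; local terms are memoised in a score cache.

Hill climbing over the Add/Delete/Reverse neighbourhood finds a local
optimum quickly but gets stuck.  `ilsbn` escapes local optima by iterated
local search over DAG space itself, using three compound perturbation
operators that are acyclicity-preserving by construction:

* **Leaf(X)** — reverse every outgoing edge of X (X becomes a leaf; no
  cycle can pass through a childless node).  Structural effect between 1
  and u units (u = max out-degree).
* **Root(X)** — reverse every incoming edge of X (X becomes a root).
  Effect between 1 and k units (k = max in-degree).
* **Swap(X, Y)** — exchange the to-nodes of one incoming edge of each of X
  and Y (two deletes + two adds); candidate partners are screened so the
  swap is never a no-op and never creates self-loops, duplicate edges or
  bidirectional pairs.  A swap that closes a cycle is repaired by applying
  Leaf to the from-node of the offending edge.  Effect between 4 and
  4 + 2u units.

The **Momentum** factor applies m random draws from {Leaf, Root, Swap} in
one kick.  The full search (`ilsm`) runs inner iterated local search with
basic-move perturbation (`ilsg`), and when the best score stalls, applies
Momentum, steps the perturbation stride along {n/10, n/5, n/2, n}, and
eventually restarts from a fresh random DAG.

Learned structures are evaluated against a ground truth with the structural
Hamming distance (SHD = missing + extra + wrongly oriented edges) and the
balanced scoring function BSF = ½(TP/a + TN/i − FP/i − FN/a), with a the
true edge count and i = V(V−1)/2 − a the number of independent pairs.

A discrete-network simulator (ancestral sampling, random Dirichlet CPTs,
BIF file I/O, a shipped 8-node chest-clinic fixture) makes every experiment
runnable offline.

## Worked example

Simulate 1000 records from the chest-clinic fixture, learn a structure with
ILSM, and compare it with the truth:

```sh
ilsbn simulate --fixture asia --n 1000 --seed 7 --out asia1000.csv
printf 'inner_budget: 5\nrs: 3\nrh: 2\nmax_deltas: 15000\n' > ilsm.yaml
ilsbn learn --data asia1000.csv --algo ilsm --config ilsm.yaml \
      --seed 1 --budget 200 --out learned.edgelist
ilsbn metrics --learned learned.edgelist --truth truth.edgelist
```

The learn step prints the best score found, `-3867.739503` — the BIC of the
learned DAG on the 1000 records (higher, i.e. less negative, is better).
The metrics step prints

```
TP      TN      FP      FN      SHD     BSF
6       20      2       2       2       0.7000
```

meaning the learned graph recovered the exact skeleton of the true 8-edge
network: six edges with the correct orientation, two reversed (each
reversal counts one SHD unit, and one FP plus one FN for BSF), and all 20
truly independent pairs left unconnected.  Reversals of this kind are
expected: BIC scores Markov-equivalent orientations identically, so the
data cannot prefer one of them.

The same functionality is available as a library:

```python
import numpy as np
from ilsbn import fixture_asia, sample_dataset, SearchConfig, ilsm, shd

bn = fixture_asia()
data = sample_dataset(bn, 1000, np.random.default_rng(7))
result = ilsm(data, SearchConfig(seed=1, budget=200, inner_budget=5,
                                 rs=3, rh=2, max_deltas=15000))
print(result.best_score, shd(result.best_dag, bn.dag))
```

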