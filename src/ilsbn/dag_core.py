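"""Directed acyclic graphs for structure search.

The DAG type used throughout the package stores a fixed node universe plus a
directed edge set, with the usual structure-learning invariants enforced at
construction: no self-loops, no duplicate edges, at most one orientation per
node pair, and acyclicity.  Besides an adjacency view (parent/child sets,
O(1) edge queries) every graph exposes the *edge matrix* — two parallel
lists, a from-list and a to-list — which is the representation the
perturbation operators in :mod:`ilsbn.operators` are defined on.

Acyclicity is checked two ways: a full Kahn-style topological sort when a
whole edge set is validated, and an incremental reachability query
(:meth:`DAG.would_create_cycle`) for the "may I add this one edge?" question
the search loop asks millions of times.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from typing import Optional

import numpy as np

__all__ = [
    "DAG",
    "MalformedStructureError",
    "CyclicStructureError",
    "is_acyclic",
    "max_in_degree",
    "max_out_degree",
    "leaf_nodes",
    "root_nodes",
    "random_dag",
    "shd_pair",
    "read_edgelist",
    "write_edgelist",
]

Edge = tuple[str, str]


class MalformedStructureError(ValueError):
    """An edge set referencing unknown nodes, self-loops or duplicates."""


class CyclicStructureError(MalformedStructureError):
    """A directed edge set that admits no topological order."""


def is_acyclic(edges: Iterable[Edge], node_labels: Sequence[str]) -> bool:
    """True iff ``edges`` over ``node_labels`` admits a topological order.

    Pure query (Kahn's algorithm); raises :class:`MalformedStructureError`
    for edges touching unknown labels or self-loops.
    """
    nodes = list(node_labels)
    known = set(nodes)
    indeg = {v: 0 for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        if u not in known or v not in known:
            raise MalformedStructureError(f"edge ({u!r}, {v!r}) references unknown node")
        if u == v:
            raise MalformedStructureError(f"self-loop on {u!r}")
        children[u].append(v)
        indeg[v] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for w in children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


class DAG:
    """A labelled directed acyclic graph with a fixed node universe."""

    __slots__ = ("_nodes", "_parents", "_children")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()):
        node_tuple = tuple(nodes)
        if len(set(node_tuple)) != len(node_tuple):
            raise MalformedStructureError("duplicate node labels")
        self._nodes = node_tuple
        self._parents: dict[str, set[str]] = {v: set() for v in node_tuple}
        self._children: dict[str, set[str]] = {v: set() for v in node_tuple}
        for u, v in edges:
            self._insert(u, v)
        if not is_acyclic(self.edges, self._nodes):
            raise CyclicStructureError("edge set contains a directed cycle")

    # -- construction helpers -------------------------------------------------

    def _insert(self, u: str, v: str) -> None:
        if u not in self._parents or v not in self._parents:
            raise MalformedStructureError(f"edge ({u!r}, {v!r}) references unknown node")
        if u == v:
            raise MalformedStructureError(f"self-loop on {u!r}")
        if v in self._children[u]:
            raise MalformedStructureError(f"duplicate edge {u!r}->{v!r}")
        if u in self._children[v]:
            raise MalformedStructureError(f"bidirectional pair {u!r}<->{v!r}")
        self._children[u].add(v)
        self._parents[v].add(u)

    def copy(self) -> "DAG":
        new = object.__new__(DAG)
        new._nodes = self._nodes
        new._parents = {v: set(s) for v, s in self._parents.items()}
        new._children = {v: set(s) for v, s in self._children.items()}
        return new

    # -- views ----------------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(
            (u, v) for u, cs in self._children.items() for v in cs
        )

    @property
    def n_edges(self) -> int:
        return sum(len(cs) for cs in self._children.values())

    def edge_list(self) -> list[Edge]:
        """Edges in deterministic (from, to) lexicographic order."""
        return sorted((u, v) for u, cs in self._children.items() for v in cs)

    @property
    def edge_matrix(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """The parallel from-list / to-list representation of the edge set."""
        es = self.edge_list()
        if not es:
            return ((), ())
        froms, tos = zip(*es)
        return (froms, tos)

    def parents(self, x: str) -> frozenset[str]:
        return frozenset(self._parents[x])

    def children(self, x: str) -> frozenset[str]:
        return frozenset(self._children[x])

    def in_degree(self, x: str) -> int:
        return len(self._parents[x])

    def out_degree(self, x: str) -> int:
        return len(self._children[x])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    def adjacent(self, u: str, v: str) -> bool:
        return self.has_edge(u, v) or self.has_edge(v, u)

    def has_node(self, x: str) -> bool:
        return x in self._parents

    # -- incremental acyclicity ----------------------------------------------

    def would_create_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v close a directed cycle?

        True iff a directed path v ~> u already exists (DFS from v).
        """
        if u == v:
            return True
        stack = [v]
        seen = {v}
        while stack:
            w = stack.pop()
            if w == u:
                return True
            for c in self._children[w]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def reverse_would_create_cycle(self, u: str, v: str) -> bool:
        """Would reversing the existing edge u -> v close a cycle?

        True iff a directed path u ~> v exists that does not use the edge
        itself.
        """
        if not self.has_edge(u, v):
            raise MalformedStructureError(f"no edge {u!r}->{v!r} to reverse")
        stack = [c for c in self._children[u] if c != v]
        seen = set(stack)
        while stack:
            w = stack.pop()
            if w == v:
                return True
            for c in self._children[w]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    # -- mutation (validated) -------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if self.adjacent(u, v):
            raise MalformedStructureError(f"{u!r} and {v!r} already adjacent")
        if self.would_create_cycle(u, v):
            raise CyclicStructureError(f"adding {u!r}->{v!r} creates a cycle")
        self._insert(u, v)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise MalformedStructureError(f"no edge {u!r}->{v!r}")
        self._children[u].remove(v)
        self._parents[v].remove(u)

    def reverse_edge(self, u: str, v: str) -> None:
        if self.reverse_would_create_cycle(u, v):
            raise CyclicStructureError(f"reversing {u!r}->{v!r} creates a cycle")
        self.remove_edge(u, v)
        self._insert(v, u)

    def topological_order(self) -> list[str]:
        """A topological order, lexicographic among simultaneously-ready nodes."""
        indeg = {v: len(self._parents[v]) for v in self._nodes}
        import heapq

        ready = [v for v in self._nodes if indeg[v] == 0]
        heapq.heapify(ready)
        order: list[str] = []
        while ready:
            u = heapq.heappop(ready)
            order.append(u)
            for w in sorted(self._children[u]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    heapq.heappush(ready, w)
        if len(order) != self.n:
            raise CyclicStructureError("graph is cyclic")
        return order

    # -- dunder ---------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DAG(n={self.n}, edges={self.edge_list()})"


# -- degree / role queries ----------------------------------------------------


def max_in_degree(dag: DAG) -> int:
    """Largest parent-set size over all nodes (k); 0 for an edgeless graph."""
    return max((dag.in_degree(v) for v in dag.nodes), default=0)


def max_out_degree(dag: DAG) -> int:
    """Largest child-set size over all nodes (u); 0 for an edgeless graph."""
    return max((dag.out_degree(v) for v in dag.nodes), default=0)


def leaf_nodes(dag: DAG) -> frozenset[str]:
    """Nodes with no children.  An isolated node is both leaf and root."""
    return frozenset(v for v in dag.nodes if dag.out_degree(v) == 0)


def root_nodes(dag: DAG) -> frozenset[str]:
    """Nodes with no parents."""
    return frozenset(v for v in dag.nodes if dag.in_degree(v) == 0)


# -- random generation --------------------------------------------------------


def random_dag(
    node_labels: Sequence[str],
    edge_probability: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> DAG:
    """Sample a random DAG: uniform topological order + Bernoulli forward edges.

    A uniform random permutation of the nodes is drawn as the topological
    order and each of the n(n-1)/2 order-respecting pairs is included
    independently with ``edge_probability``.  Every draw is acyclic by
    construction.  The default probability 2/(n-1) gives n expected edges,
    a typical sparsity for benchmark networks.
    """
    labels = list(node_labels)
    if not labels:
        raise MalformedStructureError("cannot build a DAG on an empty node set")
    if rng is None:
        rng = np.random.default_rng()
    n = len(labels)
    if edge_probability is None:
        edge_probability = 1.0 if n == 1 else min(1.0, 2.0 / (n - 1))
    if not 0.0 <= edge_probability <= 1.0:
        raise ValueError("edge_probability must lie in [0, 1]")
    order = [labels[i] for i in rng.permutation(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_probability:
                edges.append((order[i], order[j]))
    return DAG(labels, edges)


# -- structural Hamming distance ----------------------------------------------


def shd_pair(dag_a: DAG, dag_b: DAG) -> int:
    """Structural Hamming distance between two DAGs on the same node set.

    Counts unordered pairs adjacent in exactly one graph (missing/extra
    edges) plus pairs adjacent in both with opposite orientation (each
    reversal counts one).  Symmetric, zero iff the edge sets are equal.
    """
    if set(dag_a.nodes) != set(dag_b.nodes):
        raise MalformedStructureError("SHD requires identical node sets")
    ea = dag_a.edges
    eb = dag_b.edges
    dist = 0
    seen_pairs = set()
    for u, v in ea | eb:
        pair = frozenset((u, v))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        a_fwd, a_rev = (u, v) in ea, (v, u) in ea
        b_fwd, b_rev = (u, v) in eb, (v, u) in eb
        a_adj = a_fwd or a_rev
        b_adj = b_fwd or b_rev
        if a_adj != b_adj:
            dist += 1  # missing or extra
        elif a_adj and (a_fwd != b_fwd):
            dist += 1  # incorrectly oriented
    return dist


# -- plain-text edge-list I/O --------------------------------------------------
#
# Format: an optional header line "NODES: A,B,C" declaring the node universe
# (so isolated nodes survive a round-trip), then one "FROM<TAB>TO" pair per
# line; '#' starts a comment.


def write_edgelist(dag: DAG, path) -> None:
    lines = ["NODES: " + ",".join(dag.nodes)]
    lines += [f"{u}\t{v}" for u, v in dag.edge_list()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edgelist(path) -> DAG:
    nodes: Optional[list[str]] = None
    edges: list[Edge] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper().startswith("NODES:"):
                nodes = [s.strip() for s in line[len("NODES:"):].split(",") if s.strip()]
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise MalformedStructureError(f"malformed edge line: {raw!r}")
            edges.append((parts[0], parts[1]))
    if nodes is None:
        # fall back to the labels appearing in edges, in order of appearance
        nodes = list(dict.fromkeys(x for e in edges for x in e))
    return DAG(nodes, edges)
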