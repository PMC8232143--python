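"""The move algebra for DAG-space perturbation.

Basic moves (Add, Delete, Reverse) perturb one edge; if an Add would close a
cycle the edge is inserted in the opposite orientation, and a cycle-closing
Reverse is dropped.  On top of these sit three compound operators that act on
a node rather than an edge and preserve acyclicity by construction:

* **Leaf(X)** — reverse every outgoing edge of X, making X a leaf.  A cycle
  through X would need X to keep a child, so none can exist.
* **Root(X)** — the mirror image: reverse every incoming edge of X.
* **Swap(X, Y)** — exchange the to-nodes of one incoming edge of X and one of
  Y (two deletes + two adds).  A swap can close a cycle; repair applies Leaf
  to the from-node of each cycle-generating new edge until the graph is
  acyclic again.  Candidate partners are screened first: swaps that are
  no-ops (shared parent), create self-loops, bidirectional pairs or
  duplicate edges are never attempted.

**Momentum(m)** draws m random (node, operator) pairs from {Leaf, Root,
Swap} and applies them in sequence — the heavy perturbation used to escape
local optima.  `perturb` is its lightweight counterpart over the basic
moves.  `effect_trials` measures the structural impact (SHD against the
starting graph) of repeated applications of any operator, reproducing the
operator-effect experiment layout.

Every compound operator records the primitive edge operations it actually
performed in a :class:`Move` trail, and ``replay`` re-applies a trail to the
pre-state to reproduce the post-state exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dag_core import (
    DAG,
    MalformedStructureError,
    is_acyclic,
    leaf_nodes,
    root_nodes,
    shd_pair,
)

__all__ = [
    "Move",
    "replay",
    "apply_basic",
    "leaf_op",
    "leaf_move",
    "root_op",
    "root_move",
    "swap_candidates",
    "swap_pairs",
    "swap_op",
    "swap_move",
    "momentum",
    "perturb",
    "effect_trials",
    "parse_operator_spec",
]

#: retry budget for inapplicable random draws inside momentum/perturb/trials
MAX_RETRIES = 10

Primitive = tuple[str, str, str]  # ("add"|"delete"|"reverse", from, to)


@dataclass(frozen=True)
class Move:
    """A compound operation plus the primitive trail actually performed.

    ``trail`` lists ("add"|"delete"|"reverse", from, to) steps in execution
    order, including any cycle-repair reversals; replaying the trail on the
    pre-state reproduces the post-state exactly.
    """

    kind: str
    operands: tuple[str, ...]
    trail: tuple[Primitive, ...] = field(default_factory=tuple)


# -- raw (possibly transiently cyclic) edge structure --------------------------
#
# Swap repair passes through a cyclic intermediate, which the DAG type
# refuses to represent; the helpers below work on a plain children-set dict
# and validate a DAG only at the end.


def _raw_of(dag: DAG) -> dict[str, set[str]]:
    return {v: set(dag.children(v)) for v in dag.nodes}


def _raw_apply(raw: dict[str, set[str]], prim: Primitive) -> None:
    kind, u, v = prim
    if kind == "add":
        raw[u].add(v)
    elif kind == "delete":
        raw[u].discard(v)
    elif kind == "reverse":
        raw[u].discard(v)
        raw[v].add(u)
    else:  # pragma: no cover - internal
        raise ValueError(kind)


def _raw_find_cycle(raw: dict[str, set[str]]) -> Optional[list[tuple[str, str]]]:
    """Return the edge list of some directed cycle, or None if acyclic."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {v: WHITE for v in raw}
    parent: dict[str, str] = {}
    for start in sorted(raw):
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, iter]] = [(start, iter(sorted(raw[start])))]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if colour[child] == GREY:
                    # unwind the grey path child -> ... -> node, close with node->child
                    cycle = [(node, child)]
                    w = node
                    while w != child:
                        cycle.append((parent[w], w))
                        w = parent[w]
                    cycle.reverse()
                    return cycle
                if colour[child] == WHITE:
                    colour[child] = GREY
                    parent[child] = node
                    stack.append((child, iter(sorted(raw[child]))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return None


def _dag_from_raw(nodes: tuple[str, ...], raw: dict[str, set[str]]) -> DAG:
    return DAG(nodes, [(u, v) for u, cs in raw.items() for v in cs])


def replay(dag: DAG, move: Move) -> DAG:
    """Apply a recorded primitive trail to ``dag`` and return the result."""
    raw = _raw_of(dag)
    for prim in move.trail:
        _raw_apply(raw, prim)
    return _dag_from_raw(dag.nodes, raw)


# -- basic operators -----------------------------------------------------------


def apply_basic(
    dag: DAG,
    kind: str,
    edge: tuple[str, str],
    rng: Optional[np.random.Generator] = None,
) -> DAG:
    """One basic move with the cycle-repair conventions.

    Add X->Y closing a cycle inserts Y->X instead ("operate it in the
    opposite way"); a cycle-closing Reverse is dropped (state returned
    unchanged).  Adding over an existing adjacency raises, as does
    Delete/Reverse of a missing edge — resampling is the caller's job.
    """
    u, v = edge
    if u == v or not (dag.has_node(u) and dag.has_node(v)):
        raise MalformedStructureError(f"bad edge operand ({u!r}, {v!r})")
    out = dag.copy()
    if kind == "add":
        if dag.adjacent(u, v):
            raise MalformedStructureError(f"{u!r} and {v!r} already adjacent")
        if out.would_create_cycle(u, v):
            out.add_edge(v, u)
        else:
            out.add_edge(u, v)
        return out
    if kind == "delete":
        out.remove_edge(u, v)
        return out
    if kind == "reverse":
        if not dag.has_edge(u, v):
            raise MalformedStructureError(f"no edge {u!r}->{v!r} to reverse")
        if out.reverse_would_create_cycle(u, v):
            return out  # dropped
        out.reverse_edge(u, v)
        return out
    raise MalformedStructureError(f"unknown basic operator {kind!r}")


# -- Leaf / Root ---------------------------------------------------------------


def leaf_move(dag: DAG, x: str) -> Move:
    if not dag.has_node(x):
        raise MalformedStructureError(f"unknown node {x!r}")
    trail = tuple(("reverse", x, c) for c in sorted(dag.children(x)))
    return Move("leaf", (x,), trail)


def leaf_op(dag: DAG, x: str) -> DAG:
    """Reverse every outgoing edge of x, converting x into a leaf.

    Acyclicity-preserving: any new cycle would have to leave x, but x has no
    children afterwards.  A node that is already a leaf is returned
    unchanged.
    """
    return replay(dag, leaf_move(dag, x))


def root_move(dag: DAG, x: str) -> Move:
    if not dag.has_node(x):
        raise MalformedStructureError(f"unknown node {x!r}")
    trail = tuple(("reverse", p, x) for p in sorted(dag.parents(x)))
    return Move("root", (x,), trail)


def root_op(dag: DAG, x: str) -> DAG:
    """Reverse every incoming edge of x, converting x into a root."""
    return replay(dag, root_move(dag, x))


# -- Swap ----------------------------------------------------------------------


def swap_pairs(dag: DAG, x: str, y: str) -> list[tuple[str, str]]:
    """Legal (P, Q) parent pairs for exchanging P->x and Q->y into P->y, Q->x.

    A pair survives screening iff the swap is neither meaningless (P == Q:
    the exchange reproduces the same edges) nor illegal: self-loop (P == y
    or Q == x), bidirectional pair (y->P or x->Q present), or duplicate of
    an existing edge (P->y or Q->x present).
    """
    if x == y:
        return []
    pairs = []
    for p in sorted(dag.parents(x)):
        for q in sorted(dag.parents(y)):
            if p == q:
                continue  # shared parent: swap is a no-op
            if p == y or q == x:
                continue  # would create a self-loop
            if dag.has_edge(y, p) or dag.has_edge(x, q):
                continue  # would create a bidirectional pair
            if dag.has_edge(p, y) or dag.has_edge(q, x):
                continue  # would duplicate an existing edge
            pairs.append((p, q))
    return pairs


def swap_candidates(dag: DAG, x: str) -> list[str]:
    """Whitelist of partners y for Swap(x, y): nodes with >= 1 incoming edge
    admitting at least one legal parent pair.  Empty when x has no parents
    (Swap inapplicable)."""
    if not dag.has_node(x):
        raise MalformedStructureError(f"unknown node {x!r}")
    if dag.in_degree(x) == 0:
        return []
    return [
        y
        for y in sorted(dag.nodes)
        if y != x and dag.in_degree(y) > 0 and swap_pairs(dag, x, y)
    ]


def _leaf_raw(raw: dict[str, set[str]], v: str, trail: list[Primitive]) -> None:
    for c in sorted(raw[v]):
        prim = ("reverse", v, c)
        _raw_apply(raw, prim)
        trail.append(prim)


def swap_move(
    dag: DAG,
    x: str,
    y: str,
    rng: Optional[np.random.Generator] = None,
    pair: Optional[tuple[str, str]] = None,
) -> Move:
    """Construct the primitive trail of Swap(x, y) including cycle repair.

    The exchanged parent pair (P, Q) is drawn uniformly from the legal pairs
    unless ``pair`` pins it explicitly.
    """
    if rng is None:
        rng = np.random.default_rng()
    pairs = swap_pairs(dag, x, y)
    if not pairs:
        raise MalformedStructureError(f"Swap({x!r}, {y!r}) has no legal parent pair")
    if pair is not None:
        if tuple(pair) not in pairs:
            raise MalformedStructureError(f"parent pair {pair!r} is not legal for Swap({x!r}, {y!r})")
        p, q = pair
    else:
        p, q = pairs[int(rng.integers(len(pairs)))]
    trail: list[Primitive] = [
        ("delete", p, x),
        ("delete", q, y),
        ("add", p, y),
        ("add", q, x),
    ]
    raw = _raw_of(dag)
    for prim in trail:
        _raw_apply(raw, prim)
    # cycle repair: Leaf on the from-node of a cycle-generating new edge,
    # preferring the swap's own additions, until acyclic
    new_edges = [(p, y), (q, x)]
    if rng.random() < 0.5:
        new_edges.reverse()
    guard = 0
    while True:
        cycle = _raw_find_cycle(raw)
        if cycle is None:
            break
        cycle_edges = set(cycle)
        culprit = next((e for e in new_edges if e in cycle_edges), cycle[0])
        _leaf_raw(raw, culprit[0], trail)
        guard += 1
        if guard > dag.n + 4:  # pragma: no cover - safety net
            raise RuntimeError("swap cycle repair failed to terminate")
    return Move("swap", (x, y), tuple(trail))


def swap_op(
    dag: DAG,
    x: str,
    y: str,
    rng: Optional[np.random.Generator] = None,
    pair: Optional[tuple[str, str]] = None,
) -> DAG:
    """Exchange one incoming edge of x with one of y; repair cycles via Leaf.

    The exchanged parent pair is drawn uniformly from the legal pairs; the
    result is acyclic and differs from the input by at least 4 SHD units.
    """
    return replay(dag, swap_move(dag, x, y, rng, pair))


# -- compound random perturbation ---------------------------------------------

_MOMENTUM_OPS = ("leaf", "root", "swap")


def momentum(dag: DAG, m: int, rng: Optional[np.random.Generator] = None) -> DAG:
    """Apply m uniformly random draws from {Leaf, Root, Swap} on random nodes.

    Inapplicable draws (Leaf of a leaf, Root of a root, Swap with an empty
    whitelist) are resampled up to a bounded retry count, then the iteration
    is skipped.  The result is always acyclic.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    g = dag
    nodes = sorted(dag.nodes)
    for _ in range(m):
        for _attempt in range(MAX_RETRIES):
            op = _MOMENTUM_OPS[int(rng.integers(3))]
            node = nodes[int(rng.integers(len(nodes)))]
            if op == "leaf":
                if g.out_degree(node) == 0:
                    continue
                g = leaf_op(g, node)
            elif op == "root":
                if g.in_degree(node) == 0:
                    continue
                g = root_op(g, node)
            else:
                wl = swap_candidates(g, node)
                if not wl:
                    continue
                partner = wl[int(rng.integers(len(wl)))]
                g = swap_op(g, node, partner, rng)
            break
    return g


_BASIC_OPS = ("add", "delete", "reverse")


def _sample_basic(g: DAG, kind: str, rng: np.random.Generator) -> Optional[DAG]:
    """One effective random basic move of the given kind, or None if impossible."""
    nodes = sorted(g.nodes)
    if kind == "add":
        free = [
            (u, v)
            for i, u in enumerate(nodes)
            for v in nodes
            if u != v and not g.adjacent(u, v)
        ]
        # each unordered pair appears twice (both orientations); either works
        if not free:
            return None
        return apply_basic(g, "add", free[int(rng.integers(len(free)))], rng)
    edges = g.edge_list()
    if not edges:
        return None
    if kind == "delete":
        return apply_basic(g, "delete", edges[int(rng.integers(len(edges)))], rng)
    # reverse: a cycle-closing draw is a no-op; retry a few times for effect
    for _ in range(MAX_RETRIES):
        e = edges[int(rng.integers(len(edges)))]
        out = apply_basic(g, "reverse", e, rng)
        if out.edges != g.edges:
            return out
    return None


def perturb(dag: DAG, pf: int, rng: Optional[np.random.Generator] = None) -> DAG:
    """Apply pf uniformly random basic moves with the repair conventions."""
    if pf < 0:
        raise ValueError("pf must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    g = dag
    for _ in range(pf):
        for _attempt in range(MAX_RETRIES):
            kind = _BASIC_OPS[int(rng.integers(3))]
            out = _sample_basic(g, kind, rng)
            if out is not None:
                g = out
                break
    return g


# -- operator-effect experiment harness ---------------------------------------


def parse_operator_spec(spec: str, n: int) -> tuple[str, int]:
    """Parse "leaf", "swap(n/2)", "momentum(2*n)" ... into (kind, count).

    The count expression may use the literal ``n`` (number of nodes) with
    +-*/ arithmetic; non-integers are rounded half away from zero as in
    ``round()`` of the experiment description.  A bare operator name means a
    single application.
    """
    s = spec.strip().lower()
    if "(" in s:
        name, _, rest = s.partition("(")
        expr = rest.rstrip(")").strip()
        allowed = set("0123456789n+-*/. ()")
        if not expr or set(expr) - allowed:
            raise ValueError(f"bad operator spec {spec!r}")
        count = eval(expr, {"__builtins__": {}}, {"n": n})  # arithmetic only
        count = int(math.floor(count + 0.5))
    else:
        name, count = s, 1
    if name not in ("add", "delete", "reverse", "leaf", "root", "swap", "momentum"):
        raise ValueError(f"unknown operator {name!r}")
    if count < 1:
        raise ValueError("operator count must be >= 1")
    return name, count


def _apply_spec(g: DAG, kind: str, m: int, rng: np.random.Generator) -> DAG:
    if kind == "momentum":
        return momentum(g, m, rng)
    for _ in range(m):
        for _attempt in range(MAX_RETRIES):
            if kind in _BASIC_OPS:
                out = _sample_basic(g, kind, rng)
            elif kind == "leaf":
                pool = sorted(set(g.nodes) - leaf_nodes(g))
                out = leaf_op(g, pool[int(rng.integers(len(pool)))]) if pool else None
            elif kind == "root":
                pool = sorted(set(g.nodes) - root_nodes(g))
                out = root_op(g, pool[int(rng.integers(len(pool)))]) if pool else None
            elif kind == "swap":
                xs = [v for v in sorted(g.nodes) if swap_candidates(g, v)]
                if xs:
                    x = xs[int(rng.integers(len(xs)))]
                    wl = swap_candidates(g, x)
                    out = swap_op(g, x, wl[int(rng.integers(len(wl)))], rng)
                else:
                    out = None
            else:  # pragma: no cover
                raise ValueError(kind)
            if out is not None:
                g = out
                break
    return g


def effect_trials(
    true_dag: DAG,
    operator_spec: str | tuple[str, int],
    trials: int,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Structural impact of an operator: SHD statistics over repeated trials.

    Each trial applies ``operator_spec`` — a single operator such as
    ``"leaf"`` or a multi-object form such as ``"swap(n/2)"`` — to a fresh
    copy of ``true_dag`` and measures SHD against it.  Returns
    ``{"max", "min", "mean"}`` over the trials.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(operator_spec, str):
        kind, m = parse_operator_spec(operator_spec, true_dag.n)
    else:
        kind, m = operator_spec
    shds = []
    for _ in range(trials):
        g = _apply_spec(true_dag, kind, m, rng)
        shds.append(shd_pair(true_dag, g))
    arr = np.asarray(shds, dtype=float)
    return {"max": float(arr.max()), "min": float(arr.min()), "mean": float(arr.mean())}
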