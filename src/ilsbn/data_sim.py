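"""Discrete Bayesian networks: CPTs, ancestral sampling, BIF I/O, fixtures.

A :class:`BayesianNetwork` couples a DAG with one conditional probability
table per node, the joint factorising as P(X1..Xn) = prod_i P(Xi | Pa_i).
Datasets are generated by ancestral sampling: nodes are visited in
topological order and each is drawn from its CPT row given its already
sampled parents.  CPT parent axes follow the lexicographically sorted
parent labels; state labels map to indices lexicographically so CSV
round-trips are stable.

The module also reads and writes the plain-text BIF (Bayesian Interchange
Format) dialect used by the bnlearn repository and JavaBayes
(network/variable/probability blocks), so externally published benchmark
networks can be used when available.  The shipped Asia-structure fixture
makes every test self-contained: its graph is the classic 8-node chest
clinic network, but its CPT values are this package's own synthetic
parameterization, not the published ones.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dag_core import DAG, MalformedStructureError
from .scoring import DiscreteDataset

__all__ = [
    "BayesianNetwork",
    "sample_dataset",
    "random_cpts",
    "fixture_asia",
    "read_bif",
    "write_bif",
    "BIFParseError",
]

_SUM_TOL = 1e-6


class BIFParseError(ValueError):
    """Malformed BIF text; message carries the offending line number."""


@dataclass
class BayesianNetwork:
    """A DAG plus per-node CPTs over lexicographically sorted parent axes.

    ``cpts[x]`` has shape ``(*cards_of_sorted_parents, card_x)``; every
    conditional distribution (last axis) sums to one.
    """

    dag: DAG
    cardinalities: dict[str, int]
    cpts: dict[str, np.ndarray]
    state_names: dict[str, tuple[str, ...]]
    name: str = "network"

    def __post_init__(self):
        for x in self.dag.nodes:
            r = self.cardinalities[x]
            if r < 2:
                raise ValueError(f"node {x!r} needs >= 2 states")
            if len(self.state_names[x]) != r:
                raise ValueError(f"state names of {x!r} inconsistent with cardinality")
            parents = self.sorted_parents(x)
            expect = tuple(self.cardinalities[p] for p in parents) + (r,)
            cpt = np.asarray(self.cpts[x], dtype=np.float64)
            if cpt.shape != expect:
                raise ValueError(
                    f"CPT of {x!r} has shape {cpt.shape}, expected {expect}"
                )
            rows = cpt.reshape(-1, r)
            if (rows < -1e-12).any():
                raise ValueError(f"negative probability in CPT of {x!r}")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {x!r} do not sum to 1")
            self.cpts[x] = cpt

    def sorted_parents(self, x: str) -> tuple[str, ...]:
        return tuple(sorted(self.dag.parents(x)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BayesianNetwork):
            return NotImplemented
        if self.dag != other.dag or self.cardinalities != other.cardinalities:
            return False
        if self.state_names != other.state_names:
            return False
        return all(
            np.allclose(self.cpts[x], other.cpts[x], atol=1e-9)
            for x in self.dag.nodes
        )


def sample_dataset(
    bn: BayesianNetwork, n_records: int, rng: Optional[np.random.Generator] = None
) -> DiscreteDataset:
    """Ancestral sampling: draw each node given its sampled parents.

    Vectorised over records; reproducible for a fixed generator state.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    labels = bn.dag.nodes
    col = {v: j for j, v in enumerate(labels)}
    cards = [bn.cardinalities[v] for v in labels]
    data = np.zeros((n_records, len(labels)), dtype=np.int64)
    for x in bn.dag.topological_order():
        parents = bn.sorted_parents(x)
        r = bn.cardinalities[x]
        flat = bn.cpts[x].reshape(-1, r)
        cfg = np.zeros(n_records, dtype=np.int64)
        for p in parents:
            cfg = cfg * bn.cardinalities[p] + data[:, col[p]]
        probs = flat[cfg]  # (N, r)
        u = rng.random(n_records)
        draws = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        data[:, col[x]] = np.minimum(draws, r - 1)
    return DiscreteDataset(
        labels, cards, data, [bn.state_names[v] for v in labels]
    )


def random_cpts(
    dag: DAG,
    cardinalities: dict[str, int],
    concentration: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> BayesianNetwork:
    """Equip a DAG with random CPTs whose skew is set by ``concentration``.

    Each conditional row is a symmetric-Dirichlet(``concentration``) draw;
    low concentration (< 1) gives near-deterministic rows, large values
    approach uniform rows (vanishing dependence).  Two refinements keep low
    concentration synonymous with *recoverable* structure: rows for
    successive parent configurations are re-anchored (sorted, then rotated)
    so their modal child state cycles through the states — otherwise
    independent skewed rows land on the same state about half the time and
    encode almost no dependence — and parentless nodes use
    ``max(concentration, 1)`` so no exogenous state is vanishingly rare.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    cpts: dict[str, np.ndarray] = {}
    states = {}
    for x in dag.nodes:
        r = cardinalities[x]
        parents = tuple(sorted(dag.parents(x)))
        if not parents:
            rows = rng.dirichlet([max(concentration, 1.0)] * r, size=1)
        else:
            q = int(np.prod([cardinalities[p] for p in parents]))
            rows = rng.dirichlet([concentration] * r, size=q)
            rows = -np.sort(-rows, axis=1)  # descending: peak on state 0
            rows = np.stack([np.roll(rows[c], c % r) for c in range(q)])
        shape = tuple(cardinalities[p] for p in parents) + (r,)
        cpts[x] = rows.reshape(shape)
        states[x] = tuple(f"s{i}" for i in range(r))
    return BayesianNetwork(dag.copy(), dict(cardinalities), cpts, states)


def fixture_asia() -> BayesianNetwork:
    """The 8-node chest-clinic ("Asia") structure with synthetic CPTs.

    Structure: A->T, S->L, S->B, T->E, L->E, E->X, E->D, B->D (8 nodes,
    8 edges, max in- and out-degree 2).  The CPT values are this package's
    own moderately strong binary conditionals — NOT the published Asia
    parameters — chosen so the structure is recoverable from a few hundred
    records.
    """
    nodes = ("A", "S", "T", "L", "B", "E", "X", "D")
    edges = [
        ("A", "T"),
        ("S", "L"),
        ("S", "B"),
        ("T", "E"),
        ("L", "E"),
        ("E", "X"),
        ("E", "D"),
        ("B", "D"),
    ]
    dag = DAG(nodes, edges)
    cards = {v: 2 for v in nodes}
    # index 0 = "no", 1 = "yes" (lexicographic)
    yes = lambda p: np.array([1.0 - p, p])

    def table(parent_probs):  # rows in mixed-radix parent order
        return np.array([[1.0 - p, p] for p in parent_probs])

    cpts = {
        "A": yes(0.30),
        "S": yes(0.50),
        # T | A: rows A=no, A=yes
        "T": table([0.10, 0.70]),
        # L | S
        "L": table([0.10, 0.60]),
        # B | S
        "B": table([0.20, 0.70]),
        # E | (L, T): rows (no,no), (no,yes), (yes,no), (yes,yes)
        "E": table([0.05, 0.90, 0.85, 0.97]).reshape(2, 2, 2),
        # X | E
        "X": table([0.08, 0.90]),
        # D | (B, E): rows (no,no), (no,yes), (yes,no), (yes,yes)
        "D": table([0.10, 0.75, 0.30, 0.92]).reshape(2, 2, 2),
    }
    states = {v: ("no", "yes") for v in nodes}
    return BayesianNetwork(dag, cards, cpts, states, name="asia")


# -- BIF reading / writing -----------------------------------------------------

_TOKEN = re.compile(r"//[^\n]*|[A-Za-z0-9_.\-]+|[{}()|,;\[\]]|\"[^\"]*\"")


def _tokenize(text: str) -> list[tuple[str, int]]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for m in _TOKEN.finditer(line):
            tok = m.group(0)
            if tok.startswith("//"):
                break
            out.append((tok, lineno))
    return out


class _TokenStream:
    def __init__(self, tokens):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self):
        if self.pos >= len(self.tokens):
            raise BIFParseError("unexpected end of file")
        tok, self.lineno = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, want):
        tok = self.next()
        if tok != want:
            raise BIFParseError(f"line {self.lineno}: expected {want!r}, got {tok!r}")
        return tok

    def skip_block(self):
        """Consume a balanced { ... } block, returning its raw tokens."""
        self.expect("{")
        depth = 1
        raw = []
        while depth:
            tok = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1
                if depth == 0:
                    break
            raw.append(tok)
        return raw


def read_bif(path) -> BayesianNetwork:
    """Parse a BIF file into a :class:`BayesianNetwork`.

    Accepts the bnlearn/JavaBayes grammar (network / variable / probability
    blocks, whitespace-insensitive).  CPT rows are validated to sum to one;
    cyclic structures and malformed blocks raise with a line number.
    Unknown ``property`` lines are warned about, never silently dropped.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    ts = _TokenStream(_tokenize(text))
    if ts.peek() is None:
        raise BIFParseError("empty BIF file")
    name = "network"
    states: dict[str, tuple[str, ...]] = {}
    tables: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}  # node -> (parents, rows)
    while ts.peek() is not None:
        kw = ts.next()
        if kw == "network":
            name = ts.next()
            ts.skip_block()
        elif kw == "variable":
            var = ts.next()
            ts.expect("{")
            while ts.peek() != "}":
                tok = ts.next()
                if tok == "type":
                    ts.expect("discrete")
                    ts.expect("[")
                    card = int(ts.next())
                    ts.expect("]")
                    ts.expect("{")
                    vals = []
                    while ts.peek() != "}":
                        t = ts.next()
                        if t != ",":
                            vals.append(t.strip('"'))
                    ts.expect("}")
                    ts.expect(";")
                    if len(vals) != card:
                        raise BIFParseError(
                            f"line {ts.lineno}: variable {var!r} declares {card} "
                            f"states but lists {len(vals)}"
                        )
                    states[var] = tuple(vals)
                elif tok == "property":
                    prop = []
                    while ts.peek() != ";":
                        prop.append(ts.next())
                    ts.next()
                    warnings.warn(
                        f"BIF property on variable {var!r} ignored: {' '.join(prop)}"
                    )
                else:
                    raise BIFParseError(f"line {ts.lineno}: unexpected token {tok!r}")
            ts.expect("}")
        elif kw == "probability":
            ts.expect("(")
            child = ts.next()
            parents: list[str] = []
            if ts.peek() == "|":
                ts.next()
                while ts.peek() != ")":
                    t = ts.next()
                    if t != ",":
                        parents.append(t)
            ts.expect(")")
            if child not in states:
                raise BIFParseError(f"line {ts.lineno}: undeclared variable {child!r}")
            for p in parents:
                if p not in states:
                    raise BIFParseError(f"line {ts.lineno}: undeclared parent {p!r}")
            r = len(states[child])
            q = int(np.prod([len(states[p]) for p in parents])) if parents else 1
            rows = np.full((q, r), np.nan)
            ts.expect("{")
            while ts.peek() != "}":
                tok = ts.next()
                if tok == "table":
                    vals = []
                    while ts.peek() != ";":
                        t = ts.next()
                        if t != ",":
                            vals.append(float(t))
                    ts.next()
                    if len(vals) != q * r:
                        raise BIFParseError(
                            f"line {ts.lineno}: table for {child!r} has {len(vals)} "
                            f"entries, expected {q * r}"
                        )
                    rows = np.asarray(vals).reshape(q, r)
                elif tok == "(":
                    cfg_states = []
                    while ts.peek() != ")":
                        t = ts.next()
                        if t != ",":
                            cfg_states.append(t.strip('"'))
                    ts.next()
                    if len(cfg_states) != len(parents):
                        raise BIFParseError(
                            f"line {ts.lineno}: row for {child!r} names "
                            f"{len(cfg_states)} parent states, expected {len(parents)}"
                        )
                    idx = 0
                    for p, s in zip(parents, cfg_states):
                        try:
                            k = states[p].index(s)
                        except ValueError:
                            raise BIFParseError(
                                f"line {ts.lineno}: unknown state {s!r} of {p!r}"
                            ) from None
                        idx = idx * len(states[p]) + k
                    vals = []
                    while ts.peek() != ";":
                        t = ts.next()
                        if t != ",":
                            vals.append(float(t))
                    ts.next()
                    if len(vals) != r:
                        raise BIFParseError(
                            f"line {ts.lineno}: row for {child!r} has {len(vals)} "
                            f"probabilities, expected {r}"
                        )
                    rows[idx] = vals
                elif tok == "property":
                    prop = []
                    while ts.peek() != ";":
                        prop.append(ts.next())
                    ts.next()
                    warnings.warn(f"BIF property in probability block ignored: {' '.join(prop)}")
                else:
                    raise BIFParseError(f"line {ts.lineno}: unexpected token {tok!r}")
            ts.expect("}")
            if np.isnan(rows).any():
                raise BIFParseError(f"incomplete probability table for {child!r}")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=_SUM_TOL):
                raise BIFParseError(
                    f"probability rows of {child!r} do not sum to 1"
                )
            tables[child] = (tuple(parents), rows)
        else:
            raise BIFParseError(f"line {ts.lineno}: unexpected keyword {kw!r}")
    missing = set(states) - set(tables)
    if missing:
        raise BIFParseError(f"no probability block for {sorted(missing)}")
    edges = [(p, x) for x, (ps, _) in tables.items() for p in ps]
    try:
        dag = DAG(tuple(states), edges)
    except MalformedStructureError as err:  # cyclic, bidirectional, duplicate
        raise BIFParseError(f"invalid structure in file: {err}") from err
    # permute each table's parent axes into sorted-label order
    cpts = {}
    for x, (parents, rows) in tables.items():
        r = len(states[x])
        shape = tuple(len(states[p]) for p in parents) + (r,)
        arr = rows.reshape(shape)
        order = sorted(range(len(parents)), key=lambda k: parents[k])
        arr = np.transpose(arr, axes=tuple(order) + (len(parents),))
        cpts[x] = np.ascontiguousarray(arr)
    cards = {v: len(states[v]) for v in states}
    return BayesianNetwork(dag, cards, cpts, dict(states), name=name)


def write_bif(bn: BayesianNetwork, path) -> None:
    """Serialise a network in BIF; round-trips through :func:`read_bif`."""
    lines = [f"network {bn.name} {{", "}"]
    for x in bn.dag.nodes:
        vals = ", ".join(bn.state_names[x])
        lines += [
            f"variable {x} {{",
            f"  type discrete [ {bn.cardinalities[x]} ] {{ {vals} }};",
            "}",
        ]
    for x in bn.dag.nodes:
        parents = bn.sorted_parents(x)
        r = bn.cardinalities[x]
        flat = bn.cpts[x].reshape(-1, r)
        if not parents:
            row = ", ".join(repr(float(v)) for v in flat[0])
            lines += [f"probability ( {x} ) {{", f"  table {row};", "}"]
        else:
            head = ", ".join(parents)
            lines.append(f"probability ( {x} | {head} ) {{")
            radices = [bn.cardinalities[p] for p in parents]
            for idx in range(flat.shape[0]):
                rem, cfg = idx, []
                for rad in reversed(radices):
                    cfg.append(rem % rad)
                    rem //= rad
                cfg.reverse()
                names = ", ".join(
                    bn.state_names[p][k] for p, k in zip(parents, cfg)
                )
                row = ", ".join(repr(float(v)) for v in flat[idx])
                lines.append(f"  ({names}) {row};")
            lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
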