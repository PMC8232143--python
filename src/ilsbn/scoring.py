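"""Decomposable BIC scoring of candidate structures against discrete data.

The score of a DAG factorises over nodes: each variable contributes a local
term depending only on its own parent set,

    local(X, Pa) = sum_pi sum_x N(x, pi) * ln( N(x, pi) / N(pi) )
                   - (ln N)/2 * (r_X - 1) * q_Pa,

where N(x, pi) are joint counts of the child state with the parent
configuration, r_X is the child's cardinality and q_Pa the product of parent
cardinalities (1 for the empty set).  Natural logarithms throughout; zero
counts contribute nothing (0 ln 0 = 0).  The global BIC is the sum of local
terms, which lets a search evaluate an edge move by rescoring at most two
nodes (`score_delta`).  Local terms are memoised in a
:class:`LocalScoreCache` keyed by (variable, sorted parent tuple).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .dag_core import DAG, MalformedStructureError

__all__ = [
    "DiscreteDataset",
    "LocalScoreCache",
    "count_table",
    "local_bic",
    "bic",
    "score_delta",
    "Move",
]

#: An edge move as (kind, from, to) with kind in {"add", "delete", "reverse"}.
Move = tuple[str, str, str]


class DiscreteDataset:
    """N complete records over n categorical variables with known cardinalities.

    ``data`` holds state indices (row-major, one column per variable); state
    labels are mapped to indices lexicographically so CSV round-trips are
    stable.
    """

    __slots__ = ("labels", "cardinalities", "data", "state_names", "_col")

    def __init__(
        self,
        labels: Sequence[str],
        cardinalities: Sequence[int],
        data: np.ndarray,
        state_names: Optional[Sequence[Sequence[str]]] = None,
    ):
        self.labels = tuple(labels)
        self.cardinalities = tuple(int(c) for c in cardinalities)
        arr = np.ascontiguousarray(data, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != len(self.labels):
            raise ValueError("data must be an (N, n) array of state indices")
        if arr.shape[0] < 1:
            raise ValueError("dataset must contain at least one record")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate variable labels")
        for j, r in enumerate(self.cardinalities):
            if r < 2:
                raise ValueError(f"variable {self.labels[j]!r} needs >= 2 states")
        if (arr < 0).any():
            raise ValueError("negative state index (missing values are not supported)")
        if (arr >= np.asarray(self.cardinalities)).any():
            raise ValueError("state index exceeds declared cardinality")
        self.data = arr
        if state_names is None:
            state_names = tuple(
                tuple(f"s{i}" for i in range(r)) for r in self.cardinalities
            )
        self.state_names = tuple(tuple(s) for s in state_names)
        for names, r in zip(self.state_names, self.cardinalities):
            if len(names) != r:
                raise ValueError("state_names inconsistent with cardinalities")
        self._col = {v: j for j, v in enumerate(self.labels)}

    @property
    def n_records(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return len(self.labels)

    def column(self, variable: str) -> np.ndarray:
        try:
            return self.data[:, self._col[variable]]
        except KeyError:
            raise MalformedStructureError(f"unknown variable {variable!r}") from None

    def cardinality(self, variable: str) -> int:
        try:
            return self.cardinalities[self._col[variable]]
        except KeyError:
            raise MalformedStructureError(f"unknown variable {variable!r}") from None

    # -- pandas / CSV interop -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DiscreteDataset":
        """Build from a label-valued frame; states indexed lexicographically."""
        labels = [str(c) for c in df.columns]
        cols = []
        cards = []
        states = []
        for c in df.columns:
            vals = df[c].astype(str)
            uniq = sorted(vals.unique())
            if len(uniq) < 2:
                raise ValueError(
                    f"column {c!r} has a single observed state; "
                    "discrete scoring needs >= 2"
                )
            lut = {s: i for i, s in enumerate(uniq)}
            cols.append(vals.map(lut).to_numpy(dtype=np.int64))
            cards.append(len(uniq))
            states.append(tuple(uniq))
        return cls(labels, cards, np.column_stack(cols), states)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            v: pd.Categorical.from_codes(
                self.data[:, j], categories=list(self.state_names[j])
            ).astype(str)
            for j, v in enumerate(self.labels)
        }
        return pd.DataFrame(cols, columns=list(self.labels))

    @classmethod
    def read_csv(cls, path) -> "DiscreteDataset":
        return cls.from_dataframe(pd.read_csv(path, dtype=str))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class LocalScoreCache:
    """Memoised (variable, sorted parent tuple) -> local BIC map."""

    __slots__ = ("_store", "hits", "misses")

    def __init__(self):
        self._store: dict[tuple[str, tuple[str, ...]], float] = {}
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._store)

    def lookup(self, variable: str, parents: tuple[str, ...]) -> Optional[float]:
        val = self._store.get((variable, parents))
        if val is None:
            self.misses += 1
        else:
            self.hits += 1
        return val

    def store(self, variable: str, parents: tuple[str, ...], value: float) -> None:
        self._store[(variable, parents)] = value


def count_table(
    dataset: DiscreteDataset, variable: str, parent_set: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Joint counts N(x, pi) and parent-configuration counts N(pi).

    Returns ``(counts, parent_counts)`` with ``counts`` shaped (q, r) — one
    row per parent configuration in mixed-radix order over the
    lexicographically sorted parent list — and ``parent_counts`` its row
    sums.  The grand total equals N.
    """
    parents = tuple(sorted(set(parent_set)))
    if variable in parents:
        raise MalformedStructureError(f"{variable!r} cannot be its own parent")
    x = dataset.column(variable)
    r = dataset.cardinality(variable)
    q = 1
    cfg = np.zeros(dataset.n_records, dtype=np.int64)
    for p in parents:
        rp = dataset.cardinality(p)
        cfg = cfg * rp + dataset.column(p)
        q *= rp
    flat = np.bincount(cfg * r + x, minlength=q * r)
    counts = flat.reshape(q, r)
    return counts, counts.sum(axis=1)


def _local_bic_from_counts(counts: np.ndarray, parent_counts: np.ndarray, n_records: int, r: int) -> float:
    q = counts.shape[0]
    nz = counts > 0
    c = counts[nz].astype(np.float64)
    npi = np.repeat(parent_counts.astype(np.float64), counts.shape[1]).reshape(counts.shape)[nz]
    loglik = float(np.sum(c * (np.log(c) - np.log(npi))))
    penalty = 0.5 * math.log(n_records) * (r - 1) * q
    return loglik - penalty


def local_bic(
    variable: str,
    parent_set: Iterable[str],
    dataset: DiscreteDataset,
    cache: Optional[LocalScoreCache] = None,
) -> float:
    """Local BIC of one variable given a parent set (natural log).

    Parent configurations with zero support contribute nothing to the
    likelihood but still count toward the parameter penalty, which uses
    q = product of parent cardinalities (all configurations, observed or
    not; q = 1 for the empty set).
    """
    parents = tuple(sorted(set(parent_set)))
    if cache is not None:
        hit = cache.lookup(variable, parents)
        if hit is not None:
            return hit
    counts, parent_counts = count_table(dataset, variable, parents)
    value = _local_bic_from_counts(
        counts, parent_counts, dataset.n_records, dataset.cardinality(variable)
    )
    if cache is not None:
        cache.store(variable, parents, value)
    return value


def bic(
    dag: DAG,
    dataset: DiscreteDataset,
    cache: Optional[LocalScoreCache] = None,
) -> float:
    """Global BIC: sum of local scores of every node with its parent set."""
    unknown = set(dag.nodes) - set(dataset.labels)
    if unknown:
        raise MalformedStructureError(f"variables missing from dataset: {sorted(unknown)}")
    return sum(local_bic(v, dag.parents(v), dataset, cache) for v in dag.nodes)


def score_delta(
    dag: DAG,
    move: Move,
    dataset: DiscreteDataset,
    cache: Optional[LocalScoreCache] = None,
) -> float:
    """Exact BIC change of a single edge move, touching only affected nodes.

    Add/Delete rescore the to-node; Reverse rescores both endpoints.  The
    move must be legal on ``dag`` (including acyclicity for add/reverse);
    otherwise :class:`MalformedStructureError` is raised.
    """
    kind, u, v = move
    if not (dag.has_node(u) and dag.has_node(v)):
        raise MalformedStructureError(f"unknown node in move {move!r}")
    if kind == "add":
        if dag.adjacent(u, v):
            raise MalformedStructureError(f"cannot add {u!r}->{v!r}: already adjacent")
        if dag.would_create_cycle(u, v):
            raise MalformedStructureError(f"adding {u!r}->{v!r} creates a cycle")
        pv = dag.parents(v)
        return local_bic(v, pv | {u}, dataset, cache) - local_bic(v, pv, dataset, cache)
    if kind == "delete":
        if not dag.has_edge(u, v):
            raise MalformedStructureError(f"cannot delete missing edge {u!r}->{v!r}")
        pv = dag.parents(v)
        return local_bic(v, pv - {u}, dataset, cache) - local_bic(v, pv, dataset, cache)
    if kind == "reverse":
        if not dag.has_edge(u, v):
            raise MalformedStructureError(f"cannot reverse missing edge {u!r}->{v!r}")
        if dag.reverse_would_create_cycle(u, v):
            raise MalformedStructureError(f"reversing {u!r}->{v!r} creates a cycle")
        pv = dag.parents(v)
        pu = dag.parents(u)
        return (
            local_bic(v, pv - {u}, dataset, cache)
            - local_bic(v, pv, dataset, cache)
            + local_bic(u, pu | {v}, dataset, cache)
            - local_bic(u, pu, dataset, cache)
        )
    raise MalformedStructureError(f"unknown move kind {kind!r}")
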