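"""Hill climbing and iterated local search over DAG space.

Three search drivers share one move-evaluation machinery:

* :func:`hill_climb` — best-improvement steepest ascent over the
  Add/Delete/Reverse neighbourhood, scored by exact BIC deltas.
* :func:`ilsg` — iterated local search: perturb the incumbent with ``pf``
  random basic moves, re-optimise, keep the better graph; soft-restart from
  a random DAG after ``sr`` non-improving iterations while tracking the best
  graph ever seen.
* :func:`ilsm` — ILSG wrapped in an outer schedule: when the best score
  stalls for ``rs`` outer iterations the Momentum factor (``mo`` random
  Leaf/Root/Swap applications) kicks the incumbent and the perturbation
  stride advances one step along ``{n/10, n/5, n/2, n}``; after ``rh``
  Momentum kicks without a new best, the search restarts from a fresh
  random DAG and the stride resets.

:func:`restart_hill_climb` is the classic random-restart HC baseline.  All
drivers honour a shared move-evaluation budget (``max_deltas``) so paired
comparisons can grant each algorithm exactly the same number of score-delta
evaluations, plus an iteration budget and an optional wall-clock ceiling.
Runs are deterministic given (dataset, config): one seeded generator drives
every random choice and ties among equally good moves break
lexicographically.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .dag_core import DAG, random_dag
from .operators import momentum, perturb
from .scoring import DiscreteDataset, LocalScoreCache, Move, bic, score_delta

__all__ = [
    "SearchConfig",
    "SearchResult",
    "TraceRecord",
    "hill_climb",
    "ilsg",
    "ilsm",
    "restart_hill_climb",
]

#: score improvements below this are treated as ties (floating-point guard)
IMPROVEMENT_TOL = 1e-9


def default_stride(n: int) -> tuple[int, ...]:
    """Perturbation-magnitude schedule {n/10, n/5, n/2, n}, rounded, >= 1."""
    return tuple(max(1, round(n / d)) for d in (10, 5, 2, 1))


@dataclass
class SearchConfig:
    """Tunables of the search drivers.

    ``pf``/``stride``/``mo`` default to values derived from the variable
    count n at run time (round(n/10), {n/10, n/5, n/2, n} and n
    respectively).  ``budget`` caps outer iterations; ``inner_budget`` caps
    the ILSG iterations inside each ILSM step; ``max_deltas`` caps total
    move evaluations across the whole run; ``max_seconds`` is an optional
    wall-clock ceiling.  ``k`` (max in-degree) is unenforced when None.
    """

    pf: Optional[int] = None
    sr: int = 20
    stride: Optional[tuple[int, ...]] = None
    mo: Optional[int] = None
    rs: int = 20
    rh: int = 5
    budget: int = 1000
    inner_budget: int = 50
    max_deltas: Optional[int] = None
    max_seconds: Optional[float] = None
    seed: int = 0
    k: Optional[int] = None

    def __post_init__(self):
        for name in ("sr", "rs", "rh", "budget", "inner_budget"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stride is not None:
            s = tuple(int(v) for v in self.stride)
            if any(b < a for a, b in zip(s, s[1:])):
                raise ValueError("stride must be nondecreasing")
            self.stride = s

    def resolve(self, n: int) -> "SearchConfig":
        """Fill n-dependent defaults for a dataset with n variables."""
        out = SearchConfig(**{**self.__dict__})
        if out.stride is None:
            out.stride = default_stride(n)
        if out.pf is None:
            out.pf = out.stride[0]
        if out.mo is None:
            out.mo = n
        return out


TraceRecord = tuple[int, str, float, float]  # (iteration, event, score, best score)


@dataclass
class SearchResult:
    """Outcome of a search run: best graph, its BIC, and the event trace."""

    best_dag: DAG
    best_score: float
    trace: list[TraceRecord] = field(default_factory=list)
    n_evals: int = 0


class _Evaluator:
    """Counts and budget-caps score-delta evaluations around one cache."""

    __slots__ = ("dataset", "cache", "max_deltas", "deadline", "n_evals")

    def __init__(self, dataset, cache=None, max_deltas=None, max_seconds=None):
        self.dataset = dataset
        self.cache = cache if cache is not None else LocalScoreCache()
        self.max_deltas = max_deltas
        self.deadline = None if max_seconds is None else time.monotonic() + max_seconds
        self.n_evals = 0

    @property
    def exhausted(self) -> bool:
        if self.max_deltas is not None and self.n_evals >= self.max_deltas:
            return True
        return self.deadline is not None and time.monotonic() > self.deadline

    def delta(self, dag: DAG, move: Move) -> float:
        self.n_evals += 1
        return score_delta(dag, move, self.dataset, self.cache)

    def score(self, dag: DAG) -> float:
        return bic(dag, self.dataset, self.cache)


def _enforce_k(dag: DAG, k: Optional[int]) -> DAG:
    """Trim parent sets to at most k (keep lexicographically first parents).

    Random starts and perturbations are not in-degree aware; this projects
    them back into the constrained space before local search.
    """
    if k is None:
        return dag
    out = dag.copy()
    for v in out.nodes:
        extra = sorted(out.parents(v))[k:]
        for p in extra:
            out.remove_edge(p, v)
    return out


def _legal_moves(dag: DAG, k: Optional[int]) -> Iterator[Move]:
    """Legal basic moves in deterministic lexicographic (kind, from, to) order."""
    nodes = sorted(dag.nodes)
    for u in nodes:
        for v in nodes:
            if u == v or dag.adjacent(u, v):
                continue
            if k is not None and dag.in_degree(v) >= k:
                continue
            if not dag.would_create_cycle(u, v):
                yield ("add", u, v)
    edges = dag.edge_list()
    for u, v in edges:
        yield ("delete", u, v)
    for u, v in edges:
        if k is not None and dag.in_degree(u) >= k:
            continue
        if not dag.reverse_would_create_cycle(u, v):
            yield ("reverse", u, v)


def _apply_move(dag: DAG, move: Move) -> None:
    kind, u, v = move
    if kind == "add":
        dag.add_edge(u, v)
    elif kind == "delete":
        dag.remove_edge(u, v)
    else:
        dag.reverse_edge(u, v)


def hill_climb(
    start_dag: DAG,
    dataset: DiscreteDataset,
    cache: Optional[LocalScoreCache] = None,
    k: Optional[int] = None,
    evaluator: Optional[_Evaluator] = None,
) -> DAG:
    """Best-improvement steepest ascent to a local optimum.

    Every sweep evaluates all legal Add/Delete/Reverse moves and applies the
    single best one while its gain exceeds the improvement tolerance; ties
    keep the lexicographically first move.  Stops at a local optimum or
    when the evaluator's budget runs out.
    """
    ev = evaluator if evaluator is not None else _Evaluator(dataset, cache)
    g = start_dag.copy()
    while True:
        best_move = None
        best_delta = IMPROVEMENT_TOL
        for move in _legal_moves(g, k):
            if ev.exhausted:
                return g
            d = ev.delta(g, move)
            if d > best_delta:
                best_move, best_delta = move, d
        if best_move is None:
            return g
        _apply_move(g, best_move)


def _compare(g: DAG, s: float, g2: DAG, s2: float) -> tuple[DAG, float, bool]:
    """Keep the better-scoring graph; exact ties keep the incumbent."""
    if s2 > s + IMPROVEMENT_TOL:
        return g2, s2, True
    return g, s, False


def _ilsg_loop(
    start: DAG,
    pf: int,
    budget: int,
    sr: int,
    rng: np.random.Generator,
    ev: _Evaluator,
    k: Optional[int],
    trace: list[TraceRecord],
    outer: int = 0,
    best_floor: float = -math.inf,
) -> tuple[DAG, float]:
    """Shared ILSG core: returns the best (graph, score) found.

    ``best_floor`` is the caller's global best-so-far, so trace records stay
    monotone when this loop runs inside an outer schedule.
    """
    g = hill_climb(_enforce_k(start, k), ev.dataset, evaluator=ev, k=k)
    score = ev.score(g)
    best, best_score = g, score
    stall = 0
    for it in range(budget):
        if ev.exhausted:
            break
        g2 = _enforce_k(perturb(g, pf, rng), k)
        g2 = hill_climb(g2, ev.dataset, evaluator=ev, k=k)
        s2 = ev.score(g2)
        g, score, improved = _compare(g, score, g2, s2)
        if score > best_score + IMPROVEMENT_TOL:
            best, best_score = g, score
            trace.append((outer, "improve", score, max(best_score, best_floor)))
            stall = 0
        else:
            stall = stall + 1
        if sr and stall >= sr:
            g = _enforce_k(random_dag(start.nodes, rng=rng), k)
            score = ev.score(g)
            trace.append((outer, "soft-restart", score, max(best_score, best_floor)))
            stall = 0
    return best, best_score


def ilsg(
    dataset: DiscreteDataset,
    config: SearchConfig,
    start: Optional[DAG] = None,
) -> SearchResult:
    """Iterated local search with basic-move perturbation."""
    cfg = config.resolve(dataset.n_variables)
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(dataset, max_deltas=cfg.max_deltas, max_seconds=cfg.max_seconds)
    if start is None:
        start = random_dag(dataset.labels, rng=rng)
    trace: list[TraceRecord] = []
    best, best_score = _ilsg_loop(
        start, cfg.pf, cfg.budget, cfg.sr, rng, ev, cfg.k, trace
    )
    return SearchResult(best, best_score, trace, ev.n_evals)


def ilsm(dataset: DiscreteDataset, config: SearchConfig) -> SearchResult:
    """ILSG with Momentum kicks, stride stepping, and scheduled restarts."""
    cfg = config.resolve(dataset.n_variables)
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(dataset, max_deltas=cfg.max_deltas, max_seconds=cfg.max_seconds)
    trace: list[TraceRecord] = []
    stride = cfg.stride
    si = 0
    g = random_dag(dataset.labels, rng=rng)
    g, score = _ilsg_loop(g, stride[si], cfg.inner_budget, cfg.sr, rng, ev, cfg.k, trace)
    best, best_score = g, score
    stall = 0
    kicks = 0
    for outer in range(1, cfg.budget + 1):
        if ev.exhausted:
            break
        g2, s2 = _ilsg_loop(
            g, stride[si], cfg.inner_budget, cfg.sr, rng, ev, cfg.k, trace, outer,
            best_floor=best_score,
        )
        g, score, _ = _compare(g, score, g2, s2)
        if score > best_score + IMPROVEMENT_TOL:
            best, best_score = g, score
            stall = 0
            kicks = 0
            trace.append((outer, "improve", score, best_score))
        else:
            stall += 1
        if cfg.rs and stall >= cfg.rs:
            kicks += 1
            if cfg.rh and kicks >= cfg.rh:
                g = _enforce_k(random_dag(dataset.labels, rng=rng), cfg.k)
                score = ev.score(g)
                si = 0
                kicks = 0
                trace.append((outer, "restart", score, best_score))
            else:
                g = _enforce_k(momentum(g, cfg.mo, rng), cfg.k)
                score = ev.score(g)
                trace.append((outer, "momentum", score, best_score))
                if si < len(stride) - 1:
                    si += 1
                    trace.append((outer, "stride-step", score, best_score))
            stall = 0
    return SearchResult(best, best_score, trace, ev.n_evals)


def restart_hill_climb(dataset: DiscreteDataset, config: SearchConfig) -> SearchResult:
    """Random-restart hill climbing: the classic local-search baseline."""
    cfg = config.resolve(dataset.n_variables)
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(dataset, max_deltas=cfg.max_deltas, max_seconds=cfg.max_seconds)
    trace: list[TraceRecord] = []
    best: Optional[DAG] = None
    best_score = -math.inf
    for it in range(max(1, cfg.budget)):
        if best is not None and ev.exhausted:
            break
        g = _enforce_k(random_dag(dataset.labels, rng=rng), cfg.k)
        g = hill_climb(g, dataset, evaluator=ev, k=cfg.k)
        s = ev.score(g)
        if s > best_score + IMPROVEMENT_TOL or best is None:
            best, best_score = g, s
            trace.append((it, "improve", s, best_score))
        else:
            trace.append((it, "restart", s, best_score))
    return SearchResult(best, best_score, trace, ev.n_evals)
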