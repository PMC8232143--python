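"""Structural evaluation of a learned graph against a ground truth.

Two complementary metrics are provided.  The structural Hamming distance
(SHD) counts missing edges, extra edges and incorrectly oriented edges —
the edit distance to the true graph, 0 for a perfect fit.  The balanced
scoring function (BSF) rewards both discovered edges and discovered
independencies,

    BSF = 0.5 * (TP/a + TN/i - FP/i - FN/a),    i = V(V-1)/2 - a,

where a is the true edge count and i the number of directly independent
pairs; it ranges over [-1, 1], with 1 for a perfect match and 0 for an
empty baseline.  TP/FP/FN use directed edge matching (a reversed edge is
one FP plus one FN), while TN counts unordered pairs non-adjacent in both
graphs; SHD counts the same reversal as a single unit — the two metrics
legitimately differ on reversals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dag_core import DAG, MalformedStructureError, shd_pair

__all__ = ["ConfusionCounts", "confusion", "shd", "bsf", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """BSF needs a true graph that is neither empty nor complete."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Directed-edge confusion counts plus the true graph's a and i totals."""

    tp: int
    tn: int
    fp: int
    fn: int
    a: int  # true-graph edge count
    i: int  # true-graph direct-independence count, V(V-1)/2 - a


def confusion(learned: DAG, truth: DAG) -> ConfusionCounts:
    """Directed confusion counts of a learned graph against the truth.

    TP: directed edges present in both; FP: learned edges absent from the
    truth; FN: true edges absent from the learned graph; TN: unordered
    pairs non-adjacent in both graphs.
    """
    if set(learned.nodes) != set(truth.nodes):
        raise MalformedStructureError("confusion requires identical node sets")
    el, et = learned.edges, truth.edges
    tp = len(el & et)
    fp = len(el - et)
    fn = len(et - el)
    nodes = sorted(truth.nodes)
    tn = 0
    for idx, u in enumerate(nodes):
        for v in nodes[idx + 1 :]:
            if not learned.adjacent(u, v) and not truth.adjacent(u, v):
                tn += 1
    n = len(nodes)
    a = len(et)
    i = n * (n - 1) // 2 - a
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, a=a, i=i)


def shd(learned: DAG, truth: DAG) -> int:
    """Structural Hamming distance (missing + extra + wrongly oriented)."""
    return shd_pair(learned, truth)


def bsf(learned: DAG, truth: DAG) -> float:
    """Balanced scoring function; 1 = perfect match, 0 = empty learned graph.

    Nominally ranges over [-1, 1].  Under directed matching the exact lower
    bound is -1 - a/(2i): a learned graph that reverses true edges while
    also filling every independent pair can push FP above i.  Real learned
    graphs sit far from that corner.
    """
    c = confusion(learned, truth)
    if c.a == 0 or c.i == 0:
        raise UndefinedMetricError(
            "BSF is undefined for an empty or complete true graph"
        )
    return 0.5 * (c.tp / c.a + c.tn / c.i - c.fp / c.i - c.fn / c.a)
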