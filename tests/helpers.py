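"""Shared test utilities: exhaustive DAG enumeration and a forcing RNG."""

from __future__ import annotations

import itertools

import numpy as np

from ilsbn.dag_core import DAG, is_acyclic


def enumerate_dags(nodes: tuple[str, ...]):
    """Yield every labelled DAG on ``nodes``: 25 on 3 nodes, 543 on 4, ..."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product(range(3), repeat=len(pairs)):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        if is_acyclic(edges, nodes):
            yield DAG(nodes, edges)


class ForcedRNG:
    """Wraps a Generator, answering the first `integers` calls from a queue.

    Lets a test pin the discrete choices of a stochastic operator (which
    operator, which node) while leaving the rest of the stream random.
    """

    def __init__(self, forced, seed=0):
        self._forced = list(forced)
        self._rng = np.random.default_rng(seed)

    def integers(self, *args, **kwargs):
        if self._forced:
            return self._forced.pop(0)
        return self._rng.integers(*args, **kwargs)

    def __getattr__(self, name):
        return getattr(self._rng, name)
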