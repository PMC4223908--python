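"""Descending-weight rank clique filtration.

Edge weights are sorted in descending order and their *dense ranks* are
used as filtration indices: the heaviest edge(s) enter at step 1, and all
edges of equal weight enter simultaneously. At each step the binary graph
of the edges seen so far is promoted to its clique (flag) complex, so a
k-simplex is present exactly when its k+1 vertices are pairwise connected.
Scanning the nested sequence of complexes reveals when holes open and
close in the weight fabric of the network.

Three ranking modes handle signed weights:

``signed``
    rank on the signed value, most positive first (negative edges enter
    last) — the default;
``absolute``
    rank on |w| descending;
``positive``
    drop edges with w <= 0, rank the rest descending.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .graphio import WeightedNetwork

__all__ = ["Filtration", "CliqueComplex", "rank_filtration", "clique_complex_at",
           "simplex_stream"]

MODES = ("signed", "absolute", "positive")


@dataclass
class Filtration:
    """The rank-indexed sequence of binary graphs of a weighted network.

    ``steps[k]`` is the weight threshold of 1-based step ``k+1``;
    ``edge_rank`` maps an edge (pair of node positions, i < j) to the step
    at which it enters. Vertices all enter at step 0.
    """

    source: WeightedNetwork
    steps: list[float]
    edge_rank: dict[tuple[int, int], int]
    mode: str = "signed"
    max_clique_size: int = 3

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def weight_of_step(self, step: int) -> float:
        """Threshold weight of a 1-based step; step 0 maps to steps[0]."""
        if step <= 0:
            return self.steps[0]
        return self.steps[min(step, self.n_steps) - 1]

    def mean_step_gap(self) -> float:
        """Mean gap between consecutive thresholds (1.0 for a one-step
        filtration); used as the weight-unit analogue of one rank step."""
        if self.n_steps < 2:
            return 1.0
        return float(np.mean(np.abs(np.diff(self.steps))))


@dataclass
class CliqueComplex:
    """Clique complex of one filtration step, with appearance steps.

    ``simplices[d]`` lists d-simplices as ascending tuples of node
    positions; ``appearance[sigma]`` is the max edge rank over the
    simplex's edges (0 for vertices).
    """

    simplices: dict[int, list[tuple[int, ...]]]
    appearance: dict[tuple[int, ...], int] = field(default_factory=dict)

    @property
    def max_dim(self) -> int:
        return max((d for d, s in self.simplices.items() if s), default=-1)

    def counts(self) -> dict[int, int]:
        return {d: len(s) for d, s in self.simplices.items()}


def rank_filtration(net: WeightedNetwork, mode: str = "signed",
                    max_clique_size: int = 3) -> Filtration:
    """Dense descending rank of the edge weights of ``net``.

    Ties share one rank (they index the same threshold ω), so the number
    of steps equals the number of distinct ranking keys.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if net.n_edges == 0:
        raise ValueError("network has no edges; a filtration needs >= 1 edge")
    items = list(net.edge_positions())
    if mode == "positive":
        items = [(e, w) for e, w in items if w > 0]
        if not items:
            raise ValueError("no positive-weight edges in 'positive' mode")
        keys = {e: w for e, w in items}
    elif mode == "absolute":
        keys = {e: abs(w) for e, w in items}
    else:
        keys = {e: w for e, w in items}
    distinct = sorted(set(keys.values()), reverse=True)
    rank_of = {w: r for r, w in enumerate(distinct, start=1)}
    edge_rank = {e: rank_of[k] for e, k in keys.items()}
    return Filtration(source=net, steps=distinct, edge_rank=edge_rank,
                      mode=mode, max_clique_size=max_clique_size)


def _cliques_up_to(adj: dict[int, set[int]], vertices: list[int],
                   max_size: int) -> dict[int, list[tuple[int, ...]]]:
    """All cliques of size <= max_size, by simplex dimension (size - 1).

    Grown by extension: each (k+1)-clique is a k-clique plus one vertex
    larger than its max that is adjacent to all members.
    """
    out: dict[int, list[tuple[int, ...]]] = {0: [(v,) for v in sorted(vertices)]}
    current = out[0]
    for size in range(2, max_size + 1):
        nxt: list[tuple[int, ...]] = []
        for c in current:
            cand = set(adj.get(c[0], ()))
            for v in c[1:]:
                cand &= adj.get(v, set())
            for v in sorted(cand):
                if v > c[-1]:
                    nxt.append(c + (v,))
        if not nxt:
            break
        out[size - 1] = nxt
        current = nxt
    return out


def _adjacency(edges: list[tuple[int, int]]) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    return adj


def _appearance_of(simplex: tuple[int, ...], edge_rank: dict[tuple[int, int], int]) -> int:
    if len(simplex) == 1:
        return 0
    return max(edge_rank[(a, b)] for a, b in itertools.combinations(simplex, 2))


def clique_complex_at(filt: Filtration, step: int) -> CliqueComplex:
    """Clique complex K_ω at 1-based ``step`` (dimension capped at
    ``max_clique_size - 1``). Output at step s is a subcomplex of step s+1."""
    if not 1 <= step <= filt.n_steps:
        raise ValueError(f"step {step} out of range 1..{filt.n_steps}")
    edges = [e for e, r in filt.edge_rank.items() if r <= step]
    adj = _adjacency(edges)
    vertices = list(range(filt.source.n_nodes))
    simplices = _cliques_up_to(adj, vertices, filt.max_clique_size)
    appearance = {s: _appearance_of(s, filt.edge_rank)
                  for dim in simplices for s in simplices[dim]}
    return CliqueComplex(simplices=simplices, appearance=appearance)


def simplex_stream(filt: Filtration) -> list[tuple[tuple[int, ...], int]]:
    """Totally ordered simplex stream for the reduction algorithm.

    Simplices of the final complex sorted by (appearance step, dimension,
    lexicographic vertex tuple); every simplex comes after all its faces,
    and the order is a deterministic function of the input network.
    """
    full = clique_complex_at(filt, filt.n_steps)
    stream = [(s, full.appearance[s]) for dim in sorted(full.simplices)
              for s in full.simplices[dim]]
    stream.sort(key=lambda item: (item[1], len(item[0]), item[0]))
    return stream
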