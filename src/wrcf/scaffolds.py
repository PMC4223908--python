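"""Homological scaffolds: summary networks built from H1 generators.

The scaffolds project the persistence information back onto single edges.
For each edge e of the original node set:

* the **persistence scaffold** weighs e by the summed persistence of all
  representative cycles that pass through it,
  ``W_p(e) = sum_i pi_{g_i} * 1[e in g_i]``;
* the **frequency scaffold** weighs e by the number of representative
  cycles it belongs to, ``W_f(e) = sum_i 1[e in g_i]``.

Both scaffolds share one edge set (the union of all representative
edges); a heavy persistence-scaffold edge marks a locally strong bridge
whose surroundings are comparatively weak. Because representatives are a
basis choice, scaffolds are summaries, not topological invariants; the
``triangle_audit`` quantifies how often a chord entering a live cycle's
neighbourhood could have re-routed the representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .filtration import Filtration
from .graphio import WeightedNetwork
from .homology import Generator

__all__ = ["Scaffold", "persistence_scaffold", "frequency_scaffold",
           "triangle_audit", "threshold_scaffold", "TriangleAuditReport"]


@dataclass
class Scaffold:
    """Weighted graph on the source node set with scaffold edge weights."""

    network: WeightedNetwork
    kind: str                 # "persistence" | "frequency"
    units: str                # "rank" | "weight"

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((u, v) for u, v, _ in self.network.edges())

    def weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): w for u, v, w in self.network.edges()}

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.network.edges())


def _select(generators: list[Generator], include_zero_persistence: bool,
            include_essential: bool) -> list[Generator]:
    out = []
    for g in generators:
        if g.dimension != 1:
            raise ValueError("scaffolds are built from H1 generators only")
        if g.zero_persistence and not include_zero_persistence:
            continue
        if g.essential and not include_essential:
            continue
        out.append(g)
    return out


def _build(generators: list[Generator], nodes: list[str], kind: str, units: str,
           include_zero_persistence: bool, include_essential: bool) -> Scaffold:
    chosen = _select(generators, include_zero_persistence, include_essential)
    if nodes is None:
        top = 1 + max((v for g in chosen for s in g.representative for v in s),
                      default=-1)
        nodes = [str(i) for i in range(top)]
    acc: dict[tuple[int, int], float] = {}
    for g in chosen:
        contrib = 1.0 if kind == "frequency" else (
            float(g.persistence) if units == "rank" else g.persistence_weight)
        for e in g.representative_edges():
            acc[e] = acc.get(e, 0.0) + contrib
    net = WeightedNetwork.from_nodes(nodes)
    for (i, j), w in sorted(acc.items()):
        net.add_edge(nodes[i], nodes[j], w, create_nodes=False)
    return Scaffold(network=net, kind=kind, units=units)


def persistence_scaffold(generators: list[Generator], nodes: list[str] | None = None,
                         units: str = "rank", include_zero_persistence: bool = False,
                         include_essential: bool = True) -> Scaffold:
    """Persistence scaffold W_p: edge weight = summed persistence of the
    representative cycles through that edge. ``units`` selects rank-step
    or weight-unit persistence; essential generators contribute their
    sentinel-resolved persistence. Zero-persistence tie pairs are skipped
    by default (they would add 0 here but would still inflate the
    frequency scaffold, and the two must keep one edge set)."""
    if units not in ("rank", "weight"):
        raise ValueError("units must be 'rank' or 'weight'")
    return _build(generators, nodes, "persistence", units,
                  include_zero_persistence, include_essential)


def frequency_scaffold(generators: list[Generator], nodes: list[str] | None = None,
                       include_zero_persistence: bool = False,
                       include_essential: bool = True) -> Scaffold:
    """Frequency scaffold W_f: edge weight = number of representative
    cycles through that edge. Same selection rules as the persistence
    scaffold, so the two share one edge set by construction."""
    return _build(generators, nodes, "frequency", "rank",
                  include_zero_persistence, include_essential)


@dataclass
class TriangleAuditReport:
    """Per-generator triangle-creation flags and the unflagged fraction.

    A generator is flagged when some edge entering the filtration during
    its lifetime (beta, delta], with both endpoints on the representative,
    closes a triangle with two representative edges — in that case part of
    the persistence mass may be attributed to the two old edges while the
    shortest live cycle runs through the new chord.
    """

    flags: list[bool] = field(default_factory=list)
    n_generators: int = 0

    @property
    def fraction_unflagged(self) -> float:
        if self.n_generators == 0:
            return 1.0
        return 1.0 - sum(self.flags) / self.n_generators


def triangle_audit(generators: list[Generator], filt: Filtration) -> TriangleAuditReport:
    """Audit representative misattribution for each H1 generator."""
    flags: list[bool] = []
    for g in generators:
        if g.dimension != 1:
            raise ValueError("triangle_audit expects H1 generators")
        rep_edges = g.representative_edges()
        rep_vertices = {v for e in rep_edges for v in e}
        adjacency: dict[int, set[int]] = {}
        for a, b in rep_edges:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        flagged = False
        for (a, b), rank in filt.edge_rank.items():
            if not (g.birth_step < rank <= g.death_step):
                continue
            if a not in rep_vertices or b not in rep_vertices or (a, b) in rep_edges:
                continue
            if adjacency.get(a, set()) & adjacency.get(b, set()):
                flagged = True
                break
        flags.append(flagged)
    return TriangleAuditReport(flags=flags, n_generators=len(flags))


def threshold_scaffold(s: Scaffold, w_min: float) -> Scaffold:
    """Keep edges with weight >= w_min; the node table is retained in full
    (isolated nodes are dropped only at render time)."""
    if w_min < 0:
        raise ValueError("w_min must be >= 0")
    net = WeightedNetwork.from_nodes(s.network.nodes)
    for u, v, w in s.network.edges():
        if w >= w_min:
            net.add_edge(u, v, w, create_nodes=False)
    return Scaffold(network=net, kind=s.kind, units=s.units)
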