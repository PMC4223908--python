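"""Persistent homology of the rank filtration, with representative cycles.

The computation is the standard column reduction of the boundary matrix
over the two-element field GF(2), processed in simplex-stream order.
Columns are Python integers used as bitsets (bit i = simplex at stream
position i), so column addition is a single XOR and the pivot is the
highest set bit.

Alongside the reduced matrix R we track V with D = R V (also as bitsets).
When the column of a d-simplex sigma reduces to zero, sigma *creates* a
d-cycle and the V column at that moment is a concrete cycle containing
sigma — this is the representative frozen at birth, with no later
shortening, so scaffolds built from it are deliberately basis-dependent
(they are not topological invariants). When a later column keeps sigma as
its pivot, the cycle dies there; creators never used as a pivot are
essential.

A generator's birth and death are filtration *steps* (dense weight
ranks); the corresponding threshold weights are carried along so
persistence can be measured in rank or weight units. Essential
generators get the sentinel death ``last step + 1`` (in weight units the
last threshold minus the mean threshold gap) so scaffold arithmetic
stays finite; the essential flag is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .filtration import Filtration, CliqueComplex, simplex_stream

__all__ = ["Generator", "PersistenceDiagram", "persistent_homology",
           "betti_numbers", "diagram_of", "generators_to_records"]


@dataclass(frozen=True)
class Generator:
    """One persistence pair (or essential class) of the filtration.

    ``representative`` is a tuple of k-simplices (ascending vertex tuples
    of node positions) whose GF(2) sum has empty boundary; every simplex
    in it appears at or before the birth step.
    """

    dimension: int
    birth_step: int
    death_step: int          # sentinel (n_steps + 1) when essential
    birth_weight: float
    death_weight: float
    essential: bool
    representative: tuple[tuple[int, ...], ...]

    @property
    def persistence(self) -> int:
        """Lifespan in rank steps, pi = delta - beta."""
        return self.death_step - self.birth_step

    @property
    def persistence_weight(self) -> float:
        """Lifespan in weight units (birth threshold - death threshold)."""
        return self.birth_weight - self.death_weight

    @property
    def zero_persistence(self) -> bool:
        """Born and dead within a single tie step."""
        return self.death_step == self.birth_step

    def representative_edges(self) -> frozenset[tuple[int, int]]:
        """Edges of the representative (dimension-1 generators only)."""
        if self.dimension != 1:
            raise ValueError("representative_edges is defined for H1 generators")
        return frozenset(self.representative)


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) points of one homology dimension."""

    dimension: int
    points: list[tuple[int, int]] = field(default_factory=list)
    essential_flags: list[bool] = field(default_factory=list)

    def multiset(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for p in self.points:
            out[p] = out.get(p, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.points)


def _boundary_bits(simplex: tuple[int, ...], position: dict[tuple[int, ...], int]) -> int:
    bits = 0
    for k in range(len(simplex)):
        face = simplex[:k] + simplex[k + 1:]
        bits |= 1 << position[face]
    return bits


def _bits(x: int):
    while x:
        low = x & -x
        yield low.bit_length() - 1
        x ^= low


def persistent_homology(filt: Filtration, max_dim: int = 1) -> list[Generator]:
    """All generators of H_0..H_max_dim along the filtration.

    Requires the filtration's clique cap to cover ``max_dim + 2``: deaths
    of k-cycles are caused by (k+1)-simplices only. One Generator per
    reduction pairing plus one essential Generator per never-paired cycle
    column. Zero-persistence pairs (possible under weight ties) are kept
    and exposed via ``Generator.zero_persistence``. Output order is a
    deterministic function of the input network.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    if filt.max_clique_size < max_dim + 2:
        raise ValueError(
            f"clique cap {filt.max_clique_size} insufficient for H_{max_dim}; "
            f"need max_clique_size >= {max_dim + 2}"
        )
    stream = simplex_stream(filt)
    position = {s: i for i, (s, _) in enumerate(stream)}
    appearance = [step for _, step in stream]

    pivot_owner: dict[int, int] = {}   # row (stream pos) -> column owning it
    r_col: dict[int, int] = {}         # reduced boundary columns
    v_col: dict[int, int] = {}         # matching V columns (D = R V)
    cycle_chain: dict[int, int] = {}   # creator pos -> cycle chain bitset
    killed: dict[int, int] = {}        # creator pos -> killer pos

    for j, (simplex, _) in enumerate(stream):
        if len(simplex) == 1:
            cycle_chain[j] = 1 << j    # vertices create H0 classes
            continue
        r = _boundary_bits(simplex, position)
        v = 1 << j
        while r:
            pivot = r.bit_length() - 1
            owner = pivot_owner.get(pivot)
            if owner is None:
                break
            r ^= r_col[owner]
            v ^= v_col[owner]
        if r:
            pivot = r.bit_length() - 1
            pivot_owner[pivot] = j
            r_col[j] = r
            v_col[j] = v
            killed[pivot] = j
        else:
            cycle_chain[j] = v         # V_j is a cycle containing simplex j
            r_col[j] = 0
            v_col[j] = v

    sentinel_step = filt.n_steps + 1
    sentinel_weight = filt.steps[-1] - filt.mean_step_gap()

    generators: list[Generator] = []
    for j, chain in cycle_chain.items():
        dim = len(stream[j][0]) - 1
        if dim > max_dim:
            continue
        birth_step = appearance[j]
        if j in killed:
            death_step = appearance[killed[j]]
            essential = False
            death_weight = filt.weight_of_step(death_step)
        else:
            death_step = sentinel_step
            essential = True
            death_weight = sentinel_weight
        rep = tuple(sorted(stream[i][0] for i in _bits(chain)))
        generators.append(Generator(
            dimension=dim,
            birth_step=birth_step,
            death_step=death_step,
            birth_weight=filt.weight_of_step(birth_step),
            death_weight=death_weight,
            essential=essential,
            representative=rep,
        ))
    generators.sort(key=lambda g: (g.dimension, g.birth_step, g.death_step,
                                   g.representative))
    return generators


# -- Betti numbers ---------------------------------------------------------


def _gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix given as bitset columns."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            p = col.bit_length() - 1
            if p in pivots:
                col ^= pivots[p]
            else:
                pivots[p] = col
                rank += 1
                break
    return rank


def betti_numbers(complex: CliqueComplex, max_dim: int = 1) -> list[int]:
    """b_0..b_max_dim of a clique complex over GF(2).

    b_k = n_k - rank(d_k) - rank(d_{k+1}) where d_k is the k-th boundary
    map. The complex must contain (k+1)-simplices for b_k to be exact; a
    dimension cap below k+1 truncates, which the caller acknowledges by
    having chosen the cap.
    """
    simplices = complex.simplices
    position: dict[int, dict[tuple[int, ...], int]] = {
        d: {s: i for i, s in enumerate(simplices.get(d, []))}
        for d in range(max_dim + 2)
    }

    def boundary_rank(d: int) -> int:
        if d <= 0 or not simplices.get(d):
            return 0
        faces = position[d - 1]
        cols = []
        for s in simplices[d]:
            bits = 0
            for k in range(len(s)):
                bits |= 1 << faces[s[:k] + s[k + 1:]]
            cols.append(bits)
        return _gf2_rank(cols)

    return [len(simplices.get(k, [])) - boundary_rank(k) - boundary_rank(k + 1)
            for k in range(max_dim + 1)]


def diagram_of(generators: list[Generator], dimension: int) -> PersistenceDiagram:
    """Persistence diagram (multiset of (beta, delta)) for one dimension;
    essential deaths already carry the sentinel step and stay flagged."""
    pts = [(g.birth_step, g.death_step) for g in generators if g.dimension == dimension]
    flags = [g.essential for g in generators if g.dimension == dimension]
    return PersistenceDiagram(dimension=dimension, points=pts, essential_flags=flags)


def remap_generators(generators: list[Generator], from_labels: list[str],
                     to_labels: list[str]) -> list[Generator]:
    """Re-index representative vertices from one node order to another.

    Generator representatives store *positions* in the source network's
    node list; before aggregating generators of several subjects (group
    scaffolds), remap each subject onto the shared node universe.
    """
    to_pos = {l: i for i, l in enumerate(to_labels)}
    try:
        lut = [to_pos[l] for l in from_labels]
    except KeyError as exc:
        raise KeyError(f"node {exc.args[0]!r} missing from target labels") from None
    out = []
    for g in generators:
        rep = tuple(sorted(tuple(sorted(lut[v] for v in s))
                           for s in g.representative))
        out.append(Generator(
            dimension=g.dimension, birth_step=g.birth_step,
            death_step=g.death_step, birth_weight=g.birth_weight,
            death_weight=g.death_weight, essential=g.essential,
            representative=rep))
    return out


# -- serialization ---------------------------------------------------------


def generators_to_records(generators: list[Generator], node_labels: list[str]) -> list[dict]:
    """Rows for the generator CSV: dimension, birth/death step and weight,
    essential flag, and the representative as a ';'-separated simplex list
    with vertices joined by '|' (labels may themselves contain '-')."""
    rows = []
    for g in generators:
        rep = ";".join("|".join(node_labels[v] for v in s) for s in g.representative)
        rows.append({
            "dimension": g.dimension,
            "birth_step": g.birth_step,
            "death_step": g.death_step,
            "birth_weight": g.birth_weight,
            "death_weight": g.death_weight,
            "persistence_steps": g.persistence,
            "persistence_weight": g.persistence_weight,
            "essential": g.essential,
            "representative": rep,
        })
    return rows
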