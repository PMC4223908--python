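"""Synthetic fixtures with known topological ground truth.

Three generators:

* :func:`planted_network` — a single cycle whose boundary edges are drawn
  from a *high* weight range and whose filling chords (a triangulation
  fan) from a strictly *lower* range, optionally embedded next to a
  background random graph in an intermediate weight band that never
  touches the cycle (except through one bridge, which cannot create
  cycles). The separation of the ranges makes the planted (birth, death)
  bar an exact, assertable consequence of the construction.
* :func:`group_ensemble` — per-subject modular networks whose planted
  cycle persistences (in weight units) are drawn from one of two laws
  emulating a two-condition contrast: a broad uniform law versus a law
  peaked at small persistence with a heavy (Pareto) tail.
* :func:`gaussian_panel` — multivariate Gaussian time series from a known
  precision matrix, with optional additive nuisance components, the
  upstream fixture for partial-correlation estimation.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphio import WeightedNetwork
from .netbuild import TimeSeriesPanel

__all__ = ["PlantedCycleSpec", "GroupSpec", "ExpectedBar", "planted_network",
           "group_ensemble", "gaussian_panel", "sample_persistences",
           "ground_truth_partial_correlations", "LAWS"]

LAWS = ("broad_uniform", "peaked_plus_heavy_tail")


@dataclass(frozen=True)
class PlantedCycleSpec:
    """Recipe for one planted cycle.

    The boundary range must sit strictly above the chord range so that the
    full cycle is assembled before any chord arrives, making birth and
    death deterministic.
    """

    cycle_length: int = 4
    boundary_weight_range: tuple[float, float] = (0.7, 0.95)
    chord_weight_range: tuple[float, float] = (0.05, 0.3)
    chord_pattern: str = "closing_chord"     # "closing_chord" | "none"

    def __post_init__(self) -> None:
        if self.cycle_length < 4:
            raise ValueError("cycle_length must be >= 4")
        blo, bhi = self.boundary_weight_range
        clo, chi = self.chord_weight_range
        if not (blo < bhi and clo < chi):
            raise ValueError("weight ranges must be (low, high) with low < high")
        if blo <= chi:
            raise ValueError(
                "infeasible spec: boundary range must lie strictly above the chord range"
            )
        if self.chord_pattern not in ("closing_chord", "none"):
            raise ValueError(f"unknown chord_pattern {self.chord_pattern!r}")


@dataclass(frozen=True)
class ExpectedBar:
    """Ground-truth H1 bar implied by a planted construction."""

    birth_step: int
    death_step: int | None            # None = essential
    birth_weight: float
    death_weight: float | None
    edges: frozenset[tuple[str, str]]

    @property
    def essential(self) -> bool:
        return self.death_step is None


def _dense_ranks(weights: list[float]) -> dict[float, int]:
    distinct = sorted(set(weights), reverse=True)
    return {w: r for r, w in enumerate(distinct, start=1)}


def _distinct_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    for _ in range(100):
        draws = rng.uniform(lo, hi, size=n)
        if len(np.unique(draws)) == n:
            return draws
    raise RuntimeError("could not draw distinct weights")


def planted_network(spec: PlantedCycleSpec, n_background_nodes: int = 0,
                    seed: int | np.random.Generator = 0,
                    node_prefix: str = "c",
                    ) -> tuple[WeightedNetwork, list[ExpectedBar]]:
    """Build a network with one planted H1 bar and return the expected bar.

    The cycle c0..c{L-1} gets distinct boundary weights from the high
    range. With ``chord_pattern='closing_chord'`` a triangulation fan from
    c0 (chords (c0, c2)...(c0, c{L-2})) enters in *descending* chord
    weight order, so each fan chord is filled instantly by a triangle with
    already-present edges and the planted class survives exactly until the
    lightest fan chord. Background nodes form an Erdos-Renyi graph in the
    band strictly between the two ranges, joined to the cycle by a single
    bridge (a cut edge, so it can create no cycle through planted nodes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = spec.cycle_length
    cyc = [f"{node_prefix}{i}" for i in range(L)]
    net = WeightedNetwork.from_nodes(cyc)

    bw = _distinct_uniform(rng, *spec.boundary_weight_range, L)
    boundary_edges = [(cyc[i], cyc[(i + 1) % L]) for i in range(L)]
    for (u, v), w in zip(boundary_edges, bw):
        net.add_edge(u, v, float(w), create_nodes=False)

    chord_weights: list[float] = []
    if spec.chord_pattern == "closing_chord":
        n_chords = L - 3
        cw = np.sort(_distinct_uniform(rng, *spec.chord_weight_range, n_chords))[::-1]
        for k, w in zip(range(2, L - 1), cw):
            net.add_edge(cyc[0], cyc[k], float(w), create_nodes=False)
        chord_weights = [float(w) for w in cw]

    if n_background_nodes > 0:
        band = (spec.chord_weight_range[1], spec.boundary_weight_range[0])
        bg = [f"{node_prefix}bg{i}" for i in range(n_background_nodes)]
        for b in bg:
            net.add_node(b)
        for i in range(n_background_nodes):
            for j in range(i + 1, n_background_nodes):
                if rng.random() < 0.3:
                    net.add_edge(bg[i], bg[j], float(rng.uniform(*band)),
                                 create_nodes=False)
        net.add_edge(cyc[0], bg[0], float(rng.uniform(*band)), create_nodes=False)

    all_weights = [w for _, _, w in net.edges()]
    rank = _dense_ranks(all_weights)
    birth_w = float(np.min(bw))
    edges = frozenset(tuple(sorted(e)) for e in boundary_edges)
    if chord_weights:
        death_w = float(np.min(chord_weights))
        bar = ExpectedBar(birth_step=rank[birth_w], death_step=rank[death_w],
                          birth_weight=birth_w, death_weight=death_w, edges=edges)
    else:
        bar = ExpectedBar(birth_step=rank[birth_w], death_step=None,
                          birth_weight=birth_w, death_weight=None, edges=edges)
    return net, [bar]


# -- persistence laws ------------------------------------------------------

#: law parameters for the two-condition contrast; persistences are in
#: weight units on the partial-correlation-like [0, 1] scale
_BROAD_RANGE = (0.08, 0.35)
_PEAK_SCALE = 0.04
_PEAK_FLOOR = 0.01
_TAIL_PROB = 0.25
_TAIL_XM = 0.25
_TAIL_ALPHA = 1.2
_PI_MAX = 0.9


def sample_persistences(law: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw cycle persistences (weight units) from one of the two group
    laws.

    ``broad_uniform`` is U(0.08, 0.35): moderately long-lived cycles over
    a limited band, no extremes. ``peaked_plus_heavy_tail`` mixes a sharp
    exponential peak near zero (prob 0.75, scale 0.04) with a truncated
    Pareto tail (x_m = 0.25, alpha = 1.2, truncated at 0.9): most cycles
    are transient, but a minority live far beyond anything the broad law
    produces. The tail starts above the broad law's maximum so that the
    top of the pooled persistence-scaffold weight distribution is carried
    by the heavy-tail condition alone — the planted analogue of a small
    population of unusually stable cycles."""
    if law == "broad_uniform":
        return rng.uniform(*_BROAD_RANGE, size=size)
    if law == "peaked_plus_heavy_tail":
        peak = np.minimum(_PEAK_FLOOR + rng.exponential(_PEAK_SCALE, size=size),
                          _PI_MAX)
        # inverse-CDF truncated Pareto on [x_m, _PI_MAX] (no boundary atom)
        trunc = 1.0 - (_TAIL_XM / _PI_MAX) ** _TAIL_ALPHA
        tail = _TAIL_XM * (1.0 - trunc * rng.uniform(size=size)) ** (-1.0 / _TAIL_ALPHA)
        use_tail = rng.uniform(size=size) < _TAIL_PROB
        return np.where(use_tail, tail, peak)
    raise ValueError(f"unknown law {law!r}; expected one of {LAWS}")


@dataclass(frozen=True)
class GroupSpec:
    """Recipe for a group of subjects (one experimental condition)."""

    group_label: str = "group"
    n_subjects: int = 8
    n_nodes: int = 60
    law: str = "broad_uniform"
    cycle_length_range: tuple[int, int] = (4, 6)
    seed: int = 0
    bridge_weight_range: tuple[float, float] = (0.3, 0.5)

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}")
        lo, hi = self.cycle_length_range
        if lo < 4 or hi < lo:
            raise ValueError("cycle_length_range must be (lo, hi) with 4 <= lo <= hi")


def _planted_module(net: WeightedNetwork, prefix: str, length: int, pi: float,
                    rng: np.random.Generator) -> tuple[float, float, list[str]]:
    """Append one cycle module with exact weight-unit persistence ``pi``.

    The lightest boundary edge sits at b, the lightest fan chord at
    b - pi, all other chords strictly between, so the module contributes
    the bar (b, b - pi) in weight units.
    """
    b = rng.uniform(min(pi + 0.02, 0.96), 0.97)
    names = [f"{prefix}n{i}" for i in range(length)]
    for n in names:
        net.add_node(n)
    bw = np.concatenate([[b], _distinct_uniform(rng, b + 1e-6, min(b + 0.02, 0.999),
                                                length - 1)])
    for i, w in enumerate(bw):
        net.add_edge(names[i], names[(i + 1) % length], float(w), create_nodes=False)
    death = b - pi
    n_chords = length - 3
    if n_chords == 1:
        cw = np.array([death])
    else:
        hi = min(b - 1e-4, death + 0.015)
        cw = np.concatenate([np.sort(_distinct_uniform(rng, death + 1e-6, hi,
                                                       n_chords - 1))[::-1], [death]])
    for k, w in zip(range(2, length - 1), cw):
        net.add_edge(names[0], names[k], float(w), create_nodes=False)
    return b, death, names


def group_ensemble(spec: GroupSpec) -> tuple[list[WeightedNetwork], pd.DataFrame]:
    """Generate one subject network per subject plus the planted-truth log.

    Each subject is a chain of planted cycle modules (lengths drawn from
    ``cycle_length_range``) linked by bridge edges; bridges are cut edges,
    so the subject's H1 bars are exactly the planted ones. The log records
    subject, module, birth and death weight and the drawn persistence.
    """
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    networks: list[WeightedNetwork] = []
    rows = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(root.integers(2**31))
        net = WeightedNetwork()
        used = 0
        module = 0
        prev_anchor: str | None = None
        while True:
            length = int(rng.integers(spec.cycle_length_range[0],
                                      spec.cycle_length_range[1] + 1))
            if used + length > spec.n_nodes:
                break
            pi = float(sample_persistences(spec.law, 1, rng)[0])
            b, death, names = _planted_module(net, f"s{s}m{module}", length, pi, rng)
            if prev_anchor is not None:
                net.add_edge(prev_anchor, names[0],
                             float(rng.uniform(*spec.bridge_weight_range)),
                             create_nodes=False)
            prev_anchor = names[0]
            rows.append({"subject": s, "module": module, "cycle_length": length,
                         "birth_weight": b, "death_weight": death,
                         "persistence_weight": pi})
            used += length
            module += 1
        networks.append(net)
    return networks, pd.DataFrame(rows)


# -- Gaussian panels -------------------------------------------------------


def ground_truth_partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Closed-form partial correlations -P_ij / sqrt(P_ii P_jj) (unit
    diagonal) implied by a precision matrix."""
    P = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def gaussian_panel(precision: np.ndarray, n_samples: int,
                   n_nuisance: int = 0, nuisance_loading: float = 0.5,
                   seed: int | np.random.Generator = 0,
                   region_prefix: str = "r") -> TimeSeriesPanel:
    """Multivariate Gaussian panel from a known precision matrix.

    Latent regional signals are drawn from N(0, P^-1); if ``n_nuisance``
    > 0, independent standard-normal nuisance series are added to the
    regions with random loadings of magnitude ``nuisance_loading``, so
    conditioning on the nuisance recovers the latent partial
    correlations exactly (in the large-sample limit).
    """
    P = np.asarray(precision, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("precision must be square")
    try:
        np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        raise ValueError("precision matrix is not positive definite") from None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = P.shape[0]
    cov = np.linalg.inv(P)
    latent = rng.multivariate_normal(np.zeros(k), cov, size=n_samples,
                                     method="cholesky")
    nuis = rng.standard_normal((n_samples, n_nuisance))
    if n_nuisance:
        B = nuisance_loading * rng.standard_normal((k, n_nuisance))
        observed = latent + nuis @ B.T
    else:
        observed = latent
    return TimeSeriesPanel(
        region_labels=[f"{region_prefix}{i}" for i in range(k)],
        series=observed,
        nuisance_labels=[f"nuis_{i}" for i in range(n_nuisance)],
        nuisance=nuis,
    )
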