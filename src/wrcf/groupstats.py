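"""Group-level comparison of persistence diagrams and scaffolds.

Diagrams from all subjects of a condition are pooled (every generator is
one observation), summarized as binned probability densities, and two
conditions are contrasted with two-sample Kolmogorov–Smirnov tests on
persistence, birth, and scaffold edge-weight samples. The per-edge
relationship between frequency- and persistence-scaffold weights is
summarized by an ordinary least-squares fit, and the slopes of two
conditions are compared by a t-test on the slope difference using each
fit's standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .homology import Generator
from .scaffolds import Scaffold

__all__ = ["GroupSummary", "KSResult", "FitResult", "ComparisonReport",
           "pooled_density", "ks_two_sample", "frequency_persistence_fit",
           "slope_difference_test", "modularity_communities",
           "cross_group_edge_report", "CrossGroupEdgeReport",
           "DegenerateFitError"]


class DegenerateFitError(ValueError):
    """OLS slope undefined (zero variance in the regressor)."""


@dataclass
class GroupSummary:
    """Pooled H1 persistence information for one group of subjects."""

    group_label: str
    subject_generators: list[list[Generator]]
    units: str = "rank"                      # units for persistence samples

    def _vals(self, g: Generator, what: str) -> float:
        if what == "persistence":
            return float(g.persistence) if self.units == "rank" else g.persistence_weight
        if what == "birth":
            return float(g.birth_step) if self.units == "rank" else g.birth_weight
        if what == "death":
            return float(g.death_step) if self.units == "rank" else g.death_weight
        raise ValueError(what)

    def pooled(self, what: str = "persistence", dimension: int = 1,
               include_zero_persistence: bool = False) -> np.ndarray:
        """Pooled sample across subjects; every generator is one
        observation (no per-subject weighting)."""
        out = []
        for gens in self.subject_generators:
            for g in gens:
                if g.dimension != dimension:
                    continue
                if g.zero_persistence and not include_zero_persistence:
                    continue
                out.append(self._vals(g, what))
        return np.asarray(out, dtype=float)

    def pooled_points(self, dimension: int = 1) -> np.ndarray:
        """Concatenated (birth, death) multiset, shape (n, 2)."""
        pts = [(self._vals(g, "birth"), self._vals(g, "death"))
               for gens in self.subject_generators for g in gens
               if g.dimension == dimension]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    @property
    def n_generators(self) -> int:
        return sum(len(g) for g in self.subject_generators)


def pooled_density(group: GroupSummary, variable: str = "persistence",
                   bins: int | np.ndarray = 30, log_bins: bool = False,
                   dimension: int = 1) -> pd.DataFrame:
    """Binned probability density of a pooled variable.

    ``variable`` is one of ``birth_death`` (joint, returned long-form with
    bin indices), ``persistence`` or ``birth``. Densities normalize to 1
    over the support; ``log10_density`` is NaN (missing), never -inf, on
    empty bins. ``log_bins`` uses log10-spaced bin edges (positive data
    only), the layout used for scaffold weight histograms.
    """
    if variable == "birth_death":
        pts = group.pooled_points(dimension)
        if pts.shape[0] == 0:
            raise ValueError(f"group {group.group_label!r} has no points")
        h, bx, by = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
        area = np.outer(np.diff(bx), np.diff(by))
        dens = h / h.sum() / area
        rows = []
        for i in range(h.shape[0]):
            for j in range(h.shape[1]):
                rows.append({
                    "birth_low": bx[i], "birth_high": bx[i + 1],
                    "death_low": by[j], "death_high": by[j + 1],
                    "count": h[i, j], "density": dens[i, j],
                    "log10_density": np.log10(dens[i, j]) if h[i, j] > 0 else np.nan,
                })
        return pd.DataFrame(rows)
    sample = group.pooled(variable, dimension)
    if sample.size == 0:
        raise ValueError(f"group {group.group_label!r} has no points")
    if log_bins:
        pos = sample[sample > 0]
        if pos.size == 0:
            raise ValueError("log-binning needs positive data")
        edges = np.logspace(np.log10(pos.min()), np.log10(pos.max()),
                            (bins if isinstance(bins, int) else len(bins)) + 1)
        sample = pos
    elif isinstance(bins, int):
        edges = np.histogram_bin_edges(sample, bins=bins)
    else:
        edges = np.asarray(bins, dtype=float)
    h, edges = np.histogram(sample, bins=edges)
    width = np.diff(edges)
    dens = h / h.sum() / width
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "count": h,
        "density": dens,
        "log10_density": np.where(h > 0, np.log10(np.where(h > 0, dens, 1.0)), np.nan),
    })


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test, D = sup |ECDF_a - ECDF_b|,
    asymptotic p-value, right-continuous ECDFs under ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    n1=a.size, n2=b.size)


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int
    degenerate: bool = False


def frequency_persistence_fit(freq: Scaffold, pers: Scaffold) -> tuple[FitResult, pd.DataFrame]:
    """OLS of persistence-scaffold weight on frequency-scaffold weight
    across the shared edge set; returns the fit and the per-edge scatter
    table. Mismatched edge sets are an error (the two scaffolds of one
    generator list always share an edge set); constant frequency is
    flagged degenerate."""
    fw, pw = freq.weights(), pers.weights()
    if set(fw) != set(pw):
        raise ValueError("frequency and persistence scaffolds have different edge sets")
    edges = sorted(fw)
    x = np.array([fw[e] for e in edges])
    y = np.array([pw[e] for e in edges])
    table = pd.DataFrame({
        "source": [e[0] for e in edges], "target": [e[1] for e in edges],
        "frequency": x, "persistence": y,
    })
    if x.size < 2 or np.ptp(x) == 0.0:
        return FitResult(np.nan, np.nan, np.nan, np.nan, x.size, degenerate=True), table
    res = stats.linregress(x, y)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2, stderr=float(res.stderr),
                     n=x.size), table


def slope_difference_test(fit_a: FitResult, fit_b: FitResult) -> tuple[float, float]:
    """t-test for equality of two regression slopes:
    t = (b_a - b_b) / sqrt(se_a^2 + se_b^2), df = n_a + n_b - 4,
    two-sided p."""
    if fit_a.degenerate or fit_b.degenerate:
        raise DegenerateFitError("cannot compare slopes of a degenerate fit")
    se = np.hypot(fit_a.stderr, fit_b.stderr)
    if se == 0.0:
        t = 0.0 if fit_a.slope == fit_b.slope else np.inf * np.sign(fit_a.slope - fit_b.slope)
    else:
        t = (fit_a.slope - fit_b.slope) / se
    df = fit_a.n + fit_b.n - 4
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), min(p, 1.0)


def modularity_communities(s: Scaffold, resolution: float = 1.0,
                           seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain modularity communities of a scaffold at the given
    resolution and seed; labels canonicalized by descending community
    size (ties broken by smallest member node position). Returns
    (node -> community, modularity)."""
    g = s.network.to_networkx()
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_nodes() == 0:
        raise ValueError("empty scaffold")
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=seed)
    pos = {n: i for i, n in enumerate(s.network.nodes)}
    comms = sorted(comms, key=lambda c: (-len(c), min(pos[n] for n in c)))
    part = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return part, float(q)


@dataclass
class CrossGroupEdgeReport:
    w_min: float
    n_edges_ref: int
    n_edges_other: int
    n_shared: int
    n_between_communities: int


def cross_group_edge_report(s_ref: Scaffold, s_other: Scaffold,
                            partition: dict[str, int],
                            w_min: float) -> CrossGroupEdgeReport:
    """Threshold both scaffolds at ``w_min`` and count surviving edges,
    shared edges, and surviving ``s_other`` edges whose endpoints lie in
    different communities of the reference partition."""
    if set(s_ref.network.nodes) != set(s_other.network.nodes):
        raise ValueError("scaffolds are on different node universes")
    ref_edges = {e for e, w in s_ref.weights().items() if w >= w_min}
    oth_edges = {e for e, w in s_other.weights().items() if w >= w_min}
    between = sum(1 for u, v in oth_edges
                  if partition.get(u) is not None and partition.get(v) is not None
                  and partition[u] != partition[v])
    return CrossGroupEdgeReport(
        w_min=w_min,
        n_edges_ref=len(ref_edges),
        n_edges_other=len(oth_edges),
        n_shared=len(ref_edges & oth_edges),
        n_between_communities=between,
    )


@dataclass
class ComparisonReport:
    """Full two-condition comparison: KS battery, per-group fits, slope
    test and optional cross-group edge counts."""

    group_a: str
    group_b: str
    ks_persistence: KSResult | None = None
    ks_birth: KSResult | None = None
    ks_scaffold_weights: KSResult | None = None
    ks_frequency_weights: KSResult | None = None
    fit_a: FitResult | None = None
    fit_b: FitResult | None = None
    slope_test: tuple[float, float] | None = None
    cross_edges: CrossGroupEdgeReport | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(x):
            if x is None or isinstance(x, (str, int, float, bool, list, tuple)):
                return x
            return asdict(x)
        return {
            "group_a": self.group_a, "group_b": self.group_b,
            "ks_persistence": conv(self.ks_persistence),
            "ks_birth": conv(self.ks_birth),
            "ks_scaffold_weights": conv(self.ks_scaffold_weights),
            "ks_frequency_weights": conv(self.ks_frequency_weights),
            "fit_a": conv(self.fit_a), "fit_b": conv(self.fit_b),
            "slope_test": self.slope_test,
            "cross_edges": conv(self.cross_edges),
            "notes": self.notes,
        }
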