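"""Signed partial-correlation networks from regional time series.

Given per-region mean time courses and a set of nuisance regressors
(motion parameters, CSF and white-matter signals), the connectivity
between regions i and j is the partial correlation conditioned on *all*
other regions and all nuisance regressors. It is computed in one linear
algebra step from the joint precision matrix P = C^-1:

    rho_ij = -P_ij / sqrt(P_ii P_jj)

restricted to the region rows/columns. Conditioning on the nuisance
series simultaneously with the regions is mathematically equivalent to
pre-regressing them out, since linear conditioning commutes; the joint
route keeps a single testable code path.

Non-neural rows/columns are dropped *after* the computation
(``drop_nonneural``): the conditioning on the dropped series is retained
in the remaining entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphio import WeightedNetwork

__all__ = ["TimeSeriesPanel", "PartialCorrelationMatrix", "RankDeficiencyError",
           "partial_correlation", "drop_nonneural"]

#: relative eigenvalue threshold below which the joint covariance is
#: declared rank-deficient
_SINGULAR_RTOL = 1e-10


class RankDeficiencyError(ValueError):
    """Joint covariance is singular; names the collinear columns."""


@dataclass
class TimeSeriesPanel:
    """Regional time courses plus nuisance regressors, column-aligned.

    All sequences share one length; labels are unique; values must be
    finite (validated at construction).
    """

    region_labels: list[str]
    series: np.ndarray          # (samples, n_regions)
    nuisance_labels: list[str] = field(default_factory=list)
    nuisance: np.ndarray | None = None   # (samples, n_nuisance)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != len(self.region_labels):
            raise ValueError("series must be (samples, n_regions)")
        if self.nuisance is None:
            self.nuisance = np.empty((self.series.shape[0], 0))
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.nuisance.shape != (self.series.shape[0], len(self.nuisance_labels)):
            raise ValueError("nuisance must be (samples, n_nuisance)")
        labels = self.region_labels + self.nuisance_labels
        if len(set(labels)) != len(labels):
            raise ValueError("region/nuisance labels are not unique")
        if not np.all(np.isfinite(self.series)) or not np.all(np.isfinite(self.nuisance)):
            raise ValueError("non-finite values in panel")

    @property
    def samples(self) -> int:
        return self.series.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path, nuisance_prefix: str = "nuis_") -> "TimeSeriesPanel":
        """Read a panel from CSV (first row = labels, one column per
        series); columns whose label starts with ``nuisance_prefix`` are
        nuisance regressors."""
        df = pd.read_csv(path)
        nuis_cols = [c for c in df.columns if str(c).startswith(nuisance_prefix)]
        reg_cols = [c for c in df.columns if c not in nuis_cols]
        return cls(
            region_labels=[str(c) for c in reg_cols],
            series=df[reg_cols].to_numpy(dtype=float),
            nuisance_labels=[str(c) for c in nuis_cols],
            nuisance=df[nuis_cols].to_numpy(dtype=float),
        )


@dataclass
class PartialCorrelationMatrix:
    """Symmetric matrix of region-by-region partial correlations with
    unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_network(self) -> WeightedNetwork:
        """Dense signed network on the region labels (diagonal dropped)."""
        net = WeightedNetwork.from_nodes(self.labels)
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                net.add_edge(self.labels[i], self.labels[j], float(self.values[i, j]),
                             create_nodes=False)
        return net

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.12g")


def _collinear_columns(cov: np.ndarray, labels: list[str]) -> list[str]:
    vals, vecs = np.linalg.eigh(cov)
    bad = vals <= _SINGULAR_RTOL * max(vals.max(), 1.0)
    names: list[str] = []
    for k in np.nonzero(bad)[0]:
        load = np.abs(vecs[:, k])
        for idx in np.nonzero(load > 0.1 * load.max())[0]:
            if labels[idx] not in names:
                names.append(labels[idx])
    return names


def partial_correlation(panel: TimeSeriesPanel, shrinkage: float = 0.0) -> PartialCorrelationMatrix:
    """Partial correlations among regions, conditioning on all other
    regions and all nuisance regressors via the joint precision matrix.

    ``shrinkage`` in [0, 1) mixes the sample covariance with its diagonal
    (C <- (1-s) C + s diag C) before inversion; the default 0 applies no
    regularization, and a rank-deficient covariance raises
    :class:`RankDeficiencyError` naming the collinear columns instead of
    silently ridging.
    """
    X = np.hstack([panel.series, panel.nuisance])
    labels = panel.region_labels + panel.nuisance_labels
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"need more samples than variables: {n} samples, {p} variables "
            f"({len(panel.region_labels)} regions + {len(panel.nuisance_labels)} nuisance)"
        )
    if not 0.0 <= shrinkage < 1.0:
        raise ValueError("shrinkage must be in [0, 1)")
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if shrinkage > 0.0:
        cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    vals = np.linalg.eigvalsh(cov)
    if vals.min() <= _SINGULAR_RTOL * max(vals.max(), 1.0):
        bad = _collinear_columns(cov, labels)
        raise RankDeficiencyError(
            "joint covariance is singular; collinear columns: " + ", ".join(bad)
        )
    P = np.linalg.inv(cov)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    k = len(panel.region_labels)
    rho = rho[:k, :k]
    rho = 0.5 * (rho + rho.T)          # symmetrize numerical noise
    np.fill_diagonal(rho, 1.0)
    return PartialCorrelationMatrix(labels=list(panel.region_labels), values=rho)


def drop_nonneural(matrix: PartialCorrelationMatrix,
                   drop_labels: list[str]) -> PartialCorrelationMatrix:
    """Discard non-neural rows/columns (CSF, white matter, motion) from a
    partial-correlation matrix *without* recomputing: the conditioning on
    the dropped series is deliberately retained. Remaining label order is
    preserved."""
    unknown = [l for l in drop_labels if l not in matrix.labels]
    if unknown:
        raise KeyError("unknown labels to drop: " + ", ".join(unknown))
    drop = set(drop_labels)
    keep_idx = [i for i, l in enumerate(matrix.labels) if l not in drop]
    keep_labels = [matrix.labels[i] for i in keep_idx]
    return PartialCorrelationMatrix(labels=keep_labels,
                                    values=matrix.values[np.ix_(keep_idx, keep_idx)])
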