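"""Functional connectomes and their pseudo-distance representation.

A functional connectome is the symmetric matrix of pairwise Pearson
correlations between regional time series.  The topology chain consumes the
pseudo-distance transform ``omega = 1 - r`` restricted to positive
correlations: a pair with ``r <= 0`` carries no coupling evidence and is
excluded from every filtration threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "FunctionalConnectome",
    "PseudoDistanceMatrix",
    "CentralityVector",
    "compute_fc",
    "to_pseudo_distance",
    "degree_centrality",
]


def _default_labels(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


@dataclasses.dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric Pearson-correlation matrix over labelled regions."""

    r: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if len(self.region_labels) != r.shape[0]:
            raise ValueError("region_labels length must match matrix size")
        if not np.all(np.isfinite(r)):
            raise ValueError("correlation matrix contains non-finite values")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(r > 1 + 1e-9) or np.any(r < -1 - 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    @classmethod
    def from_matrix(
        cls, r: np.ndarray, region_labels: Sequence[str] | None = None
    ) -> "FunctionalConnectome":
        r = np.asarray(r, dtype=float)
        labels = region_labels if region_labels is not None else _default_labels(r.shape[0])
        return cls(r=r, region_labels=tuple(labels))


@dataclasses.dataclass(frozen=True)
class PseudoDistanceMatrix:
    """``omega = 1 - r`` on retained (positive-r) pairs; others masked out.

    ``omega`` holds ``+inf`` on excluded pairs and on the diagonal so that an
    excluded edge is never present at any finite filtration threshold.
    """

    omega: np.ndarray
    mask: np.ndarray  # True where the pair is retained
    region_labels: tuple[str, ...]

    @property
    def n_regions(self) -> int:
        return self.omega.shape[0]

    def retained_edges(self) -> list[tuple[int, int, float]]:
        """All retained (i, j, omega) pairs with i < j."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        keep = self.mask[iu, ju]
        return list(
            zip(iu[keep].tolist(), ju[keep].tolist(), self.omega[iu, ju][keep].tolist())
        )


@dataclasses.dataclass(frozen=True)
class CentralityVector:
    """Normalized per-region centrality: values >= 0 summing to one."""

    values: np.ndarray
    kind: str  # "PC" | "DC"
    region_labels: tuple[str, ...]
    condition: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("centrality values must be nonnegative")
        total = v.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("centrality values must sum to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))


def compute_fc(
    data: np.ndarray, region_labels: Sequence[str] | None = None
) -> FunctionalConnectome:
    """Pearson correlation connectome from a (regions x timepoints) array.

    Raises if any series is constant (correlation undefined) or contains
    NaNs, naming the offending region.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (regions x timepoints) array")
    n_regions, n_t = x.shape
    labels = list(region_labels) if region_labels is not None else _default_labels(n_regions)
    if n_t < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    bad_nan = np.where(~np.all(np.isfinite(x), axis=1))[0]
    if bad_nan.size:
        raise ValueError(f"non-finite values in series for region {labels[bad_nan[0]]}")
    stds = x.std(axis=1)
    bad_const = np.where(stds == 0)[0]
    if bad_const.size:
        raise ValueError(f"constant time series for region {labels[bad_const[0]]}")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return FunctionalConnectome(r=r, region_labels=tuple(labels))


def to_pseudo_distance(G: FunctionalConnectome) -> PseudoDistanceMatrix:
    """``omega := 1 - r`` for positive-r pairs; pairs with r <= 0 excluded."""
    r = G.r
    n = G.n_regions
    mask = r > 0
    np.fill_diagonal(mask, False)
    omega = np.full_like(r, np.inf)
    omega[mask] = 1.0 - r[mask]
    return PseudoDistanceMatrix(omega=omega, mask=mask, region_labels=G.region_labels)


def degree_centrality(
    G: FunctionalConnectome, include_negative: bool = False
) -> CentralityVector:
    """DC(i) = sum_j r_ij / sum_{j,k} r_jk over off-diagonal ordered pairs.

    By default both sums run over the retained (positive) entries only, i.e.
    over the graph the topology chain actually analyses; pass
    ``include_negative=True`` to sum every off-diagonal entry.
    """
    r = G.r.copy()
    np.fill_diagonal(r, 0.0)
    if not include_negative:
        r = np.where(r > 0, r, 0.0)
    total = r.sum()
    if total <= 0:
        raise ValueError("degree centrality undefined: no positive total weight")
    values = r.sum(axis=1) / total
    return CentralityVector(values=values, kind="DC", region_labels=G.region_labels)
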