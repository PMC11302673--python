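"""Persistence homological scaffolds and persistence centrality.

The scaffold of one subject-condition barcode is the region x region network
whose edge weight is the summed persistence of every volume-optimal cycle
passing through that edge:  w_ij = sum over cycles g containing edge (i,j) of
pi_g = d_g - b_g.  Group scaffolds are entrywise means over subjects, and
persistence centrality is each region's normalized share of total scaffold
weight, PC(i) = sum_j w_ij / sum_{j,k} w_jk (ordered-pair denominator, so
that PC is a probability distribution over regions).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .connectome import CentralityVector
from .homology import PersistentFeature

__all__ = [
    "ScaffoldNetwork",
    "build_scaffold",
    "group_average",
    "persistence_centrality",
]


@dataclasses.dataclass(frozen=True)
class ScaffoldNetwork:
    """Symmetric nonnegative cycle-persistence network over regions."""

    w_pi: np.ndarray
    region_labels: tuple[str, ...]
    provenance: str = "subject-level"  # "subject-level" | "group-averaged"
    condition: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w_pi, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("scaffold matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("scaffold matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("scaffold weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("scaffold diagonal must be zero")
        object.__setattr__(self, "w_pi", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.w_pi.shape[0]

    @property
    def total_mass(self) -> float:
        """Sum of w_ij over unordered pairs (i < j)."""
        return float(np.triu(self.w_pi, k=1).sum())


def build_scaffold(
    features: Sequence[PersistentFeature],
    n_regions: int,
    region_labels: Sequence[str] | None = None,
    condition: str | None = None,
) -> ScaffoldNetwork:
    """Sum cycle persistences onto the edges of every optimal cycle."""
    labels = (
        tuple(region_labels)
        if region_labels is not None
        else tuple(f"R{i:03d}" for i in range(n_regions))
    )
    w = np.zeros((n_regions, n_regions))
    for feat in features:
        pi = feat.interval.persistence
        for (i, j) in feat.cycle_edges:
            if not (0 <= i < n_regions and 0 <= j < n_regions):
                raise ValueError(f"cycle edge ({i}, {j}) out of range for {n_regions} regions")
            w[i, j] += pi
            w[j, i] += pi
    return ScaffoldNetwork(
        w_pi=w, region_labels=labels, provenance="subject-level", condition=condition
    )


def group_average(scaffolds: Sequence[ScaffoldNetwork]) -> ScaffoldNetwork:
    """Entrywise arithmetic mean of subject-level scaffolds."""
    if not scaffolds:
        raise ValueError("need at least one scaffold")
    first = scaffolds[0]
    for s in scaffolds[1:]:
        if s.region_labels != first.region_labels:
            raise ValueError("scaffolds have mismatched region labels")
        if s.condition != first.condition:
            raise ValueError("scaffolds have mismatched conditions")
    w = np.mean([s.w_pi for s in scaffolds], axis=0)
    return ScaffoldNetwork(
        w_pi=w,
        region_labels=first.region_labels,
        provenance="group-averaged",
        condition=first.condition,
    )


def persistence_centrality(S: ScaffoldNetwork) -> CentralityVector:
    """PC(i) = sum_j w_ij / sum_{j,k} w_jk; sums over ordered off-diagonal pairs."""
    total = S.w_pi.sum()  # ordered-pair sum (symmetric, zero diagonal)
    if total <= 0:
        raise ValueError("persistence centrality undefined for an all-zero scaffold")
    values = S.w_pi.sum(axis=1) / total
    return CentralityVector(
        values=values, kind="PC", region_labels=S.region_labels, condition=S.condition
    )
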