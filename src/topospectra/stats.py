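"""Condition-difference vectors and comparison statistics.

Implements the statistics used to relate the topology and spectral chains:
task-minus-rest difference vectors, cosine similarity and angular difference,
Kendall's tau-b rank association, the Mann-Whitney U test (exact for small
samples, with midrank tie handling), and a cluster-based sign-flip
permutation paired t-test across ordered frequency bands with familywise
control via the maximal-cluster-mass null.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .connectome import CentralityVector
from .spectral import BandPowerRatios, THETA_ALPHA

__all__ = [
    "DeltaVector",
    "Cluster",
    "ClusterTestResult",
    "delta",
    "cosine_similarity",
    "angular_difference",
    "kendall_tau",
    "mann_whitney_u",
    "cluster_permutation_paired_t",
    "compare_modalities",
]


@dataclasses.dataclass(frozen=True)
class DeltaVector:
    """Task-minus-rest difference of a regional vector."""

    values: np.ndarray
    kind: str  # "dPC" | "dDC" | "dBPR"
    condition: str | None = None
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def delta(task, rest, condition: str | None = None):
    """Elementwise task - rest for centrality vectors or band-power ratios."""
    if isinstance(task, CentralityVector) and isinstance(rest, CentralityVector):
        if task.kind != rest.kind:
            raise ValueError(f"kind mismatch: {task.kind} vs {rest.kind}")
        if task.region_labels != rest.region_labels:
            raise ValueError("region label mismatch between task and rest")
        return DeltaVector(
            values=task.values - rest.values,
            kind=f"d{task.kind}",
            condition=condition,
            region_labels=task.region_labels,
        )
    if isinstance(task, BandPowerRatios) and isinstance(rest, BandPowerRatios):
        if task.band_edges != rest.band_edges:
            raise ValueError("band-edge mismatch between task and rest")
        if task.region_labels != rest.region_labels:
            raise ValueError("region label mismatch between task and rest")
        return DeltaVector(
            values=task.bpr - rest.bpr,
            kind="dBPR",
            condition=condition,
            region_labels=task.region_labels,
        )
    raise TypeError("task and rest must both be CentralityVector or BandPowerRatios")


def _as_array(u) -> np.ndarray:
    if isinstance(u, DeltaVector):
        return u.values
    return np.asarray(u, dtype=float)


def cosine_similarity(u, v) -> float:
    """Sum(u*v) / (||u|| ||v||); raises on zero vectors."""
    ua, va = _as_array(u).ravel(), _as_array(v).ravel()
    if ua.shape != va.shape:
        raise ValueError("vectors have different lengths")
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(ua, va) / (nu * nv), -1.0, 1.0))


def angular_difference(u, v) -> float:
    """arccos of the cosine similarity, in [0, pi] radians."""
    return float(math.acos(cosine_similarity(u, v)))


def kendall_tau(u, v) -> tuple[float, float]:
    """Kendall's tau-b with exact p for small untied samples, else asymptotic."""
    ua, va = _as_array(u), _as_array(v)
    if ua.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(ua == ua[0]) or np.all(va == va[0]):
        raise ValueError("Kendall's tau undefined for a constant vector")
    res = sstats.kendalltau(ua, va, variant="b", method="auto")
    return float(res.statistic), float(res.pvalue)


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by counting labelings over midranks.

    A dynamic program over (group size, doubled rank sum) counts, for every
    attainable rank sum, the number of ways to assign n of the pooled ranks to
    group x — exactly the enumeration of all C(n+m, n) labelings, including
    ties via midranks.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * sstats.rankdata(pooled)).astype(int)  # doubled midranks
    r_x = int(ranks2[:n].sum())
    total = int(ranks2.sum())
    max_s = total
    # dp[k][s] = number of k-subsets of pooled ranks with doubled rank sum s
    dp = np.zeros((n + 1, max_s + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n, n), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    counts = dp[n]
    n_total = counts.sum()  # == C(n+m, n)
    # U for group x from its rank sum; doubled to stay integral under ties
    u_obs2 = r_x - n * (n + 1)  # = 2 * U_x
    mid2 = n * m  # = 2 * (n*m/2)
    dev_obs = abs(u_obs2 - mid2)
    sums = np.arange(max_s + 1)
    u2 = sums - n * (n + 1)
    p = counts[np.abs(u2 - mid2) >= dev_obs - 1e-9].sum() / n_total
    return u_obs2 / 2.0, float(min(1.0, p))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact (enumerative, midrank ties) when n*m <= 400; otherwise the normal
    approximation with tie correction.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    if xa.size * ya.size <= 400:
        return _exact_u_pvalue(xa, ya)
    res = sstats.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class Cluster:
    """A maximal run of contiguous supra-threshold bands."""

    band_start: int
    band_stop: int  # inclusive
    mass: float
    p_value: float

    def overlaps_bands(self, band_indices: Sequence[int]) -> bool:
        return any(self.band_start <= b <= self.band_stop for b in band_indices)


@dataclasses.dataclass(frozen=True)
class ClusterTestResult:
    clusters: tuple[Cluster, ...]
    n_permutations: int
    exact: bool
    t_threshold: float
    t_observed: np.ndarray

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _paired_t_rows(d: np.ndarray) -> np.ndarray:
    """Per-column paired t over the first axis; +-inf where the sd is zero."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def _clusters_from_t(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous same-sign runs with |t| > thr; mass = sum of t."""
    out: list[tuple[int, int, float]] = []
    start = None
    sign = 0
    for i, ti in enumerate(list(t) + [0.0]):  # sentinel flushes the last run
        s = 0 if abs(ti) <= thr else (1 if ti > 0 else -1)
        if start is not None and s != sign:
            out.append((start, i - 1, float(t[start:i].sum())))
            start = None
        if s != 0 and start is None:
            start = i
            sign = s
    return out


def cluster_permutation_paired_t(
    a: np.ndarray,
    b: np.ndarray,
    threshold_p: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
    exact_max_n: int = 12,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation paired t-test across ordered bands.

    ``a`` and ``b`` are (n_conditions x n_bands) matrices of paired
    observations.  Per band a paired t statistic of ``a - b`` is formed;
    clusters are maximal contiguous runs of same-sign bands whose |t| exceeds
    the two-sided t threshold at ``threshold_p``.  The null flips the sign of
    whole condition-level difference rows: all 2^n flips are enumerated when
    n <= ``exact_max_n``, otherwise ``n_perm`` random flips are drawn.  Each
    cluster's p is the fraction of null maximal |cluster mass| values at least
    as large as its own (the observed flip counts).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired matrices must have the same shape")
    n, n_bands = a.shape
    if n < 2:
        raise ValueError("need at least 2 paired conditions")
    d = a - b
    thr = float(sstats.t.ppf(1.0 - threshold_p / 2.0, df=n - 1))
    t_obs = _paired_t_rows(d)
    obs_clusters = _clusters_from_t(t_obs, thr)

    exact = n <= exact_max_n
    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        signs[0] = 1.0  # observed labeling included in the null
    n_flips = signs.shape[0]

    # t for every flip from sufficient statistics: flipping rows changes the
    # mean but not the per-band sum of squares
    sum_sq = (d ** 2).sum(axis=0)
    means = signs @ d / n
    var = (sum_sq - n * means ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n)
        t_null = np.where(
            var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t_null
        )
    null_max = np.zeros(n_flips)
    for f in range(n_flips):
        runs = _clusters_from_t(t_null[f], thr)
        if runs:
            null_max[f] = max(abs(m) for _, _, m in runs)

    clusters = tuple(
        Cluster(
            band_start=s,
            band_stop=e,
            mass=m,
            p_value=float(
                (null_max >= abs(m) - max(1e-9 * abs(m), 1e-12)).sum() / n_flips
            ),
        )
        for s, e, m in obs_clusters
    )
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_flips,
        exact=exact,
        t_threshold=thr,
        t_observed=t_obs,
    )


def compare_modalities(
    pc_rest: CentralityVector,
    pc_tasks: dict[str, CentralityVector],
    dc_rest: CentralityVector,
    dc_tasks: dict[str, CentralityVector],
    bpr_rest: BandPowerRatios,
    bpr_tasks: dict[str, BandPowerRatios],
    threshold_p: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """Full cross-modal comparison report.

    Assembles per-task dPC, dDC and per-band dBPR; computes per-band absolute
    cosine similarities of dBPR with each centrality change, the
    condition-averaged curves, the cluster test contrasting them (when >= 2
    task conditions exist), and Kendall's tau of resting PC against each dPC.
    """
    tasks = sorted(pc_tasks)
    if sorted(dc_tasks) != tasks or sorted(bpr_tasks) != tasks:
        raise ValueError("task condition sets differ across modalities")
    if not tasks:
        raise ValueError("need at least one task condition")
    band_edges = bpr_rest.band_edges
    n_bands = len(band_edges)
    theta_alpha_bands = [
        k for k, (lo, hi) in enumerate(band_edges)
        if hi > THETA_ALPHA[0] and lo < THETA_ALPHA[1]
    ]

    cos_pc = np.zeros((len(tasks), n_bands))
    cos_dc = np.zeros((len(tasks), n_bands))
    kendall = {}
    d_pc = {}
    for ti, task in enumerate(tasks):
        dpc = delta(pc_tasks[task], pc_rest, condition=task)
        ddc = delta(dc_tasks[task], dc_rest, condition=task)
        dbpr = delta(bpr_tasks[task], bpr_rest, condition=task)
        d_pc[task] = dpc
        for band in range(n_bands):
            col = dbpr.values[:, band]
            cos_pc[ti, band] = cosine_similarity(col, dpc.values)
            cos_dc[ti, band] = cosine_similarity(col, ddc.values)
        kendall[task] = kendall_tau(pc_rest.values, dpc.values)

    report: dict = {
        "tasks": tasks,
        "band_edges": [list(b) for b in band_edges],
        "theta_alpha_bands": theta_alpha_bands,
        "cos_pc": cos_pc,
        "cos_dc": cos_dc,
        "abs_cos_pc_mean": np.abs(cos_pc).mean(axis=0),
        "abs_cos_dc_mean": np.abs(cos_dc).mean(axis=0),
        "kendall_rest_pc_vs_dpc": kendall,
        "cluster_test": None,
    }
    if len(tasks) >= 2:
        report["cluster_test"] = cluster_permutation_paired_t(
            np.abs(cos_pc), np.abs(cos_dc),
            threshold_p=threshold_p, n_perm=n_perm, seed=seed,
        )
    return report
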