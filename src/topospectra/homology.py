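"""Flag-complex persistent homology in dimension one, with volume-optimal cycles.

The filtration is the Vietoris--Rips (clique) filtration of a pseudo-distance
matrix: vertices at 0, edges at their pseudo-distance ``omega``, triangles at
the maximum of their three edge values.  The H1 barcode is computed over Z/2
by column reduction of the dimension-2 boundary matrix; H0 pairing (needed to
identify cycle-creating edges) uses a union-find sweep.

For each finite interval ``[b, d)`` a *volume-optimal* representative is
extracted: among all 2-chains ``tau`` over triangles born no later than ``d``
that contain the death triangle and whose mod-2 boundary uses only edges born
no later than ``b``, one minimizing the triangle count ``|tau|`` is found.
The search is formulated as a 0/1 program: a real linear-program relaxation
with oriented (integer) boundary coefficients is solved first and accepted
when integral; otherwise an exact parity integer program runs.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .connectome import PseudoDistanceMatrix

__all__ = [
    "FlagFiltration",
    "PersistenceInterval",
    "PersistentFeature",
    "Barcode",
    "build_flag_filtration",
    "compute_h1_barcode",
    "betti1_at",
    "volume_optimal_cycle",
    "brute_force_optimal_cycle",
]


@dataclasses.dataclass(frozen=True)
class FlagFiltration:
    """Vertices, edges and triangles of a clique filtration, in filtration order.

    Edges and triangles are stored sorted by (birth, lexicographic vertex
    tuple); since every face of a triangle has a birth value no larger than
    the triangle's, the global order (birth, dimension, lexicographic) is a
    valid filtration order.
    """

    n_vertices: int
    edges: tuple[tuple[int, int], ...]          # sorted (i, j), i < j
    edge_births: np.ndarray                     # aligned with edges
    triangles: tuple[tuple[int, int, int], ...]  # sorted (i, j, k), i < j < k
    triangle_births: np.ndarray                 # aligned with triangles
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edge_births", np.asarray(self.edge_births, dtype=float))
        object.__setattr__(
            self, "triangle_births", np.asarray(self.triangle_births, dtype=float)
        )

    @property
    def edge_index(self) -> dict[tuple[int, int], int]:
        cached = getattr(self, "_edge_index_cache", None)
        if cached is None:
            cached = {e: k for k, e in enumerate(self.edges)}
            object.__setattr__(self, "_edge_index_cache", cached)
        return cached

    def triangle_edge_ids(self) -> np.ndarray:
        """(n_triangles x 3) array of edge indices (ij, ik, jk) per triangle."""
        cached = getattr(self, "_tri_edge_cache", None)
        if cached is None:
            idx = self.edge_index
            cached = np.empty((len(self.triangles), 3), dtype=np.int64)
            for t, (i, j, k) in enumerate(self.triangles):
                cached[t, 0] = idx[(i, j)]
                cached[t, 1] = idx[(i, k)]
                cached[t, 2] = idx[(j, k)]
            object.__setattr__(self, "_tri_edge_cache", cached)
        return cached


@dataclasses.dataclass(frozen=True)
class PersistenceInterval:
    """A finite or infinite H1 interval ``[b, d)`` with its creator/destroyer."""

    birth: float
    death: float  # math.inf for unpaired cycles
    birth_edge: tuple[int, int]
    death_triangle: tuple[int, int, int] | None

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def finite(self) -> bool:
        return math.isfinite(self.death)


@dataclasses.dataclass(frozen=True)
class Barcode:
    """H1 intervals sorted by (birth, death); infinite intervals kept apart."""

    intervals: tuple[PersistenceInterval, ...]
    infinite_intervals: tuple[PersistenceInterval, ...] = ()
    dimension: int = 1

    def __len__(self) -> int:
        return len(self.intervals)


@dataclasses.dataclass(frozen=True)
class PersistentFeature:
    """A finite interval with its volume-optimal cycle and bounding 2-chain."""

    interval: PersistenceInterval
    cycle_edges: frozenset[tuple[int, int]]
    bounding_triangles: tuple[tuple[int, int, int], ...]

    @property
    def volume(self) -> int:
        return len(self.bounding_triangles)


def build_flag_filtration(D: PseudoDistanceMatrix, max_dim: int = 2) -> FlagFiltration:
    """Clique filtration of the retained-edge graph, up to triangles.

    Triangle birth = max of its three edge births (flag property).
    """
    if max_dim != 2:
        raise ValueError("only max_dim=2 (triangles) is supported")
    n = D.n_regions
    retained = D.retained_edges()
    edges = sorted(((b, (i, j)) for i, j, b in retained), key=lambda t: (t[0], t[1]))
    edge_list = tuple(e for _, e in edges)
    edge_births = np.array([b for b, _ in edges], dtype=float)

    # adjacency for triangle enumeration
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _ in retained:
        adj[i].add(j)
        adj[j].add(i)
    omega = D.omega
    tris: list[tuple[float, tuple[int, int, int]]] = []
    for i in range(n):
        nbr_i = adj[i]
        for j in sorted(v for v in nbr_i if v > i):
            common = nbr_i & adj[j]
            for k in sorted(v for v in common if v > j):
                birth = max(omega[i, j], omega[i, k], omega[j, k])
                tris.append((birth, (i, j, k)))
    tris.sort(key=lambda t: (t[0], t[1]))
    return FlagFiltration(
        n_vertices=n,
        edges=edge_list,
        edge_births=edge_births,
        triangles=tuple(t for _, t in tris),
        triangle_births=np.array([b for b, _ in tris], dtype=float),
        region_labels=D.region_labels,
    )


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _positive_edges(F: FlagFiltration) -> np.ndarray:
    """Boolean mask over edges: True where the edge creates a 1-cycle."""
    uf = _UnionFind(F.n_vertices)
    pos = np.zeros(len(F.edges), dtype=bool)
    for k, (i, j) in enumerate(F.edges):
        pos[k] = not uf.union(i, j)
    return pos


def compute_h1_barcode(F: FlagFiltration, return_representatives: bool = False):
    """H1 persistence pairs over Z/2 by reduction of the triangle boundary matrix.

    Zero-persistence pairs (b == d) are discarded.  Cycle-creating edges never
    killed by a triangle are reported as infinite intervals.  With
    ``return_representatives=True`` also returns, per finite interval, the
    (non-optimized) representative cycle read off the reduced column.
    """
    if np.any(np.diff(F.edge_births) < 0) or np.any(np.diff(F.triangle_births) < 0):
        raise ValueError("filtration simplices are not sorted by birth")
    n_edges = len(F.edges)
    pos = _positive_edges(F)
    # columns as Python-int bitsets over edge indices; low = highest set bit
    low_to_col: dict[int, int] = {}
    reduced_cols: list[int] = []
    pairs: list[tuple[int, int]] = []  # (edge index, triangle index)
    tri_edge_ids = F.triangle_edge_ids()
    for t in range(len(F.triangles)):
        e0, e1, e2 = tri_edge_ids[t]
        col = (1 << int(e0)) | (1 << int(e1)) | (1 << int(e2))
        while col:
            lw = col.bit_length() - 1
            other = low_to_col.get(lw)
            if other is None:
                break
            col ^= reduced_cols[other]
        reduced_cols.append(col)
        if col:
            lw = col.bit_length() - 1
            low_to_col[lw] = t
            pairs.append((lw, t))

    finite: list[PersistenceInterval] = []
    reps: list[frozenset[tuple[int, int]]] = []
    paired_edges = set()
    for e_idx, t_idx in pairs:
        paired_edges.add(e_idx)
        b = float(F.edge_births[e_idx])
        d = float(F.triangle_births[t_idx])
        if d <= b:  # zero-persistence (b == d under valid filtrations)
            continue
        finite.append(
            PersistenceInterval(
                birth=b,
                death=d,
                birth_edge=F.edges[e_idx],
                death_triangle=F.triangles[t_idx],
            )
        )
        if return_representatives:
            col = reduced_cols[t_idx]
            cyc = frozenset(
                F.edges[k] for k in range(n_edges) if (col >> k) & 1
            )
            reps.append(cyc)
    infinite = tuple(
        PersistenceInterval(
            birth=float(F.edge_births[k]),
            death=math.inf,
            birth_edge=F.edges[k],
            death_triangle=None,
        )
        for k in range(n_edges)
        if pos[k] and k not in paired_edges
    )
    order = sorted(range(len(finite)), key=lambda i: (finite[i].birth, finite[i].death))
    barcode = Barcode(
        intervals=tuple(finite[i] for i in order),
        infinite_intervals=tuple(sorted(infinite, key=lambda iv: iv.birth)),
    )
    if return_representatives:
        return barcode, [reps[i] for i in order]
    return barcode


def betti1_at(barcode: Barcode, t: float) -> int:
    """Number of independent 1-cycles alive at threshold ``t`` (b <= t < d)."""
    count = sum(1 for iv in barcode.intervals if iv.birth <= t < iv.death)
    count += sum(1 for iv in barcode.infinite_intervals if iv.birth <= t)
    return count


# ---------------------------------------------------------------------------
# volume-optimal representative cycles
# ---------------------------------------------------------------------------

#: diagnostic counter for how often the LP relaxation was fractional and the
#: exact parity program had to run; read (and reset) by the pipeline log
solver_counts = {"lp_to_ilp_fallbacks": 0}


def _candidate_system(F: FlagFiltration, interval: PersistenceInterval):
    """Candidate triangles (birth <= d) and forbidden edges (birth > b)."""
    if not interval.finite:
        raise ValueError("volume-optimal cycles are defined for finite intervals only")
    b, d = interval.birth, interval.death
    cand = np.where(F.triangle_births <= d)[0]
    death_idx = F.triangles.index(interval.death_triangle)
    if death_idx not in cand:
        raise RuntimeError("death triangle missing from candidate set")
    tri_edge_ids = F.triangle_edge_ids()[cand]
    forbidden = F.edge_births > b  # per edge index
    return cand, death_idx, tri_edge_ids, forbidden


def _chain_boundary_edges(
    F: FlagFiltration, triangles: Iterable[tuple[int, int, int]]
) -> frozenset[tuple[int, int]]:
    """Mod-2 boundary of a set of triangles as an edge set."""
    count: dict[tuple[int, int], int] = {}
    for (i, j, k) in triangles:
        for e in ((i, j), (i, k), (j, k)):
            count[e] = count.get(e, 0) + 1
    return frozenset(e for e, c in count.items() if c % 2 == 1)


def _feature_from_support(
    F: FlagFiltration,
    interval: PersistenceInterval,
    support: Sequence[tuple[int, int, int]],
) -> PersistentFeature:
    cycle = _chain_boundary_edges(F, support)
    if not cycle:
        raise RuntimeError("bounding chain has empty boundary; not a valid cycle")
    births = {e: float(F.edge_births[k]) for k, e in enumerate(F.edges)}
    if any(births[e] > interval.birth + 1e-12 for e in cycle):
        raise RuntimeError("optimal-cycle boundary leaks outside the birth complex")
    return PersistentFeature(
        interval=interval,
        cycle_edges=cycle,
        bounding_triangles=tuple(sorted(support)),
    )


def brute_force_optimal_cycle(
    F: FlagFiltration, interval: PersistenceInterval, max_candidates: int = 20
) -> PersistentFeature:
    """Exhaustive minimum-volume bounding chain; oracle for the LP/ILP route.

    Refuses when more than ``max_candidates`` triangles are born by the death
    value (2^20 enumeration cap).
    """
    cand, death_idx, tri_edge_ids, forbidden = _candidate_system(F, interval)
    if len(cand) > max_candidates:
        raise ValueError(
            f"{len(cand)} candidate triangles exceed the enumeration cap "
            f"({max_candidates})"
        )
    others = [t for t in cand if t != death_idx]
    best: list[int] | None = None
    for size in range(0, len(others) + 1):
        if best is not None:
            break
        for combo in itertools.combinations(others, size):
            support_idx = (death_idx,) + combo
            tris = [F.triangles[t] for t in support_idx]
            cycle = _chain_boundary_edges(F, tris)
            if not cycle:
                continue
            idx = F.edge_index
            if any(forbidden[idx[e]] for e in cycle):
                continue
            best = list(support_idx)
            break
    if best is None:
        raise RuntimeError("no admissible bounding chain found (invalid pair?)")
    return _feature_from_support(F, interval, [F.triangles[t] for t in best])


def volume_optimal_cycle(
    F: FlagFiltration,
    interval: PersistenceInterval,
    method: str = "auto",
) -> PersistentFeature:
    """Minimum-triangle-count bounding chain containing the death triangle.

    ``method='auto'`` tries the real LP relaxation (oriented coefficients,
    death-triangle coefficient fixed to 1) and accepts integral, parity-
    feasible solutions; otherwise (or with ``method='ilp'``) solves the exact
    0/1 parity program with HiGHS.
    """
    cand, death_idx, tri_edge_ids, forbidden = _candidate_system(F, interval)
    # (ij, ik, jk) edge ids per candidate, aligned with `cand`
    death_pos = int(np.where(cand == death_idx)[0][0])

    # quick win: the death triangle alone is a valid chain when its own
    # boundary lies inside the birth complex
    death_edges = tri_edge_ids[death_pos]
    n_forb_death = int(forbidden[death_edges].sum())
    if n_forb_death == 0:
        return _feature_from_support(F, interval, [F.triangles[death_idx]])
    if n_forb_death == 1:
        # a two-triangle chain is possible only by cancelling the single
        # forbidden edge against a partner triangle whose other edges are
        # admissible (two distinct triangles share at most one edge)
        bad_edge = int(death_edges[forbidden[death_edges]][0])
        partners = np.where((tri_edge_ids == bad_edge).any(axis=1))[0]
        for p in partners:
            if p == death_pos:
                continue
            others = [int(e) for e in tri_edge_ids[p] if int(e) != bad_edge]
            if not forbidden[others].any():
                return _feature_from_support(
                    F, interval,
                    [F.triangles[death_idx], F.triangles[int(cand[p])]],
                )

    # only forbidden edges actually incident to a candidate triangle constrain
    touched = np.unique(tri_edge_ids)
    forb_rows = touched[forbidden[touched]]
    forb_pos = {int(e): r for r, e in enumerate(forb_rows)}

    if method not in ("auto", "ilp"):
        raise ValueError("method must be 'auto' or 'ilp'")

    if method == "auto":
        feature = _lp_relaxation(
            F, interval, cand, death_pos, tri_edge_ids, forbidden, forb_pos
        )
        if feature is not None:
            return feature
        solver_counts["lp_to_ilp_fallbacks"] += 1
    return _parity_ilp(F, interval, cand, death_pos, tri_edge_ids, forbidden, forb_pos)


def _lp_relaxation(F, interval, cand, death_pos, tri_edge_ids, forbidden, forb_pos):
    """Real relaxation with oriented coefficients; None when fractional."""
    n_cand = len(cand)
    free = [p for p in range(n_cand) if p != death_pos]
    if not free:
        return None
    rhs = np.zeros(len(forb_pos))
    signs = (1.0, -1.0, 1.0)  # oriented boundary of (i<j<k): +[ij] -[ik] +[jk]
    # the fixed death coefficient (z = 1) moves to the right-hand side
    for s, e in zip(signs, tri_edge_ids[death_pos]):
        r = forb_pos.get(int(e))
        if r is not None:
            rhs[r] -= s
    pos_of = {p: q for q, p in enumerate(free)}
    rows, cols, data = [], [], []
    for p in free:
        for s, e in zip(signs, tri_edge_ids[p]):
            r = forb_pos.get(int(e))
            if r is None:
                continue
            rows.append(r)
            cols.append(pos_of[p])
            data.append(s)
    n_free = len(free)
    if rows:
        A = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(forb_pos), n_free)
        )
    else:
        A = sparse.csr_matrix((len(forb_pos), n_free))
    # z = u - v, u,v >= 0; minimize sum(u + v)
    A_eq = sparse.hstack([A, -A], format="csr")
    c = np.ones(2 * n_free)
    res = linprog(c, A_eq=A_eq, b_eq=rhs, bounds=(0, None), method="highs")
    if not res.success:
        return None
    z = res.x[:n_free] - res.x[n_free:]
    z_round = np.round(z)
    if np.max(np.abs(z - z_round)) > 1e-6:
        return None
    support = [cand[p] for p, zr in zip(free, z_round) if zr != 0]
    support.append(cand[death_pos])
    tris = [F.triangles[int(t)] for t in support]
    cycle = _chain_boundary_edges(F, tris)
    if not cycle:
        return None
    idx = F.edge_index
    if any(forbidden[idx[e]] for e in cycle):
        return None
    if len(tris) - 1 > res.fun + 1e-6:  # rounding inflated the objective
        return None
    return _feature_from_support(F, interval, tris)


def _parity_ilp(
    F, interval, cand, death_pos, tri_edge_ids, forbidden, forb_pos,
    force_birth_edge: bool = False,
):
    """Exact 0/1 program: parity of every forbidden edge's incidence is even."""
    n_cand = len(cand)
    n_forb = len(forb_pos)
    rows, cols, data = [], [], []
    for p in range(n_cand):
        for e in tri_edge_ids[p]:
            r = forb_pos.get(int(e))
            if r is not None:
                rows.append(r)
                cols.append(p)
                data.append(1.0)
    extra_rows = 0
    birth_edge_id = F.edge_index[interval.birth_edge]
    if force_birth_edge:
        for p in range(n_cand):
            if birth_edge_id in set(int(e) for e in tri_edge_ids[p]):
                rows.append(n_forb)
                cols.append(p)
                data.append(1.0)
        extra_rows = 1
    n_rows = n_forb + extra_rows
    # slack integers y: incidence - 2y = 0 (forbidden) / = 1 (birth edge odd)
    for r in range(n_rows):
        rows.append(r)
        cols.append(n_cand + r)
        data.append(-2.0)
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n_rows, n_cand + n_rows))
    rhs = np.zeros(n_rows)
    if force_birth_edge:
        rhs[n_forb] = 1.0
    lb = np.zeros(n_cand + n_rows)
    ub = np.concatenate([np.ones(n_cand), np.full(n_rows, np.inf)])
    lb[death_pos] = 1.0
    c = np.concatenate([np.ones(n_cand), np.zeros(n_rows)])
    res = milp(
        c=c,
        constraints=LinearConstraint(A, rhs, rhs),
        integrality=np.ones(n_cand + n_rows),
        bounds=Bounds(lb, ub),
    )
    if res.status != 0:
        raise RuntimeError(
            f"optimal-cycle integer program infeasible for interval "
            f"[{interval.birth}, {interval.death}) — invalid persistence pair?"
        )
    z = np.round(res.x[:n_cand]).astype(int)
    support = [F.triangles[int(cand[p])] for p in range(n_cand) if z[p] == 1]
    cycle = _chain_boundary_edges(F, support)
    if not cycle and not force_birth_edge:
        # degenerate optimum is a 2-cycle (e.g. tetrahedron shell); force the
        # representative through the birth edge instead
        return _parity_ilp(
            F, interval, cand, death_pos, tri_edge_ids, forbidden, forb_pos,
            force_birth_edge=True,
        )
    return _feature_from_support(F, interval, support)


def extract_features(
    F: FlagFiltration, barcode: Barcode, method: str = "auto"
) -> list[PersistentFeature]:
    """Volume-optimal features for every finite interval of a barcode."""
    return [volume_optimal_cycle(F, iv, method=method) for iv in barcode.intervals]
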