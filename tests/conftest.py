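"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from topospectra.connectome import FunctionalConnectome, to_pseudo_distance
from topospectra.homology import build_flag_filtration
from topospectra.synth import fixture_ring_connectome


def random_connectome(rng: np.random.Generator, n: int) -> FunctionalConnectome:
    """A random valid correlation matrix with a spread of signs and ties."""
    x = rng.standard_normal((n, max(3, n // 2 + 2)))
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome.from_matrix(np.clip((r + r.T) / 2, -1, 1))


def gf2_rank(matrix: np.ndarray) -> int:
    """Rank over GF(2) by plain Gaussian elimination (independent oracle)."""
    m = (np.asarray(matrix) % 2).astype(np.uint8).copy()
    rank = 0
    n_rows, n_cols = m.shape
    for col in range(n_cols):
        pivot = None
        for row in range(rank, n_rows):
            if m[row, col]:
                pivot = row
                break
        if pivot is None:
            continue
        m[[rank, pivot]] = m[[pivot, rank]]
        for row in range(n_rows):
            if row != rank and m[row, col]:
                m[row] ^= m[rank]
        rank += 1
        if rank == n_rows:
            break
    return rank


def betti1_direct(G: FunctionalConnectome, t: float) -> int:
    """dim ker d1 - rank d2 of the clique complex at threshold t.

    Builds the boundary matrices of the complex explicitly and computes ranks
    over GF(2) — no filtration, no pairing; a from-scratch check of the
    barcode-based Betti count.
    """
    D = to_pseudo_distance(G)
    n = D.n_regions
    edges = [(i, j) for i, j, w in D.retained_edges() if w <= t]
    if not edges:
        return 0
    eidx = {e: k for k, e in enumerate(edges)}
    present = set(edges)
    d1 = np.zeros((n, len(edges)), dtype=np.uint8)
    for k, (i, j) in enumerate(edges):
        d1[i, k] = d1[j, k] = 1
    tris = [
        (i, j, k)
        for i, j, k in itertools.combinations(range(n), 3)
        if (i, j) in present and (i, k) in present and (j, k) in present
    ]
    rank_d1 = gf2_rank(d1)
    dim_ker_d1 = len(edges) - rank_d1
    if not tris:
        return dim_ker_d1
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for c, (i, j, k) in enumerate(tris):
        d2[eidx[(i, j)], c] = d2[eidx[(i, k)], c] = d2[eidx[(j, k)], c] = 1
    return dim_ker_d1 - gf2_rank(d2)


@pytest.fixture
def four_ring():
    """The analytic 4-ring connectome: ring r=0.6, chords r=0.2."""
    return fixture_ring_connectome(4, 0.6, 0.2)


@pytest.fixture
def four_ring_filtration(four_ring):
    return build_flag_filtration(to_pseudo_distance(four_ring))
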