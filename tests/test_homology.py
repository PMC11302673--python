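import math

import numpy as np
import pytest

from topospectra.connectome import FunctionalConnectome, to_pseudo_distance
from topospectra.homology import (
    betti1_at,
    brute_force_optimal_cycle,
    build_flag_filtration,
    compute_h1_barcode,
    extract_features,
    volume_optimal_cycle,
)
from topospectra.synth import fixture_ring_connectome

from conftest import betti1_direct, random_connectome


def filtration_of(r: np.ndarray):
    return build_flag_filtration(
        to_pseudo_distance(FunctionalConnectome.from_matrix(r))
    )


class TestFlagFiltration:
    def test_four_ring_simplex_census(self, four_ring_filtration):
        F = four_ring_filtration
        assert np.sum(F.edge_births == 0.4) == 4
        assert np.sum(F.edge_births == 0.8) == 2
        assert len(F.triangles) == 4
        assert np.all(F.triangle_births == 0.8)

    def test_single_edge_has_no_triangles(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.5
        F = filtration_of(r)
        assert len(F.edges) == 1
        assert len(F.triangles) == 0

    def test_complete_equal_weight_graph(self):
        n = 6
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 1.0)
        F = filtration_of(r)
        assert len(F.triangles) == math.comb(n, 3)
        assert np.all(F.triangle_births == 0.5)

    def test_triangle_birth_is_max_edge_birth(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            G = random_connectome(rng, 8)
            D = to_pseudo_distance(G)
            F = build_flag_filtration(D)
            births = {e: b for e, b in zip(F.edges, F.edge_births)}
            for (i, j, k), b in zip(F.triangles, F.triangle_births):
                assert b == max(births[(i, j)], births[(i, k)], births[(j, k)])


class TestBarcode:
    def test_four_ring_single_interval(self, four_ring_filtration):
        bc = compute_h1_barcode(four_ring_filtration)
        assert len(bc.intervals) == 1
        iv = bc.intervals[0]
        assert (iv.birth, iv.death) == (0.4, 0.8)
        assert not bc.infinite_intervals

    def test_tree_graph_has_empty_barcode(self):
        r = np.eye(5)
        for i in range(4):  # path graph
            r[i, i + 1] = r[i + 1, i] = 0.5
        bc = compute_h1_barcode(filtration_of(r))
        assert len(bc.intervals) == 0
        assert len(bc.infinite_intervals) == 0

    def test_two_disjoint_rings(self):
        # blocks joined by zero correlation (excluded edges)
        r = np.zeros((8, 8))
        a = fixture_ring_connectome(4, 0.6, 0.2).r
        b = fixture_ring_connectome(4, 0.5, 0.3).r
        r[:4, :4] = a
        r[4:, 4:] = b
        np.fill_diagonal(r, 1.0)
        bc = compute_h1_barcode(filtration_of(r))
        assert sorted((iv.birth, iv.death) for iv in bc.intervals) == [
            (0.4, 0.8),
            (0.5, 0.7),
        ]

    def test_unfilled_ring_yields_infinite_interval(self):
        # ring whose chords are negative: no triangles ever form
        r = np.full((4, 4), -0.3)
        for i in range(4):
            j = (i + 1) % 4
            r[i, j] = r[j, i] = 0.6
        np.fill_diagonal(r, 1.0)
        bc = compute_h1_barcode(filtration_of(r))
        assert len(bc.intervals) == 0
        assert len(bc.infinite_intervals) == 1
        assert betti1_at(bc, 0.99) == 1

    def test_betti1_at_examples(self, four_ring_filtration):
        bc = compute_h1_barcode(four_ring_filtration)
        assert betti1_at(bc, 0.5) == 1
        assert betti1_at(bc, 0.3) == 0
        assert betti1_at(bc, 0.8) == 0  # death threshold excluded

    def test_interval_endpoints_are_input_distances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            G = random_connectome(rng, 9)
            D = to_pseudo_distance(G)
            values = {w for *_, w in D.retained_edges()}
            bc = compute_h1_barcode(build_flag_filtration(D))
            for iv in bc.intervals:
                assert iv.birth in values and iv.death in values

    def test_betti_matches_rank_nullity_small(self):
        # spot check against the direct boundary-rank oracle (full sweep in
        # the acceptance tests)
        rng = np.random.default_rng(21)
        for _ in range(20):
            G = random_connectome(rng, 7)
            D = to_pseudo_distance(G)
            bc = compute_h1_barcode(build_flag_filtration(D))
            thresholds = sorted({w for *_, w in D.retained_edges()})
            for t in thresholds:
                assert betti1_at(bc, t) == betti1_direct(G, t)


class TestVolumeOptimalCycles:
    def test_four_ring_cycle_and_volume(self, four_ring_filtration):
        bc = compute_h1_barcode(four_ring_filtration)
        feat = volume_optimal_cycle(four_ring_filtration, bc.intervals[0])
        assert feat.cycle_edges == {(0, 1), (1, 2), (2, 3), (0, 3)}
        assert feat.volume == 2
        assert feat.interval.death_triangle in feat.bounding_triangles

    def test_brute_force_matches_on_four_ring(self, four_ring_filtration):
        bc = compute_h1_barcode(four_ring_filtration)
        feat = brute_force_optimal_cycle(four_ring_filtration, bc.intervals[0])
        assert feat.volume == 2
        assert feat.cycle_edges == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_brute_force_refuses_large_candidate_sets(self):
        n = 8  # C(8,3) = 56 candidate triangles
        r = np.full((n, n), 0.3)
        for i in range(n):
            j = (i + 1) % n
            r[i, j] = r[j, i] = 0.7
        np.fill_diagonal(r, 1.0)
        F = filtration_of(r)
        bc = compute_h1_barcode(F)
        with pytest.raises(ValueError, match="cap"):
            brute_force_optimal_cycle(F, bc.intervals[0])

    def test_infinite_interval_rejected(self):
        r = np.full((4, 4), -0.3)
        for i in range(4):
            j = (i + 1) % 4
            r[i, j] = r[j, i] = 0.6
        np.fill_diagonal(r, 1.0)
        F = filtration_of(r)
        bc = compute_h1_barcode(F)
        with pytest.raises(ValueError, match="finite"):
            volume_optimal_cycle(F, bc.infinite_intervals[0])

    def test_chorded_six_ring_shorter_than_reduction_representative(self):
        # one chord splits the 6-ring into a 3-loop and a 5-loop; the 3-loop
        # fills the moment the chord appears (zero persistence, discarded),
        # the surviving interval's optimal cycle must not exceed the plain
        # reduction representative in edge count
        r = np.full((6, 6), 0.15)
        for i in range(6):
            j = (i + 1) % 6
            r[i, j] = r[j, i] = 0.7
        r[0, 2] = r[2, 0] = 0.6  # chord
        np.fill_diagonal(r, 1.0)
        F = filtration_of(r)
        bc, reps = compute_h1_barcode(F, return_representatives=True)
        assert len(bc.intervals) == 1
        for iv, rep in zip(bc.intervals, reps):
            feat = volume_optimal_cycle(F, iv)
            assert len(feat.cycle_edges) <= len(rep)
            # the chord (born after b) cannot appear in the cycle
            assert (0, 2) not in feat.cycle_edges

    def test_lp_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        n_checked = 0
        for _ in range(60):
            G = random_connectome(rng, 7)
            D = to_pseudo_distance(G)
            F = build_flag_filtration(D)
            bc = compute_h1_barcode(F)
            for iv in bc.intervals:
                cand = int(np.sum(F.triangle_births <= iv.death))
                if cand > 20:
                    continue
                auto = volume_optimal_cycle(F, iv, method="auto")
                exact = volume_optimal_cycle(F, iv, method="ilp")
                oracle = brute_force_optimal_cycle(F, iv)
                assert auto.volume == exact.volume == oracle.volume
                n_checked += 1
        assert n_checked >= 10

    def test_feature_invariants_on_random_inputs(self):
        rng = np.random.default_rng(29)
        births = lambda F: dict(zip(F.edges, F.edge_births))
        for _ in range(10):
            G = random_connectome(rng, 8)
            D = to_pseudo_distance(G)
            F = build_flag_filtration(D)
            bc = compute_h1_barcode(F)
            eb = births(F)
            tb = dict(zip(F.triangles, F.triangle_births))
            for feat in extract_features(F, bc):
                iv = feat.interval
                # boundary of the bounding chain equals the cycle (mod 2)
                count = {}
                for (i, j, k) in feat.bounding_triangles:
                    for e in ((i, j), (i, k), (j, k)):
                        count[e] = count.get(e, 0) + 1
                boundary = {e for e, c in count.items() if c % 2}
                assert boundary == feat.cycle_edges
                assert feat.cycle_edges  # nonempty Z/2 cycle
                assert all(eb[e] <= iv.birth for e in feat.cycle_edges)
                assert all(tb[t] <= iv.death for t in feat.bounding_triangles)
                assert iv.death_triangle in feat.bounding_triangles
                # even degree at every vertex
                deg = {}
                for (i, j) in feat.cycle_edges:
                    deg[i] = deg.get(i, 0) + 1
                    deg[j] = deg.get(j, 0) + 1
                assert all(d % 2 == 0 for d in deg.values())

    def test_perturbation_stability(self):
        # on tie-free inputs, noise smaller than half the minimum gap between
        # distinct omega values (1.0 included: an edge must not change sign)
        # must not change any interval's simplex identity
        rng = np.random.default_rng(13)
        n_checked = 0
        for _ in range(20):
            G = random_connectome(rng, 8)
            D = to_pseudo_distance(G)
            values = sorted({w for *_, w in D.retained_edges()} | {1.0})
            if len(values) < 2:
                continue
            gaps = np.diff(values)
            if gaps.min() < 1e-9:  # effectively tied; identity not unique
                continue
            eps = gaps.min() / 2.0
            F0 = build_flag_filtration(D)
            bc0 = compute_h1_barcode(F0)
            if not bc0.intervals:
                continue
            noise = rng.uniform(-eps / 2, eps / 2, size=G.r.shape)
            noise = (noise + noise.T) / 2
            r = np.clip(G.r + noise, -1, 1)
            np.fill_diagonal(r, 1.0)
            bc1 = compute_h1_barcode(
                build_flag_filtration(
                    to_pseudo_distance(FunctionalConnectome.from_matrix(r))
                )
            )
            assert [iv.birth_edge for iv in bc1.intervals] == [
                iv.birth_edge for iv in bc0.intervals
            ]
            assert [iv.death_triangle for iv in bc1.intervals] == [
                iv.death_triangle for iv in bc0.intervals
            ]
            n_checked += 1
        assert n_checked >= 5
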