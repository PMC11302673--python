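import itertools
import math

import numpy as np
import pytest

from topospectra.connectome import CentralityVector
from topospectra.spectral import BandPowerRatios
from topospectra.stats import (
    angular_difference,
    cluster_permutation_paired_t,
    compare_modalities,
    cosine_similarity,
    delta,
    kendall_tau,
    mann_whitney_u,
)


def kendall_brute_force(u, v):
    """tau-b by explicit concordant/discordant pair counting."""
    n = len(u)
    conc = disc = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(u[i] - u[j])
        b = np.sign(v[i] - v[j])
        if a == 0 and b == 0:
            continue
        if a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - _tie_term(u)) * (n0 - _tie_term(v)))


def _tie_term(x):
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(x).values())


def mwu_brute_force(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    from scipy.stats import rankdata

    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    obs_u = ranks[:n].sum() - n * (n + 1) / 2
    mid = n * m / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mid) >= abs(obs_u - mid) - 1e-9:
            count += 1
    return obs_u, count / total


class TestDelta:
    def _cv(self, values, kind="PC"):
        v = np.asarray(values, dtype=float)
        return CentralityVector(
            values=v / v.sum(), kind=kind,
            region_labels=tuple(f"R{i}" for i in range(len(v))),
        )

    def test_identical_gives_zero(self):
        c = self._cv([1, 2, 3])
        assert np.all(delta(c, c).values == 0)

    def test_unit_sum_vectors_give_zero_sum_delta(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = self._cv(rng.uniform(0.1, 1, 6))
            b = self._cv(rng.uniform(0.1, 1, 6))
            assert delta(a, b).values.sum() == pytest.approx(0.0, abs=1e-10)

    def test_elementwise_subtraction(self):
        a = self._cv([2, 1, 1])
        b = self._cv([1, 1, 2])
        assert delta(a, b).values == pytest.approx([0.25, 0.0, -0.25])

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            delta(self._cv([1, 2], "PC"), self._cv([1, 2], "DC"))

    def test_bpr_delta(self):
        mk = lambda v: BandPowerRatios(
            band_edges=((4.0, 12.0),), bpr=np.array([[v]]), region_labels=("R0",)
        )
        d = delta(mk(0.3), mk(0.1))
        assert d.values[0, 0] == pytest.approx(0.2)
        assert d.kind == "dBPR"


class TestCosine:
    def test_parallel_orthogonal_antipodal(self):
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity(u, v) == pytest.approx(0.0)
        assert angular_difference(u, v) == pytest.approx(math.pi / 2)
        assert cosine_similarity(u, -u) == pytest.approx(-1.0)
        assert angular_difference(u, -u) == pytest.approx(math.pi)

    def test_angle_antipodal_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.standard_normal(7)
            v = rng.standard_normal(7)
            assert angular_difference(u, v) + angular_difference(u, -v) == pytest.approx(
                math.pi, abs=1e-9
            )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestKendall:
    def test_perfect_and_reversed(self):
        u = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        tau, _ = kendall_tau(u, u)
        assert tau == pytest.approx(1.0)
        tau, _ = kendall_tau(u, -u)
        assert tau == pytest.approx(-1.0)

    def test_tied_sample_matches_pair_counting(self):
        u = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        tau, _ = kendall_tau(u, v)
        assert tau == pytest.approx(kendall_brute_force(u, v), abs=1e-12)

    def test_matches_brute_force_exhaustively(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = rng.integers(3, 9)
            u = rng.integers(0, 5, n).astype(float)
            v = rng.integers(0, 5, n).astype(float)
            if np.all(u == u[0]) or np.all(v == v[0]):
                continue
            tau, _ = kendall_tau(u, v)
            assert tau == pytest.approx(kendall_brute_force(u, v), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau(np.ones(5), np.arange(5.0))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = mann_whitney_u(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_complete_separation_n3(self):
        x = np.array([4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        u, p = mann_whitney_u(x, y)
        assert u == 9.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 labelings as extreme

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5)
        y = rng.standard_normal(4)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(y, x)
        assert u1 + u2 == pytest.approx(20.0)  # U + U' = n*m
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            if n * m > 36:
                continue
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = mwu_brute_force(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u(np.array([]), np.array([1.0]))


class TestClusterPermutation:
    def test_identical_matrices_no_clusters(self):
        a = np.random.default_rng(5).standard_normal((8, 32))
        res = cluster_permutation_paired_t(a, a.copy())
        assert res.clusters == ()
        assert res.exact and res.n_permutations == 256

    def test_minimum_exact_p_is_two_over_256(self):
        rng = np.random.default_rng(6)
        # strong effect in a mid-band window only
        a = rng.normal(0, 0.05, (8, 32))
        a[:, 10:18] += 1.0
        b = rng.normal(0, 0.05, (8, 32))
        res = cluster_permutation_paired_t(a, b)
        assert res.exact
        best = min(res.clusters, key=lambda c: c.p_value)
        assert best.p_value == pytest.approx(2 / 256)
        for c in res.clusters:
            assert (c.p_value * 256) == pytest.approx(round(c.p_value * 256))

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            d = rng.normal(0.0, 0.2, (8, 32))
            d[:, 10:18] += 1.0
            res = cluster_permutation_paired_t(d, np.zeros_like(d))
            found = any(
                c.band_start == 10 and c.band_stop == 17 and c.p_value <= 0.05
                for c in res.clusters
            )
            hits += found
        assert hits >= 95

    def test_monte_carlo_path_when_many_conditions(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((15, 10))
        b = rng.standard_normal((15, 10))
        res = cluster_permutation_paired_t(a, b, n_perm=500, seed=1)
        assert not res.exact
        assert res.n_permutations == 500

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="2 paired"):
            cluster_permutation_paired_t(np.ones((1, 5)), np.zeros((1, 5)))


class TestCompareModalities:
    def _cv(self, rng, kind):
        v = rng.uniform(0.1, 1.0, 6)
        return CentralityVector(
            values=v / v.sum(), kind=kind,
            region_labels=tuple(f"R{i}" for i in range(6)),
        )

    def _bpr(self, rng):
        return BandPowerRatios(
            band_edges=tuple((2.0 * 1.2 ** k, 2.0 * 1.2 ** (k + 1)) for k in range(8)),
            bpr=rng.uniform(0, 0.2, (6, 8)),
            region_labels=tuple(f"R{i}" for i in range(6)),
        )

    def test_single_task_skips_cluster_test(self):
        rng = np.random.default_rng(9)
        rep = compare_modalities(
            pc_rest=self._cv(rng, "PC"),
            pc_tasks={"t1": self._cv(rng, "PC")},
            dc_rest=self._cv(rng, "DC"),
            dc_tasks={"t1": self._cv(rng, "DC")},
            bpr_rest=self._bpr(rng),
            bpr_tasks={"t1": self._bpr(rng)},
        )
        assert rep["cluster_test"] is None
        assert rep["cos_pc"].shape == (1, 8)
        assert np.all(np.abs(rep["cos_pc"]) <= 1.0)

    def test_mismatched_task_sets_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="condition sets"):
            compare_modalities(
                pc_rest=self._cv(rng, "PC"),
                pc_tasks={"t1": self._cv(rng, "PC")},
                dc_rest=self._cv(rng, "DC"),
                dc_tasks={"t2": self._cv(rng, "DC")},
                bpr_rest=self._bpr(rng),
                bpr_tasks={"t1": self._bpr(rng)},
            )
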