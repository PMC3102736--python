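"""LD statistics, windows, correlated sets, tagging and alpha derivation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixfine.ld import (
    build_window,
    correlated_set,
    derive_alphas,
    dprime,
    em_haplotype_freqs,
    greedy_tags,
    pairwise_r2,
    r2_matrix,
)
from admixfine.synthetic import panel_from_founders
from tests.conftest import make_matrix


class TestR2:
    def test_self_is_one(self):
        a = np.array([0.0, 1, 2, 1, 0, 2])
        assert pairwise_r2(a, a) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([0.0, 0, 1, 1, 2, 2])
        b = np.array([2.0, 2, 1, 1, 0, 0])
        assert pairwise_r2(a, b) == pytest.approx(1.0)

    def test_hand_computed_pearson_squared(self):
        a = np.array([0.0, 1, 2, 0, 1, 2])
        b = np.array([0.0, 0, 2, 1, 1, 2])
        # independent arithmetic: r = cov / (sd_a sd_b) via explicit sums
        n = 6
        sab = np.sum(a * b) - np.sum(a) * np.sum(b) / n
        saa = np.sum(a * a) - np.sum(a) ** 2 / n
        sbb = np.sum(b * b) - np.sum(b) ** 2 / n
        assert pairwise_r2(a, b) == pytest.approx(sab**2 / (saa * sbb), abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(pairwise_r2(np.ones(5), np.array([0.0, 1, 2, 1, 0])))

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        dm = make_matrix(rng.integers(0, 3, size=(50, 6)).astype(float))
        m = r2_matrix(dm).to_numpy()
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)


def _genotype_loglik(table, h):
    """Log-likelihood of a 3x3 genotype table under haplotype freqs h
    (AB, Ab, aB, ab) with random haplotype pairing."""
    probs = np.zeros((3, 3))
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]
    for (a1, b1), p1 in zip(haps, h):
        for (a2, b2), p2 in zip(haps, h):
            probs[a1 + a2, b1 + b2] += p1 * p2
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if table[i, j]:
                ll += table[i, j] * np.log(max(probs[i, j], 1e-300))
    return ll


class TestDprime:
    def test_two_founder_block_full_dprime(self):
        founders = np.array([[1, 1], [0, 0]], dtype=np.int8)
        panel = panel_from_founders("X", founders, [0.3, 0.7], pool_size=2000, rng=1)
        g = panel.pool[::2] + panel.pool[1::2]
        assert dprime(g[:, 0], g[:, 1]) == pytest.approx(1.0)

    def test_linkage_equilibrium_low_median(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(60):
            a = rng.binomial(2, 0.4, size=1000).astype(float)
            b = rng.binomial(2, 0.5, size=1000).astype(float)
            vals.append(dprime(a, b))
        assert np.median(vals) < 0.3

    def test_em_matches_likelihood_grid(self):
        """EM haplotype frequency equals the 1-D profile-likelihood grid
        argmax (margins fixed at their MLEs) on a 20-sample fixture."""
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=20).astype(float)
        b = np.clip(a + rng.integers(-1, 2, size=20), 0, 2).astype(float)
        h = em_haplotype_freqs(a, b)
        pA, pB = a.mean() / 2, b.mean() / 2
        table = np.zeros((3, 3))
        for i, j in zip(a.astype(int), b.astype(int)):
            table[i, j] += 1
        lo = max(0.0, pA + pB - 1.0)
        hi = min(pA, pB)
        grid = np.arange(lo, hi + 1e-12, 1e-4)
        lls = [
            _genotype_loglik(
                table, np.array([x, pA - x, pB - x, 1 - pA - pB + x])
            )
            for x in grid
        ]
        assert h[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_monomorphic_is_nan(self):
        assert np.isnan(dprime(np.zeros(30), np.random.default_rng(4).integers(0, 3, 30).astype(float)))


class TestWindows:
    def test_flank_arithmetic(self):
        assert build_window([1_000_000]) == [(750_001, 1_250_000)]

    def test_block_extension_covers_full_block(self):
        w = build_window([1_000_000], blocks=[(600_000, 1_400_000)])
        assert w == [(600_000, 1_400_000)]

    def test_nearby_indices_merge(self):
        w = build_window([1_000_000, 1_100_000])
        assert w == [(750_001, 1_350_000)]

    def test_clamped_at_chromosome_start(self):
        assert build_window([100_000])[0][0] == 1


class TestCorrelatedSet:
    def _panel(self):
        rng = np.random.default_rng(5)
        idx = rng.integers(0, 3, size=400).astype(float)
        # engineered proxies: r^2 ~ high (few discordant) and low (shuffled)
        strong = idx.copy()
        strong[:60] = rng.integers(0, 3, size=60)
        weak = rng.permutation(idx)
        other = rng.integers(0, 3, size=400).astype(float)
        return make_matrix(np.column_stack([idx, strong, weak, other]))

    def test_index_always_member(self):
        dm = self._panel()
        out = correlated_set(dm, ["v0"], [(1000, 2000)], 0.2)
        assert "v0" in out

    def test_threshold_partitions_proxies(self):
        dm = self._panel()
        r_strong = pairwise_r2(dm.dosage_of("v0"), dm.dosage_of("v1"))
        r_weak = pairwise_r2(dm.dosage_of("v0"), dm.dosage_of("v2"))
        assert r_strong >= 0.2 > r_weak
        out = correlated_set(dm, ["v0"], [(1000, 2000)], 0.2)
        assert "v1" in out and "v2" not in out

    def test_absent_index_gives_empty_set(self):
        dm = self._panel()
        assert correlated_set(dm, ["missing"], [(1000, 2000)], 0.2) == []


def brute_force_min_cover(members, ld, r2_tag):
    cover = {
        v: {u for u in members if u == v or ld.loc[v, u] >= r2_tag} for v in members
    }
    for r in range(1, len(members) + 1):
        for comb in itertools.combinations(members, r):
            if set().union(*(cover[c] for c in comb)) >= set(members):
                return r
    return len(members)


class TestGreedyTags:
    def _ld(self, mat, ids):
        return pd.DataFrame(mat, index=ids, columns=ids)

    def test_complete_graph_single_tag(self):
        ids = list("abcd")
        ld = self._ld(np.ones((4, 4)), ids)
        assert len(greedy_tags(ids, ld, 0.8)) == 1

    def test_empty_graph_all_tags(self):
        ids = list("abcd")
        ld = self._ld(np.eye(4), ids)
        assert sorted(greedy_tags(ids, ld, 0.8)) == ids

    @pytest.mark.parametrize("seed", range(6))
    def test_cover_property_and_brute_force_bound(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        ids = [f"m{i}" for i in range(k)]
        m = rng.uniform(0, 1, size=(k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = self._ld(m, ids)
        tags = greedy_tags(ids, ld, 0.8, positions={v: i for i, v in enumerate(ids)})
        covered = set()
        for t in tags:
            covered |= {u for u in ids if u == t or ld.loc[t, u] >= 0.8}
        assert covered == set(ids)
        opt = brute_force_min_cover(ids, ld, 0.8)
        assert opt <= len(tags) <= 2 * opt + 1

    def test_raising_threshold_never_reduces_tag_count(self):
        rng = np.random.default_rng(11)
        k = 10
        ids = [f"m{i}" for i in range(k)]
        m = rng.uniform(0, 1, size=(k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = self._ld(m, ids)
        counts = [len(greedy_tags(ids, ld, t)) for t in (0.2, 0.5, 0.8, 0.95)]
        assert counts == sorted(counts)


class TestAlphas:
    def test_per_region_arithmetic(self):
        a, b = derive_alphas({"r1": 12}, 12, mode="per_region")
        assert a["r1"] == pytest.approx(0.05 / 12)

    def test_global_average_mode(self):
        a, _ = derive_alphas({"r1": 10, "r2": 14}, 24, mode="global_average")
        assert a["r1"] == a["r2"] == pytest.approx(0.05 / 12)

    def test_total_tags_scale(self):
        _, alpha_b = derive_alphas({"r": 5}, 8929)
        assert alpha_b == pytest.approx(5.6e-6, rel=2e-3)

    def test_single_tag_boundary(self):
        _, alpha_b = derive_alphas({"r": 1}, 1)
        assert alpha_b == pytest.approx(0.05)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            derive_alphas({"r": 0}, 10)
        with pytest.raises(ValueError):
            derive_alphas({"r": 3}, 0)
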