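"""Dest, AMOVA, Nei distance, PCoA: trivial cases and brute-force oracles."""

import math

import numpy as np
import pytest

from clonalpop.differentiation import (DistanceMatrix, amova_fst,
                                       dest_pairwise, nei_distance,
                                       nei_distance_matrix, pcoa,
                                       _dest_locus, _indicator_matrix)
from conftest import make_dataset


class TestDest:
    def test_identical_sites_zero(self):
        geno = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]] * 2
        ds = make_dataset(geno, sites=["A"] * 4 + ["B"] * 4)
        d, p = dest_pairwise(ds, n_perm=99, seed=0)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert p.iloc[0, 1] > 0.5

    def test_fixed_different_alleles_one(self):
        geno = [[(1, 1)]] * 4 + [[(2, 2)]] * 4
        ds = make_dataset(geno, sites=["A"] * 4 + ["B"] * 4)
        d, _ = dest_pairwise(ds, n_perm=49, seed=0)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic_single_locus(self):
        # site A: 3x(1,1), 1x(1,2); site B: 1x(1,2), 3x(2,2)
        geno = [[(1, 1)]] * 3 + [[(1, 2)]] + [[(1, 2)]] + [[(2, 2)]] * 3
        ds = make_dataset(geno, sites=["A"] * 4 + ["B"] * 4)
        pA, pB = 7 / 8, 1 / 8  # freq of allele 1 in A and B
        ho = (0.25 + 0.25) / 2
        n_harm = 4.0
        hs_raw = 1 - ((pA ** 2 + (1 - pA) ** 2) + (pB ** 2 + (1 - pB) ** 2)) / 2
        hs = n_harm / (n_harm - 1) * (hs_raw - ho / (2 * n_harm))
        pbar1 = (pA + pB) / 2
        ht_raw = 1 - pbar1 ** 2 - (1 - pbar1) ** 2
        ht = ht_raw + hs / (2 * n_harm) - ho / (4 * n_harm)
        expected = 2 * (ht - hs) / (1 - hs)
        assert _dest_locus(ds, np.arange(4), np.arange(4, 8), 0) == \
            pytest.approx(expected)

    def test_permutation_p_seeded_reproducible(self):
        geno = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 1)],
                [(2, 2)], [(2, 2)], [(1, 2)], [(2, 2)]]
        ds = make_dataset(geno, sites=["A"] * 4 + ["B"] * 4)
        _, p1 = dest_pairwise(ds, n_perm=199, seed=5)
        _, p2 = dest_pairwise(ds, n_perm=199, seed=5)
        assert p1.equals(p2)


class TestAmova:
    def test_two_sites_fixed_fst_one(self):
        geno = [[(1, 1)]] * 5 + [[(2, 2)]] * 5
        ds = make_dataset(geno, sites=["A"] * 5 + ["B"] * 5)
        res = amova_fst(ds, n_perm=0)
        assert res.phi["F_st"] == pytest.approx(1.0)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([1, 2, 3, 4], size=(200, 8, 2))
        sites = ["A"] * 100 + ["B"] * 100
        res = amova_fst(make_dataset(geno, sites=sites), n_perm=0)
        assert abs(res.phi["F_st"]) < 0.02

    def test_components_sum_to_total_and_match_ss_oracle(self, rng):
        """Brute-force sums-of-squares decomposition on a small fixture."""
        geno = rng.choice([1, 2, 3], size=(12, 3, 2))
        sites = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        ds = make_dataset(geno, sites=sites)
        res = amova_fst(ds, n_perm=0)
        # oracle: ANOVA on indicator vectors scaled so that squared Euclidean
        # distance/2 equals the allele-mismatch metric
        X = _indicator_matrix(ds, np.arange(12), True, np.asarray(sites)) / np.sqrt(2)
        grand = X.mean(axis=0)
        ss_total = ((X - grand) ** 2).sum()
        ss_within = 0.0
        for s in ("A", "B", "C"):
            sel = np.asarray(sites) == s
            ss_within += ((X[sel] - X[sel].mean(axis=0)) ** 2).sum()
        ss_among = ss_total - ss_within
        sigma_w = ss_within / (12 - 3)
        n0 = (12 - (3 * 16) / 12) / 2
        sigma_a = (ss_among / 2 - sigma_w) / n0
        assert res.components["among_sites"] == pytest.approx(sigma_a)
        assert res.components["within_sites"] == pytest.approx(sigma_w)
        assert res.phi["F_st"] == pytest.approx(sigma_a / (sigma_a + sigma_w))

    def test_hierarchical_components_and_permutation_p(self, rng):
        geno = rng.choice([1, 2, 3, 4], size=(24, 4, 2))
        sites = sum(([f"S{i}"] * 6 for i in range(4)), [])
        groups = ["pre"] * 12 + ["post"] * 12
        ds = make_dataset(geno, sites=sites)
        res = amova_fst(ds, groups=groups, n_perm=99, seed=3)
        total = sum(res.components.values())
        assert total == pytest.approx(
            res.components["among_groups"]
            + res.components["among_sites_within_groups"]
            + res.components["within_sites"])
        assert set(res.p_values) == {"F_st", "F_sg", "F_ct"}
        assert all(0 < p <= 1 for p in res.p_values.values())
        res2 = amova_fst(ds, groups=groups, n_perm=99, seed=3)
        assert res.p_values == res2.p_values

    def test_singleton_site_dropped_with_warning(self, rng):
        geno = rng.choice([1, 2], size=(9, 2, 2))
        sites = ["A"] * 4 + ["B"] * 4 + ["C"]
        with pytest.warns(UserWarning, match="one individual"):
            amova_fst(make_dataset(geno, sites=sites), n_perm=0)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        f = {"L1": {1: 0.5, 2: 0.5}, "L2": {3: 1.0}}
        assert nei_distance(f, f) == pytest.approx(0.0)

    def test_no_shared_alleles_infinite(self):
        a = {"L1": {1: 1.0}}
        b = {"L1": {2: 1.0}}
        assert math.isinf(nei_distance(a, b))

    def test_two_locus_hand_computation(self):
        a = {"L1": {1: 0.7, 2: 0.3}, "L2": {5: 1.0}}
        b = {"L1": {1: 0.2, 2: 0.8}, "L2": {5: 0.6, 6: 0.4}}
        jxy = (0.7 * 0.2 + 0.3 * 0.8) + (1.0 * 0.6)
        jx = (0.49 + 0.09) + 1.0
        jy = (0.04 + 0.64) + (0.36 + 0.16)
        assert nei_distance(a, b) == pytest.approx(
            -math.log(jxy / math.sqrt(jx * jy)))

    def test_allele_relabeling_invariance(self, rng):
        geno = rng.choice([10, 14, 18], size=(12, 3, 2))
        sites = ["A"] * 6 + ["B"] * 6
        ds1 = make_dataset(geno, sites=sites)
        relabel = {10: 50, 14: 90, 18: 70}
        geno2 = np.vectorize(relabel.get)(geno)
        ds2 = make_dataset(geno2, sites=sites)
        m1 = nei_distance_matrix(ds1)
        m2 = nei_distance_matrix(ds2)
        np.testing.assert_allclose(m1.values, m2.values)


class TestPcoa:
    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        D = np.abs(pts - pts.T)
        r = pcoa(DistanceMatrix(labels=list("abcd"), values=D))
        assert r.percent_explained[0] == pytest.approx(100.0)

    def test_recovers_known_2d_configuration(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        r = pcoa(DistanceMatrix(labels=[str(i) for i in range(8)], values=D))
        got = r.coordinates[:, :2]
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts - pts.mean(0), got)
        assert disparity < 1e-12

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        mine = pcoa(DistanceMatrix(labels=[str(i) for i in range(7)], values=D))
        ref = sk_pcoa(skbio.DistanceMatrix(D))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues)[::-1][:4],
            np.sort(ref.eigvals.to_numpy())[::-1][:4], atol=1e-8)
        np.testing.assert_allclose(
            np.abs(mine.coordinates[:, 0]),
            np.abs(ref.samples.iloc[:, 0].to_numpy()), atol=1e-8)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=[[0, 1], [2, 0]])

    def test_two_cluster_structure_separates_on_axis_one(self, paper_like):
        """Site ordination reflects the two river clusters, not period."""
        from clonalpop.mlg_clones import assign_mlgs, collapse_clones

        ds, _ = paper_like
        m = assign_mlgs(ds)
        cc = collapse_clones(ds, m, scope="per_site")
        r = pcoa(nei_distance_matrix(cc))
        # sites 0-5 are upstream of the barrier, 6-12 downstream
        upstream = {f"PRE{i+1}" for i in range(5)} | {"POST1"}
        ax1 = dict(zip(r.labels, r.coordinates[:, 0]))
        up = [v for k, v in ax1.items() if k in upstream]
        down = [v for k, v in ax1.items() if k not in upstream]
        assert (max(up) < min(down)) or (min(up) > max(down))
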