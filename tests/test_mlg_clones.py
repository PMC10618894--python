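"""MLG assignment, round-robin frequencies, pgen/psex, clone records."""

import numpy as np
import pytest
from scipy.stats import binom

from clonalpop.genotype_io import MISSING
from clonalpop.mlg_clones import (MLGError, assign_mlgs, attach_psex,
                                  collapse_clones, clone_records, pgen,
                                  psex_multiple, round_robin_frequencies,
                                  POOLED)
from conftest import make_dataset, random_dataset


class TestAssignMlgs:
    def test_identical_samples_one_mlg(self):
        geno = [[(100, 104)] * 10] * 5
        m = assign_mlgs(make_dataset(geno))
        assert m.n_mlg == 1
        assert len(next(iter(m.members.values()))) == 5

    def test_all_distinct_samples(self):
        geno = [[(100 + 4 * i, 100 + 4 * i)] * 10 for i in range(5)]
        assert assign_mlgs(make_dataset(geno)).n_mlg == 5

    def test_missing_locus_merges_into_unique_compatible_mlg(self):
        base = [(100, 104)] * 10
        a = list(base)
        a[3] = (MISSING, MISSING)
        other = [(108, 108)] * 10
        ds = make_dataset([base, a, other], ids=["B", "A", "C"])
        m = assign_mlgs(ds, min_scored_loci=7)
        assert m.mlg_of["A"] == m.mlg_of["B"]
        assert m.n_mlg == 2

    def test_ambiguous_merge_kept_separate_and_flagged(self):
        b1 = [(100, 104)] * 10
        b2 = list(b1)
        b2[3] = (108, 108)
        a = list(b1)
        a[3] = (MISSING, MISSING)  # compatible with both b1 and b2
        ds = make_dataset([b1, b2, a], ids=["B1", "B2", "A"])
        m = assign_mlgs(ds, min_scored_loci=7)
        assert m.n_mlg == 3
        assert "A" in m.flagged

    def test_too_few_scored_loci_unassigned(self):
        full = [(100, 104)] * 10
        sparse = [(100, 104)] * 3 + [(MISSING, MISSING)] * 7
        ds = make_dataset([full, sparse], ids=["B", "A"])
        m = assign_mlgs(ds, min_scored_loci=7)
        assert m.mlg_of["A"].startswith("unassigned:")
        assert "A" in m.flagged

    def test_all_missing_sample_rejected(self):
        ds = make_dataset([[(1, 2)], [(MISSING, MISSING)]])
        with pytest.raises(MLGError, match="all loci missing"):
            assign_mlgs(ds, min_scored_loci=1)

    def test_order_invariant_up_to_relabeling(self, rng):
        ds = random_dataset(rng, n=20, loci=5, missing_rate=0.1)
        m1 = assign_mlgs(ds, min_scored_loci=3)
        perm = np.random.default_rng(7).permutation(ds.n_samples)
        m2 = assign_mlgs(ds.subset(perm), min_scored_loci=3)
        part1 = {frozenset(v) for v in m1.members.values()}
        part2 = {frozenset(v) for v in m2.members.values()}
        assert part1 == part2


class TestRoundRobinFrequencies:
    def test_all_unique_equals_plain_frequencies(self):
        geno = [[(100, 104), (96, 96)], [(100, 100), (92, 96)],
                [(104, 104), (92, 92)]]
        ds = make_dataset(geno)
        f = round_robin_frequencies(ds).freqs[POOLED]
        # all MLGs unique at the complementary loci, so every sample counts:
        # L1 alleles 100 x3, 104 x3; L2 alleles 96 x3, 92 x3
        assert f["L1"] == pytest.approx({100: 0.5, 104: 0.5})
        assert f["L2"] == pytest.approx({96: 0.5, 92: 0.5})

    def test_monomorphic_locus(self):
        ds = make_dataset([[(100, 100), (1, 2)], [(100, 100), (3, 4)]])
        assert round_robin_frequencies(ds).freqs[POOLED]["L1"] == {100: 1.0}

    def test_dropping_locus_merges_mlgs_hand_enumeration(self):
        # three MLGs; without L1, samples 1 and 2 collapse to one MLG, so
        # L1 frequencies count samples {1 or 2} once plus sample 3:
        # alleles at L1 among representatives (s1, s3): 100,104 | 108,108
        geno = [[(100, 104), (50, 52)],
                [(108, 108), (50, 52)],
                [(108, 108), (54, 54)]]
        ds = make_dataset(geno)
        f = round_robin_frequencies(ds).freqs[POOLED]
        # dropping L1: s1==s2 merge (both (50,52)); reps are s1 and s3
        assert f["L1"] == pytest.approx({100: 0.25, 104: 0.25, 108: 0.5})
        # dropping L2: s2==s3 merge (both (108,108)); reps are s1 and s2,
        # whose L2 calls are (50,52) and (50,52)
        assert f["L2"] == pytest.approx({50: 0.5, 52: 0.5})


class TestPgenPsex:
    def test_homozygote_fixed_allele(self):
        assert pgen(np.array([[(100, 100)]])[0],
                    {"L1": {100: 1.0}}, ["L1"]) == 1.0

    def test_heterozygote_half(self):
        assert pgen(np.array([[(100, 104)]])[0],
                    {"L1": {100: 0.5, 104: 0.5}}, ["L1"]) == pytest.approx(0.5)

    def test_two_locus_hand_arithmetic(self):
        g = np.array([(100, 100), (96, 92)])
        f = {"L1": {100: 0.4}, "L2": {96: 0.2, 92: 0.3}}
        assert pgen(g, f, ["L1", "L2"]) == pytest.approx(0.16 * 0.12)

    def test_missing_locus_skipped(self):
        g = np.array([(100, 100), (MISSING, MISSING)])
        f = {"L1": {100: 0.4}, "L2": {96: 0.2}}
        assert pgen(g, f, ["L1", "L2"]) == pytest.approx(0.16)

    def test_pgen_never_exceeds_largest_single_locus_term(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            terms = []
            f = {}
            g = []
            for j in range(k):
                p, q = rng.uniform(0.05, 0.5, 2)
                f[f"L{j}"] = {1: p, 2: q, 3: max(1 - p - q, 0.0)}
                het = rng.random() < 0.5
                g.append((1, 2) if het else (1, 1))
                terms.append(2 * p * q if het else p * p)
            val = pgen(np.array(g), f, [f"L{j}" for j in range(k)])
            assert val <= max(terms) + 1e-12

    def test_psex_certain_genotype(self):
        assert psex_multiple(1.0, 2, 2) == pytest.approx(1.0)

    def test_psex_impossible_genotype(self):
        assert psex_multiple(0.0, 2, 5) == 0.0

    def test_psex_binomial_tail_arithmetic(self):
        expected = 1 - 0.9 ** 3 - 3 * 0.1 * 0.9 ** 2
        assert psex_multiple(0.1, 2, 3) == pytest.approx(expected)

    def test_psex_nonincreasing_in_n_obs(self):
        for pg in (0.01, 0.1, 0.5):
            vals = [psex_multiple(pg, k, 20) for k in range(2, 20)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_psex_rejects_bad_counts(self):
        with pytest.raises(MLGError):
            psex_multiple(0.1, 5, 3)

    def test_attach_psex_marks_repeated_mlgs(self, rng):
        ds = random_dataset(rng, n=8, loci=3)
        # force a repeat
        ds.genotypes[1] = ds.genotypes[0]
        m = attach_psex(ds, assign_mlgs(ds, min_scored_loci=1))
        repeated = [mid for mid, mem in m.members.items() if len(mem) >= 2]
        assert repeated and all(mid in m.psex for mid in repeated)
        assert all(0 <= v <= 1 for v in m.psex.values())


class TestCollapseAndRecords:
    def _clonal_ds(self):
        base = [(100, 104)] * 4
        other = [(108, 108)] * 4
        geno = [base] * 3 + [other] * 2 + [base]
        sites = ["A"] * 5 + ["B"]
        xy = [(0, 0), (3, 4), (0, 8), (10, 0), (11, 0), (500, 0)]
        periods = ["pre"] * 5 + ["post"]
        return make_dataset(geno, sites=sites, periods=periods, xy=xy)

    def test_all_unique_unchanged(self, rng):
        ds = random_dataset(rng, n=6, loci=6, alleles=tuple(range(100, 140, 2)))
        m = assign_mlgs(ds, min_scored_loci=1)
        if m.n_mlg == ds.n_samples:
            assert collapse_clones(ds, m).n_samples == ds.n_samples

    def test_per_site_scope_keeps_one_per_mlg_per_site(self):
        ds = self._clonal_ds()
        m = assign_mlgs(ds, min_scored_loci=1)
        cc = collapse_clones(ds, m, scope="per_site")
        # site A: 2 MLGs -> 2 reps; site B: 1 MLG -> 1 rep
        assert cc.n_samples == 3
        cc_global = collapse_clones(ds, m, scope="global")
        assert cc_global.n_samples == 2

    def test_clone_extent_max_pairwise(self):
        ds = self._clonal_ds()
        m = assign_mlgs(ds, min_scored_loci=1)
        recs = {r.mlg_id: r for r in clone_records(ds, m)}
        big = recs[m.mlg_of["s1"]]
        assert big.n_shoots["pre"] == 3
        # points (0,0), (3,4), (0,8): pairwise 5, 8, 5 -> extent 8
        assert big.max_extent["pre"] == pytest.approx(8.0)
        assert big.sites == {"A", "B"}
        single = recs[m.mlg_of["s4"]]
        assert single.max_extent["pre"] == pytest.approx(1.0)

    def test_single_shoot_extent_zero(self):
        ds = make_dataset([[(1, 2)]], xy=[(5, 5)])
        m = assign_mlgs(ds, min_scored_loci=1)
        assert clone_records(ds, m)[0].max_extent["all"] == 0.0

    def test_mlg_set_union_arithmetic(self):
        # two period-specific MLG id sets with known overlap combine by union
        pre = {f"m{i}" for i in range(1, 74)}
        post = {f"m{i}" for i in range(38, 148)} | {"x1", "x2", "x3"}
        post = set(list(post)[:110])
        shared = pre & post
        assert len(pre | post) == len(pre) + len(post) - len(shared)
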