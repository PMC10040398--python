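import itertools

import numpy as np
import pandas as pd
import pytest

import finsoc as fs
from finsoc.permtests import two_sided_p


class TestTwoSidedP:
    def test_doubled_tail_arithmetic(self):
        # 250 of 10,000 permuted values >= observed -> p = 0.05
        perm = np.concatenate([np.zeros(9750), np.ones(250)])
        p, label = two_sided_p(0.5, perm, direction="upper")
        assert p == pytest.approx(0.05)
        assert label == "0.05"

    def test_observed_at_median_capped_at_one(self):
        perm = np.arange(100, dtype=float)
        p, _ = two_sided_p(49.5, perm, direction="upper")
        assert p == 1.0

    def test_zero_count_reported_as_floor(self):
        perm = np.zeros(10_000)
        p, label = two_sided_p(5.0, perm, direction="upper")
        assert p == pytest.approx(2 / 10_000)
        assert label == "< 0.0002"

    def test_auto_picks_informative_tail(self):
        perm = np.arange(1000, dtype=float)
        p_low, _ = two_sided_p(5.0, perm, direction="auto")
        p_up, _ = two_sided_p(995.0, perm, direction="auto")
        assert p_low < 0.05 and p_up < 0.05


def labelled(ids, labels):
    return dict(zip(ids, labels))


class TestRelatednessPermutation:
    def test_constant_relatedness_gives_p_one(self):
        ids = [f"i{k}" for k in range(8)]
        r = pd.DataFrame(np.full((8, 8), 0.3), index=ids, columns=ids)
        part = labelled(ids, [0, 0, 0, 0, 1, 1, 1, 1])
        res = fs.perm_relatedness(r, part, n_perm=200, seed=1)
        assert all(p == 1.0 for p in res.p.values())

    def test_matches_exhaustive_enumeration_four_individuals(self):
        """With 4 individuals in two pairs there are only 3 distinct pairings;
        the Monte Carlo p must match the exact enumeration."""
        ids = ["a", "b", "c", "d"]
        r = np.array(
            [
                [1.0, 0.9, 0.1, 0.0],
                [0.9, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.05],
                [0.0, 0.1, 0.05, 1.0],
            ]
        )
        rel = pd.DataFrame(r, index=ids, columns=ids)
        part = labelled(ids, [0, 0, 1, 1])
        n_perm = 30_000
        res = fs.perm_relatedness(rel, part, n_perm=n_perm, seed=3)

        # exhaustive null for community 0's mean (all 4!/(2!2!)/... label perms)
        labels = np.array([0, 0, 1, 1])
        stats_c0 = []
        for perm in set(itertools.permutations(labels)):
            members = [i for i, lab in enumerate(perm) if lab == 0]
            stats_c0.append(r[members[0], members[1]])
        stats_c0 = np.array(stats_c0)
        obs = r[0, 1]
        exact_upper = (stats_c0 >= obs).mean()
        exact_p = min(1.0, 2 * exact_upper)
        mc_se = 3 * np.sqrt(exact_p * (1 - exact_p) / n_perm) + 2 / n_perm
        assert res.p["community_0"] == pytest.approx(exact_p, abs=max(mc_se, 0.02))

    def test_singleton_community_reported_missing(self):
        ids = ["a", "b", "c"]
        rel = pd.DataFrame(np.eye(3) * 0.5 + 0.5, index=ids, columns=ids)
        part = labelled(ids, [0, 0, 1])
        res = fs.perm_relatedness(rel, part, n_perm=50, seed=0)
        assert np.isnan(res.observed["community_1"])
        assert res.p_label["community_1"] == "undefined"

    def test_planted_kin_communities_detected(self):
        rng = np.random.default_rng(5)
        n, k = 36, 3
        labels = np.repeat(range(k), n // k)
        r = np.full((n, n), 0.02)
        within = labels[:, None] == labels[None, :]
        r[within] = 0.25
        r += rng.normal(0, 0.005, (n, n))
        r = np.clip((r + r.T) / 2, 0, 1)
        np.fill_diagonal(r, 1.0)
        ids = [f"i{j}" for j in range(n)]
        rel = pd.DataFrame(r, index=ids, columns=ids)
        res = fs.perm_relatedness(rel, labelled(ids, labels), n_perm=2000, seed=6)
        assert all(p < 0.01 for p in res.p.values())


class TestBinomialRandomisationTests:
    def test_single_haplotype_edge_case(self):
        ids = [f"i{k}" for k in range(6)]
        hap = pd.Series(["H0"] * 6, index=ids)
        part = labelled(ids, [0, 0, 0, 1, 1, 1])
        res = fs.perm_haplotype(hap, part, n_perm=100, seed=2)
        assert res.observed["within"] == 1.0
        assert res.p["within"] == 1.0

    def test_ungenotyped_dyads_excluded(self):
        ids = [f"i{k}" for k in range(6)]
        hap = pd.Series(["H0", "H0", None, "H1", "H1", None], index=ids)
        part = labelled(ids, [0, 0, 0, 1, 1, 1])
        res = fs.perm_haplotype(hap, part, n_perm=500, seed=2)
        # only dyads among the 4 genotyped individuals count:
        # within pairs: (i0,i1)=1 share, (i3,i4)=1 share -> mean 1.0
        assert res.observed["within"] == pytest.approx(1.0)
        assert res.observed["between"] == pytest.approx(0.0)

    def test_no_genotypes_raises(self):
        ids = ["a", "b"]
        hap = pd.Series([None, None], index=ids, dtype=object)
        with pytest.raises(ValueError):
            fs.perm_haplotype(hap, labelled(ids, [0, 1]), n_perm=10, seed=0)

    def test_frequency_p_hat_mode(self):
        ids = [f"i{k}" for k in range(8)]
        hap = pd.Series(["A", "A", "A", "A", "B", "B", "B", "B"], index=ids)
        part = labelled(ids, [0, 0, 0, 0, 1, 1, 1, 1])
        res = fs.perm_haplotype(
            hap, part, n_perm=4000, seed=4, p_hat_mode="freq"
        )
        # expected sharing under frequencies: 2 * 0.5^2 = 0.5
        assert np.mean(res.permuted["between"]) == pytest.approx(0.5, abs=0.03)

    def test_spongers_planted_in_one_community_detected(self):
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 36
            labels = np.repeat([0, 1, 2], n // 3)
            sponger = labels == 0  # perfectly aligned with community 0
            # flip a couple of individuals for realism
            flip = rng.integers(0, n, 2)
            sponger = sponger.copy()
            sponger[flip] = ~sponger[flip]
            ids = [f"i{j}" for j in range(n)]
            res = fs.perm_foraging(
                pd.Series(sponger, index=ids),
                labelled(ids, labels),
                n_perm=600,
                seed=seed + 100,
            )
            if res.p["within"] < 0.05 and res.observed["within"] > np.mean(
                res.permuted["within"]
            ):
                hits += 1
        assert hits >= 0.9 * n_rep


class TestDepthSDPermutation:
    def test_equal_depths_give_p_one(self):
        ids = [f"i{k}" for k in range(8)]
        depths = pd.Series(7.0, index=ids)
        part = labelled(ids, [0] * 4 + [1] * 4)
        res = fs.perm_depth_sd(depths, part, n_perm=100, seed=0)
        assert all(p == 1.0 for p in res.p.values())

    def test_matches_exhaustive_enumeration_four_individuals(self):
        ids = ["a", "b", "c", "d"]
        depths = pd.Series([1.0, 1.5, 11.0, 12.0], index=ids)
        part = labelled(ids, [0, 0, 1, 1])
        n_perm = 30_000
        res = fs.perm_depth_sd(depths, part, n_perm=n_perm, seed=8)

        vals = depths.to_numpy()
        null_c0 = []
        for perm in set(itertools.permutations([0, 0, 1, 1])):
            members = vals[[i for i, lab in enumerate(perm) if lab == 0]]
            null_c0.append(members.std(ddof=1))
        null_c0 = np.array(null_c0)
        obs = res.observed["community_0"]
        exact_lower = (null_c0 <= obs).mean()
        exact_p = min(1.0, 2 * exact_lower)
        assert res.p["community_0"] == pytest.approx(exact_p, abs=0.02)

    def test_habitat_segregated_communities_detected(self):
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 30
            labels = np.repeat([0, 1], n // 2)
            depths = np.where(labels == 0, 3.0, 13.0) + rng.normal(0, 1.0, n)
            ids = [f"i{j}" for j in range(n)]
            res = fs.perm_depth_sd(
                pd.Series(depths, index=ids),
                labelled(ids, labels),
                n_perm=600,
                seed=seed + 50,
            )
            if all(p < 0.05 for p in res.p.values()):
                hits += 1
        assert hits >= 0.95 * n_rep


def test_seed_reproducibility_and_mc_stability():
    rng = np.random.default_rng(12)
    n = 24
    ids = [f"i{j}" for j in range(n)]
    labels = labelled(ids, np.repeat([0, 1, 2], n // 3))
    r = rng.beta(0.5, 5, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    rel = pd.DataFrame(r, index=ids, columns=ids)

    a = fs.perm_relatedness(rel, labels, n_perm=800, seed=99)
    b = fs.perm_relatedness(rel, labels, n_perm=800, seed=99)
    assert a.p == b.p
    # doubling n_perm moves p by no more than a few MC standard errors
    c = fs.perm_relatedness(rel, labels, n_perm=1600, seed=100)
    for key, p in a.p.items():
        se = np.sqrt(max(p, 0.01) * (1 - min(p, 0.99)) / 800)
        assert abs(c.p[key] - p) <= 2 * (2 * se) + 4 / 800
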