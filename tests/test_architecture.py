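"""Linkage-map assignment, clustering permutation tests, LD, nnBlocks."""

import numpy as np
import pandas as pd
import pytest

from shoreclines.architecture import (
    LinkageMap,
    assign_snps_to_map,
    detect_nn_blocks,
    ld_decay_profile,
    pairwise_ld,
    permutation_cluster_test,
)


@pytest.fixture()
def lmap():
    rows = []
    for lg in (1, 2):
        for k, cm in enumerate(np.arange(0.0, 50.0, 0.2)):
            rows.append((f"lg{lg}c{k}", 5000, lg, round(cm, 1)))
    return LinkageMap(pd.DataFrame(rows, columns=["contig", "bp", "lg", "cm"]))


class TestMapAssignment:
    def test_exact_hit(self, lmap):
        snps = pd.DataFrame({"contig": ["lg1c10"], "bp": [5000]})
        out = assign_snps_to_map(snps, lmap)
        assert out["lg"].item() == 1
        assert out["cm"].item() == pytest.approx(2.0)

    def test_1000bp_boundary(self, lmap):
        snps = pd.DataFrame({"contig": ["lg1c0", "lg1c0"],
                             "bp": [5999, 6001]})
        out = assign_snps_to_map(snps, lmap, max_bp=1000)
        assert list(out["mapped"]) == [True, False]

    def test_unknown_contig_dropped(self, lmap):
        out = assign_snps_to_map(
            pd.DataFrame({"contig": ["nope"], "bp": [5000]}), lmap)
        assert not out["mapped"].item()

    def test_tie_breaks_to_lower_cm(self):
        # two map entries on one contig equidistant from the SNP
        lm = LinkageMap(pd.DataFrame({
            "contig": ["c", "c"], "bp": [4000, 6000], "lg": [3, 3],
            "cm": [7.4, 2.2]}))
        out = assign_snps_to_map(pd.DataFrame({"contig": ["c"], "bp": [5000]}),
                                 lm)
        assert out["cm"].item() == pytest.approx(2.2)


class TestPermutationClustering:
    def _mapped(self, lgs, cms=None):
        n = len(lgs)
        return pd.DataFrame({
            "contig": [f"c{i}" for i in range(n)], "bp": [5000] * n,
            "lg": lgs, "cm": cms if cms is not None else [1.0] * n,
            "mapped": [True] * n,
        })

    def test_all_labelled_gives_p_one(self):
        mapped = self._mapped([1] * 5 + [2] * 5)
        out = permutation_cluster_test(mapped, [True] * 10, "linkage_group",
                                       n_perm=200, seed=0)
        assert (out["p_value"] == 1.0).all()

    def test_matches_exhaustive_enumeration(self):
        # 10 SNPs on 2 LGs (6 + 4), 3 non-neutral all on the small LG;
        # oracle enumerates all C(10,3) labelings exactly
        from itertools import combinations

        lgs = [1] * 6 + [2] * 4
        labels = np.array([False] * 6 + [True, True, True, False])
        mapped = self._mapped(lgs)
        n_perm = 200000  # large enough to pin the tail probability
        out = permutation_cluster_test(mapped, labels, "linkage_group",
                                       n_perm=n_perm, seed=1)
        obs2 = 3 / 4  # proportion on LG2
        count = sum(1 for c in combinations(range(10), 3)
                    if sum(1 for i in c if i >= 6) / 4 >= obs2)
        exact = count / 120
        p2 = out.loc[out["unit"] == "2", "p_value"].item()
        assert p2 == pytest.approx(exact, abs=0.01)

    def test_type_i_calibration(self):
        rng = np.random.default_rng(7)
        lgs = np.repeat(np.arange(1, 6), 12)
        mapped = self._mapped(list(lgs))
        rejections = 0
        tests = 0
        for rep in range(150):
            labels = rng.random(60) < 0.2
            if labels.sum() == 0:
                continue
            out = permutation_cluster_test(mapped, labels, "linkage_group",
                                           n_perm=400, seed=rep)
            rejections += int((out["p_value"] < 0.05).sum())
            tests += len(out)
        rate = rejections / tests
        assert 0.02 <= rate <= 0.08

    def test_window_scale_partitions_by_10cm(self):
        mapped = self._mapped([1] * 6, cms=[0.5, 4.0, 9.9, 10.1, 15.0, 25.0])
        labels = [True, True, True, False, False, False]
        out = permutation_cluster_test(mapped, labels, "window_10cM",
                                       n_perm=500, seed=0)
        assert set(out["unit"]) == {"1:w0", "1:w1", "1:w2"}
        w0 = out.loc[out["unit"] == "1:w0"].iloc[0]
        assert w0["proportion"] == pytest.approx(1.0)

    def test_within_contig_pair_ratio(self):
        mapped = pd.DataFrame({
            "contig": ["a", "a", "a", "b", "b"],
            "bp": [100, 150, 5000, 200, 20000],
            "lg": [1] * 5, "cm": [1.0] * 5, "mapped": [True] * 5,
        })
        labels = np.array([True, True, False, True, False])
        out = permutation_cluster_test(mapped, labels, "within_contig_bp",
                                       n_perm=300, seed=0)
        near = out[out["unit"] == "[0,100)"].iloc[0]
        # pairs <100 bp apart: (a1,a2) both non-neutral -> ratio 1
        assert near["proportion"] == pytest.approx(1.0)


class TestPairwiseLD:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(3, 60))
        out = pairwise_ld(d, [(1, 1)])
        assert out["abs_r"].item() == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        g1 = np.array([0, 1, 2, 2, 1, 0])
        g2 = np.array([0, 1, 1, 2, 2, 0])
        expected = abs(np.corrcoef(g1, g2)[0, 1])
        out = pairwise_ld(np.vstack([g1, g2]), [(0, 1)], min_n=6)
        assert out["abs_r"].item() == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(2, 100))
        a = pairwise_ld(d, [(0, 1)])["abs_r"].item()
        b = pairwise_ld(d, [(1, 0)])["abs_r"].item()
        assert a == pytest.approx(b, abs=1e-15)

    def test_independent_null_level(self):
        # for independent loci, E|r| ~ sqrt(2 / (pi n))
        rng = np.random.default_rng(2)
        n = 373
        d = rng.binomial(2, 0.5, size=(220, n))
        pairs = [(2 * i, 2 * i + 1) for i in range(110)]
        out = pairwise_ld(d, pairs)
        expected = np.sqrt(2 / (np.pi * n))
        assert out["abs_r"].mean() == pytest.approx(expected, rel=0.2)

    def test_monomorphic_and_small_groups_flagged(self):
        d = np.array([[1] * 20, [0, 1] * 10])
        out = pairwise_ld(d, [(0, 1)])
        assert np.isnan(out["abs_r"].item()) and out["note"].item() == "monomorphic"
        out = pairwise_ld(d, [(0, 1)], group_mask=[True] * 5 + [False] * 15)
        assert out["note"].item() == "too_few_individuals"


class TestLdDecay:
    def test_single_bin(self):
        ld = pd.DataFrame({"abs_r": [0.2, 0.4, 0.6]})
        out = ld_decay_profile(ld, [0.3, 0.5, 0.7])
        assert len(out) == 1
        assert out["mean_abs_r"].item() == pytest.approx(0.4)

    def test_constructed_contrast(self):
        ld = pd.DataFrame({"abs_r": [0.6] * 4 + [0.1] * 4})
        dist = [0.5] * 8
        strata = ["within_block"] * 4 + ["outside_block"] * 4
        out = ld_decay_profile(ld, dist, strata)
        vals = dict(zip(out["stratum"], out["mean_abs_r"]))
        assert vals["within_block"] == pytest.approx(0.6)
        assert vals["outside_block"] == pytest.approx(0.1)

    def test_exponential_decay_is_monotone(self):
        rng = np.random.default_rng(3)
        dist = rng.uniform(0, 20, 4000)
        r = np.clip(0.8 * np.exp(-dist / 5) + rng.normal(0, 0.02, 4000), 0, 1)
        out = ld_decay_profile(pd.DataFrame({"abs_r": r}), dist, bin_width=2.0)
        means = out.sort_values("cm_bin_low")["mean_abs_r"].to_numpy()
        assert (np.diff(means) <= 0.01).all()


class TestNnBlocks:
    def _mapped(self, lgs, cms):
        n = len(lgs)
        return pd.DataFrame({
            "contig": [f"c{i}" for i in range(n)], "bp": [5000] * n,
            "lg": lgs, "cm": cms, "mapped": [True] * n,
        })

    def test_uniform_low_proportion_no_blocks(self):
        rng = np.random.default_rng(4)
        cms = list(rng.uniform(0, 50, 200))
        mapped = self._mapped([1] * 200, cms)
        labels = rng.random(200) < 0.02
        blocks = detect_nn_blocks(mapped, labels)
        assert blocks == []

    def test_planted_block_detected_with_ld_condition(self):
        rng = np.random.default_rng(5)
        n_out, n_in = 300, 30
        cms = list(rng.uniform(0, 50, n_out)) + list(rng.uniform(20, 35, n_in))
        lgs = [1] * n_out + [2] * n_in
        mapped = self._mapped(lgs, cms)
        labels = np.concatenate([rng.random(n_out) < 0.01,
                                 np.ones(n_in, bool)])
        # correlated dosages inside the block, independent outside
        latent = rng.binomial(2, 0.5, 100)
        dos = rng.binomial(2, 0.5, size=(n_out + n_in, 100))
        for i in range(n_out, n_out + n_in):
            copy = rng.random(100) < 0.9
            dos[i] = np.where(copy, latent, dos[i])
        groups = {"all": np.ones(100, bool)}
        blocks = detect_nn_blocks(mapped, labels, dos, groups)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.lg == 2
        assert b.cm_start >= 18 and b.cm_end <= 37
        assert b.mean_abs_r["all"] >= 0.3

    def test_saturated_lg_single_block(self):
        # one LG uniformly non-neutral against a large mostly-neutral
        # background merges into a single block spanning the LG
        rng = np.random.default_rng(6)
        cms = sorted(rng.uniform(0, 50, 100))
        rest = list(rng.uniform(0, 50, 1900))
        mapped = self._mapped([1] * 100 + list(np.repeat([2, 3, 4, 5], 475)),
                              cms + rest)
        labels = np.concatenate([np.ones(100, bool),
                                 rng.random(1900) < 0.01])
        blocks = detect_nn_blocks(mapped, labels)
        lg1 = [b for b in blocks if b.lg == 1]
        assert len(lg1) == 1
        assert lg1[0].cm_end - lg1[0].cm_start >= 45

    def test_cm_translation_invariance(self):
        rng = np.random.default_rng(7)
        cms = np.concatenate([rng.uniform(0, 50, 150),
                              rng.uniform(10, 22, 25)])
        lgs = [1] * 150 + [2] * 25
        labels = np.concatenate([rng.random(150) < 0.01, np.ones(25, bool)])
        b1 = detect_nn_blocks(self._mapped(lgs, list(cms)), labels)
        shifted = cms.copy()
        shifted[150:] += 7.3  # arbitrary, not a multiple of the window
        b2 = detect_nn_blocks(self._mapped(lgs, list(shifted)), labels)
        assert len(b1) == len(b2) == 1
        assert b2[0].cm_start == pytest.approx(b1[0].cm_start + 7.3, abs=1e-9)
        assert b2[0].cm_end == pytest.approx(b1[0].cm_end + 7.3, abs=1e-9)
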