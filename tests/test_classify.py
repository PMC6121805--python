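"""Neutrality threshold, classification, Fst, dispersal-from-LD."""

import numpy as np
import pandas as pd
import pytest

from shoreclines.classify import (
    NeutralityClassifier,
    classification_counts,
    classify_snps,
    em_gametic_d,
    end_differentiation,
    estimate_dispersal_from_ld,
    hudson_fst,
    ml_genotype_calls,
    neutral_varex_threshold,
    summarize_nonneutral_centers,
)
from shoreclines.exceptions import ConfigurationError, InsufficientNullError


class TestThreshold:
    def test_degenerate_distribution(self):
        assert neutral_varex_threshold(np.full(150, 12.5)) == 12.5

    def test_matches_sort_based_oracle(self):
        vals = np.arange(1.0, 1001.0)
        got = neutral_varex_threshold(vals, 0.99)
        # same linear-interpolation definition, written out directly
        h = 0.99 * (len(vals) - 1)
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        s = np.sort(vals)
        expected = s[lo] + (h - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientNullError):
            neutral_varex_threshold(np.arange(50))

    def test_monotone_in_q_and_max_at_one(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 10, size=500)
        qs = [0.5, 0.9, 0.99, 1.0]
        ts = [neutral_varex_threshold(vals, q) for q in qs]
        assert all(a <= b for a, b in zip(ts, ts[1:]))
        assert ts[-1] == pytest.approx(vals.max())

    def test_duplicating_null_leaves_threshold_stable(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2, 10, size=400)
        t1 = neutral_varex_threshold(vals)
        t2 = neutral_varex_threshold(np.concatenate([vals, vals]))
        assert t1 == pytest.approx(t2, rel=0.02)


def _fits_frame(var_ex, clinal, centers=None):
    n = len(var_ex)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "clinal": clinal, "var_ex": var_ex,
        "center": centers if centers is not None else np.full(n, 80.0),
    })


class TestClassification:
    def test_all_below_threshold(self):
        df = _fits_frame([1.0, 5.0, 8.0], [True, True, False])
        out = classify_snps(df, 10.0)
        assert (out["category"] != "non_neutral").all()

    def test_boundary_is_strict(self):
        df = _fits_frame([35.69, 35.70], [True, True])
        out = classify_snps(df, 35.69)
        assert list(out["category"]) == ["clinal_neutral", "non_neutral"]

    def test_non_clinal_never_non_neutral(self):
        df = _fits_frame([99.0], [False])
        assert classify_snps(df, 10.0)["category"].item() == "non_clinal"

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        df = _fits_frame(rng.uniform(0, 60, 50), rng.random(50) < 0.7)
        a = classify_snps(df, 30.0)["category"].to_numpy()
        perm = rng.permutation(50)
        b = classify_snps(df.iloc[perm].reset_index(drop=True), 30.0)
        assert (b["category"].to_numpy() == a[perm]).all()

    def test_estimator_api_and_counts(self):
        rng = np.random.default_rng(3)
        null = rng.gamma(2, 5, 300)
        clf = NeutralityClassifier(q=0.99).fit(null)
        df = _fits_frame([clf.threshold_ + 1, 1.0, 2.0],
                         [True, True, False])
        cats = clf.predict(df)
        assert list(cats) == ["non_neutral", "clinal_neutral", "non_clinal"]
        counts = classification_counts(classify_snps(df, clf.threshold_))
        assert counts["non_neutral"] == 1 and counts["n"] == 3


class TestCenterSummary:
    def test_singleton(self):
        df = classify_snps(_fits_frame([50.0], [True], [90.0]), 10.0)
        s = summarize_nonneutral_centers(df, transitions=[85.0])
        assert s["mean_center"] == 90.0
        assert s["displacements"][85.0] == pytest.approx(5.0)

    def test_symmetric_pair(self):
        df = classify_snps(_fits_frame([50.0, 60.0], [True, True],
                                       [80.0, 100.0]), 10.0)
        s = summarize_nonneutral_centers(df, transitions=[85.0])
        assert s["mean_center"] == pytest.approx(90.0)
        assert s["displacements"][85.0] == pytest.approx(5.0)

    def test_empty_warns(self):
        df = classify_snps(_fits_frame([1.0], [True]), 10.0)
        with pytest.warns(UserWarning):
            s = summarize_nonneutral_centers(df)
        assert s["n"] == 0


class TestDispersal:
    def test_zero_ld_gives_zero(self):
        est = estimate_dispersal_from_ld([0.0], [20.0], [20.0], [1.0], [1.0])
        assert est.sigma_hat == 0.0

    def test_direct_formula(self):
        est = estimate_dispersal_from_ld([0.01], [20.0], [20.0], [1.0], [1.0],
                                         r=0.5)
        assert est.sigma_hat == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_negative_d_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            est = estimate_dispersal_from_ld([-0.01, 0.01], [20, 20.0],
                                             [20, 20.0], [1, 1.0], [1, 1.0])
        assert est.n_pairs_used == 1

    def test_invalid_widths_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_dispersal_from_ld([0.01], [0.0], [20.0], [1.0], [1.0])


class TestEmGameticD:
    def test_perfect_coupling(self):
        # a locus paired with itself: D = p (1 - p)
        g = np.array([0, 0, 1, 1, 2, 2, 2, 0])
        p = g.mean() / 2
        assert em_gametic_d(g, g) == pytest.approx(p * (1 - p), abs=1e-6)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(4)
        g1 = rng.binomial(2, 0.5, 4000)
        g2 = rng.binomial(2, 0.5, 4000)
        assert abs(em_gametic_d(g1, g2)) < 0.02

    def test_known_haplotype_mixture(self):
        # construct genotypes from explicit haplotype draws; EM must
        # recover D = h11 - pA pB of the generating haplotype pool
        rng = np.random.default_rng(5)
        h_freq = np.array([0.4, 0.1, 0.2, 0.3])  # 11, 10, 01, 00
        hap = rng.choice(4, size=(5000, 2), p=h_freq)
        a1 = (hap < 2).astype(int)  # allele at locus 1
        a2 = ((hap == 0) | (hap == 2)).astype(int)
        g1, g2 = a1.sum(axis=1), a2.sum(axis=1)
        d_true = 0.4 - 0.5 * 0.6
        assert em_gametic_d(g1, g2) == pytest.approx(d_true, abs=0.02)


class TestEndDifferentiation:
    def test_identical_ends(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([np.linspace(0, 30, 50), np.linspace(122, 152, 50)])
        g = rng.binomial(2, 0.5, 100)
        d = np.full(100, 50)
        mu = 0.01 + g / 2 * 0.98
        ref = rng.binomial(d, mu)
        out = end_differentiation(ref, d - ref, x)
        assert out["fst"].item() < 0.05

    def test_fixed_difference(self):
        x = np.concatenate([np.linspace(0, 30, 50), np.linspace(122, 152, 50)])
        g = np.where(x < 80, 2, 0)
        d = np.full(100, 60)
        ref = (d * g // 2)
        out = end_differentiation(ref, d - ref, x, error_rate=0.001)
        assert out["delta_p"].item() == pytest.approx(1.0)
        assert out["fst"].item() == pytest.approx(1.0)

    def test_hudson_estimator_hand_value(self):
        # two samples: p1 = 0.2 (n=40 alleles), p2 = 0.7 (n=60 alleles)
        p1, n1, p2, n2 = 0.2, 40, 0.7, 60
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert hudson_fst(p1, n1, p2, n2) == pytest.approx(num / den, abs=1e-12)

    def test_empty_region_rejected(self):
        with pytest.raises(ConfigurationError):
            end_differentiation([[1]], [[1]], [75.0],
                                end_regions=((0, 30), (122, 152)))


def test_ml_genotype_calls_thresholds():
    ref = np.array([20, 10, 0, 0])
    alt = np.array([0, 10, 20, 0])
    calls = ml_genotype_calls(ref, alt)
    assert list(calls) == [2, 1, 0, -1]
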