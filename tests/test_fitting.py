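"""SNP cline fitting: model selection, var.ex oracle, width floor, filters."""

import numpy as np
import pandas as pd
import pytest

from shoreclines.architecture import LinkageMap
from shoreclines.cline_models import ClineModel, ClineParams, cline_frequency
from shoreclines.filters import FilterConfig, filter_snps, hwe_exact_test
from shoreclines.fitting import (
    LikelihoodConfig,
    ReadDepthClineFitter,
    fit_snp_cline,
    select_cline_model,
    variance_explained,
)
from shoreclines.io import SnpReadMatrix
from shoreclines.synth import generate_cline_snp_reads

RNG = np.random.default_rng(123)
POSITIONS = np.sort(RNG.uniform(0, 152, 373))


class TestFitSnpCline:
    def test_clinal_models_nest_the_null(self):
        flat = ClineParams(ClineModel.NULL, p_c=0.4)
        ref, alt, _ = generate_cline_snp_reads(flat, POSITIONS, seed=0)
        res = fit_snp_cline(ref, alt, POSITIONS, rng=0)
        logl = {m: d["logl"] for m, d in res.models.items()}
        assert logl[ClineModel.SIGMOID] >= logl[ClineModel.NULL] - 1e-6

    def test_sigmoid_parameter_recovery_short(self):
        true = ClineParams(ClineModel.SIGMOID, p_c=0.1, p_w=0.9, center=85,
                           width=10)
        c_hits, widths = 0, []
        for s in range(12):
            ref, alt, _ = generate_cline_snp_reads(
                true, POSITIONS, depth_mean=30, depth_dispersion=None, seed=s)
            res = fit_snp_cline(ref, alt, POSITIONS, rng=s)
            sig = res.models[ClineModel.SIGMOID]["params"]
            c_hits += abs(sig.center - 85) <= 2
            widths.append(sig.width)
        assert c_hits >= 9
        # width is weakly identified at this depth; its median is unbiased
        assert abs(np.median(widths) - 10) <= 2.5

    def test_step_data_hits_width_floor(self):
        # near-instantaneous frequency change at very high depth: the
        # fitted width parks exactly on the 1 m lower bound
        p = np.where(POSITIONS < 85, 0.0, 1.0)
        rng = np.random.default_rng(5)
        g = rng.binomial(2, p)
        depth = np.full(len(p), 200)
        mu = 0.01 + (g / 2) * 0.98
        ref = rng.binomial(depth, mu)
        res = fit_snp_cline(ref, depth - ref, POSITIONS, rng=5)
        assert res.clinal
        assert res.params.width == pytest.approx(1.0, abs=1e-9)

    def test_too_few_individuals_flagged(self):
        ref = np.zeros(373, dtype=int)
        ref[:5] = 10
        res = fit_snp_cline(ref, np.zeros_like(ref), POSITIONS)
        assert not res.ok and res.note == "too_few_individuals"

    def test_estimator_api(self):
        true = ClineParams(ClineModel.SIGMOID, p_c=0.1, p_w=0.9, center=85,
                           width=10)
        ref, alt, _ = generate_cline_snp_reads(true, POSITIONS, seed=2)
        est = ReadDepthClineFitter(random_state=0).fit(
            POSITIONS, np.column_stack([ref, alt]))
        assert est.clinal_
        pred = est.predict([0.0, 152.0])
        assert pred[0] < 0.3 < 0.7 < pred[1]
        assert est.get_params()["error_rate"] == 0.01


class TestModelSelection:
    def test_all_equal_aics_retain_null(self):
        aics = {m: 100.0 for m in ClineModel}
        best, clinal = select_cline_model(aics)
        assert best is ClineModel.NULL and not clinal

    def test_delta_aic_exactly_four_not_clinal(self):
        aics = {ClineModel.NULL: 104.0, ClineModel.SIGMOID: 100.0,
                ClineModel.LEFT_TAILED: 104.0, ClineModel.RIGHT_TAILED: 104.0,
                ClineModel.TWO_TAILED: 104.0}
        best, clinal = select_cline_model(aics)
        assert not clinal

    def test_complexity_ladder(self):
        # a more complex model wins only by beating every simpler clinal
        # model by more than 4 AIC units
        aics = {ClineModel.NULL: 200.0, ClineModel.SIGMOID: 100.0,
                ClineModel.LEFT_TAILED: 97.0, ClineModel.RIGHT_TAILED: 98.0,
                ClineModel.TWO_TAILED: 94.0}
        best, clinal = select_cline_model(aics)
        assert clinal and best is ClineModel.SIGMOID  # no >4 step anywhere
        aics[ClineModel.LEFT_TAILED] = 95.0  # beats sigmoid by 5
        best, _ = select_cline_model(aics)
        assert best is ClineModel.LEFT_TAILED
        # two-tailed beats sigmoid by >4 but not the one-tailed models
        aics[ClineModel.TWO_TAILED] = 93.0
        best, _ = select_cline_model(aics)
        assert best is ClineModel.LEFT_TAILED
        aics[ClineModel.TWO_TAILED] = 80.0  # now beats everything by >4
        best, _ = select_cline_model(aics)
        assert best is ClineModel.TWO_TAILED

    def test_strong_two_tailed_cline_selected(self):
        # a stepped cline (steep center, slow symmetric tails) sampled
        # densely enough that the 4 extra tail parameters earn their AIC
        # penalty under the conservative complexity ladder
        x = np.sort(np.random.default_rng(42).uniform(0, 152, 1000))
        true = ClineParams(ClineModel.TWO_TAILED, p_c=0.02, p_w=0.98,
                           center=76, width=6.0, delta_l=2, tau_l=0.05,
                           delta_r=2, tau_r=0.05)
        wins = 0
        for s in range(8):
            ref, alt, _ = generate_cline_snp_reads(
                true, x, depth_mean=100, depth_dispersion=None, seed=s)
            res = fit_snp_cline(ref, alt, x, rng=s)
            if res.best_model is ClineModel.TWO_TAILED:
                wins += 1
        assert wins >= 5


class TestVarianceExplained:
    def test_null_model_explains_nothing(self):
        p = ClineParams(ClineModel.NULL, p_c=0.37)
        assert variance_explained(p, POSITIONS, np.linspace(0, 1, 373),
                                  np.ones(373)) == 0.0

    def test_perfect_fit_is_100(self):
        params = ClineParams(ClineModel.SIGMOID, p_c=0.1, p_w=0.9, center=85,
                             width=10)
        y = np.atleast_1d(cline_frequency(params, POSITIONS))
        assert variance_explained(params, POSITIONS, y, np.full(373, 7.0)) \
            == pytest.approx(100.0, abs=1e-9)

    def test_matches_weighted_regression_oracle(self):
        # independent oracle: weighted R^2 computed with lstsq residuals
        rng = np.random.default_rng(8)
        params = ClineParams(ClineModel.SIGMOID, p_c=0.05, p_w=0.95,
                             center=85, width=6)
        d = rng.integers(0, 60, size=373).astype(float)
        y = np.atleast_1d(cline_frequency(params, POSITIONS)) \
            + rng.normal(0, 0.1, 373)
        got = variance_explained(params, POSITIONS, y, d)
        m = d > 0
        w = d[m]
        fitted = np.atleast_1d(cline_frequency(params, POSITIONS[m]))
        ybar = np.sum(w * y[m]) / w.sum()
        r2 = 1 - np.sum(w * (y[m] - fitted) ** 2) / np.sum(w * (y[m] - ybar) ** 2)
        assert got == pytest.approx(100 * r2, abs=1e-9)

    def test_permuting_positions_destroys_signal(self):
        true = ClineParams(ClineModel.SIGMOID, p_c=0.02, p_w=0.98, center=85,
                           width=5)
        drops = []
        rng = np.random.default_rng(11)
        for s in range(6):
            ref, alt, _ = generate_cline_snp_reads(true, POSITIONS,
                                                   depth_mean=30, seed=s)
            v1 = fit_snp_cline(ref, alt, POSITIONS, rng=s).var_ex
            perm = rng.permutation(len(POSITIONS))
            v2 = fit_snp_cline(ref, alt, POSITIONS[perm], rng=s).var_ex
            drops.append((v1 - v2) / max(v1, 1e-9))
        assert np.median(drops) > 0.5


class TestFilters:
    def _matrix(self, n_snps, n_ind, rng, p=0.5, depth=20):
        g = rng.binomial(2, p, size=(n_snps, n_ind))
        d = np.full((n_snps, n_ind), depth)
        mu = 0.01 + (g / 2) * 0.98
        ref = rng.binomial(d, mu)
        return ref, d - ref

    def test_map_distance_boundary(self):
        rng = np.random.default_rng(1)
        ref, alt = self._matrix(2, 80, rng)
        mat = SnpReadMatrix(
            snp_id=np.array(["near", "far"]),
            contig=np.array(["c1", "c1"]), bp=np.array([5999, 6001]),
            ref=ref, alt=alt,
        )
        lmap = LinkageMap(pd.DataFrame(
            {"contig": ["c1"], "bp": [5000], "lg": [1], "cm": [0.0]}))
        x = np.concatenate([np.linspace(0, 30, 40), np.linspace(122, 152, 40)])
        kept, log = filter_snps(mat, x, lmap)
        assert list(kept.snp_id) == ["near"]
        assert log.loc[log.snp_id == "far", "reason"].item().startswith("no_map")

    def test_universal_heterozygote_fails_hwe(self):
        n = 80
        rng = np.random.default_rng(2)
        ref_ok, alt_ok = self._matrix(1, n, rng)
        # SNP heterozygous in every individual
        d = np.full((1, n), 30)
        het_mu = 0.5
        ref_bad = rng.binomial(d, het_mu)
        mat = SnpReadMatrix(
            snp_id=np.array(["ok", "allhet"]), contig=np.array(["c1", "c1"]),
            bp=np.array([5000, 5100]),
            ref=np.vstack([ref_ok, ref_bad]),
            alt=np.vstack([alt_ok, d - ref_bad]),
        )
        lmap = LinkageMap(pd.DataFrame(
            {"contig": ["c1"], "bp": [5000], "lg": [1], "cm": [0.0]}))
        x = np.concatenate([np.linspace(0, 30, 40), np.linspace(122, 152, 40)])
        kept, log = filter_snps(mat, x, lmap)
        assert "allhet" not in list(kept.snp_id)
        assert log.loc[log.snp_id == "allhet", "reason"].item() == "hwe_departure"

    def test_planted_violations_all_caught(self):
        # 100 SNPs: 90 clean, 4 unmapped, 3 monomorphic, 3 sex-associated
        rng = np.random.default_rng(3)
        n_ind = 120
        x = np.concatenate([np.linspace(0, 30, 60), np.linspace(122, 152, 60)])
        sex = np.array(["F", "M"] * 60)
        ref, alt = self._matrix(100, n_ind, rng, p=0.5)
        bps = np.full(100, 5000)
        planted = {}
        for i in range(90, 94):
            bps[i] = 8000  # > 1000 bp from the mapped SNP
            planted[f"s{i}"] = {"no_map_within_1000bp"}
        for i in range(94, 97):
            d = ref[i] + alt[i]
            ref[i] = d  # monomorphic reference
            alt[i] = 0
            planted[f"s{i}"] = {"monomorphic_or_low_maf"}
        for i in range(97, 100):
            g = np.where(sex == "F", 2, 0)
            d = np.full(n_ind, 20)
            mu = 0.01 + (g / 2) * 0.98
            ref[i] = rng.binomial(d, mu)
            alt[i] = d - ref[i]
            # sex-fixed genotypes also violate HWE within regions; either
            # filter may fire first
            planted[f"s{i}"] = {"sex_difference", "hwe_departure"}
        mat = SnpReadMatrix(
            snp_id=np.array([f"s{i}" for i in range(100)]),
            contig=np.array(["c1"] * 100), bp=bps, ref=ref, alt=alt)
        lmap = LinkageMap(pd.DataFrame(
            {"contig": ["c1"], "bp": [5000], "lg": [1], "cm": [0.0]}))
        cfg = FilterConfig()
        kept, log = filter_snps(mat, x, lmap, sex=sex, cfg=cfg)
        excluded = dict(zip(log.loc[~log.kept, "snp_id"],
                            log.loc[~log.kept, "reason"]))
        for sid, acceptable in planted.items():
            assert sid in excluded, f"{sid} should have been excluded"
            assert excluded[sid] in acceptable
        # sex-fixed SNPs fail HWE or the sex test; either way they are gone,
        # and no clean SNP is lost
        assert len(kept.snp_id) == 90

    def test_hwe_exact_test_matches_enumeration(self):
        # tiny case checked against direct enumeration of the conditional
        # distribution of heterozygote counts
        from math import comb

        n_het, n_a, n_b = 2, 4, 4  # 10 individuals, rare allele count 10
        n = n_het + n_a + n_b
        rare = 2 * min(n_a, n_b) + n_het

        def prob(h):
            hr = (rare - h) // 2
            hc = n - h - hr
            return (comb(n, h) * comb(n - h, hr) * 2 ** h) if (rare - h) % 2 == 0 else 0

        weights = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
        tot = sum(weights.values())
        obs = weights[n_het] / tot
        expected = sum(w for w in weights.values() if w / tot <= obs + 1e-12) / tot
        assert hwe_exact_test(n_het, n_a, n_b) == pytest.approx(expected, rel=1e-9)
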