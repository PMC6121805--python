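"""Reference experiments that exercise the whole pipeline.

Each function re-runs one well-defined experiment from scratch -- the
neutral null and its var.ex threshold, the parameter-recovery study, the
simulator calibration checks, the planted-truth recovery on synthetic
data, and the dispersal round trip -- and returns a dict of summary
numbers.  They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import detect_nn_blocks
from .classify import (
    classify_snps,
    ml_genotype_calls,
    neutral_varex_threshold,
)
from .cline_models import ClineModel, ClineParams
from .fitting import LikelihoodConfig, fit_many, fit_snp_cline
from .pipeline import dispersal_from_simulation, neutral_null_varex, stage_seed
from .simulate import SimulationConfig, run_simulation
from .synth import SynthConfig, generate_cline_snp_reads, generate_study_like_dataset

SENSITIVITY_SCENARIOS = {
    "sigma_1.09": dict(sigma=1.09),
    "sigma_1.70": dict(sigma=1.70),
    "N_50": dict(n_per_deme=50),
    "N_200": dict(n_per_deme=200),
    "secondary_contact": dict(model="secondary_contact"),
}


def neutral_null_summary(seed: int, n_neutral: int = 500, sim_cfg=None,
                         fits: pd.DataFrame | None = None) -> dict:
    """Neutral clinal fraction and the 99%-quantile var.ex threshold for
    one simulation scenario (the default study conditions unless given)."""
    if fits is None:
        cfg = sim_cfg or SimulationConfig(n_neutral=n_neutral)
        fits = neutral_null_varex(cfg, LikelihoodConfig(), seed=seed)
    clinal = fits["clinal"].to_numpy(bool)
    varex = fits.loc[clinal, "var_ex"].to_numpy(float)
    thr = neutral_varex_threshold(varex, 0.99) if clinal.sum() >= 100 else np.nan
    return {
        "n_neutral_polymorphic": int(len(fits)),
        "clinal_fraction_pct": 100.0 * float(np.mean(clinal)),
        "varex_threshold": float(thr),
        "fits": fits,
    }


def sensitivity_thresholds(seed: int, n_neutral: int = 250) -> dict:
    """var.ex thresholds across the sigma/N/secondary-contact sweep."""
    out = {}
    for i, (name, kw) in enumerate(SENSITIVITY_SCENARIOS.items()):
        cfg = SimulationConfig(n_neutral=n_neutral, **kw)
        res = neutral_null_summary(stage_seed(seed, name), sim_cfg=cfg)
        out[name] = {k: v for k, v in res.items() if k != "fits"}
    return out


def parameter_recovery(seed: int, n_reps: int = 100, depth: float = 30.0,
                       n_individuals: int = 373) -> dict:
    """Recovery of a known sigmoid cline (p_C=0.1, p_W=0.9, c=85 m,
    w=10 m) from read depths, over seeded replicates."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 152, n_individuals))
    true = ClineParams(ClineModel.SIGMOID, p_c=0.1, p_w=0.9, center=85,
                       width=10)
    c_hits = w_hits = joint = 0
    for rep in range(n_reps):
        ref, alt, _ = generate_cline_snp_reads(
            true, x, depth_mean=depth, depth_dispersion=None,
            seed=stage_seed(seed, f"rec-{rep}"))
        res = fit_snp_cline(ref, alt, x, rng=stage_seed(seed, f"fit-{rep}"))
        sig = res.models[ClineModel.SIGMOID]["params"]
        c_ok = abs(sig.center - 85.0) <= 2.0
        w_ok = abs(sig.width - 10.0) <= 2.5
        c_hits += c_ok
        w_hits += w_ok
        joint += c_ok and w_ok
    return {
        "n_reps": n_reps,
        "center_within_2m_pct": 100.0 * c_hits / n_reps,
        "width_within_25pct_pct": 100.0 * w_hits / n_reps,
        "joint_recovery_pct": 100.0 * joint / n_reps,
    }


def simulator_calibration(seed: int, sim=None) -> dict:
    """Single-deme drift vs the Wright-Fisher closed form, selected-locus
    cline centers vs the habitat boundary, and width vs selection."""
    # drift variance
    N, t = 100, 20
    ps = []
    for rep in range(250):
        cfg = SimulationConfig(n_demes=1, habitat_switch_after_deme=0,
                               n_per_deme=N, sigma=0.0, s_total=0.0,
                               n_selected=0, n_neutral=32, generations=t,
                               thin=t, seed=stage_seed(seed, f"wf-{rep}"))
        ps.append(run_simulation(cfg).final_freq[0])
    ps = np.asarray(ps)
    var_emp = float(ps.var(axis=0).mean())
    var_wf = 0.25 * (1 - (1 - 1 / (2 * N)) ** t)

    # selected-locus centers under the default scenario
    if sim is None:
        sim = run_simulation(SimulationConfig(),
                             seed=stage_seed(seed, "simulate"))
    from .simulate import profile_cline_center

    freq = sim.final_freq
    sel = np.nonzero(sim.selected)[0]
    centers = [profile_cline_center(freq[:, j]) for j in sel]

    # width monotonicity in s_total (least-squares sigmoid on the mean
    # selected-locus profile; independent of the ML pipeline)
    from scipy.optimize import curve_fit

    def sig(x, pc, pw, c, w):
        return pc + (pw - pc) / (1 + np.exp(-4 * (x - c) / w))

    xg = np.arange(152) + 0.5
    widths = {}
    for s_tot in (0.1, 0.4, 0.7):
        med = []
        for rep in range(3):
            cfg = SimulationConfig(n_per_deme=50, n_selected=50, n_neutral=0,
                                   generations=400, s_total=s_tot, thin=400,
                                   seed=stage_seed(seed, f"s{s_tot}-{rep}"))
            f = run_simulation(cfg).final_freq.mean(axis=1)
            p, _ = curve_fit(sig, xg, f, p0=[0.2, 0.8, 85, 20],
                             bounds=([0, 0, 0, 0.5], [1, 1, 152, 400]),
                             maxfev=5000)
            med.append(p[3])
        widths[s_tot] = float(np.median(med))

    return {
        "wf_drift_variance_ratio": var_emp / var_wf,
        "selected_center_median_m": float(np.median(centers)),
        "habitat_boundary_m": 85.0,
        "width_by_s_total": widths,
        "width_monotone_decreasing": widths[0.1] > widths[0.4] > widths[0.7],
    }


def planted_truth_recovery(seed: int, ds=None, fits: pd.DataFrame | None = None
                           ) -> dict:
    """End-to-end recovery of planted selected SNPs and LD blocks from the
    synthetic study-like dataset, thresholding on the same generator's
    neutral SNPs."""
    if ds is None:
        ds = generate_study_like_dataset(SynthConfig(seed=stage_seed(seed, "synth")))
    if fits is None:
        fits = fit_many(ds.reads.ref, ds.reads.alt, ds.positions,
                        LikelihoodConfig(), seed=stage_seed(seed, "fit"),
                        snp_ids=list(ds.reads.snp_id))
    merged = fits.merge(ds.truth, on="snp_id")
    neutral = ~merged["selected"].to_numpy(bool)
    null_varex = merged.loc[neutral & merged["clinal"], "var_ex"].to_numpy()
    thr = neutral_varex_threshold(null_varex, 0.99)
    classified = classify_snps(merged, thr)
    flagged = (classified["category"] == "non_neutral").to_numpy()
    n_sel = int((~neutral).sum())

    # block detection on the classified SNPs (true map positions)
    classified["mapped"] = True
    dosages = ml_genotype_calls(ds.reads.ref, ds.reads.alt)
    lo, hi = ds.positions.min(), ds.positions.max()
    groups = {"crab_end": ds.positions <= lo + 30,
              "wave_end": ds.positions >= hi - 30}
    blocks = detect_nn_blocks(classified, flagged, dosages, groups,
                              seed=stage_seed(seed, "blocks"))
    truth_blocks = ds.manifest["blocks"]
    matched = 0
    boundary_errs = []
    for tb in truth_blocks:
        cands = [b for b in blocks if b.lg == tb["lg"]]
        if not cands:
            continue
        err = min(max(abs(b.cm_start - tb["cm_start"]),
                      abs(b.cm_end - tb["cm_end"])) for b in cands)
        boundary_errs.append(err)
        if err <= 3.0:
            matched += 1
    return {
        "n_planted_selected": n_sel,
        "n_planted_flagged": int(flagged[~neutral].sum()),
        "neutral_false_positive_pct": 100.0 * float(flagged[neutral].mean()),
        "varex_threshold": float(thr),
        "n_true_blocks": len(truth_blocks),
        "n_blocks_detected_on_true_lgs": int(
            len({b.lg for b in blocks} & {tb["lg"] for tb in truth_blocks})),
        "n_blocks_matched_within_3cm": matched,
        "max_boundary_error_cm": (float(np.max(boundary_errs))
                                  if boundary_errs else np.nan),
    }


def oracle_agreement(seed: int = 0) -> dict:
    """Brute-force cross-checks of the core numerics.

    Compares (a) the read-depth likelihood against direct 3-genotype
    binomial-mixture enumeration on tiny read counts, (b) var.ex against a
    hand-rolled weighted R-squared, and (c) permutation cluster p-values
    against exact enumeration over all C(10, 3) labelings.
    """
    import math
    from itertools import combinations

    from .architecture import permutation_cluster_test
    from .cline_models import cline_frequency
    from .fitting import read_depth_loglik, variance_explained

    rng = np.random.default_rng(seed)

    # (a) likelihood vs enumeration, depths <= 4
    max_ll_err = 0.0
    for _ in range(60):
        n_ind = int(rng.integers(1, 8))
        ref = rng.integers(0, 3, n_ind)
        alt = rng.integers(0, 3, n_ind)
        x = rng.uniform(0, 152, n_ind)
        eps = float(rng.uniform(0, 0.2))
        params = ClineParams(ClineModel.SIGMOID, p_c=rng.uniform(0.05, 0.45),
                             p_w=rng.uniform(0.55, 0.95),
                             center=rng.uniform(10, 140),
                             width=rng.uniform(1, 80))
        pvals = np.atleast_1d(cline_frequency(params, x))
        expected = 0.0
        for r, a, p in zip(ref, alt, pvals):
            if r + a == 0:
                continue
            like = 0.0
            for g, prior in ((0, (1 - p) ** 2), (1, 2 * p * (1 - p)),
                             (2, p * p)):
                mu = eps + (g / 2) * (1 - 2 * eps)
                like += prior * math.comb(r + a, r) * mu ** r * (1 - mu) ** a
            expected += math.log(like)
        got = read_depth_loglik(ref, alt, x, params,
                                LikelihoodConfig(error_rate=eps))
        max_ll_err = max(max_ll_err, abs(got - expected))

    # (b) var.ex vs weighted regression R^2
    max_vx_err = 0.0
    for _ in range(20):
        params = ClineParams(ClineModel.SIGMOID, p_c=0.05, p_w=0.95,
                             center=rng.uniform(60, 100),
                             width=rng.uniform(3, 30))
        x = rng.uniform(0, 152, 200)
        d = rng.integers(0, 50, 200).astype(float)
        y = np.atleast_1d(cline_frequency(params, x)) + rng.normal(0, 0.1, 200)
        got = variance_explained(params, x, y, d)
        m = d > 0
        w = d[m]
        fit = np.atleast_1d(cline_frequency(params, x[m]))
        ybar = np.sum(w * y[m]) / w.sum()
        r2 = 1 - np.sum(w * (y[m] - fit) ** 2) / np.sum(w * (y[m] - ybar) ** 2)
        max_vx_err = max(max_vx_err, abs(got - 100 * min(r2, 1.0)))

    # (c) permutation p-values vs exact enumeration, 10 SNPs / 2 LGs / 3 labels
    mapped = pd.DataFrame({
        "contig": [f"c{i}" for i in range(10)], "bp": [5000] * 10,
        "lg": [1] * 6 + [2] * 4, "cm": [1.0] * 10, "mapped": [True] * 10,
    })
    labels = np.array([False] * 6 + [True, True, True, False])
    out = permutation_cluster_test(mapped, labels, "linkage_group",
                                   n_perm=200000, seed=seed)
    max_pm_err = 0.0
    for lg, size, offset in ((1, 6, 0), (2, 4, 6)):
        obs = labels[offset:offset + size].mean()
        count = sum(1 for c in combinations(range(10), 3)
                    if sum(offset <= i < offset + size for i in c) / size
                    >= obs - 1e-15)
        exact = count / 120
        got = out.loc[out["unit"] == str(lg), "p_value"].item()
        max_pm_err = max(max_pm_err, abs(got - exact))

    return {
        "loglik_enumeration_max_abs_err": float(max_ll_err),
        "varex_regression_max_abs_err": float(max_vx_err),
        "permutation_exact_max_abs_err": float(max_pm_err),
    }


def dispersal_roundtrip(seed: int, n_reps: int = 10, generations: int = 1000
                        ) -> dict:
    """sigma estimated from LD at the cline center of replicate
    simulations with true sigma = 1.46 m."""
    sigmas = []
    for rep in range(n_reps):
        cfg = SimulationConfig(n_selected=200, n_neutral=0,
                               generations=generations, thin=generations,
                               seed=stage_seed(seed, f"disp-{rep}"))
        sim = run_simulation(cfg)
        est = dispersal_from_simulation(sim, n_pairs=16,
                                        seed=stage_seed(seed, f"pairs-{rep}"))
        sigmas.append(est.sigma_hat)
    sigmas = np.asarray(sigmas, dtype=float)
    return {
        "true_sigma_m": 1.46,
        "sigma_hat_median_m": float(np.nanmedian(sigmas)),
        "sigma_hat_per_replicate": [float(s) for s in sigmas],
        "relative_error_pct": 100.0 * abs(float(np.nanmedian(sigmas)) - 1.46) / 1.46,
    }
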