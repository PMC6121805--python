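"""End-to-end orchestration of the hybrid-zone analysis.

Stage order mirrors the analysis: transect path -> SNP filters -> SNP
clines -> neutral simulations -> var.ex threshold -> classification ->
clustering / LD / blocks -> phenotype clines -> dispersal from LD.  Every
stochastic stage receives a seed derived deterministically from the global
seed and the stage name, so stages can be re-run independently and a full
run is reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import detect_nn_blocks, pairwise_ld, permutation_cluster_test
from .classify import (
    classification_counts,
    classify_snps,
    em_gametic_d,
    end_differentiation,
    estimate_dispersal_from_ld,
    ml_genotype_calls,
    neutral_varex_threshold,
    summarize_nonneutral_centers,
)
from .exceptions import ConfigurationError, ShoreclinesError
from .filters import FilterConfig, filter_snps
from .fitting import LikelihoodConfig, fit_many
from .io import SnpReadMatrix
from .phenotypes import fit_morph_cline, fit_trait_cline, scale_quantitative_trait
from .simulate import SimulationConfig, run_simulation, sample_transect
from .transect import TransectPathFitter, detect_habitat_transitions

log = logging.getLogger("shoreclines")

__all__ = ["RunConfig", "run_full_analysis", "stage_seed",
           "neutral_null_varex", "dispersal_from_simulation"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    outdir: str = "shoreclines_run"
    seed: int = 0
    n_segments: int = 11
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quantile: float = 0.99
    n_perm: int = 10000
    trait_columns: tuple = ("size", "shape")
    trait_increasing: dict = field(default_factory=lambda: {"size": False})
    morph_columns: tuple = ("beige", "dark_beige", "black", "banded")
    run_simulation_null: bool = True
    null_varex_file: str | None = None
    cluster_scales: tuple = ("linkage_group", "map_position", "window_10cM")


def neutral_null_varex(sim_cfg: SimulationConfig, lik_cfg: LikelihoodConfig,
                       seed: int, n_individuals: int = 373,
                       depth_mean: float = 20.0, depth_dispersion: float = 5.0,
                       progress: bool = False, sim=None) -> pd.DataFrame:
    """Simulate the neutral null and fit clines to every neutral locus.

    Returns the per-locus fit table for the *neutral, polymorphic* loci of
    one simulation run, sampled with the study-like transect profile.
    Pass ``sim`` to reuse an existing simulation output.
    """
    if sim is None:
        sim = run_simulation(sim_cfg, seed=stage_seed(seed, "simulate"))
    st = sample_transect(sim, n_individuals=n_individuals,
                         depth_mean=depth_mean,
                         depth_dispersion=depth_dispersion,
                         seed=stage_seed(seed, "sample"))
    neutral = ~st.selected
    ref = st.ref[neutral]
    alt = st.alt[neutral]
    depth = ref + alt
    with np.errstate(invalid="ignore"):
        frac = np.divide(ref.sum(axis=1), depth.sum(axis=1),
                         out=np.full(ref.shape[0], np.nan),
                         where=depth.sum(axis=1) > 0)
    poly = np.isfinite(frac) & (np.minimum(frac, 1 - frac) >= 0.01)
    fits = fit_many(ref[poly], alt[poly], st.positions, lik_cfg,
                    seed=stage_seed(seed, "fit-null"), progress=progress)
    fits["locus"] = np.nonzero(neutral)[0][poly]
    return fits


def _profile_cline_summary(freq: np.ndarray, deme_width: float = 1.0,
                           smooth: int = 9, lag: int = 4):
    """(center, width, |dp|) of one per-deme frequency profile.

    The profile is boxcar-smoothed and the maximum gradient taken from
    long-lag central differences, so binomial sampling noise in the
    per-deme frequencies (SD ~ sqrt(pq/2N)) does not masquerade as a steep
    cline.  Width is |dp| / max gradient, the same definition the cline
    models use.
    """
    ones = np.ones(smooth)
    # edge-corrected moving average (zero-padding would fake steep
    # gradients at the chain ends)
    f = np.convolve(freq, ones, mode="same") / \
        np.convolve(np.ones_like(freq), ones, mode="same")
    dp = f[-(smooth + 1):].mean() - f[:smooth + 1].mean()
    grad = (f[2 * lag:] - f[:-2 * lag]) / (2 * lag * deme_width)
    i = int(np.argmax(np.abs(grad)))
    gmax = abs(grad[i])
    if gmax <= 0:
        return np.nan, np.nan, abs(dp)
    center = (i + lag + 0.5) * deme_width
    return float(center), float(abs(dp) / gmax), float(abs(dp))


def dispersal_from_simulation(sim, n_pairs: int = 16, seed: int = 0,
                              center_window_m: float = 2.0):
    """Round-trip dispersal estimate from LD at the simulated cline center.

    Per-locus widths and end-frequency differences come from noise-robust
    gradients of the per-deme frequency profiles; gametic D is the EM
    estimate between selected-locus pairs among individuals within
    ``center_window_m`` of the mean center.  The window must stay narrow
    relative to the cline width: composite D over a wide window picks up
    the spatial covariance of allele frequencies (admixture LD) on top of
    the within-deme gametic LD that the cline-theory relation refers to.
    """
    rng = np.random.default_rng(seed)
    freq = sim.final_freq
    sel = np.nonzero(sim.selected)[0]
    summaries = [_profile_cline_summary(freq[:, j], sim.config.deme_width)
                 for j in sel]
    centers = np.array([s[0] for s in summaries])
    widths = np.array([s[1] for s in summaries])
    dps = np.array([s[2] for s in summaries])
    ok = np.isfinite(widths) & (widths > 0) & (dps > 0.2)
    sel, centers, widths, dps = sel[ok], centers[ok], widths[ok], dps[ok]
    if len(sel) < 4:
        raise ShoreclinesError("too few usable selected clines for dispersal")
    c_mean = centers.mean()
    near = np.abs((sim.deme + 0.5) * sim.config.deme_width - c_mean) \
        <= center_window_m
    g = sim.genotypes[near]
    d_vals, w1s, w2s, p1s, p2s = [], [], [], [], []
    for _ in range(n_pairs):
        i, j = rng.choice(len(sel), size=2, replace=False)
        d = em_gametic_d(g[:, sel[i]], g[:, sel[j]])
        if not np.isfinite(d):
            continue
        d_vals.append(d)
        w1s.append(widths[i])
        w2s.append(widths[j])
        p1s.append(dps[i])
        p2s.append(dps[j])
    est = estimate_dispersal_from_ld(d_vals, w1s, w2s, p1s, p2s, r=0.5)
    return est


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def run_full_analysis(samples: pd.DataFrame, habitat, reads: SnpReadMatrix,
                      lmap, cfg: RunConfig) -> dict:
    """Run all stages on in-memory inputs; writes tables under cfg.outdir.

    ``samples`` must carry id/x/y plus trait and morph columns and a
    ``genotyped`` flag aligning the read matrix with its True rows.
    Returns the consolidated summary dict (also written as summary.json).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": []}
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        summary["stages"].append(name)

    try:
        # ---- transect path ------------------------------------------------
        stage("path-fit")
        fitter = TransectPathFitter(n_segments=cfg.n_segments)
        xy = samples[["x", "y"]].to_numpy(float)
        fitter.fit(xy)
        proj = fitter.transform(xy)
        samples = samples.copy()
        samples["path_pos"] = proj[:, 0]
        samples["path_dist"] = proj[:, 1]
        samples.to_csv(out / "samples_projected.csv", index=False)
        transitions = []
        if habitat is not None:
            transitions = list(detect_habitat_transitions(habitat, fitter.path_))
        summary["path"] = {"objective_m2": fitter.objective_,
                           "total_length_m": fitter.path_.total_length,
                           "habitat_transitions_m": transitions}

        geno_mask = samples["genotyped"].to_numpy(bool) \
            if "genotyped" in samples else np.ones(len(samples), bool)
        positions = samples.loc[geno_mask, "path_pos"].to_numpy(float)
        if len(positions) != reads.n_individuals:
            raise ConfigurationError(
                "genotyped sample count does not match read matrix"
            )

        # ---- filters ------------------------------------------------------
        stage("filter")
        sex = samples.loc[geno_mask, "sex"].to_numpy() \
            if "sex" in samples else None
        filtered, flog = filter_snps(reads, positions, lmap, sex, cfg.filters)
        flog.to_csv(out / "filter_log.tsv", sep="\t", index=False)
        summary["filters"] = {
            "n_input": reads.n_snps, "n_kept": filtered.n_snps,
            "reasons": flog[~flog["kept"]]["reason"].value_counts().to_dict(),
        }

        # ---- SNP clines ---------------------------------------------------
        stage("fit-clines")
        fits = fit_many(filtered.ref, filtered.alt, positions, cfg.likelihood,
                        seed=stage_seed(cfg.seed, "fit-clines"),
                        snp_ids=list(filtered.snp_id))
        fits["contig"] = filtered.contig
        fits["bp"] = filtered.bp
        fits["lg"] = filtered.lg
        fits["cm"] = filtered.cm
        fits["mapped"] = filtered.lg >= 0
        fits.to_csv(out / "snp_clines.tsv", sep="\t", index=False)
        summary["clines"] = {
            "n_fitted": int(fits["ok"].sum()),
            "n_clinal": int(fits["clinal"].sum()),
            "prop_clinal": float(fits["clinal"].mean()) if len(fits) else np.nan,
        }

        # ---- neutral null -------------------------------------------------
        stage("threshold")
        if cfg.null_varex_file:
            null_varex = np.loadtxt(cfg.null_varex_file)
        elif cfg.run_simulation_null:
            null_fits = neutral_null_varex(cfg.simulation, cfg.likelihood,
                                           cfg.seed,
                                           n_individuals=reads.n_individuals)
            null_fits.to_csv(out / "null_fits.tsv", sep="\t", index=False)
            null_varex = null_fits.loc[null_fits["clinal"], "var_ex"].to_numpy()
        else:
            raise ConfigurationError("no neutral null source configured")
        threshold = neutral_varex_threshold(null_varex, cfg.quantile)
        summary["threshold"] = {
            "quantile": cfg.quantile, "value": float(threshold),
            "n_null": int(len(null_varex)),
            "quantile_definition": "linear interpolation of order statistics",
        }

        # ---- classification ----------------------------------------------
        stage("classify")
        classified = classify_snps(fits, threshold)
        classified.to_csv(out / "snp_classified.tsv", sep="\t", index=False)
        summary["classification"] = classification_counts(classified)
        summary["nonneutral_centers"] = summarize_nonneutral_centers(
            classified, transitions)

        # ---- differentiation ----------------------------------------------
        stage("differentiation")
        diff = end_differentiation(filtered.ref, filtered.alt, positions,
                                   error_rate=cfg.likelihood.error_rate)
        diff.insert(0, "snp_id", filtered.snp_id)
        diff.to_csv(out / "end_differentiation.tsv", sep="\t", index=False)

        # ---- clustering / LD / blocks --------------------------------------
        stage("cluster")
        labels = (classified["category"] == "non_neutral").to_numpy()
        mapped_mask = classified["mapped"].to_numpy(bool)
        cluster_tables = []
        for scale in cfg.cluster_scales:
            tab = permutation_cluster_test(
                classified[mapped_mask], labels[mapped_mask], scale,
                n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, f"perm-{scale}"))
            cluster_tables.append(tab)
        cluster_df = pd.concat(cluster_tables, ignore_index=True)
        cluster_df.to_csv(out / "cluster_tests.tsv", sep="\t", index=False)

        stage("blocks")
        dosages = ml_genotype_calls(filtered.ref, filtered.alt,
                                    cfg.likelihood.error_rate)
        lo, hi = positions.min(), positions.max()
        groups = {"crab_end": positions <= lo + cfg.filters.end_width,
                  "wave_end": positions >= hi - cfg.filters.end_width}
        blocks = detect_nn_blocks(classified, labels, dosages, groups,
                                  seed=stage_seed(cfg.seed, "blocks"))
        block_df = pd.DataFrame([
            dict(lg=b.lg, cm_start=b.cm_start, cm_end=b.cm_end,
                 length_cm=b.length_cm, n_snps=b.n_snps,
                 n_nonneutral=b.n_nonneutral,
                 **{f"mean_abs_r_{g}": v for g, v in b.mean_abs_r.items()})
            for b in blocks
        ])
        block_df.to_csv(out / "nn_blocks.tsv", sep="\t", index=False)
        summary["blocks"] = block_df.to_dict("records")

        # ---- phenotypes -----------------------------------------------------
        stage("fit-phenotypes")
        pheno_rows = []
        ppos = samples["path_pos"].to_numpy(float)
        for col in cfg.trait_columns:
            if col not in samples:
                continue
            scaled = scale_quantitative_trait(
                samples[col].to_numpy(float),
                increasing=cfg.trait_increasing.get(col, True))
            res = fit_trait_cline(scaled, ppos, cfg.likelihood,
                                  stage_seed(cfg.seed, f"trait-{col}"))
            pheno_rows.append(_pheno_row(col, "trait", res))
        for col in cfg.morph_columns:
            if col not in samples:
                continue
            res = fit_morph_cline(samples[col].to_numpy(float), ppos,
                                  cfg.likelihood,
                                  stage_seed(cfg.seed, f"morph-{col}"))
            pheno_rows.append(_pheno_row(col, "morph", res))
        pheno_df = pd.DataFrame(pheno_rows)
        pheno_df.to_csv(out / "phenotype_clines.tsv", sep="\t", index=False)
        summary["phenotypes"] = pheno_df.to_dict("records")

        # ---- dispersal from LD ---------------------------------------------
        stage("dispersal")
        summary["dispersal"] = _dispersal_from_observed(
            classified, dosages, positions, threshold,
            seed=stage_seed(cfg.seed, "dispersal"))

    except ShoreclinesError as err:
        summary["error"] = {"stage": summary["stages"][-1], "message": str(err)}
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=_jsonable)
        raise

    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    return summary


def _pheno_row(name, kind, res):
    row = dict(trait=name, kind=kind, ok=res.ok, clinal=bool(res.clinal),
               best_model=res.best_model.value, var_ex=res.var_ex,
               n_used=res.n_used)
    if res.ok and res.models:
        p = res.params
        row.update(p_c=p.p_c, p_w=p.p_w,
                   center=p.center if res.clinal else np.nan,
                   width=p.width if res.clinal else np.nan)
    return row


def _dispersal_from_observed(classified, dosages, positions, threshold,
                             n_pairs: int = 16, seed: int = 0):
    """Sigma estimate from non-neutral SNP pairs on different LGs."""
    nn = classified[(classified["category"] == "non_neutral")
                    & np.isfinite(classified["width"])]
    if len(nn) < 4:
        return {"sigma_hat_m": np.nan, "n_pairs_used": 0,
                "note": "too few non-neutral clines"}
    rng = np.random.default_rng(seed)
    idx = nn.index.to_numpy()
    centers = nn["center"].to_numpy(float)
    widths = nn["width"].to_numpy(float)
    dps = nn["abs_delta_p"].to_numpy(float)
    lgs = nn["lg"].to_numpy()
    c_mean = float(np.mean(centers))
    w_mean = float(np.mean(widths))
    near = np.abs(positions - c_mean) <= max(w_mean, 2.0)
    d_vals, w1, w2, p1, p2 = [], [], [], [], []
    tries = 0
    while len(d_vals) < n_pairs and tries < 20 * n_pairs:
        tries += 1
        i, j = rng.choice(len(idx), size=2, replace=False)
        if lgs[i] == lgs[j] or dps[i] <= 0.05 or dps[j] <= 0.05:
            continue
        # polarize both dosage vectors to the Wave-increasing allele so the
        # expected gametic D at the center is positive
        gi = dosages[idx[i]][near].astype(int)
        gj = dosages[idx[j]][near].astype(int)
        if nn["delta_p"].to_numpy(float)[i] < 0:
            gi = np.where(gi >= 0, 2 - gi, -1)
        if nn["delta_p"].to_numpy(float)[j] < 0:
            gj = np.where(gj >= 0, 2 - gj, -1)
        d = em_gametic_d(gi, gj)
        if not np.isfinite(d):
            continue
        d_vals.append(d)
        w1.append(widths[i])
        w2.append(widths[j])
        p1.append(dps[i])
        p2.append(dps[j])
    if not d_vals:
        return {"sigma_hat_m": np.nan, "n_pairs_used": 0,
                "note": "no usable pairs"}
    est = estimate_dispersal_from_ld(d_vals, w1, w2, p1, p2, r=0.5)
    return {"sigma_hat_m": est.sigma_hat, "n_pairs_used": est.n_pairs_used}
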