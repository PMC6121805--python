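"""Study-like synthetic data with known ground truth.

Generates the full set of pipeline inputs -- sample coordinates along a
wiggly 11-segment shore path with sampling gaps and a density trough,
phenotypes following trait clines, a 17-LG linkage map totalling 1011.9 cM
at ~0.2 cM resolution, and per-SNP read depths -- plus a manifest of every
generating truth.  Neutral SNPs follow gentle spatially autocorrelated
frequency curves (a smoothed random walk along the transect, mimicking
isolation-by-distance clines); selected SNPs follow steep sigmoid clines,
mostly concentrated in three planted high-LD blocks generated from shared
latent "karyotype" variables (the inversion stand-in).

This generator is the cheap, fully controlled fixture for testing the
analysis pipeline; the mechanistic neutral null comes from the forward
simulator instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import LinkageMap
from .cline_models import ClineModel, ClineParams, cline_frequency
from .exceptions import ConfigurationError
from .io import SnpReadMatrix
from .simulate import SamplingProfile, default_study_profile

__all__ = ["SynthConfig", "SynthDataset", "generate_cline_snp_reads",
           "generate_study_like_dataset"]


@dataclass
class BlockSpec:
    lg: int
    cm_start: float
    cm_end: float
    n_selected: int = 5
    karyotype_width: float = 12.0  # metres, width of the latent cline
    concordance: float = 0.95  # P(SNP genotype copies the karyotype)


def _default_blocks():
    return (
        BlockSpec(lg=6, cm_start=20.0, cm_end=45.5, karyotype_width=10.0),
        BlockSpec(lg=14, cm_start=10.0, cm_end=24.0, karyotype_width=14.0),
        BlockSpec(lg=17, cm_start=30.0, cm_end=47.5, karyotype_width=12.0),
    )


@dataclass
class SynthConfig:
    n_individuals: int = 600
    n_genotyped: int = 373
    path_length: float = 152.0  # metres
    n_segments: int = 11
    profile: SamplingProfile = field(default_factory=default_study_profile)
    n_snps: int = 1000
    fraction_selected: float = 0.02
    nonblock_selected_fraction: float = 0.25  # selected SNPs outside blocks
    selected_center_mean: float = 91.8
    selected_center_sd: float = 2.0
    selected_width_range: tuple = (6.0, 18.0)
    neutral_walk_sd: float = 0.1  # end-to-end SD of neutral frequency walks
    neutral_autocorr_scale: float = 20.0  # metres
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.01
    n_linkage_groups: int = 17
    total_map_cm: float = 1011.9
    map_resolution_cm: float = 0.2
    blocks: tuple = field(default_factory=_default_blocks)
    habitat_transitions: tuple = (67.0, 85.0)
    n_habitat_points: int = 1663
    seed: int = 0


@dataclass
class SynthDataset:
    samples: pd.DataFrame  # all sampled individuals (600)
    habitat: pd.DataFrame
    reads: SnpReadMatrix  # genotyped individuals only
    positions: np.ndarray  # 1D path positions of genotyped individuals
    linkage_map: LinkageMap
    dosages: np.ndarray  # (n_snps, n_genotyped) true ref-allele dosage
    truth: pd.DataFrame  # per-SNP generating truth
    manifest: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_counts_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.habitat.to_csv(out / "habitat.csv", index=False)
        write_counts_tsv(self.reads, out / "read_counts.tsv")
        self.linkage_map.table.to_csv(out / "linkage_map.tsv", sep="\t",
                                      index=False)
        self.truth.to_csv(out / "snp_truth.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=float)


def generate_cline_snp_reads(params: ClineParams, positions, depth_mean=20.0,
                             depth_dispersion=5.0, error_rate=0.01,
                             seed=None, rng=None):
    """One SNP's (ref, alt, dosage) drawn from the cline's own generative
    assumptions: HWE genotypes at p(x), negative-binomial depth, binomial
    reads with symmetric error."""
    rng = np.random.default_rng(seed) if rng is None else rng
    x = np.asarray(positions, dtype=float)
    p = np.atleast_1d(cline_frequency(params, x))
    g = rng.binomial(2, p)
    n = len(x)
    if depth_dispersion is None:
        depth = np.full(n, int(round(depth_mean)), dtype=np.int64)
    elif depth_mean <= 0:
        depth = np.zeros(n, dtype=np.int64)
    else:
        k = depth_dispersion
        depth = rng.negative_binomial(k, k / (k + depth_mean), size=n)
    mu = error_rate + (g / 2.0) * (1.0 - 2.0 * error_rate)
    ref = rng.binomial(depth, mu)
    return ref, depth - ref, g


def _neutral_frequency_curve(cfg: SynthConfig, rng) -> np.ndarray:
    """Smoothed random-walk frequency curve on a 1 m grid."""
    n = int(np.ceil(cfg.path_length)) + 1
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n))
    scale = max(1, int(cfg.neutral_autocorr_scale))
    kern = np.exp(-0.5 * (np.arange(-3 * scale, 3 * scale + 1) / scale) ** 2)
    walk = np.convolve(walk, kern / kern.sum(), mode="same")
    walk -= walk.mean()
    sd = walk.std()
    if sd > 0:
        # signed amplitude: typical along-shore excursion ~ neutral_walk_sd
        walk *= rng.normal(0.0, cfg.neutral_walk_sd) / sd
    p0 = rng.uniform(0.1, 0.9)
    return np.clip(p0 + walk, 0.02, 0.98)


def _build_map(cfg: SynthConfig) -> tuple[LinkageMap, np.ndarray]:
    """17 LGs with lengths between ~45 and ~74 cM summing exactly to the
    configured total, gridded at the map resolution."""
    n = cfg.n_linkage_groups
    base = np.round(np.linspace(45.5, 73.5, n), 1)
    base[-1] = np.round(cfg.total_map_cm - base[:-1].sum(), 6)
    rows = []
    for lg in range(1, n + 1):
        length = base[lg - 1]
        pos = np.arange(0.0, length, cfg.map_resolution_cm)
        pos = np.round(np.append(pos, length), 6)
        pos = np.unique(pos)
        for k, cm in enumerate(pos):
            rows.append((f"lg{lg}c{k}", 5000, lg, cm))
    table = pd.DataFrame(rows, columns=["contig", "bp", "lg", "cm"])
    return LinkageMap(table), base


def _make_path(cfg: SynthConfig, rng) -> np.ndarray:
    """A gently curving 11-segment polyline of total length path_length."""
    m = cfg.n_segments + 1
    t = np.linspace(0.0, 1.0, m)
    xs = t * cfg.path_length
    ys = 8.0 * np.sin(1.3 * np.pi * t) + rng.normal(0, 0.5, size=m)
    verts = np.column_stack([xs, ys])
    # rescale to the requested arc length
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    verts *= cfg.path_length / seg.sum()
    return verts


def _xy_from_path(verts, path_pos, lateral, rng):
    """Embed 1D path positions in 2D with perpendicular offsets."""
    seg = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((len(path_pos), 2))
    for i, s in enumerate(path_pos):
        j = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        t = (s - cum[j]) / seg_len[j]
        base = verts[j] + t * seg[j]
        normal = np.array([-seg[j, 1], seg[j, 0]]) / seg_len[j]
        out[i] = base + lateral[i] * normal
    return out


def generate_study_like_dataset(cfg: SynthConfig | None = None,
                                seed: int | None = None) -> SynthDataset:
    """Generate the full synthetic input set plus its truth manifest."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    lmap, lg_lengths = _build_map(cfg)
    for b in cfg.blocks:
        if b.cm_end > lg_lengths[b.lg - 1] + 1e-9 or b.cm_start < 0:
            raise ConfigurationError(
                f"block on LG{b.lg} exceeds the linkage group length"
            )

    # --- individuals along the path -------------------------------------
    grid = np.arange(0.0, cfg.path_length, 0.25)
    w = cfg.profile.weight(grid)
    if w.sum() <= 0:
        raise ConfigurationError("sampling profile has zero total weight")
    cells = rng.choice(len(grid), size=cfg.n_individuals, p=w / w.sum())
    path_pos = np.sort(grid[cells] + rng.uniform(0, 0.25, cfg.n_individuals))
    verts = _make_path(cfg, rng)
    xy = _xy_from_path(verts, path_pos, rng.normal(0, 1.5, cfg.n_individuals), rng)
    z = rng.normal(1.0, 0.5, cfg.n_individuals)
    sex = rng.choice(["F", "M"], size=cfg.n_individuals)
    genotyped = np.zeros(cfg.n_individuals, dtype=bool)
    genotyped[rng.choice(cfg.n_individuals, cfg.n_genotyped, replace=False)] = True

    # --- phenotypes ------------------------------------------------------
    def sig(p_c, p_w, c, wdt):
        return np.atleast_1d(cline_frequency(
            ClineParams(ClineModel.SIGMOID, p_c=p_c, p_w=p_w, center=c,
                        width=wdt), path_pos))

    size_raw = 12.0 - 8.0 * sig(0.0, 1.0, 70.0, 30.0) + rng.normal(0, 0.8, cfg.n_individuals)
    shape_raw = sig(0.0, 1.0, 85.0, 15.0) + rng.normal(0, 0.12, cfg.n_individuals)
    morph_truth = {
        "beige": (0.7, 0.15, 80.0, 25.0),
        "dark_beige": (0.2, 0.1, 80.0, 30.0),
        "black": (0.05, 0.5, 88.0, 12.0),
        "banded": (0.1, 0.35, 85.0, 20.0),
    }
    morphs = {k: rng.binomial(1, sig(*v)) for k, v in morph_truth.items()}

    samples = pd.DataFrame({
        "id": [f"snail{i:04d}" for i in range(cfg.n_individuals)],
        "x": xy[:, 0], "y": xy[:, 1], "z": z, "sex": sex,
        "path_pos_true": path_pos, "size": size_raw, "shape": shape_raw,
        **morphs, "genotyped": genotyped,
    })

    # --- habitat survey --------------------------------------------------
    hpos = np.sort(rng.uniform(0, cfg.path_length, cfg.n_habitat_points))
    t1, t2 = cfg.habitat_transitions
    hlab = np.where(hpos < t1, "boulder",
                    np.where(hpos < t2, "platform", "cliff"))
    hxy = _xy_from_path(verts, hpos, rng.normal(0, 1.0, len(hpos)), rng)
    habitat = pd.DataFrame({"x": hxy[:, 0], "y": hxy[:, 1], "habitat": hlab})

    # --- SNPs ------------------------------------------------------------
    n_sel = int(round(cfg.n_snps * cfg.fraction_selected))
    n_block_sel = sum(b.n_selected for b in cfg.blocks)
    if n_block_sel > n_sel:
        raise ConfigurationError("more block-selected SNPs than selected SNPs")
    gx = path_pos[genotyped]
    n_g = int(genotyped.sum())

    map_tab = lmap.table
    # uniform random map placement for all SNPs, then force block members
    placement = rng.integers(0, len(map_tab), size=cfg.n_snps)
    snp_rows = []
    dosage = np.zeros((cfg.n_snps, n_g), dtype=np.int8)
    ref = np.zeros((cfg.n_snps, n_g), dtype=np.int64)
    alt = np.zeros((cfg.n_snps, n_g), dtype=np.int64)

    sel_flags = np.zeros(cfg.n_snps, dtype=bool)
    sel_flags[:n_sel] = True
    block_of = np.full(cfg.n_snps, -1, dtype=int)

    def in_block_zone(row, margin=5.0):
        lg, cm = map_tab.iloc[row][["lg", "cm"]]
        return any(b.lg == lg and b.cm_start - margin <= cm <= b.cm_end + margin
                   for b in cfg.blocks)

    # free (non-block) selected SNPs stay clear of the planted blocks so
    # their "outside block" label is consistent with their map position
    for i in range(cfg.n_snps):
        if sel_flags[i]:
            for _ in range(100):
                if not in_block_zone(placement[i]):
                    break
                placement[i] = rng.integers(0, len(map_tab))
    k = 0
    for bi, b in enumerate(cfg.blocks):
        in_lg = map_tab[(map_tab["lg"] == b.lg)
                        & (map_tab["cm"] >= b.cm_start)
                        & (map_tab["cm"] <= b.cm_end)]
        # members tile the whole span (inversion-wide LD reaches the
        # breakpoints): evenly spaced cM targets with small jitter
        targets = np.linspace(b.cm_start, b.cm_end, b.n_selected)
        targets = targets + rng.uniform(-0.5, 0.5, b.n_selected)
        cms_in = in_lg["cm"].to_numpy()
        rows = [in_lg.index.to_numpy()[np.argmin(np.abs(cms_in - t))]
                for t in targets]
        placement[k:k + b.n_selected] = rows
        block_of[k:k + b.n_selected] = bi
        k += b.n_selected

    # latent karyotype dosage per block
    kary = {}
    for bi, b in enumerate(cfg.blocks):
        pk = np.atleast_1d(cline_frequency(
            ClineParams(ClineModel.SIGMOID, p_c=0.03, p_w=0.95,
                        center=cfg.selected_center_mean,
                        width=b.karyotype_width), gx))
        kary[bi] = (rng.binomial(2, pk), pk)

    truth_rows = []
    for i in range(cfg.n_snps):
        mrow = map_tab.iloc[placement[i]]
        bp = int(5000 + rng.integers(-800, 801))
        if sel_flags[i]:
            if block_of[i] >= 0:
                b = cfg.blocks[block_of[i]]
                kd, pk = kary[block_of[i]]
                copy = rng.random(n_g) < b.concordance
                g = np.where(copy, kd, rng.binomial(2, pk))
                gen = dict(kind="selected_block", block_lg=int(b.lg),
                           p_c=0.03, p_w=0.95,
                           center=cfg.selected_center_mean,
                           width=b.karyotype_width)
            else:
                p_c = rng.uniform(0.02, 0.15)
                p_w = rng.uniform(0.8, 0.98)
                c = rng.normal(cfg.selected_center_mean, cfg.selected_center_sd)
                wdt = rng.uniform(*cfg.selected_width_range)
                params = ClineParams(ClineModel.SIGMOID, p_c=p_c, p_w=p_w,
                                     center=c, width=wdt)
                p = np.atleast_1d(cline_frequency(params, gx))
                g = rng.binomial(2, p)
                gen = dict(kind="selected_free", block_lg=-1, p_c=p_c,
                           p_w=p_w, center=c, width=wdt)
        else:
            curve = _neutral_frequency_curve(cfg, rng)
            p = curve[np.clip(path_pos[genotyped].astype(int), 0,
                              len(curve) - 1)]
            g = rng.binomial(2, p)
            gen = dict(kind="neutral", block_lg=-1, p_c=float(p[0]),
                       p_w=float(p[-1]), center=np.nan, width=np.nan)
        kk = cfg.depth_dispersion
        depth = rng.negative_binomial(kk, kk / (kk + cfg.depth_mean), size=n_g)
        mu = cfg.error_rate + (g / 2.0) * (1.0 - 2.0 * cfg.error_rate)
        ref[i] = rng.binomial(depth, mu)
        alt[i] = depth - ref[i]
        dosage[i] = g
        snp_rows.append((f"s{i:05d}", mrow["contig"], bp))
        truth_rows.append(dict(snp_id=f"s{i:05d}", selected=bool(sel_flags[i]),
                               **gen, lg=int(mrow["lg"]),
                               cm=float(mrow["cm"])))

    snp_ids = np.array([r[0] for r in snp_rows])
    reads = SnpReadMatrix(
        snp_id=snp_ids,
        contig=np.array([r[1] for r in snp_rows]),
        bp=np.array([r[2] for r in snp_rows], dtype=int),
        ref=ref, alt=alt,
        samples=list(samples.loc[genotyped, "id"]),
    )
    truth = pd.DataFrame(truth_rows)

    manifest = {
        "config": {"n_snps": cfg.n_snps, "n_selected": int(n_sel),
                   "n_individuals": cfg.n_individuals,
                   "n_genotyped": cfg.n_genotyped,
                   "seed": int(cfg.seed if seed is None else seed)},
        "blocks": [dict(lg=b.lg, cm_start=b.cm_start, cm_end=b.cm_end,
                        n_selected=b.n_selected) for b in cfg.blocks],
        "habitat_transitions": list(cfg.habitat_transitions),
        "selected_snp_ids": list(snp_ids[sel_flags]),
        "path_vertices": verts.tolist(),
    }
    return SynthDataset(samples=samples, habitat=habitat, reads=reads,
                        positions=gx, linkage_map=lmap, dosages=dosage,
                        truth=truth, manifest=manifest)
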