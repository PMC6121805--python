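"""Genomic architecture of non-neutral SNPs.

Maps SNPs onto a linkage map (nearest mapped SNP on the same contig within
1,000 bp), tests for clustering of non-neutral SNPs at several genomic
scales with label-permutation tests, computes composite LD (|r| of
genotype dosages) and its decay with map distance, and detects large
high-LD blocks enriched in non-neutral SNPs ("nnBlocks", the putative
chromosomal inversions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "LinkageMap",
    "assign_snps_to_map",
    "permutation_cluster_test",
    "pairwise_ld",
    "ld_decay_profile",
    "NnBlock",
    "detect_nn_blocks",
]


@dataclass
class LinkageMap:
    """contig/bp -> (linkage group, cM) lookup built from a map table."""

    table: pd.DataFrame  # columns: contig, bp, lg, cm

    def __post_init__(self) -> None:
        need = {"contig", "bp", "lg", "cm"}
        if not need.issubset(self.table.columns):
            raise ConfigurationError(f"linkage map needs columns {sorted(need)}")
        self.table = self.table.sort_values(["contig", "bp"]).reset_index(drop=True)

    @property
    def n_linkage_groups(self) -> int:
        return self.table["lg"].nunique()

    @property
    def lg_lengths(self) -> pd.Series:
        return self.table.groupby("lg")["cm"].max()

    @property
    def total_length(self) -> float:
        return float(self.lg_lengths.sum())


def assign_snps_to_map(snps: pd.DataFrame, lmap: LinkageMap,
                       max_bp: int = 1000) -> pd.DataFrame:
    """Assign each SNP the (lg, cM) of the nearest mapped SNP on its contig.

    SNPs farther than ``max_bp`` from any mapped SNP (or on unmapped
    contigs) get lg = -1 / cm = NaN and ``mapped = False``.  Ties (SNP
    equidistant from two map entries) break to the lower cM.
    """
    out = snps.copy()
    lgs = np.full(len(out), -1, dtype=int)
    cms = np.full(len(out), np.nan)
    dists = np.full(len(out), np.iinfo(np.int64).max, dtype=np.int64)
    grouped = {c: g for c, g in lmap.table.groupby("contig")}
    for i, (contig, bp) in enumerate(zip(out["contig"], out["bp"])):
        g = grouped.get(contig)
        if g is None:
            continue
        d = np.abs(g["bp"].to_numpy() - int(bp))
        dmin = d.min()
        if dmin > max_bp:
            continue
        cand = g[d == dmin]
        row = cand.loc[cand["cm"].idxmin()]
        lgs[i], cms[i], dists[i] = int(row["lg"]), float(row["cm"]), int(dmin)
    out["lg"] = lgs
    out["cm"] = cms
    out["map_bp_dist"] = np.where(lgs >= 0, dists, -1)
    out["mapped"] = lgs >= 0
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    finite = np.isfinite(p)
    adj = np.full_like(p, np.nan, dtype=float)
    if finite.sum():
        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return adj


def _unit_ids(mapped: pd.DataFrame, scale: str) -> pd.Series:
    if scale == "linkage_group":
        return mapped["lg"].astype(str)
    if scale == "map_position":
        return mapped["lg"].astype(str) + ":" + mapped["cm"].round(4).astype(str)
    if scale == "window_10cM":
        return (mapped["lg"].astype(str) + ":w"
                + (mapped["cm"] // 10).astype(int).astype(str))
    raise ConfigurationError(f"unknown clustering scale {scale!r}")


def permutation_cluster_test(mapped: pd.DataFrame, labels, scale: str,
                             n_perm: int = 10000, seed: int | None = 0,
                             bp_classes=(100, 1000, 10000)) -> pd.DataFrame:
    """One-sided enrichment tests for clustering of non-neutral SNPs.

    ``scale`` is one of linkage_group, map_position, window_10cM (per-unit
    proportion of non-neutral SNPs vs label permutations) or
    within_contig_bp (per bp-distance class, the fraction of same-contig
    SNP pairs in which both members are non-neutral among pairs containing
    at least one).  P-values use the add-one estimator
    (1 + #perm >= obs) / (1 + n_perm) and are BH-adjusted across units.
    """
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    if labels.sum() == 0:
        warnings.warn("no non-neutral labels; all p-values are 1")
    if scale == "within_contig_bp":
        return _contig_pair_test(mapped, labels, n_perm, rng, bp_classes)

    units = _unit_ids(mapped, scale)
    codes, uniq = pd.factorize(units, sort=True)
    n_units = len(uniq)
    if n_units < 2:
        raise ConfigurationError("need >= 2 units at the chosen scale")
    sizes = np.bincount(codes, minlength=n_units)
    obs = np.bincount(codes, weights=labels, minlength=n_units) / sizes
    exceed = np.zeros(n_units, dtype=np.int64)
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        perm = np.bincount(codes, weights=lab, minlength=n_units) / sizes
        exceed += perm >= obs - 1e-15
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({
        "scale": scale, "unit": uniq, "n_snps": sizes,
        "n_nonneutral": np.bincount(codes, weights=labels,
                                    minlength=n_units).astype(int),
        "proportion": obs, "p_value": p, "p_adjusted": _bh_adjust(p),
    })


def _contig_pair_test(mapped, labels, n_perm, rng, bp_classes):
    """Fig.-S3-style ratio: among same-contig pairs with >= 1 non-neutral
    member, the fraction where both members are non-neutral, per
    bp-distance class."""
    contigs = mapped["contig"].to_numpy()
    bps = mapped["bp"].to_numpy()
    ii, jj, dd = [], [], []
    order = np.argsort(contigs, kind="stable")
    k = 0
    while k < len(order):
        k2 = k
        while k2 < len(order) and contigs[order[k2]] == contigs[order[k]]:
            k2 += 1
        grp = order[k:k2]
        for a in range(len(grp)):
            for b in range(a + 1, len(grp)):
                ii.append(grp[a])
                jj.append(grp[b])
                dd.append(abs(int(bps[grp[a]]) - int(bps[grp[b]])))
        k = k2
    ii = np.asarray(ii, dtype=int)
    jj = np.asarray(jj, dtype=int)
    dd = np.asarray(dd, dtype=np.int64)
    edges = [0, *bp_classes, np.iinfo(np.int64).max]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dd >= lo) & (dd < hi)
        name = f"[{lo},{hi})" if hi < np.iinfo(np.int64).max else f">={lo}"

        def ratio(lab):
            both = (lab[ii[sel]] & lab[jj[sel]]).sum()
            any_ = (lab[ii[sel]] | lab[jj[sel]]).sum()
            return both / any_ if any_ else 0.0

        obs = ratio(labels)
        exceed = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if ratio(lab) >= obs - 1e-15:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        rows.append(dict(scale="within_contig_bp", unit=name,
                         n_snps=int(sel.sum()), n_nonneutral=np.nan,
                         proportion=obs, p_value=p))
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _bh_adjust(df["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def pairwise_ld(dosages, pairs, group_mask=None, min_n: int = 10) -> pd.DataFrame:
    """|r| (absolute Pearson correlation of dosages, composite LD) per pair.

    ``dosages`` is (n_snps, n_individuals) with negative values treated as
    missing; ``pairs`` an iterable of (i, j) index pairs; ``group_mask``
    restricts to an individual subset (e.g. one cline end).  Pairs with a
    monomorphic member or fewer than ``min_n`` complete individuals are
    reported with NaN.
    """
    d = np.asarray(dosages, dtype=float)
    d = np.where(d < 0, np.nan, d)
    if group_mask is not None:
        d = d[:, np.asarray(group_mask, dtype=bool)]
    rows = []
    for i, j in pairs:
        xi, xj = d[i], d[j]
        m = np.isfinite(xi) & np.isfinite(xj)
        note = ""
        r = np.nan
        if m.sum() < min_n:
            note = "too_few_individuals"
        else:
            a, b = xi[m], xj[m]
            if a.std() == 0 or b.std() == 0:
                note = "monomorphic"
            else:
                r = float(abs(np.corrcoef(a, b)[0, 1]))
        rows.append(dict(i=int(i), j=int(j), n=int(m.sum()), abs_r=r, note=note))
    return pd.DataFrame(rows)


def ld_decay_profile(ld: pd.DataFrame, cm_dist, strata=None,
                     bin_width: float = 1.0) -> pd.DataFrame:
    """Mean |r| per map-distance bin, optionally per stratum.

    ``cm_dist`` aligns with the rows of ``ld``; ``strata`` is an optional
    label array (e.g. within_block/outside_block x ecotype).
    """
    dist = np.asarray(cm_dist, dtype=float)
    strat = (np.asarray(strata) if strata is not None
             else np.full(len(dist), "all"))
    r = ld["abs_r"].to_numpy(dtype=float)
    ok = np.isfinite(r) & np.isfinite(dist)
    rows = []
    for s in pd.unique(strat):
        m = ok & (strat == s)
        if m.sum() == 0:
            warnings.warn(f"stratum {s!r} has no usable pairs")
            continue
        bins = np.floor(dist[m] / bin_width).astype(int)
        for b in np.unique(bins):
            mm = bins == b
            rows.append(dict(stratum=s, cm_bin_low=b * bin_width,
                             cm_bin_high=(b + 1) * bin_width,
                             mean_abs_r=float(r[m][mm].mean()),
                             n_pairs=int(mm.sum())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nnBlock detection
# ---------------------------------------------------------------------------


@dataclass
class NnBlock:
    """A linkage-map region with elevated non-neutral density and high LD."""

    lg: int
    cm_start: float
    cm_end: float
    member_index: np.ndarray  # row indices into the mapped SNP table
    n_snps: int
    n_nonneutral: int
    mean_abs_r: dict = field(default_factory=dict)  # per individual group

    @property
    def length_cm(self) -> float:
        return self.cm_end - self.cm_start


def detect_nn_blocks(mapped: pd.DataFrame, labels, dosages=None, groups=None,
                     window_cm: float = 5.0, enrichment: float = 5.0,
                     min_abs_r: float = 0.3, min_snps_per_window: int = 3,
                     max_gap_windows: int = 1, max_ld_pairs: int = 300,
                     seed: int | None = 0):
    """Detect maximal contiguous cM regions enriched in non-neutral SNPs.

    Windows of ``window_cm`` on each LG qualify when their non-neutral
    proportion exceeds ``enrichment`` times the genome-wide proportion
    (and contain at least ``min_snps_per_window`` SNPs); qualifying
    windows merge into a run, bridging up to ``max_gap_windows``
    non-qualifying windows (a single sparse window should not split a
    rearrangement), and block boundaries are the outermost non-neutral
    map positions inside the merged run.  If ``dosages`` is
    given (with ``groups`` a dict of individual masks, e.g. the two cline
    ends), a block is kept only if the mean |r| among its non-neutral
    members reaches ``min_abs_r`` in at least one group; the per-group
    means are recorded on the block.
    """
    labels = np.asarray(labels, dtype=bool)
    mapped = mapped.reset_index(drop=True)
    mm = mapped["mapped"].to_numpy() if "mapped" in mapped else np.ones(len(mapped), bool)
    global_prop = labels[mm].mean() if mm.sum() else 0.0
    if global_prop == 0:
        return []
    rng = np.random.default_rng(seed)
    blocks = []
    for lg, g in mapped[mm].groupby("lg"):
        cm = g["cm"].to_numpy(dtype=float)
        lab = labels[g.index.to_numpy()]
        # windows anchored at the LG's first map position, so detection is
        # invariant to translating a whole LG in cM
        wins = np.floor((cm - cm.min()) / window_cm).astype(int)
        qual = []
        for wid in np.unique(wins):
            sel = wins == wid
            if sel.sum() < min_snps_per_window:
                continue
            if lab[sel].mean() >= enrichment * global_prop and lab[sel].any():
                qual.append(wid)
        if not qual:
            continue
        qual = np.sort(np.asarray(qual))
        runs = np.split(qual, np.nonzero(
            np.diff(qual) > 1 + max_gap_windows)[0] + 1)
        for run in runs:
            in_run = np.isin(wins, np.arange(run[0], run[-1] + 1))
            nn_in = in_run & lab
            if not nn_in.any():
                continue
            cm_start = float(cm[nn_in].min())
            cm_end = float(cm[nn_in].max())
            members = g.index.to_numpy()[in_run]
            block = NnBlock(
                lg=int(lg), cm_start=cm_start, cm_end=cm_end,
                member_index=members, n_snps=int(in_run.sum()),
                n_nonneutral=int(nn_in.sum()),
            )
            blocks.append(block)

    if dosages is None:
        return blocks

    groups = groups or {"all": np.ones(np.asarray(dosages).shape[1], bool)}
    kept = []
    for block in blocks:
        nn_members = [i for i in block.member_index if labels[i]]
        # LD-coherence trim: a block is a cluster of mutually correlated
        # non-neutral SNPs, so a member uncorrelated with the rest (e.g.
        # an isolated false positive at the edge) does not set boundaries
        if len(nn_members) >= 3:
            per_member = {}
            for name, mask in groups.items():
                pairs = [(a, b) for ai, a in enumerate(nn_members)
                         for b in nn_members[ai + 1:]]
                ld = pairwise_ld(dosages, pairs, mask)
                for m in nn_members:
                    rows = ld[(ld["i"] == m) | (ld["j"] == m)]
                    r = float(np.nanmean(rows["abs_r"])) if len(rows) else np.nan
                    per_member[m] = max(per_member.get(m, -np.inf),
                                        r if np.isfinite(r) else -np.inf)
            coherent = [m for m in nn_members
                        if per_member.get(m, -np.inf) >= min_abs_r]
            if len(coherent) >= 2:
                nn_members = coherent
            # seed-and-extend: absorb nearby non-neutral SNPs on the same
            # LG that are in LD with the block (their window may have
            # missed the enrichment cutoff by chance)
            reach = (max_gap_windows + 1) * window_cm
            same_lg = mapped.index[(mapped["lg"] == block.lg)
                                   & labels[mapped.index]].to_numpy()
            changed = True
            while changed:
                changed = False
                cm_vals = mapped.loc[nn_members, "cm"].to_numpy(dtype=float)
                lo, hi = cm_vals.min(), cm_vals.max()
                for m in same_lg:
                    if m in nn_members:
                        continue
                    cm_m = float(mapped.loc[m, "cm"])
                    if not (lo - reach <= cm_m <= hi + reach):
                        continue
                    rs = []
                    for name, mask in groups.items():
                        ld = pairwise_ld(dosages,
                                         [(m, o) for o in nn_members], mask)
                        v = float(np.nanmean(ld["abs_r"])) if len(ld) else np.nan
                        if np.isfinite(v):
                            rs.append(v)
                    if rs and max(rs) >= min_abs_r:
                        nn_members.append(m)
                        changed = True
            cm_vals = mapped.loc[nn_members, "cm"].to_numpy(dtype=float)
            block.cm_start = float(cm_vals.min())
            block.cm_end = float(cm_vals.max())
            block.n_nonneutral = len(nn_members)
        pairs = [(a, b) for ai, a in enumerate(nn_members)
                 for b in nn_members[ai + 1:]]
        if len(pairs) > max_ld_pairs:
            sel = rng.choice(len(pairs), size=max_ld_pairs, replace=False)
            pairs = [pairs[s] for s in sel]
        ok = False
        for name, mask in groups.items():
            if not pairs:
                block.mean_abs_r[name] = np.nan
                continue
            ld = pairwise_ld(dosages, pairs, mask)
            mean_r = float(np.nanmean(ld["abs_r"])) if len(ld) else np.nan
            block.mean_abs_r[name] = mean_r
            if np.isfinite(mean_r) and mean_r >= min_abs_r:
                ok = True
        if ok:
            kept.append(block)
    return kept
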