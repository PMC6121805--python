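"""Pre-fit SNP filters.

Retains only SNPs close enough to the linkage map (within 1,000 bp of a
mapped SNP), then removes SNPs that are monomorphic/low-MAF, depart from
Hardy-Weinberg expectations within either transect-end reference region,
or differ in allele frequency between the sexes.  Every exclusion is
logged with its (first) reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .architecture import LinkageMap, assign_snps_to_map
from .classify import ml_genotype_calls
from .exceptions import ConfigurationError
from .io import SnpReadMatrix

__all__ = ["FilterConfig", "filter_snps", "hwe_exact_test"]


@dataclass
class FilterConfig:
    max_bp_to_map: int = 1000
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6  # stringent Bonferroni-style raw-p threshold
    sex_alpha: float = 1e-6
    end_width: float = 30.0  # metres defining each end reference region
    min_called_per_region: int = 10
    error_rate: float = 0.01


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, under the hypergeometric null.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # enumerate heterozygote counts with the parity of the rare-allele count
    from scipy.special import gammaln

    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1)
            - gammaln(homc + 1) + hets * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(np.clip(p[p <= obs + 1e-12].sum(), 0.0, 1.0))


def _sex_test(calls: np.ndarray, is_female: np.ndarray) -> float:
    """Two-proportion (chi-square) test of allele frequency between sexes."""
    rows = []
    for mask in (is_female, ~is_female):
        c = calls[mask]
        c = c[c >= 0]
        a1 = int(c.sum())
        rows.append([a1, 2 * len(c) - a1])
    tab = np.asarray(rows)
    if tab.sum(axis=1).min() < 4 or tab.sum(axis=0).min() == 0:
        return 1.0
    return float(chi2_contingency(tab, correction=False)[1])


def filter_snps(mat: SnpReadMatrix, positions, lmap: LinkageMap | None,
                sex=None, cfg: FilterConfig | None = None):
    """Apply all pre-fit filters; returns (filtered matrix, exclusion log).

    ``positions`` are 1D transect positions aligned with the matrix's
    individuals; ``sex`` an optional array of 'F'/'M' labels.  The HWE test
    runs separately within each outermost ``end_width``-metre reference
    region; a SNP fails if either region rejects at ``hwe_alpha``.
    """
    cfg = cfg or FilterConfig()
    if lmap is None:
        raise ConfigurationError("a linkage map is required for filtering")
    x = np.asarray(positions, dtype=float)
    reasons = np.array([""] * mat.n_snps, dtype=object)

    mapped = assign_snps_to_map(mat.site_table(), lmap, cfg.max_bp_to_map)
    reasons[~mapped["mapped"].to_numpy()] = "no_map_within_%dbp" % cfg.max_bp_to_map

    depth = mat.depth
    total = depth.sum(axis=1)
    ref_frac = np.divide(mat.ref.sum(axis=1), total,
                         out=np.full(mat.n_snps, np.nan), where=total > 0)
    maf = np.minimum(ref_frac, 1 - ref_frac)
    mono = (reasons == "") & (~np.isfinite(maf) | (maf < cfg.min_maf))
    reasons[mono] = "monomorphic_or_low_maf"

    lo, hi = x.min(), x.max()
    regions = [(x <= lo + cfg.end_width), (x >= hi - cfg.end_width)]
    candidates = np.nonzero(reasons == "")[0]
    calls_cache = {}
    for i in candidates:
        calls = ml_genotype_calls(mat.ref[i], mat.alt[i], cfg.error_rate)
        calls_cache[i] = calls
        for region in regions:
            c = calls[region]
            c = c[c >= 0]
            if len(c) < cfg.min_called_per_region:
                continue
            n_hom_ref = int(np.sum(c == 2))
            n_het = int(np.sum(c == 1))
            n_hom_alt = int(np.sum(c == 0))
            if hwe_exact_test(n_het, n_hom_ref, n_hom_alt) < cfg.hwe_alpha:
                reasons[i] = "hwe_departure"
                break

    if sex is not None:
        sex = np.asarray(sex)
        is_female = sex == "F"
        for i in np.nonzero(reasons == "")[0]:
            calls = calls_cache.get(i)
            if calls is None:
                calls = ml_genotype_calls(mat.ref[i], mat.alt[i], cfg.error_rate)
            if _sex_test(calls, is_female) < cfg.sex_alpha:
                reasons[i] = "sex_difference"

    keep = reasons == ""
    log = pd.DataFrame({"snp_id": mat.snp_id, "kept": keep,
                        "reason": reasons})
    filtered = mat.subset(keep)
    filtered.lg = mapped["lg"].to_numpy()[keep]
    filtered.cm = mapped["cm"].to_numpy()[keep]
    return filtered, log
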