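"""Neutrality classification, end differentiation and dispersal from LD.

The var.ex of clinal loci simulated under a system-tailored neutral model
defines an empirical null distribution; observed SNPs whose var.ex exceeds
its ``q``-quantile (q = 0.99 by default) are classified non-neutral.  The
module also summarizes non-neutral cline centers relative to the habitat
transitions, estimates per-SNP differentiation between cline ends (Δp and
Hudson's Fst), and recovers the dispersal SD σ from the elevation of
gametic LD at the cline center via the cline-theory relation
D ≈ σ² Δp₁ Δp₂ / (r w₁ w₂).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, InsufficientNullError

__all__ = [
    "neutral_varex_threshold",
    "NeutralityClassifier",
    "classify_snps",
    "summarize_nonneutral_centers",
    "em_gametic_d",
    "estimate_dispersal_from_ld",
    "end_differentiation",
    "hudson_fst",
    "ml_genotype_calls",
]

CATEGORIES = ("non_clinal", "clinal_neutral", "non_neutral")


def neutral_varex_threshold(null_varex, q: float = 0.99,
                            min_values: int = 100) -> float:
    """Empirical q-quantile of simulated neutral var.ex values.

    Uses the linear-interpolation quantile definition (numpy's default),
    recorded here so the threshold is comparable across implementations.
    """
    v = np.asarray(null_varex, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < min_values:
        raise InsufficientNullError(
            f"need >= {min_values} neutral var.ex values, got {len(v)}"
        )
    if not 0 < q <= 1:
        raise ConfigurationError("quantile q must lie in (0, 1]")
    return float(np.quantile(v, q, method="linear"))


def classify_snps(fits: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Three-way classification of fitted SNPs.

    ``non_neutral`` requires a clinal best model AND var.ex strictly above
    the threshold; clinal SNPs at or below the threshold are
    ``clinal_neutral``; the rest are ``non_clinal``.
    """
    out = fits.copy()
    clinal = out["clinal"].astype(bool).to_numpy()
    varex = out["var_ex"].to_numpy(dtype=float)
    cat = np.where(~clinal, "non_clinal",
                   np.where(varex > threshold, "non_neutral", "clinal_neutral"))
    out["category"] = cat
    out["threshold"] = threshold
    return out


def classification_counts(classified: pd.DataFrame) -> dict:
    n = len(classified)
    counts = {c: int((classified["category"] == c).sum()) for c in CATEGORIES}
    props = {f"prop_{c}": (counts[c] / n if n else np.nan) for c in CATEGORIES}
    return {"n": n, **counts, **props}


class NeutralityClassifier(BaseEstimator):
    """Estimator interface: ``fit`` on simulated-neutral var.ex values,
    ``predict`` categories for a fitted-SNP table.

    Fitted attributes: ``threshold_`` (the q-quantile of the null) and
    ``null_values_``.
    """

    def __init__(self, q: float = 0.99, min_values: int = 100):
        self.q = q
        self.min_values = min_values

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).reshape(-1)
        self.null_values_ = X[np.isfinite(X)]
        self.threshold_ = neutral_varex_threshold(self.null_values_, self.q,
                                                  self.min_values)
        return self

    def predict(self, fits: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        return classify_snps(fits, self.threshold_)["category"].to_numpy()


def summarize_nonneutral_centers(classified: pd.DataFrame,
                                 transitions=()) -> dict:
    """Mean/dispersion of non-neutral cline centers and their signed
    displacement from each habitat transition (positive = toward Wave)."""
    nn = classified[classified["category"] == "non_neutral"]
    if len(nn) == 0:
        warnings.warn("no non-neutral SNPs; empty center summary")
        return {"n": 0, "mean_center": np.nan, "sd_center": np.nan,
                "displacements": {}}
    centers = nn["center"].to_numpy(dtype=float)
    mean_c = float(np.mean(centers))
    return {
        "n": int(len(nn)),
        "mean_center": mean_c,
        "sd_center": float(np.std(centers, ddof=1)) if len(nn) > 1 else 0.0,
        "displacements": {float(t): mean_c - float(t) for t in transitions},
    }


# ---------------------------------------------------------------------------
# gametic LD via EM and dispersal from LD at the cline center
# ---------------------------------------------------------------------------


def em_gametic_d(g1, g2, max_iter: int = 200, tol: float = 1e-10) -> float:
    """Composite gametic D between two biallelic loci from unphased
    genotype dosages (0/1/2; negative = missing) by the standard two-locus
    EM for haplotype frequencies."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    m = (g1 >= 0) & (g2 >= 0)
    g1, g2 = g1[m].astype(int), g2[m].astype(int)
    n = len(g1)
    if n == 0:
        return np.nan
    pa = g1.mean() / 2.0
    pb = g2.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    # haplotypes: h11, h10, h01, h00 over alleles (locus1, locus2)
    h = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    ndh = int(np.sum((g1 == 1) & (g2 == 1)))  # double heterozygotes
    # every other genotype class has a unique haplotype decomposition;
    # count the haplotype copies contributed by unambiguous individuals
    c11 = c10 = c01 = c00 = 0
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            if a == 1 and b == 1:
                continue
            cnt = int(np.sum((g1 == a) & (g2 == b)))
            if cnt == 0:
                continue
            # haplotype pair is determined: e.g. a=2,b=1 -> 11 + 10
            ones1, ones2 = a, b
            pairs = {(1, 1): 0, (1, 0): 0, (0, 1): 0, (0, 0): 0}
            for _hap in range(2):
                x1 = 1 if ones1 > 0 else 0
                x2 = 1 if ones2 > 0 else 0
                pairs[(x1, x2)] += 1
                ones1 -= x1
                ones2 -= x2
            c11 += cnt * pairs[(1, 1)]
            c10 += cnt * pairs[(1, 0)]
            c01 += cnt * pairs[(0, 1)]
            c00 += cnt * pairs[(0, 0)]
    total = 2.0 * n
    for _ in range(max_iter):
        # E-step: split double heterozygotes between coupling (11/00) and
        # repulsion (10/01)
        pc = h[0] * h[3]
        pr = h[1] * h[2]
        denom = pc + pr
        fc = pc / denom if denom > 0 else 0.5
        new = np.array([
            c11 + ndh * fc, c10 + ndh * (1 - fc),
            c01 + ndh * (1 - fc), c00 + ndh * fc,
        ]) / total
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return float(h[0] - (h[0] + h[1]) * (h[0] + h[2]))


@dataclass
class DispersalEstimate:
    """Per-pair inputs and the pooled dispersal estimate."""

    pair_sigmas: np.ndarray
    sigma_hat: float
    n_pairs_used: int


def estimate_dispersal_from_ld(d_values, widths1, widths2, dp1, dp2,
                               r: float = 0.5) -> DispersalEstimate:
    """Dispersal SD from LD elevation at the cline center.

    For each pair: sigma = sqrt(D * r * w1 * w2 / (dp1 * dp2)); pairs with
    non-positive D are skipped with a warning.  The aggregate is the median
    across pairs (robust to the heavy right tail of D estimates).
    """
    d = np.asarray(d_values, dtype=float)
    w1 = np.asarray(widths1, dtype=float)
    w2 = np.asarray(widths2, dtype=float)
    p1 = np.asarray(dp1, dtype=float)
    p2 = np.asarray(dp2, dtype=float)
    if np.any(w1 <= 0) or np.any(w2 <= 0) or np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ConfigurationError("widths and end-frequency differences must be > 0")
    ok = np.isfinite(d) & (d >= 0)
    skipped = int(np.sum(np.isfinite(d) & (d < 0)))
    if skipped:
        warnings.warn(f"{skipped} pair(s) with negative D skipped")
    sig = np.sqrt(d[ok] * r * w1[ok] * w2[ok] / (p1[ok] * p2[ok]))
    agg = float(np.median(sig)) if len(sig) else np.nan
    return DispersalEstimate(sig, agg, int(len(sig)))


# ---------------------------------------------------------------------------
# differentiation between cline ends
# ---------------------------------------------------------------------------


def ml_genotype_calls(ref, alt, error_rate: float = 0.01) -> np.ndarray:
    """Maximum-likelihood reference-allele dosage per individual (-1 when
    depth is zero), from the binomial read model with symmetric error."""
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    mu = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (ref[..., None] * np.log(mu) + alt[..., None] * np.log(1.0 - mu))
    calls = np.argmax(ll, axis=-1).astype(np.int8)
    calls[(ref + alt) <= 0] = -1
    return calls


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's Fst estimator from two allele-frequency samples.

    ``n1``/``n2`` are allele (not individual) sample sizes.  Negative
    estimates are truncated to 0, and the result is capped at 1.
    """
    if n1 < 2 or n2 < 2:
        return np.nan
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den <= 0:
        return 0.0 if abs(p1 - p2) < 1e-12 else 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def end_differentiation(ref, alt, positions, end_regions=None,
                        transect_length: float | None = None,
                        end_width: float = 30.0,
                        error_rate: float = 0.01) -> pd.DataFrame:
    """Per-SNP Δp and Hudson Fst between the two cline-end samples.

    End regions default to the outermost ``end_width`` metres on each side.
    Allele frequencies come from ML genotype calls of individuals with
    nonzero depth in each region.
    """
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    x = np.asarray(positions, dtype=float)
    if end_regions is None:
        total = transect_length if transect_length is not None else float(x.max())
        end_regions = ((x.min(), x.min() + end_width), (total - end_width, total))
    (l0, l1), (r0, r1) = end_regions
    crab = (x >= l0) & (x <= l1)
    wave = (x >= r0) & (x <= r1)
    if crab.sum() == 0 or wave.sum() == 0:
        raise ConfigurationError("an end region contains no individuals")
    rows = []
    for i in range(ref.shape[0]):
        calls = ml_genotype_calls(ref[i], alt[i], error_rate)
        res = {}
        for name, mask in (("crab", crab), ("wave", wave)):
            c = calls[mask]
            c = c[c >= 0]
            res[name] = (c.sum() / (2.0 * len(c)) if len(c) else np.nan,
                         2 * len(c))
        p_c, n_c = res["crab"]
        p_w, n_w = res["wave"]
        dp = abs(p_w - p_c)
        rows.append(dict(p_crab=p_c, p_wave=p_w, delta_p=dp,
                         fst=hudson_fst(p_c, n_c, p_w, n_w)))
    return pd.DataFrame(rows)
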