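"""Clines in quantitative traits and color/pattern morph frequencies.

Quantitative traits (shell size, shape) are rescaled to [0, 1] so that the
most extreme Crab-ecotype individual scores 0 and the most extreme
Wave-ecotype individual scores 1, then fitted with the same cline family
as SNPs but with Gaussian residuals of constant SD (profiled out).  Morph
indicators (beige, dark beige, black, banded) are fitted with a Bernoulli
likelihood where the cline gives the morph frequency.  Model selection is
identical to SNP clines (AIC, ΔAIC > 4).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._likelihood import negll_kernel
from .cline_models import ClineModel, ClineParams
from .exceptions import DegenerateDataError, ZeroRangeError
from .fitting import (
    ClineFitResult,
    LikelihoodConfig,
    _assemble_result,
    _fit_family,
)

__all__ = [
    "scale_quantitative_trait",
    "fit_trait_cline",
    "fit_morph_cline",
    "TraitClineFitter",
    "MorphClineFitter",
]


def scale_quantitative_trait(values, increasing: bool = True) -> np.ndarray:
    """Affine rescale of a trait to [0, 1].

    ``increasing=True`` maps the minimum to 0 and the maximum to 1; use
    ``increasing=False`` when the raw trait decreases from Crab to Wave
    (e.g. shell size), so the scaled trait still rises toward Wave.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not np.isfinite(lo) or hi - lo <= 0:
        raise ZeroRangeError("trait has zero range; cannot rescale")
    scaled = (v - lo) / (hi - lo)
    return scaled if increasing else 1.0 - scaled


def fit_trait_cline(values, positions, cfg: LikelihoodConfig | None = None,
                    rng=None, min_individuals: int = 50) -> ClineFitResult:
    """ML cline fit to a scaled quantitative trait (Gaussian residuals).

    The cline gives the trait mean; the residual SD is a free parameter
    profiled out of the likelihood (one extra AIC parameter per model).
    """
    cfg = cfg or LikelihoodConfig()
    rng = np.random.default_rng(rng)
    y = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if len(y) < min_individuals:
        return ClineFitResult(models={}, best_model=ClineModel.NULL,
                              clinal=False, delta_aic_vs_null=np.nan,
                              var_ex=np.nan, summary=None, n_used=len(y),
                              ok=False, note="too_few_individuals")
    dummy = np.zeros_like(y)
    models = _fit_family(1, x, y, dummy, dummy, cfg, rng)
    return _assemble_result(models, cfg.delta_aic, x, y,
                            np.ones_like(y), len(y))


def fit_morph_cline(indicator, positions, cfg: LikelihoodConfig | None = None,
                    rng=None) -> ClineFitResult:
    """ML cline fit to a binary morph indicator (Bernoulli likelihood).

    If only one class is present no spatial model is identifiable: the
    result is the null model with the boundary frequency and a
    ``single_class`` note (a degenerate-data condition, not a failure).
    """
    cfg = cfg or LikelihoodConfig()
    rng = np.random.default_rng(rng)
    y = np.asarray(indicator, dtype=float)
    x = np.asarray(positions, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    dummy = np.zeros_like(y)
    if len(np.unique(y)) < 2:
        p = float(y[0]) if len(y) else 0.0
        th = np.array([np.clip(p, 1e-9, 1 - 1e-9)])
        f = float(negll_kernel(2, th, 0, x, y, dummy, dummy, cfg.error_rate))
        models = {ClineModel.NULL: dict(
            params=ClineParams(ClineModel.NULL, p_c=p), logl=-f,
            aic=2 + 2 * f, k=1)}
        res = ClineFitResult(models=models, best_model=ClineModel.NULL,
                             clinal=False, delta_aic_vs_null=0.0,
                             var_ex=0.0, summary=None, n_used=len(y),
                             note="single_class")
        return res
    models = _fit_family(2, x, y, dummy, dummy, cfg, rng)
    return _assemble_result(models, cfg.delta_aic, x, y,
                            np.ones_like(y), len(y))


class _PhenotypeFitterBase(BaseEstimator):
    def __init__(self, error_rate: float = 0.01, width_lower: float = 1.0,
                 n_starts: int = 3, delta_aic: float = 4.0,
                 random_state: int | None = 0):
        self.error_rate = error_rate
        self.width_lower = width_lower
        self.n_starts = n_starts
        self.delta_aic = delta_aic
        self.random_state = random_state

    def _config(self) -> LikelihoodConfig:
        return LikelihoodConfig(
            error_rate=self.error_rate, width_lower=self.width_lower,
            n_starts=self.n_starts, delta_aic=self.delta_aic,
        )

    def _finish(self, res: ClineFitResult):
        self.results_ = res
        self.params_ = res.params if res.ok else None
        self.best_model_ = res.best_model
        self.clinal_ = res.clinal
        self.var_ex_ = res.var_ex
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        from .cline_models import cline_frequency

        check_is_fitted(self, "results_")
        return np.atleast_1d(
            cline_frequency(self.params_, np.asarray(X, float).reshape(-1))
        )


class TraitClineFitter(_PhenotypeFitterBase):
    """Estimator for quantitative-trait clines: ``fit(X, y)`` with 1D
    positions X and scaled trait values y; ``predict`` gives the mean."""

    def fit(self, X, y):
        X = np.asarray(X, float).reshape(-1)
        res = fit_trait_cline(y, X, self._config(),
                              np.random.default_rng(self.random_state))
        return self._finish(res)


class MorphClineFitter(_PhenotypeFitterBase):
    """Estimator for morph-frequency clines: y is a 0/1 indicator;
    ``predict`` gives the morph frequency."""

    def fit(self, X, y):
        X = np.asarray(X, float).reshape(-1)
        res = fit_morph_cline(y, X, self._config(),
                              np.random.default_rng(self.random_state))
        return self._finish(res)
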