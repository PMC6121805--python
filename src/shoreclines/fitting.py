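"""Maximum-likelihood cline fitting and model selection.

Fits the five-member cline model family to one response at a time --
allelic read depths (the primary use), a scaled quantitative trait, or a
binary morph indicator -- by bounded multi-start L-BFGS-B on a numba
negative log-likelihood, then selects the best model by AIC with a
conservative complexity ladder (a more complex model must beat every
simpler clinal model by more than ``delta_aic``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from ._likelihood import (
    log_binom_coeff,
    negll_and_grad,
    negll_kernel,
    negll_read_fast,
    negll_read_fast_grad,
    precompute_read_terms,
)
from .cline_models import (
    MODEL_CODES,
    MODEL_NPARAMS,
    ClineModel,
    ClineParams,
    ClineSummary,
    cline_frequency,
)
from .exceptions import InvalidParameterError

__all__ = [
    "LikelihoodConfig",
    "ClineFitResult",
    "read_depth_loglik",
    "fit_snp_cline",
    "select_cline_model",
    "variance_explained",
    "fit_many",
    "ReadDepthClineFitter",
]

CLINAL_MODELS = (
    ClineModel.SIGMOID,
    ClineModel.LEFT_TAILED,
    ClineModel.RIGHT_TAILED,
    ClineModel.TWO_TAILED,
)


@dataclass
class LikelihoodConfig:
    """Bounds, starting values and read-error settings for ML fitting.

    ``error_rate`` is the symmetric per-read error epsilon; ``width_lower``
    is the hard floor on cline width (1 m), which caps how steep a fitted
    cline can be.
    """

    error_rate: float = 0.01
    width_lower: float = 1.0
    width_upper: float = 500.0
    center_margin: float = 50.0
    delta_upper: float = 100.0
    tau_lower: float = 0.01
    n_starts: int = 3
    min_individuals: int = 20
    maxiter: int = 200
    delta_aic: float = 4.0
    symmetric_tails: bool = False
    models: tuple = tuple(m.value for m in CLINAL_MODELS)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidParameterError("error_rate must lie in [0, 0.5)")
        if self.width_lower <= 0:
            raise InvalidParameterError("width lower bound must be positive")


@dataclass
class ClineFitResult:
    """All per-model fits for one response plus the AIC selection."""

    models: dict  # ClineModel -> dict(params, logl, aic, k)
    best_model: ClineModel
    clinal: bool
    delta_aic_vs_null: float
    var_ex: float
    summary: ClineSummary | None
    n_used: int
    ok: bool = True
    note: str = ""

    @property
    def best(self) -> dict:
        return self.models[self.best_model]

    @property
    def params(self) -> ClineParams:
        return self.best["params"]


def read_depth_loglik(ref, alt, positions, params: ClineParams,
                      cfg: LikelihoodConfig | None = None) -> float:
    """Log-likelihood of per-individual (ref, alt) read counts under a cline.

    Individuals with zero total depth contribute zero.  The binomial
    coefficient is included so the value is an absolute log probability.
    """
    cfg = cfg or LikelihoodConfig()
    ref = np.asarray(ref, dtype=np.float64)
    alt = np.asarray(alt, dtype=np.float64)
    x = np.asarray(positions, dtype=np.float64)
    pr = cline_frequency(params, x)
    pr = np.atleast_1d(pr)
    if np.any(pr < -1e-12) or np.any(pr > 1 + 1e-12):
        raise InvalidParameterError("cline frequency outside [0, 1]")
    logc = log_binom_coeff(ref, alt)
    code = MODEL_CODES[params.model]
    return -float(
        negll_kernel(0, params.to_theta(), code, x, ref, alt, logc,
                     cfg.error_rate)
    )


# ---------------------------------------------------------------------------
# fitting engine (shared by SNP, trait and morph clines)
# ---------------------------------------------------------------------------


def _model_bounds(model: ClineModel, x: np.ndarray, cfg: LikelihoodConfig):
    lo, hi = float(np.min(x)), float(np.max(x))
    base = [
        (0.0, 1.0),
        (0.0, 1.0),
        (lo - cfg.center_margin, hi + cfg.center_margin),
        (cfg.width_lower, cfg.width_upper),
    ]
    tail = [(0.0, cfg.delta_upper), (cfg.tau_lower, 1.0)]
    if model is ClineModel.SIGMOID:
        return base
    if model in (ClineModel.LEFT_TAILED, ClineModel.RIGHT_TAILED):
        return base + tail
    return base + tail + tail


def _initial_sigmoid(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Data-driven start: center at the steepest smoothed gradient."""
    order = np.argsort(x)
    xs, ys, ws = x[order], y[order], w[order]
    nbin = max(6, min(15, len(xs) // 10))
    edges = np.linspace(xs[0], xs[-1] + 1e-9, nbin + 1)
    idx = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, nbin - 1)
    num = np.bincount(idx, weights=ws * ys, minlength=nbin)
    den = np.bincount(idx, weights=ws, minlength=nbin)
    with np.errstate(invalid="ignore"):
        fb = num / den
    centers = 0.5 * (edges[:-1] + edges[1:])
    good = den > 0
    fb, centers = fb[good], centers[good]
    if len(fb) < 3:
        c0 = float(np.median(xs))
        p_c0, p_w0 = float(np.mean(ys)), float(np.mean(ys))
    else:
        grad = np.abs(np.diff(fb) / np.maximum(np.diff(centers), 1e-9))
        j = int(np.argmax(grad))
        c0 = float(0.5 * (centers[j] + centers[j + 1]))
        p_c0 = float(np.mean(fb[: max(1, len(fb) // 5)]))
        p_w0 = float(np.mean(fb[-max(1, len(fb) // 5):]))
    q75, q25 = np.percentile(xs, [75, 25])
    w0 = max(float(q75 - q25), 2.0)
    return np.array([np.clip(p_c0, 0.01, 0.99), np.clip(p_w0, 0.01, 0.99), c0, w0])


def _optimize(kind, code, theta0, bounds, x, a, b, logc, eps, maxiter):
    res = minimize(
        lambda t: negll_and_grad(kind, t, code, x, a, b, logc, eps),
        np.asarray(theta0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    return res.x, float(res.fun)


def _optimize_symmetric_two_tailed(run_opt_raw, th0, bounds, maxiter):
    """Two-tailed fit with shared (delta, tau): 6 free parameters."""
    res = minimize(run_opt_raw, np.asarray(th0, dtype=float),
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10})
    return res.x, float(res.fun)


def _fit_null(kind, x, a, b, logc, eps) -> tuple[np.ndarray, float]:
    if kind == 1:  # Gaussian: closed form
        p = float(np.clip(np.mean(a), 0.0, 1.0))
        th = np.array([p])
        return th, float(negll_kernel(1, th, 0, x, a, b, logc, eps))
    if kind == 2:
        p = float(np.clip(np.mean(a), 1e-9, 1 - 1e-9))
        th = np.array([p])
        return th, float(negll_kernel(2, th, 0, x, a, b, logc, eps))
    res = minimize_scalar(
        lambda p: negll_kernel(0, np.array([p]), 0, x, a, b, logc, eps),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return np.array([res.x]), float(res.fun)


def _fit_family(kind, x, a, b, logc, cfg: LikelihoodConfig, rng: np.random.Generator):
    """Fit all five models; returns {ClineModel: dict(params, logl, aic, k)}."""
    eps = cfg.error_rate
    x = np.ascontiguousarray(x, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    logc = np.ascontiguousarray(logc, dtype=np.float64)
    extra_k = 1 if kind == 1 else 0  # Gaussian residual SD

    if kind == 0:
        # read depths: factor the parameter-free binomial terms out once
        e0, e1, e2, offset = precompute_read_terms(a, b, logc, eps)

        def run_opt(code, th0, bounds):
            res = minimize(
                lambda t: negll_read_fast_grad(t, code, x, e0, e1, e2),
                np.asarray(th0, dtype=float), jac=True, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": cfg.maxiter, "ftol": 1e-10},
            )
            return res.x, float(res.fun)

        def run_null():
            res = minimize_scalar(
                lambda p: negll_read_fast(np.array([p]), 0, x, e0, e1, e2),
                bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-9},
            )
            return np.array([res.x]), float(res.fun)
    else:
        offset = 0.0

        def run_opt(code, th0, bounds):
            return _optimize(kind, code, th0, bounds, x, a, b, logc, eps,
                             cfg.maxiter)

        def run_null():
            return _fit_null(kind, x, a, b, logc, eps)

    out = {}
    th_null, f_null = run_null()
    k = MODEL_NPARAMS[ClineModel.NULL] + extra_k
    logl = -f_null + offset
    out[ClineModel.NULL] = dict(
        params=ClineParams.from_theta(ClineModel.NULL, th_null),
        logl=logl, aic=2 * k - 2 * logl, k=k,
    )

    if kind == 0:
        d = a + b
        with np.errstate(invalid="ignore"):
            y = np.where(d > 0, a / np.maximum(d, 1), 0.5)
        wts = d
    else:
        y = a
        wts = np.ones_like(a)
    th_sig0 = _initial_sigmoid(x, y, wts)

    # sigmoid: data-driven start plus seeded jitters
    code = MODEL_CODES[ClineModel.SIGMOID]
    bounds = _model_bounds(ClineModel.SIGMOID, x, cfg)
    starts = [th_sig0]
    span = float(np.max(x) - np.min(x))
    for _ in range(max(0, cfg.n_starts - 1)):
        jit = th_sig0.copy()
        jit[0] = np.clip(jit[0] + rng.normal(0, 0.1), 0.01, 0.99)
        jit[1] = np.clip(jit[1] + rng.normal(0, 0.1), 0.01, 0.99)
        jit[2] += rng.normal(0, 0.08 * span)
        jit[3] = np.clip(jit[3] * rng.uniform(0.4, 2.5),
                         cfg.width_lower, cfg.width_upper)
        starts.append(jit)
    best = None
    for th0 in starts:
        th0 = np.clip(th0, [bb[0] for bb in bounds], [bb[1] for bb in bounds])
        th, f = run_opt(code, th0, bounds)
        if best is None or f < best[1]:
            best = (th, f)
    th_sig, f_sig = best
    k = MODEL_NPARAMS[ClineModel.SIGMOID] + extra_k
    logl = -f_sig + offset
    out[ClineModel.SIGMOID] = dict(
        params=ClineParams.from_theta(ClineModel.SIGMOID, th_sig),
        logl=logl, aic=2 * k - 2 * logl, k=k,
    )

    wanted = {ClineModel(m) for m in cfg.models}
    for model in (ClineModel.LEFT_TAILED, ClineModel.RIGHT_TAILED,
                  ClineModel.TWO_TAILED):
        if model not in wanted:
            continue
        code = MODEL_CODES[model]
        bounds = _model_bounds(model, x, cfg)
        if model is ClineModel.TWO_TAILED:
            tails0 = [5.0, 0.5, 5.0, 0.5]
        else:
            tails0 = [5.0, 0.5]
        starts = [np.concatenate([th_sig, tails0])]
        jit = starts[0].copy()
        jit[4::2] = rng.uniform(2.0, 25.0, size=len(tails0) // 2)
        jit[5::2] = rng.uniform(0.1, 0.9, size=len(tails0) // 2)
        starts.append(jit)
        symmetric = (model is ClineModel.TWO_TAILED and cfg.symmetric_tails)
        best = None
        for th0 in starts:
            th0 = np.clip(th0, [bb[0] for bb in bounds], [bb[1] for bb in bounds])
            if symmetric:
                th, f = _optimize_symmetric_two_tailed(
                    run_opt_raw=lambda t: (negll_read_fast(
                        np.concatenate([t, t[4:6]]), code, x, e0, e1, e2)
                        if kind == 0 else negll_kernel(
                            kind, np.concatenate([t, t[4:6]]), code, x, a, b,
                            logc, eps)),
                    th0=th0[:6], bounds=bounds[:6], maxiter=cfg.maxiter)
                th = np.concatenate([th, th[4:6]])
            else:
                th, f = run_opt(code, th0, bounds)
            if best is None or f < best[1]:
                best = (th, f)
        th_m, f_m = best
        # nested models: never report a tailed fit worse than the sigmoid
        if f_m > f_sig:
            th_m = np.concatenate([th_sig, [0.0, 1.0] * (len(tails0) // 2)])
            f_m = f_sig
        k = MODEL_NPARAMS[model] + extra_k
        if symmetric:
            k -= 2  # shared (delta, tau) across the two tails
        logl = -f_m + offset
        out[model] = dict(
            params=ClineParams.from_theta(model, th_m),
            logl=logl, aic=2 * k - 2 * logl, k=k,
        )
    return out


def select_cline_model(aics: dict, delta_aic: float = 4.0):
    """AIC selection with a strict complexity ladder.

    Clinal iff AIC(null) - min AIC(clinal) > ``delta_aic`` (strict).  Among
    clinal models, a more complex model is chosen only if it beats every
    simpler clinal model by more than ``delta_aic``; otherwise the simplest
    adequate model (the sigmoid) wins.  Between the equally complex
    one-tailed models the lower AIC wins.
    """
    present = [m for m in CLINAL_MODELS if m in aics]
    best_clinal_aic = min(aics[m] for m in present)
    clinal = (aics[ClineModel.NULL] - best_clinal_aic) > delta_aic
    if not clinal:
        return ClineModel.NULL, False
    best = ClineModel.SIGMOID
    one_tailed = [m for m in (ClineModel.LEFT_TAILED, ClineModel.RIGHT_TAILED)
                  if m in aics]
    if one_tailed:
        k6 = min(one_tailed, key=lambda m: aics[m])
        if aics[ClineModel.SIGMOID] - aics[k6] > delta_aic:
            best = k6
    if ClineModel.TWO_TAILED in aics:
        simpler = [ClineModel.SIGMOID] + one_tailed
        if all(aics[m] - aics[ClineModel.TWO_TAILED] > delta_aic for m in simpler):
            best = ClineModel.TWO_TAILED
    return best, True


def variance_explained(params: ClineParams, positions, y, weights) -> float:
    """Weighted R-squared (x100) of observations against the fitted cline.

    For read-depth data ``y`` is the per-individual reference-read fraction
    and ``weights`` the total depth; zero-weight individuals are ignored.
    May be negative for a bad fit; capped above at 100.  The constant null
    model explains no spatial variance by construction (returns 0).
    """
    if params.model is ClineModel.NULL:
        return 0.0
    x = np.asarray(positions, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    m = w > 0
    if m.sum() == 0:
        return float("nan")
    x, y, w = x[m], y[m], w[m]
    ybar = np.sum(w * y) / np.sum(w)
    denom = np.sum(w * (y - ybar) ** 2)
    if denom <= 0:
        return float("nan")
    fitted = np.atleast_1d(cline_frequency(params, x))
    num = np.sum(w * (y - fitted) ** 2)
    return float(min(100.0, 100.0 * (1.0 - num / denom)))


def _assemble_result(models: dict, delta_aic: float, x, y, weights,
                     n_used: int) -> ClineFitResult:
    """Model selection + var.ex + summary from a fitted family."""
    aics = {m: d["aic"] for m, d in models.items()}
    best, clinal = select_cline_model(aics, delta_aic)
    delta = aics[ClineModel.NULL] - min(
        aics[m] for m in aics if m is not ClineModel.NULL
    )
    var_ex = variance_explained(models[best]["params"], x, y, weights)
    summary = None
    if clinal:
        p = models[best]["params"]
        dp = p.p_w - p.p_c
        summary = ClineSummary(
            delta_p=float(dp), abs_delta_p=float(abs(dp)),
            slope=float(abs(dp) / p.width), center=float(p.center),
            width=float(p.width),
        )
    return ClineFitResult(
        models=models, best_model=best, clinal=clinal,
        delta_aic_vs_null=float(delta), var_ex=var_ex, summary=summary,
        n_used=n_used,
    )


def fit_snp_cline(ref, alt, positions, cfg: LikelihoodConfig | None = None,
                  rng: np.random.Generator | int | None = None) -> ClineFitResult:
    """Fit the full cline family to one SNP's allelic read depths."""
    cfg = cfg or LikelihoodConfig()
    rng = np.random.default_rng(rng)
    ref = np.asarray(ref, dtype=np.float64)
    alt = np.asarray(alt, dtype=np.float64)
    x = np.asarray(positions, dtype=np.float64)
    depth = ref + alt
    n_used = int(np.sum(depth > 0))
    if n_used < cfg.min_individuals:
        return ClineFitResult(
            models={}, best_model=ClineModel.NULL, clinal=False,
            delta_aic_vs_null=np.nan, var_ex=np.nan, summary=None,
            n_used=n_used, ok=False, note="too_few_individuals",
        )
    logc = log_binom_coeff(ref, alt)
    try:
        models = _fit_family(0, x, ref, alt, logc, cfg, rng)
    except Exception:  # optimizer failure on all restarts
        return ClineFitResult(
            models={}, best_model=ClineModel.NULL, clinal=False,
            delta_aic_vs_null=np.nan, var_ex=np.nan, summary=None,
            n_used=n_used, ok=False, note="optimizer_failure",
        )
    with np.errstate(invalid="ignore"):
        y = np.where(depth > 0, ref / np.maximum(depth, 1), 0.0)
    return _assemble_result(models, cfg.delta_aic, x, y, depth, n_used)


def _result_row(snp_id, res: ClineFitResult) -> dict:
    row = dict(
        snp_id=snp_id, ok=res.ok, n_used=res.n_used,
        best_model=res.best_model.value if res.ok else "failed",
        clinal=bool(res.clinal), delta_aic_vs_null=res.delta_aic_vs_null,
        var_ex=res.var_ex, note=res.note,
    )
    if res.ok:
        p = res.params
        dp = p.p_w - p.p_c
        row.update(
            p_c=p.p_c, p_w=p.p_w, center=p.center,
            width=p.width if res.clinal else np.nan,
            delta_p=dp, abs_delta_p=abs(dp),
            slope=(abs(dp) / p.width) if res.clinal else np.nan,
            wave_allele=("ref" if dp >= 0 else "alt"),
            aic_null=res.models[ClineModel.NULL]["aic"],
            aic_best=res.models[res.best_model]["aic"],
            logl_best=res.models[res.best_model]["logl"],
        )
    else:
        row.update(p_c=np.nan, p_w=np.nan, center=np.nan, width=np.nan,
                   delta_p=np.nan, abs_delta_p=np.nan, slope=np.nan,
                   wave_allele="", aic_null=np.nan, aic_best=np.nan,
                   logl_best=np.nan)
    return row


def fit_many(ref_matrix, alt_matrix, positions, cfg: LikelihoodConfig | None = None,
             seed: int | None = 0, snp_ids=None, progress: bool = False):
    """Fit clines for many SNPs; returns a per-SNP pandas DataFrame.

    ``ref_matrix``/``alt_matrix`` are (n_snps, n_individuals) arrays.
    """
    import pandas as pd

    cfg = cfg or LikelihoodConfig()
    ref_matrix = np.asarray(ref_matrix)
    alt_matrix = np.asarray(alt_matrix)
    n_snps = ref_matrix.shape[0]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(n_snps)]
    ss = np.random.SeedSequence(seed)
    rows = []
    it = range(n_snps)
    if progress:
        from tqdm import tqdm

        it = tqdm(it, desc="fitting clines")
    children = ss.spawn(n_snps)
    for i in it:
        res = fit_snp_cline(ref_matrix[i], alt_matrix[i], positions, cfg,
                            np.random.default_rng(children[i]))
        rows.append(_result_row(snp_ids[i], res))
    return pd.DataFrame(rows)


class ReadDepthClineFitter(BaseEstimator):
    """Scikit-learn style estimator fitting one SNP cline from read depths.

    ``fit(X, y)`` takes 1D transect positions ``X`` (metres) and an
    ``(n, 2)`` array ``y`` of (ref, alt) read counts.  Fitted attributes:
    ``params_``, ``best_model_``, ``clinal_``, ``var_ex_``, ``results_``.
    ``predict(X)`` returns the expected reference-allele frequency.
    """

    def __init__(self, error_rate: float = 0.01, width_lower: float = 1.0,
                 n_starts: int = 3, delta_aic: float = 4.0,
                 min_individuals: int = 20, random_state: int | None = 0):
        self.error_rate = error_rate
        self.width_lower = width_lower
        self.n_starts = n_starts
        self.delta_aic = delta_aic
        self.min_individuals = min_individuals
        self.random_state = random_state

    def _config(self) -> LikelihoodConfig:
        return LikelihoodConfig(
            error_rate=self.error_rate, width_lower=self.width_lower,
            n_starts=self.n_starts, delta_aic=self.delta_aic,
            min_individuals=self.min_individuals,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be an (n, 2) array of (ref, alt) counts")
        res = fit_snp_cline(y[:, 0], y[:, 1], X, self._config(),
                            np.random.default_rng(self.random_state))
        self.results_ = res
        self.params_ = res.params if res.ok else None
        self.best_model_ = res.best_model
        self.clinal_ = res.clinal
        self.var_ex_ = res.var_ex
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        X = np.asarray(X, dtype=float).reshape(-1)
        return np.atleast_1d(cline_frequency(self.params_, X))
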