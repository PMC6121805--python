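"""Geographic cline model family.

The family comprises a constant-frequency null model, the simple sigmoid
cline, and stepped clines with an exponential tail on the left (Crab) side,
the right (Wave) side, or both.  The central segment is

    p(x) = p_C + (p_W - p_C) * S(x),      S(x) = 1 / (1 + exp(-4 (x - c) / w))

so that the slope of p at the center is exactly (p_W - p_C) / w, which makes
``width`` the inverse of the maximum relative slope.  A left tail replaces S
below the junction x_L = c - delta_L by an exponential that is continuous
with the central sigmoid at the junction and whose log-slope there is tau_L
times the sigmoid's; the right tail mirrors this above x_R = c + delta_R.
With the junctions pushed outside the data range (large delta) every tailed
model coincides exactly with the sigmoid.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import InvalidParameterError, UndefinedSlopeError

__all__ = [
    "ClineModel",
    "ClineParams",
    "ClineSummary",
    "cline_frequency",
    "cline_slope",
    "MODEL_NPARAMS",
]


class ClineModel(str, enum.Enum):
    NULL = "null"
    SIGMOID = "sigmoid"
    LEFT_TAILED = "left_tailed"
    RIGHT_TAILED = "right_tailed"
    TWO_TAILED = "two_tailed"


#: integer codes shared with the numba kernels
MODEL_CODES = {
    ClineModel.NULL: 0,
    ClineModel.SIGMOID: 1,
    ClineModel.LEFT_TAILED: 2,
    ClineModel.RIGHT_TAILED: 3,
    ClineModel.TWO_TAILED: 4,
}
CODE_TO_MODEL = {v: k for k, v in MODEL_CODES.items()}

#: number of free parameters of each frequency model (excludes any residual
#: scale parameter added by Gaussian trait fits)
MODEL_NPARAMS = {
    ClineModel.NULL: 1,
    ClineModel.SIGMOID: 4,
    ClineModel.LEFT_TAILED: 6,
    ClineModel.RIGHT_TAILED: 6,
    ClineModel.TWO_TAILED: 8,
}


@dataclass
class ClineParams:
    """Parameters of one member of the cline model family.

    ``p_c``/``p_w`` are the asymptotic frequencies at the Crab (x -> -inf)
    and Wave (x -> +inf) ends, ``center``/``width`` in metres, ``delta_*``
    the tail junction offsets (metres, >= 0) and ``tau_*`` the tail
    slope-ratios in [0, 1].  For the null model only ``p_c`` is used.
    """

    model: ClineModel
    p_c: float
    p_w: float = field(default=np.nan)
    center: float = 0.0
    width: float = 1.0
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0

    def __post_init__(self) -> None:
        self.model = ClineModel(self.model)
        if self.model is ClineModel.NULL:
            self.p_w = self.p_c
            return
        if not np.isfinite(self.width) or self.width <= 0:
            raise InvalidParameterError(f"cline width must be > 0, got {self.width}")
        for nm in ("p_c", "p_w"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{nm}={v} outside [0, 1]")
        for nm in ("delta_l", "delta_r"):
            if getattr(self, nm) < 0:
                raise InvalidParameterError(f"{nm} must be >= 0")
        for nm in ("tau_l", "tau_r"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{nm}={v} outside [0, 1]")

    def to_theta(self) -> np.ndarray:
        """Free-parameter vector in the order used by the fitting kernels."""
        m = self.model
        if m is ClineModel.NULL:
            return np.array([self.p_c])
        base = [self.p_c, self.p_w, self.center, self.width]
        if m is ClineModel.LEFT_TAILED:
            base += [self.delta_l, self.tau_l]
        elif m is ClineModel.RIGHT_TAILED:
            base += [self.delta_r, self.tau_r]
        elif m is ClineModel.TWO_TAILED:
            base += [self.delta_l, self.tau_l, self.delta_r, self.tau_r]
        return np.asarray(base, dtype=float)

    @classmethod
    def from_theta(cls, model: ClineModel, theta: np.ndarray) -> "ClineParams":
        model = ClineModel(model)
        t = np.asarray(theta, dtype=float)
        if model is ClineModel.NULL:
            return cls(model, p_c=t[0])
        kw = dict(p_c=t[0], p_w=t[1], center=t[2], width=t[3])
        if model is ClineModel.LEFT_TAILED:
            kw.update(delta_l=t[4], tau_l=t[5])
        elif model is ClineModel.RIGHT_TAILED:
            kw.update(delta_r=t[4], tau_r=t[5])
        elif model is ClineModel.TWO_TAILED:
            kw.update(delta_l=t[4], tau_l=t[5], delta_r=t[6], tau_r=t[7])
        return cls(model, **kw)


@dataclass
class ClineSummary:
    """Derived quantities of a fitted cline."""

    delta_p: float  # signed p_W - p_C
    abs_delta_p: float
    slope: float  # per metre, |delta_p| / width
    center: float
    width: float


@njit(cache=False)
def _s_scaled(code: int, c: float, w: float, dl: float, tl: float,
              dr: float, tr: float, x: float) -> float:
    """Shape function S(x) in [0, 1] for model ``code`` (1..4)."""
    if code == 2 or code == 4:  # left tail active
        xl = c - dl
        if x < xl:
            sl = 1.0 / (1.0 + math.exp(min(4.0 * dl / w, 700.0)))
            # log-slope of the sigmoid at the junction is (4/w)(1 - S_L)
            return sl * math.exp(tl * (4.0 / w) * (1.0 - sl) * (x - xl))
    if code == 3 or code == 4:  # right tail active
        xr = c + dr
        if x > xr:
            sr = 1.0 / (1.0 + math.exp(min(-4.0 * dr / w, 700.0)))
            return 1.0 - (1.0 - sr) * math.exp(-tr * (4.0 / w) * sr * (x - xr))
    u = 4.0 * (x - c) / w
    if u > 700.0:
        return 1.0
    if u < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-u))


@njit(cache=False)
def _freq_one(code: int, theta: np.ndarray, x: float) -> float:
    """Expected frequency at x for parameter vector ``theta`` (kernel form)."""
    if code == 0:
        return theta[0]
    pc, pw, c, w = theta[0], theta[1], theta[2], theta[3]
    dl = 0.0
    tl = 1.0
    dr = 0.0
    tr = 1.0
    if code == 2:
        dl, tl = theta[4], theta[5]
    elif code == 3:
        dr, tr = theta[4], theta[5]
    elif code == 4:
        dl, tl, dr, tr = theta[4], theta[5], theta[6], theta[7]
    s = _s_scaled(code, c, w, dl, tl, dr, tr, x)
    return pc + (pw - pc) * s


def cline_frequency(params: ClineParams, x) -> np.ndarray | float:
    """Expected allele frequency p(x) under ``params``.

    Continuous in x for every model; vectorized over ``x``.
    """
    code = MODEL_CODES[params.model]
    theta = params.to_theta()
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(xs)
    for i, xi in enumerate(xs):
        out[i] = _freq_one(code, theta, xi)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out


def cline_slope(params: ClineParams) -> float:
    """Maximum cline slope |p_W - p_C| / w (per metre).

    Undefined for the null model.
    """
    if params.model is ClineModel.NULL:
        raise UndefinedSlopeError("slope is undefined for the constant-frequency null")
    return abs(params.p_w - params.p_c) / params.width


def tail_junctions(params: ClineParams) -> list[float]:
    """Positions (metres) of the active tail junctions of ``params``."""
    out = []
    if params.model in (ClineModel.LEFT_TAILED, ClineModel.TWO_TAILED):
        out.append(params.center - params.delta_l)
    if params.model in (ClineModel.RIGHT_TAILED, ClineModel.TWO_TAILED):
        out.append(params.center + params.delta_r)
    return out
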