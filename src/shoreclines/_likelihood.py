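"""Numba kernels for cline likelihoods.

Three observation models share the cline frequency function:

* ``kind=0`` read depths: per individual the likelihood sums over the three
  Hardy-Weinberg genotypes at the local expected frequency p(x), each
  contributing a binomial probability for the observed reference-read count
  with genotype-dependent success probability mu_g = eps + (g/2)(1 - 2 eps).
* ``kind=1`` Gaussian trait: cline gives the mean, residual SD profiled out.
* ``kind=2`` Bernoulli morph indicator: cline gives the morph frequency.

All kernels return the *negative* log-likelihood.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .cline_models import _freq_one

_BIG = 1e12


@njit(cache=False)
def negll_kernel(kind: int, theta: np.ndarray, code: int, x: np.ndarray,
                 a: np.ndarray, b: np.ndarray, logc: np.ndarray,
                 eps: float) -> float:
    n = x.shape[0]
    if kind == 1:
        # Gaussian: profile out the residual variance
        ssr = 0.0
        m = 0
        for i in range(n):
            mu = _freq_one(code, theta, x[i])
            if mu < 0.0:
                mu = 0.0
            elif mu > 1.0:
                mu = 1.0
            d = a[i] - mu
            ssr += d * d
            m += 1
        if m == 0:
            return 0.0
        s2 = ssr / m
        if s2 < 1e-12:
            s2 = 1e-12
        return 0.5 * m * (math.log(2.0 * math.pi * s2) + 1.0)

    total = 0.0
    mu0 = eps
    mu1 = 0.5
    mu2 = 1.0 - eps
    for i in range(n):
        p = _freq_one(code, theta, x[i])
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        if kind == 2:
            pi = p
            if pi < 1e-12:
                pi = 1e-12
            elif pi > 1.0 - 1e-12:
                pi = 1.0 - 1e-12
            if a[i] > 0.5:
                total += math.log(pi)
            else:
                total += math.log(1.0 - pi)
            continue
        ref = a[i]
        alt = b[i]
        if ref + alt <= 0:
            continue
        q = 1.0 - p
        best = -1.0e308
        t0 = -1.0e308
        t1 = -1.0e308
        t2 = -1.0e308
        # g = number of reference alleles; HWE prior at local p
        pr0 = q * q
        pr1 = 2.0 * p * q
        pr2 = p * p
        ok = False
        if pr0 > 0.0 and not (ref > 0 and mu0 <= 0.0):
            t0 = math.log(pr0)
            if ref > 0:
                t0 += ref * math.log(mu0)
            if alt > 0:
                t0 += alt * math.log(1.0 - mu0)
            ok = True
            if t0 > best:
                best = t0
        if pr1 > 0.0:
            t1 = math.log(pr1) + ref * math.log(mu1) + alt * math.log(1.0 - mu1)
            ok = True
            if t1 > best:
                best = t1
        if pr2 > 0.0 and not (alt > 0 and mu2 >= 1.0):
            t2 = math.log(pr2)
            if ref > 0:
                t2 += ref * math.log(mu2)
            if alt > 0:
                t2 += alt * math.log(1.0 - mu2)
            ok = True
            if t2 > best:
                best = t2
        if not ok or best <= -1.0e308:
            return _BIG
        acc = 0.0
        if t0 > -1.0e308:
            acc += math.exp(t0 - best)
        if t1 > -1.0e308:
            acc += math.exp(t1 - best)
        if t2 > -1.0e308:
            acc += math.exp(t2 - best)
        total += best + math.log(acc) + logc[i]
    return -total


@njit(cache=False)
def negll_and_grad(kind: int, theta: np.ndarray, code: int, x: np.ndarray,
                   a: np.ndarray, b: np.ndarray, logc: np.ndarray,
                   eps: float):
    """Value plus central-difference gradient of ``negll_kernel``."""
    f0 = negll_kernel(kind, theta, code, x, a, b, logc, eps)
    k = theta.shape[0]
    grad = np.zeros(k)
    work = theta.copy()
    for j in range(k):
        h = 1e-6 * (1.0 + abs(theta[j]))
        work[j] = theta[j] + h
        fp = negll_kernel(kind, work, code, x, a, b, logc, eps)
        work[j] = theta[j] - h
        fm = negll_kernel(kind, work, code, x, a, b, logc, eps)
        work[j] = theta[j]
        grad[j] = (fp - fm) / (2.0 * h)
    return f0, grad


@njit(cache=False)
def precompute_read_terms(ref, alt, logc, eps):
    """Per-individual genotype read-likelihood terms, normalized.

    The binomial factor for each genotype g does not depend on the cline
    parameters, so it is computed once per SNP: e_g[i] = exp(term_g - max_g)
    and the running constant collects max_g + log C(n, ref).  Zero-depth
    individuals get e = (1, 1, 1) and contribute nothing.
    """
    n = ref.shape[0]
    e0 = np.ones(n)
    e1 = np.ones(n)
    e2 = np.ones(n)
    const = 0.0
    mu0 = eps
    mu1 = 0.5
    mu2 = 1.0 - eps
    for i in range(n):
        r = ref[i]
        a = alt[i]
        if r + a <= 0:
            continue
        t0 = -1.0e308
        t1 = r * math.log(mu1) + a * math.log(1.0 - mu1)
        t2 = -1.0e308
        if not (r > 0 and mu0 <= 0.0):
            t0 = 0.0
            if r > 0:
                t0 += r * math.log(mu0)
            if a > 0:
                t0 += a * math.log(1.0 - mu0)
        if not (a > 0 and mu2 >= 1.0):
            t2 = 0.0
            if r > 0:
                t2 += r * math.log(mu2)
            if a > 0:
                t2 += a * math.log(1.0 - mu2)
        mx = max(t0, max(t1, t2))
        e0[i] = math.exp(t0 - mx) if t0 > -1.0e308 else 0.0
        e1[i] = math.exp(t1 - mx)
        e2[i] = math.exp(t2 - mx) if t2 > -1.0e308 else 0.0
        const += mx + logc[i]
    return e0, e1, e2, const


@njit(cache=False)
def negll_read_fast(theta, code, x, e0, e1, e2):
    """Read-depth negative log-likelihood minus its parameter-free constant."""
    tot = 0.0
    for i in range(x.shape[0]):
        p = _freq_one(code, theta, x[i])
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        q = 1.0 - p
        li = q * q * e0[i] + 2.0 * p * q * e1[i] + p * p * e2[i]
        if li <= 0.0:
            return _BIG
        tot += math.log(li)
    return -tot


@njit(cache=False)
def negll_read_fast_grad(theta, code, x, e0, e1, e2):
    f0 = negll_read_fast(theta, code, x, e0, e1, e2)
    k = theta.shape[0]
    grad = np.zeros(k)
    work = theta.copy()
    for j in range(k):
        h = 1e-6 * (1.0 + abs(theta[j]))
        work[j] = theta[j] + h
        fp = negll_read_fast(work, code, x, e0, e1, e2)
        work[j] = theta[j] - h
        fm = negll_read_fast(work, code, x, e0, e1, e2)
        work[j] = theta[j]
        grad[j] = (fp - fm) / (2.0 * h)
    return f0, grad


def log_binom_coeff(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """log C(ref+alt, ref), the parameter-free term of the read likelihood."""
    from scipy.special import gammaln

    n = ref + alt
    return gammaln(n + 1) - gammaln(ref + 1) - gammaln(alt + 1)
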