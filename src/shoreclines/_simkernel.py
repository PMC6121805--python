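"""Numba kernel for the deme-chain forward simulation.

Diploid genotypes are stored as two allele bit-planes packed into uint64
words (one bit per locus per haploid genome), so Mendelian transmission of
a whole gamete is a handful of masked word operations with one random
64-bit mask per word.  Selection acts multiplicatively across the selected
loci with additive within-locus effects, which reduces the per-individual
log-fitness to two popcount reductions over the selected-locus mask.

The kernel uses its own xoshiro256++ generator (seeded via splitmix64) so
that runs are bit-identical for a given seed regardless of numpy/numba
internals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_U1 = np.uint64(1)
_U64 = np.uint64(64)


@njit(cache=False, inline="always")
def _popcount(x):
    x = x - ((x >> _U1) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return (x * _H01) >> np.uint64(56)


@njit(cache=False, inline="always")
def _splitmix64(state):
    state[0] = state[0] + np.uint64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=False, inline="always")
def _rotl(x, k):
    return (x << k) | (x >> (_U64 - k))


@njit(cache=False, inline="always")
def _next64(s):
    result = _rotl(s[0] + s[3], np.uint64(23)) + s[0]
    t = s[1] << np.uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], np.uint64(45))
    return result


@njit(cache=False, inline="always")
def _uniform(s):
    # 53-bit uniform in [0, 1)
    return float(_next64(s) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=False, inline="always")
def _normal(s):
    u1 = (float(_next64(s) >> np.uint64(11)) + 1.0) * 1.1102230246251565e-16
    u2 = float(_next64(s) >> np.uint64(11)) * 1.1102230246251565e-16
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(6.283185307179586 * u2)


@njit(cache=False, inline="always")
def _pick_parent(cum, s0, cnt, r):
    lo = 0
    hi = cnt - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[s0 + mid] < r:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False)
def _record(traj_slice, a1, a2, deme, n_loci):
    n, nw = a1.shape
    for i in range(n):
        d = deme[i]
        loc = 0
        for w in range(nw):
            w1 = a1[i, w]
            w2 = a2[i, w]
            if w1 == np.uint64(0) and w2 == np.uint64(0):
                loc += 64
                if loc >= n_loci:
                    break
                continue
            m = _U1
            for _ in range(64):
                if loc >= n_loci:
                    break
                c = 0
                if w1 & m:
                    c += 1
                if w2 & m:
                    c += 1
                if c:
                    traj_slice[d, loc] += c
                m = m << _U1
                loc += 1
    return


@njit(cache=False)
def unpack_genotypes(a1, a2, n_loci):
    """Dosage of allele 1 per individual and locus as an int8 matrix."""
    n, nw = a1.shape
    g = np.zeros((n, n_loci), np.int8)
    for i in range(n):
        loc = 0
        for w in range(nw):
            w1 = a1[i, w]
            w2 = a2[i, w]
            m = _U1
            for _ in range(64):
                if loc >= n_loci:
                    break
                c = 0
                if w1 & m:
                    c += 1
                if w2 & m:
                    c += 1
                g[i, loc] = c
                m = m << _U1
                loc += 1
    return g


@njit(cache=False)
def run_kernel(a1, a2, deme, out_a1, out_a2, out_deme, n_demes, n_per_deme,
               sigma, switch_idx, log_f_het, log_f_curv, selmask, n_selected,
               n_loci, generations, rec_gens, traj, mu, seed):
    """Advance the deme chain ``generations`` steps.

    ``log_f_het`` (A) and ``log_f_curv`` (B) encode the per-locus fitness
    triple (1, 1-s/2, 1-s) on the favoured-allele dosage scale:
    log w = A*g + B*[g == 2] summed over selected loci.  Returns
    (extinct_generation, extinct_deme) or (-1, -1) on success.
    """
    n, nw = a1.shape
    st = np.empty(1, np.uint64)
    st[0] = np.uint64(seed)
    s = np.empty(4, np.uint64)
    for i in range(4):
        s[i] = _splitmix64(st)

    b1 = np.empty_like(a1)
    b2 = np.empty_like(a2)
    ndeme = np.empty_like(deme)
    counts = np.zeros(n_demes, np.int64)
    starts = np.zeros(n_demes + 1, np.int64)
    fill = np.zeros(n_demes, np.int64)
    idx = np.empty(n, np.int64)
    logw = np.empty(n, np.float64)
    cum = np.empty(n, np.float64)

    two_ls = 2 * n_selected
    rec_ptr = 0
    cur1, cur2, curd = a1, a2, deme
    new1, new2, newd = b1, b2, ndeme

    for gen in range(1, generations + 1):
        # dispersal of the adults produced last generation (Gaussian
        # displacement from the natal deme center, reflected at the ends)
        lim = float(n_demes)
        for i in range(n):
            x = curd[i] + 0.5 + sigma * _normal(s)
            while x < 0.0 or x > lim:
                if x < 0.0:
                    x = -x
                else:
                    x = 2.0 * lim - x
            dd = int(x)
            if dd >= n_demes:
                dd = n_demes - 1
            curd[i] = dd

        counts[:] = 0
        for i in range(n):
            counts[curd[i]] += 1
        for d in range(n_demes):
            if counts[d] == 0:
                return gen, d
        starts[0] = 0
        for d in range(n_demes):
            starts[d + 1] = starts[d] + counts[d]
            fill[d] = starts[d]
        for i in range(n):
            d = curd[i]
            idx[fill[d]] = i
            fill[d] += 1

        if n_selected > 0 and (log_f_het != 0.0 or log_f_curv != 0.0):
            for i in range(n):
                g = 0
                o = 0
                h = 0
                for w in range(nw):
                    sa1 = cur1[i, w] & selmask[w]
                    sa2 = cur2[i, w] & selmask[w]
                    g += int(_popcount(sa1)) + int(_popcount(sa2))
                    o += int(_popcount(sa1 | sa2))
                    h += int(_popcount(sa1 & sa2))
                if curd[i] < switch_idx:
                    # crab side: allele 0 favoured, so the mismatch dosage
                    # per locus is g itself
                    logw[i] = log_f_het * g + log_f_curv * h
                else:
                    # wave side: mismatch dosage is 2 - g per locus
                    logw[i] = log_f_het * (two_ls - g) + \
                        log_f_curv * (n_selected - o)
        else:
            for i in range(n):
                logw[i] = 0.0

        ci = 0
        for d in range(n_demes):
            s0 = starts[d]
            cnt = counts[d]
            mx = -1.0e308
            for j in range(cnt):
                v = logw[idx[s0 + j]]
                if v > mx:
                    mx = v
            tot = 0.0
            for j in range(cnt):
                tot += math.exp(logw[idx[s0 + j]] - mx)
                cum[s0 + j] = tot
            for _child in range(n_per_deme):
                r1 = _uniform(s) * tot
                j1 = _pick_parent(cum, s0, cnt, r1)
                p1 = idx[s0 + j1]
                p2 = p1
                if cnt > 1:
                    for _try in range(32):
                        r2 = _uniform(s) * tot
                        j2 = _pick_parent(cum, s0, cnt, r2)
                        if j2 != j1:
                            p2 = idx[s0 + j2]
                            break
                for w in range(nw):
                    m1 = _next64(s)
                    m2 = _next64(s)
                    new1[ci, w] = (cur1[p1, w] & m1) | (cur2[p1, w] & ~m1)
                    new2[ci, w] = (cur1[p2, w] & m2) | (cur2[p2, w] & ~m2)
                if mu > 0.0:
                    for w in range(nw):
                        lo = w * 64
                        span = min(64, n_loci - lo)
                        m = _U1
                        for _b in range(span):
                            if _uniform(s) < mu:
                                new1[ci, w] = new1[ci, w] ^ m
                            if _uniform(s) < mu:
                                new2[ci, w] = new2[ci, w] ^ m
                            m = m << _U1
                newd[ci] = d  # offspring are born in the mating deme
                ci += 1

        tmp1, tmp2, tmpd = cur1, cur2, curd
        cur1, cur2, curd = new1, new2, newd
        new1, new2, newd = tmp1, tmp2, tmpd

        if rec_ptr < rec_gens.shape[0] and gen == rec_gens[rec_ptr]:
            _record(traj[rec_ptr], cur1, cur2, curd, n_loci)
            rec_ptr += 1

    for i in range(n):
        out_deme[i] = curd[i]
        for w in range(nw):
            out_a1[i, w] = cur1[i, w]
            out_a2[i, w] = cur2[i, w]
    return -1, -1
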