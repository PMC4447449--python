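"""Bit-packed evaluation kernels for the simulator harness.

Scoring every ledgered variant at every evaluation generation requires, per
variant, the per-site allele counts within each haplotype class over a
±radius window.  Representing each site's carrier set as a bitmask makes
that an AND + popcount per (site, word): the class mask of a focal variant
*is* the packed focal column, so class counts at window site w are
``popcount(bits[w] & bits[focal])`` and its complement against the site
total.  The numba kernel below evaluates both θ estimators for all
candidates of a generation in one pass; a pure-numpy equivalent is kept as
a fallback and as an independent check.
"""
from __future__ import annotations

import math

import numpy as np

from .theta import folded_moments_from_counts

try:  # pragma: no cover - exercised implicitly everywhere
    import numba
    from llvmlite import ir
    from numba import njit, types
    from numba.extending import intrinsic

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

# outcome codes shared with simulate.py (kept literal for numba)
_CORRECT, _WRONG, _TIE, _FILTERED, _UNDEFINED = 0, 1, 2, 3, 4


def pack_columns(H: np.ndarray) -> np.ndarray:
    """Pack a (n_hap, L) 0/1 matrix into per-site bitmasks (L, n_words).

    Padded to a multiple of four 64-bit words so populations of up to 256
    haplotypes hit the unrolled kernel path.
    """
    P8 = np.packbits(np.ascontiguousarray(H.T), axis=1)  # (L, ceil(n/8))
    pad = (-P8.shape[1]) % 32
    if pad:
        P8 = np.hstack([P8, np.zeros((P8.shape[0], pad), dtype=np.uint8)])
    return np.ascontiguousarray(P8).view(np.uint64)


if HAVE_NUMBA:

    @intrinsic
    def _popcnt64(typingctx, x):
        sig = types.uint64(types.uint64)

        def codegen(context, builder, signature, args):
            fn = builder.module.declare_intrinsic("llvm.ctpop", [ir.IntType(64)])
            return builder.call(fn, [args[0]])

        return sig, codegen

    @njit(cache=True)
    def _eval_kernel(P64, S, cand, derived, two_n, radius, min2):  # pragma: no cover
        L, nw = P64.shape
        k = cand.size
        t1a = np.empty(k, dtype=np.float32)
        t1d = np.empty(k, dtype=np.float32)
        t2a = np.full(k, np.nan, dtype=np.float32)
        t2d = np.full(k, np.nan, dtype=np.float32)
        o1 = np.empty(k, dtype=np.int8)
        o2 = np.empty(k, dtype=np.int8)
        ndc = np.empty(k, dtype=np.int32)
        half = two_n // 2 + 1
        b1 = np.empty(half, dtype=np.int64)
        b0 = np.empty(half, dtype=np.int64)
        cbuf = np.empty(2 * radius + 1, dtype=np.int64)
        unroll4 = nw == 4
        for j in range(k):
            site = cand[j]
            lo = site - radius
            if lo < 0:
                lo = 0
            hi = site + radius + 1
            if hi > L:
                hi = L
            s1 = S[site]
            s0 = two_n - s1
            h1 = s1 // 2
            h0 = s0 // 2
            for i in range(h1 + 1):
                b1[i] = 0
            for i in range(h0 + 1):
                b0[i] = 0
            # pass 1: class-1 counts per window site (vectorizable popcounts)
            nwin = hi - lo
            if unroll4:
                m0 = P64[site, 0]
                m1 = P64[site, 1]
                m2 = P64[site, 2]
                m3 = P64[site, 3]
                for i in range(nwin):
                    ws = lo + i
                    cbuf[i] = (
                        _popcnt64(P64[ws, 0] & m0)
                        + _popcnt64(P64[ws, 1] & m1)
                        + _popcnt64(P64[ws, 2] & m2)
                        + _popcnt64(P64[ws, 3] & m3)
                    )
            else:
                for i in range(nwin):
                    ws = lo + i
                    c = np.uint64(0)
                    for b in range(nw):
                        c += _popcnt64(P64[ws, b] & P64[site, b])
                    cbuf[i] = np.int64(c)
            # pass 2: scalar window statistics, skipping the focal site
            poly1 = 0
            poly0 = 0
            w = nwin - 1
            focal = site - lo
            for i in range(nwin):
                if i == focal:
                    continue
                c1 = cbuf[i]
                c0 = S[lo + i] - c1
                if 0 < c1 < s1:
                    poly1 += 1
                if 0 < c0 < s0:
                    poly0 += 1
                k1 = c1 if c1 <= s1 - c1 else s1 - c1
                k0 = c0 if c0 <= s0 - c0 else s0 - c0
                b1[k1] += 1
                b0[k0] += 1
            # theta1 per class
            if poly1 == 0:
                v1 = 0.0
            elif poly1 == w:
                v1 = np.inf
            else:
                v1 = math.log1p(-poly1 / w) / math.log(1.0 / s1)
            if poly0 == 0:
                v0 = 0.0
            elif poly0 == w:
                v0 = np.inf
            else:
                v0 = math.log1p(-poly0 / w) / math.log(1.0 / s0)
            d = derived[j]
            ndc[j] = s1 if d == 1 else s0
            ta = v0 if d == 1 else v1
            td = v1 if d == 1 else v0
            t1a[j] = ta
            t1d[j] = td
            if ta > td:
                o1[j] = _CORRECT
            elif ta < td:
                o1[j] = _WRONG
            else:
                o1[j] = _TIE
            # theta2 per class (allele-count filter: both classes > min2-1)
            if min(s1, s0) >= min2:
                m1 = 0.0
                q1 = 0.0
                r = 0
                for i in range(h1 + 1):
                    c = b1[i]
                    if c > 0:
                        nodd = (c + (r & 1)) // 2
                        neven = c - nodd
                        val = i / s1
                        m1 += neven * val + nodd * (1.0 - val)
                        q1 += neven * val * val + nodd * (1.0 - val) * (1.0 - val)
                        r += c
                m1 /= w
                var1 = q1 / w - m1 * m1
                m0 = 0.0
                q0 = 0.0
                r = 0
                for i in range(h0 + 1):
                    c = b0[i]
                    if c > 0:
                        nodd = (c + (r & 1)) // 2
                        neven = c - nodd
                        val = i / s0
                        m0 += neven * val + nodd * (1.0 - val)
                        q0 += neven * val * val + nodd * (1.0 - val) * (1.0 - val)
                        r += c
                m0 /= w
                var0 = q0 / w - m0 * m0
                if var1 <= 0.0 or var0 <= 0.0:
                    o2[j] = _UNDEFINED
                else:
                    w1 = 0.5 * (m1 * (1.0 - m1) / var1 - 1.0)
                    w0 = 0.5 * (m0 * (1.0 - m0) / var0 - 1.0)
                    if w1 < 0.0:
                        w1 = 0.0
                    if w0 < 0.0:
                        w0 = 0.0
                    ta2 = w0 if d == 1 else w1
                    td2 = w1 if d == 1 else w0
                    t2a[j] = ta2
                    t2d[j] = td2
                    if ta2 > td2:
                        o2[j] = _CORRECT
                    elif ta2 < td2:
                        o2[j] = _WRONG
                    else:
                        o2[j] = _TIE
            else:
                o2[j] = _FILTERED
        return t1a, t1d, t2a, t2d, o1, o2, ndc


def _theta1_value(counts: np.ndarray, n: int) -> float:
    w = counts.size
    poly = int(np.count_nonzero((counts > 0) & (counts < n)))
    if poly == 0:
        return 0.0
    if poly == w:
        return math.inf
    return math.log1p(-poly / w) / math.log(1.0 / n)


def eval_candidates_numpy(H, S, cand, derived, radius, min2):
    """Pure-numpy evaluation of candidate variants (fallback/oracle path)."""
    two_n, L = H.shape
    k = len(cand)
    t1a = np.empty(k, np.float32)
    t1d = np.empty(k, np.float32)
    t2a = np.full(k, np.nan, np.float32)
    t2d = np.full(k, np.nan, np.float32)
    o1 = np.empty(k, np.int8)
    o2 = np.empty(k, np.int8)
    ndc = np.empty(k, np.int32)
    for j, site in enumerate(cand):
        lo = max(site - radius, 0)
        hi = min(site + radius + 1, L)
        s1 = int(S[site])
        s0 = two_n - s1
        col = H[:, site]
        Hw = H[:, lo:hi]
        swin = S[lo:hi]
        if s1 <= s0:
            cnt1 = np.count_nonzero(Hw[col == 1], axis=0).astype(np.int64)
            cnt0 = swin - cnt1
        else:
            cnt0 = np.count_nonzero(Hw[col == 0], axis=0).astype(np.int64)
            cnt1 = swin - cnt0
        f = site - lo
        cnt1 = np.delete(cnt1, f)
        cnt0 = np.delete(cnt0, f)
        d = int(derived[j])
        if d == 1:
            cnt_d, n_d, cnt_a, n_a = cnt1, s1, cnt0, s0
        else:
            cnt_d, n_d, cnt_a, n_a = cnt0, s0, cnt1, s1
        ndc[j] = n_d
        ta = _theta1_value(cnt_a, n_a)
        td = _theta1_value(cnt_d, n_d)
        t1a[j], t1d[j] = ta, td
        o1[j] = _CORRECT if ta > td else (_WRONG if ta < td else _TIE)
        if min(n_d, n_a) >= min2:
            m_a, v_a = folded_moments_from_counts(cnt_a, n_a)
            m_d, v_d = folded_moments_from_counts(cnt_d, n_d)
            if v_a <= 0.0 or v_d <= 0.0:
                o2[j] = _UNDEFINED
            else:
                wa = max(0.5 * (m_a * (1.0 - m_a) / v_a - 1.0), 0.0)
                wd = max(0.5 * (m_d * (1.0 - m_d) / v_d - 1.0), 0.0)
                t2a[j], t2d[j] = wa, wd
                o2[j] = _CORRECT if wa > wd else (_WRONG if wa < wd else _TIE)
        else:
            o2[j] = _FILTERED
    return t1a, t1d, t2a, t2d, o1, o2, ndc


def eval_candidates(H, P64, S, cand, derived, radius, min2, use_numba=None):
    """Evaluate all candidate variants of one generation; returns arrays
    (theta1_anc, theta1_der, theta2_anc, theta2_der, outcome1, outcome2,
    derived_count)."""
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba and HAVE_NUMBA:
        return _eval_kernel(
            P64,
            S.astype(np.int64, copy=False),
            np.asarray(cand, dtype=np.int64),
            np.asarray(derived, dtype=np.int8),
            np.int64(H.shape[0]),
            np.int64(radius),
            np.int64(min2),
        )
    return eval_candidates_numpy(H, S, cand, derived, radius, min2)
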