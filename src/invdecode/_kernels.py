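"""Fused single-pass kernels for the hot inner loops of network training.

The ensemble trainer is memory-bandwidth bound: its large tensors are the
(N*R*T, S*K) temporal-convolution activations.  These numba kernels fuse
reductions and affine maps into single passes over those arrays.  Each has
a NumPy fallback with identical semantics (used if numba is unavailable),
and the trainer is tested against the plain reference implementation.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=True, fastmath=True)
def _col_mean_sq(h):  # (n, c) float32 -> mean, mean-square per column
    n, c = h.shape
    s = np.zeros(c, np.float64)
    q = np.zeros(c, np.float64)
    for i in range(n):
        for j in range(c):
            v = np.float64(h[i, j])
            s[j] += v
            q[j] += v * v
    return s / n, q / n


@njit(cache=True, fastmath=True)
def _affine(h, a, c):  # z = h * a + c, per column
    n, m = h.shape
    z = np.empty_like(h)
    for i in range(n):
        for j in range(m):
            z[i, j] = h[i, j] * a[j] + c[j]
    return z


@njit(cache=True, fastmath=True)
def _paired_col_sums(d, h):  # sum(d), sum(d*h) per column
    n, c = d.shape
    s = np.zeros(c, np.float64)
    sh = np.zeros(c, np.float64)
    for i in range(n):
        for j in range(c):
            dv = np.float64(d[i, j])
            s[j] += dv
            sh[j] += dv * np.float64(h[i, j])
    return s, sh


@njit(cache=True, fastmath=True)
def _affine2(d, h, A, B, C):  # out = d*A + h*B + C, per column
    n, m = d.shape
    out = np.empty_like(d)
    for i in range(n):
        for j in range(m):
            out[i, j] = d[i, j] * A[j] + h[i, j] * B[j] + C[j]
    return out


@njit(cache=True, fastmath=True)
def _spatial_fwd(z1v, Wst):
    # z1v: (N, R, T, Q) f32; Wst: (R, Q, M) -> out (N, T, Q, M)
    # channel-last layout: the (T, Q, M) accumulator of one sample fits in L1
    N, R, T, Q = z1v.shape
    M = Wst.shape[2]
    out = np.zeros((N, T, Q, M), np.float32)
    for n in range(N):
        for r in range(R):
            for t in range(T):
                for q in range(Q):
                    v = z1v[n, r, t, q]
                    for m in range(M):
                        out[n, t, q, m] += Wst[r, q, m] * v
    return out


@njit(cache=True, fastmath=True)
def _spatial_bwd(ds2t, z1v, Wst):
    # ds2t: (N, T, Q, M), z1v: (N, R, T, Q), Wst: (R, Q, M)
    # returns dWst (R, Q, M) f64 and dz1 (N, R, T, Q) f32
    N, R, T, Q = z1v.shape
    M = Wst.shape[2]
    dWst = np.zeros((R, Q, M), np.float64)
    dz1 = np.empty((N, R, T, Q), np.float32)
    for n in range(N):
        for r in range(R):
            for t in range(T):
                for q in range(Q):
                    z = np.float64(z1v[n, r, t, q])
                    acc = np.float32(0.0)
                    for m in range(M):
                        d = ds2t[n, t, q, m]
                        dWst[r, q, m] += np.float64(d) * z
                        acc += d * Wst[r, q, m]
                    dz1[n, r, t, q] = acc
    return dWst, dz1


@njit(cache=True, fastmath=True)
def _max_cluster_mass_rows(T, thr):
    # per row: largest |sum of t| over contiguous same-sign supra-threshold runs
    P, n = T.shape
    out = np.zeros(P)
    for p in range(P):
        best = 0.0
        cur_p = 0.0
        cur_n = 0.0
        for j in range(n):
            v = T[p, j]
            if v > thr:
                cur_p += v
            else:
                if cur_p > best:
                    best = cur_p
                cur_p = 0.0
            if v < -thr:
                cur_n -= v
            else:
                if cur_n > best:
                    best = cur_n
                cur_n = 0.0
        if cur_p > best:
            best = cur_p
        if cur_n > best:
            best = cur_n
        out[p] = best
    return out


# -- NumPy fallbacks ---------------------------------------------------------


def col_mean_sq(h):
    if HAVE_NUMBA:
        return _col_mean_sq(h)
    m = h.mean(axis=0, dtype=np.float64)
    q = np.einsum("ij,ij->j", h, h, dtype=np.float64) / h.shape[0]
    return m, q


def affine(h, a, c):
    if HAVE_NUMBA:
        return _affine(h, a.astype(h.dtype), c.astype(h.dtype))
    return h * a + c


def paired_col_sums(d, h):
    if HAVE_NUMBA:
        return _paired_col_sums(d, h)
    return d.sum(axis=0, dtype=np.float64), np.einsum("ij,ij->j", d, h, dtype=np.float64)


def affine2(d, h, A, B, C):
    if HAVE_NUMBA:
        return _affine2(d, h, A.astype(d.dtype), B.astype(d.dtype), C.astype(d.dtype))
    out = d * A
    out += h * B
    out += C
    return out


def max_cluster_mass_rows(T, thr):
    """Row-wise maximum cluster mass of 1-D t-value maps (see cluster tests)."""
    T = np.ascontiguousarray(T, dtype=np.float64)
    if HAVE_NUMBA:
        return _max_cluster_mass_rows(T, float(thr))
    out = np.zeros(T.shape[0])
    for p in range(T.shape[0]):
        best = 0.0
        for sign in (1.0, -1.0):
            mask = sign * T[p] > thr
            cur = 0.0
            for v, m in zip(sign * T[p], mask):
                if m:
                    cur += v
                    best = max(best, cur)
                else:
                    cur = 0.0
        out[p] = best
    return out


def spatial_fwd(z1r, Ws):
    """s2[n,s,k,m,t] = sum_r z1r[n,r,t,s,k] * Ws[s,k,m,r]."""
    if HAVE_NUMBA:
        N, R, T, S, K = z1r.shape
        M = Ws.shape[2]
        Wst = np.ascontiguousarray(Ws.transpose(3, 0, 1, 2).reshape(R, S * K, M))
        out = _spatial_fwd(z1r.reshape(N, R, T, S * K), Wst)  # (N, T, Q, M)
        return np.ascontiguousarray(
            out.reshape(N, T, S, K, M).transpose(0, 2, 3, 4, 1)
        )
    return np.einsum("nrtsk,skmr->nskmt", z1r, Ws, optimize=True)


def spatial_bwd(ds2r, z1r, Ws):
    """Gradients of the depthwise spatial contraction.

    dWs[s,k,m,r] = sum_{n,t} ds2r[n,s,k,m,t] * z1r[n,r,t,s,k]
    dz1[n,r,t,s,k] = sum_m  ds2r[n,s,k,m,t] * Ws[s,k,m,r]
    """
    N, R, T, S, K = z1r.shape
    M = Ws.shape[2]
    if HAVE_NUMBA:
        Wst = np.ascontiguousarray(Ws.transpose(3, 0, 1, 2).reshape(R, S * K, M))
        ds2t = np.ascontiguousarray(
            ds2r.transpose(0, 4, 1, 2, 3).reshape(N, T, S * K, M)
        )
        dWst, dz1 = _spatial_bwd(ds2t, z1r.reshape(N, R, T, S * K), Wst)
        dWs = dWst.reshape(R, S, K, M).transpose(1, 2, 3, 0)
        return dWs, dz1.reshape(N, R, T, S, K)
    dWs = np.einsum("nskmt,nrtsk->skmr", ds2r, z1r, optimize=True)
    dz1 = np.empty(z1r.shape, dtype=z1r.dtype)
    np.einsum("nskmt,skmr->nrtsk", ds2r, Ws, optimize=True, out=dz1)
    return dWs, dz1
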