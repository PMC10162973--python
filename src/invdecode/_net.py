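"""Minimal NumPy engine for the compact orientation-decoding CNN.

The network is small (about 1.5k parameters), so a hand-rolled engine is
both fast enough on one CPU and transparent enough to support exact
layer-wise relevance propagation.  Layer stack:

    temporal conv (K kernels, 1 x L, same padding, no bias)
    -> batch norm -> depthwise spatial conv (R x 1 per input channel,
    depth multiplier M, no bias) -> batch norm -> ReLU
    -> average pooling (factor P over time) -> dropout
    -> dense (n_out units, bias) -> softmax

Convolutions are evaluated as matmuls over sliding windows (BLAS-backed).
The backward pass is standard reverse-mode; gradients are verified against
finite differences in the test suite.  :meth:`CompactCNN.lrp` implements
the epsilon-rule backward relevance pass with batch-norm parameters folded
into the adjacent convolution's effective weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BN_EPS = 1e-5


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int,
            dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class CompactCNN:
    """The compact CNN f(X; theta) mapping a (R, T) trial to class scores."""

    def __init__(
        self,
        n_rois: int = 68,
        n_times: int = 100,
        n_temporal: int = 4,
        kernel_len: int = 33,
        multiplier: int = 2,
        pool: int = 2,
        dropout_p: float = 0.25,
        n_out: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        if kernel_len % 2 != 1:
            raise ValueError("temporal kernel length must be odd for same padding")
        if n_times % pool != 0:
            raise ValueError(f"pool factor {pool} must divide T={n_times}")
        self.R, self.T = n_rois, n_times
        self.K, self.L, self.M, self.P = n_temporal, kernel_len, multiplier, pool
        self.C = self.K * self.M
        self.F = self.C * (self.T // self.P)
        self.p_drop = dropout_p
        self.n_out = n_out
        self.dtype = dtype

        rng = np.random.default_rng(seed)
        self.Wt = _glorot(rng, (self.K, self.L), self.L, self.K, dtype)
        self.g1 = np.ones(self.K, dtype)
        self.b1 = np.zeros(self.K, dtype)
        self.Ws = _glorot(rng, (self.K, self.M, self.R), self.R, self.M, dtype)
        self.g2 = np.ones(self.C, dtype)
        self.b2 = np.zeros(self.C, dtype)
        self.Wd = _glorot(rng, (n_out, self.F), self.F, n_out, dtype)
        self.bd = np.zeros(n_out, dtype)
        # batch-norm running statistics (eval mode)
        self.rm1 = np.zeros(self.K, dtype)
        self.rv1 = np.ones(self.K, dtype)
        self.rm2 = np.zeros(self.C, dtype)
        self.rv2 = np.ones(self.C, dtype)
        self.bn_momentum = 0.1
        self._cache: dict | None = None

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [self.Wt, self.g1, self.b1, self.Ws, self.g2, self.b2, self.Wd, self.bd]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        for own, new in zip(self.parameters(), params):
            own[...] = new

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def state(self) -> dict[str, np.ndarray]:
        names = ["Wt", "g1", "b1", "Ws", "g2", "b2", "Wd", "bd", "rm1", "rv1", "rm2", "rv2"]
        return {n: getattr(self, n).copy() for n in names}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for n, v in state.items():
            getattr(self, n)[...] = v

    def count_parameters(self) -> int:
        """Number of learnable scalars (conv weights, BN scale/shift, dense)."""
        return int(sum(p.size for p in self.parameters()))

    # -- forward --------------------------------------------------------------

    def _windows(self, x: np.ndarray) -> np.ndarray:
        pad = self.L // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        return sliding_window_view(xpad, self.L, axis=-1)  # (N, R, T, L)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class scores o_k for a batch x of shape (N, R, T)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        N = x.shape[0]
        xw = self._windows(x)
        h1 = xw @ self.Wt.T  # (N, R, T, K)

        if training:
            m1 = h1.mean(axis=(0, 1, 2))
            v1 = h1.var(axis=(0, 1, 2))
            self.rm1 += self.bn_momentum * (m1 - self.rm1)
            self.rv1 += self.bn_momentum * (v1 - self.rv1)
        else:
            m1, v1 = self.rm1, self.rv1
        i1 = 1.0 / np.sqrt(v1 + _BN_EPS)
        h1n = (h1 - m1) * i1
        z1 = self.g1 * h1n + self.b1

        s2 = np.einsum("nrtk,kmr->nkmt", z1, self.Ws, optimize=True).reshape(N, self.C, self.T)
        if training:
            m2 = s2.mean(axis=(0, 2))
            v2 = s2.var(axis=(0, 2))
            self.rm2 += self.bn_momentum * (m2 - self.rm2)
            self.rv2 += self.bn_momentum * (v2 - self.rv2)
        else:
            m2, v2 = self.rm2, self.rv2
        i2 = 1.0 / np.sqrt(v2 + _BN_EPS)
        s2n = (s2 - m2[:, None]) * i2[:, None]
        z2 = self.g2[:, None] * s2n + self.b2[:, None]

        h3 = np.maximum(z2, 0.0)
        h4 = h3.reshape(N, self.C, self.T // self.P, self.P).mean(axis=-1)

        if training and self.p_drop > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            keep = (rng.random(h4.shape) >= self.p_drop).astype(self.dtype)
            h5 = h4 * keep / (1.0 - self.p_drop)
        else:
            keep = None
            h5 = h4
        flat = h5.reshape(N, self.F)
        o = flat @ self.Wd.T + self.bd

        self._cache = dict(xw=xw, h1n=h1n, i1=i1, z1=z1, s2n=s2n, i2=i2, z2=z2,
                           h3=h3, keep=keep, flat=flat, training=training)
        return o

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    # -- backward -------------------------------------------------------------

    def backward(self, do: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. parameters given dL/do; same order as parameters()."""
        c = self._cache
        if c is None or not c["training"]:
            raise RuntimeError("backward requires a preceding training-mode forward")
        N = do.shape[0]
        do = do.astype(self.dtype)

        dWd = do.T @ c["flat"]
        dbd = do.sum(axis=0)
        dflat = do @ self.Wd
        dh5 = dflat.reshape(N, self.C, self.T // self.P)
        if c["keep"] is not None:
            dh4 = dh5 * c["keep"] / (1.0 - self.p_drop)
        else:
            dh4 = dh5
        dh3 = np.repeat(dh4 / self.P, self.P, axis=-1)
        dz2 = dh3 * (c["z2"] > 0)

        # batch norm 2 (normalized over batch and time)
        s2n = c["s2n"]
        dg2 = (dz2 * s2n).sum(axis=(0, 2))
        db2 = dz2.sum(axis=(0, 2))
        dn = dz2 * self.g2[:, None]
        mean_dn = dn.mean(axis=(0, 2), keepdims=True)
        mean_dn_x = (dn * s2n).mean(axis=(0, 2), keepdims=True)
        ds2 = c["i2"][:, None] * (dn - mean_dn - s2n * mean_dn_x)

        ds2r = ds2.reshape(N, self.K, self.M, self.T)
        dWs = np.einsum("nkmt,nrtk->kmr", ds2r, c["z1"], optimize=True)
        dz1 = np.einsum("nkmt,kmr->nrtk", ds2r, self.Ws, optimize=True)

        # batch norm 1 (normalized over batch, ROI and time)
        h1n = c["h1n"]
        dg1 = (dz1 * h1n).sum(axis=(0, 1, 2))
        db1 = dz1.sum(axis=(0, 1, 2))
        dn1 = dz1 * self.g1
        mean_dn1 = dn1.mean(axis=(0, 1, 2), keepdims=True)
        mean_dn1_x = (dn1 * h1n).mean(axis=(0, 1, 2), keepdims=True)
        dh1 = c["i1"] * (dn1 - mean_dn1 - h1n * mean_dn1_x)

        xw2 = c["xw"].reshape(-1, self.L)
        dh1_2 = dh1.reshape(-1, self.K)
        dWt = dh1_2.T @ xw2

        return [dWt, dg1, db1, dWs, dg2, db2, dWd, dbd]

    # -- layer-wise relevance propagation ------------------------------------

    def lrp(self, x: np.ndarray, epsilon: float = 1e-6, target: int = 1) -> np.ndarray:
        """Epsilon-rule relevance of each input sample for the target class score.

        Propagates the pre-softmax score o_target backward to the input.
        Batch-norm (eval-mode affine) is folded into the adjacent
        convolution's effective weights.  Each layer's bias/shift term is
        redistributed uniformly over that layer's inputs, so the
        decomposition conserves the propagated score up to the epsilon
        stabilizer and convolution edge effects.  Returns a signed
        (N, R, T) map.
        """
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        x = np.ascontiguousarray(x, dtype=np.float64)
        N = x.shape[0]
        xw = self._windows(x)

        a1 = np.asarray(self.g1, np.float64) / np.sqrt(np.asarray(self.rv1, np.float64) + _BN_EPS)
        c1 = np.asarray(self.b1, np.float64) - a1 * np.asarray(self.rm1, np.float64)
        a2 = np.asarray(self.g2, np.float64) / np.sqrt(np.asarray(self.rv2, np.float64) + _BN_EPS)
        c2 = np.asarray(self.b2, np.float64) - a2 * np.asarray(self.rm2, np.float64)
        Wt_eff = a1[:, None] * np.asarray(self.Wt, np.float64)  # (K, L)
        Ws64 = np.asarray(self.Ws, np.float64)
        Ws_eff = a2.reshape(self.K, self.M)[:, :, None] * Ws64  # (K, M, R)

        # eval-mode forward with folded BN
        z1 = xw @ Wt_eff.T + c1  # (N, R, T, K)
        z2 = (np.einsum("nrtk,kmr->nkmt", z1, Ws_eff, optimize=True)
              .reshape(N, self.C, self.T) + c2[:, None])
        h3 = np.maximum(z2, 0.0)
        h4 = h3.reshape(N, self.C, self.T // self.P, self.P).mean(axis=-1)
        flat = h4.reshape(N, self.F)
        Wd64 = np.asarray(self.Wd, np.float64)
        o = flat @ Wd64.T + np.asarray(self.bd, np.float64)

        def stab(z):
            return z + epsilon * np.where(z >= 0, 1.0, -1.0)

        # dense layer (bias share spread over the F inputs)
        R_o = np.zeros_like(o)
        R_o[:, target] = o[:, target]
        s = R_o / stab(o)
        bd64 = np.asarray(self.bd, np.float64)
        R_flat = flat * (s @ Wd64) + (s * bd64).sum(axis=1, keepdims=True) / self.F
        R_h4 = R_flat.reshape(N, self.C, self.T // self.P)

        # average pooling: linear layer with weights 1/P
        s = R_h4 / stab(h4)
        R_h3 = (h3 / self.P) * np.repeat(s, self.P, axis=-1)

        # ReLU: identity on relevance (non-positive units carry none)
        R_z2 = R_h3

        # spatial depthwise conv (+ folded BN); BN shift spread over the R ROIs
        s = (R_z2 / stab(z2)).reshape(N, self.K, self.M, self.T)
        R_z1 = z1 * np.einsum("nkmt,kmr->nrtk", s, Ws_eff, optimize=True)
        c2r = c2.reshape(self.K, self.M)
        R_z1 += np.einsum("nkmt,km->ntk", s, c2r / self.R, optimize=True)[:, None]

        # temporal conv (+ folded BN); BN shift spread over the L window taps
        s1 = R_z1 / stab(z1)  # (N, R, T, K)
        pad = self.L // 2
        s1pad = np.pad(s1, ((0, 0), (0, 0), (pad, pad), (0, 0)))
        sw = sliding_window_view(s1pad, self.L, axis=2)  # (N, R, T, K, L)
        R_x = x * np.einsum("nrtkl,kl->nrt", sw, Wt_eff[:, ::-1], optimize=True)
        R_x += np.einsum("nrtkl,kl->nrt", sw,
                         np.tile(c1[:, None] / self.L, (1, self.L)), optimize=True)
        return R_x


def softmax(o: np.ndarray) -> np.ndarray:
    e = np.exp(o - o.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(o: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the class scores."""
    p = softmax(np.asarray(o, dtype=np.float64))
    n = o.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dp = p
    dp[np.arange(n), y] -= 1.0
    return loss, (dp / n).astype(o.dtype)


class Adam:
    """Adaptive-moment gradient descent over a parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)
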