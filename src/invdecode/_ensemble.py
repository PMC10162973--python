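"""Lockstep multi-seed training of the compact CNN.

The cross-validation protocol trains the same architecture on the same fold
data under several random initializations.  Those runs share every
data-dependent quantity (mini-batch sequence, validation split), so they
are vectorized here across a seed axis S: weights get shape (S, ...) and
the heavy temporal-convolution work -- the only large tensors in this
network -- is amortized across seeds through single BLAS calls.  Seeds
remain statistically independent: initialization and dropout masks are
drawn per seed; early stopping is tracked per seed.

``fit_ensemble`` with a single seed is the reference single-model training
path; ``EnsembleCNN.extract`` yields an eval-ready :class:`CompactCNN` per
seed for evaluation and relevance propagation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._kernels import affine, affine2, col_mean_sq, paired_col_sums, spatial_bwd, spatial_fwd
from ._net import _BN_EPS, CompactCNN, _glorot, softmax


def make_windows(X: np.ndarray, kernel_len: int, dtype=np.float32) -> np.ndarray:
    """Precompute contiguous sliding windows (M, R, T, L) for a trial stack."""
    pad = kernel_len // 2
    Xp = np.pad(np.asarray(X, dtype=dtype), ((0, 0), (0, 0), (pad, pad)))
    return np.ascontiguousarray(sliding_window_view(Xp, kernel_len, axis=-1))


class EnsembleCNN:
    """S independent CompactCNNs trained in lockstep on shared data."""

    def __init__(self, seeds: list[int], n_rois: int = 68, n_times: int = 100,
                 n_temporal: int = 4, kernel_len: int = 33, multiplier: int = 2,
                 pool: int = 2, dropout_p: float = 0.25, n_out: int = 2,
                 dtype=np.float32):
        self.seeds = list(seeds)
        S = len(self.seeds)
        if S < 1:
            raise ValueError("need at least one seed")
        self.S = S
        self.R, self.T = n_rois, n_times
        self.K, self.L, self.M, self.P = n_temporal, kernel_len, multiplier, pool
        self.C = self.K * self.M
        self.F = self.C * (self.T // self.P)
        self.p_drop = dropout_p
        self.n_out = n_out
        self.dtype = dtype

        # Per-seed initialization identical to CompactCNN(seed) draw order.
        Wt, Ws, Wd = [], [], []
        for seed in self.seeds:
            rng = np.random.default_rng(seed)
            Wt.append(_glorot(rng, (self.K, self.L), self.L, self.K, dtype))
            Ws.append(_glorot(rng, (self.K, self.M, self.R), self.R, self.M, dtype))
            Wd.append(_glorot(rng, (n_out, self.F), self.F, n_out, dtype))
        self.Wt = np.stack(Wt)          # (S, K, L)
        self.Ws = np.stack(Ws)          # (S, K, M, R)
        self.Wd = np.stack(Wd)          # (S, n_out, F)
        self.g1 = np.ones((S, self.K), dtype)
        self.b1 = np.zeros((S, self.K), dtype)
        self.g2 = np.ones((S, self.C), dtype)
        self.b2 = np.zeros((S, self.C), dtype)
        self.bd = np.zeros((S, n_out), dtype)
        self.rm1 = np.zeros((S, self.K), dtype)
        self.rv1 = np.ones((S, self.K), dtype)
        self.rm2 = np.zeros((S, self.C), dtype)
        self.rv2 = np.ones((S, self.C), dtype)
        self.bn_momentum = 0.1

    def parameters(self) -> list[np.ndarray]:
        return [self.Wt, self.g1, self.b1, self.Ws, self.g2, self.b2, self.Wd, self.bd]

    # -- forward / backward ---------------------------------------------------

    def forward(self, xw: np.ndarray, training: bool = False,
                drop_rngs: list[np.random.Generator] | None = None) -> np.ndarray:
        """Class scores (N, S, n_out) from precomputed windows (N, R, T, L)."""
        N = xw.shape[0]
        S, K, C, T, P = self.S, self.K, self.C, self.T, self.P
        xw2 = xw.reshape(-1, self.L)  # (NRT, L)
        WtT = np.ascontiguousarray(self.Wt.reshape(S * K, self.L).T)
        h1 = xw2 @ WtT  # (NRT, S*K)
        n_red = h1.shape[0]

        if training:
            m1, q1 = col_mean_sq(h1)
            v1 = np.maximum(q1 - m1 * m1, 0.0)
            self.rm1 += self.bn_momentum * (m1.reshape(S, K) - self.rm1).astype(self.dtype)
            self.rv1 += self.bn_momentum * (v1.reshape(S, K) - self.rv1).astype(self.dtype)
        else:
            m1 = self.rm1.reshape(-1).astype(np.float64)
            v1 = self.rv1.reshape(-1).astype(np.float64)
        i1 = 1.0 / np.sqrt(v1 + _BN_EPS)
        a1 = self.g1.reshape(-1) * i1
        c1 = self.b1.reshape(-1) - m1 * a1
        z1 = affine(h1, a1.astype(self.dtype), c1.astype(self.dtype))  # (NRT, S*K)

        z1r = z1.reshape(N, self.R, T, S, K)
        s2 = spatial_fwd(z1r, self.Ws).reshape(N, S, C, T)

        if training:
            m2 = s2.mean(axis=(0, 3))
            v2 = s2.var(axis=(0, 3))
            self.rm2 += self.bn_momentum * (m2 - self.rm2)
            self.rv2 += self.bn_momentum * (v2 - self.rv2)
        else:
            m2, v2 = self.rm2, self.rv2
        i2 = 1.0 / np.sqrt(v2 + _BN_EPS)
        a2 = self.g2 * i2
        z2 = s2 * a2[None, :, :, None] + (self.b2 - m2 * a2)[None, :, :, None]

        h3 = np.maximum(z2, 0.0)
        h4 = h3.reshape(N, S, C, T // P, P).mean(axis=-1)
        if training and self.p_drop > 0:
            if drop_rngs is None:
                raise ValueError("training forward needs per-seed dropout rngs")
            keep = np.stack(
                [(rng.random((N, C, T // P)) >= self.p_drop) for rng in drop_rngs], axis=1
            ).astype(self.dtype)
            h5 = h4 * keep / (1.0 - self.p_drop)
        else:
            keep = None
            h5 = h4
        flat = h5.reshape(N, S, self.F)
        o = np.einsum("nsf,sof->nso", flat, self.Wd, optimize=True) + self.bd

        self._cache = dict(xw2=xw2, h1=h1, m1=m1, i1=i1, a1=a1, z1r=z1r, s2=s2,
                           m2=m2, i2=i2, z2=z2, h3=h3, keep=keep, flat=flat,
                           training=training)
        return o

    def backward(self, do: np.ndarray) -> list[np.ndarray]:
        c = self._cache
        N = do.shape[0]
        S, K, C, T, P = self.S, self.K, self.C, self.T, self.P
        do = do.astype(self.dtype)

        dWd = np.einsum("nso,nsf->sof", do, c["flat"], optimize=True)
        dbd = do.sum(axis=0)
        dflat = np.einsum("nso,sof->nsf", do, self.Wd, optimize=True)
        dh5 = dflat.reshape(N, S, C, T // P)
        dh4 = dh5 if c["keep"] is None else dh5 * c["keep"] / (1.0 - self.p_drop)
        dh3 = np.repeat(dh4 / P, P, axis=-1)
        dz2 = dh3 * (c["z2"] > 0)

        s2n = (c["s2"] - c["m2"][None, :, :, None]) * c["i2"][None, :, :, None]
        dg2 = (dz2 * s2n).sum(axis=(0, 3))
        db2 = dz2.sum(axis=(0, 3))
        dn = dz2 * self.g2[None, :, :, None]
        n_red2 = N * T
        mean_dn = dn.sum(axis=(0, 3)) / n_red2
        mean_dn_x = (dn * s2n).sum(axis=(0, 3)) / n_red2
        ds2 = c["i2"][None, :, :, None] * (
            dn - mean_dn[None, :, :, None] - s2n * mean_dn_x[None, :, :, None]
        )

        ds2r = ds2.reshape(N, S, K, self.M, T)
        dWs64, dz1 = spatial_bwd(ds2r, c["z1r"], self.Ws)
        dWs = dWs64.astype(self.dtype)
        dz1_2 = dz1.reshape(-1, S * K)

        # batch norm 1 backward, fused: dh1 = A*dz1 + B*h1 + D with per-column
        # coefficients (avoids materializing the normalized activations)
        h1, m1, i1 = c["h1"], c["m1"], c["i1"]
        n_red1 = h1.shape[0]
        g1f = self.g1.reshape(-1).astype(np.float64)
        sum_dz, sum_dz_h1 = paired_col_sums(dz1_2, h1)
        # sums against normalized activations from raw-activation sums
        sum_dz_h1n = i1 * (sum_dz_h1 - m1 * sum_dz)
        dg1 = sum_dz_h1n.reshape(S, K)
        db1 = sum_dz.reshape(S, K)
        # dh1 = i1*g1*(dz1 - sum_dz/n - h1n * sum_dz_h1n/n)
        #     = A*dz1 + (-A*i1*sum_dz_h1n/n) * h1 + A*(m1*i1*sum_dz_h1n - sum_dz)/n
        A = g1f * i1
        B = -A * i1 * sum_dz_h1n / n_red1
        D = A * (m1 * i1 * sum_dz_h1n - sum_dz) / n_red1
        dh1 = affine2(dz1_2, h1, A.astype(self.dtype), B.astype(self.dtype),
                      D.astype(self.dtype))

        dWt = (dh1.T @ c["xw2"]).reshape(S, K, self.L)
        return [dWt, dg1.astype(self.dtype), db1.astype(self.dtype),
                dWs, dg2, db2, dWd, dbd]

    # -- model extraction -----------------------------------------------------

    def extract(self, s: int) -> CompactCNN:
        """Materialize seed ``s`` as a standalone CompactCNN (eval/LRP ready)."""
        net = CompactCNN(n_rois=self.R, n_times=self.T, n_temporal=self.K,
                         kernel_len=self.L, multiplier=self.M, pool=self.P,
                         dropout_p=self.p_drop, n_out=self.n_out,
                         seed=self.seeds[s], dtype=self.dtype)
        net.load_state({
            "Wt": self.Wt[s], "g1": self.g1[s], "b1": self.b1[s],
            "Ws": self.Ws[s], "g2": self.g2[s], "b2": self.b2[s],
            "Wd": self.Wd[s], "bd": self.bd[s],
            "rm1": self.rm1[s], "rv1": self.rv1[s],
            "rm2": self.rm2[s], "rv2": self.rv2[s],
        })
        return net

    def seed_state(self, s: int) -> dict[str, np.ndarray]:
        return {n: getattr(self, n)[s].copy()
                for n in ("Wt", "g1", "b1", "Ws", "g2", "b2", "Wd", "bd",
                          "rm1", "rv1", "rm2", "rv2")}

    def load_seed_state(self, s: int, state: dict[str, np.ndarray]) -> None:
        for n, v in state.items():
            getattr(self, n)[s] = v


def ensemble_cross_entropy(o: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-seed mean CE loss (S,) and gradient (N, S, n_out)."""
    p = softmax(np.asarray(o, dtype=np.float64))
    n = o.shape[0]
    picked = np.clip(p[np.arange(n), :, y], 1e-12, None)
    loss = -np.log(picked).mean(axis=0)
    dp = p
    dp[np.arange(n), :, y] -= 1.0
    return loss, (dp / n).astype(o.dtype)


def fit_ensemble(
    net: EnsembleCNN,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 500,
    patience: int = 20,
    data_seed: int = 0,
) -> dict:
    """Train all seeds in lockstep with early stopping on validation loss.

    Mini-batch order is shared across seeds (drawn from ``data_seed``);
    initialization and dropout are per seed.  Each seed's best-validation
    parameters are restored at the end.  Returns a history dict.
    """
    from ._net import Adam  # local import to keep module load light

    if len(X_val) == 0:
        raise ValueError("empty validation set")
    S = net.S
    shuffle_rng = np.random.default_rng(data_seed)
    # One initial shuffle randomizes mini-batch composition; thereafter the
    # batch partitions are fixed (zero-copy views into the precomputed
    # windows) and only their order is re-drawn each epoch.
    perm = shuffle_rng.permutation(len(X_train))
    X_train = np.asarray(X_train)[perm]
    y_train = np.asarray(y_train, dtype=int)[perm]
    xw_train = make_windows(X_train, net.L, net.dtype)
    xw_val = make_windows(X_val, net.L, net.dtype)
    y_val = np.asarray(y_val, dtype=int)
    drop_rngs = [np.random.default_rng(int(seed) + 1) for seed in net.seeds]
    opt = Adam(net.parameters(), lr=lr)

    n = len(y_train)
    best_loss = np.full(S, np.inf)
    best_epoch = np.zeros(S, dtype=int)
    best_states = [net.seed_state(s) for s in range(S)]
    wait = np.zeros(S, dtype=int)
    active = np.ones(S, dtype=bool)
    history: dict = {"val_loss": [], "train_loss": []}

    starts = list(range(0, n, batch_size))
    for epoch in range(max_epochs):
        order = shuffle_rng.permutation(len(starts))
        ep_loss = np.zeros(S)
        n_batches = 0
        for bi in order:
            sl = slice(starts[bi], starts[bi] + batch_size)
            o = net.forward(xw_train[sl], training=True, drop_rngs=drop_rngs)
            loss, do = ensemble_cross_entropy(o, y_train[sl])
            grads = net.backward(do)
            opt.step(grads)
            ep_loss += loss
            n_batches += 1
        o_val = net.forward(xw_val, training=False)
        val_loss, _ = ensemble_cross_entropy(o_val, y_val)
        history["train_loss"].append(ep_loss / n_batches)
        history["val_loss"].append(val_loss)

        improved = active & (val_loss < best_loss - 1e-6)
        for s in np.nonzero(improved)[0]:
            best_loss[s] = val_loss[s]
            best_epoch[s] = epoch
            best_states[s] = net.seed_state(s)
        wait[improved] = 0
        stalled = active & ~improved
        wait[stalled] += 1
        active &= wait <= patience
        if not active.any():
            break

    for s in range(S):
        net.load_seed_state(s, best_states[s])
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    history["epochs_run"] = epoch + 1
    return history
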