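"""A compact numpy implementation of the four-path convolutional regressor.

Three convolutional paths (residue atomic composition, diamino composition,
one-hot sequence) each apply a width-4 convolution, ReLU and global max
pooling; a fourth path passes the global feature vector through a dense
layer. The concatenated path outputs feed a stack of six dense layers whose
last unit emits the (standardized) CCS. Training is mini-batch Adam on the
mean-squared error with early stopping on a validation split.

Weights are initialized from N(mu, sigma^2); the conventional choice for
this architecture family is mu = 0, sigma = 1, which the Adam updates
tolerate because gradient steps are normalized per parameter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _relu(x):
    return np.maximum(x, 0.0)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class FourPathConvNet:
    """Four-path convolutional CCS regressor (numpy forward/backward)."""

    def __init__(
        self,
        path_shapes: tuple[tuple[int, int], ...],  # (length, channels) x3
        n_global: int,
        n_filters: int = 12,
        kernel: int = 4,
        dense_sizes: tuple[int, ...] = (64, 32, 16, 8, 4, 1),
        init_mu: float = 0.0,
        init_sigma: float = 1.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.kernel = kernel
        self.n_filters = n_filters
        init = lambda *shape: rng.normal(init_mu, init_sigma, shape)
        self.conv_w = [init(n_filters, kernel, c) for _, c in path_shapes]
        self.conv_b = [np.zeros(n_filters) for _ in path_shapes]
        self.glob_w = init(n_global, 32)
        self.glob_b = np.zeros(32)
        sizes = [3 * n_filters + 32, *dense_sizes]
        self.dense_w = [init(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.dense_b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    # -- parameter plumbing -------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.glob_w, self.glob_b,
                *self.dense_w, *self.dense_b]

    # -- forward ------------------------------------------------------------
    def _forward(self, paths: list[np.ndarray], glob: np.ndarray, cache: bool):
        """paths[p]: (B, L_p, C_p); glob: (B, G). Returns (B,) predictions."""
        caches = {"conv": [], "dense": []}
        pooled = []
        for p, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            x = paths[p]
            win = sliding_window_view(x, self.kernel, axis=1)  # (B, L-k+1, C, k)
            pre = np.einsum("blck,fkc->blf", win, w) + b
            act = _relu(pre)
            arg = act.argmax(axis=1)  # (B, F)
            pool = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            pooled.append(pool)
            if cache:
                caches["conv"].append((win, pre, arg))
        gpre = glob @ self.glob_w + self.glob_b
        gact = _relu(gpre)
        h = np.concatenate([*pooled, gact], axis=1)
        caches["concat_in"] = (paths, glob, gpre, h)
        acts = [h]
        for li, (w, b) in enumerate(zip(self.dense_w, self.dense_b)):
            z = acts[-1] @ w + b
            a = _relu(z) if li < len(self.dense_w) - 1 else z
            if cache:
                caches["dense"].append((acts[-1], z))
            acts.append(a)
        return acts[-1][:, 0], caches

    def predict(self, paths: list[np.ndarray], glob: np.ndarray) -> np.ndarray:
        out, _ = self._forward(paths, glob, cache=False)
        return out

    # -- backward -----------------------------------------------------------
    def _backward(self, caches, d_out: np.ndarray) -> list[np.ndarray]:
        B = len(d_out)
        grads_dense_w, grads_dense_b = [], []
        delta = d_out[:, None]
        for li in range(len(self.dense_w) - 1, -1, -1):
            a_in, z = caches["dense"][li]
            if li < len(self.dense_w) - 1:
                delta = delta * (z > 0)
            grads_dense_w.insert(0, a_in.T @ delta / B)
            grads_dense_b.insert(0, delta.mean(axis=0))
            delta = delta @ self.dense_w[li].T
        # delta is gradient w.r.t. concat input h
        F = self.n_filters
        grads_conv_w, grads_conv_b = [], []
        for p in range(3):
            dp = delta[:, p * F: (p + 1) * F]  # (B, F)
            win, pre, arg = caches["conv"][p]
            dact = np.zeros_like(pre)
            np.put_along_axis(dact, arg[:, None, :], dp[:, None, :], axis=1)
            dpre = dact * (pre > 0)
            gw = np.einsum("blf,blck->fkc", dpre, win) / B
            grads_conv_w.append(gw)
            grads_conv_b.append(dpre.sum(axis=1).mean(axis=0))
        dg = delta[:, 3 * F:]
        _, glob, gpre, _ = caches["concat_in"]
        dgpre = dg * (gpre > 0)
        g_glob_w = glob.T @ dgpre / B
        g_glob_b = dgpre.mean(axis=0)
        return [*grads_conv_w, *grads_conv_b, g_glob_w, g_glob_b,
                *grads_dense_w, *grads_dense_b]

    # -- training -----------------------------------------------------------
    def fit(
        self,
        paths: list[np.ndarray],
        glob: np.ndarray,
        y: np.ndarray,
        val_paths: list[np.ndarray],
        val_glob: np.ndarray,
        val_y: np.ndarray,
        epochs: int = 300,
        patience: int = 10,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> dict:
        rng = np.random.default_rng(seed)
        opt = _Adam(self._params(), lr)
        best_val = np.inf
        best_state = [p.copy() for p in self._params()]
        wait = 0
        history = []
        n = len(y)
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start: start + batch_size]
                bp = [p[idx] for p in paths]
                pred, caches = self._forward(bp, glob[idx], cache=True)
                d_out = 2 * (pred - y[idx])
                grads = self._backward(caches, d_out)
                opt.step(self._params(), grads)
            val_pred = self.predict(val_paths, val_glob)
            val_mse = float(np.mean((val_pred - val_y) ** 2))
            history.append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_state = [p.copy() for p in self._params()]
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
            if not np.isfinite(val_mse):
                break
        for p, b in zip(self._params(), best_state):
            p[...] = b
        return {"epochs_run": len(history), "best_val_mse": best_val,
                "val_history": history}
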