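"""Minimal convolutional patch classifier, implemented on numpy.

The dot detector only needs a very small network: five trained layers
(three 3x3 convolutions with ReLU and 2x2 max-pooling in between, then
two fully connected layers with a softmax pair output) over a 25x25
single-channel patch.  At this size a hand-rolled im2col implementation
with Adam trains in seconds on one CPU, and keeping it dependency-free
makes the trained model a plain ``.npz`` archive.

Shapes through the default network::

    1x25x25 -> conv 8  -> 8x23x23 -> pool -> 8x11x11
            -> conv 16 -> 16x9x9  -> pool -> 16x4x4
            -> conv 32 -> 32x2x2  -> fc 64 -> fc 2 -> softmax
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

PATCH_SIZE = 25


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, H-k+1, W-k+1, C*k*k) view-based patch matrix."""
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # v: (N, C, H', W', k, k) -> (N, H', W', C, k, k)
    v = v.transpose(0, 2, 3, 1, 4, 5)
    n, hh, ww = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n, hh, ww, -1)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int = 3) -> np.ndarray:
    """Scatter-add gradient of _im2col back onto the input."""
    n, c, h, w = x_shape
    hh, ww = h - k + 1, w - k + 1
    dc = dcols.reshape(n, hh, ww, c, k, k)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + hh, j:j + ww] += dc[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xv = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = xv.argmax(axis=-1)
    out = np.take_along_axis(xv, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _maxpool_back(dout: np.ndarray, arg: np.ndarray, x_shape: tuple) -> np.ndarray:
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dxv = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dxv, arg[..., None], dout[..., None], axis=-1)
    dxv = dxv.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : 2 * h2, : 2 * w2] = dxv.reshape(n, c, 2 * h2, 2 * w2)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PatchCNN:
    """Dot / no-dot classifier over 25x25 grayscale patches."""

    def __init__(self, seed: int = 0, channels: tuple[int, int, int] = (8, 16, 32),
                 hidden: int = 64):
        self.channels = tuple(int(c) for c in channels)
        self.hidden = int(hidden)
        self.seed = int(seed)
        self.mean = 0.0
        self.std = 1.0
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels
        self.params = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)

        self.params["W1"] = he((9, c1), 9)
        self.params["b1"] = np.zeros(c1, np.float32)
        self.params["W2"] = he((c1 * 9, c2), c1 * 9)
        self.params["b2"] = np.zeros(c2, np.float32)
        self.params["W3"] = he((c2 * 9, c3), c2 * 9)
        self.params["b3"] = np.zeros(c3, np.float32)
        flat = c3 * 2 * 2
        self.params["W4"] = he((flat, hidden), flat)
        self.params["b4"] = np.zeros(hidden, np.float32)
        self.params["W5"] = he((hidden, 2), hidden)
        self.params["b5"] = np.zeros(2, np.float32)

    # ----------------------------------------------------------------- forward
    def _prep(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patches must be {PATCH_SIZE}x{PATCH_SIZE}, "
                             f"got {x.shape[-2:]}")
        return ((x - self.mean) / self.std)[:, None]  # (N, 1, 25, 25)

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        cache: dict = {"x": x}
        cols1 = _im2col(x)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0).transpose(0, 3, 1, 2)
        p1, arg1 = _maxpool(a1)

        cols2 = _im2col(p1)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0).transpose(0, 3, 1, 2)
        p2, arg2 = _maxpool(a2)

        cols3 = _im2col(p2)
        z3 = cols3 @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0).transpose(0, 3, 1, 2)

        flat = a3.reshape(len(x), -1)
        z4 = flat @ p["W4"] + p["b4"]
        a4 = np.maximum(z4, 0)
        z5 = a4 @ p["W5"] + p["b5"]
        probs = _softmax(z5)
        if want_cache:
            cache.update(cols1=cols1, z1=z1, a1=a1, arg1=arg1, p1=p1,
                         cols2=cols2, z2=z2, a2=a2, arg2=arg2, p2=p2,
                         cols3=cols3, z3=z3, a3=a3, flat=flat, z4=z4, a4=a4,
                         probs=probs)
            return probs, cache
        return probs, None

    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        p = self.params
        n = len(y)
        dz5 = cache["probs"].copy()
        dz5[np.arange(n), y] -= 1.0
        dz5 /= n
        g = {}
        g["W5"] = cache["a4"].T @ dz5
        g["b5"] = dz5.sum(0)
        da4 = dz5 @ p["W5"].T
        dz4 = da4 * (cache["z4"] > 0)
        g["W4"] = cache["flat"].T @ dz4
        g["b4"] = dz4.sum(0)
        dflat = dz4 @ p["W4"].T
        da3 = dflat.reshape(cache["a3"].shape)

        dz3 = da3.transpose(0, 2, 3, 1) * (cache["z3"] > 0)
        g["W3"] = np.tensordot(cache["cols3"], dz3, axes=([0, 1, 2], [0, 1, 2]))
        g["b3"] = dz3.sum((0, 1, 2))
        dcols3 = dz3 @ p["W3"].T
        dp2 = _col2im(dcols3, cache["p2"].shape)

        da2 = _maxpool_back(dp2, cache["arg2"], cache["a2"].shape)
        dz2 = da2.transpose(0, 2, 3, 1) * (cache["z2"] > 0)
        g["W2"] = np.tensordot(cache["cols2"], dz2, axes=([0, 1, 2], [0, 1, 2]))
        g["b2"] = dz2.sum((0, 1, 2))
        dcols2 = dz2 @ p["W2"].T
        dp1 = _col2im(dcols2, cache["p1"].shape)

        da1 = _maxpool_back(dp1, cache["arg1"], cache["a1"].shape)
        dz1 = da1.transpose(0, 2, 3, 1) * (cache["z1"] > 0)
        g["W1"] = np.tensordot(cache["cols1"], dz1, axes=([0, 1, 2], [0, 1, 2]))
        g["b1"] = dz1.sum((0, 1, 2))
        return g

    # ------------------------------------------------------------------- train
    def fit(self, patches: np.ndarray, labels: np.ndarray,
            epochs: int = 40, batch_size: int = 32, lr: float = 1e-3,
            val_fraction: float = 0.1, patience: int = 6,
            min_epochs: int = 12, verbose: bool = False) -> dict:
        """Adam training with early stopping on a held-back validation slice.

        At least ``min_epochs`` epochs are always run: validation
        accuracy can saturate within one epoch on easy data while the
        decision boundary is still soft, which matters downstream where
        the sliding-window scan thresholds raw probabilities.
        """
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        x_all = np.asarray(patches, dtype=np.float32)
        self.mean = float(x_all.mean())
        self.std = float(x_all.std() + 1e-6)
        x = self._prep(x_all)

        rng = np.random.default_rng(self.seed + 1)
        # stratified validation slice: both classes must be represented,
        # otherwise a degenerate constant net can look perfect
        val_parts, tr_parts = [], []
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            n_val = max(int(round(val_fraction * len(idx))), 1)
            val_parts.append(idx[:n_val])
            tr_parts.append(idx[n_val:])
        val_idx = np.concatenate(val_parts)
        tr_idx = rng.permutation(np.concatenate(tr_parts))

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        t = 0
        best_acc, best_params, stall = -1.0, None, 0
        history = []
        for epoch in range(epochs):
            perm = rng.permutation(tr_idx)
            for i in range(0, len(perm), batch_size):
                idx = perm[i:i + batch_size]
                probs, cache = self._forward(x[idx], want_cache=True)
                grads = self._backward(cache, y[idx])
                t += 1
                for k in self.params:
                    m[k] = 0.9 * m[k] + 0.1 * grads[k]
                    v[k] = 0.999 * v[k] + 0.001 * grads[k] ** 2
                    mh = m[k] / (1 - 0.9 ** t)
                    vh = v[k] / (1 - 0.999 ** t)
                    self.params[k] -= (lr * mh / (np.sqrt(vh) + 1e-8)).astype(np.float32)
            val_acc = float(np.mean(
                self._forward(x[val_idx])[0].argmax(1) == y[val_idx]))
            history.append(val_acc)
            if verbose:
                print(f"epoch {epoch + 1}: val acc {val_acc:.4f}")
            if val_acc > best_acc + 1e-12:
                best_acc = val_acc
                best_params = {k: vv.copy() for k, vv in self.params.items()}
                stall = 0
            else:
                stall += 1
                if val_acc >= best_acc - 1e-12:
                    # same validation accuracy, later epoch: keep the
                    # sharper (lower-loss) parameters
                    best_params = {k: vv.copy() for k, vv in self.params.items()}
            if epoch + 1 >= min_epochs and (
                    best_acc >= 1.0 - 1e-12 or stall >= patience):
                break
        if best_params is not None:
            self.params = best_params
        return {"val_accuracy": best_acc, "epochs_run": epoch + 1,
                "history": history}

    # ----------------------------------------------------------------- predict
    def predict_proba(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Probability pairs (no-dot, dot), rows summing to 1."""
        x = self._prep(patches)
        out = np.empty((len(x), 2), dtype=np.float32)
        for i in range(0, len(x), batch_size):
            out[i:i + batch_size] = self._forward(x[i:i + batch_size])[0]
        return out

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)

    # --------------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        meta = {"channels": list(self.channels), "hidden": self.hidden,
                "seed": self.seed, "mean": self.mean, "std": self.std}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            net = cls(seed=meta["seed"], channels=tuple(meta["channels"]),
                      hidden=meta["hidden"])
            net.mean, net.std = meta["mean"], meta["std"]
            for k in net.params:
                net.params[k] = z[k]
        return net
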