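"""A small convolutional network for particle-image classification.

The network is deliberately tiny so it can run on single-board
instrument hardware: alternating convolution / max-pool stages feeding
a narrow dense head,

    INPUT - 32CONV(5x5) - MP(2x2) - 16CONV(5x5) - MP(2x2)
          - 8CONV(3x3) - MP(2x2) - 16FC - NFC(softmax)

trained with Adam (learning rate 0.01) on categorical cross-entropy.
Implemented directly on NumPy (im2col convolutions, float32), which is
ample for networks of this size and keeps training fully deterministic
under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detect import ROI

ARCHITECTURE = (
    ("conv", 32, 5),
    ("pool", 2),
    ("conv", 16, 5),
    ("pool", 2),
    ("conv", 8, 3),
    ("pool", 2),
    ("dense", 16),
    ("dense", "n_classes"),
)

_CLIP_NORM = 5.0  # global gradient-norm clip keeps Adam at lr 0.01 stable


def micro_cnn_param_count(input_side: int, n_classes: int, in_channels: int = 2) -> int:
    """Closed-form trainable parameter count of the architecture.

    Convolution: ``filters * (k^2 * in_channels + 1)``; dense:
    ``in * out + out``.  Spatial size after each 2x2 pool is floored.
    """
    side, chans, total = input_side, in_channels, 0
    for layer in ARCHITECTURE:
        if layer[0] == "conv":
            _, f, k = layer
            total += f * (k * k * chans + 1)
            chans = f
        elif layer[0] == "pool":
            side //= layer[1]
        elif layer[0] == "dense":
            out = n_classes if layer[1] == "n_classes" else layer[1]
            n_in = side * side * chans if chans else side
            total += n_in * out + out
            side, chans = out, 0
    return total


def _conv_forward(x, W, b):
    n, h, w, cin = x.shape
    kh, kw = W.shape[0], W.shape[1]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (n, h, w, cin, kh, kw) -> columns (n*h*w, kh*kw*cin)
    col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, kh * kw * cin
    )
    Wm = W.reshape(kh * kw * cin, -1)
    out = (col @ Wm + b).reshape(n, h, w, -1)
    return out, col


def _conv_backward(dout, x_shape, col, W):
    n, h, w, cin = x_shape
    kh, kw = W.shape[0], W.shape[1]
    ph, pw = kh // 2, kw // 2
    f = W.shape[3]
    dflat = dout.reshape(n * h * w, f)
    Wm = W.reshape(kh * kw * cin, f)
    dW = (col.T @ dflat).reshape(W.shape)
    db = dflat.sum(axis=0)
    dcol = (dflat @ Wm.T).reshape(n, h, w, kh, kw, cin)
    dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, cin), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
    return dxp[:, ph : ph + h, pw : pw + w, :], dW, db


def _pool_forward(x, size):
    n, h, w, c = x.shape
    h2, w2 = h // size, w // size
    xt = x[:, : h2 * size, : w2 * size, :].reshape(n, h2, size, w2, size, c)
    out = xt.max(axis=(2, 4))
    return out, xt


def _pool_backward(dout, x_shape, xt, out, size):
    n, h, w, c = x_shape
    h2, w2 = out.shape[1], out.shape[2]
    mask = xt == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    spread = mask * (dout[:, :, None, :, None, :] / counts)
    dx[:, : h2 * size, : w2 * size, :] = spread.reshape(n, h2 * size, w2 * size, c)
    return dx


class MicroCNN:
    """The fixed small conv-net; see module docstring for the layout."""

    def __init__(self, input_side: int, n_classes: int, in_channels: int = 2,
                 seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least two output classes")
        if input_side < 8:
            raise ValueError("input side must be at least 8 pixels")
        self.input_side = input_side
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.classes: Optional[np.ndarray] = None
        rng = np.random.default_rng(seed)
        self.params: list[dict] = []
        side, chans = input_side, in_channels
        self._layers = []
        for layer in ARCHITECTURE:
            if layer[0] == "conv":
                _, f, k = layer
                fan_in = k * k * chans
                W = rng.normal(0, np.sqrt(2.0 / fan_in), (k, k, chans, f))
                self.params.append(
                    {"W": W.astype(np.float32), "b": np.zeros(f, dtype=np.float32)}
                )
                self._layers.append(("conv", len(self.params) - 1))
                chans = f
            elif layer[0] == "pool":
                self._layers.append(("pool", layer[1]))
                side //= layer[1]
            elif layer[0] == "dense":
                out = n_classes if layer[1] == "n_classes" else layer[1]
                if chans:
                    n_in = side * side * chans
                    self._layers.append(("flatten", None))
                    chans = 0
                else:
                    n_in = side
                W = rng.normal(0, np.sqrt(2.0 / n_in), (n_in, out))
                self.params.append(
                    {"W": W.astype(np.float32), "b": np.zeros(out, dtype=np.float32)}
                )
                self._layers.append(("dense", len(self.params) - 1))
                side = out
        self._adam_t = 0
        for p in self.params:
            for key in ("W", "b"):
                p["m" + key] = np.zeros_like(p[key])
                p["v" + key] = np.zeros_like(p[key])

    # -- introspection ------------------------------------------------
    def describe(self) -> list[str]:
        """Layer sequence as printable tokens."""
        tokens = ["INPUT"]
        for layer in ARCHITECTURE:
            if layer[0] == "conv":
                tokens.append(f"{layer[1]}CONV({layer[2]}x{layer[2]})")
            elif layer[0] == "pool":
                tokens.append(f"MP({layer[1]}x{layer[1]})")
            elif layer[0] == "dense":
                out = self.n_classes if layer[1] == "n_classes" else layer[1]
                tokens.append(f"{out}FC")
        return tokens

    def param_count(self) -> int:
        return int(sum(p["W"].size + p["b"].size for p in self.params))

    # -- forward / backward -------------------------------------------
    def _forward(self, x, with_cache=False):
        cache = []
        dense_seen = 0
        n_dense = sum(1 for t, _ in self._layers if t == "dense")
        for kind, arg in self._layers:
            if kind == "conv":
                p = self.params[arg]
                out, col = _conv_forward(x, p["W"], p["b"])
                relu_mask = out > 0
                out = out * relu_mask
                if with_cache:
                    cache.append(("conv", arg, x.shape, col, relu_mask))
                x = out
            elif kind == "pool":
                out, xt = _pool_forward(x, arg)
                if with_cache:
                    cache.append(("pool", arg, x.shape, xt, out))
                x = out
            elif kind == "flatten":
                if with_cache:
                    cache.append(("flatten", None, x.shape, None, None))
                x = x.reshape(x.shape[0], -1)
            elif kind == "dense":
                dense_seen += 1
                p = self.params[arg]
                out = x @ p["W"] + p["b"]
                last = dense_seen == n_dense
                relu_mask = None
                if not last:
                    relu_mask = out > 0
                    out = out * relu_mask
                if with_cache:
                    cache.append(("dense", arg, x, None, relu_mask))
                x = out
        return x, cache

    def _backward(self, dlogits, cache):
        grads = {i: {"W": None, "b": None} for i in range(len(self.params))}
        dx = dlogits
        for kind, arg, a, b_, c_ in reversed(cache):
            if kind == "dense":
                x_in, relu_mask = a, c_
                if relu_mask is not None:
                    dx = dx * relu_mask
                p = self.params[arg]
                grads[arg]["W"] = x_in.T @ dx
                grads[arg]["b"] = dx.sum(axis=0)
                dx = dx @ p["W"].T
            elif kind == "flatten":
                dx = dx.reshape(a)
            elif kind == "pool":
                dx = _pool_backward(dx, a, b_, c_, arg)
            elif kind == "conv":
                x_shape, col, relu_mask = a, b_, c_
                dx = dx * relu_mask
                dxp, dW, db = _conv_backward(dx, x_shape, col, self.params[arg]["W"])
                grads[arg]["W"] = dW
                grads[arg]["b"] = db
                dx = dxp
        return grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        # global gradient-norm clipping
        sq = sum(
            float((g["W"] ** 2).sum() + (g["b"] ** 2).sum()) for g in grads.values()
        )
        norm = np.sqrt(sq)
        scale = _CLIP_NORM / norm if norm > _CLIP_NORM else 1.0
        self._adam_t += 1
        t = self._adam_t
        for i, p in enumerate(self.params):
            for key in ("W", "b"):
                g = grads[i][key] * scale
                p["m" + key] = beta1 * p["m" + key] + (1 - beta1) * g
                p["v" + key] = beta2 * p["v" + key] + (1 - beta2) * g * g
                mhat = p["m" + key] / (1 - beta1**t)
                vhat = p["v" + key] / (1 - beta2**t)
                p[key] = p[key] - lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ----------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        outs = []
        for i in range(0, len(X), batch_size):
            logits, _ = self._forward(X[i : i + batch_size])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        if self.classes is not None:
            return self.classes[idx]
        return idx

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p["W"]).tobytes())
            h.update(np.ascontiguousarray(p["b"]).tobytes())
        return h.hexdigest()


def build_micro_cnn(
    input_side: int = 48, n_classes: int = 2, in_channels: int = 2, seed: int = 0
) -> MicroCNN:
    """Construct the network; ``input_side`` divisible by 8 preferred."""
    return MicroCNN(input_side, n_classes, in_channels=in_channels, seed=seed)


def crops_to_tensor(
    items: Sequence, input_side: int, use_bright: bool = True
) -> np.ndarray:
    """Stack ROI crops into an (N, side, side, C) float32 tensor.

    Darkfield is channel 0 and (when present and requested) brightfield
    channel 1.  Crops of a different size are rescaled.
    """
    from skimage.transform import resize

    def prep(img):
        img = np.asarray(img, dtype=np.float32)
        if img.shape != (input_side, input_side):
            img = resize(img, (input_side, input_side), anti_aliasing=True).astype(
                np.float32
            )
        return img

    tensors = []
    for item in items:
        if isinstance(item, ROI):
            chans = [prep(item.crop)]
            if use_bright and item.crop_bright is not None:
                chans.append(prep(item.crop_bright))
        else:
            arr = np.asarray(item, dtype=np.float32)
            if arr.ndim == 2:
                chans = [prep(arr)]
            else:
                chans = [prep(arr[..., c]) for c in range(arr.shape[-1])]
        tensors.append(np.stack(chans, axis=-1))
    return np.stack(tensors, axis=0)


def train_micro_cnn(
    model: MicroCNN,
    X: np.ndarray,
    y: Sequence,
    epochs: int = 12,
    cv_batches: int = 3,
    batch_size: int = 32,
    learning_rate: float = 0.01,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> dict:
    """Train the network; returns a history of per-epoch validation accuracy.

    The epoch budget is divided into ``cv_batches`` segments; at the
    start of each segment the train/validation subsets are randomly
    resampled, so every part of the data eventually informs both
    fitting and validation.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(y_idx)
    if np.any(counts == 0):
        raise ValueError("empty class in training data")
    model.classes = classes
    onehot = np.eye(classes.size, dtype=np.float32)[y_idx]
    rng = np.random.default_rng(seed)
    n = len(X)
    n_val = max(1, int(round(val_fraction * n)))
    history = {"val_accuracy": [], "train_loss": []}
    per_segment = max(1, epochs // cv_batches)
    epoch = 0
    for _ in range(cv_batches):
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        for _ in range(per_segment):
            if epoch >= epochs:
                break
            order = rng.permutation(tr_idx)
            losses = []
            for i in range(0, len(order), batch_size):
                sel = order[i : i + batch_size]
                logits, cache = model._forward(X[sel], with_cache=True)
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs = e / e.sum(axis=1, keepdims=True)
                t = onehot[sel]
                loss = -np.mean(np.sum(t * np.log(probs + 1e-12), axis=1))
                losses.append(float(loss))
                dlogits = (probs - t) / len(sel)
                grads = model._backward(dlogits.astype(np.float32), cache)
                model._adam_step(grads, learning_rate)
            val_pred = model.predict_proba(X[val_idx]).argmax(axis=1)
            acc = float(np.mean(val_pred == y_idx[val_idx]))
            history["val_accuracy"].append(acc)
            history["train_loss"].append(float(np.mean(losses)))
            epoch += 1
    return history
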