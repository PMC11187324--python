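"""Minimal convolutional network stack for MIL bag classification.

Implements exactly what the training protocol needs, in numpy with explicit
backprop: 3x3 same-padding convolutions, ReLU, 2x2 max pooling, global
average pooling to a per-instance embedding, and two bag heads — a plain
head (per-instance softmax, bag probability = mean of instance
probabilities) and a gated-attention head (per-instance score -> softmax
weights -> weighted sum of embeddings -> softmax classifier).  Loss is
two-class cross-entropy on the bag output; the optimizer is Adam.

Backbone presets are small CNNs of differing capacity; they are pluggable,
so a large pretrained feature extractor can stand behind the same
interface where one is available.
"""

from __future__ import annotations

import numpy as np

#: backbone name -> per-block channel widths (3x3 conv + ReLU + 2x2 maxpool each)
BACKBONES = {
    "tiny-cnn": (8, 16, 32),
    "efficientnet-like": (6, 12, 24),
    "googlenet-like": (10, 20, 40),
    "resnet50-like": (12, 24, 48),
}


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution.  x: (N,H,W,C); w: (9*C, F); b: (F,)."""
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N*H*W, 3*3*C) with (ky, kx, c) fastest-varying c
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * wd, 9 * c)
    y = (cols @ w + b).reshape(n, h, wd, -1)
    return y, cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    n, h, wd, c = x_shape
    f = dy.shape[-1]
    dyf = dy.reshape(n * h * wd, f)
    dw = cols.T @ dyf
    db = dyf.sum(axis=0)
    dcols = (dyf @ w.T).reshape(n, h, wd, 3, 3, c)
    dxp = np.zeros((n, h + 2, wd + 2, c), dtype=dy.dtype)
    for ky in range(3):
        for kx in range(3):
            dxp[:, ky : ky + h, kx : kx + wd, :] += dcols[:, :, :, ky, kx, :]
    return dxp[:, 1 : h + 1, 1 : wd + 1, :], dw, db


def _maxpool_forward(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    n, h, w, c = x_shape
    dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    dxr = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(n, h, w, c)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MILNet:
    """Bag classifier: conv backbone + (plain | gated-attention) pooling head.

    Parameters are plain float32 numpy arrays in ``self.params``; gradients
    are returned by :meth:`loss_and_grads` keyed the same way.
    """

    def __init__(
        self,
        backbone: str = "tiny-cnn",
        attention: bool = False,
        attention_head_size: int = 16,
        embed_dim: int | None = None,
        seed: int = 0,
    ):
        if backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {backbone!r}; expected one of {sorted(BACKBONES)}")
        self.backbone = backbone
        self.attention = attention
        self.widths = BACKBONES[backbone]
        self.embed_dim = self.widths[-1] if embed_dim is None else embed_dim
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        cin = 3
        for i, cout in enumerate(self.widths):
            fan_in = 9 * cin
            p[f"conv{i}_w"] = (rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
            p[f"conv{i}_b"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        d = self.embed_dim
        if attention:
            a = attention_head_size
            p["attn_V"] = (rng.standard_normal((d, a)) * np.sqrt(1.0 / d)).astype(np.float32)
            p["attn_U"] = (rng.standard_normal((d, a)) * np.sqrt(1.0 / d)).astype(np.float32)
            p["attn_w"] = (rng.standard_normal(a) * np.sqrt(1.0 / a)).astype(np.float32)
        p["cls_w"] = (rng.standard_normal((d, 2)) * np.sqrt(1.0 / d)).astype(np.float32)
        p["cls_b"] = np.zeros(2, dtype=np.float32)
        self.params = p

    # ------------------------------------------------------------------ embed
    def _embed_forward(self, x: np.ndarray, need_cache: bool):
        caches = []
        h = x
        for i in range(len(self.widths)):
            y, cols = _conv_forward(h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            mask = y > 0
            y = y * mask
            pooled, idx = _maxpool_forward(y)
            if need_cache:
                caches.append((h.shape, cols, mask, idx, y.shape))
            h = pooled
        emb = h.mean(axis=(1, 2))  # (k, D)
        if need_cache:
            return emb, (caches, h.shape)
        return emb

    def _embed_backward(self, demb: np.ndarray, cache, grads: dict) -> None:
        caches, pooled_shape = cache
        k, hh, ww, c = pooled_shape
        dh = np.broadcast_to(demb[:, None, None, :] / (hh * ww), pooled_shape).astype(np.float32)
        for i in reversed(range(len(self.widths))):
            x_shape, cols, mask, idx, y_shape = caches[i]
            dy = _maxpool_backward(dh, idx, y_shape)
            dy = dy * mask
            dh, dw, db = _conv_backward(dy, cols, self.params[f"conv{i}_w"], x_shape)
            grads[f"conv{i}_w"] = grads.get(f"conv{i}_w", 0) + dw
            grads[f"conv{i}_b"] = grads.get(f"conv{i}_b", 0) + db

    # ------------------------------------------------------------------ heads
    def _head_forward(self, emb: np.ndarray):
        """Returns (bag probability vector (2,), per-instance attention or None, cache)."""
        p = self.params
        if not self.attention:
            logits = emb @ p["cls_w"] + p["cls_b"]  # (k, 2)
            probs = _softmax(logits)
            bag = probs.mean(axis=0)
            return bag, None, ("plain", emb, probs)
        t = np.tanh(emb @ p["attn_V"])
        s = 1.0 / (1.0 + np.exp(-(emb @ p["attn_U"])))
        g = t * s
        a = g @ p["attn_w"]
        alpha = _softmax(a[None, :])[0]
        z = alpha @ emb  # (D,)
        logits = z @ p["cls_w"] + p["cls_b"]
        bag = _softmax(logits[None, :])[0]
        return bag, alpha, ("attn", emb, t, s, g, alpha, z, bag)

    def _head_backward(self, dbag: np.ndarray, cache, grads: dict) -> np.ndarray:
        """dbag: gradient wrt the bag probability vector.  Returns demb."""
        p = self.params
        if cache[0] == "plain":
            _, emb, probs = cache
            k = emb.shape[0]
            dprobs = np.broadcast_to(dbag / k, probs.shape)
            # softmax jacobian per instance
            dot = (dprobs * probs).sum(axis=1, keepdims=True)
            dlogits = probs * (dprobs - dot)
            grads["cls_w"] = grads.get("cls_w", 0) + emb.T @ dlogits
            grads["cls_b"] = grads.get("cls_b", 0) + dlogits.sum(axis=0)
            return (dlogits @ p["cls_w"].T).astype(np.float32)
        _, emb, t, s, g, alpha, z, bag = cache
        # softmax jacobian at the bag output
        dlogits = bag * (dbag - (dbag * bag).sum())
        grads["cls_w"] = grads.get("cls_w", 0) + np.outer(z, dlogits)
        grads["cls_b"] = grads.get("cls_b", 0) + dlogits
        dz = p["cls_w"] @ dlogits  # (D,)
        dalpha = emb @ dz  # (k,)
        demb = np.outer(alpha, dz)
        da = alpha * (dalpha - (dalpha * alpha).sum())
        dg = np.outer(da, p["attn_w"])
        grads["attn_w"] = grads.get("attn_w", 0) + g.T @ da
        dt = dg * s
        ds = dg * t
        dpreV = dt * (1.0 - t * t)
        dpreU = ds * s * (1.0 - s)
        grads["attn_V"] = grads.get("attn_V", 0) + emb.T @ dpreV
        grads["attn_U"] = grads.get("attn_U", 0) + emb.T @ dpreU
        demb += dpreV @ p["attn_V"].T + dpreU @ p["attn_U"].T
        return demb.astype(np.float32)

    # ------------------------------------------------------------------- API
    def forward_bag(self, x: np.ndarray):
        """Inference.  x: preprocessed instances (k, S, S, 3) float32.
        Returns (positive-class probability, attention weights or None)."""
        emb = self._embed_forward(x.astype(np.float32), need_cache=False)
        bag, alpha, _ = self._head_forward(emb)
        return float(bag[1]), alpha

    def loss_and_grads(self, x: np.ndarray, label: int):
        """Cross-entropy loss on one bag and gradients for every parameter."""
        emb, cache = self._embed_forward(x.astype(np.float32), need_cache=True)
        bag, _, head_cache = self._head_forward(emb)
        eps = 1e-12
        loss = -float(np.log(bag[label] + eps))
        dbag = np.zeros(2, dtype=np.float64)
        dbag[label] = -1.0 / (bag[label] + eps)
        grads: dict[str, np.ndarray] = {}
        demb = self._head_backward(dbag, head_cache, grads)
        self._embed_backward(demb, cache, grads)
        return loss, float(bag[1]), grads

    def bag_loss(self, x: np.ndarray, label: int) -> tuple[float, float]:
        """Inference-mode loss (no gradients)."""
        emb = self._embed_forward(x.astype(np.float32), need_cache=False)
        bag, _, _ = self._head_forward(emb)
        return -float(np.log(bag[label] + 1e-12)), float(bag[1])


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(self, params: dict, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            g = np.asarray(g, dtype=self.params[k].dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
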