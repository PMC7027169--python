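"""Patch CNN for tau-tangle detection: architecture, training, density maps.

The classifier assigns the *center pixel* of a 56 x 56 x 3 patch to one of
three classes (tau tangle / other tissue / background) and is applied to
whole sections as a sliding window.  The architecture is a small standard
convnet: three (5x5 conv, ReLU, 2x2 max-pool) stages with 16/32/64
channels, a 1024-unit fully-connected layer with dropout 0.5, and a softmax
cross-entropy head.  Exact per-layer trainable-parameter counts are exposed
via :func:`build_architecture` / :func:`count_parameters`:

    conv1 5*5*3*16+16      =     1,216
    conv2 5*5*16*32+32     =    12,832
    conv3 5*5*32*64+64     =    51,264
    fc1   3136*1024+1024   = 3,212,288
    fc2   1024*3+3         =     3,075
    total                  = 3,280,675

Training uses Adam on mini-batches; forward/backward passes are written in
numpy (im2col convolutions), which is entirely adequate for the fixture
scale this package trains at.  The estimator follows the sklearn
classifier protocol (fit / predict / predict_proba).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

PATCH = 56


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: kind, shapes, and trainable-parameter count."""

    kind: str
    input_shape: tuple
    output_shape: tuple
    n_params: int


def build_architecture(patch_size: int = PATCH, classes: int = 3,
                       channels=(16, 32, 64), fc_units: int = 1024,
                       dropout: float = 0.5) -> list:
    """Layer-by-layer specification of the patch classifier.

    Convolutions are 5x5, same-padded; pools are 2x2 stride 2 (implied by
    the successive halving of the spatial dimensions), so the patch size
    must be divisible by 8.
    """
    if patch_size % 8 != 0 or patch_size < 8:
        raise ValueError("patch size must be a positive multiple of 8")
    specs = []
    side = patch_size
    cin = 3
    for k, cout in enumerate(channels, start=1):
        specs.append(
            LayerSpec(
                f"conv5x5_{k}", (side, side, cin), (side, side, cout),
                5 * 5 * cin * cout + cout,
            )
        )
        specs.append(LayerSpec(f"relu_{k}", (side, side, cout),
                               (side, side, cout), 0))
        specs.append(
            LayerSpec(f"maxpool_{k}", (side, side, cout),
                      (side // 2, side // 2, cout), 0)
        )
        side //= 2
        cin = cout
    flat = side * side * cin
    specs.append(LayerSpec("flatten", (side, side, cin), (flat,), 0))
    specs.append(
        LayerSpec("fully_connected_1", (flat,), (fc_units,),
                  flat * fc_units + fc_units)
    )
    specs.append(LayerSpec("relu_fc", (fc_units,), (fc_units,), 0))
    specs.append(LayerSpec(f"dropout_p{dropout}", (fc_units,), (fc_units,), 0))
    specs.append(
        LayerSpec("fully_connected_2", (fc_units,), (classes,),
                  fc_units * classes + classes)
    )
    specs.append(LayerSpec("softmax_crossentropy", (classes,), (classes,), 0))
    return specs


def count_parameters(specs: list):
    """Per-layer and total trainable-parameter counts."""
    per_layer = {s.kind: s.n_params for s in specs}
    return per_layer, sum(s.n_params for s in specs)


# ----------------------------------------------------------------------
# Convolutions are realized as a sum over the 25 kernel shifts of plain
# matrix products on contiguous views, which is considerably faster in
# numpy than materializing im2col patch matrices.
K5, PAD = 5, 2


def _conv_forward(x, W, b):
    """Same-padded 5x5 convolution; x (n,H,W,Cin), W (5,5,Cin,Cout)."""
    n, H, Wd, Cin = x.shape
    Cout = W.shape[-1]
    xp = np.pad(x, ((0, 0), (PAD, PAD), (PAD, PAD), (0, 0)))
    out = np.empty((n, H, Wd, Cout), dtype=x.dtype)
    out[:] = b
    for di in range(K5):
        for dj in range(K5):
            out += xp[:, di : di + H, dj : dj + Wd, :] @ W[di, dj]
    return out, xp


def _conv_backward(xp, W, dz):
    """Gradients of the same-padded convolution.

    Returns (dW, db, dx); xp is the padded input cached by the forward.
    """
    n, H, Wd, Cout = dz.shape
    Cin = W.shape[2]
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    dzf = dz.reshape(-1, Cout)
    for di in range(K5):
        for dj in range(K5):
            xs = xp[:, di : di + H, dj : dj + Wd, :].reshape(-1, Cin)
            dW[di, dj] = xs.T @ dzf
            dxp[:, di : di + H, dj : dj + Wd, :] += dz @ W[di, dj].T
    db = dzf.sum(0)
    dx = dxp[:, PAD : PAD + H, PAD : PAD + Wd, :]
    return dW, db, dx


class _ConvNet:
    """Forward/backward of the fixed conv-pool-fc stack (numpy)."""

    def __init__(self, rng, classes=3, channels=(16, 32, 64), fc_units=1024,
                 patch=PATCH):
        self.channels = channels
        self.patch = patch
        self.params = {}
        cin = 3
        for k, cout in enumerate(channels, 1):
            fan_in = 5 * 5 * cin
            self.params[f"W{k}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), (5, 5, cin, cout)
            ).astype(np.float32)
            self.params[f"b{k}"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        side = patch // 2 ** len(channels)
        flat = side * side * cin
        self.params["Wf"] = rng.normal(
            0, np.sqrt(2.0 / flat), (flat, fc_units)
        ).astype(np.float32)
        self.params["bf"] = np.zeros(fc_units, dtype=np.float32)
        self.params["Wo"] = rng.normal(
            0, np.sqrt(2.0 / fc_units), (fc_units, classes)
        ).astype(np.float32)
        self.params["bo"] = np.zeros(classes, dtype=np.float32)

    def forward(self, x, dropout_rng=None, p_drop=0.5):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache = {"x": x}
        h = x
        n = x.shape[0]
        for k, cout in enumerate(self.channels, 1):
            H = h.shape[1]
            z, xp = _conv_forward(h, self.params[f"W{k}"], self.params[f"b{k}"])
            r = np.maximum(z, 0.0)
            # 2x2 max pool, stride 2
            pooled = r.reshape(n, H // 2, 2, H // 2, 2, cout).max(axis=(2, 4))
            cache[f"xp{k}"] = xp
            cache[f"z{k}"] = z
            cache[f"r{k}"] = r
            cache[f"pooled{k}"] = pooled
            h = pooled
        flat = h.reshape(n, -1)
        zf = flat @ self.params["Wf"] + self.params["bf"]
        rf = np.maximum(zf, 0.0)
        if dropout_rng is not None:
            mask = (
                (dropout_rng.random(rf.shape) >= p_drop) / (1.0 - p_drop)
            ).astype(np.float32)
            rf = rf * mask
            cache["drop_mask"] = mask
        out = rf @ self.params["Wo"] + self.params["bo"]
        cache.update(flat=flat, zf=zf, rf=rf, out=out)
        return out, cache

    def backward(self, cache, dout):
        dout = dout.astype(np.float32)
        g = {}
        rf = cache["rf"]
        g["Wo"] = rf.T @ dout
        g["bo"] = dout.sum(0)
        drf = dout @ self.params["Wo"].T
        if "drop_mask" in cache:
            drf = drf * cache["drop_mask"]
        dzf = drf * (cache["zf"] > 0)
        g["Wf"] = cache["flat"].T @ dzf
        g["bf"] = dzf.sum(0)
        dflat = dzf @ self.params["Wf"].T
        h = cache[f"pooled{len(self.channels)}"]
        dh = dflat.reshape(h.shape)
        for k in range(len(self.channels), 0, -1):
            r = cache[f"r{k}"]
            n, H, _, cout = r.shape
            # window-major layout (n, h, w, 4, c) of the 2x2 pool windows
            r5 = (
                r.reshape(n, H // 2, 2, H // 2, 2, cout)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, H // 2, H // 2, 4, cout)
            )
            pooled = cache[f"pooled{k}"]
            # route gradient to the (first) argmax within each pool window
            is_max = r5 == pooled[:, :, :, None, :]
            first = np.cumsum(is_max, axis=3) == 1
            is_max = is_max & first
            dr5 = is_max * dh[:, :, :, None, :]
            dr = (
                dr5.reshape(n, H // 2, H // 2, 2, 2, cout)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, H, H, cout)
            )
            dz = dr * (cache[f"z{k}"] > 0)
            dW, db, dh = _conv_backward(
                cache[f"xp{k}"], self.params[f"W{k}"], dz
            )
            g[f"W{k}"] = dW
            g[f"b{k}"] = db
        return g


class TangleDetectorCNN(BaseEstimator, ClassifierMixin):
    """Sliding-window patch classifier for tangle density maps.

    Parameters
    ----------
    epochs, batch_size, lr, betas : Adam training configuration (the
        optimizer the network is trained with).
    dropout : dropout probability of the penultimate layer (training only).
    val_fraction : held-out fraction used to report ``val_accuracy_``.
    random_state : seed; training is deterministic given the seed.

    Attributes
    ----------
    net_ : the underlying parameter container.
    val_accuracy_ : held-out accuracy after training.
    classes_ : the integer class labels seen in fit.
    """

    def __init__(self, epochs: int = 12, batch_size: int = 16, lr: float = 1e-3,
                 betas=(0.9, 0.999), dropout: float = 0.5,
                 val_fraction: float = 0.2, random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.betas = betas
        self.dropout = dropout
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        """Train on patches X (n, 56, 56, 3) with integer labels y."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        yi = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, trn_idx = perm[:n_val], perm[n_val:]
        net = _ConvNet(rng, classes=len(self.classes_))
        m = {k: np.zeros_like(v) for k, v in net.params.items()}
        vv = {k: np.zeros_like(v) for k, v in net.params.items()}
        b1, b2 = self.betas
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(trn_idx)
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                xb, yb = X[idx], yi[idx]
                out, cache = net.forward(xb, dropout_rng=rng,
                                         p_drop=self.dropout)
                z = out - out.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                dout = p.copy()
                dout[np.arange(len(yb)), yb] -= 1.0
                dout /= len(yb)
                grads = net.backward(cache, dout)
                step += 1
                for k in net.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    vv[k] = b2 * vv[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    vh = vv[k] / (1 - b2**step)
                    net.params[k] -= self.lr * mh / (np.sqrt(vh) + 1e-8)
        self.net_ = net
        pred = self._predict_indices(X[val_idx])
        self.val_accuracy_ = float(np.mean(pred == yi[val_idx]))
        return self

    def _logits(self, X, chunk=64):
        outs = []
        for s in range(0, len(X), chunk):
            out, _ = self.net_.forward(np.asarray(X[s : s + chunk], float))
            outs.append(out)
        return np.concatenate(outs)

    def _predict_indices(self, X):
        return np.argmax(self._logits(X), axis=1)

    def predict_proba(self, X):
        z = self._logits(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self._predict_indices(X)]

    def save_weights(self, path):
        """Write trained parameters (plus the class labels) to an .npz."""
        if not hasattr(self, "net_"):
            raise AttributeError("detector is not fitted")
        np.savez_compressed(path, classes=self.classes_, **self.net_.params)

    @classmethod
    def load_weights(cls, path) -> "TangleDetectorCNN":
        data = np.load(path)
        det = cls()
        det.classes_ = data["classes"]
        net = _ConvNet(np.random.default_rng(0), classes=len(det.classes_))
        for k in net.params:
            net.params[k] = data[k]
        det.net_ = net
        return det

    # ------------------------------------------------------------------
    def sliding_window_density(self, image: np.ndarray, stride: int = 1,
                               chunk: int = 256):
        """Per-pixel class probabilities by scanning overlapping patches.

        ``image`` is (H, W, 3).  Returns ``(proba, offsets)`` where
        ``proba`` has shape (nh, nw, n_classes) on the stride lattice of
        valid patch centers, nh = floor((H - 56)/stride) + 1, and
        ``offsets`` gives the (row, col) image coordinates of lattice cell
        (0, 0) (a border of width 28 has no valid centers and is thereby
        marked missing).
        """
        img = np.asarray(image, dtype=float)
        if img.ndim == 2:
            img = np.repeat(img[..., None], 3, axis=2)
        H, W = img.shape[:2]
        if H < PATCH or W < PATCH:
            raise ValueError(f"image smaller than the {PATCH}-pixel patch")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        rows = np.arange(0, H - PATCH + 1, stride)
        cols = np.arange(0, W - PATCH + 1, stride)
        out = np.zeros((len(rows), len(cols), len(self.classes_)))
        batch, where = [], []
        for ri, r in enumerate(rows):
            for ci, c in enumerate(cols):
                batch.append(img[r : r + PATCH, c : c + PATCH])
                where.append((ri, ci))
                if len(batch) == chunk:
                    p = self.predict_proba(np.stack(batch))
                    for (a, b), pr in zip(where, p):
                        out[a, b] = pr
                    batch, where = [], []
        if batch:
            p = self.predict_proba(np.stack(batch))
            for (a, b), pr in zip(where, p):
                out[a, b] = pr
        return out, (PATCH // 2, PATCH // 2)


def train(dataset, seed: int = 0, epochs: int = 12) -> TangleDetectorCNN:
    """Train a detector on a PatchDataset; deterministic given the seed."""
    det = TangleDetectorCNN(epochs=epochs, random_state=seed)
    det.fit(dataset.patches, dataset.labels)
    return det


def sliding_window_density(image, detector: TangleDetectorCNN, stride: int = 1):
    return detector.sliding_window_density(image, stride=stride)
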