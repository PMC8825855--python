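"""Small seeded numpy neural networks used by the latent-embedding and odor
decoding stages.

Two architectures:

* :class:`MLPAutoencoder` — fully connected autoencoder with rectifier hidden
  layers, a linear 2-unit bottleneck, and a linear output, trained by
  mini-batch stochastic gradient descent with momentum to minimize mean
  squared reconstruction error.
* :class:`TetrodeCNN` — odor classifier whose 1-D convolution filters are
  applied to each tetrode's multivariate time series separately (LFP channel
  + per-unit spike counts on a common grid); rectified convolution features
  are time-averaged, concatenated across tetrodes, and passed through
  dropout-regularized dense layers to a softmax over odors. Trained with
  SGD + momentum and early stopping on a validation split.

Training is deterministic for a fixed seed under serial execution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MLPAutoencoder:
    def __init__(
        self,
        input_dim: int,
        encoder_widths: tuple[int, ...] = (500, 500),
        bottleneck: int = 2,
        lr: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 64,
        epochs: int = 200,
        clip_norm: float = 1.0,
        seed: int = 0,
    ) -> None:
        if bottleneck != 2:
            # the latent analyses are defined on a 2-D embedding
            raise ValueError("bottleneck must be 2")
        self.widths = [input_dim, *encoder_widths, bottleneck,
                       *encoder_widths[::-1], input_dim]
        self.bottleneck_layer = len(encoder_widths)  # index into weight list
        self.lr, self.momentum = lr, momentum
        self.batch_size, self.epochs = batch_size, epochs
        self.clip_norm = clip_norm
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.W = [
            rng.normal(0, np.sqrt(2.0 / a), size=(a, b))
            for a, b in zip(self.widths[:-1], self.widths[1:])
        ]
        self.b = [np.zeros(w.shape[1]) for w in self.W]
        self.loss_history: list[float] = []

    def _is_linear(self, layer: int) -> bool:
        # linear at the bottleneck and at the output
        return layer in (self.bottleneck_layer, len(self.W) - 1)

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            acts.append(z if self._is_linear(l) else _relu(z))
        return acts

    def fit(self, X: np.ndarray) -> "MLPAutoencoder":
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.seed + 1)
        vW = [np.zeros_like(w) for w in self.W]
        vb = [np.zeros_like(b) for b in self.b]
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for s in range(0, n, self.batch_size):
                xb = X[order[s:s + self.batch_size]]
                acts = self._forward(xb)
                err = acts[-1] - xb
                ep_loss += float((err**2).mean()) * xb.shape[0]
                g = 2 * err / xb.shape[0]  # mean over batch, sum over features
                gWs, gbs = [None] * len(self.W), [None] * len(self.b)
                for l in range(len(self.W) - 1, -1, -1):
                    if not self._is_linear(l):
                        g = g * (acts[l + 1] > 0)
                    gWs[l] = acts[l].T @ g
                    gbs[l] = g.sum(axis=0)
                    g = g @ self.W[l].T
                # global gradient-norm clipping keeps plain SGD+momentum
                # stable across input dimensionalities
                norm = np.sqrt(sum(float((gw**2).sum()) for gw in gWs)
                               + sum(float((gb**2).sum()) for gb in gbs))
                scale = min(1.0, self.clip_norm / (norm + 1e-12))
                for l in range(len(self.W)):
                    vW[l] = self.momentum * vW[l] - self.lr * scale * gWs[l]
                    vb[l] = self.momentum * vb[l] - self.lr * scale * gbs[l]
                    self.W[l] += vW[l]
                    self.b[l] += vb[l]
            loss = ep_loss / n
            if not np.isfinite(loss):
                raise RuntimeError("autoencoder diverged; reduce the learning rate")
            self.loss_history.append(loss)
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        acts = [np.asarray(X, dtype=float)]
        for l in range(self.bottleneck_layer + 1):
            z = acts[-1] @ self.W[l] + self.b[l]
            acts.append(z if self._is_linear(l) else _relu(z))
        return acts[-1]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def mse(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        return float(((self.reconstruct(X) - X) ** 2).mean())


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TetrodeCNN:
    """Tetrode-wise 1-D CNN odor decoder.

    ``inputs`` are a list (one entry per tetrode) of arrays
    (n_samples, n_channels_t, n_timesteps); convolution weights are not
    shared across tetrodes.
    """

    def __init__(
        self,
        channel_counts: list[int],
        n_timesteps: int,
        n_classes: int = 4,
        n_filters: int = 8,
        filter_width: int = 5,
        hidden: tuple[int, ...] = (64, 32),
        dropout: float = 0.5,
        lr: float = 0.05,
        momentum: float = 0.9,
        batch_size: int = 32,
        max_epochs: int = 300,
        val_fraction: float = 0.15,
        patience: int = 10,
        seed: int = 0,
    ) -> None:
        self.channel_counts = channel_counts
        self.T = n_timesteps
        self.K, self.Wd = n_filters, filter_width
        self.hidden, self.dropout = hidden, dropout
        self.lr, self.momentum = lr, momentum
        self.batch_size, self.max_epochs = batch_size, max_epochs
        self.val_fraction, self.patience = val_fraction, patience
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv_W = [
            rng.normal(0, np.sqrt(2.0 / (c * filter_width)), size=(n_filters, c * filter_width))
            for c in channel_counts
        ]
        self.conv_b = [np.zeros(n_filters) for _ in channel_counts]
        feat = n_filters * len(channel_counts)
        dims = [feat, *hidden, n_classes]
        self.W = [rng.normal(0, np.sqrt(2.0 / a), size=(a, b))
                  for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(d) for d in dims[1:]]
        self.n_classes = n_classes

    # ---- forward pieces -------------------------------------------------
    def _cols(self, x: np.ndarray) -> np.ndarray:
        """(n, C, T) -> (n, C*Wd, P) sliding windows."""
        v = sliding_window_view(x, self.Wd, axis=2)  # (n, C, P, Wd)
        n, C, P, Wd = v.shape
        return v.transpose(0, 1, 3, 2).reshape(n, C * Wd, P)

    def _features(self, inputs: list[np.ndarray], cache: dict | None = None) -> np.ndarray:
        feats = []
        for t, x in enumerate(inputs):
            cols = self._cols(np.asarray(x, dtype=float))
            pre = np.einsum("kf,nfp->nkp", self.conv_W[t], cols) + self.conv_b[t][None, :, None]
            act = _relu(pre)
            feats.append(act.mean(axis=2))
            if cache is not None:
                cache.setdefault("cols", []).append(cols)
                cache.setdefault("pre", []).append(pre)
        return np.concatenate(feats, axis=1)

    def _dense(self, f: np.ndarray, drop_rng: np.random.Generator | None = None,
               cache: dict | None = None) -> np.ndarray:
        a = f
        if cache is not None:
            cache["acts"] = [a]
            cache["masks"] = []
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if l < len(self.W) - 1:
                a = _relu(z)
                if drop_rng is not None and self.dropout > 0:
                    m = (drop_rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                    a = a * m
                    if cache is not None:
                        cache["masks"].append(m)
                elif cache is not None:
                    cache["masks"].append(np.ones_like(a))
            else:
                a = z
            if cache is not None:
                cache["acts"].append(a)
        return a

    # ---- API ------------------------------------------------------------
    def fit(self, inputs: list[np.ndarray], labels: np.ndarray) -> "TetrodeCNN":
        y = np.asarray(labels)
        n = y.size
        if len(np.unique(y)) < 2:
            raise ValueError("need >= 2 classes to train")
        rng = np.random.default_rng(self.seed + 1)
        # stratified validation split for the early-stopping rule
        val_parts = []
        for c in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == c))
            val_parts.append(idx[: max(1, int(round(self.val_fraction * idx.size)))])
        val_idx = np.concatenate(val_parts)
        tr_idx = np.setdiff1d(np.arange(n), val_idx)
        n_val = val_idx.size
        Y = np.eye(self.n_classes)[y]

        vcW = [np.zeros_like(w) for w in self.conv_W]
        vcb = [np.zeros_like(b) for b in self.conv_b]
        vW = [np.zeros_like(w) for w in self.W]
        vb = [np.zeros_like(b) for b in self.b]
        best_val, best_state, since = np.inf, None, 0
        for _ in range(self.max_epochs):
            ep_order = tr_idx[rng.permutation(tr_idx.size)]
            for s in range(0, ep_order.size, self.batch_size):
                idx = ep_order[s:s + self.batch_size]
                xb = [x[idx] for x in inputs]
                cache: dict = {}
                f = self._features(xb, cache)
                logits = self._dense(f, drop_rng=rng, cache=cache)
                p = _softmax(logits)
                g = (p - Y[idx]) / idx.size
                # dense backward
                for l in range(len(self.W) - 1, -1, -1):
                    a_prev = cache["acts"][l]
                    gW = a_prev.T @ g
                    gb = g.sum(axis=0)
                    g = g @ self.W[l].T
                    if l > 0:
                        g = g * cache["masks"][l - 1] * (cache["acts"][l] > 0)
                    vW[l] = self.momentum * vW[l] - self.lr * gW
                    vb[l] = self.momentum * vb[l] - self.lr * gb
                    self.W[l] += vW[l]
                    self.b[l] += vb[l]
                # conv backward: g is gradient w.r.t. concatenated features
                off = 0
                for t in range(len(inputs)):
                    gt = g[:, off:off + self.K]
                    off += self.K
                    pre = cache["pre"][t]
                    P = pre.shape[2]
                    dpre = (pre > 0) * gt[:, :, None] / P
                    gcW = np.einsum("nkp,nfp->kf", dpre, cache["cols"][t])
                    gcb = dpre.sum(axis=(0, 2))
                    vcW[t] = self.momentum * vcW[t] - self.lr * gcW
                    vcb[t] = self.momentum * vcb[t] - self.lr * gcb
                    self.conv_W[t] += vcW[t]
                    self.conv_b[t] += vcb[t]
            val_p = self.predict_proba([x[val_idx] for x in inputs])
            val_loss = -float(np.mean(np.log(val_p[np.arange(n_val), y[val_idx]] + 1e-12)))
            if not np.isfinite(val_loss):
                raise RuntimeError("CNN diverged; reduce the learning rate")
            if val_loss < best_val - 1e-5:
                best_val, since = val_loss, 0
                best_state = ([w.copy() for w in self.conv_W], [b.copy() for b in self.conv_b],
                              [w.copy() for w in self.W], [b.copy() for b in self.b])
            else:
                since += 1
                if since >= self.patience:
                    break
        if best_state is not None:
            self.conv_W, self.conv_b, self.W, self.b = best_state
        return self

    def predict_proba(self, inputs: list[np.ndarray]) -> np.ndarray:
        return _softmax(self._dense(self._features(inputs)))

    def latent(self, inputs: list[np.ndarray]) -> np.ndarray:
        """Activations of the hidden layer feeding the output (the supervised
        latent space)."""
        a = self._features(inputs)
        for l in range(len(self.W) - 1):
            a = _relu(a @ self.W[l] + self.b[l])
        return a
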