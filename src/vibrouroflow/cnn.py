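"""A compact convolutional network for spectrogram classification, in numpy.

Three 3x3 conv blocks (batch-norm, ReLU, 2x2 max-pool) followed by global
average pooling, one dense hidden layer with dropout, and a softmax output,
trained with Adam on cross-entropy. Sized for CPU-minutes training on small
biomedical cohorts; fully deterministic given its seed.

The implementation is deliberately self-contained: forward/backward passes
are written against numpy's matmul (im2col convolutions), so the classifier
has no deep-learning framework dependency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CnnClassifier"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class _Conv:
    def __init__(self, cin, cout, rng, needs_input_grad=True):
        scale = np.sqrt(2.0 / (cin * 9))
        self.w = (rng.standard_normal((cin * 9, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.needs_input_grad = needs_input_grad

    def forward(self, x, train):
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = (cols @ self.w + self.b).reshape(n, h, w, self.cout)
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if not self.needs_input_grad:
            self._cols = None
            return None
        # input gradient = convolution of dout with the rotated kernels
        wk = self.w.reshape(self.cin, 3, 3, self.cout)
        wback = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.cout * 9, self.cin)
        cols_b = _im2col(dout)
        dx = (cols_b @ wback).reshape(n, h, w, self.cin)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm:
    def __init__(self, c):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mu = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = 1e-5, 0.1

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if getattr(self, "_calibrating", False):
                self._cal_mu.append(mu)
                self._cal_var.append(var)
            else:
                self.run_mu += self.momentum * (mu - self.run_mu)
                self.run_var += self.momentum * (var - self.run_var)
        else:
            mu, var = self.run_mu, self.run_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * ivstd[:, None, None]
        if train:
            self._xhat, self._ivstd = xhat, ivstd
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dout):
        xhat, ivstd = self._xhat, self._ivstd
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[:, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        self._xhat = None
        return dx * ivstd[:, None, None]

    def begin_calibration(self):
        self._calibrating = True
        self._cal_mu, self._cal_var = [], []

    def end_calibration(self):
        mus = np.stack(self._cal_mu)
        # law of total variance across calibration batches
        self.run_mu = mus.mean(axis=0)
        self.run_var = (np.stack(self._cal_var).mean(axis=0)
                        + mus.var(axis=0))
        self._calibrating = False
        self._cal_mu = self._cal_var = None

    def params(self):
        return [("gamma", self), ("beta", self)]


class _MaxPool:
    def forward(self, x, train):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        win = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        grad = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(grad, self._idx[..., None], dout[..., None], axis=-1)
        grad = grad.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = grad.reshape(n, c, h2 * 2, w2 * 2)
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, din, dout, rng):
        scale = np.sqrt(2.0 / din)
        self.w = (rng.standard_normal((din, dout)) * scale).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class CnnClassifier:
    """Small deterministic CNN for fixed-size spectrogram inputs.

    Parameters mirror common training hyperparameters; inputs to
    :meth:`fit`/:meth:`predict` are arrays of shape ``(n, frames, coeffs)``.
    Per-coefficient standardization statistics are estimated on the training
    set inside :meth:`fit` and re-applied at prediction time.
    """

    def __init__(self, n_classes: int = 6, channels=(8, 16, 32),
                 dense_units: int = 64, dropout: float = 0.3,
                 learning_rate: float = 1e-3, epochs: int = 30,
                 batch_size: int = 16, seed: int = 0,
                 lr_decay: str = "cosine", augment_shift: bool = True,
                 use_delta_channel: bool = True):
        self.n_classes = n_classes
        self.channels = tuple(channels)
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        if lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")
        self.lr_decay = lr_decay
        self.augment_shift = augment_shift
        self.use_delta_channel = use_delta_channel
        self._rng = np.random.default_rng(seed)
        self._built = False
        self.history_: list[float] = []

    # -- construction ---------------------------------------------------------

    def _build(self):
        rng = self._rng
        self.blocks = []
        cin = 2 if self.use_delta_channel else 1
        for i, cout in enumerate(self.channels):
            conv = _Conv(cin, cout, rng, needs_input_grad=(i > 0))
            self.blocks.append((conv, _BatchNorm(cout), _MaxPool()))
            cin = cout
        # average pooling summarizes sustained structure; max pooling keeps
        # localized events (intra-void pauses, dips) from washing out
        self.fc1 = _Dense(2 * cin, self.dense_units, rng)
        self.fc2 = _Dense(self.dense_units, self.n_classes, rng)
        self._adam_state = {}
        self._adam_t = 0
        self._built = True

    def _layers(self):
        out = []
        for conv, bn, pool in self.blocks:
            out += [conv, bn, pool]
        out += [self.fc1, self.fc2]
        return out

    # -- forward / backward ---------------------------------------------------

    def _channels(self, x):
        """(n, T, F) standardized input -> (n, C, T, F) network input.

        The optional second channel carries central-difference deltas along
        time (rescaled to unit variance on the training set): temporal
        modulation — oscillating vs smooth envelopes — becomes a first-layer
        feature instead of something the network must differentiate itself.
        """
        if not self.use_delta_channel:
            return x[:, None, :, :]
        d = np.zeros_like(x)
        d[:, 1:-1] = (x[:, 2:] - x[:, :-2]) * 0.5
        return np.stack([x, d / self._dscale], axis=1)

    def _forward(self, x, train):
        h = x
        for conv, bn, pool in self.blocks:
            a = bn.forward(conv.forward(h, train), train)
            if train:
                bn._relu_mask = a > 0
            h = pool.forward(np.maximum(a, 0.0), train)
        feat = self._pool_head(h, train)
        z1 = self.fc1.forward(feat, train)
        a1 = np.maximum(z1, 0.0)
        if train:
            self._a1_mask = z1 > 0
            if self.dropout > 0:
                self._drop = (self._rng.random(a1.shape) >= self.dropout) / (1.0 - self.dropout)
                a1 = a1 * self._drop
        logits = self.fc2.forward(a1, train)
        return logits

    def _pool_head(self, h, train):
        n, c, hh, ww = h.shape
        flat = h.reshape(n, c, hh * ww)
        gap = flat.mean(axis=-1)
        idx = flat.argmax(axis=-1)
        gmp = np.take_along_axis(flat, idx[:, :, None], axis=-1)[:, :, 0]
        if train:
            self._head_shape, self._gmp_idx = h.shape, idx
        return np.concatenate([gap, gmp], axis=1)

    def _backward(self, dlogits):
        da1 = self.fc2.backward(dlogits)
        if self.dropout > 0:
            da1 = da1 * self._drop
        dfeat = self.fc1.backward(da1 * self._a1_mask)
        n, c, hh, ww = self._head_shape
        dgap, dgmp = dfeat[:, :c], dfeat[:, c:]
        dflat = np.broadcast_to(dgap[:, :, None] / (hh * ww),
                                (n, c, hh * ww)).copy()
        np.put_along_axis(
            dflat, self._gmp_idx[:, :, None],
            np.take_along_axis(dflat, self._gmp_idx[:, :, None], axis=-1)
            + dgmp[:, :, None], axis=-1)
        dh = dflat.reshape(n, c, hh, ww).astype(np.float32)
        for conv, bn, pool in reversed(self.blocks):
            dpre = pool.backward(dh)
            dpre = dpre * bn._relu_mask
            dh = conv.backward(bn.backward(dpre))
        return dh

    def _adam_step(self, lr):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for layer in self._layers():
            for name, obj in layer.params():
                g = getattr(obj, "d" + name).astype(np.float32)
                key = (id(obj), name)
                m, v = self._adam_state.get(key, (np.zeros_like(g), np.zeros_like(g)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - b1 ** t)
                vhat = v / (1 - b2 ** t)
                p = getattr(obj, name)
                setattr(obj, name, p - lr * mhat / (np.sqrt(vhat) + eps))

    # -- public API -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CnnClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("X must be (n, frames, coeffs)")
        if np.unique(y).size < 2:
            raise ValueError("training data must contain at least two classes")
        self._mu = X.mean(axis=(0, 1))
        self._sd = X.std(axis=(0, 1)) + 1e-8
        Xs = (X - self._mu) / self._sd
        if self.use_delta_channel:
            d = (Xs[:, 2:] - Xs[:, :-2]) * 0.5
            self._dscale = d.std(axis=(0, 1)) + 1e-8
        if not self._built:
            self._build()
        n = Xs.shape[0]
        if self.augment_shift:
            # random time shifts are label-preserving because the canvas is
            # mostly silence; never shift content past the canvas end
            c0 = X[:, :, 0]
            floor = np.percentile(c0, 5, axis=1, keepdims=True)
            peak = c0.max(axis=1, keepdims=True)
            act = c0 > floor + 0.05 * (peak - floor)
            ends = np.where(act.any(axis=1),
                            Xs.shape[1] - 1 - np.argmax(act[:, ::-1], axis=1),
                            Xs.shape[1] - 1)
            max_shift = np.maximum(Xs.shape[1] - 1 - ends, 0)
        for epoch in range(self.epochs):
            if self.lr_decay == "cosine":
                lr = self.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / self.epochs))
            else:
                lr = self.learning_rate
            perm = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                xb, yb = Xs[idx], y[idx]
                if self.augment_shift:
                    shifts = (self._rng.random(idx.size)
                              * (max_shift[idx] + 1)).astype(int)
                    tgrid = (np.arange(Xs.shape[1])[None, :]
                             - shifts[:, None]) % Xs.shape[1]
                    xb = xb[np.arange(idx.size)[:, None], tgrid, :]
                logits = self._forward(self._channels(xb), train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                expl = np.exp(logits)
                p = expl / expl.sum(axis=1, keepdims=True)
                losses.append(float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12))))
                dlogits = p.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                self._backward((dlogits / len(yb)).astype(np.float32))
                self._adam_step(lr)
            self.history_.append(float(np.mean(losses)))
        self._calibrate_bn(Xs)
        return self

    def _calibrate_bn(self, Xs):
        """Replace BN running statistics with population statistics over the
        training set (small-batch running averages are noticeably biased)."""
        for _, bn, _ in self.blocks:
            bn.begin_calibration()
        for start in range(0, Xs.shape[0], 64):
            h = self._channels(Xs[start:start + 64])
            for conv, bn, pool in self.blocks:
                h = pool.forward(np.maximum(bn.forward(conv.forward(h, False), True), 0.0), False)
        for _, bn, _ in self.blocks:
            bn.end_calibration()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        Xs = (X - self._mu) / self._sd
        out = []
        for start in range(0, Xs.shape[0], 64):
            logits = self._forward(self._channels(Xs[start:start + 64]),
                                   train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (for embedding/visualization)."""
        X = np.asarray(X, dtype=np.float32)
        Xs = (X - self._mu) / self._sd
        out = []
        for start in range(0, Xs.shape[0], 64):
            h = self._channels(Xs[start:start + 64])
            for conv, bn, pool in self.blocks:
                h = pool.forward(np.maximum(bn.forward(conv.forward(h, False), False), 0.0), False)
            feat = self._pool_head(h, False)
            out.append(np.maximum(self.fc1.forward(feat, False), 0.0))
        return np.concatenate(out, axis=0)
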