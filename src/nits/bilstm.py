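"""Bidirectional LSTM sequence classifier in plain numpy.

A compact, dependency-free recurrent classifier used for the speech
sequence experiment: stacked bidirectional LSTM layers, mean pooling over
time, and a softmax output layer, trained with RMSProp on mini-batches
with per-epoch shuffling and a piecewise learning-rate schedule.  All
randomness flows from an explicit seed, so training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class _LSTMDirection:
    """One direction of one LSTM layer; gate order [i, f, g, o]."""

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray

    @classmethod
    def init(cls, d_in: int, hidden: int, rng: np.random.Generator) -> "_LSTMDirection":
        s = 1.0 / np.sqrt(d_in + hidden)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        return cls(
            Wx=rng.uniform(-s, s, size=(d_in, 4 * hidden)),
            Wh=rng.uniform(-s, s, size=(hidden, 4 * hidden)),
            b=b,
        )

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (T, B, D) -> H: (T, B, hidden), plus cache for backprop."""
        T, B, _ = X.shape
        hdim = self.Wh.shape[0]
        h = np.zeros((B, hdim))
        c = np.zeros((B, hdim))
        Hs = np.empty((T, B, hdim))
        cache = []
        for t in range(T):
            z = X[t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((X[t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            Hs[t] = h
        return Hs, cache

    def backward(self, dH: np.ndarray, cache: list):
        """dH: (T, B, hidden) gradient on outputs -> (dX, grads)."""
        T, B, hdim = dH.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((T, B, self.Wx.shape[0]))
        dh_next = np.zeros((B, hdim))
        dc_next = np.zeros((B, hdim))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = dH[t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dX, (dWx, dWh, db)

    def params(self):
        return [self.Wx, self.Wh, self.b]


@dataclass
class BiLSTMConfig:
    """Training configuration for the sequence classifier."""

    hidden: int = 100
    n_layers: int = 2
    max_epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 5  # epochs between piecewise LR drops
    rho: float = 0.9  # RMSProp decay
    eps: float = 1e-8
    seed: int = 0


class BiLSTMClassifier:
    """Stacked bidirectional LSTM + mean-pool + softmax, trained by RMSProp."""

    def __init__(self, config: BiLSTMConfig | None = None, **overrides):
        cfg = config or BiLSTMConfig()
        for k, v in overrides.items():
            setattr(cfg, k, v)
        self.config = cfg
        self.classes_: np.ndarray | None = None
        self._layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        self._Wout: np.ndarray | None = None
        self._bout: np.ndarray | None = None

    # -- architecture -------------------------------------------------
    def _build(self, d_in: int, n_classes: int, rng: np.random.Generator) -> None:
        cfg = self.config
        self._layers = []
        d = d_in
        for _ in range(cfg.n_layers):
            fwd = _LSTMDirection.init(d, cfg.hidden, rng)
            bwd = _LSTMDirection.init(d, cfg.hidden, rng)
            self._layers.append((fwd, bwd))
            d = 2 * cfg.hidden
        s = 1.0 / np.sqrt(d)
        self._Wout = rng.uniform(-s, s, size=(d, n_classes))
        self._bout = np.zeros(n_classes)

    def _forward(self, X: np.ndarray):
        caches = []
        cur = X
        for fwd, bwd in self._layers:
            Hf, cf = fwd.forward(cur)
            Hb, cb = bwd.forward(cur[::-1])
            cur = np.concatenate([Hf, Hb[::-1]], axis=2)
            caches.append((cf, cb))
        pooled = cur.mean(axis=0)  # (B, 2*hidden)
        logits = pooled @ self._Wout + self._bout
        return cur, pooled, logits, caches

    def _all_params(self):
        ps = []
        for fwd, bwd in self._layers:
            ps += fwd.params() + bwd.params()
        ps += [self._Wout, self._bout]
        return ps

    # -- training -----------------------------------------------------
    def fit(self, sequences: list[np.ndarray], y) -> "BiLSTMClassifier":
        """Fit on a list of (T_i, D) float sequences with integer labels."""
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training needs at least two classes")
        yi = np.searchsorted(self.classes_, y)
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
        d_in = seqs[0].shape[1]
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._build(d_in, len(self.classes_), rng)
        params = self._all_params()
        caches_rms = [np.zeros_like(p) for p in params]
        n = len(seqs)
        lr = cfg.learning_rate
        for epoch in range(cfg.max_epochs):
            if epoch > 0 and epoch % cfg.lr_drop_period == 0:
                lr *= cfg.lr_drop_factor
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                grads = [np.zeros_like(p) for p in params]
                # group equal-length sequences so each group runs batched
                by_len: dict[int, list[int]] = {}
                for k in idx:
                    by_len.setdefault(seqs[k].shape[0], []).append(k)
                for T, ks in by_len.items():
                    X = np.stack([seqs[k] for k in ks], axis=1)  # (T, B, D)
                    yb = yi[ks]
                    g = self._batch_grads(X, yb)
                    for acc, gi in zip(grads, g):
                        acc += gi * (len(ks) / len(idx))
                for p, cch, g in zip(params, caches_rms, grads):
                    cch *= cfg.rho
                    cch += (1.0 - cfg.rho) * g * g
                    p -= lr * g / (np.sqrt(cch) + cfg.eps)
        return self

    def _batch_grads(self, X: np.ndarray, yb: np.ndarray):
        T, B, _ = X.shape
        cur, pooled, logits, caches = self._forward(X)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        dlogits = p.copy()
        dlogits[np.arange(B), yb] -= 1.0
        dlogits /= B
        dWout = pooled.T @ dlogits
        dbout = dlogits.sum(axis=0)
        dpooled = dlogits @ self._Wout.T
        dcur = np.broadcast_to(dpooled / T, (T, B, dpooled.shape[1])).copy()
        layer_grads = []
        for (fwd, bwd), (cf, cb) in zip(reversed(self._layers), reversed(caches)):
            h = fwd.Wh.shape[0]
            dHf = dcur[:, :, :h]
            dHb = dcur[:, :, h:][::-1]
            dXf, gf = fwd.backward(dHf, cf)
            dXb, gb = bwd.backward(dHb, cb)
            dcur = dXf + dXb[::-1]
            layer_grads.append((gf, gb))
        grads = []
        for gf, gb in reversed(layer_grads):
            grads += list(gf) + list(gb)
        grads += [dWout, dbout]
        return grads

    # -- inference ----------------------------------------------------
    def predict_proba(self, sequences: list[np.ndarray]) -> np.ndarray:
        out = np.empty((len(sequences), len(self.classes_)))
        for i, s in enumerate(sequences):
            X = np.atleast_2d(np.asarray(s, dtype=float))[:, None, :]
            _, _, logits, _ = self._forward(X)
            z = logits[0] - logits[0].max()
            p = np.exp(z)
            out[i] = p / p.sum()
        return out

    def predict(self, sequences: list[np.ndarray]) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(sequences), axis=1)]


class BiLSTMTabular(BaseEstimator, ClassifierMixin):
    """Adapter presenting the sequence model as a tabular classifier.

    Each feature vector is treated as a length-1 sequence, which reduces
    the recurrent layers to gated dense layers; used as the `lstm_seq`
    member of the tabular ensemble.
    """

    def __init__(self, **kwargs):
        self._kwargs = kwargs
        self._model: BiLSTMClassifier | None = None

    def get_params(self, deep: bool = False):  # sklearn-compat for clone()
        return dict(self._kwargs)

    def set_params(self, **params):
        self._kwargs.update(params)
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return self._model is not None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self._model = BiLSTMClassifier(**self._kwargs)
        self._model.fit([row[None, :] for row in X], y)
        self.classes_ = self._model.classes_
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return self._model.predict_proba([row[None, :] for row in X])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def majority_vote(labels: np.ndarray) -> int:
    """Modal label; ties broken toward the smaller label."""
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])
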