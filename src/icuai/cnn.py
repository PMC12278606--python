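"""1-D convolutional network on vital-sign windows.

Maps a five-channel window of 1-minute vitals ending at a landmark to the
probability of infection onset within the prediction horizon.  The network
is a sequence of blocks, each three hidden layers (convolution, max-pool,
dropout), followed by a flattened fully-connected sigmoid output; the
reference preset uses five blocks.  Implemented directly on numpy
(im2col convolutions, Adam, inverted dropout, class-weighted binary
cross-entropy); training is fully seeded and deterministic.

Hyperparameters are selected by mean validation AUC over patient-grouped
5-fold cross-validation, then the winning configuration is refit on all
training data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .cohort import VitalStream
from .config import CnnConfig, VITAL_CHANNELS


@dataclass
class VitalWindow:
    admission_id: str
    series_id: int
    t_lm: float
    values: np.ndarray  # (5, T)
    gap_mask: np.ndarray  # (5, T) True where the original minute was missing


def extract_window(stream: VitalStream, t_lm: float, window_minutes: int,
                   series_id: int = 0) -> VitalWindow:
    """The vital-sign window [t_lm - window_minutes, t_lm).

    Gap policy: interior gaps of at most 5 minutes are linearly
    interpolated, longer gaps carry the last value forward, and leading
    gaps are filled with the channel's observed median in the window
    (falling back to the stream median).  The mask records the original
    missingness.
    """
    if stream.values.shape[1] != len(VITAL_CHANNELS):
        raise ValueError("stream is missing a vital channel")
    end = int(round(t_lm * 60.0))
    start = end - int(window_minutes)
    lo = max(start, 0)
    seg = stream.values[lo:min(end, stream.n_minutes)]
    T = int(window_minutes)
    values = np.full((len(VITAL_CHANNELS), T), np.nan)
    if len(seg):
        values[:, lo - start : lo - start + len(seg)] = seg.T
    mask = np.isnan(values)
    for c in range(values.shape[0]):
        values[c] = _fill_channel(values[c], mask[c], stream.values[:, c])
    return VitalWindow(stream.admission_id, series_id, t_lm, values, mask)


def _fill_channel(x: np.ndarray, miss: np.ndarray, full_stream: np.ndarray) -> np.ndarray:
    if not miss.any():
        return x
    obs = np.nonzero(~miss)[0]
    if len(obs) == 0:
        med = np.nanmedian(full_stream)
        return np.full_like(x, med if np.isfinite(med) else 0.0)
    out = x.copy()
    # leading gap: channel baseline median of the window
    base = np.median(x[obs])
    if obs[0] > 0:
        out[: obs[0]] = base
    # interior gaps: <=5 min linear interpolation, else carry forward
    jumps = np.nonzero(np.diff(obs) > 1)[0]
    for j in jumps:
        a, b = obs[j], obs[j + 1]
        gap = b - a - 1
        if gap <= 5:
            out[a + 1 : b] = np.interp(np.arange(a + 1, b), [a, b], [x[a], x[b]])
        else:
            out[a + 1 : b] = x[a]
    if obs[-1] < len(x) - 1:
        out[obs[-1] + 1 :] = x[obs[-1]]
    return out


# ---------------------------------------------------------------------------
# network layers (numpy, im2col)


def _conv_forward(x, W, b):
    """Same-padding 1-D convolution. x: (N, C, T), W: (F, C, K) -> (N, F, T)."""
    N, C, T = x.shape
    F, _, K = W.shape
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (N, C, T, K)
    cols = cols.transpose(0, 2, 1, 3).reshape(N * T, C * K)
    out = cols @ W.reshape(F, C * K).T + b
    return out.reshape(N, T, F).transpose(0, 2, 1), cols


def _conv_backward(dout, cols, x_shape, W):
    N, C, T = x_shape
    F, _, K = W.shape
    dmat = dout.transpose(0, 2, 1).reshape(N * T, F)
    dW = (dmat.T @ cols).reshape(F, C, K)
    db = dmat.sum(axis=0)
    # gradient w.r.t. input = same-padding convolution of dout with flipped,
    # transposed kernels
    Wt = W[:, :, ::-1].transpose(1, 0, 2)  # (C, F, K)
    dx, _ = _conv_forward(dout, Wt, np.zeros(C))
    return dx, dW, db


def _pool_forward(x, size):
    N, F, T = x.shape
    Tp = T // size
    xr = x[:, :, : Tp * size].reshape(N, F, Tp, size)
    am = xr.argmax(axis=3)
    return xr.max(axis=3), (am, T, Tp, size)


def _pool_backward(dout, cache, x_shape):
    am, T, Tp, size = cache
    N, F, _ = x_shape
    dx = np.zeros((N, F, T))
    n, f, t = np.meshgrid(np.arange(N), np.arange(F), np.arange(Tp), indexing="ij")
    dx[n, f, t * size + am] = dout
    return dx


class CnnNet:
    """Parameter container with forward/backward passes."""

    def __init__(self, config: CnnConfig, n_channels: int, rng: np.random.Generator):
        self.config = config
        self.params = {}
        c_in, t = n_channels, config.window_minutes
        for i, f in enumerate(config.filters):
            scale = math.sqrt(2.0 / (c_in * config.kernel_size))
            self.params[f"W{i}"] = rng.normal(0, scale, (f, c_in, config.kernel_size))
            self.params[f"b{i}"] = np.zeros(f)
            c_in, t = f, t // config.pool_size
        self.flat_dim = c_in * t
        self.params["Wd"] = rng.normal(0, math.sqrt(1.0 / self.flat_dim), self.flat_dim)
        self.params["bd"] = np.zeros(1)

    def forward(self, x, rng: Optional[np.random.Generator] = None):
        """Returns logits; caches intermediates when training (rng given)."""
        cfg = self.config
        caches = []
        for i in range(cfg.n_blocks):
            out, cols = _conv_forward(x, self.params[f"W{i}"], self.params[f"b{i}"])
            relu_mask = out > 0
            out = out * relu_mask
            pooled, pcache = _pool_forward(out, cfg.pool_size)
            if rng is not None and cfg.dropout > 0:
                keep = rng.random(pooled.shape) >= cfg.dropout
                pooled = pooled * keep / (1.0 - cfg.dropout)
            else:
                keep = None
            caches.append((x.shape, cols, relu_mask, pcache, out.shape, keep))
            x = pooled
        flat = x.reshape(x.shape[0], -1)
        logits = flat @ self.params["Wd"] + self.params["bd"][0]
        caches.append((flat, x.shape))
        self._caches = caches
        return logits

    def backward(self, dlogits):
        cfg = self.config
        grads = {}
        flat, xshape = self._caches[-1]
        grads["Wd"] = flat.T @ dlogits
        grads["bd"] = np.array([dlogits.sum()])
        dx = np.outer(dlogits, self.params["Wd"]).reshape(xshape)
        for i in range(cfg.n_blocks - 1, -1, -1):
            in_shape, cols, relu_mask, pcache, conv_shape, keep = self._caches[i]
            if keep is not None:
                dx = dx * keep / (1.0 - cfg.dropout)
            dx = _pool_backward(dx, pcache, conv_shape)
            dx = dx * relu_mask
            dx, grads[f"W{i}"], grads[f"b{i}"] = _conv_backward(
                dx, cols, in_shape, self.params[f"W{i}"]
            )
        return grads


@dataclass
class CnnModel:
    """Fitted network plus the preprocessing constants of its training fold."""

    net: CnnNet
    channel_mean: np.ndarray
    channel_sd: np.ndarray
    config: CnnConfig
    train_fingerprint: str = ""

    def scores(self, windows: np.ndarray, batch: int = 512) -> np.ndarray:
        """Probabilities in (0, 1) for an array of windows (N, 5, T)."""
        x = (windows - self.channel_mean[:, None]) / self.channel_sd[:, None]
        out = np.empty(len(x))
        for a in range(0, len(x), batch):
            logits = self.net.forward(x[a : a + batch], rng=None)
            out[a : a + batch] = 1.0 / (1.0 + np.exp(-logits))
        return out

    def score_window(self, window: VitalWindow) -> float:
        if window.values.shape[1] != self.config.window_minutes:
            raise ValueError(
                f"window length {window.values.shape[1]} != model "
                f"window_minutes {self.config.window_minutes}"
            )
        return float(self.scores(window.values[None]))

    def save(self, path) -> None:
        arrays = {k: v for k, v in self.net.params.items()}
        arrays["channel_mean"] = self.channel_mean
        arrays["channel_sd"] = self.channel_sd
        meta = json.dumps(
            {"config": self.config.to_dict(), "fingerprint": self.train_fingerprint}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CnnModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            config = CnnConfig.from_dict(meta["config"])
            net = CnnNet(config, n_channels=len(VITAL_CHANNELS), rng=np.random.default_rng(0))
            for k in net.params:
                net.params[k] = z[k]
            return cls(
                net=net,
                channel_mean=z["channel_mean"],
                channel_sd=z["channel_sd"],
                config=config,
                train_fingerprint=meta["fingerprint"],
            )


def _bce_grad(logits, y, weights):
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -np.mean(weights * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogits = weights * (p - y) / len(y)
    return loss, dlogits


def _fit_one(x, y, config: CnnConfig, seed: int, x_val=None, y_val=None) -> CnnNet:
    rng = np.random.default_rng(seed)
    net = CnnNet(config, n_channels=x.shape[1], rng=rng)
    if config.class_weighting:
        n1 = max(y.sum(), 1)
        n0 = max(len(y) - y.sum(), 1)
        w1, w0 = len(y) / (2.0 * n1), len(y) / (2.0 * n0)
    else:
        w1 = w0 = 1.0
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val, best_params, patience_left = np.inf, None, config.patience
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        for a in range(0, len(x), config.batch_size):
            idx = order[a : a + config.batch_size]
            logits = net.forward(x[idx], rng=rng)
            weights = np.where(y[idx] == 1, w1, w0)
            _, dlogits = _bce_grad(logits, y[idx], weights)
            grads = net.backward(dlogits)
            step += 1
            for k in net.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                net.params[k] -= config.learning_rate * mh / (np.sqrt(vh) + eps)
        if x_val is not None and len(x_val):
            logits = net.forward(x_val, rng=None)
            wv = np.where(y_val == 1, w1, w0)
            val_loss, _ = _bce_grad(logits, y_val, wv)
            if val_loss < best_val - 1e-5:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in net.params.items()}
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        net.params = best_params
    return net


def _standardize_stats(x):
    mean = x.mean(axis=(0, 2))
    sd = x.std(axis=(0, 2))
    sd[sd == 0] = 1.0
    return mean, sd


def fit_cnn(windows: np.ndarray, labels: np.ndarray, config: CnnConfig, seed: int = 0) -> CnnModel:
    """Fit one configuration directly (no hyperparameter selection).

    Used inside outer cross-validation folds where the configuration is
    already chosen; a seeded slice of the training windows serves for
    early stopping.
    """
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are single-class; cannot train")
    config.validate()
    mean, sd = _standardize_stats(windows)
    x = (windows - mean[:, None]) / sd[:, None]
    rng = np.random.default_rng(seed)
    val_n = max(int(config.val_fraction * len(x)), 1)
    perm = rng.permutation(len(x))
    va, tr = perm[:val_n], perm[val_n:]
    net = _fit_one(x[tr], labels[tr], config, seed=seed, x_val=x[va], y_val=labels[va])
    return CnnModel(net=net, channel_mean=mean, channel_sd=sd, config=config,
                    train_fingerprint=f"n={len(x)};seed={seed}")


def train_cnn(
    windows: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    grid: list,
    k: int = 5,
    seed: int = 0,
) -> tuple:
    """Select a configuration by k-fold mean AUC and refit on all data.

    ``windows``: (N, 5, T) arrays; ``labels``: binary infection-within-
    horizon; ``groups``: patient ids (folds never split a patient).
    Returns (CnnModel, selection report).  AUC ties break in grid order.
    """
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are single-class; cannot train")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    for cfg in grid:
        cfg.validate()
        if cfg.window_minutes != windows.shape[2]:
            raise ValueError("config window_minutes does not match window array")
    n_splits = min(k, len(np.unique(groups)))
    report = []
    for ci, cfg in enumerate(grid):
        aucs = []
        gkf = GroupKFold(n_splits=n_splits)
        for fi, (tr, va) in enumerate(gkf.split(windows, labels, groups)):
            if len(np.unique(labels[va])) < 2 or len(np.unique(labels[tr])) < 2:
                continue
            mean, sd = _standardize_stats(windows[tr])
            xtr = (windows[tr] - mean[:, None]) / sd[:, None]
            xva = (windows[va] - mean[:, None]) / sd[:, None]
            net = _fit_one(xtr, labels[tr], cfg, seed=seed * 1000 + ci * 10 + fi,
                           x_val=xva, y_val=labels[va])
            pva = 1.0 / (1.0 + np.exp(-net.forward(xva, rng=None)))
            aucs.append(roc_auc_score(labels[va], pva))
        report.append({"config": cfg.to_dict(), "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                       "fold_aucs": [float(a) for a in aucs]})
    best_i = int(np.nanargmax([r["mean_auc"] for r in report]))
    best_cfg = grid[best_i]
    mean, sd = _standardize_stats(windows)
    x = (windows - mean[:, None]) / sd[:, None]
    # refit on everything, holding out a seeded slice for early stopping
    rng = np.random.default_rng(seed)
    val_n = max(int(best_cfg.val_fraction * len(x)), 1)
    perm = rng.permutation(len(x))
    va, tr = perm[:val_n], perm[val_n:]
    net = _fit_one(x[tr], labels[tr], best_cfg, seed=seed, x_val=x[va], y_val=labels[va])
    fp = f"n={len(x)};groups={len(np.unique(groups))};seed={seed}"
    model = CnnModel(net=net, channel_mean=mean, channel_sd=sd, config=best_cfg,
                     train_fingerprint=fp)
    return model, {"selected": best_i, "report": report}
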