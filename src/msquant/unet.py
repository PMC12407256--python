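"""1-D U-net peak-region segmentation, implemented on numpy.

The network maps a length-400 intensity window to a per-point probability of
belonging to the peak region.  Encoder stages halve the length, decoder
stages double it, and skip connections concatenate matching-resolution
feature maps.  Forward, backward, and the Adam update are written out
explicitly so that training is deterministic given (data, config, seed) and
carries no framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .windows import WINDOW_LENGTH, LabelVector, PeakWindow, longest_run


class ConfigError(ValueError):
    """U-net configuration incompatible with the input length."""


class TrainingError(RuntimeError):
    """Training could not proceed (empty data, NaN loss, ...)."""


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    base_channels: int = 16
    kernel_size: int = 3
    pool_factor: int = 2
    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd (same-padding convolutions)")
        if self.base_channels < 1 or self.pool_factor < 2:
            raise ConfigError("base_channels >= 1 and pool_factor >= 2 required")

    def validate_length(self, length: int) -> None:
        if length % self.pool_factor ** self.depth != 0:
            raise ConfigError(
                f"input length {length} not divisible by "
                f"{self.pool_factor}^{self.depth}"
            )


# ---------------------------------------------------------------------------
# layer primitives (functional; caches returned to the caller)

def _conv1d_forward(x, W, b):
    """Same-padding 1-D convolution.  x: (N, C, L); W: (O, C, K); b: (O,)."""
    n, c, length = x.shape
    o, _, k = W.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N, C, L, K)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(n, length, c * k)
    out = cols2 @ W.reshape(o, c * k).T + b  # (N, L, O)
    return out.transpose(0, 2, 1), (cols2, x.shape, W.shape)


def _conv1d_backward(dout, W, cache):
    cols2, x_shape, w_shape = cache
    n, c, length = x_shape
    o, _, k = w_shape
    p = k // 2
    dout2 = dout.transpose(0, 2, 1)  # (N, L, O)
    dW = (dout2.reshape(-1, o).T @ cols2.reshape(-1, c * k)).reshape(o, c, k)
    db = dout.sum(axis=(0, 2))
    dcols2 = dout2 @ W.reshape(o, c * k)  # (N, L, C*K)
    dcols = dcols2.reshape(n, length, c, k).transpose(0, 2, 1, 3)  # (N, C, L, K)
    dxp = np.zeros((n, c, length + 2 * p), dtype=dout.dtype)
    for j in range(k):
        dxp[:, :, j: j + length] += dcols[:, :, :, j]
    return dxp[:, :, p: p + length], dW, db


def _maxpool_forward(x, factor):
    n, c, length = x.shape
    xr = x.reshape(n, c, length // factor, factor)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), (idx, x.shape, factor)


def _maxpool_backward(dout, cache):
    idx, x_shape, factor = cache
    n, c, length = x_shape
    dxr = np.zeros((n, c, length // factor, factor), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    return dxr.reshape(n, c, length)


def _upsample_forward(x, factor):
    return np.repeat(x, factor, axis=2), (x.shape, factor)


def _upsample_backward(dout, cache):
    x_shape, factor = cache
    n, c, length = x_shape
    return dout.reshape(n, c, length, factor).sum(axis=3)


# ---------------------------------------------------------------------------
# model

class UNet1D:
    """Encoder-decoder segmentation network with skip connections.

    Channel plan for depth d with base channels c: encoder stages use
    c, 2c, ..., 2^(d-1)c; the bottleneck 2^d c; each decoder stage halves the
    channel count back down after concatenating its skip.
    """

    def __init__(self, cfg: UNetConfig, input_length: int = WINDOW_LENGTH):
        cfg.validate_length(input_length)
        self.cfg = cfg
        self.input_length = input_length
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self._adam_state = None
        self.trained = False

    # -- construction ------------------------------------------------------
    def _add_conv(self, rng, name, c_in, c_out, k):
        scale = np.sqrt(2.0 / (c_in * k))  # He initialization for ReLU
        # float32 throughout the network: halves BLAS time on one CPU
        self.params[f"{name}_W"] = rng.normal(
            0.0, scale, size=(c_out, c_in, k)
        ).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    def _init_params(self):
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel_size
        c_in = 1
        for i in range(cfg.depth):
            c = cfg.base_channels * 2 ** i
            self._add_conv(rng, f"enc{i}_a", c_in, c, k)
            self._add_conv(rng, f"enc{i}_b", c, c, k)
            c_in = c
        c_bott = cfg.base_channels * 2 ** cfg.depth
        self._add_conv(rng, "bott_a", c_in, c_bott, k)
        self._add_conv(rng, "bott_b", c_bott, c_bott, k)
        c_in = c_bott
        for i in reversed(range(cfg.depth)):
            c_skip = cfg.base_channels * 2 ** i
            self._add_conv(rng, f"dec{i}_a", c_in + c_skip, c_skip, k)
            self._add_conv(rng, f"dec{i}_b", c_skip, c_skip, k)
            c_in = c_skip
        self._add_conv(rng, "out", c_in, 1, 1)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------
    def _conv_relu(self, x, name, caches):
        z, cache = _conv1d_forward(x, self.params[f"{name}_W"], self.params[f"{name}_b"])
        a = np.maximum(z, 0.0)
        caches[name] = (cache, z > 0)
        return a

    def forward_logits(self, x: np.ndarray, caches: dict | None = None):
        """x: (N, 400) raw or normalized windows -> logits (N, 400)."""
        cfg = self.cfg
        store = caches if caches is not None else {}
        h = np.asarray(x, dtype=np.float32)[:, None, :]
        skips = []
        for i in range(cfg.depth):
            h = self._conv_relu(h, f"enc{i}_a", store)
            h = self._conv_relu(h, f"enc{i}_b", store)
            skips.append(h)
            h, store[f"pool{i}"] = _maxpool_forward(h, cfg.pool_factor)
        h = self._conv_relu(h, "bott_a", store)
        h = self._conv_relu(h, "bott_b", store)
        for i in reversed(range(cfg.depth)):
            h, store[f"up{i}"] = _upsample_forward(h, cfg.pool_factor)
            store[f"cat{i}"] = (h.shape[1], skips[i].shape[1])
            h = np.concatenate([h, skips[i]], axis=1)
            h = self._conv_relu(h, f"dec{i}_a", store)
            h = self._conv_relu(h, f"dec{i}_b", store)
        logits, store["out_cache"] = _conv1d_forward(
            h, self.params["out_W"], self.params["out_b"]
        )
        return logits[:, 0, :]

    def _conv_relu_backward(self, d, name, caches, grads):
        cache, relu_mask = caches[name]
        d = d * relu_mask
        dx, dW, db = _conv1d_backward(d, self.params[f"{name}_W"], cache)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
        return dx

    def backward(self, dlogits: np.ndarray, caches: dict) -> dict:
        cfg = self.cfg
        grads: dict[str, np.ndarray] = {}
        d = np.asarray(dlogits, dtype=np.float32)[:, None, :]
        d, grads["out_W"], grads["out_b"] = _conv1d_backward(
            d, self.params["out_W"], caches["out_cache"]
        )
        dskips = {}
        for i in range(cfg.depth):
            d = self._conv_relu_backward(d, f"dec{i}_b", caches, grads)
            d = self._conv_relu_backward(d, f"dec{i}_a", caches, grads)
            c_up, _ = caches[f"cat{i}"]
            dskips[i] = d[:, c_up:, :]
            d = _upsample_backward(d[:, :c_up, :], caches[f"up{i}"])
        d = self._conv_relu_backward(d, "bott_b", caches, grads)
        d = self._conv_relu_backward(d, "bott_a", caches, grads)
        for i in reversed(range(cfg.depth)):
            d = _maxpool_backward(d, caches[f"pool{i}"])
            d = d + dskips[i]
            d = self._conv_relu_backward(d, f"enc{i}_b", caches, grads)
            d = self._conv_relu_backward(d, f"enc{i}_a", caches, grads)
        return grads

    # -- prediction --------------------------------------------------------
    def predict_proba(self, windows: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Per-point peak probabilities for (N, 400) windows (raw intensities;
        per-window max normalization is applied internally)."""
        x = normalize_windows(np.atleast_2d(np.asarray(windows, dtype=float)))
        out = np.empty_like(x)
        for s in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[s: s + batch_size])
            out[s: s + batch_size] = expit(logits)
        return out

    # -- optimizer ---------------------------------------------------------
    def _adam_step(self, grads: dict, lr: float, t: int,
                   beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {
                k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()
            }
        for k, g in grads.items():
            m, v = self._adam_state[k]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, __config__=np.array([repr(asdict(self.cfg))]),
                 __trained__=np.array([int(self.trained)]), **self.params)

    @classmethod
    def load(cls, path) -> "UNet1D":
        import ast

        data = np.load(path, allow_pickle=False)
        cfg = UNetConfig(**ast.literal_eval(str(data["__config__"][0])))
        model = cls(cfg)
        for k in model.params:
            model.params[k] = data[k]
        model.trained = bool(int(data["__trained__"][0]))
        return model


def build_unet(cfg: UNetConfig, input_length: int = WINDOW_LENGTH) -> UNet1D:
    """Construct an untrained U-net; raises :class:`ConfigError` if the input
    length is not divisible by ``pool_factor ** depth``."""
    return UNet1D(cfg, input_length=input_length)


def normalize_windows(windows: np.ndarray) -> np.ndarray:
    """Per-window max scaling used for model input only; peak areas are always
    computed on raw intensities."""
    windows = np.asarray(windows, dtype=float)
    peak = np.abs(windows).max(axis=-1, keepdims=True)
    peak = np.where(peak > 0, peak, 1.0)
    return windows / peak


def _bce_from_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean per-point binary cross-entropy and its gradient w.r.t. logits."""
    n = logits.size
    loss = float(np.mean(np.logaddexp(0.0, logits) - targets * logits))
    return loss, (expit(logits) - targets) / n


@dataclass
class TrainResult:
    model: UNet1D
    loss_trace: list[float]


def train_model(
    model: UNet1D, windows: np.ndarray, labels: np.ndarray, cfg: UNetConfig | None = None
) -> TrainResult:
    """Train with per-point binary cross-entropy and Adam.

    ``windows``/``labels``: (N, 400) raw windows and 0/1 masks.  The epoch
    shuffle stream is seeded from ``cfg.seed`` so identical inputs give
    identical loss traces.
    """
    cfg = cfg or model.cfg
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if windows.ndim != 2 or windows.shape[0] == 0:
        raise TrainingError("training set is empty or misshaped")
    if windows.shape != labels.shape:
        raise TrainingError("windows and labels must have identical shapes")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise TrainingError("labels must be binary")
    x = normalize_windows(windows)
    rng = np.random.default_rng(cfg.seed + 1)  # distinct from the init stream
    n = x.shape[0]
    trace = []
    t = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s: s + cfg.batch_size]
            caches: dict = {}
            logits = model.forward_logits(x[idx], caches)
            loss, dlogits = _bce_from_logits(logits, labels[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at step {t}: {loss!r}; "
                    "lower the learning rate or check the inputs"
                )
            grads = model.backward(dlogits, caches)
            t += 1
            model._adam_step(grads, cfg.learning_rate, t)
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    model.trained = True
    return TrainResult(model=model, loss_trace=trace)


def predict_labels(
    model: UNet1D, window: PeakWindow | np.ndarray, threshold: float = 0.5
) -> LabelVector:
    """Binarize the network output at ``threshold`` and keep only the longest
    contiguous run of ones (leftmost on ties)."""
    if not getattr(model, "trained", False):
        raise TrainingError("model has not been trained")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    intensities = window.intensities if isinstance(window, PeakWindow) else window
    probs = model.predict_proba(np.asarray(intensities, dtype=float)[None, :])[0]
    return LabelVector(mask=longest_run(probs >= threshold))


def predict_masks(
    model: UNet1D, windows: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Batch version of :func:`predict_labels`; returns (N, 400) masks."""
    if not getattr(model, "trained", False):
        raise TrainingError("model has not been trained")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    probs = model.predict_proba(np.asarray(windows, dtype=float))
    return np.stack([longest_run(p >= threshold) for p in probs])
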