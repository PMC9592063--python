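"""Deep feed-forward regression of prosody targets from reduced features.

Four schemes share one architecture family and differ only in target
transform, optimizer defaults and the batch-norm flag:

==================  ======  ==========  ====================  ==========
scheme              lr      batch size  target transform      batch norm
==================  ======  ==========  ====================  ==========
single_f0           0.001   1024        ST re speaker mean    no
single_intensity    0.005   2048        dB SPL (raw)          no
multi_f0            0.001   1024        ST re 90 Hz           no
multi_intensity     0.0005  4096        per-speaker 0-1       yes (first)
==================  ======  ==========  ====================  ==========

Training is plain mini-batch Adam on MSE with early stopping on validation
loss; everything is implemented on numpy so runs are exactly reproducible
from the seed.  Predictions are returned in output units rounded to 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acoustics import hz_to_semitones, semitones_to_hz

__all__ = [
    "ModelConfig",
    "TargetTransform",
    "TrainedModel",
    "transform_targets",
    "train_model",
    "predict",
]

SCHEMES = ("single_f0", "single_intensity", "multi_f0", "multi_intensity")

_SCHEME_DEFAULTS: dict[str, dict] = {
    "single_f0": dict(
        learning_rate=0.001,
        batch_size=1024,
        hidden_layers=(512, 256, 128),
        batch_norm_first=False,
        target_transform="st_ref_speaker_mean",
    ),
    "single_intensity": dict(
        learning_rate=0.005,
        batch_size=2048,
        hidden_layers=(512, 256, 128),
        batch_norm_first=False,
        target_transform="spl_raw",
    ),
    "multi_f0": dict(
        learning_rate=0.001,
        batch_size=1024,
        hidden_layers=(1024, 512, 256, 128),
        batch_norm_first=False,
        target_transform="st_ref_90hz",
    ),
    "multi_intensity": dict(
        learning_rate=0.0005,
        batch_size=4096,
        hidden_layers=(1024, 512, 256, 128),
        batch_norm_first=True,
        target_transform="spl_normalized_0_1",
    ),
}

OUTPUT_RESOLUTION = 0.01


@dataclass(frozen=True)
class ModelConfig:
    scheme: str
    input_dim: int
    hidden_layers: tuple[int, ...]
    learning_rate: float
    batch_size: int
    batch_norm_first: bool
    target_transform: str
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    dtype: str = "float64"

    @staticmethod
    def for_scheme(scheme: str, input_dim: int, **overrides) -> "ModelConfig":
        if scheme not in _SCHEME_DEFAULTS:
            raise ValueError(f"unknown scheme {scheme!r}")
        kw = dict(_SCHEME_DEFAULTS[scheme])
        kw.update(overrides)
        kw["hidden_layers"] = tuple(kw["hidden_layers"])
        return ModelConfig(scheme=scheme, input_dim=input_dim, **kw)

    def with_(self, **overrides) -> "ModelConfig":
        return replace(self, **overrides)


@dataclass
class TargetTransform:
    """Maps raw targets (Hz or dB SPL) to the training space and back."""

    kind: str
    ref: float = np.nan  # speaker-mean or fixed Hz reference
    vmin: float = np.nan  # min-max bounds for 0-1 normalization
    vmax: float = np.nan

    @staticmethod
    def fit(kind: str, values: np.ndarray) -> "TargetTransform":
        v = np.asarray(values, dtype=np.float64)
        if kind == "st_ref_speaker_mean":
            return TargetTransform(kind, ref=float(np.mean(v)))
        if kind == "st_ref_90hz":
            return TargetTransform(kind, ref=90.0)
        if kind == "spl_raw":
            return TargetTransform(kind)
        if kind == "spl_normalized_0_1":
            lo, hi = float(np.min(v)), float(np.max(v))
            if hi <= lo:
                raise ValueError("degenerate intensity range (min == max)")
            return TargetTransform(kind, vmin=lo, vmax=hi)
        raise ValueError(f"unknown target transform {kind!r}")

    def forward(self, values):
        v = np.asarray(values, dtype=np.float64)
        if self.kind in ("st_ref_speaker_mean", "st_ref_90hz"):
            return hz_to_semitones(v, self.ref)
        if self.kind == "spl_raw":
            return v.copy()
        return (v - self.vmin) / (self.vmax - self.vmin)

    def inverse(self, values):
        v = np.asarray(values, dtype=np.float64)
        if self.kind in ("st_ref_speaker_mean", "st_ref_90hz"):
            return semitones_to_hz(v, self.ref)
        if self.kind == "spl_raw":
            return v.copy()
        return v * (self.vmax - self.vmin) + self.vmin

    @property
    def output_unit(self) -> str:
        if self.kind in ("st_ref_speaker_mean", "st_ref_90hz"):
            return "ST"
        if self.kind == "spl_raw":
            return "dB SPL"
        return "dB (normalized)"


def transform_targets(values, scheme: str, speaker_stats=None):
    """Convenience wrapper: fit the scheme's transform on ``speaker_stats``
    (or on ``values`` itself) and apply it.  Returns (transformed, tt)."""
    kind = _SCHEME_DEFAULTS[scheme]["target_transform"]
    tt = TargetTransform.fit(
        kind, np.asarray(values if speaker_stats is None else speaker_stats)
    )
    return tt.forward(values), tt


# ---------------------------------------------------------------------------
# network internals


def _gelu(z):
    from scipy.special import erf

    return 0.5 * z * (1.0 + erf(z / np.sqrt(2.0)))


def _gelu_grad(z):
    from scipy.special import erf

    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0))) + z * phi


class _Net:
    """Weights + optional first-layer batch norm, with manual backprop."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_layers, 1]
        dt = np.dtype(config.dtype)
        self.W = [
            (rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i]))
            .astype(dt)
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1], dtype=dt) for i in range(len(dims) - 1)]
        self.bn = config.batch_norm_first
        if self.bn:
            w = config.hidden_layers[0]
            self.gamma = np.ones(w, dtype=dt)
            self.beta = np.zeros(w, dtype=dt)
            self.run_mean = np.zeros(w, dtype=dt)
            self.run_var = np.ones(w, dtype=dt)

    def params(self):
        out = list(self.W) + list(self.b)
        if self.bn:
            out += [self.gamma, self.beta]
        return out

    def forward(self, X, training: bool):
        cache = {"h": [X], "z": [], "bn": None}
        h = X
        n_hidden = len(self.W) - 1
        for layer in range(n_hidden):
            z = h @ self.W[layer] + self.b[layer]
            if layer == 0 and self.bn:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean = (
                        (1 - self.BN_MOMENTUM) * self.run_mean + self.BN_MOMENTUM * mu
                    )
                    self.run_var = (
                        (1 - self.BN_MOMENTUM) * self.run_var + self.BN_MOMENTUM * var
                    )
                else:
                    mu, var = self.run_mean, self.run_var
                inv = 1.0 / np.sqrt(var + self.BN_EPS)
                zhat = (z - mu) * inv
                cache["bn"] = (zhat, inv)
                z = self.gamma * zhat + self.beta
            cache["z"].append(z)
            h = _gelu(z)
            cache["h"].append(h)
        out = h @ self.W[-1] + self.b[-1]
        return out[:, 0], cache

    def backward(self, cache, dout):
        """MSE gradient backprop; ``dout`` is dLoss/dprediction, shape (n,)."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        g = dout[:, None]
        grads_W[-1] = cache["h"][-1].T @ g
        grads_b[-1] = g.sum(axis=0)
        g = g @ self.W[-1].T
        n_hidden = len(self.W) - 1
        g_gamma = g_beta = None
        for layer in range(n_hidden - 1, -1, -1):
            z = cache["z"][layer]
            g = g * _gelu_grad(z)
            if layer == 0 and self.bn:
                zhat, inv = cache["bn"]
                g_beta = g.sum(axis=0)
                g_gamma = (g * zhat).sum(axis=0)
                n = g.shape[0]
                g = (
                    self.gamma
                    * inv
                    * (g - g.mean(axis=0) - zhat * (g * zhat).mean(axis=0))
                )
                del n
            grads_W[layer] = cache["h"][layer].T @ g
            grads_b[layer] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.W[layer].T
        out = grads_W + grads_b
        if self.bn:
            out += [g_gamma, g_beta]
        return out


@dataclass
class TrainedModel:
    config: ModelConfig
    net: _Net
    target_transform: TargetTransform
    feat_mean: np.ndarray
    feat_std: np.ndarray
    history: list[tuple[float, float]] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def output_unit(self) -> str:
        return self.target_transform.output_unit


def train_model(
    config: ModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> TrainedModel:
    """Mini-batch Adam on MSE with early stopping on validation loss.

    Targets are given in raw units (Hz for f0 schemes, dB SPL for intensity
    schemes); the scheme's transform is fit on the training targets.  The
    returned model carries the best-validation weights and the per-epoch
    (train, validation) loss history.
    """
    X_train = np.asarray(X_train, dtype=config.dtype)
    X_val = np.asarray(X_val, dtype=config.dtype)
    if X_train.shape[1] != config.input_dim:
        raise ValueError("input_dim does not match feature width")
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation sets must be nonempty")
    if config.max_epochs < 1:
        raise ValueError("max_epochs must be at least 1")

    tt = TargetTransform.fit(config.target_transform, y_train)
    ty_train = np.asarray(tt.forward(y_train), dtype=config.dtype)
    ty_val = np.asarray(tt.forward(y_val), dtype=config.dtype)

    feat_mean = X_train.mean(axis=0)
    feat_std = X_train.std(axis=0)
    feat_std = np.where(feat_std > 1e-12, feat_std, 1.0)
    Xt = (X_train - feat_mean) / feat_std
    Xv = (X_val - feat_mean) / feat_std

    net = _Net(config)
    # start the linear output at the target mean so un-centered targets
    # (raw dB SPL) do not waste epochs learning a large offset
    net.b[-1][:] = ty_train.mean()
    params = net.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(config.seed + 1)

    best_val = np.inf
    best_state = [p.copy() for p in params]
    best_bn = (net.run_mean.copy(), net.run_var.copy()) if net.bn else None
    best_epoch = 0
    history: list[tuple[float, float]] = []
    bad_epochs = 0
    n = Xt.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss_acc = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = Xt[idx], ty_train[idx]
            pred, cache = net.forward(xb, training=True)
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            train_loss_acc += loss * idx.size
            grads = net.backward(cache, (2.0 / idx.size) * resid)
            step += 1
            lr_t = (
                config.learning_rate
                * np.sqrt(1.0 - beta2**step)
                / (1.0 - beta1**step)
            )
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + eps)
        train_loss = train_loss_acc / n
        val_pred, _ = net.forward(Xv, training=False)
        val_loss = float(np.mean((val_pred - ty_val) ** 2))
        history.append((train_loss, val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.copy() for p in params]
            if net.bn:
                best_bn = (net.run_mean.copy(), net.run_var.copy())
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    for p, saved in zip(params, best_state):
        p[...] = saved
    if net.bn and best_bn is not None:
        net.run_mean, net.run_var = best_bn
    return TrainedModel(
        config=config,
        net=net,
        target_transform=tt,
        feat_mean=feat_mean,
        feat_std=feat_std,
        history=history,
        best_epoch=best_epoch,
    )


def predict(
    model: TrainedModel,
    features: np.ndarray,
    unit: str = "output",
) -> np.ndarray:
    """Forward pass with rounding to the 0.01 output resolution.

    ``unit="output"`` (default) returns values in the scheme's output unit
    (ST for f0 schemes, dB SPL or normalized dB for intensity schemes),
    rounded to the nearest 0.01.  ``unit="raw"`` additionally inverts the
    target transform (e.g. ST back to Hz, for contour overlays) after
    rounding.
    """
    X = np.asarray(features, dtype=model.config.dtype)
    if X.ndim != 2 or X.shape[1] != model.config.input_dim:
        raise ValueError("feature width does not match the model input_dim")
    Xs = (X - model.feat_mean) / model.feat_std
    out, _ = model.net.forward(Xs, training=False)
    out = np.asarray(out, dtype=np.float64)
    rounded = np.round(out / OUTPUT_RESOLUTION) * OUTPUT_RESOLUTION
    if unit == "output":
        return rounded
    if unit == "raw":
        return model.target_transform.inverse(rounded)
    raise ValueError(f"unknown unit {unit!r}")
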