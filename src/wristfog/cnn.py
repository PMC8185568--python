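"""A small 1D convolutional network for 3-class window classification.

The architecture is the compact CNN that works well for short wearable
time-series windows: two 1D convolution stages (valid padding, stride 1,
ReLU), each followed by pooling — max-of-3 after the first, average-of-2
after the second — then flatten, 50% dropout and a dense softmax head
with one node per class (FOG, STOP, WALK).  At the default geometry a
384×6 window flows 384 → conv 375 → maxpool 125 → conv 116 → avgpool 58
→ flatten 2320 → dense 3.

Training minimizes categorical cross-entropy with Adam, monitors a
held-out validation split and stops early when validation loss fails to
improve, restoring the best-epoch weights.  Everything — weight
initialization, batch order, dropout masks, the validation split — is
driven by one seeded generator, so a (data, config, seed) triple fully
determines the fitted model.

The forward/backward passes are written directly in numpy (im2col
convolutions lowered to BLAS matmuls), which is entirely adequate for the
~50k-parameter models this problem calls for.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import LABELS
from .windowing import LabeledWindow, NormalizationScale

logger = logging.getLogger(__name__)

POOL_KINDS = ("max", "avg")


class ConfigurationError(ValueError):
    """Raised when a model configuration yields impossible layer geometry."""


@dataclass
class ModelConfig:
    """Hyperparameters of the window classifier.

    ``conv_filters[i]`` filters of width ``kernel_size`` at stage i, each
    stage followed by ``pool_spec[i] = (kind, size)`` pooling.  With
    ``global_avg_pool`` the flatten step is replaced by a global average
    over the time axis (one value per feature detector).
    """

    window_n: int = 384
    n_channels: int = 6
    conv_filters: tuple[int, ...] = (100, 40)
    kernel_size: int = 10
    pool_spec: tuple[tuple[str, int], ...] = (("max", 3), ("avg", 2))
    dropout_rate: float = 0.5
    n_classes: int = 3
    global_avg_pool: bool = False

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.pool_spec = tuple((str(k), int(s)) for k, s in self.pool_spec)
        if len(self.conv_filters) != len(self.pool_spec):
            raise ConfigurationError("conv_filters and pool_spec must have equal length")
        if self.kernel_size < 1:
            raise ConfigurationError("kernel_size must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        for kind, size in self.pool_spec:
            if kind not in POOL_KINDS or size < 1:
                raise ConfigurationError(f"invalid pool spec ({kind}, {size})")
        self.stage_lengths()  # validates geometry

    def stage_lengths(self) -> list[int]:
        """Time-axis length after each conv/pool stage; raises if any collapses."""
        lengths = []
        n = self.window_n
        for i, (filters, (kind, size)) in enumerate(
            zip(self.conv_filters, self.pool_spec)
        ):
            n = n - self.kernel_size + 1
            if n < 1:
                raise ConfigurationError(
                    f"conv stage {i}: kernel {self.kernel_size} collapses length to {n}"
                )
            lengths.append(n)
            n = n // size
            if n < 1:
                raise ConfigurationError(
                    f"pool stage {i}: {kind}-pool {size} collapses length to {n}"
                )
            lengths.append(n)
        return lengths

    @property
    def flat_dim(self) -> int:
        final_len = 1 if self.global_avg_pool else self.stage_lengths()[-1]
        return final_len * self.conv_filters[-1]


@dataclass
class TrainConfig:
    """Optimization settings: Adam, early stopping on validation loss."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0
    class_weights: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out)).astype(np.float32)


class FogCnn:
    """Untrained network: parameters plus forward/backward machinery."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        c_in = config.n_channels
        k = config.kernel_size
        for i, f in enumerate(config.conv_filters):
            self.params[f"convW{i}"] = _he_init(rng, k * c_in, (k * c_in, f))
            self.params[f"convb{i}"] = np.zeros(f, dtype=np.float32)
            c_in = f
        self.params["denseW"] = _glorot_init(rng, config.flat_dim, config.n_classes)
        self.params["denseb"] = np.zeros(config.n_classes, dtype=np.float32)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (probabilities, cache). ``x`` is (B, window_n, channels)."""
        cfg = self.config
        cache = {"inputs": [], "relu": [], "pool": [], "x_in": x}
        h = x
        for i, (kind, size) in enumerate(cfg.pool_spec):
            cols = _im2col(h, cfg.kernel_size)
            pre = cols @ self.params[f"convW{i}"] + self.params[f"convb{i}"]
            mask = pre > 0
            h = pre * mask
            cache["inputs"].append((cols, h.shape[1] + cfg.kernel_size - 1, h.shape[2]))
            cache["relu"].append(mask)
            h, pcache = _pool_forward(h, kind, size)
            cache["pool"].append((kind, size, pcache))
        if cfg.global_avg_pool:
            cache["gap_len"] = h.shape[1]
            h = h.mean(axis=1)
            flat = h
        else:
            cache["flat_shape"] = h.shape
            flat = h.reshape(h.shape[0], -1)
        if train and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(flat.shape) < keep).astype(np.float32) / keep
            flat = flat * mask
            cache["dropout"] = mask
        cache["flat"] = flat
        logits = flat @ self.params["denseW"] + self.params["denseb"]
        probs = _softmax(logits)
        return probs, cache

    # -- backward ----------------------------------------------------------

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache,
                 sample_weight: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Gradients of mean weighted cross-entropy w.r.t. every parameter."""
        cfg = self.config
        b = probs.shape[0]
        dlogits = (probs - y_onehot) / b
        if sample_weight is not None:
            dlogits = dlogits * sample_weight[:, None]
        grads = {
            "denseW": cache["flat"].T @ dlogits,
            "denseb": dlogits.sum(axis=0),
        }
        dflat = dlogits @ self.params["denseW"].T
        if "dropout" in cache:
            dflat = dflat * cache["dropout"]
        if cfg.global_avg_pool:
            n = cache["gap_len"]
            dh = np.repeat(dflat[:, None, :], n, axis=1) / n
        else:
            dh = dflat.reshape(cache["flat_shape"])
        for i in reversed(range(len(cfg.pool_spec))):
            kind, size, pcache = cache["pool"][i]
            dh = _pool_backward(dh, kind, size, pcache)
            dh = dh * cache["relu"][i]
            cols, in_len, _ = cache["inputs"][i]
            f = dh.shape[2]
            grads[f"convW{i}"] = (
                cols.reshape(-1, cols.shape[2]).T @ dh.reshape(-1, f)
            )
            grads[f"convb{i}"] = dh.sum(axis=(0, 1))
            if i > 0:
                dh = _col2im(dh @ self.params[f"convW{i}"].T,
                             cfg.kernel_size, in_len)
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) patch matrix for a width-k convolution."""
    windows = sliding_window_view(x, k, axis=1)          # (B, L', C, k)
    return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


def _col2im(dcols: np.ndarray, k: int, in_len: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to (B, L, C)."""
    b, l_out, kc = dcols.shape
    c = kc // k
    d4 = dcols.reshape(b, l_out, k, c)
    dx = np.zeros((b, in_len, c), dtype=dcols.dtype)
    for i in range(k):
        dx[:, i:i + l_out, :] += d4[:, :, i, :]
    return dx


def _pool_forward(h: np.ndarray, kind: str, size: int):
    b, length, f = h.shape
    trunc = (length // size) * size
    blocks = h[:, :trunc].reshape(b, trunc // size, size, f)
    if kind == "max":
        idx = blocks.argmax(axis=2)
        out = np.take_along_axis(blocks, idx[:, :, None, :], axis=2)[:, :, 0, :]
        return out, (length, idx)
    out = blocks.mean(axis=2)
    return out, (length, None)


def _pool_backward(dout: np.ndarray, kind: str, size: int, pcache) -> np.ndarray:
    length, idx = pcache
    b, l_pool, f = dout.shape
    dblocks = np.zeros((b, l_pool, size, f), dtype=dout.dtype)
    if kind == "max":
        np.put_along_axis(dblocks, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    else:
        dblocks += dout[:, :, None, :] / size
    dh = np.zeros((b, length, f), dtype=dout.dtype)
    dh[:, :l_pool * size] = dblocks.reshape(b, l_pool * size, f)
    return dh


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _cross_entropy(probs: np.ndarray, y: np.ndarray,
                   sample_weight: np.ndarray | None = None) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    losses = -np.log(p)
    if sample_weight is not None:
        return float(np.sum(losses * sample_weight) / len(y))
    return float(losses.mean())


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted classifier: parameters, provenance and training history."""

    model: FogCnn
    config: ModelConfig
    train_config: TrainConfig
    history: list[tuple[int, float, float]]  # (epoch, train_loss, val_loss)
    label_order: tuple[str, ...] = LABELS
    scales: NormalizationScale | None = None

    @property
    def best_val_loss(self) -> float:
        return min(v for _, _, v in self.history)


def build_model(config: ModelConfig | None = None,
                seed: int = 0) -> FogCnn:
    """Instantiate the network with seeded weight initialization."""
    config = config or ModelConfig()
    return FogCnn(config, np.random.default_rng(seed))


def _windows_to_arrays(windows: list[LabeledWindow]):
    x = np.stack([w.data for w in windows]).astype(np.float32)
    y = np.array([LABELS.index(w.label) for w in windows], dtype=np.int64)
    return x, y


def train(model: FogCnn | ModelConfig | None, windows: list[LabeledWindow],
          tcfg: TrainConfig | None = None,
          scales: NormalizationScale | None = None) -> TrainedModel:
    """Fit the network on labeled windows with Adam + early stopping.

    A ``validation_fraction`` of the windows (seeded shuffle) is held out
    to monitor loss; training halts when validation loss has not improved
    for ``patience`` epochs and the best-epoch weights are restored.
    """
    tcfg = tcfg or TrainConfig()
    if not windows:
        raise ValueError("cannot train on an empty window set")
    x, y = _windows_to_arrays(windows)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    if isinstance(model, ModelConfig) or model is None:
        cfg = model or ModelConfig(window_n=x.shape[1], n_channels=x.shape[2])
        rng = np.random.default_rng(tcfg.seed)
        model = FogCnn(cfg, rng)
    else:
        cfg = model.config
        rng = np.random.default_rng(tcfg.seed)
    if x.shape[1] != cfg.window_n or x.shape[2] != cfg.n_channels:
        raise ValueError(
            f"window shape {x.shape[1:]} does not match model input "
            f"({cfg.window_n}, {cfg.n_channels})"
        )

    n = len(x)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tcfg.validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training data")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]

    weights = None
    if tcfg.class_weights:
        counts = np.bincount(y_tr, minlength=cfg.n_classes).astype(float)
        counts[counts == 0] = 1.0
        per_class = counts.sum() / (cfg.n_classes * counts)
        weights = per_class[y_tr].astype(np.float32)

    eye = np.eye(cfg.n_classes, dtype=np.float32)
    opt = _Adam(model.params, tcfg.learning_rate)
    history: list[tuple[int, float, float]] = []
    best_val, best_params, stall = np.inf, model.copy_params(), 0

    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        batch_losses = []
        for start in range(0, len(x_tr), tcfg.batch_size):
            sel = order[start:start + tcfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            wb = weights[sel] if weights is not None else None
            probs, cache = model.forward(xb, train=True, rng=rng)
            batch_losses.append(_cross_entropy(probs, yb, wb))
            grads = model.backward(probs, eye[yb], cache, wb)
            opt.step(model.params, grads)
        val_probs = predict_proba(model, x_val)
        val_loss = _cross_entropy(val_probs, y_val)
        train_loss = float(np.mean(batch_losses))
        history.append((epoch, train_loss, val_loss))
        logger.debug("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_params, stall = val_loss, model.copy_params(), 0
        else:
            stall += 1
            if stall >= tcfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    model.set_params(best_params)
    return TrainedModel(model, cfg, tcfg, history, LABELS, scales)


def predict_proba(model: FogCnn | TrainedModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one window (L×C) or a batch (B×L×C).

    Dropout is inactive: inference is deterministic.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    expected = (net.config.window_n, net.config.n_channels)
    if x.shape[1:] != expected:
        raise ValueError(f"window shape {x.shape[1:]} does not match {expected}")
    probs, _ = net.forward(x, train=False)
    return probs[0] if single else probs


def predict_class(model: FogCnn | TrainedModel, x: np.ndarray) -> str | list[str]:
    """Argmax label(s); ties break toward the earliest label in LABELS order."""
    probs = predict_proba(model, x)
    if probs.ndim == 1:
        return LABELS[int(np.argmax(probs))]
    return [LABELS[i] for i in np.argmax(probs, axis=1)]


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


@dataclass
class SearchSpace:
    """Random/grid search ranges for depth, kernel size and filter counts."""

    depths: tuple[int, ...] = (2, 3, 4, 5)
    kernel_range: tuple[int, int] = (3, 12)
    filter_range: tuple[int, int] = (10, 100)
    budget: int = 10
    strategy: str = "random"

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("search budget must be >= 1")
        if self.strategy not in ("random", "grid"):
            raise ValueError("strategy must be 'random' or 'grid'")


def _sample_config(space: SearchSpace, rng: np.random.Generator,
                   window_n: int, n_channels: int) -> ModelConfig:
    depth = int(rng.choice(space.depths))
    kernel = int(rng.integers(space.kernel_range[0], space.kernel_range[1] + 1))
    filters = tuple(
        int(rng.integers(space.filter_range[0], space.filter_range[1] + 1))
        for _ in range(depth)
    )
    pools = (("max", 3),) + (("avg", 2),) * (depth - 1)
    return ModelConfig(window_n=window_n, n_channels=n_channels,
                       conv_filters=filters, kernel_size=kernel, pool_spec=pools)


def hyperparameter_search(space: SearchSpace, windows: list[LabeledWindow],
                          tcfg: TrainConfig,
                          candidates: list[ModelConfig] | None = None):
    """Pick the candidate with the lowest inner-validation loss.

    Candidates come either from an explicit list or from seeded random
    draws out of ``space``.  Each trial trains with ``tcfg`` on the same
    data (the inner validation split is re-drawn per trial from the same
    seed, so trials are comparable and runs reproducible).  Returns
    ``(best_config, trials)`` where trials is a list of dicts.
    """
    x0 = windows[0].data
    rng = np.random.default_rng(tcfg.seed)
    if candidates is None:
        candidates = []
        attempts = 0
        while len(candidates) < space.budget and attempts < space.budget * 20:
            attempts += 1
            try:
                candidates.append(
                    _sample_config(space, rng, x0.shape[0], x0.shape[1])
                )
            except ConfigurationError:
                continue
    trials = []
    best_cfg, best_loss = None, np.inf
    for i, cfg in enumerate(candidates):
        try:
            fitted = train(cfg, windows, tcfg)
        except ConfigurationError as exc:
            trials.append({"trial": i, "config": asdict(cfg), "error": str(exc)})
            continue
        loss = fitted.best_val_loss
        trials.append({"trial": i, "config": asdict(cfg), "val_loss": loss})
        logger.info("trial %d: val loss %.4f", i, loss)
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    if best_cfg is None:
        raise ConfigurationError("every candidate configuration failed")
    return best_cfg, trials


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(trained: TrainedModel, path_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.npz`` (weights) + ``<prefix>.json`` (sidecar).

    The sidecar carries the model/train configs, label order and the
    cohort normalization scales, so streaming inference is self-contained.
    """
    weights_path = f"{path_prefix}.npz"
    sidecar_path = f"{path_prefix}.json"
    np.savez(weights_path, **trained.model.params)
    sidecar = {
        "model_config": asdict(trained.config),
        "train_config": asdict(trained.train_config),
        "label_order": list(trained.label_order),
        "scales": None if trained.scales is None else trained.scales.scales.tolist(),
        "history": trained.history,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return weights_path, sidecar_path


def load_checkpoint(path_prefix: str) -> TrainedModel:
    with open(f"{path_prefix}.json") as fh:
        sidecar = json.load(fh)
    mc = sidecar["model_config"]
    mc["conv_filters"] = tuple(mc["conv_filters"])
    mc["pool_spec"] = tuple((k, s) for k, s in mc["pool_spec"])
    config = ModelConfig(**mc)
    tcfg = TrainConfig(**sidecar["train_config"])
    model = FogCnn(config)
    with np.load(f"{path_prefix}.npz") as data:
        model.params = {k: data[k].astype(np.float32) for k in data.files}
    scales = sidecar["scales"]
    return TrainedModel(
        model, config, tcfg,
        [tuple(h) for h in sidecar["history"]],
        tuple(sidecar["label_order"]),
        None if scales is None else NormalizationScale(np.array(scales)),
    )
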