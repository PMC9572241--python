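"""Model families and the shared training protocol.

Eight classifier families are compared on identical footing: LR and a
128-unit MLP on the 192 handcrafted features; three 1-D convolutional
networks (CNN-simple, CNN-base, ResNet) on the raw 250x4 windows; and a
hybrid variant of each convolutional backbone that concatenates the
scaled handcrafted features with the flattened convolutional
representation before a fusion layer.

Every family is trained by the same procedure: Adam, class-weighted
cross-entropy, a seeded 10% validation split, a 140-epoch cap with
patience-30 early stopping, and restoration of the checkpoint with the
best validation loss.  The layer stack (dense, 1-D convolution, max
pooling, residual blocks) and backpropagation are implemented directly
on numpy arrays, which keeps every arithmetic step visible and makes
runs bit-reproducible under a seed.

Convolutions use stride 1 and no padding; max pooling defaults to
stride 1 as well (the architecture's stated convention) with a config
switch for the conventional stride = kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import N_FEATURES, RepresentationMatrix
from .synthgen import CANONICAL_ACTIVITIES, ConfigurationError

logger = logging.getLogger(__name__)

FAMILIES = ("LR", "MLP", "CNN-simple", "CNN-base", "ResNet",
            "CNN-simple-hybrid", "CNN-base-hybrid", "ResNet-hybrid")
FEATURE_FAMILIES = ("LR", "MLP")
HYBRID_FAMILIES = ("CNN-simple-hybrid", "CNN-base-hybrid", "ResNet-hybrid")

GRID_LEARNING_RATES = (0.0008, 0.001, 0.003)
GRID_BATCH_SIZES = (64, 128, 256)


# ---------------------------------------------------------------------------
# Layers (forward / backward on numpy arrays)

class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv1d(_Layer):
    """1-D convolution, stride 1, no padding; input [N x C x L]."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * kernel)),
                            size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._cols = sliding_window_view(x, self.kernel, axis=2)  # N,C,L',K
        out = np.einsum("nclk,fck->nfl", self._cols, self.W, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, g):
        self.grads[0][...] = np.einsum("nfl,nclk->fck", g, self._cols, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 2))
        n, c, lp, k = self._cols.shape
        gx = np.zeros((n, c, lp + k - 1))
        gcols = np.einsum("nfl,fck->nclk", g, self.W, optimize=True)
        for j in range(k):
            gx[:, :, j:j + lp] += gcols[:, :, :, j]
        return gx


class MaxPool1d(_Layer):
    def __init__(self, kernel: int, stride: int = 1):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x):
        self._in_shape = x.shape
        win = sliding_window_view(x, self.kernel, axis=2)[:, :, ::self.stride]
        self._arg = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, g):
        n, c, lp = g.shape
        gx = np.zeros(self._in_shape)
        starts = np.arange(lp) * self.stride
        pos = starts[None, None, :] + self._arg
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gx, (ni, ci, pos), g)
        return gx


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class ResBlock(_Layer):
    """Two stride-1, padding-0 convolutions with a projection skip.

    Because valid convolutions shorten the sequence, the skip path
    center-crops the input and projects channels with a kernel-1
    convolution before the additive merge; ReLU follows the merge.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(c_in, c_out, kernel, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, rng)
        self.proj = Conv1d(c_in, c_out, 1, rng)
        self.crop = kernel - 1  # (k-1)/2 per conv, two convs
        self.params = self.conv1.params + self.conv2.params + self.proj.params
        self.grads = self.conv1.grads + self.conv2.grads + self.proj.grads

    def forward(self, x):
        a = self.conv1.forward(x)
        self._mask1 = a > 0
        y = self.conv2.forward(a * self._mask1)
        s = self.proj.forward(x[:, :, self.crop:x.shape[2] - self.crop])
        z = y + s
        self._mask2 = z > 0
        return z * self._mask2

    def backward(self, g):
        gz = g * self._mask2
        gs = self.proj.backward(gz)
        gy = self.conv2.backward(gz) * self._mask1
        gx = self.conv1.backward(gy)
        gx[:, :, self.crop:gx.shape[2] - self.crop] += gs
        return gx


# ---------------------------------------------------------------------------
# Specs and model construction

@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for one family.

    ``conv_defs`` lists (kernel, filters) per convolutional stage;
    ``pool_stride`` of 1 follows the stated pooling convention, while
    ``pool_stride=None`` selects the conventional stride = kernel.
    """

    family: str
    mlp_hidden: int = 128
    conv_defs: tuple = ()
    pool_kernel: int = 2
    pool_stride: int | None = 1
    dense_width: int = 128
    fusion_width: int = 128

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.family == "MLP" and self.mlp_hidden != 128:
            raise ConfigurationError("MLP hidden width is fixed at 128")
        expected_fusion = 256 if self.family == "ResNet-hybrid" else 128
        if self.family in HYBRID_FAMILIES and self.fusion_width != expected_fusion:
            raise ConfigurationError(
                f"{self.family} fusion width must be {expected_fusion}")

    @property
    def input_kind(self) -> str:
        if self.family in FEATURE_FAMILIES:
            return "features-192"
        if self.family in HYBRID_FAMILIES:
            return "both"
        return "window-250x4"


def default_spec(family: str, pool_stride: int | None = 1) -> ModelSpec:
    base = family.replace("-hybrid", "")
    conv_defs = {
        "LR": (), "MLP": (),
        "CNN-simple": ((5, 16), (5, 32)),
        "CNN-base": ((5, 16), (5, 32), (5, 64)),
        "ResNet": ((5, 32), (5, 32), (5, 64)),  # stem, then two residual blocks
    }[base]
    fusion = 256 if family == "ResNet-hybrid" else 128
    return ModelSpec(family, conv_defs=conv_defs, pool_stride=pool_stride,
                     fusion_width=fusion)


class Network:
    """A built (possibly hybrid) network with explicit forward/backward.

    ``backbone`` maps windows to a flattened representation, ``trunk``
    maps the (possibly feature-concatenated) representation to the
    embedding, and ``classifier`` produces logits.  The embedding is the
    activation vector feeding the classifier.
    """

    def __init__(self, spec: ModelSpec, n_classes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        base = spec.family.replace("-hybrid", "")
        self.hybrid = spec.family in HYBRID_FAMILIES
        self.backbone: list[_Layer] = []
        self.trunk: list[_Layer] = []
        if base == "CNN-simple":
            (k1, f1), (k2, f2) = spec.conv_defs
            self.backbone = [Conv1d(4, f1, k1, rng), ReLU(),
                             Conv1d(f1, f2, k2, rng), ReLU(), Flatten()]
        elif base == "CNN-base":
            stride = spec.pool_stride or spec.pool_kernel
            c_in = 4
            for k, f in spec.conv_defs:
                self.backbone += [Conv1d(c_in, f, k, rng), ReLU(),
                                  MaxPool1d(spec.pool_kernel, stride)]
                c_in = f
            self.backbone.append(Flatten())
        elif base == "ResNet":
            (ks, fs), (k1, f1), (k2, f2) = spec.conv_defs
            self.backbone = [Conv1d(4, fs, ks, rng), ReLU(),
                             ResBlock(fs, f1, k1, rng),
                             ResBlock(f1, f2, k2, rng), Flatten()]
        flat_width = self._infer_flat_width() if self.backbone else 0
        if base in FEATURE_FAMILIES:
            trunk_in = N_FEATURES
        elif self.hybrid:
            trunk_in = flat_width + N_FEATURES
        else:
            trunk_in = flat_width
        if spec.family == "MLP":
            self.trunk = [Dense(N_FEATURES, spec.mlp_hidden, rng), ReLU()]
            clf_in = spec.mlp_hidden
        elif self.hybrid:
            self.trunk = [Dense(trunk_in, spec.fusion_width, rng), ReLU()]
            clf_in = spec.fusion_width
        elif base in ("CNN-base", "ResNet"):
            self.trunk = [Dense(trunk_in, spec.dense_width, rng), ReLU()]
            clf_in = spec.dense_width
        else:  # LR, CNN-simple: classifier applied directly
            clf_in = trunk_in
        self.classifier = Dense(clf_in, n_classes, rng)
        self.n_classes = n_classes
        self._flat_width = flat_width

    def _infer_flat_width(self) -> int:
        h = np.zeros((1, 4, 250))
        for layer in self.backbone:
            h = layer.forward(h)
        return h.shape[1]

    @property
    def layers(self) -> list[_Layer]:
        return self.backbone + self.trunk + [self.classifier]

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, windows: np.ndarray | None, feats: np.ndarray | None):
        """Return (logits, embedding)."""
        if self.backbone:
            if windows is None:
                raise ValueError(f"{self.spec.family} requires window input")
            h = windows
            for layer in self.backbone:
                h = layer.forward(h)
            if self.hybrid:
                if feats is None:
                    raise ValueError("hybrid models require feature input")
                h = np.concatenate([h, feats], axis=1)
        else:
            if feats is None:
                raise ValueError(f"{self.spec.family} requires feature input")
            h = feats
        for layer in self.trunk:
            h = layer.forward(h)
        return self.classifier.forward(h), h

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.classifier.backward(dlogits)
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        if self.backbone:
            if self.hybrid:
                g = g[:, :self._flat_width]
            for layer in reversed(self.backbone):
                g = layer.backward(g)


def build_model(spec: ModelSpec, n_classes: int = 5, seed: int = 0) -> Network:
    return Network(spec, n_classes, seed)


# ---------------------------------------------------------------------------
# Class weights and the weighted cross-entropy loss

def class_weights(train_labels, classes=CANONICAL_ACTIVITIES,
                  mode: str = "inverse-frequency"):
    """Per-class loss weights for the present classes.

    ``inverse-frequency`` (default) gives w_c = N / (K * n_c), which
    upweights rare classes.  ``paper-literal`` gives w_c = n_c / N, the
    class *percentage* handed to the loss verbatim; it is preserved as a
    switch because it is the opposite reading of the same convention.
    Classes absent from the training labels are excluded (and logged).
    """
    labels = np.asarray(train_labels)
    present = [c for c in classes if (labels == c).sum() > 0]
    absent = [c for c in classes if c not in present]
    if absent:
        logger.warning("classes absent from training set, excluded from loss: %s", absent)
    counts = np.array([(labels == c).sum() for c in present], dtype=float)
    n, k = counts.sum(), len(present)
    if mode == "inverse-frequency":
        w = n / (k * counts)
    elif mode == "paper-literal":
        w = counts / n
    else:
        raise ConfigurationError(f"unknown class-weight mode {mode!r}")
    return tuple(present), w


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits, y_idx, weights):
    """Loss and dlogits; per-sample weights w[y], normalized by their sum."""
    p = _softmax(logits)
    n = len(y_idx)
    w = weights[y_idx]
    wsum = w.sum()
    logp = np.log(np.clip(p[np.arange(n), y_idx], 1e-12, None))
    loss = -(w * logp).sum() / wsum
    d = p.copy()
    d[np.arange(n), y_idx] -= 1.0
    d *= (w / wsum)[:, None]
    return loss, d


# ---------------------------------------------------------------------------
# Training protocol

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 140
    patience: int = 30
    validation_fraction: float = 0.10
    class_weight_mode: str = "inverse-frequency"
    seed: int = 0


def grid_configs(base_seed: int = 0, learning_rates=GRID_LEARNING_RATES,
                 batch_sizes=GRID_BATCH_SIZES, **overrides) -> list[TrainConfig]:
    """The full 3 x 3 (learning rate, batch size) grid; run i gets seed
    base_seed + i so no two runs share initialization or batching."""
    return [TrainConfig(learning_rate=lr, batch_size=bs, seed=base_seed + i,
                        **overrides)
            for i, (lr, bs) in enumerate(
                (lr, bs) for lr in learning_rates for bs in batch_sizes)]


def early_stopping_trace(val_losses, max_epochs: int = 140, patience: int = 30):
    """(stop_epoch, checkpoint_epoch) implied by a validation-loss history.

    Training stops at the epoch cap or once ``patience`` epochs pass
    without a new validation-loss minimum, whichever is first.
    """
    best = np.inf
    checkpoint = 0
    for epoch, v in enumerate(val_losses[:max_epochs], start=1):
        if v < best:
            best, checkpoint = v, epoch
        if epoch - checkpoint >= patience:
            return epoch, checkpoint
    return min(len(val_losses), max_epochs), checkpoint


@dataclass
class TrainedModel:
    network: Network
    spec: ModelSpec
    config: TrainConfig
    classes: tuple[str, ...]
    history: dict = field(default_factory=dict)
    checkpoint_epoch: int = 0
    stop_epoch: int = 0


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _gather_inputs(windows, feats, idx, spec: ModelSpec):
    w = windows[idx] if spec.input_kind in ("window-250x4", "both") else None
    f = feats[idx] if spec.input_kind in ("features-192", "both") else None
    return w, f


def train(model: Network, train_data: dict, config: TrainConfig) -> TrainedModel:
    """Train under the shared protocol and restore the best checkpoint.

    ``train_data`` holds ``labels`` (strings) and, per the family's input
    kind, ``windows`` [N x 4 x 250] (already window-normalized) and/or
    ``features`` [N x 192] (already train-scaled).  Validation is a
    seeded 10% subset sampled without replacement; its loss uses the same
    class weights as training.
    """
    labels = np.asarray(train_data["labels"])
    n = len(labels)
    if n == 0:
        raise ValueError("empty training data")
    windows = train_data.get("windows")
    feats = train_data.get("features")
    classes, weights = class_weights(labels, mode=config.class_weight_mode)
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[l] for l in labels])

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError(f"degenerate validation split ({n_val} of {n})")
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    opt = _Adam(model.parameters, config.learning_rate)
    best_val, checkpoint_epoch, best_params = np.inf, 0, None
    history = {"train_loss": [], "val_loss": []}
    stop_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr_idx)
        losses, sizes = [], []
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            w, f = _gather_inputs(windows, feats, batch, model.spec)
            logits, _ = model.forward(w, f)
            loss, dlogits = weighted_cross_entropy(logits, y[batch], weights)
            model.backward(dlogits)
            opt.step(model.gradients)
            losses.append(loss)
            sizes.append(len(batch))
        train_loss = float(np.average(losses, weights=sizes))
        w, f = _gather_inputs(windows, feats, val_idx, model.spec)
        val_logits, _ = model.forward(w, f)
        val_loss, _ = weighted_cross_entropy(val_logits, y[val_idx], weights)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val, checkpoint_epoch = val_loss, epoch
            best_params = [p.copy() for p in model.parameters]
        stop_epoch = epoch
        if epoch - checkpoint_epoch >= config.patience:
            break
    for p, best in zip(model.parameters, best_params):
        p[...] = best
    return TrainedModel(model, model.spec, config, classes, history,
                        checkpoint_epoch, stop_epoch)


def predict(trained: TrainedModel, data: dict) -> np.ndarray:
    """Argmax class labels; exact logit ties resolve to the lowest class index."""
    logits, _ = trained.network.forward(data.get("windows"), data.get("features"))
    return np.array([trained.classes[i] for i in logits.argmax(axis=1)], dtype=object)


def embed(trained: TrainedModel, data: dict) -> RepresentationMatrix:
    """The activation vector feeding the final classification layer.

    For LR this is its (scaled) 192-feature input; for CNN-simple the
    flattened feature maps; for the others the dense/fusion output.
    """
    if trained.checkpoint_epoch == 0:
        raise ValueError("model has not been trained")
    _, emb = trained.network.forward(data.get("windows"), data.get("features"))
    names = tuple(f"emb_{i}" for i in range(emb.shape[1]))
    return RepresentationMatrix(emb, names, "embedding")


# ---------------------------------------------------------------------------
# Window normalization for the convolutional inputs (a single global
# mean/sd over all training-window entries; per-channel available)

def fit_window_norm(train_windows: np.ndarray, per_channel: bool = False):
    if per_channel:
        axes = (0, 2)
        mean = train_windows.mean(axis=axes, keepdims=True)
        sd = train_windows.std(axis=axes, keepdims=True)
    else:
        mean = float(train_windows.mean())
        sd = float(train_windows.std())
    return mean, sd


def apply_window_norm(norm, windows: np.ndarray) -> np.ndarray:
    mean, sd = norm
    sd = np.where(np.asarray(sd) > 0, sd, 1.0)
    return (windows - mean) / sd


def write_run_manifest(trained: TrainedModel, path, extra: dict | None = None) -> None:
    manifest = {
        "family": trained.spec.family,
        "learning_rate": trained.config.learning_rate,
        "batch_size": trained.config.batch_size,
        "seed": trained.config.seed,
        "stop_epoch": trained.stop_epoch,
        "checkpoint_epoch": trained.checkpoint_epoch,
        "history": trained.history,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
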