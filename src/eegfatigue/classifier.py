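"""A compact convolutional network for 72x72x3 topographic-map images.

Eight-layer stack (sizes verified against the convolution/pooling output
formulas at construction time):

    conv 3x3x16, pad 1 -> ReLU -> maxpool 2x2 /2
    conv 3x3x32, pad 1 -> ReLU -> maxpool 2x2 /2
    fully connected 128 -> fully connected 3 (softmax)

so the spatial chain is 72 -> 72 -> 36 -> 36 -> 18, giving an 18x18x32
feature map (~1.33M parameters, comfortably CPU-trainable).  Training is
mini-batch Adam on the cross-entropy loss with optional L1/L2 weight
penalties, dropout on the first fully connected layer, or early stopping on
a held-out validation split.  Everything is seeded: the weight
initialisation, the batch shuffling, the dropout masks and the
stratified splits, so identical inputs give identical trained weights.

The network is implemented directly in numpy (im2col convolutions via
stride tricks); forward/backward passes are exact gradients, not autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, TrainingError
from .preprocess import STATES

__all__ = [
    "ConvLayerConfig",
    "PoolLayerConfig",
    "TrainConfig",
    "FatigueCNN",
    "conv_output_size",
    "pool_output_size",
    "relu",
    "build_cnn",
    "split_dataset",
    "train",
    "predict_proba",
    "kfold_cv",
]

REGULARIZERS = ("none", "L1", "L2", "dropout", "early_stopping")


@dataclass
class ConvLayerConfig:
    filters: int
    size: int
    stride: int = 1
    dilation: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        if (self.filters < 1 or self.size < 1 or self.stride < 1
                or self.dilation < 1 or self.padding < 0):
            raise ConfigurationError(f"invalid conv layer config: {self}")


@dataclass
class PoolLayerConfig:
    window: int
    stride: int

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ConfigurationError(f"invalid pool layer config: {self}")


@dataclass
class TrainConfig:
    train_fraction: float = 0.75
    folds: int = 10
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    regularization: str = "none"
    l1_weight: float = 1e-4
    l2_weight: float = 1e-4
    dropout_rate: float = 0.5
    early_stopping_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.regularization not in REGULARIZERS:
            raise ConfigurationError(
                f"regularization must be one of {REGULARIZERS}, "
                f"got {self.regularization!r}"
            )


def conv_output_size(i: int, h: int, g: int = 1, q: int = 0, s: int = 1) -> int:
    """Spatial output size of a convolution: floor((I-((H-1)G+1)+2Q)/S)+1."""
    if i < 1 or h < 1 or g < 1 or s < 1 or q < 0:
        raise ConfigurationError("conv size arguments below their minima")
    eff = (h - 1) * g + 1
    if eff > i + 2 * q:
        raise ConfigurationError(
            f"effective kernel {eff} exceeds padded input {i + 2 * q}"
        )
    return (i - eff + 2 * q) // s + 1


def pool_output_size(wa: int, d: int, s: int) -> int:
    """Spatial output size of pooling: floor((Wa-D)/S)+1."""
    if d < 1 or s < 1 or wa < 1:
        raise ConfigurationError("pool size arguments below their minima")
    if d > wa:
        raise ConfigurationError(f"pool window {d} exceeds input {wa}")
    return (wa - d) // s + 1


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """Patch matrix of a channels-last batch for a 3x3 'same' convolution.

    x (N,H,W,C) -> (N*H*W, 9*C), filled by nine block copies so every pass
    reduces to a plain GEMM (far faster here than strided tensordots).
    """
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 3, 3, c), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            cols[:, :, :, u, v, :] = xp[:, u:u + h, v:v + w, :]
    return cols.reshape(n * h * w, 9 * c)


def _kernel_matrix(w: np.ndarray) -> np.ndarray:
    """(F,C,3,3) kernels -> (9*C, F) matrix matching _im2col's layout."""
    return np.ascontiguousarray(w.transpose(2, 3, 1, 0)).reshape(
        -1, w.shape[0])


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 stride-1 'same' convolution; x (N,H,W,C), w (F,C,3,3)."""
    n, h, wd, _ = x.shape
    cols = _im2col(x)
    out = (cols @ _kernel_matrix(w)).reshape(n, h, wd, w.shape[0])
    return out + b, cols


def _conv_backward(cols: np.ndarray, x_shape: tuple, w: np.ndarray,
                   dy: np.ndarray):
    """Gradients of the 'same' 3x3 convolution w.r.t. x, w and b.

    Uses the cached forward patch matrix for dW and a 9-offset scatter-add
    (col2im) for dX.
    """
    n, h, wd, c = x_shape
    f = w.shape[0]
    dy_mat = dy.reshape(-1, f)
    dwm = cols.T @ dy_mat                      # (9C, F)
    dw = np.ascontiguousarray(
        dwm.reshape(3, 3, c, f).transpose(3, 2, 0, 1))
    db = dy_mat.sum(axis=0)
    dcols = (dy_mat @ _kernel_matrix(w).T).reshape(n, h, wd, 3, 3, c)
    dxp = np.zeros((n, h + 2, wd + 2, c), dtype=dy.dtype)
    for u in range(3):
        for v in range(3):
            dxp[:, u:u + h, v:v + wd, :] += dcols[:, :, :, u, v, :]
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool_forward(x: np.ndarray):
    """2x2 stride-2 max pooling via pairwise selects; ties route their
    gradient to the earlier element (a valid, deterministic subgradient)."""
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    va, vb = r[:, :, 0], r[:, :, 1]          # (n, h/2, w/2, 2, c)
    sel_v = vb > va
    m1 = np.where(sel_v, vb, va)
    ha, hb = m1[:, :, :, 0], m1[:, :, :, 1]  # (n, h/2, w/2, c)
    sel_h = hb > ha
    out = np.where(sel_h, hb, ha)
    return out, (sel_v, sel_h, x.shape)


def _pool_backward(dy: np.ndarray, cache) -> np.ndarray:
    sel_v, sel_h, shape = cache
    n, h, w, c = shape
    dm1 = np.zeros((n, h // 2, w // 2, 2, c), dtype=dy.dtype)
    dm1[:, :, :, 0] = np.where(sel_h, 0.0, dy)
    dm1[:, :, :, 1] = np.where(sel_h, dy, 0.0)
    dr = np.zeros((n, h // 2, 2, w // 2, 2, c), dtype=dy.dtype)
    dr[:, :, 0] = np.where(sel_v, 0.0, dm1)
    dr[:, :, 1] = np.where(sel_v, dm1, 0.0)
    return dr.reshape(shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class FatigueCNN:
    """Parameter container for the default 8-layer stack."""

    params: dict
    input_shape: tuple = (72, 72, 3)
    n_classes: int = 3
    classes: tuple = STATES
    feature_shape: tuple = (18, 18, 32)

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "FatigueCNN":
        return FatigueCNN({k: v.copy() for k, v in self.params.items()},
                          self.input_shape, self.n_classes, self.classes,
                          self.feature_shape)

    def save(self, path) -> None:
        """Checkpoint weights and architecture metadata to an .npz file."""
        meta = {
            "input_shape": np.array(self.input_shape),
            "n_classes": np.array(self.n_classes),
            "classes": np.array(self.classes),
            "feature_shape": np.array(self.feature_shape),
        }
        np.savez(path, **self.params, **{f"meta_{k}": v
                                         for k, v in meta.items()})

    @classmethod
    def load(cls, path) -> "FatigueCNN":
        with np.load(path, allow_pickle=False) as data:
            params = {k: data[k] for k in data.files
                      if not k.startswith("meta_")}
            return cls(
                params=params,
                input_shape=tuple(int(v) for v in data["meta_input_shape"]),
                n_classes=int(data["meta_n_classes"]),
                classes=tuple(str(c) for c in data["meta_classes"]),
                feature_shape=tuple(int(v)
                                    for v in data["meta_feature_shape"]),
            )


def build_cnn(input_shape: tuple = (72, 72, 3), n_classes: int = 3,
              seed: int = 0, conv_filters: tuple = (16, 32),
              fc_units: int = 128, classes: tuple = STATES) -> FatigueCNN:
    """Construct the untrained network, verifying the layer-size chain."""
    h, w, c = input_shape
    if h != w:
        raise ConfigurationError("input images must be square")
    s1 = conv_output_size(h, 3, 1, 1, 1)          # conv1, pad 1
    s2 = pool_output_size(s1, 2, 2)               # pool1
    s3 = conv_output_size(s2, 3, 1, 1, 1)         # conv2, pad 1
    s4 = pool_output_size(s3, 2, 2)               # pool2
    if (s1, s2, s3, s4) != (h, h // 2, h // 2, h // 4):
        raise ConfigurationError(
            f"inconsistent size chain {h}->{s1}->{s2}->{s3}->{s4}"
        )
    f1, f2 = conv_filters
    flat = s4 * s4 * f2
    rng = np.random.default_rng(seed)

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape
                          ).astype(np.float32)

    params = {
        "W1": he((f1, c, 3, 3), c * 9),
        "b1": np.zeros(f1, dtype=np.float32),
        "W2": he((f2, f1, 3, 3), f1 * 9),
        "b2": np.zeros(f2, dtype=np.float32),
        "Wf1": he((flat, fc_units), flat),
        "bf1": np.zeros(fc_units, dtype=np.float32),
        "Wf2": he((fc_units, n_classes), fc_units),
        "bf2": np.zeros(n_classes, dtype=np.float32),
    }
    return FatigueCNN(params, input_shape, n_classes, tuple(classes),
                      (s4, s4, f2))


def _forward(model: FatigueCNN, x: np.ndarray, dropout_mask=None,
             want_cache: bool = True):
    p = model.params
    z1, cols1 = _conv_forward(x, p["W1"], p["b1"])
    a1 = relu(z1)
    p1, pc1 = _pool_forward(a1)
    z2, cols2 = _conv_forward(p1, p["W2"], p["b2"])
    a2 = relu(z2)
    p2, pc2 = _pool_forward(a2)
    flat = p2.reshape(x.shape[0], -1)
    zf1 = flat @ p["Wf1"] + p["bf1"]
    af1 = relu(zf1)
    if dropout_mask is not None:
        af1 = af1 * dropout_mask
    logits = af1 @ p["Wf2"] + p["bf2"]
    probs = _softmax(logits)
    if not want_cache:
        return probs, None
    cache = (x.shape, cols1, z1, p1.shape, pc1, cols2, z2, pc2, p2.shape,
             flat, zf1, af1, dropout_mask)
    return probs, cache


def _backward(model: FatigueCNN, probs: np.ndarray, y_onehot: np.ndarray,
              cache) -> dict:
    p = model.params
    (x_shape, cols1, z1, p1_shape, pc1, cols2, z2, pc2, p2_shape,
     flat, zf1, af1, mask) = cache
    n = x_shape[0]
    dlogits = (probs - y_onehot) / n
    grads = {
        "Wf2": af1.T @ dlogits,
        "bf2": dlogits.sum(axis=0),
    }
    daf1 = dlogits @ p["Wf2"].T
    if mask is not None:
        daf1 = daf1 * mask
    dzf1 = daf1 * (zf1 > 0)
    grads["Wf1"] = flat.T @ dzf1
    grads["bf1"] = dzf1.sum(axis=0)
    dflat = dzf1 @ p["Wf1"].T
    dp2 = dflat.reshape(p2_shape)
    da2 = _pool_backward(dp2, pc2)
    dz2 = da2 * (z2 > 0)
    dp1, dw2, db2 = _conv_backward(cols2, p1_shape, p["W2"], dz2)
    grads["W2"], grads["b2"] = dw2, db2
    da1 = _pool_backward(dp1, pc1)
    dz1 = da1 * (z1 > 0)
    _, dw1, db1 = _conv_backward(cols1, x_shape, p["W1"], dz1)
    grads["W1"], grads["b1"] = dw1, db1
    return grads


def _as_images(x: np.ndarray) -> np.ndarray:
    """Coerce a batch to the internal channels-last (N, H, W, C) layout."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise InputError("expected a batch of images (N, H, W, C)")
    if x.shape[1] in (1, 3) and x.shape[-1] not in (1, 3):
        x = np.ascontiguousarray(np.moveaxis(x, 1, -1))
    return x


def predict_proba(model: FatigueCNN, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Class probabilities, (N, n_classes)."""
    x = _as_images(images)
    out = []
    for i in range(0, x.shape[0], batch_size):
        probs, _ = _forward(model, x[i:i + batch_size], want_cache=False)
        out.append(probs)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------

def _labels_of(items) -> np.ndarray:
    return np.array([getattr(e, "state", e) for e in items])


def split_dataset(items, train_fraction: float = 0.75, seed: int = 0):
    """Stratified random train/test split over items (epochs or labels).

    Per state, the train count is round(fraction * state total); returns
    (train_indices, test_indices) as sorted integer arrays.
    """
    import warnings as _warnings

    if not (0 < train_fraction < 1):
        raise InputError("train_fraction must be in (0, 1)")
    labels = _labels_of(items)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for state in STATES:
        idx = np.flatnonzero(labels == state)
        if idx.size == 0:
            _warnings.warn(f"state {state!r} has no epochs", stacklevel=2)
            continue
        n_train = int(round(train_fraction * idx.size))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx, dtype=int)), \
        np.sort(np.array(test_idx, dtype=int))


def _encode_labels(y, classes) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[v] for v in y], dtype=int)
    except KeyError as exc:
        raise InputError(f"unknown class label {exc}") from exc


def train(model: FatigueCNN, images: np.ndarray, y, config: TrainConfig
          ) -> tuple[FatigueCNN, dict]:
    """Mini-batch Adam on cross-entropy; returns (model, history).

    ``history`` holds per-epoch train loss/accuracy (and validation curves
    when early stopping is active).  Raises TrainingError on divergence.
    """
    x = _as_images(images)
    yi = _encode_labels(y, model.classes)
    if x.shape[0] == 0:
        raise InputError("empty training set")
    if x.shape[0] != yi.shape[0]:
        raise InputError("images and labels differ in length")

    val_x = val_y = None
    if config.regularization == "early_stopping":
        tr, va = split_dataset(
            [model.classes[i] for i in yi],
            train_fraction=1 - config.validation_fraction,
            seed=config.seed + 1,
        )
        val_x, val_y = x[va], yi[va]
        x, yi = x[tr], yi[tr]

    rng = np.random.default_rng(config.seed + 2)
    n = x.shape[0]
    k = model.n_classes
    onehot = np.eye(k, dtype=np.float32)

    adam_m = {key: np.zeros_like(v) for key, v in model.params.items()}
    adam_v = {key: np.zeros_like(v) for key, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val, best_params, patience_left = np.inf, None, \
        config.early_stopping_patience

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = x[batch], yi[batch]
            mask = None
            if config.regularization == "dropout":
                keep = 1.0 - config.dropout_rate
                mask = (rng.random((xb.shape[0],
                                    model.params["bf1"].size)) < keep
                        ).astype(np.float32) / keep
            probs, cache = _forward(model, xb, dropout_mask=mask)
            loss = -np.log(np.maximum(probs[np.arange(len(yb)), yb],
                                      1e-12)).mean()
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged at epoch {_epoch}")
            epoch_loss += loss * len(yb)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            grads = _backward(model, probs, onehot[yb], cache)
            if config.regularization == "L2":
                for key in ("W1", "W2", "Wf1", "Wf2"):
                    grads[key] = grads[key] + \
                        2 * config.l2_weight * model.params[key]
            elif config.regularization == "L1":
                for key in ("W1", "W2", "Wf1", "Wf2"):
                    grads[key] = grads[key] + \
                        config.l1_weight * np.sign(model.params[key])
            t += 1
            for key, g in grads.items():
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                mhat = adam_m[key] / (1 - beta1 ** t)
                vhat = adam_v[key] / (1 - beta2 ** t)
                model.params[key] = (
                    model.params[key]
                    - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                ).astype(np.float32)

        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)

        if val_x is not None and len(val_x):
            vprobs = predict_proba(model, val_x)
            vloss = -np.log(np.maximum(
                vprobs[np.arange(len(val_y)), val_y], 1e-12)).mean()
            vacc = float((vprobs.argmax(axis=1) == val_y).mean())
            history["val_loss"].append(float(vloss))
            history["val_accuracy"].append(vacc)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = {key: v.copy()
                               for key, v in model.params.items()}
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_params is not None:
        model.params = best_params
    return model, history


def kfold_cv(images: np.ndarray, y, k: int = 10,
             config: TrainConfig | None = None,
             build_kwargs: dict | None = None) -> list:
    """Stratified k-fold cross-validation of freshly built networks.

    Every sample lands in exactly one validation fold.  Returns a list of
    :class:`eegfatigue.evaluation.EvaluationReport`, one per fold.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import evaluate

    config = config or TrainConfig()
    x = _as_images(images)
    labels = _labels_of(y)
    if k < 2:
        raise InputError("k must be >= 2")
    if x.shape[0] < k:
        raise InputError("dataset smaller than the number of folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    reports = []
    for fold, (tr, va) in enumerate(skf.split(x, labels)):
        model = build_cnn(input_shape=x.shape[1:],
                          seed=config.seed + fold,
                          **(build_kwargs or {}))
        model, _ = train(model, x[tr], labels[tr], config)
        probs = predict_proba(model, x[va])
        reports.append(evaluate(labels[va], probs, classes=model.classes,
                                fold=fold, indices=va))
    return reports
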