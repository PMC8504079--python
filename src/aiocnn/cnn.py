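"""Two-branch CNN classifiers for artificial image objects.

The 2D architecture has two branches joined by concatenation before the
fully connected head:

* a modified-VGG branch — six 3x3 convolution stages followed by one 1x1
  convolution stage, each stage conv -> (batch norm) -> ReLU, with
  pooling after every second 3x3 stage and a global spatial average
  before the head;
* an embedding branch — pixel intensities (vocabulary 0-255) embedded into
  learned dense vectors and average-pooled over positions.

The merged features feed four fully connected layers (three hidden + the
output layer).  A binary task ends in a single sigmoid unit; a K-class
task ends in a K-way softmax.  The 1D variant applies the same stage
pattern with length-3 kernels to the gene sequence in genome order.

Layer counts and kernel sizes are fixed by the architecture; filter
counts, embedding dimension, dense widths, regularization and all
optimizer settings are configurable.  Training uses Adam with early
stopping on a held-out validation split and is deterministic given the
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .errors import (
    ConfigError,
    DegenerateLabelsError,
    DivergenceError,
    ShapeError,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "PredictionSet",
    "RunResult",
    "RunEnsemble",
    "CNNClassifier",
    "default_model_spec",
    "save_model",
    "load_model",
    "build_2d_classifier",
    "build_1d_classifier",
    "train_model",
    "predict_proba",
    "repeated_runs",
]

N_CONV_STAGES = 6  # six 3x3 stages, per the published architecture
N_DENSE = 4        # four fully connected layers (three hidden + output)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for the 2D or 1D classifier.

    ``input_shape`` is (channels, height, width) for 2D and
    (length, channels) for 1D.  ``dense_widths`` lists the three hidden
    widths; the output layer (width 1 or n_classes) completes the four
    fully connected layers.
    """

    input_shape: tuple[int, ...]
    n_classes: int = 2
    conv_filters: tuple[int, ...] = (8, 8, 16, 16, 32, 32)
    conv1x1_filters: int = 64
    kernel_size: int = 3
    pool_every: int = 2          # pool after every `pool_every` 3x3 stages
    pool_size: int | None = None  # default 2 for 2D, 4 for 1D
    pool_type: str = "avg"       # "avg" or "max"
    embedding_dim: int = 8
    use_embedding: bool = True
    dense_widths: tuple[int, ...] = (128, 64, 32)
    global_pool: bool = True   # spatial mean after the 1x1 stage (vs flatten)
    batch_norm: bool = True    # batch norm after every conv stage
    dropout: float = 0.25      # on hidden dense layers (0 disables)
    l2: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.conv_filters) != N_CONV_STAGES:
            raise ConfigError(
                f"the architecture uses exactly {N_CONV_STAGES} 3x3 conv "
                f"stages; got {len(self.conv_filters)} filter counts"
            )
        if len(self.dense_widths) != N_DENSE - 1:
            raise ConfigError(
                f"need {N_DENSE - 1} hidden dense widths (output layer is "
                f"added automatically); got {len(self.dense_widths)}"
            )
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd ('same' padding)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings; ``seed`` fixes all randomness."""

    learning_rate: float = 1e-3
    lr_decay: float = 0.97       # per-epoch multiplicative decay
    epsilon: float = 1e-7        # Adam stability constant
    batch_size: int = 32
    epochs: int = 30
    patience: int = 8            # early-stop patience on validation loss
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epsilon, self.batch_size,
               self.epochs) <= 0:
            raise ConfigError("rates and sizes must be positive")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ConfigError("lr_decay must lie in (0, 1]")
        if not (0.0 <= self.validation_fraction < 0.5):
            raise ConfigError("validation_fraction must be in [0, 0.5)")


@dataclass
class PredictionSet:
    """Per-sample class probabilities plus the hard-call rule.

    Binary: ``probs`` is (N,), call = 1 iff p > threshold (strict).
    Multiclass: ``probs`` is (N, K), call = argmax with ties broken toward
    the lowest class index.
    """

    sample_ids: list[str]
    probs: np.ndarray
    threshold: float = 0.5

    def calls(self) -> np.ndarray:
        if self.probs.ndim == 1:
            return (self.probs > self.threshold).astype(int)
        return np.argmax(self.probs, axis=1)


class CNNClassifier:
    """A built (possibly trained) two-branch classifier."""

    def __init__(self, spec: ModelSpec, mode: str, seed: int) -> None:
        if mode not in ("2d", "1d"):
            raise ConfigError(f"unknown mode {mode!r}")
        self.spec = spec
        self.mode = mode
        self.seed = seed
        self.train_config: TrainConfig | None = None
        rng = np.random.default_rng(seed)

        l2 = spec.l2
        k = spec.kernel_size
        conv: list[nn.Layer] = []
        if spec.pool_type not in ("avg", "max"):
            raise ConfigError(f"unknown pool type {spec.pool_type!r}")
        if mode == "2d":
            c, h, w = spec.input_shape
            pool = spec.pool_size or 2
            Convolution = nn.Conv2D
            Pool = nn.AvgPool2D if spec.pool_type == "avg" else nn.MaxPool2D
            size = (h, w)
        else:
            length, c = spec.input_shape
            pool = spec.pool_size or 4
            Convolution = nn.Conv1D
            Pool = nn.AvgPool1D if spec.pool_type == "avg" else nn.MaxPool1D
            size = (length,)
        c_in = c
        for i, f in enumerate(spec.conv_filters, start=1):
            conv.append(Convolution(c_in, f, k, l2, rng))
            if spec.batch_norm:
                conv.append(nn.BatchNorm(f))
            conv.append(nn.ReLU())
            c_in = f
            if i % spec.pool_every == 0:
                if any(s % pool for s in size):
                    raise ConfigError(
                        f"spatial size {size} not divisible by pool {pool}"
                    )
                conv.append(Pool(pool))
                size = tuple(s // pool for s in size)
        conv.append(Convolution(c_in, spec.conv1x1_filters, 1, l2, rng))
        if spec.batch_norm:
            conv.append(nn.BatchNorm(spec.conv1x1_filters))
        conv.append(nn.ReLU())
        if spec.global_pool:
            conv.append(nn.GlobalAvgPool2D() if mode == "2d"
                        else nn.GlobalAvgPool1D())
            feat = spec.conv1x1_filters
        else:
            conv.append(nn.Flatten())
            feat = spec.conv1x1_filters * int(np.prod(size))
        self.conv_branch = conv

        self.embed = (
            nn.HistogramEmbedding(spec.embedding_dim, rng)
            if spec.use_embedding else None
        )
        if self.embed is not None:
            feat += spec.embedding_dim

        out_dim = 1 if spec.n_classes == 2 else spec.n_classes
        head: list[nn.Layer] = []
        n_in = feat
        for i, wdt in enumerate(spec.dense_widths):
            head.append(nn.Dense(n_in, wdt, l2, rng))
            head.append(nn.ReLU())
            if spec.dropout > 0:
                head.append(nn.Dropout(spec.dropout, seed=seed + 77 + i))
            n_in = wdt
        head.append(nn.Dense(n_in, out_dim, l2, rng))
        self.head = head

    # -- plumbing ----------------------------------------------------------

    @property
    def layers(self) -> list[nn.Layer]:
        out = list(self.conv_branch)
        if self.embed is not None:
            out.append(self.embed)
        return out + list(self.head)

    def prepare_inputs(self, aios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """AIO stack (N, C, H, W) uint8 -> (branch input, histogram)."""
        aios = np.asarray(aios)
        if aios.ndim != 4:
            raise ShapeError(f"expected (N, C, H, W) AIOs, got {aios.shape}")
        if self.mode == "2d":
            c, h, w = self.spec.input_shape
            if aios.shape[1:] != (c, h, w):
                raise ShapeError(
                    f"model expects {(c, h, w)} images, got {aios.shape[1:]}"
                )
            x = aios.transpose(0, 2, 3, 1).astype(np.float32) / np.float32(255)
        else:
            length, c = self.spec.input_shape
            if int(np.prod(aios.shape[1:])) != length * c:
                raise ShapeError(
                    f"model expects sequences of {length}x{c} values, "
                    f"got images of {int(np.prod(aios.shape[1:]))}"
                )
            x = aios.reshape(aios.shape[0], length, c).astype(np.float32)
            x /= np.float32(255)
        hist = nn.intensity_histogram(aios) if self.embed is not None else None
        return x, hist

    def forward(self, x: np.ndarray, hist: np.ndarray | None,
                train: bool = False) -> np.ndarray:
        h = x
        for ly in self.conv_branch:
            h = ly.forward(h, train=train)
        if self.embed is not None:
            e = self.embed.forward(hist, train=train)
            self._split = h.shape[1]
            h = np.concatenate([h, e], axis=1)
        z = h
        for ly in self.head:
            z = ly.forward(z, train=train)
        return z

    def backward(self, dz: np.ndarray) -> None:
        d = dz
        for ly in reversed(self.head):
            d = ly.backward(d)
        if self.embed is not None:
            d_conv, d_emb = d[:, : self._split], d[:, self._split:]
            self.embed.backward(d_emb)
            d = d_conv
        for ly in reversed(self.conv_branch):
            d = ly.backward(d)

    def reg_loss(self) -> float:
        return sum(ly.reg_loss() for ly in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        out = []
        for ly in self.layers:
            w = {k: v.copy() for k, v in ly.p.items()}
            if isinstance(ly, nn.BatchNorm):
                w["_run_mean"] = ly.run_mean.copy()
                w["_run_var"] = ly.run_var.copy()
            out.append(w)
        return out

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for ly, w in zip(self.layers, weights):
            for k in ly.p:
                ly.p[k][...] = w[k]
            if isinstance(ly, nn.BatchNorm):
                ly.run_mean[...] = w["_run_mean"]
                ly.run_var[...] = w["_run_var"]

    def summary(self) -> str:
        lines = [f"{type(self).__name__} mode={self.mode} "
                 f"input={self.spec.input_shape} classes={self.spec.n_classes}"]
        for name, branch in (("conv", self.conv_branch),
                             ("embed", [self.embed] if self.embed else []),
                             ("head", self.head)):
            for ly in branch:
                shapes = {k: tuple(v.shape) for k, v in ly.p.items()}
                lines.append(f"  [{name}] {type(ly).__name__} {shapes or ''}")
        return "\n".join(lines)


def save_model(model: CNNClassifier, path) -> None:
    """Persist a classifier: weights in an ``.npz`` container plus a JSON
    sidecar (``<path>.json``) recording ModelSpec, mode, build seed and
    the TrainConfig it was trained with."""
    import json

    arrays = {}
    for i, w in enumerate(model.get_weights()):
        for k, v in w.items():
            arrays[f"{i}/{k}"] = v
    np.savez(path, **arrays)
    meta = {
        "mode": model.mode,
        "seed": model.seed,
        "spec": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in model.spec.__dict__.items()},
        "train_config": (model.train_config.__dict__
                         if model.train_config else None),
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> CNNClassifier:
    """Rebuild a classifier saved by :func:`save_model`."""
    import json

    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    spec_kw = {k: tuple(v) if isinstance(v, list) else v
               for k, v in meta["spec"].items()}
    model = CNNClassifier(ModelSpec(**spec_kw), mode=meta["mode"],
                          seed=meta["seed"])
    if meta["train_config"]:
        model.train_config = TrainConfig(**meta["train_config"])
    with np.load(path) as z:
        weights = model.get_weights()
        for key in z.files:
            i, k = key.split("/", 1)
            weights[int(i)][k] = z[key]
    model.set_weights(weights)
    return model


def default_model_spec(mode: str, input_shape: tuple[int, ...],
                       n_classes: int = 2) -> ModelSpec:
    """The package's canonical architecture for each convolution mode.

    2D images use batch-normalized conv stages with average pooling and a
    global spatial average before the dense head (translation-invariant
    summary).  1D gene sequences keep the positional flatten — genome
    position is the one axis whose coordinates are meaningful — with
    dropout-regularized dense layers and no batch norm.
    """
    if mode == "2d":
        return ModelSpec(input_shape=input_shape, n_classes=n_classes)
    if mode == "1d":
        return ModelSpec(input_shape=input_shape, n_classes=n_classes,
                         global_pool=False, batch_norm=False)
    raise ConfigError(f"unknown mode {mode!r}")


def build_2d_classifier(spec: ModelSpec, seed: int = 0) -> CNNClassifier:
    """Build the two-branch 2D CNN for (C, H, W) image objects."""
    if len(spec.input_shape) != 3:
        raise ShapeError("2D classifier needs input_shape (channels, H, W)")
    return CNNClassifier(spec, mode="2d", seed=seed)


def build_1d_classifier(spec: ModelSpec, seed: int = 0) -> CNNClassifier:
    """Build the 1D-convolution variant for (length, channels) sequences."""
    if len(spec.input_shape) != 2:
        raise ShapeError("1D classifier needs input_shape (length, channels)")
    return CNNClassifier(spec, mode="1d", seed=seed)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of a class-balanced validation holdout."""
    mask = np.zeros(y.size, dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * idx.size))) if fraction > 0 else 0
        mask[idx[:n_val]] = True
    return mask


def train_model(
    model: CNNClassifier,
    aios: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> dict[str, list[float]]:
    """Train a classifier in place; returns the per-epoch loss history.

    Labels must be non-missing integers with at least two classes present.
    A stratified ``validation_fraction`` of the data is held out for early
    stopping; the weights from the best validation epoch are restored.
    A non-finite loss aborts with a hint to lower the learning rate.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels)
    if y.ndim != 1 or len(y) != len(aios):
        raise ShapeError("labels must be one per training sample")
    if np.any(pd.isna(y)):
        raise DegenerateLabelsError("training labels contain missing values")
    y = y.astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError(
            f"training needs >= 2 classes, got only {classes.tolist()}"
        )
    binary = model.spec.n_classes == 2
    if not binary and classes.max() >= model.spec.n_classes:
        raise ShapeError("label exceeds the model's class count")

    rng = np.random.default_rng(cfg.seed)
    x, hist = model.prepare_inputs(aios)

    use_val = cfg.validation_fraction > 0 and cfg.patience > 0
    if use_val:
        val_mask = _stratified_holdout(y, cfg.validation_fraction, rng)
    else:
        val_mask = np.zeros(y.size, dtype=bool)
    tr = np.flatnonzero(~val_mask)
    va = np.flatnonzero(val_mask)

    opt = nn.Adam(model.layers, learning_rate=cfg.learning_rate,
                  epsilon=cfg.epsilon)
    loss_fn = nn.binary_loss_and_grad if binary else nn.categorical_loss_and_grad

    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    stall = 0
    for _epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** _epoch
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            z = model.forward(x[b], None if hist is None else hist[b],
                              train=True)
            loss, dz, _ = loss_fn(z, y[b])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss is not finite; lower the learning rate"
                )
            model.backward(dz)
            opt.step()
            epoch_loss += loss * b.size
        history["loss"].append(epoch_loss / tr.size)

        if use_val:
            zv = model.forward(x[va], None if hist is None else hist[va])
            val_loss, _, _ = loss_fn(zv, y[va])
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    if best_weights is not None:
        model.set_weights(best_weights)
    model.train_config = cfg
    return history


def predict_proba(
    model: CNNClassifier,
    aios: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    threshold: float = 0.5,
    batch_size: int = 256,
) -> PredictionSet:
    """Class probabilities for an AIO stack (binary: scalar p per sample)."""
    x, hist = model.prepare_inputs(aios)
    chunks = []
    for start in range(0, len(x), batch_size):
        z = model.forward(x[start:start + batch_size],
                          None if hist is None else hist[start:start + batch_size])
        if model.spec.n_classes == 2:
            chunks.append(nn.sigmoid(z.reshape(-1)))
        else:
            chunks.append(nn.softmax(z))
    probs = np.concatenate(chunks, axis=0)
    ids = (list(map(str, sample_ids)) if sample_ids is not None
           else [str(i) for i in range(len(aios))])
    return PredictionSet(sample_ids=ids, probs=probs, threshold=threshold)


# ---------------------------------------------------------------------------
# repeated runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: TrainConfig
    metrics: dict[str, float]
    predictions: object | None = None


@dataclass
class RunEnsemble:
    """Results of repeated runs with perturbed hyperparameters/seeds."""

    runs: list[RunResult]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, sd) across runs (population sd, ddof=0)."""
        keys = sorted({k for r in self.runs for k in r.metrics
                       if r.metrics[k] is not None})
        out = {}
        for k in keys:
            vals = np.array([r.metrics[k] for r in self.runs], dtype=float)
            out[k] = (float(vals.mean()), float(vals.std()))
        return out


def repeated_runs(
    run_fn: Callable[[TrainConfig], dict[str, float]],
    base_cfg: TrainConfig,
    n_runs: int = 5,
    perturbations: Sequence[dict] | None = None,
) -> RunEnsemble:
    """Execute ``run_fn`` ``n_runs`` times with perturbed configurations.

    ``perturbations`` lists per-run overrides of :class:`TrainConfig`
    fields (e.g. learning-rate multipliers expressed as absolute values,
    alternative seeds).  Missing entries default to re-seeding run i with
    ``base_cfg.seed + i``.  With no perturbations, a single fixed seed and
    ``n_runs > 1`` the runs would be identical, which triggers a warning.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    if not perturbations and n_runs > 1:
        perturbations = [{"seed": base_cfg.seed + i} for i in range(n_runs)]
    elif not perturbations:
        perturbations = [{}]
    if len(perturbations) < n_runs:
        perturbations = list(perturbations) + [
            {"seed": base_cfg.seed + i} for i in range(len(perturbations), n_runs)
        ]
    if n_runs > 1 and all(not p for p in perturbations[:n_runs]):
        warnings.warn("all runs share one config and seed; results will be "
                      "identical", stacklevel=2)
    runs = []
    valid = {f.name for f in fields(TrainConfig)}
    for i in range(n_runs):
        over = {k: v for k, v in perturbations[i].items() if k in valid}
        cfg = replace(base_cfg, **over)
        metrics = run_fn(cfg)
        runs.append(RunResult(config=cfg, metrics=metrics))
    return RunEnsemble(runs=runs)
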