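"""Sequence classifiers over tooth feature images, plus the ablation harness.

The reference architecture reads the T×12 feature image row by row — each
triangle is one timestep — through two recurrent layers of gated recurrent
units (128 each by default; the first returns its full hidden sequence, the
second only its final state), then a 64-unit ReLU layer and a softmax head
with 4, 8 or 16 outputs. Training uses sparse categorical cross-entropy and
Adam at learning rate 5e-4.

Ablation variants keep matched capacity: vanilla RNN and LSTM mirror the GRU
stack exactly; the CNN treats the feature image as a one-channel 2D image
through two (3×3 conv → ReLU → 2×2 max-pool) blocks and the same dense head.

All networks run on the numpy engine in :mod:`toothseq.nn`; training is
deterministic given the seed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import nn
from .encoding import SUBSETS, FeatureImage, extract_features, to_feature_image
from .mesh import TriMesh
from .metrics import EvaluationReport, compute_metrics

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "build_model",
    "train",
    "evaluate",
    "predict",
    "run_ablation",
    "parameter_count",
]

VARIANTS = ("GRU", "LSTM", "RNN", "CNN")


@dataclass
class ModelConfig:
    variant: str = "GRU"
    recurrent_layers: int = 2
    recurrent_units: int = 128
    fc_units: int = 64
    num_classes: int = 16
    input_shape: Tuple[int, int] = (900, 12)
    learning_rate: float = 5e-4
    conv_filters: Tuple[int, int] = (32, 64)
    loss: str = "sparse_categorical_crossentropy"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.num_classes not in (4, 8, 16):
            raise ValueError("num_classes must be 4, 8 or 16")
        if self.recurrent_units < 1 or self.recurrent_layers < 1:
            raise ValueError("recurrent layers/units must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


@dataclass
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 32
    early_stopping_patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


class RecurrentClassifier:
    """Stacked recurrent layers → FC(ReLU) → softmax head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: Dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(0))

    def init_params(self, rng: np.random.Generator) -> None:
        c = self.cfg
        T, D = c.input_shape
        p: Dict[str, np.ndarray] = {}
        d_in = D
        for layer in range(c.recurrent_layers):
            for k, v in nn.init_recurrent(rng, c.variant, d_in, c.recurrent_units).items():
                p[f"rec{layer}.{k}"] = v
            d_in = c.recurrent_units
        for k, v in nn.init_dense(rng, d_in, c.fc_units).items():
            p[f"fc.{k}"] = v
        for k, v in nn.init_dense(rng, c.fc_units, c.num_classes).items():
            p[f"head.{k}"] = v
        self.params = p

    def _layer_params(self, prefix: str) -> Dict[str, np.ndarray]:
        n = len(prefix) + 1
        return {k[n:]: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    def forward(self, X: np.ndarray):
        c = self.cfg
        caches = []
        H = X
        for layer in range(c.recurrent_layers):
            H, cache = nn.recurrent_forward(
                c.variant, self._layer_params(f"rec{layer}"), H
            )
            caches.append(cache)
        h_last = H[:, -1]
        a, fc_x = nn.dense_forward(self._layer_params("fc"), h_last)
        r = nn.relu(a)
        logits, head_x = nn.dense_forward(self._layer_params("head"), r)
        return logits, (caches, a, fc_x, head_x, X.shape)

    def backward(self, dlogits: np.ndarray, cache):
        caches, a, fc_x, head_x, xshape = cache
        c = self.cfg
        grads: Dict[str, np.ndarray] = {}
        dr, g = nn.dense_backward(self._layer_params("head"), dlogits, head_x)
        grads.update({f"head.{k}": v for k, v in g.items()})
        da = dr * (a > 0)
        dh_last, g = nn.dense_backward(self._layer_params("fc"), da, fc_x)
        grads.update({f"fc.{k}": v for k, v in g.items()})
        B, T = xshape[0], xshape[1]
        dH = np.zeros((B, T, c.recurrent_units))
        dH[:, -1] = dh_last
        for layer in range(c.recurrent_layers - 1, -1, -1):
            dH, g = nn.recurrent_backward(
                c.variant, self._layer_params(f"rec{layer}"), dH, caches[layer]
            )
            grads.update({f"rec{layer}.{k}": v for k, v in g.items()})
        return grads


class ConvClassifier:
    """Two 3×3 conv + max-pool blocks → FC(ReLU) → softmax head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: Dict[str, np.ndarray] = {}
        self._plan_pools()
        self.init_params(np.random.default_rng(0))

    def _plan_pools(self) -> None:
        T, D = self.cfg.input_shape
        self.pools = []
        h, w = T, D
        for _ in range(2):
            ph = 2 if h >= 2 else 1
            pw = 2 if w >= 2 else 1
            self.pools.append((ph, pw))
            h, w = h // ph, w // pw
        self.flat_dim = self.cfg.conv_filters[1] * h * w

    def init_params(self, rng: np.random.Generator) -> None:
        c = self.cfg
        f1, f2 = c.conv_filters
        p: Dict[str, np.ndarray] = {}
        for name, (fout, fin) in (("conv0", (f1, 1)), ("conv1", (f2, f1))):
            fan_in, fan_out = fin * 9, fout * 9
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            p[f"{name}.W"] = rng.uniform(-limit, limit, (fout, fin, 3, 3))
            p[f"{name}.b"] = np.zeros(fout)
        for k, v in nn.init_dense(rng, self.flat_dim, c.fc_units).items():
            p[f"fc.{k}"] = v
        for k, v in nn.init_dense(rng, c.fc_units, c.num_classes).items():
            p[f"head.{k}"] = v
        self.params = p

    def _layer_params(self, prefix: str) -> Dict[str, np.ndarray]:
        n = len(prefix) + 1
        return {k[n:]: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    def forward(self, X: np.ndarray):
        x = X[:, None, :, :]  # (B, 1, T, D)
        caches = []
        for i in range(2):
            z, ccache = nn.conv_forward(self._layer_params(f"conv{i}"), x)
            r = nn.relu(z)
            x, pcache = nn.maxpool_forward(r, *self.pools[i])
            caches.append((ccache, z, pcache))
        B = X.shape[0]
        flat = x.reshape(B, -1)
        a, fc_x = nn.dense_forward(self._layer_params("fc"), flat)
        r = nn.relu(a)
        logits, head_x = nn.dense_forward(self._layer_params("head"), r)
        return logits, (caches, x.shape, a, fc_x, head_x)

    def backward(self, dlogits: np.ndarray, cache):
        caches, xshape, a, fc_x, head_x = cache
        grads: Dict[str, np.ndarray] = {}
        dr, g = nn.dense_backward(self._layer_params("head"), dlogits, head_x)
        grads.update({f"head.{k}": v for k, v in g.items()})
        da = dr * (a > 0)
        dflat, g = nn.dense_backward(self._layer_params("fc"), da, fc_x)
        grads.update({f"fc.{k}": v for k, v in g.items()})
        dx = dflat.reshape(xshape)
        for i in (1, 0):
            ccache, z, pcache = caches[i]
            dr = nn.maxpool_backward(dx, pcache)
            dz = dr * (z > 0)
            dx, g = nn.conv_backward(self._layer_params(f"conv{i}"), dz, ccache)
            grads.update({f"conv{i}.{k}": v for k, v in g.items()})
        return grads


Model = Union[RecurrentClassifier, ConvClassifier]


def build_model(cfg: ModelConfig) -> Model:
    """Instantiate an untrained classifier for a config."""
    if cfg.variant == "CNN":
        return ConvClassifier(cfg)
    return RecurrentClassifier(cfg)


def parameter_count(model: Model) -> int:
    return int(sum(v.size for v in model.params.values()))


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def _stack(dataset: Sequence, cfg: ModelConfig) -> Tuple[np.ndarray, np.ndarray]:
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    xs, ys = [], []
    for img, label in dataset:
        pixels = img.pixels if isinstance(img, FeatureImage) else np.asarray(img)
        if pixels.shape != tuple(cfg.input_shape):
            raise ValueError(
                f"image shape {pixels.shape} does not match the model's "
                f"input shape {tuple(cfg.input_shape)}"
            )
        label = int(label)
        if not 0 <= label < cfg.num_classes:
            raise ValueError(
                f"label {label} outside [0, {cfg.num_classes}) for this model"
            )
        xs.append(np.asarray(pixels, dtype=np.float64))
        ys.append(label)
    return np.stack(xs), np.array(ys, dtype=np.int64)


def _forward_loss(model: Model, X: np.ndarray, y: np.ndarray) -> float:
    logits, _ = model.forward(X)
    loss, _, _ = nn.softmax_xent(logits, y)
    return loss


def train(model: Model, train_set: Sequence, cfg: TrainingConfig):
    """Train in place; returns (model, history).

    A ``val_fraction`` carve-out of the training set monitors early stopping
    (patience on validation loss); when the carve-out rounds to zero samples,
    the training loss is monitored instead. The parameters with the best
    monitored loss are restored at the end. Deterministic given ``cfg.seed``.
    """
    X, y = _stack(train_set, model.cfg)
    rng = np.random.default_rng(cfg.seed)
    model.init_params(rng)
    n = len(X)
    n_val = int(math.floor(n * cfg.val_fraction))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation carve-out leaves no training samples")
    opt = nn.Adam(lr=model.cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    wait = 0
    for _epoch in range(cfg.epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, cache = model.forward(X[idx])
            loss, dlogits, _ = nn.softmax_xent(logits, y[idx])
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            total += loss * len(idx)
        train_loss = total / len(order)
        history["train_loss"].append(train_loss)
        if n_val:
            val_loss = _forward_loss(model, X[val_idx], y[val_idx])
            history["val_loss"].append(val_loss)
            monitor = val_loss
        else:
            monitor = train_loss
        if monitor < best_loss - 1e-12:
            best_loss = monitor
            best_params = {k: v.copy() for k, v in model.params.items()}
            wait = 0
        else:
            wait += 1
            if cfg.early_stopping_patience and wait >= cfg.early_stopping_patience:
                break
    model.params = best_params
    return model, history


def _batched_probs(model: Model, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    out = []
    for start in range(0, len(X), chunk):
        logits, _ = model.forward(X[start : start + chunk])
        out.append(nn.softmax(logits))
    return np.vstack(out)


def predict(model: Model, image) -> Tuple[int, np.ndarray]:
    """Class label (argmax; ties to the lowest index) and probability vector."""
    pixels = image.pixels if isinstance(image, FeatureImage) else np.asarray(image)
    if pixels.shape != tuple(model.cfg.input_shape):
        raise ValueError(
            f"image shape {pixels.shape} does not match input shape "
            f"{tuple(model.cfg.input_shape)}"
        )
    probs = _batched_probs(model, pixels[None].astype(np.float64))[0]
    return int(np.argmax(probs)), probs


def evaluate(model: Model, test_set: Sequence) -> EvaluationReport:
    """Per-class precision/recall/F1, accuracy and the confusion matrix."""
    X, y = _stack(test_set, model.cfg)
    probs = _batched_probs(model, X)
    pred = probs.argmax(axis=1)
    return compute_metrics(
        y.tolist(), pred.tolist(), labels=list(range(model.cfg.num_classes))
    )


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------


def run_ablation(
    dataset: Sequence[Tuple[TriMesh, int]],
    variants: Sequence[str] = ("CNN", "RNN", "LSTM", "GRU"),
    subsets: Sequence[str] = ("vertices", "centers", "both"),
    seeds: Sequence[int] = (0,),
    num_classes: int = 4,
    model_overrides: Optional[dict] = None,
    training: Optional[TrainingConfig] = None,
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """Cross every network variant with every feature subset.

    ``dataset`` is a list of (mesh, integer label) pairs, all meshes at a
    common triangle budget. For each seed one stratified split is drawn and
    shared by every (variant, subset) cell, so cells differ only in the
    model. Returns a table with one row per cell: mean ± sd test accuracy
    over the seeds.
    """
    from sklearn.model_selection import train_test_split

    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    if len(dataset) == 0:
        raise ValueError("ablation dataset is empty")
    meshes = [m for m, _ in dataset]
    y = np.array([int(l) for _, l in dataset])
    T = meshes[0].n_faces
    images = {
        s: [to_feature_image(extract_features(m, subset=s)) for m in meshes]
        for s in subsets
    }
    training = training or TrainingConfig()
    rows = []
    for variant in variants:
        for subset in subsets:
            accs = []
            for seed in seeds:
                tr, te = train_test_split(
                    np.arange(len(meshes)),
                    train_size=train_fraction,
                    random_state=int(seed),
                    stratify=y,
                )
                cfg = ModelConfig(
                    variant=variant,
                    num_classes=num_classes,
                    input_shape=(T, SUBSETS[subset]),
                    **(model_overrides or {}),
                )
                model = build_model(cfg)
                tcfg = replace(training, seed=int(seed))
                train(model, [(images[subset][i], y[i]) for i in tr], tcfg)
                report = evaluate(model, [(images[subset][i], y[i]) for i in te])
                accs.append(report.accuracy)
            rows.append(
                {
                    "variant": variant,
                    "subset": subset,
                    "num_classes": num_classes,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                    "seeds": ",".join(str(s) for s in seeds),
                }
            )
    return pd.DataFrame(rows)
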