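"""The DLIF sequence-regression network, training loop, cross-validation
and multi-seed ensembling.

The model maps a dynamic PET sequence (T frames of a 3-D volume) to a
T-point input function.  A per-frame encoder — shared across all frames —
stacks four blocks of [3-D convolution, batch normalization, ReLU, 2x2x2
max pooling], doubling the filter count while halving each spatial
dimension, until the volume reaches its smallest spatial extent.  The
flattened features are reduced by two dense layers to a compact per-frame
embedding; a 1-D convolution along the time axis then mixes neighboring
frames, and a final dense layer maps the concatenated temporal features to
the output curve, passed through a non-negative rectifier since activity
concentrations cannot be negative.

With the default 64x48x48 input the spatial ladder is
64x48x48 -> 32x24x24 -> 16x12x12 -> 8x6x6 -> 4x3x3, giving a per-frame
flatten length of 16*4*3*3 = 576, an embedding of 32, and a 16*41 -> 41
head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ..imaging_core import DynamicImage, TimeActivityCurve, ValidationError
from .layers import (
    Adam,
    BatchNorm,
    Conv1dSame,
    Conv3dSame,
    Dense,
    MaxPool3d,
    ReLU,
    Softplus,
    mse_loss,
)

__all__ = [
    "DlifArchConfig",
    "TrainConfig",
    "DlifNet",
    "DlifPrediction",
    "build_model",
    "train",
    "cross_validate",
    "ensemble_predict",
    "dataset_to_arrays",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DlifArchConfig:
    """Architecture hyperparameters; defaults realize the full-size model."""

    n_frames: int = 41
    in_shape: tuple[int, int, int] = (64, 48, 48)
    conv_filters: tuple[int, ...] = (2, 4, 8, 16)
    conv_kernel: int = 3
    pool: int = 2
    frame_embed_dims: tuple[int, int] = (128, 32)
    temporal_filters: int = 16
    temporal_kernel: int = 3
    output_activation: str = "softplus"  # softplus | relu

    def __post_init__(self) -> None:
        for a, b in zip(self.conv_filters, self.conv_filters[1:]):
            if b != 2 * a:
                raise ConfigError("conv filter counts must double per layer")
        div = self.pool ** len(self.conv_filters)
        if any(s % div != 0 for s in self.in_shape):
            raise ConfigError(
                f"in_shape {self.in_shape} not divisible by {div} for "
                f"{len(self.conv_filters)} pooling halvings"
            )
        if self.output_activation not in ("softplus", "relu"):
            raise ConfigError(f"unknown output activation {self.output_activation!r}")

    @property
    def shape_ladder(self) -> list[tuple[int, int, int]]:
        shapes = [self.in_shape]
        for _ in self.conv_filters:
            shapes.append(tuple(s // self.pool for s in shapes[-1]))
        return shapes

    @property
    def final_spatial(self) -> tuple[int, int, int]:
        return self.shape_ladder[-1]

    @property
    def flatten_len(self) -> int:
        return self.conv_filters[-1] * int(np.prod(self.final_spatial))

    @property
    def embedding_len(self) -> int:
        return self.frame_embed_dims[-1]

    @property
    def head_in(self) -> int:
        return self.temporal_filters * self.n_frames

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=list, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DlifArchConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("in_shape", "conv_filters", "frame_embed_dims"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


#: a reduced profile that trains on a single CPU in minutes
SCALED_ARCH = DlifArchConfig(in_shape=(16, 16, 16), frame_embed_dims=(64, 32))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam on a mean-squared-error loss."""

    epochs: int = 200
    lr: float = 2e-4
    batch_size: int = 4
    seed: int = 0
    n_runs: int = 50  # ensemble size

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.lr <= 0:
            raise ConfigError("learning rate must be > 0")


class DlifNet:
    """The assembled network; build with :func:`build_model`."""

    def __init__(self, cfg: DlifArchConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = cfg.conv_kernel
        self.encoder: list = []
        c_prev = 1
        for c in cfg.conv_filters:
            self.encoder += [
                Conv3dSame(c_prev, c, k, rng),
                BatchNorm(c),
                ReLU(),
                MaxPool3d(),
            ]
            c_prev = c
        h, e = cfg.frame_embed_dims
        self.fc1 = Dense(cfg.flatten_len, h, rng)
        self.fc1_act = ReLU()
        self.fc2 = Dense(h, e, rng)
        self.fc2_act = ReLU()
        self.temporal = Conv1dSame(e, cfg.temporal_filters, cfg.temporal_kernel, rng)
        self.temporal_act = ReLU()
        self.head = Dense(cfg.head_in, cfg.n_frames, rng)
        self.out_act = Softplus() if cfg.output_activation == "softplus" else ReLU()

    # --- parameter plumbing -------------------------------------------------
    def _layers(self):
        return [
            *self.encoder,
            self.fc1,
            self.fc1_act,
            self.fc2,
            self.fc2_act,
            self.temporal,
            self.temporal_act,
            self.head,
            self.out_act,
        ]

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    # --- forward / backward -------------------------------------------------
    def _encode_frames(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Shared per-frame encoder: (N, T, D, H, W) -> (N, T, embed)."""
        N, T = x.shape[:2]
        z = x.reshape(N * T, 1, *x.shape[2:]).astype(np.float32)
        for layer in self.encoder:
            z = layer.forward(z, train)
        z = z.reshape(N * T, -1)
        z = self.fc1_act.forward(self.fc1.forward(z, train), train)
        z = self.fc2_act.forward(self.fc2.forward(z, train), train)
        return z.reshape(N, T, -1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cfg.n_frames or x.shape[2:] != self.cfg.in_shape:
            raise ValidationError(
                f"input shape {x.shape[1:]} != ({self.cfg.n_frames}, *{self.cfg.in_shape})"
            )
        N, T = x.shape[:2]
        emb = self._encode_frames(x, train)  # (N, T, e)
        z = np.ascontiguousarray(emb.transpose(0, 2, 1))  # (N, e, T)
        z = self.temporal_act.forward(self.temporal.forward(z, train), train)
        self._temporal_out_shape = z.shape
        z = z.reshape(N, -1)
        z = self.head.forward(z, train)
        return self.out_act.forward(z, train)

    def backward(self, gy: np.ndarray) -> None:
        N = gy.shape[0]
        g = self.out_act.backward(gy)
        g = self.head.backward(g)
        g = g.reshape(self._temporal_out_shape)
        g = self.temporal.backward(self.temporal_act.backward(g))
        g = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, T, e)
        T = g.shape[1]
        g = g.reshape(N * T, -1)
        g = self.fc2.backward(self.fc2_act.backward(g))
        g = self.fc1.backward(self.fc1_act.backward(g))
        g = g.reshape(N * T, self.cfg.conv_filters[-1], *self.cfg.final_spatial)
        for layer in reversed(self.encoder):
            g = layer.backward(g)

    # --- inference ----------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward (running batch-norm statistics)."""
        return self.forward(np.asarray(x, dtype=np.float32), train=False)

    def frame_embeddings(self, x: np.ndarray) -> np.ndarray:
        """Per-frame embeddings before the temporal stage, eval mode."""
        return self._encode_frames(np.asarray(x, dtype=np.float32), train=False)

    # --- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, layer in enumerate(self._layers()):
            if isinstance(layer, BatchNorm):
                arrays[f"bn{i}_mean"] = layer.running_mean
                arrays[f"bn{i}_var"] = layer.running_var
        np.savez(path, **arrays)
        self.cfg.to_json(path.with_suffix(".json"))

    @classmethod
    def load(cls, path: str | Path) -> "DlifNet":
        path = Path(path)
        cfg = DlifArchConfig.from_json(path.with_suffix(".json"))
        model = cls(cfg)
        with np.load(path) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
            for i, layer in enumerate(model._layers()):
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"bn{i}_mean"]
                    layer.running_var = data[f"bn{i}_var"]
        return model


def build_model(cfg: DlifArchConfig | None = None, seed: int = 0) -> DlifNet:
    """Construct the network with seeded He-normal initialization."""
    return DlifNet(cfg or DlifArchConfig(), seed=seed)


def dataset_to_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Convert ``[(DynamicImage, TimeActivityCurve), ...]`` to (X, y) arrays.

    Raw ``(array, array)`` pairs pass through unchanged.
    """
    xs, ys = [], []
    for img, target in dataset:
        x = img.voxels if isinstance(img, DynamicImage) else np.asarray(img)
        y = (
            target.value_suv
            if isinstance(target, TimeActivityCurve)
            else np.asarray(target)
        )
        xs.append(np.asarray(x, dtype=np.float32))
        ys.append(np.asarray(y, dtype=np.float32))
    X = np.stack(xs)
    y = np.stack(ys)
    if not all(a.shape == xs[0].shape for a in xs):
        raise ValidationError("all images must share shape and schedule")
    return X, y


def train(
    model: DlifNet, dataset, cfg: TrainConfig
) -> tuple[DlifNet, np.ndarray]:
    """Minimize the MSE between predictions and targets with Adam.

    Returns the trained model and the per-epoch mean training loss.
    Deterministic given ``cfg.seed`` (which drives only the minibatch
    shuffling; initialization is seeded at model construction).
    """
    X, y = dataset_to_arrays(dataset)
    if X.shape[1] != model.cfg.n_frames or X.shape[2:] != model.cfg.in_shape:
        raise ValidationError(
            f"dataset shape {X.shape[1:]} incompatible with model config"
        )
    if y.shape[1] != model.cfg.n_frames:
        raise ValidationError("target length must equal n_frames")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)
    n = len(X)
    history = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(X[idx], train=True)
            loss, gy = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            model.backward(gy)
            opt.step()
            losses.append(loss)
        history[epoch] = float(np.mean(losses))
    return model, history


@dataclass
class DlifPrediction:
    """A predicted input function, optionally with ensemble statistics."""

    curve: np.ndarray  # mean curve (n_frames,)
    per_run: np.ndarray | None = None  # (n_runs, n_frames)
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.curve < 0):
            raise ValidationError("predicted curve must be non-negative")


def make_folds(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded permutation of ``range(n)`` split into ``k`` nearly equal folds.

    Remainders are spread one per fold, so 68 samples at k=17 give 17 test
    sets of exactly 4.  The folds partition the index set.
    """
    if k > n:
        raise ValidationError(f"k={k} exceeds dataset size {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def cross_validate(
    dataset, k: int, cfg: TrainConfig, arch: DlifArchConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """k-fold cross-validation: each sample predicted once, out of fold.

    Fold assignment comes from :func:`make_folds` (seeded permutation,
    remainders spread one per fold).  Returns the out-of-fold predictions
    aligned to the dataset and the fold index of each sample.
    """
    X, y = dataset_to_arrays(dataset)
    n = len(X)
    folds = make_folds(n, k, cfg.seed)
    arch = arch or DlifArchConfig()
    preds = np.empty((n, arch.n_frames), dtype=np.float32)
    fold_of = np.empty(n, dtype=int)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = build_model(arch, seed=cfg.seed + 1000 + f)
        model, _ = train(
            model,
            list(zip(X[train_idx], y[train_idx])),
            replace(cfg, seed=cfg.seed + 2000 + f),
        )
        preds[test_idx] = model.predict(X[test_idx])
        fold_of[test_idx] = f
    return preds, fold_of


def ensemble_predict(
    dataset_train,
    sample: np.ndarray | DynamicImage,
    cfg: TrainConfig,
    arch: DlifArchConfig | None = None,
    z: float = 1.0,
    seeds: list[int] | None = None,
) -> DlifPrediction:
    """Train ``cfg.n_runs`` models from distinct seeds and pool predictions.

    Returns the per-run curves, their mean, and a mean ± z*SD dispersion
    band.  ``seeds`` overrides the default run seeds (cfg.seed + run index).
    """
    if cfg.n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if seeds is not None and len(seeds) != cfg.n_runs:
        raise ValidationError("seeds must have length n_runs")
    arch = arch or DlifArchConfig()
    x = sample.voxels if isinstance(sample, DynamicImage) else np.asarray(sample)
    x = x[None].astype(np.float32)
    runs = []
    for r in range(cfg.n_runs):
        run_seed = seeds[r] if seeds is not None else cfg.seed + r
        model = build_model(arch, seed=run_seed)
        model, _ = train(model, dataset_train, replace(cfg, seed=run_seed))
        runs.append(model.predict(x)[0])
    per_run = np.stack(runs)
    mean = per_run.mean(axis=0)
    sd = per_run.std(axis=0)
    return DlifPrediction(
        curve=mean, per_run=per_run, band_lo=mean - z * sd, band_hi=mean + z * sd
    )
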