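"""The modified VGG-style 3D CNN: configuration, construction, inference.

The network is a stack of ``n_conv_blocks`` blocks, each
[Conv3D(n_filters, kernel 5, same padding) -> BatchNorm -> ReLU ->
MaxPool(2,2,2)], followed by flatten -> dense hidden layer (ReLU) -> 2-way
softmax.  Input tensors are (3, 20, 50, 50): dapi, reflectance and
transmission channels of one standardized cell.  Per-channel normalization
statistics (computed on the training split) are stored with the model so
inference is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..dataset import CHANNEL_ORDER, STANDARD_SHAPE
from .layers import (
    Adam,
    BatchNorm3D,
    Conv3D,
    Dense,
    Flatten,
    MaxPool3D,
    ReLU,
    ReLUDense,
    softmax,
)

N_CLASSES = 2


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its bootstrapped training."""

    n_filters: int = 16
    kernel: int = 5
    pool: tuple[int, int, int] = (2, 2, 2)
    learning_rate: float = 0.0001
    lr_decay: float = 0.96          # exponential, per epoch
    batch_size: int = 16
    max_epochs: int = 30
    n_runs: int = 25
    n_conv_blocks: int = 3
    dense_width: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        dims = self.feature_dims()
        if min(dims) < 1:
            raise ValueError(
                f"{self.n_conv_blocks} conv blocks with pool {self.pool} collapse "
                f"the input {STANDARD_SHAPE} below one voxel"
            )

    def feature_dims(self) -> tuple[int, int, int]:
        """Spatial dims after all pooling stages."""
        dims = list(STANDARD_SHAPE)
        for _ in range(self.n_conv_blocks):
            dims = [d // p for d, p in zip(dims, self.pool)]
        return tuple(dims)

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lr_decay**epoch


class CNN3D:
    """A trained or trainable classifier instance."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.layers = []
        c_in = len(CHANNEL_ORDER)
        for block in range(config.n_conv_blocks):
            self.layers.append(
                Conv3D(c_in, config.n_filters, config.kernel, rng,
                       first_layer=(block == 0))
            )
            self.layers.append(BatchNorm3D(config.n_filters))
            self.layers.append(ReLU())
            self.layers.append(MaxPool3D(config.pool))
            c_in = config.n_filters
        self.layers.append(Flatten())
        n_flat = config.n_filters * int(np.prod(config.feature_dims()))
        self.layers.append(Dense(n_flat, config.dense_width, rng))
        self.layers.append(ReLUDense())
        self.layers.append(Dense(config.dense_width, N_CLASSES, rng))
        # per-input-channel normalization (identity until trained)
        self.norm_mean = np.zeros(len(CHANNEL_ORDER), dtype=np.float32)
        self.norm_std = np.ones(len(CHANNEL_ORDER), dtype=np.float32)

    # -- plumbing ----------------------------------------------------------
    def normalize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.norm_mean[None, :, None, None, None])
                / self.norm_std[None, :, None, None, None]).astype(np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def make_optimizer(self) -> Adam:
        return Adam(self.layers)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32,
                      normalized: bool = False) -> np.ndarray:
        """Class probabilities in inference mode (running BN statistics)."""
        if x.ndim == 4:
            x = x[None]
        expected = (len(CHANNEL_ORDER),) + STANDARD_SHAPE
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} != {expected}")
        if not normalized:
            x = self.normalize(x)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.concatenate(out)

    # -- weight snapshots --------------------------------------------------
    def state(self) -> list[np.ndarray]:
        arrays = []
        for layer in self.layers:
            for _, value, _ in layer.params():
                arrays.append(value.copy())
            if isinstance(layer, BatchNorm3D):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        arrays.append(self.norm_mean.copy())
        arrays.append(self.norm_std.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for _, value, _ in layer.params():
                value[...] = next(it)
            if isinstance(layer, BatchNorm3D):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)
        self.norm_mean[...] = next(it)
        self.norm_std[...] = next(it)

    def save(self, path) -> None:
        path = Path(path)
        arrays = self.state()
        cfg = asdict(self.config)
        np.savez_compressed(
            path, config=json.dumps(cfg),
            **{f"arr_{i}": a for i, a in enumerate(arrays)},
        )

    @classmethod
    def load(cls, path) -> "CNN3D":
        data = np.load(path, allow_pickle=False)
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["pool"] = tuple(cfg_dict["pool"])
        config = ModelConfig(**cfg_dict)
        model = cls(config, np.random.default_rng(0))
        n = len([k for k in data.files if k.startswith("arr_")])
        model.load_state([data[f"arr_{i}"] for i in range(n)])
        return model


def build_model(config: ModelConfig, rng: np.random.Generator | None = None) -> CNN3D:
    """Construct the network with seeded He initialization."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return CNN3D(config, rng)
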