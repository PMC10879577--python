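"""A scaled-down simple fully convolutional network (SFCN) for 3D volumes.

Architecture: ``n_conv_blocks`` of {3x3x3 conv -> instance norm -> ReLU ->
2x max pool}, then dropout (applied before flattening), flatten, and a
single linear layer to two logits; the disease score is the softmax
probability of the positive class.  The feature extractor is fully
convolutional; the only dense layer is the final classifier head.

Instance normalisation is used instead of batch statistics so that forward
passes are deterministic, identical in train and eval mode, and well defined
for the single-sample batches that tiny centers produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .nn import (
    Adam,
    Conv3d,
    Dropout,
    Flatten,
    InstanceNorm3d,
    Layer,
    Linear,
    MaxPool3d2x,
    ReLU,
    cross_entropy_with_grad,
    softmax,
)

__all__ = [
    "ModelConfig",
    "SFCN3D",
    "build_model",
    "predict_scores",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The defaults (4 blocks, channels 8/16/32/32, grid 24, dropout 0.20
    before the flattening stage) keep one training cycle on a few hundred
    volumes in the seconds range on a single CPU core.
    """

    n_conv_blocks: int = 4
    channels: tuple[int, ...] = (8, 16, 32, 32)
    dropout_rate: float = 0.20
    n_classes: int = 2
    grid_size: int = 24
    init_seed: int = 0
    first_conv_stride: int = 1  # stride-2 input conv halves the working grid

    def validate(self) -> None:
        if self.n_conv_blocks < 1:
            raise ConfigurationError("need at least one conv block")
        if len(self.channels) != self.n_conv_blocks:
            raise ConfigurationError(
                f"channels list length {len(self.channels)} != n_conv_blocks {self.n_conv_blocks}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.n_classes != 2:
            raise ConfigurationError("only binary classification is supported")
        if self.first_conv_stride < 1:
            raise ConfigurationError("first_conv_stride must be >= 1")
        if self.final_spatial() < 1:
            raise ConfigurationError(
                f"grid {self.grid_size} collapses below 1 voxel after "
                f"{self.n_conv_blocks} pooling stages"
            )

    def final_spatial(self) -> int:
        s = self.grid_size
        for i in range(self.n_conv_blocks):
            if i == 0:
                s = (s + self.first_conv_stride - 1) // self.first_conv_stride
            s //= 2
        return s

    def n_parameters(self) -> int:
        """Closed-form parameter count (kernels + biases + norm affines + head)."""
        total = 0
        c_in = 1
        for c_out in self.channels:
            total += c_out * c_in * 27 + c_out  # conv kernel + bias
            total += 2 * c_out  # instance-norm gamma + beta
            c_in = c_out
        feat = self.channels[-1] * self.final_spatial() ** 3
        total += feat * self.n_classes + self.n_classes  # linear head
        return total


class SFCN3D:
    """The classifier: a stack of numpy layers plus loss/score helpers."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.Generator(np.random.PCG64(derive_seed(config.init_seed, "init")))
        self.layers: list[Layer] = []
        self._names: list[str] = []
        c_in = 1
        for i, c_out in enumerate(config.channels):
            stride = config.first_conv_stride if i == 0 else 1
            self._add(
                f"block{i}.conv",
                Conv3d(c_in, c_out, rng, skip_input_grad=(i == 0), stride=stride),
            )
            self._add(f"block{i}.norm", InstanceNorm3d(c_out))
            self._add(f"block{i}.relu", ReLU())
            self._add(f"block{i}.pool", MaxPool3d2x())
            c_in = c_out
        self._add("dropout", Dropout(config.dropout_rate))
        self._add("flatten", Flatten())
        feat = config.channels[-1] * config.final_spatial() ** 3
        self._add("head", Linear(feat, config.n_classes, rng))

    def _add(self, name: str, layer: Layer) -> None:
        self.layers.append(layer)
        self._names.append(name)

    # -- parameter access ---------------------------------------------------

    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in zip(self._names, self.layers):
            for pname, arr in layer.params.items():
                out[f"{name}.{pname}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in zip(self._names, self.layers):
            for pname, arr in layer.grads.items():
                out[f"{name}.{pname}"] = arr
        return out

    def n_parameters(self) -> int:
        return sum(int(a.size) for a in self.named_params().values())

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        for name, arr in values.items():
            current[name][...] = arr

    def copy(self) -> "SFCN3D":
        clone = SFCN3D(self.config)
        clone.set_params({k: v.copy() for k, v in self.named_params().items()})
        return clone

    def make_optimizer(self) -> Adam:
        return Adam(sorted(self.named_params().keys()))

    # -- forward / training step -------------------------------------------

    def forward(
        self, x: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if x.ndim == 4:  # (B, D, H, W) -> add trailing channel axis
            x = x[..., None]
        expected = (self.config.grid_size,) * 3
        if x.shape[1:4] != expected:
            raise ValueError(f"expected spatial shape {expected}, got {x.shape[1:4]}")
        out = x if np.issubdtype(x.dtype, np.floating) else x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def loss_and_grads(
        self, x: np.ndarray, labels: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Training forward + backward; returns mean loss and named grads."""
        logits = self.forward(x, train=True, rng=rng)
        loss, dlogits = cross_entropy_with_grad(logits, np.asarray(labels))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss, self.named_grads()

    def eval_loss(self, x: np.ndarray, labels: np.ndarray) -> float:
        logits = self.forward(x, train=False)
        loss, _ = cross_entropy_with_grad(logits, np.asarray(labels))
        return loss


def build_model(config: ModelConfig) -> SFCN3D:
    """Construct the classifier with reproducible initialisation."""
    return SFCN3D(config)


def predict_scores(model: SFCN3D, volumes: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Disease scores in [0, 1] for a stack of volumes (evaluation mode)."""
    scores = []
    for start in range(0, volumes.shape[0], batch_size):
        logits = model.forward(volumes[start : start + batch_size], train=False)
        scores.append(softmax(logits.astype(np.float64))[:, 1])
    return np.concatenate(scores)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, model: SFCN3D, optimizer: Adam | None = None) -> None:
    """Single-archive checkpoint: parameters, optimizer state, config."""
    arrays: dict[str, np.ndarray] = {}
    for k, v in model.named_params().items():
        arrays[f"param/{k}"] = v
    meta = {"config": vars(model.config) | {"channels": list(model.config.channels)}}
    if optimizer is not None:
        state = optimizer.state_dict()
        for k, v in state["m"].items():
            arrays[f"adam_m/{k}"] = v
        for k, v in state["v"].items():
            arrays[f"adam_v/{k}"] = v
        meta["adam"] = {
            "t": state["t"],
            "beta1": state["beta1"],
            "beta2": state["beta2"],
            "eps": state["eps"],
            "names": optimizer.param_names,
        }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SFCN3D, Adam | None]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        cfg_dict = dict(meta["config"])
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        model = SFCN3D(ModelConfig(**cfg_dict))
        model.set_params(
            {k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")}
        )
        optimizer = None
        if "adam" in meta:
            optimizer = Adam(
                meta["adam"]["names"],
                beta1=meta["adam"]["beta1"],
                beta2=meta["adam"]["beta2"],
                eps=meta["adam"]["eps"],
            )
            optimizer.load_state_dict(
                {
                    "t": meta["adam"]["t"],
                    "m": {k[len("adam_m/") :]: data[k] for k in data.files if k.startswith("adam_m/")},
                    "v": {k[len("adam_v/") :]: data[k] for k in data.files if k.startswith("adam_v/")},
                    "beta1": meta["adam"]["beta1"],
                    "beta2": meta["adam"]["beta2"],
                    "eps": meta["adam"]["eps"],
                }
            )
    return model, optimizer
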