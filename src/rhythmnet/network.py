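"""Declarative builder for the deep 1-D CNN + BiLSTM rhythm classifier.

The default architecture is 24 same-padded convolutional layers of kernel
width 16 in three 8-layer blocks with 32, 64 and 128 filters, each
convolution followed by batch normalization, ReLU and dropout, with a 2/2
max pool after every two convolutions (12 pools in total); the pooled
feature sequence feeds a BiLSTM-64 returning sequences, then a BiLSTM-128
whose final concatenated hidden state feeds a 128/64/32/4 dense head ending
in softmax over the four rhythm classes.

``build_architecture`` emits an ordered, backend-agnostic list of
``LayerSpec`` entries; ``instantiate`` realizes it on the bundled numpy
engine with seeded, reproducible initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from . import backend

__all__ = [
    "LayerSpec",
    "ArchitectureConfig",
    "ArchitectureError",
    "build_architecture",
    "output_sequence_length",
    "instantiate",
    "parameter_count",
]

LAYER_KINDS = (
    "conv1d", "batchnorm", "activation", "dropout",
    "maxpool1d", "bilstm", "dense", "softmax",
)
FINAL_ACTIVATIONS = ("softmax", "relu-then-softmax")


class ArchitectureError(ValueError):
    """Inconsistent architecture configuration."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer: a kind plus kind-specific parameters."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ArchitectureError(f"unknown layer kind {self.kind!r}")
        for key, value in self.params.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                if key in ("filters", "kernel", "size", "stride", "units", "width") and value <= 0:
                    raise ArchitectureError(f"{self.kind}.{key} must be positive")
        if self.kind == "bilstm" and self.params.get("merge_mode", "concat") != "concat":
            raise ArchitectureError(
                "bilstm merge mode is concatenation: forward and backward "
                "hidden states are joined, never summed"
            )


@dataclass(frozen=True)
class ArchitectureConfig:
    """Tunable description of the network; defaults give the full model."""

    filters_per_block: tuple[int, ...] = (32, 64, 128)
    conv_per_block: int = 8
    kernel: int = 16
    pool_every: int = 2
    pool_size: int = 2
    pool_stride: int = 2
    dropout: float = 0.2
    bilstm_units: tuple[int, ...] = (64, 128)
    dense_widths: tuple[int, ...] = (128, 64, 32, 4)
    final_activation: str = "softmax"
    input_length: int = 9000
    n_classes: int = 4

    def validate(self) -> None:
        problems = []
        if self.conv_per_block % self.pool_every != 0:
            problems.append("conv_per_block must be divisible by pool_every")
        if self.dense_widths[-1] != self.n_classes:
            problems.append("last dense width must equal n_classes")
        if self.final_activation not in FINAL_ACTIVATIONS:
            problems.append(f"final_activation must be one of {FINAL_ACTIVATIONS}")
        if not (0 <= self.dropout < 1):
            problems.append("dropout rate must be in [0, 1)")
        if min(self.filters_per_block) <= 0 or self.kernel <= 0:
            problems.append("filter counts and kernel width must be positive")
        if self.pool_size != self.pool_stride:
            problems.append("pooling is non-overlapping: pool_size must equal pool_stride")
        if problems:
            raise ArchitectureError("; ".join(problems))

    @property
    def n_conv_layers(self) -> int:
        return len(self.filters_per_block) * self.conv_per_block

    @property
    def n_pools(self) -> int:
        return self.n_conv_layers // self.pool_every


def build_architecture(config: ArchitectureConfig | None = None) -> list[LayerSpec]:
    """Emit the ordered layer list for ``config`` (default: the full model).

    Every convolution is followed by batchnorm -> ReLU -> dropout; a max
    pool follows every ``pool_every`` convolutions; the BiLSTM stack comes
    next (all but the last return sequences, the last returns its final
    concatenated hidden state); dense layers each get a ReLU except the
    last, which uses ``config.final_activation``.
    """
    config = config or ArchitectureConfig()
    config.validate()
    specs: list[LayerSpec] = []
    conv_idx = 0
    for filters in config.filters_per_block:
        for _ in range(config.conv_per_block):
            specs.append(LayerSpec("conv1d", {
                "filters": filters, "kernel": config.kernel, "padding": "same",
            }))
            specs.append(LayerSpec("batchnorm", {}))
            specs.append(LayerSpec("activation", {"fn": "relu"}))
            specs.append(LayerSpec("dropout", {"rate": config.dropout}))
            conv_idx += 1
            if conv_idx % config.pool_every == 0:
                specs.append(LayerSpec("maxpool1d", {
                    "size": config.pool_size, "stride": config.pool_stride,
                }))
    for j, units in enumerate(config.bilstm_units):
        specs.append(LayerSpec("bilstm", {
            "units": units,
            "merge_mode": "concat",
            "return_sequences": j < len(config.bilstm_units) - 1,
        }))
    for j, width in enumerate(config.dense_widths):
        specs.append(LayerSpec("dense", {"width": width}))
        last = j == len(config.dense_widths) - 1
        if not last:
            specs.append(LayerSpec("activation", {"fn": "relu"}))
        else:
            if config.final_activation == "relu-then-softmax":
                specs.append(LayerSpec("activation", {"fn": "relu"}))
            specs.append(LayerSpec("softmax", {}))
    return specs


def output_sequence_length(config: ArchitectureConfig) -> int:
    """Temporal length entering the BiLSTM stack.

    Same-padded convolutions preserve length, so only the pools shrink it:
    repeated floor division by the pool stride, once per pool.
    """
    config.validate()
    length = config.input_length
    for _ in range(config.n_pools):
        length //= config.pool_stride
    if length < 1:
        raise ArchitectureError(
            f"input length {config.input_length} too short for "
            f"{config.n_pools} pools of stride {config.pool_stride}"
        )
    return length


def instantiate(
    specs: list[LayerSpec],
    seed: int = 0,
    in_channels: int = 1,
    dtype=np.float32,
) -> backend.Sequential:
    """Realize a LayerSpec list as a trainable numpy model.

    Initialization and dropout randomness derive from ``seed``; two
    instantiations with the same seed produce identical models.
    """
    rng = np.random.default_rng(seed)
    layers: list[backend.Layer] = []
    channels = in_channels
    in_sequence_domain = True  # (B, C, L) until we transpose for the BiLSTM
    for spec in specs:
        kind, p = spec.kind, spec.params
        if kind == "conv1d":
            layers.append(backend.Conv1D(channels, p["filters"], p["kernel"], rng, dtype))
            channels = p["filters"]
        elif kind == "batchnorm":
            layers.append(backend.BatchNorm1D(channels, dtype=dtype))
        elif kind == "activation":
            layers.append(backend.ReLU())
        elif kind == "dropout":
            layers.append(backend.Dropout(p["rate"], np.random.default_rng(rng.integers(2**31))))
        elif kind == "maxpool1d":
            layers.append(backend.MaxPool1D(p["size"]))
        elif kind == "bilstm":
            if in_sequence_domain:
                layers.append(backend.ToSequence())
                in_sequence_domain = False
            layers.append(backend.BiLSTM(
                channels, p["units"], rng,
                return_sequences=p["return_sequences"], dtype=dtype,
            ))
            channels = 2 * p["units"]
        elif kind == "dense":
            layers.append(backend.Dense(channels, p["width"], rng, dtype))
            channels = p["width"]
        elif kind == "softmax":
            layers.append(backend.Softmax())
        else:  # pragma: no cover - LayerSpec already validates kinds
            raise ArchitectureError(f"unsupported layer kind {kind!r}")
    return backend.Sequential(layers)


def parameter_count(config: ArchitectureConfig, in_channels: int = 1) -> int:
    """Closed-form trainable-parameter count for ``config``."""
    config.validate()
    total = 0
    channels = in_channels
    for filters in config.filters_per_block:
        for _ in range(config.conv_per_block):
            total += filters * channels * config.kernel + filters  # conv W + b
            total += 2 * filters  # batchnorm gamma + beta
            channels = filters
    for units in config.bilstm_units:
        per_direction = (channels * 4 * units) + (units * 4 * units) + 4 * units
        total += 2 * per_direction
        channels = 2 * units
    for width in config.dense_widths:
        total += channels * width + width
        channels = width
    return total
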