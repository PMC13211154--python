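"""The fully convolutional pain classifier.

The network is declared by :class:`FcnConfig` and assembled from the
NumPy layer engine in :mod:`edapain.nn`.  The default configuration is
the deployed real-time architecture: two valid-mode conv blocks
(1→71 maps, kernel 2, batch-norm, ReLU; 71→120 maps, kernel 3,
batch-norm, Tanh), average pooling with kernel 3, a flatten to 39 840
features, and a linear classifier to 3 logits.  The conv kernel lengths
are the unique values consistent with the published layer shapes
(1000→999 forces kernel 2; 999→997 forces kernel 3).

:func:`shape_trace` performs the deterministic layer-by-layer shape
arithmetic, and :func:`count_macs` the analytic multiply–accumulate
count, both without instantiating any weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from edapain import nn

ACTIVATIONS = ("none", "relu", "sigmoid", "tanh")


class ArchitectureError(ValueError):
    """A layer in the declared architecture cannot be realised."""


@dataclass(frozen=True)
class ConvBlock:
    out_channels: int
    kernel_len: int
    activation: str = "relu"
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.kernel_len < 1 or self.out_channels < 1:
            raise ValueError("kernel_len and out_channels must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


def _default_blocks() -> tuple[ConvBlock, ...]:
    return (ConvBlock(71, 2, "relu", True), ConvBlock(120, 3, "tanh", True))


@dataclass(frozen=True)
class FcnConfig:
    input_len: int = 1000
    input_channels: int = 1
    conv_blocks: tuple[ConvBlock, ...] = field(default_factory=_default_blocks)
    avgpool_kernel: int = 3
    n_classes: int = 3
    #: subtract each window's mean before the first convolution.  Removes the
    #: subject-specific tonic offset (which otherwise dominates batch-norm
    #: batch statistics) while preserving phasic amplitudes.
    center_input: bool = True
    zscore_input: bool = False  # full per-window standardisation, off by default

    def __post_init__(self) -> None:
        if self.avgpool_kernel < 1:
            raise ValueError("avgpool_kernel must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        return {
            "input_len": self.input_len,
            "input_channels": self.input_channels,
            "conv_blocks": [[b.out_channels, b.kernel_len, b.activation, b.batch_norm] for b in self.conv_blocks],
            "avgpool_kernel": self.avgpool_kernel,
            "n_classes": self.n_classes,
            "center_input": self.center_input,
            "zscore_input": self.zscore_input,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FcnConfig":
        blocks = tuple(ConvBlock(int(c), int(k), str(a), bool(bn)) for c, k, a, bn in d["conv_blocks"])
        return cls(
            input_len=int(d["input_len"]),
            input_channels=int(d["input_channels"]),
            conv_blocks=blocks,
            avgpool_kernel=int(d["avgpool_kernel"]),
            n_classes=int(d["n_classes"]),
            center_input=bool(d.get("center_input", True)),
            zscore_input=bool(d.get("zscore_input", False)),
        )


@dataclass
class ShapeTrace:
    """Ordered (layer name, input shape, output shape) rows; conv/pool
    shapes are (channels, length), flatten onward are (features,)."""

    rows: list[tuple[str, tuple, tuple]]

    @property
    def flatten_size(self) -> int:
        for name, _, out in self.rows:
            if name == "flatten":
                return out[0]
        raise ValueError("trace has no flatten row")

    def __str__(self) -> str:
        w = max(len(r[0]) for r in self.rows)
        return "\n".join(f"{name:<{w}}  {inp} -> {out}" for name, inp, out in self.rows)


def shape_trace(config: FcnConfig, input_len: int | None = None) -> ShapeTrace:
    """Deterministic shape arithmetic: valid-mode convs (out = in − k + 1,
    stride 1), average pool with stride = kernel and floor division,
    flatten = channels × pooled length."""
    length = config.input_len if input_len is None else input_len
    channels = config.input_channels
    rows: list[tuple[str, tuple, tuple]] = []
    for i, block in enumerate(config.conv_blocks):
        out_len = length - block.kernel_len + 1
        if out_len < 1:
            raise ArchitectureError(f"conv{i}: input length {length} shorter than kernel {block.kernel_len}")
        rows.append((f"conv{i}", (channels, length), (block.out_channels, out_len)))
        if block.batch_norm:
            rows.append((f"bn{i}", (block.out_channels, out_len), (block.out_channels, out_len)))
        if block.activation != "none":
            rows.append((f"{block.activation}{i}", (block.out_channels, out_len), (block.out_channels, out_len)))
        channels, length = block.out_channels, out_len
    pooled = length // config.avgpool_kernel
    if pooled < 1:
        raise ArchitectureError(f"avgpool: length {length} shorter than pool kernel {config.avgpool_kernel}")
    rows.append(("avgpool", (channels, length), (channels, pooled)))
    flat = channels * pooled
    rows.append(("flatten", (channels, pooled), (flat,)))
    rows.append(("classifier", (flat,), (config.n_classes,)))
    return ShapeTrace(rows)


def count_macs(config: FcnConfig) -> int:
    """Analytic multiply–accumulate count: for every conv layer
    out_len × out_channels × kernel_len × in_channels, plus the
    classifier's in × out product."""
    trace = shape_trace(config)
    total = 0
    in_ch = config.input_channels
    for i, block in enumerate(config.conv_blocks):
        out_ch, out_len = next(out for name, _, out in trace.rows if name == f"conv{i}")
        total += out_len * out_ch * block.kernel_len * in_ch
        in_ch = out_ch
    total += trace.flatten_size * config.n_classes
    return total


class FcnModel:
    """A built network: batched forward passes, prediction with softmax
    confidence, and checkpointing with the config embedded."""

    def __init__(self, config: FcnConfig, net: nn.Sequential) -> None:
        self.config = config
        self.net = net
        self.trace = shape_trace(config)

    # -- tensor plumbing ----------------------------------------------------
    def _prepare(self, X: np.ndarray, dtype) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:  # (B, S) single channel
            X = X[:, :, None]
        elif X.ndim == 3:  # (B, C, S) -> channel-last
            X = np.moveaxis(X, 1, 2)
        else:
            raise ValueError("expected (B, S) or (B, C, S) input")
        X = X.astype(dtype, copy=True)
        if self.config.center_input:
            X -= X.mean(axis=1, keepdims=True)
        if self.config.zscore_input:
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            X = (X - mu) / np.where(sd > 0, sd, 1.0)
        return X

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        dtype = self.net.layers[0].params["W"].dtype
        return self.net.forward(self._prepare(X, dtype), train=train)

    def predict_logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X)
        out = [self.forward(X[i : i + batch_size], train=False) for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0) if out else np.empty((0, self.config.n_classes))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = self.net.state()
        arrays = {f"p{i}": a for i, a in enumerate(state)}
        np.savez(path, config=np.frombuffer(json.dumps(self.config.to_dict()).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FcnModel":
        d = np.load(path)
        config = FcnConfig.from_dict(json.loads(bytes(d["config"]).decode()))
        model = build_fcn(config, seed=0)
        model.net.load_state([d[f"p{i}"] for i in range(len(d.files) - 1)])
        return model


_ACT_LAYERS = {"relu": nn.ReLU, "tanh": nn.Tanh, "sigmoid": nn.Sigmoid}


def build_fcn(config: FcnConfig, seed: int = 0, dtype=np.float32) -> FcnModel:
    """Instantiate the network with seeded uniform fan-in initialisation."""
    trace = shape_trace(config)  # raises ArchitectureError early
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = config.input_channels
    for block in config.conv_blocks:
        layers.append(nn.Conv1d(in_ch, block.out_channels, block.kernel_len, rng, dtype=dtype))
        if block.batch_norm:
            layers.append(nn.BatchNorm1d(block.out_channels, dtype=dtype))
        if block.activation != "none":
            layers.append(_ACT_LAYERS[block.activation]())
        in_ch = block.out_channels
    layers.append(nn.AvgPool1d(config.avgpool_kernel))
    layers.append(nn.Flatten())
    layers.append(nn.Linear(trace.flatten_size, config.n_classes, rng, dtype=dtype))
    return FcnModel(config, nn.Sequential(layers))


def predict_with_confidence(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softmax over the logits; class = argmax (lowest index wins ties),
    confidence = maximum class probability.  Accepts one logit vector or
    a batch; returns (classes, confidences) with matching leading shape."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits[None, :]
    p = nn.softmax(logits)
    classes = p.argmax(axis=1)
    conf = p.max(axis=1)
    if squeeze:
        return classes[0], conf[0]
    return classes, conf
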