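"""The dense-connected 1D CNN for spectra, and a shallow baseline.

The classifier has three functional parts:

* **embedding** — three same-padded convolutions ((16,5), (32,5), (64,5) by
  default), each followed by LeakyReLU(0.3) and size-2/stride-2 max pooling,
  expanding channels while shortening the sequence (2068 -> 1034 -> 517 ->
  258 for the default input).
* **dense blocks** — four blocks with channel counts doubling 64 -> 512.
  Each block projects its input to the block width with a 1x1 convolution
  (node 1), then forms three further nodes where node *l* is the elementwise
  **sum** of all previous nodes plus a pair of 3-kernel convolutions applied
  to the previous node; the last node is batch-normalized and leaves the
  block. The additive every-node-to-every-later-node wiring shortens
  gradient paths, which is what makes the deep stack trainable on small,
  heavily interfered spectral datasets.
* **exportation head** — final size-2 max pooling, flatten (129 x 512 =
  66,048 for the default), two 1024-unit dense layers (ReLU on the first),
  and a softmax output over the classes.

A width-reduced variant of the same topology (`DenseNetConfig.reduced`) is
provided for CPU-scale experiments, along with a generic shallow conv-pool
baseline of the kind the dense network is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Flatten,
    Layer,
    LeakyReLU,
    MaxPool1d,
    Param,
    ReLU,
    Sequential,
)
from .losses import softmax

__all__ = [
    "ConvSpec",
    "EmbeddingConfig",
    "DenseBlockConfig",
    "DenseNetConfig",
    "DenseBlock",
    "Network",
    "PredictionResult",
    "build_network",
    "build_shallow_baseline",
    "shape_trace",
    "format_shape_trace",
]


@dataclass(frozen=True)
class ConvSpec:
    """(out_channels, kernel_size) of one convolution."""

    out_channels: int
    kernel_size: int
    use_bias: bool = True

    def __post_init__(self) -> None:
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Three conv/LeakyReLU/pool stages that lift the raw spectrum into
    feature maps."""

    convs: tuple[ConvSpec, ...] = (ConvSpec(16, 5), ConvSpec(32, 5), ConvSpec(64, 5))
    leaky_alpha: float = 0.3
    pool: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if len(self.convs) != 3:
            raise ValueError("embedding has exactly three convolution stages")
        if not 0 < self.leaky_alpha < 1:
            raise ValueError("leaky_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class DenseBlockConfig:
    """One dense block: 4 sum-connected nodes at a fixed channel count."""

    feature_num: int
    n_nodes: int = 4
    inner_kernel: int = 3
    projection_kernel: int = 1

    def __post_init__(self) -> None:
        if self.n_nodes != 4:
            raise ValueError("a dense block has exactly 4 nodes")
        if self.feature_num < 1:
            raise ValueError("feature_num must be >= 1")


@dataclass(frozen=True)
class DenseNetConfig:
    """Full architecture description.

    The default reproduces the reference architecture: 2068-point input,
    embedding channels 16/32/64, block widths 64/128/256/512 (doubling each
    block), 1024-unit head.
    """

    n_classes: int
    input_length: int = 2068
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    blocks: tuple[DenseBlockConfig, ...] = (
        DenseBlockConfig(64),
        DenseBlockConfig(128),
        DenseBlockConfig(256),
        DenseBlockConfig(512),
    )
    head_units: int = 1024
    final_pool: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.blocks) != 4:
            raise ValueError("the network has exactly four dense blocks")
        feats = [b.feature_num for b in self.blocks]
        if any(b != 2 * a for a, b in zip(feats, feats[1:])):
            raise ValueError("block feature counts must double block to block")

    @classmethod
    def reduced(
        cls,
        n_classes: int,
        input_length: int = 512,
        embedding_channels: tuple[int, int, int] = (4, 8, 16),
        base_features: int = 16,
        head_units: int = 64,
    ) -> "DenseNetConfig":
        """Width-reduced variant of the same topology for CPU-scale runs."""
        return cls(
            n_classes=n_classes,
            input_length=input_length,
            embedding=EmbeddingConfig(
                convs=tuple(ConvSpec(c, 5) for c in embedding_channels)
            ),
            blocks=tuple(DenseBlockConfig(base_features * 2**i) for i in range(4)),
            head_units=head_units,
        )


@dataclass
class PredictionResult:
    """Class probabilities and the argmax class for one spectrum."""

    class_probabilities: np.ndarray
    predicted_class: str | int

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("class_probabilities must form a probability vector")
        self.class_probabilities = p


class DenseBlock(Layer):
    """Four sum-connected nodes at a fixed channel count.

    node 1 = Conv1x1(input); for l = 2..4,
    node l = sum(node 1 .. node l-1) + ConvPair(node l-1),
    where ConvPair is two successive 3-kernel same-padded convolutions each
    followed by LeakyReLU. The block output is BatchNorm(node 4).
    """

    def __init__(self, in_channels: int, config: DenseBlockConfig,
                 rng: np.random.Generator | None = None, leaky_alpha: float = 0.3,
                 dtype=np.float32, name: str = "block") -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        n = config.feature_num
        self.config = config
        self.proj = Conv1d(in_channels, n, config.projection_kernel, rng=rng,
                           dtype=dtype, name=f"{name}.proj")
        self.pairs = [
            Sequential([
                Conv1d(n, n, config.inner_kernel, rng=rng, dtype=dtype,
                       name=f"{name}.pair{l}a"),
                LeakyReLU(leaky_alpha),
                Conv1d(n, n, config.inner_kernel, rng=rng, dtype=dtype,
                       name=f"{name}.pair{l}b"),
                LeakyReLU(leaky_alpha),
            ])
            for l in range(config.n_nodes - 1)
        ]
        self.bn = BatchNorm1d(n, dtype=dtype, name=f"{name}.bn")

    def forward_nodes(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Run the block and return every node's feature map (pre-BN)."""
        nodes = [self.proj.forward(x, training=training)]
        for pair in self.pairs:
            conv_out = pair.forward(nodes[-1], training=training)
            nodes.append(sum(nodes) + conv_out)
        return nodes

    def forward(self, x, training=False):
        nodes = self.forward_nodes(x, training=training)
        self._n_nodes = len(nodes)
        return self.bn.forward(nodes[-1], training=training)

    def backward(self, dout):
        n = self._n_nodes
        node_grads: list[np.ndarray | None] = [None] * n
        node_grads[-1] = self.bn.backward(dout)
        for l in range(n - 1, 0, -1):
            g = node_grads[l]
            gp = self.pairs[l - 1].backward(g)
            for j in range(l):
                node_grads[j] = g if node_grads[j] is None else node_grads[j] + g
            node_grads[l - 1] = node_grads[l - 1] + gp
        return self.proj.backward(node_grads[0])

    def parameters(self):
        out = self.proj.parameters()
        for pair in self.pairs:
            out += pair.parameters()
        return out + self.bn.parameters()

    def output_shape(self, shape):
        return (shape[0], self.config.feature_num)


class Network:
    """A trained or trainable classifier: named layers producing logits.

    ``predict`` applies the softmax; training code drives ``forward`` /
    ``backward`` directly on the logits.
    """

    def __init__(self, named_layers: list[tuple[str, Layer]], input_length: int,
                 n_classes: int, class_names: list[str] | None = None) -> None:
        self.named_layers = named_layers
        self.body = Sequential([layer for _, layer in named_layers])
        self.input_length = input_length
        self.n_classes = n_classes
        self.class_names = class_names

    # -- running ---------------------------------------------------------
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 1:
            x = x[None, :, None]
        elif x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"input length {x.shape[1]} does not match the model "
                f"({self.input_length})"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.body.forward(self._as_batch(x), training=training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.body.backward(dlogits)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, computed in inference mode, batched."""
        x = self._as_batch(x)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size])))
        return np.vstack(out)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> list[PredictionResult]:
        probs = self.predict_proba(x, batch_size=batch_size)
        names = self.class_names
        results = []
        for p in probs:
            k = int(np.argmax(p))
            results.append(PredictionResult(p, names[k] if names else k))
        return results

    # -- parameters and state -------------------------------------------
    def parameters(self) -> list[Param]:
        return self.body.parameters()

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def _batch_norms(self) -> list[BatchNorm1d]:
        found: list[BatchNorm1d] = []

        def walk(layer: Layer) -> None:
            if isinstance(layer, BatchNorm1d):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, DenseBlock):
                walk(layer.proj)
                for pair in layer.pairs:
                    walk(pair)
                walk(layer.bn)

        walk(self.body)
        return found

    def get_state(self) -> list[np.ndarray]:
        """Snapshot of every trainable array plus BN moving statistics."""
        state = [p.value.copy() for p in self.parameters()]
        for bn in self._batch_norms():
            state += [bn.moving_mean.copy(), bn.moving_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state):
            p.value[...] = v
        rest = state[len(params):]
        for bn, mean, var in zip(self._batch_norms(), rest[0::2], rest[1::2]):
            bn.moving_mean[...] = mean
            bn.moving_var[...] = var

    def save(self, path) -> None:
        np.savez(path, *self.get_state())

    def load(self, path) -> None:
        with np.load(path) as z:
            self.set_state([z[k] for k in sorted(z.files, key=lambda s: int(s.split("_")[1]))])

    # -- introspection ---------------------------------------------------
    def shape_trace(self) -> list[tuple[str, tuple[int, ...]]]:
        shape: tuple[int, ...] = (self.input_length, 1)
        rows = [("input", shape)]
        for name, layer in self.named_layers:
            shape = layer.output_shape(shape)
            rows.append((name, shape))
        return rows


def _check_poolable(length: int, pool: tuple[int, int], stage: str) -> int:
    size, stride = pool
    if length < size:
        raise ValueError(f"sequence too short for pooling at {stage} (length {length})")
    return (length - size) // stride + 1


def build_network(
    config: DenseNetConfig,
    rng_seed: int = 0,
    dtype=np.float32,
    class_names: list[str] | None = None,
) -> Network:
    """Construct the dense-connected classifier described by ``config``."""
    rng = np.random.default_rng(rng_seed)
    named: list[tuple[str, Layer]] = []
    length = config.input_length
    channels = 1
    emb = config.embedding
    for i, spec in enumerate(emb.convs, start=1):
        named.append((
            f"embedding_conv{i}",
            Conv1d(channels, spec.out_channels, spec.kernel_size, rng=rng,
                   use_bias=spec.use_bias, dtype=dtype, name=f"emb{i}"),
        ))
        named.append((f"embedding_act{i}", LeakyReLU(emb.leaky_alpha)))
        named.append((f"embedding_pool{i}", MaxPool1d(*emb.pool)))
        channels = spec.out_channels
        length = _check_poolable(length, emb.pool, f"embedding stage {i}")
    for k, bcfg in enumerate(config.blocks, start=1):
        named.append((
            f"block{k}",
            DenseBlock(channels, bcfg, rng=rng, leaky_alpha=emb.leaky_alpha,
                       dtype=dtype, name=f"block{k}"),
        ))
        channels = bcfg.feature_num
    named.append(("final_pool", MaxPool1d(*config.final_pool)))
    length = _check_poolable(length, config.final_pool, "final pooling")
    named.append(("flatten", Flatten()))
    flat = length * channels
    named.append(("head_dense1", Dense(flat, config.head_units, rng=rng,
                                       dtype=dtype, name="head1")))
    named.append(("head_act1", ReLU()))
    named.append(("head_dense2", Dense(config.head_units, config.head_units,
                                       rng=rng, dtype=dtype, name="head2")))
    named.append(("output", Dense(config.head_units, config.n_classes, rng=rng,
                                  dtype=dtype, name="out")))
    return Network(named, config.input_length, config.n_classes, class_names)


def shape_trace(config: DenseNetConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes (per sample, batch axis omitted).

    Computed from the layer semantics without allocating weights: same-padded
    convolutions preserve length, pooling maps L to floor((L-size)/stride)+1.
    """
    rows: list[tuple[str, tuple[int, ...]]] = [("input", (config.input_length, 1))]
    length = config.input_length
    emb = config.embedding
    for i, spec in enumerate(emb.convs, start=1):
        rows.append((f"embedding_conv{i}", (length, spec.out_channels)))
        length = _check_poolable(length, emb.pool, f"embedding stage {i}")
        rows.append((f"embedding_pool{i}", (length, spec.out_channels)))
    for k, bcfg in enumerate(config.blocks, start=1):
        rows.append((f"block{k}_conv", (length, bcfg.feature_num)))
        rows.append((f"block{k}_norm", (length, bcfg.feature_num)))
    length = _check_poolable(length, config.final_pool, "final pooling")
    rows.append(("final_pool", (length, config.blocks[-1].feature_num)))
    rows.append(("flatten", (length * config.blocks[-1].feature_num,)))
    rows.append(("head_dense1", (config.head_units,)))
    rows.append(("head_dense2", (config.head_units,)))
    rows.append(("output", (config.n_classes,)))
    return rows


def format_shape_trace(rows: list[tuple[str, tuple[int, ...]]]) -> str:
    lines = [f"{'layer':<18} output shape"]
    for name, shape in rows:
        pretty = "(Batch, " + ", ".join(f"{d:,}" for d in shape) + ")"
        lines.append(f"{name:<18} {pretty}")
    return "\n".join(lines)


def build_shallow_baseline(
    n_conv_layers: int,
    channels: tuple[int, ...] | int = 8,
    kernel: int = 5,
    head_units: int = 64,
    n_classes: int = 2,
    input_length: int = 2068,
    rng_seed: int = 0,
    dtype=np.float32,
    class_names: list[str] | None = None,
) -> Network:
    """A plain conv/ReLU/pool stack with a dense head.

    Generic stand-in for the shallow CNN classifiers the dense network is
    compared against. ``channels`` is either the first layer's channel count
    (doubled per layer, capped at 8x) or an explicit per-layer tuple.
    """
    if not 3 <= n_conv_layers <= 7:
        raise ValueError("n_conv_layers must be between 3 and 7")
    if isinstance(channels, int):
        channels = tuple(min(channels * 2**i, channels * 8) for i in range(n_conv_layers))
    if len(channels) != n_conv_layers:
        raise ValueError("channels tuple must match n_conv_layers")
    rng = np.random.default_rng(rng_seed)
    named: list[tuple[str, Layer]] = []
    length, prev = input_length, 1
    for i, c in enumerate(channels, start=1):
        named.append((f"conv{i}", Conv1d(prev, c, kernel, rng=rng, dtype=dtype,
                                         name=f"conv{i}")))
        named.append((f"act{i}", ReLU()))
        named.append((f"pool{i}", MaxPool1d(2, 2)))
        length = _check_poolable(length, (2, 2), f"layer {i}")
        prev = c
    named.append(("flatten", Flatten()))
    named.append(("head_dense", Dense(length * prev, head_units, rng=rng,
                                      dtype=dtype, name="head")))
    named.append(("head_act", ReLU()))
    named.append(("output", Dense(head_units, n_classes, rng=rng, dtype=dtype,
                                  name="out")))
    return Network(named, input_length, n_classes, class_names)
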