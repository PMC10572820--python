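"""The modified UNet: programmatic construction, introspection, inference.

The network is an hourglass encoder–decoder. Each of the ``depth`` encoder
blocks is

    3x3 conv (linear) -> batch norm -> 3x3 conv (ReLU) -> 2x2 max pool

with filter counts ``F1(k) = base * 2^(k-1)`` for the first convolution and
``F2(k) = 2 * base * 2^(k-1)`` for the second (``base = 72`` canonically), so
at depth 5 the widths run 72/144, 144/288, ..., 1152/2304 and the post-pool
bottleneck of a 512x512 input is a 16x16 map with 2304 channels. Each of the
``depth`` decoder blocks is

    2x nearest upsample -> concatenate with the mirror encoder block's
    pre-pool activation -> 3x3 conv (ReLU)

with widths halving per level (1152, 576, 288, 144 at canonical scale); the
topmost decoder convolution is the output layer, mapping to ``out_channels``
with a sigmoid, so the network emits a per-pixel glomerulus probability map
at the input resolution. At depth 5 the layer inventory is 15 convolutions,
5 max pools, 5 upsamplings, 5 normalizations and 5 concatenations; the same
constructor at depth 4 yields the classic 12/4/4/4/4 hourglass used as the
unmodified baseline.

``width_scale`` multiplies every filter count and, together with a smaller
``tile_size``, gives a faithfully shaped desk-scale network that trains on a
CPU; the canonical configuration is scale 1 at tile size 512.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (
    BatchNorm2D,
    Concatenate,
    Conv2D,
    Layer,
    MaxPool2D,
    Parameter,
    Upsample2D,
)
from .rle_codec import validate_binary

LAYER_KINDS = ("convolutional", "max_pooling", "upsampling",
               "normalization", "concatenate")


class SpecError(ValueError):
    """Inconsistent network specification."""


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters defining the network graph.

    Defaults are the canonical configuration: 5 encoder blocks, 72 filters in
    the first convolution, 512x512 RGB input, single-channel probability
    output. ``width_scale`` shrinks every filter count for desk-scale runs.
    """

    depth: int = 5
    base_filters: int = 72
    width_scale: float = 1.0
    tile_size: int = 512
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SpecError(f"depth must be >= 1, got {self.depth}")
        if self.tile_size % (2**self.depth):
            raise SpecError(
                f"tile_size {self.tile_size} is not divisible by "
                f"2^depth = {2**self.depth}"
            )
        if self.width_scale <= 0:
            raise SpecError(
                f"width_scale must be positive, got {self.width_scale}"
            )

    def _scaled(self, n: int) -> int:
        # scaled widths are clamped at one filter
        return max(1, round(n * self.width_scale))

    def conv1_filters(self, k: int) -> int:
        """Filters of the first convolution of encoder block k (1-based)."""
        return self._scaled(self.base_filters * 2 ** (k - 1))

    def conv2_filters(self, k: int) -> int:
        """Filters of the second convolution of encoder block k (1-based)."""
        return self._scaled(2 * self.base_filters * 2 ** (k - 1))

    def decoder_filters(self, j: int) -> int:
        """Output filters of decoder block j (1-based, bottom up)."""
        if j == self.depth:
            return self.out_channels
        return self.conv2_filters(self.depth - j)

    @property
    def bottleneck_size(self) -> int:
        return self.tile_size // 2**self.depth

    @property
    def bottleneck_channels(self) -> int:
        return self.conv2_filters(self.depth)

    @classmethod
    def canonical(cls) -> "NetworkSpec":
        """The full-size modified UNet (depth 5, base 72, tile 512)."""
        return cls()

    @classmethod
    def baseline_unet(cls, **kwargs) -> "NetworkSpec":
        """The unmodified four-block hourglass, for layer-count comparison."""
        kwargs.setdefault("depth", 4)
        kwargs.setdefault("base_filters", 64)
        return cls(**kwargs)


@dataclass(frozen=True)
class LayerInventory:
    """Per-kind layer counts, derived by walking a constructed graph."""

    counts: dict[str, int]

    def __getitem__(self, kind: str) -> int:
        return self.counts.get(kind, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass(frozen=True)
class TraceRecord:
    stage: str
    spatial: int
    channels: int


@dataclass(frozen=True)
class FeatureMapTrace:
    """Ordered (stage, spatial size, channel count) records through the net."""

    records: tuple[TraceRecord, ...]

    def __iter__(self):
        return iter(self.records)

    def stage(self, name: str) -> TraceRecord:
        for r in self.records:
            if r.stage == name:
                return r
        raise KeyError(name)

    @property
    def encoder_spatial_sizes(self) -> tuple[int, ...]:
        """Input size followed by the size after each pooling."""
        sizes = [self.records[0].spatial]
        sizes += [r.spatial for r in self.records if r.stage.endswith("_pool")]
        return tuple(sizes)

    @property
    def bottleneck(self) -> TraceRecord:
        """The deepest (post-pool) record."""
        return min(self.records, key=lambda r: (r.spatial, -r.channels))

    @property
    def output(self) -> TraceRecord:
        return self.records[-1]

    def as_records(self) -> list[dict]:
        return [{"stage": r.stage, "spatial": r.spatial, "channels": r.channels}
                for r in self.records]


class ModifiedUNet:
    """A constructed network graph with forward and backward passes.

    Built by :func:`build_modified_unet`; holds the ordered per-block layer
    objects and the wiring (skip connections) between them.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.depth
        self.enc_conv1: list[Conv2D] = []
        self.enc_norm: list[BatchNorm2D] = []
        self.enc_conv2: list[Conv2D] = []
        self.enc_pool: list[MaxPool2D] = []
        in_ch = spec.in_channels
        for k in range(1, d + 1):
            f1, f2 = spec.conv1_filters(k), spec.conv2_filters(k)
            self.enc_conv1.append(Conv2D(in_ch, f1, "linear", rng=rng))
            self.enc_norm.append(BatchNorm2D(f1))
            self.enc_conv2.append(Conv2D(f1, f2, "relu", rng=rng))
            self.enc_pool.append(MaxPool2D())
            in_ch = f2
        self.dec_up: list[Upsample2D] = []
        self.dec_cat: list[Concatenate] = []
        self.dec_conv: list[Conv2D] = []
        ch = spec.bottleneck_channels
        for j in range(1, d + 1):
            skip_ch = spec.conv2_filters(d - j + 1)
            out_ch = spec.decoder_filters(j)
            act = "sigmoid" if j == d else "relu"
            self.dec_up.append(Upsample2D())
            self.dec_cat.append(Concatenate())
            self.dec_conv.append(Conv2D(ch + skip_ch, out_ch, act, rng=rng))
            ch = out_ch

    # -- introspection ----------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        """All layers in execution order (encoder top-down, decoder bottom-up)."""
        out: list[Layer] = []
        for k in range(self.spec.depth):
            out += [self.enc_conv1[k], self.enc_norm[k],
                    self.enc_conv2[k], self.enc_pool[k]]
        for j in range(self.spec.depth):
            out += [self.dec_up[j], self.dec_cat[j], self.dec_conv[j]]
        return out

    @property
    def output_layer(self) -> Conv2D:
        return self.dec_conv[-1]

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the network on an NHWC batch; returns NHWx``out_channels``
        probabilities."""
        d = self.spec.depth
        skips: list[np.ndarray] = []
        for k in range(d):
            x = self.enc_conv1[k].forward(x, training)
            x = self.enc_norm[k].forward(x, training)
            x = self.enc_conv2[k].forward(x, training)
            skips.append(x)
            x = self.enc_pool[k].forward(x, training)
        for j in range(d):
            x = self.dec_up[j].forward(x, training)
            x = self.dec_cat[j].forward(x, skips[d - 1 - j], training)
            x = self.dec_conv[j].forward(x, training)
        return x

    def backward(self, grad_out_preact: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the output layer pre-activation.

        The sigmoid output is fused with the cross-entropy loss upstream, so
        the entry gradient is already pre-activation (see
        :func:`glomseg._nn.binary_cross_entropy`).
        """
        d = self.spec.depth
        skip_grads: list[np.ndarray | None] = [None] * d
        g = grad_out_preact
        for j in range(d - 1, -1, -1):
            g = self.dec_conv[j].backward(g, preact=(j == d - 1))
            g, g_skip = self.dec_cat[j].backward(g)
            skip_grads[d - 1 - j] = g_skip
            g = self.dec_up[j].backward(g)
        for k in range(d - 1, -1, -1):
            g = self.enc_pool[k].backward(g)
            g = g + skip_grads[k]
            g = self.enc_conv2[k].backward(g)
            g = self.enc_norm[k].backward(g)
            g = self.enc_conv1[k].backward(g)

    # -- weights ----------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match the network")
        for p, w in zip(params, weights):
            p.value[...] = w

    def save(self, path: str | Path) -> None:
        """Serialize spec + weights + normalization statistics."""
        state = {
            "spec": self.spec,
            "weights": self.get_weights(),
            "bn_stats": [(bn.running_mean.copy(), bn.running_var.copy())
                         for bn in self.enc_norm],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ModifiedUNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        net = cls(state["spec"])
        net.set_weights(state["weights"])
        for bn, (mean, var) in zip(net.enc_norm, state["bn_stats"]):
            bn.running_mean, bn.running_var = mean, var
        return net


def build_modified_unet(spec: NetworkSpec | None = None,
                        seed: int = 0) -> ModifiedUNet:
    """Construct the network for a :class:`NetworkSpec` (canonical default)."""
    return ModifiedUNet(spec or NetworkSpec.canonical(), seed=seed)


def layer_inventory(net: ModifiedUNet) -> LayerInventory:
    """Count layers per kind by walking the constructed graph.

    Only the five structural kinds are counted; pointwise activations
    (including the output sigmoid) are fused into their convolutions and do
    not appear.
    """
    counts = {kind: 0 for kind in LAYER_KINDS}
    for layer in net.layers:
        counts[layer.kind] += 1
    return LayerInventory(counts)


def feature_trace(net: ModifiedUNet | NetworkSpec,
                  tile_size: int | None = None) -> FeatureMapTrace:
    """Symbolic walk of feature-map shapes through encoder and decoder.

    Records one entry per layer output, named ``enc{k}_conv1 / enc{k}_norm /
    enc{k}_conv2 / enc{k}_pool`` and ``dec{j}_up / dec{j}_concat /
    dec{j}_conv``, plus the leading ``input`` record. The deepest post-pool
    record is the bottleneck.
    """
    spec = net.spec if isinstance(net, ModifiedUNet) else net
    T = tile_size if tile_size is not None else spec.tile_size
    if T % (2**spec.depth):
        raise SpecError(
            f"tile size {T} is not divisible by 2^depth = {2**spec.depth}"
        )
    d = spec.depth
    records = [TraceRecord("input", T, spec.in_channels)]
    size = T
    for k in range(1, d + 1):
        f1, f2 = spec.conv1_filters(k), spec.conv2_filters(k)
        records.append(TraceRecord(f"enc{k}_conv1", size, f1))
        records.append(TraceRecord(f"enc{k}_norm", size, f1))
        records.append(TraceRecord(f"enc{k}_conv2", size, f2))
        size //= 2
        records.append(TraceRecord(f"enc{k}_pool", size, f2))
    ch = spec.bottleneck_channels
    for j in range(1, d + 1):
        size *= 2
        records.append(TraceRecord(f"dec{j}_up", size, ch))
        skip_ch = spec.conv2_filters(d - j + 1)
        records.append(TraceRecord(f"dec{j}_concat", size, ch + skip_ch))
        ch = spec.decoder_filters(j)
        records.append(TraceRecord(f"dec{j}_conv", size, ch))
    return FeatureMapTrace(tuple(records))


def predict_proba(net: ModifiedUNet, tile_image: np.ndarray) -> np.ndarray:
    """Per-pixel glomerulus probabilities for one T x T x C tile.

    ``tile_image`` may be uint8 (rescaled by 1/255) or float already in
    [0, 1].
    """
    T = net.spec.tile_size
    img = np.asarray(tile_image)
    if img.shape != (T, T, net.spec.in_channels):
        raise ValueError(
            f"tile shape {img.shape} does not match the network input "
            f"({T}, {T}, {net.spec.in_channels})"
        )
    x = img.astype(np.float32)
    if img.dtype == np.uint8:
        x /= 255.0
    probs = net.forward(x[None], training=False)[0, ..., 0]
    return probs


def predict_mask(net: ModifiedUNet, tile_image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Threshold the probability map into a {0,1} mask at input resolution."""
    probs = predict_proba(net, tile_image)
    return validate_binary((probs >= threshold).astype(np.uint8))
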