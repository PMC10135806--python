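"""The segmentation network: a modified U-Net for 3-class osteon labelling.

The default configuration is a depth-5 encoder-decoder with 16 base
filters: per encoder level two 3x3 same-padded biased convolutions with
ReLU followed by 2x2 max pooling; a two-convolution bottleneck; per decoder
level a 2x2 stride-2 transpose convolution that halves the channel count,
concatenation with the matching encoder feature map, and two 3x3
convolutions; a final 1x1 convolution to the 3 class logits with softmax.
No batch normalization.  Dropout (rate 0.3) is applied after the second
convolution of the deepest encoder level and of the bottleneck, the two
highest-capacity blocks.  This configuration has exactly 1,940,851
trainable parameters for 512x512 single-channel input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .annotations import LabelMask


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the U-Net."""

    input_size: int = 512
    in_channels: int = 1
    n_classes: int = 3
    depth: int = 5          # resolution levels, including the bottleneck
    base_filters: int = 16  # filters at the highest resolution
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        stride = 2 ** (self.depth - 1)
        if self.input_size % stride != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^(depth-1) = {stride}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def count_parameters(config: NetworkConfig) -> int:
    """Closed-form trainable-parameter count of the U-Net.

    Every convolution carries a bias; a 3x3 convolution c_in -> c_out costs
    ``(9*c_in + 1)*c_out``, a 2x2 transpose convolution ``(4*c_in +
    1)*c_out``, and the 1x1 head ``(c_in + 1)*n_classes``.  The default
    configuration totals 1,940,851.
    """
    f, d = config.base_filters, config.depth
    total = 0
    c_in = config.in_channels
    for i in range(d - 1):          # encoder levels
        c_out = f * 2 ** i
        total += (9 * c_in + 1) * c_out + (9 * c_out + 1) * c_out
        c_in = c_out
    c_out = f * 2 ** (d - 1)        # bottleneck
    total += (9 * c_in + 1) * c_out + (9 * c_out + 1) * c_out
    c = c_out
    for i in range(d - 2, -1, -1):  # decoder levels
        c_half = c // 2
        total += (4 * c + 1) * c_half                      # transpose conv
        total += (9 * (2 * c_half) + 1) * c_half           # conv on concat
        total += (9 * c_half + 1) * c_half
        c = c_half
    total += (c + 1) * config.n_classes                    # 1x1 head
    return total


class _Block:
    """A plain sequence of layers with mirrored forward/backward."""

    def __init__(self, layers: list[nn.Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class UNet:
    """The trainable network.  Construct via :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        f, d = config.base_filters, config.depth

        self.enc_blocks: list[_Block] = []
        self.pools: list[nn.MaxPool2d] = []
        c_in = config.in_channels
        for i in range(d - 1):
            c_out = f * 2 ** i
            layers: list[nn.Layer] = [
                nn.Conv2d(c_in, c_out, 3, rng), nn.ReLU(),
                nn.Conv2d(c_out, c_out, 3, rng), nn.ReLU(),
            ]
            if i == d - 2 and config.dropout_rate > 0:
                layers.append(nn.Dropout(config.dropout_rate, self._dropout_rng))
            self.enc_blocks.append(_Block(layers))
            self.pools.append(nn.MaxPool2d())
            c_in = c_out

        c_out = f * 2 ** (d - 1)
        bott: list[nn.Layer] = [
            nn.Conv2d(c_in, c_out, 3, rng), nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, rng), nn.ReLU(),
        ]
        if config.dropout_rate > 0:
            bott.append(nn.Dropout(config.dropout_rate, self._dropout_rng))
        self.bottleneck = _Block(bott)

        self.ups: list[nn.ConvTranspose2d] = []
        self.dec_blocks: list[_Block] = []
        c = c_out
        for i in range(d - 2, -1, -1):
            c_half = c // 2
            self.ups.append(nn.ConvTranspose2d(c, c_half, rng))
            self.dec_blocks.append(_Block([
                nn.Conv2d(2 * c_half, c_half, 3, rng), nn.ReLU(),
                nn.Conv2d(c_half, c_half, 3, rng), nn.ReLU(),
            ]))
            c = c_half
        self.head = nn.Conv2d(c, config.n_classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _param_layers(self):
        for block in self.enc_blocks:
            yield from block.layers
        yield from self.bottleneck.layers
        for up, dec in zip(self.ups, self.dec_blocks):
            yield up
            yield from dec.layers
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self._param_layers() for p in l.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self._param_layers() for g in l.gradients()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        stride = 2 ** (self.config.depth - 1)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W) "
                             f"input, got shape {x.shape}")
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {stride}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (N, n_classes, H, W) for NCHW input."""
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        self._check_input(x)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate loss gradients; layer gradients are left in place."""
        g = self.head.backward(dlogits)
        skip_grads = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec_blocks)):
            g = dec.backward(g)
            c_half = g.shape[1] // 2
            skip_grads.append(g[:, :c_half])
            g = up.backward(np.ascontiguousarray(g[:, c_half:]))
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallowest-first; encoder backward runs
        # deepest-first
        for block, pool, gskip in zip(
            reversed(self.enc_blocks), reversed(self.pools),
            reversed(skip_grads)
        ):
            g = pool.backward(g) + gskip
            g = block.backward(g)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Write weights (.npz) plus the config as JSON alongside."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.config.to_dict()))

    @classmethod
    def load(cls, path) -> "UNet":
        path = Path(path)
        config = NetworkConfig.from_dict(
            json.loads(path.with_suffix(".json").read_text())
        )
        net = cls(config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            net.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return net


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> UNet:
    """Instantiate the U-Net; its trainable-parameter tally equals
    :func:`count_parameters` by construction."""
    return UNet(config or NetworkConfig(), seed=seed)


def predict(network: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for one grayscale image.

    Dropout is disabled; the output has shape (n_classes, H, W) and each
    pixel's probabilities sum to 1.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got {image.shape}")
    logits = network.forward(image[None, None], training=False)
    return nn.softmax_channels(logits)[0]


def predict_batch(network: UNet, images: np.ndarray) -> np.ndarray:
    """Probabilities (N, n_classes, H, W) for a stack of grayscale images."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3:
        raise ValueError("expected (N, H, W) image stack")
    logits = network.forward(images[:, None], training=False)
    return nn.softmax_channels(logits)


def labels_from_probabilities(probabilities: np.ndarray) -> LabelMask:
    """Argmax labelling of a (n_classes, H, W) probability map.

    Exact ties resolve to the lowest class index (background < fragment <
    intact) — numpy's argmax convention, stated here as the contract.
    """
    p = np.asarray(probabilities)
    if p.ndim != 3:
        raise ValueError("expected (n_classes, H, W) probability map")
    return LabelMask(np.argmax(p, axis=0).astype(np.uint8))
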