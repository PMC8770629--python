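"""The 2D U-Net segmentation network.

Architecture: a symmetric encoder–decoder.  Each encoder stage is two 3×3
convolutions (each followed by batch normalisation and ReLU) and a 2×2 max
pool; stage i has ``base_channels × 2^i`` channels.  The bottleneck doubles
channels once more, so the default (depth 4, base 64, 256 px input) reaches
a 16×16 representation with 1024 channels.  The decoder mirrors the encoder
with 2×2 transposed convolutions, concatenating the matching encoder
feature map (skip connection) before each pair of 3×3 convolutions.  A
final 1×1 convolution with sigmoid yields the per-pixel muscle probability,
binarised at 0.5 by default (ties go to muscle).

Two dropout layers regularise the deepest features: one after the deepest
encoder stage and one after the bottleneck.  Inference runs with dropout
off and batch-norm running statistics, so it is deterministic.

Note that horizontal flips of the input are *not* guaranteed to produce
mirrored outputs — the network has no built-in symmetry; any left/right
robustness is learned, not structural.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .imaging_io import BinaryMask, Slice2D


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 64
    dropout_rate: float = 0.5
    batch_norm: bool = True
    input_size_px: int = 256

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_size_px % (2**self.depth) != 0:
            raise ValueError(
                f"input_size_px={self.input_size_px} must be divisible by 2^depth={2**self.depth}"
            )


def encoder_channels(config: UNetConfig) -> list[int]:
    return [config.base_channels * 2**i for i in range(config.depth)]


def bottleneck_shape(config: UNetConfig) -> tuple[int, int, int]:
    """(height, width, channels) of the bottleneck feature map — a pure
    function of the configuration."""
    side = config.input_size_px // 2**config.depth
    return side, side, config.base_channels * 2**config.depth


def parameter_count(config: UNetConfig) -> int:
    """Total trainable parameter count, computed analytically."""

    def conv(cin, cout, k):
        n = k * k * cin * cout + cout
        if config.batch_norm and k == 3:
            n += 2 * cout  # gamma, beta
        return n

    chs = encoder_channels(config)
    total = 0
    cin = 1
    for ch in chs:  # encoder blocks
        total += conv(cin, ch, 3) + conv(ch, ch, 3)
        cin = ch
    bott = chs[-1] * 2
    total += conv(cin, bott, 3) + conv(bott, bott, 3)
    prev = bott
    for ch in reversed(chs):  # decoder: up-conv then two convs
        total += 2 * 2 * prev * ch + ch
        total += conv(2 * ch, ch, 3) + conv(ch, ch, 3)
        prev = ch
    total += conv(prev, 1, 1)
    return total


class _ConvBlock:
    """conv → (BN) → ReLU, twice."""

    def __init__(self, cin, cout, batch_norm, rng, name):
        self.layers: list[nn.Layer] = []
        for j, (a, b) in enumerate(((cin, cout), (cout, cout))):
            self.layers.append(nn.Conv2d(a, b, 3, rng, f"{name}.conv{j}"))
            if batch_norm:
                self.layers.append(nn.BatchNorm2d(b, name=f"{name}.bn{j}"))
            self.layers.append(nn.ReLU())

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def stateful(self):
        return [l for l in self.layers if isinstance(l, nn.BatchNorm2d)]


class UNet:
    """The network itself; use :func:`build_unet` to construct it."""

    def __init__(self, config: UNetConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        drop_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        chs = encoder_channels(config)
        bn = config.batch_norm

        self.enc = []
        cin = 1
        for i, ch in enumerate(chs):
            self.enc.append(_ConvBlock(cin, ch, bn, rng, f"enc{i}"))
            cin = ch
        self.pools = [nn.MaxPool2() for _ in chs]
        self.drop_enc = nn.Dropout(config.dropout_rate, drop_rng)
        bott = chs[-1] * 2
        self.bottleneck = _ConvBlock(cin, bott, bn, rng, "bottleneck")
        self.drop_bott = nn.Dropout(config.dropout_rate, drop_rng)

        self.ups = []
        self.dec = []
        prev = bott
        for i in reversed(range(config.depth)):
            ch = chs[i]
            self.ups.append(nn.ConvTranspose2(prev, ch, rng, f"up{i}"))
            self.dec.append(_ConvBlock(2 * ch, ch, bn, rng, f"dec{i}"))
            prev = ch
        self.head = nn.Conv2d(prev, 1, 1, rng, "head")
        self.sigmoid = nn.Sigmoid()

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[nn.Tensor]:
        out = []
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(blk.params())
        for up in self.ups:
            out.extend(up.params())
        out.extend(self.head.params())
        return out

    def _bn_layers(self):
        out = []
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(blk.stateful())
        return out

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.value.copy() for p in self.params()]
        for bnl in self._bn_layers():
            ws.extend([bnl.running_mean.copy(), bnl.running_var.copy()])
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        ps = self.params()
        for p, w in zip(ps, ws):
            p.value[...] = w
        k = len(ps)
        for bnl in self._bn_layers():
            bnl.running_mean[...] = ws[k]
            bnl.running_var[...] = ws[k + 1]
            k += 2

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = self.config.depth
        skips = []
        for i in range(d):
            x = self.enc[i].forward(x, training)
            if i == d - 1:
                x = self.drop_enc.forward(x, training)
            skips.append(x)
            x = self.pools[i].forward(x, training)
        x = self.bottleneck.forward(x, training)
        x = self.drop_bott.forward(x, training)
        self.bottleneck_out_shape = x.shape
        self._skip_chs = [s.shape[1] for s in skips]
        for j, i in enumerate(reversed(range(d))):
            x = self.ups[j].forward(x, training)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[j].forward(x, training)
        x = self.head.forward(x, training)
        return self.sigmoid.forward(x, training)

    def backward(self, gy: np.ndarray) -> None:
        d = self.config.depth
        gy = self.sigmoid.backward(gy)
        gy = self.head.backward(gy)
        gskips = [None] * d
        for j, i in zip(reversed(range(d)), range(d)):
            gy = self.dec[j].backward(gy)
            ch = self._skip_chs[i]
            gskips[i] = gy[:, :ch]
            gy = self.ups[j].backward(np.ascontiguousarray(gy[:, ch:]))
        gy = self.drop_bott.backward(gy)
        gy = self.bottleneck.backward(gy)
        for i in reversed(range(d)):
            gy = self.pools[i].backward(gy) + gskips[i]
            if i == d - 1:
                gy = self.drop_enc.backward(gy)
            gy = self.enc[i].backward(gy)


@dataclass
class ModelHandle:
    """An opaque handle to a (possibly trained) network."""

    net: UNet
    config: UNetConfig
    seed: int
    provenance: dict = field(default_factory=dict)


def build_unet(config: UNetConfig = UNetConfig(), seed: int = 0) -> ModelHandle:
    """Construct a freshly (and reproducibly) initialised U-Net."""
    return ModelHandle(net=UNet(config, seed), config=config, seed=seed)


def predict_proba(model: ModelHandle, sl: Slice2D) -> np.ndarray:
    size = model.config.input_size_px
    if sl.shape != (size, size):
        raise ValueError(
            f"slice shape {sl.shape} does not match the model input {size}×{size}; "
            "preprocess the slice first"
        )
    x = sl.pixels[None, None].astype(np.float32)
    return model.net.forward(x, training=False)[0, 0].astype(np.float64)


def binarize(proba: np.ndarray, spacing: tuple[float, float], threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map; a pixel exactly at threshold is muscle."""
    return BinaryMask(labels=(proba >= threshold).astype(np.uint8), spacing=spacing)


def predict_mask(
    model: ModelHandle, sl: Slice2D, threshold: float = 0.5
) -> tuple[np.ndarray, BinaryMask]:
    """Probability map and binarised mask (pixel = muscle iff p >= threshold)."""
    proba = predict_proba(model, sl)
    return proba, binarize(proba, sl.spacing, threshold)


def save_checkpoint(path, model: ModelHandle) -> None:
    """Weights as .npz plus a JSON sidecar with config, seed and provenance."""
    path = str(path)
    ws = model.net.get_weights()
    np.savez(path if path.endswith(".npz") else path + ".npz", *ws)
    sidecar = {
        "config": asdict(model.config),
        "seed": model.seed,
        "provenance": model.provenance,
    }
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> ModelHandle:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    config = UNetConfig(**sidecar["config"])
    model = build_unet(config, seed=sidecar["seed"])
    with np.load(base + ".npz") as data:
        ws = [data[k] for k in data.files]
    model.net.set_weights(ws)
    model.provenance = sidecar["provenance"]
    return model
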