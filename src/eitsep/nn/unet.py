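"""U-Net computation graphs: shared encoder, task decoders, output heads.

Two network variants are assembled from the same parts:

* ``SemiSiameseNet`` — one encoder whose features and skip tensors feed two
  structurally identical but independently parameterized decoders (lung and
  heart), each ending in a 1-channel head.  The encoder receives summed
  gradient contributions from both paths.
* ``BaselineNet`` — the classical single-decoder U-Net with a 2-channel
  head (channel 0 lung, channel 1 heart).

Channel plan for depth ``d`` and base width ``c``: encoder levels carry
``c, 2c, ..., 2^(d-2) c`` with 2x2 max-pool between them and a
``2^(d-1) c`` bottleneck; decoders mirror this with nearest-neighbour
upsampling + 3x3 convolution, skip concatenation and a double-conv block
per level.  Heads emit logits; the sigmoid lives in the loss / prediction
code.
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv1x1, Conv3x3, ConvBlock, MaxPool2x2,
                     Parameter, ReLU, Upsample2x)


class Encoder:
    def __init__(self, in_channels: int, base: int, depth: int,
                 rng: np.random.Generator) -> None:
        if depth < 2:
            raise ValueError("encoder depth must be >= 2")
        self.depth = depth
        self.blocks: list[ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        c_in = in_channels
        for i in range(depth - 1):
            c_out = base * 2**i
            self.blocks.append(ConvBlock(c_in, c_out, rng))
            self.pools.append(MaxPool2x2())
            c_in = c_out
        self.bottleneck = ConvBlock(c_in, base * 2**(depth - 1), rng)

    def parameters(self) -> list[Parameter]:
        ps = [p for b in self.blocks for p in b.parameters()]
        return ps + self.bottleneck.parameters()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        return self.bottleneck.forward(x), skips

    def backward(self, dfeat: np.ndarray,
                 dskips: list[np.ndarray]) -> np.ndarray:
        dx = self.bottleneck.backward(dfeat)
        for block, pool, dskip in zip(reversed(self.blocks),
                                      reversed(self.pools),
                                      reversed(dskips)):
            dx = pool.backward(dx) + dskip
            dx = block.backward(dx)
        return dx


class Decoder:
    def __init__(self, base: int, depth: int, out_channels: int,
                 rng: np.random.Generator, head_bias: float = 0.0) -> None:
        self.depth = depth
        self.ups: list[Upsample2x] = []
        self.upconvs: list[Conv3x3] = []
        self.upbns: list[BatchNorm2d] = []
        self.uprelus: list[ReLU] = []
        self.blocks: list[ConvBlock] = []
        for i in reversed(range(depth - 1)):
            c_hi, c_lo = base * 2**(i + 1), base * 2**i
            self.ups.append(Upsample2x())
            self.upconvs.append(Conv3x3(c_hi, c_lo, rng))
            self.upbns.append(BatchNorm2d(c_lo))
            self.uprelus.append(ReLU())
            self.blocks.append(ConvBlock(2 * c_lo, c_lo, rng))
        self.head = Conv1x1(base, out_channels, rng)
        # a negative head bias starts the sigmoid outputs near the
        # foreground prior, so the large background region saturates
        # quickly and gradients concentrate on the organ boundaries
        self.head.b.value[...] = head_bias

    def parameters(self) -> list[Parameter]:
        ps = [p for c in self.upconvs for p in c.parameters()]
        ps += [p for bn in self.upbns for p in bn.parameters()]
        ps += [p for b in self.blocks for p in b.parameters()]
        return ps + self.head.parameters()

    def forward(self, feat: np.ndarray,
                skips: list[np.ndarray]) -> np.ndarray:
        self._splits = []
        x = feat
        for up, upconv, upbn, uprelu, block, skip in zip(
                self.ups, self.upconvs, self.upbns, self.uprelus,
                self.blocks, reversed(skips)):
            x = uprelu.forward(upbn.forward(upconv.forward(up.forward(x))))
            self._splits.append(skip.shape[1])
            x = block.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dx = self.head.backward(dlogits)
        dskips: list[np.ndarray] = []
        for up, upconv, upbn, uprelu, block, c_skip in zip(
                reversed(self.ups), reversed(self.upconvs),
                reversed(self.upbns), reversed(self.uprelus),
                reversed(self.blocks), reversed(self._splits)):
            dcat = block.backward(dx)
            dskips.append(dcat[:, :c_skip])
            dx = up.backward(upconv.backward(
                upbn.backward(uprelu.backward(dcat[:, c_skip:]))))
        # reversed stage order visits the shallowest level first, so the
        # appended gradients already line up with the encoder's skip list
        return dx, dskips


class SemiSiameseNet:
    """One shared encoder, two independent decoders (lung, heart)."""

    def __init__(self, base: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None,
                 head_bias: float = 0.0) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = Encoder(1, base, depth, rng)
        self.decoder_lung = Decoder(base, depth, 1, rng, head_bias)
        self.decoder_heart = Decoder(base, depth, 1, rng, head_bias)

    def parameters(self) -> list[Parameter]:
        return (self.encoder.parameters()
                + self.decoder_lung.parameters()
                + self.decoder_heart.parameters())

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        feat, skips = self.encoder.forward(x)
        return (self.decoder_lung.forward(feat, skips),
                self.decoder_heart.forward(feat, skips))

    def backward(self, dlung: np.ndarray, dheart: np.ndarray) -> None:
        dfeat_l, dskips_l = self.decoder_lung.backward(dlung)
        dfeat_h, dskips_h = self.decoder_heart.backward(dheart)
        dskips = [a + b for a, b in zip(dskips_l, dskips_h)]
        self.encoder.backward(dfeat_l + dfeat_h, dskips)


class BaselineNet:
    """Classical single-decoder U-Net with a 2-channel head."""

    def __init__(self, base: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None,
                 head_bias: float = 0.0) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = Encoder(1, base, depth, rng)
        self.decoder = Decoder(base, depth, 2, rng, head_bias)

    def parameters(self) -> list[Parameter]:
        return self.encoder.parameters() + self.decoder.parameters()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        feat, skips = self.encoder.forward(x)
        logits = self.decoder.forward(feat, skips)
        return logits[:, :1], logits[:, 1:]

    def backward(self, dlung: np.ndarray, dheart: np.ndarray) -> None:
        dlogits = np.concatenate([dlung, dheart], axis=1)
        dfeat, dskips = self.decoder.backward(dlogits)
        self.encoder.backward(dfeat, dskips)


def iter_layers(net):
    """All layer objects of either network variant, in forward order."""
    enc = net.encoder
    for b in enc.blocks:
        yield from b.layers
    yield from enc.pools
    yield from enc.bottleneck.layers
    decoders = ([net.decoder_lung, net.decoder_heart]
                if hasattr(net, "decoder_lung") else [net.decoder])
    for d in decoders:
        for up, upconv, upbn, uprelu, block in zip(
                d.ups, d.upconvs, d.upbns, d.uprelus, d.blocks):
            yield up
            yield upconv
            yield upbn
            yield uprelu
            yield from block.layers
        yield d.head


def set_training(net, training: bool) -> None:
    """Switch batch-norm layers between batch and running statistics."""
    for layer in iter_layers(net):
        if hasattr(layer, "training"):
            layer.training = training


def parameter_count(net) -> int:
    return sum(p.value.size for p in net.parameters())


def get_weights(net) -> list[np.ndarray]:
    """Snapshot all parameters plus batch-norm running statistics."""
    state = [p.value.copy() for p in net.parameters()]
    for layer in iter_layers(net):
        if isinstance(layer, BatchNorm2d):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def set_weights(net, weights: list[np.ndarray]) -> None:
    params = net.parameters()
    for p, w in zip(params, weights[:len(params)], strict=False):
        p.value[...] = w
    rest = weights[len(params):]
    i = 0
    for layer in iter_layers(net):
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = rest[i]
            layer.running_var[...] = rest[i + 1]
            i += 2
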