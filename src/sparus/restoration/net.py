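"""Residual U-shaped encoder-decoder for sparse-array artifact restoration.

The encoder alternates residual Conv-BN-ReLU blocks with 2x2 max pooling
(each stage halves the spatial size and doubles the channel count); the
decoder mirrors it with sub-pixel (pixel-shuffle) 2x upscaling and
additive encoder-to-decoder skip connections.  A final convolution maps
back to one channel; optionally the input is added back so the network
learns a residual correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..acquisition import ValidationError
from .layers import BatchNorm2d, Conv2d, Layer, MaxPool2x2, Param, PixelShuffle, ReLU

__all__ = ["RUNetConfig", "ResidualBlock", "RUNet", "build_runet", "RestorationModel"]


@dataclass(frozen=True)
class RUNetConfig:
    """Architecture and training hyper-parameters."""

    depth: int = 4
    base_channels: int = 32
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-4
    loss_weights: dict = field(default_factory=lambda: {"pixel": 1.0, "perceptual": 0.1})
    global_residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        lw = dict(self.loss_weights)
        if any(v < 0 for v in lw.values()):
            raise ValidationError("loss weights must be non-negative")
        if lw.get("pixel", 0.0) == 0.0 and lw.get("perceptual", 0.0) == 0.0:
            raise ValidationError("loss weights must not both be zero")
        object.__setattr__(self, "loss_weights", lw)

    @property
    def divisor(self) -> int:
        return 2**self.depth


class ResidualBlock(Layer):
    """output = inner(x) + skip(x); inner = Conv-BN-ReLU-Conv-BN.

    The skip path is the identity when channel counts match, else a 1x1
    projection convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None
        # namespace parameter names so checkpoint keys stay unique
        named = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.proj is not None:
            named.append(("proj", self.proj))
        for prefix, sub in named:
            for p in sub.params():
                p.name = f"{prefix}.{p.name}"

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        if h.shape != skip.shape:
            raise ValidationError("residual block must preserve spatial shape")
        return h + skip

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.bn2.backward(dout)
        dh = self.conv2.backward(dh)
        dh = self.relu.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.proj is None:
            dx = dx + dout
        else:
            dx = dx + self.proj.backward(dout)
        return dx

    def _sublayers(self) -> list[Layer]:
        subs: list[Layer] = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            subs.append(self.proj)
        return subs

    def params(self) -> list[Param]:
        return [p for s in self._sublayers() for p in s.params()]

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, s in enumerate(self._sublayers()):
            for k, v in s.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, s in enumerate(self._sublayers()):
            sub = {
                k.split(".", 1)[1]: v
                for k, v in state.items()
                if k.startswith(f"{i}.")
            }
            if sub:
                s.load_state(sub)


class RUNet:
    """The full encoder-decoder; owns all layers and the parameter list."""

    def __init__(self, config: RUNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_channels
        ch = [b * 2**i for i in range(d + 1)]

        self.stem = Conv2d(1, ch[0], 3, rng)
        self.enc_blocks = [ResidualBlock(ch[i], ch[i], rng) for i in range(d)]
        self.pools = [MaxPool2x2() for _ in range(d)]
        self.down_blocks = [ResidualBlock(ch[i], ch[i + 1], rng) for i in range(d)]
        self.up_convs = [Conv2d(ch[i + 1], ch[i] * 4, 3, rng) for i in reversed(range(d))]
        self.shuffles = [PixelShuffle(2) for _ in range(d)]
        self.dec_blocks = [ResidualBlock(ch[i], ch[i], rng) for i in reversed(range(d))]
        self.head = Conv2d(ch[0], 1, 3, rng)
        if config.global_residual:
            # identity at init: the net starts as a no-op correction
            self.head.w.value[:] = 0.0

    # ordered layer registry (stable across save/load)
    def layers(self) -> list[tuple[str, Layer]]:
        out: list[tuple[str, Layer]] = [("stem", self.stem)]
        for i, (blk, pool, down) in enumerate(
            zip(self.enc_blocks, self.pools, self.down_blocks)
        ):
            out += [(f"enc{i}", blk), (f"pool{i}", pool), (f"down{i}", down)]
        for i, (up, sh, blk) in enumerate(
            zip(self.up_convs, self.shuffles, self.dec_blocks)
        ):
            out += [(f"up{i}", up), (f"shuffle{i}", sh), (f"dec{i}", blk)]
        out.append(("head", self.head))
        return out

    def params(self) -> list[Param]:
        return [p for _, layer in self.layers() for p in layer.params()]

    def check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        div = self.config.divisor
        if h % div or w % div:
            raise ValidationError(
                f"input spatial size {h}x{w} must be divisible by 2^depth = {div}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.check_input(x)
        x0 = x
        h = self.stem.forward(x, train)
        skips = []
        for blk, pool, down in zip(self.enc_blocks, self.pools, self.down_blocks):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
            h = down.forward(h, train)
        for up, sh, blk, skip in zip(
            self.up_convs, self.shuffles, self.dec_blocks, reversed(skips)
        ):
            h = up.forward(h, train)
            h = sh.forward(h, train)
            h = h + skip
            h = blk.forward(h, train)
        out = self.head.forward(h, train)
        if self.config.global_residual:
            out = out + x0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dout)
        # decoder ran in order up0..up{d-1}; reverse it
        dskip_acc: list[np.ndarray] = []
        for up, sh, blk in zip(
            reversed(self.up_convs), reversed(self.shuffles), reversed(self.dec_blocks)
        ):
            dh = blk.backward(dh)
            dskip_acc.append(dh)  # additive skip: gradient splits equally
            dh = sh.backward(dh)
            dh = up.backward(dh)
        # dskip_acc was filled shallow-to-deep; encoder unwinds deep-to-shallow
        for blk, pool, down, dskip in zip(
            reversed(self.enc_blocks),
            reversed(self.pools),
            reversed(self.down_blocks),
            reversed(dskip_acc),
        ):
            dh = down.backward(dh)
            dh = pool.backward(dh)
            dh = blk.backward(dh + dskip)
        dx = self.stem.backward(dh)
        if self.config.global_residual:
            dx = dx + dout
        return dx

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad.fill(0.0)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers():
            for p in layer.params():
                out[f"{name}/{p.name}"] = p.value.copy()
            for k, v in layer.state().items():
                out[f"{name}/state/{k}"] = np.asarray(v).copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers():
            for p in layer.params():
                p.value = np.ascontiguousarray(weights[f"{name}/{p.name}"], dtype=np.float32)
                p.grad = np.zeros_like(p.value)
            st = {
                k.split("/state/", 1)[1]: v
                for k, v in weights.items()
                if k.startswith(f"{name}/state/")
            }
            if st:
                layer.load_state(st)


@dataclass
class RestorationModel:
    """Network plus its configuration and training history."""

    config: RUNetConfig
    net: RUNet
    training_history: list = field(default_factory=list)

    def predict_array(self, image01: np.ndarray) -> np.ndarray:
        """Map one [0, 1] grayscale array through the net (eval mode)."""
        x = np.asarray(image01, dtype=np.float32)[None, None]
        out = self.net.forward(x, train=False)[0, 0]
        return np.clip(out, 0.0, 1.0)


def build_runet(config: RUNetConfig) -> RestorationModel:
    """Construct a seeded, untrained restoration model."""
    return RestorationModel(config=config, net=RUNet(config))
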