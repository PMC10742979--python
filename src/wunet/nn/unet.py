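"""Residual U-Net built on the :mod:`wunet.nn.autograd` engine.

The architecture follows the content-aware image-restoration (CARE) lineage:
an encoder/decoder with channel width doubling per resolution level, skip
connections from each encoder stage to its decoder mirror, and an optional
residual output head (the network predicts a correction added to its input).
With the residual head and a zero-initialised final layer the freshly built
network is the exact identity map, which is both a useful training prior and
a testable contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor


@dataclass
class UNetConfig:
    """Geometry and width of one denoising network.

    Parameters
    ----------
    input_side:
        Spatial side length of (square) input patches, in pixels.
    levels:
        Number of down-/up-sampling stages. Each stage halves resolution,
        so ``input_side`` must be divisible by ``2**levels``.
    base_channels:
        Channel width after the first convolution; doubles per level.
    n_convs_per_block:
        Convolutions in each encoder/decoder block.
    residual_skips:
        Concatenate encoder features into the matching decoder stage.
    output_residual:
        Predict a correction added to the input rather than the output
        directly.
    final_zero_init:
        Zero-initialise the last convolution so the untrained residual
        network is the identity.
    padding:
        Convolution padding mode, ``"reflect"`` or ``"zeros"``.
    """

    input_side: int = 256
    levels: int = 6
    base_channels: int = 32
    n_convs_per_block: int = 2
    kernel_size: int = 3
    residual_skips: bool = True
    output_residual: bool = True
    final_zero_init: bool = True
    padding: str = "reflect"

    def validate(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.input_side % (2 ** self.levels) != 0:
            raise ValueError(
                f"input_side {self.input_side} is not divisible by "
                f"2**levels = {2 ** self.levels}")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


class Conv2d:
    """Convolution layer with He-initialised weights."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: str = "reflect", zero_init: bool = False,
                 dtype=np.float32):
        if zero_init:
            w = np.zeros((c_out, c_in, k, k), dtype=dtype)
        else:
            std = np.sqrt(2.0 / (c_in * k * k))
            w = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(dtype)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, padding=self.padding)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class UNet:
    """Encoder-decoder denoiser operating on (N, 1, H, W) patches."""

    def __init__(self, config: UNetConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        pad = config.padding
        nc = config.n_convs_per_block
        B = config.base_channels

        def block(c_in, c_out):
            convs = [Conv2d(c_in, c_out, k, rng, pad, dtype=dtype)]
            for _ in range(nc - 1):
                convs.append(Conv2d(c_out, c_out, k, rng, pad, dtype=dtype))
            return convs

        self.stem = Conv2d(1, B, k, rng, pad, dtype=dtype)
        self.enc: list[list[Conv2d]] = []
        ch = B
        for lvl in range(config.levels):
            self.enc.append(block(ch, B * 2 ** lvl))
            ch = B * 2 ** lvl
        self.bottleneck = block(ch, 2 * ch)
        ch = 2 * ch
        self.dec: list[list[Conv2d]] = []
        for lvl in reversed(range(config.levels)):
            c_out = B * 2 ** lvl
            c_in = ch + (c_out if config.residual_skips else 0)
            self.dec.append(block(c_in, c_out))
            ch = c_out
        self.head = Conv2d(ch, 1, 1, rng, pad,
                           zero_init=config.final_zero_init, dtype=dtype)

    # -- parameters ----------------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        ps = list(self.stem.params)
        for blk in self.enc + [self.bottleneck] + self.dec:
            for c in blk:
                ps.extend(c.params)
        ps.extend(self.head.params)
        return ps

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data = s.astype(p.data.dtype, copy=True)

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.params))

    # -- forward -------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        """Full graph-recording forward pass on (N, 1, H, W) input."""
        cfg = self.config
        h = ag.relu(self.stem(x))
        skips: list[Tensor] = []
        for blk in self.enc:
            for c in blk:
                h = ag.relu(c(h))
            skips.append(h)
            h = ag.maxpool2(h)
        for c in self.bottleneck:
            h = ag.relu(c(h))
        for blk, skip in zip(self.dec, reversed(skips)):
            h = ag.upsample2(h)
            if cfg.residual_skips:
                h = ag.concat([h, skip], axis=1)
            for c in blk:
                h = ag.relu(c(h))
        delta = self.head(h)
        if cfg.output_residual:
            return x + delta
        return delta

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Inference on (N, H, W) or (H, W) arrays, dtype-preserving.

        The convolutional path runs in the network dtype; for residual
        networks the final addition happens in the caller's dtype so a
        zero correction leaves the input bit-identical.
        """
        x = np.asarray(patches)
        single = x.ndim == 2
        if single:
            x = x[None]
        x4 = x[:, None].astype(self.dtype, copy=False)
        with ag.no_grad():
            if self.config.output_residual:
                # run the trunk only, add the correction in input precision
                saved = self.config.output_residual
                self.config.output_residual = False
                try:
                    delta = self.forward(Tensor(x4)).data
                finally:
                    self.config.output_residual = saved
                out = x + delta[:, 0].astype(x.dtype)
            else:
                out = self.forward(Tensor(x4)).data[:, 0].astype(x.dtype)
        return out[0] if single else out


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a seeded residual U-Net from its configuration."""
    return UNet(config, seed=seed)
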