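"""Modified U-Net for premorbid muscle boundary prediction.

The network is an encoder–decoder with skip connections in which a single
convolution (+ batch normalization + ReLU) follows every down- and
up-sampling step, instead of the double convolutions of the classic U-Net.
With the full-resolution configuration (512×512 input, 4 pooling stages,
32 channels at the first level, doubling per level) the bottleneck is a
32×32 representation with 512 channels.  Output is a single-channel
sigmoid probability map at the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .types import CTSection, PremorbidMask

#: HU window used to normalize network input to [0, 1].  The floor sits at
#: air so partial-volume pixels on the tissue/background interface keep a
#: graded value instead of clipping to the background level; the ceiling
#: keeps fat (≈ −100), muscle (≈ +50) and bone (> +166) separable.
HU_WINDOW = (-1000.0, 400.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the channel count after the first convolution;
    channels double at each of the ``depth`` pooling stages, so the
    bottleneck carries ``base_channels * 2**depth`` channels on a
    ``input_size / 2**depth`` grid.
    """

    input_size: int = 512
    depth: int = 4
    base_channels: int = 32

    def __post_init__(self):
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.input_size < 2 ** self.depth:
            raise ValueError("input_size too small for requested depth")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // (2 ** self.depth)

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * (2 ** self.depth)

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


class UNet:
    """Single-conv-per-level U-Net (see module docstring)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c = config.base_channels
        d = config.depth

        def block(cin, cout):
            return [nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU()]

        self.enc_blocks: list[list[nn.Layer]] = []
        cin = 1
        for lvl in range(d):
            cout = c * 2 ** lvl
            self.enc_blocks.append(block(cin, cout))
            cin = cout
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = block(cin, c * 2 ** d)
        cin = c * 2 ** d
        self.ups = [nn.BilinearUp2() for _ in range(d)]
        self.dec_blocks: list[list[nn.Layer]] = []
        for lvl in reversed(range(d)):
            skip = c * 2 ** lvl
            self.dec_blocks.append(block(cin + skip, skip))
            cin = skip
        self.head = nn.Conv2d(cin, 1, 1, rng)

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.enc_blocks:
            out.extend(b)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        out.extend(self.ups)
        for b in self.dec_blocks:
            out.extend(b)
        out.append(self.head)
        return out

    @property
    def n_params(self) -> int:
        return sum(
            layer.n_params for layer in self.layers() if hasattr(layer, "n_params")
        )

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _run(block: list[nn.Layer], x: np.ndarray, train: bool) -> np.ndarray:
        for layer in block:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _run_back(block: list[nn.Layer], g: np.ndarray) -> np.ndarray:
        for layer in reversed(block):
            g = layer.backward(g)
        return g

    def forward(self, x: np.ndarray, train: bool = False,
                return_bottleneck: bool = False):
        """x: (N, 1, H, W) normalized input → (N, 1, H, W) logits."""
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != configured "
                f"{self.config.input_size}"
            )
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = self._run(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self._run(self.bottleneck, x, train)
        bneck = x
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run(blk, x, train)
        z = self.head.forward(x, train)
        if return_bottleneck:
            return z, bneck
        return z

    def backward(self, dz: np.ndarray) -> None:
        g = self.head.backward(dz)
        skip_grads = []
        for up, blk, cs in zip(reversed(self.ups), reversed(self.dec_blocks),
                               reversed(self._skip_channels)):
            g = self._run_back(blk, g)
            skip_grads.append(g[:, :cs])
            g = up.backward(g[:, cs:])
        g = self._run_back(self.bottleneck, g)
        for blk, pool, sg in zip(reversed(self.enc_blocks), reversed(self.pools),
                                 reversed(skip_grads)):
            g = pool.backward(g)
            g = g + sg
            g = self._run_back(blk, g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, train=False))

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = nn.get_state(self.layers())
        cfg = self.config
        np.savez(
            path,
            input_size=cfg.input_size,
            depth=cfg.depth,
            base_channels=cfg.base_channels,
            **{f"arr_{i}": a for i, a in enumerate(state)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(path)
        cfg = NetworkConfig(
            input_size=int(data["input_size"]),
            depth=int(data["depth"]),
            base_channels=int(data["base_channels"]),
        )
        model = cls(cfg)
        n = len(nn.get_state(model.layers()))
        nn.set_state(model.layers(), [data[f"arr_{i}"] for i in range(n)])
        return model


def build_network(config: NetworkConfig, seed: int = 0) -> UNet:
    """Instantiate the premorbid segmentation network."""
    return UNet(config, np.random.default_rng(seed))


def normalize_hu(pixels: np.ndarray) -> np.ndarray:
    """Window HU values to [0, 1] for network input."""
    lo, hi = HU_WINDOW
    return ((np.clip(pixels, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def predict_mask(model: UNet, section: CTSection, threshold: float = 0.5,
                 muscle_label: str = "SS") -> PremorbidMask:
    """Binarize the network's probability map for one section.

    The section must already be resampled to the network's input size;
    postprocessing (largest component, hole filling) is applied downstream,
    not here.
    """
    h, w = section.shape
    if h != model.config.input_size or w != model.config.input_size:
        raise ValueError(
            f"section size {section.shape} does not match network input size "
            f"{model.config.input_size}; resample first"
        )
    x = normalize_hu(section.pixels)[None, None]
    proba = model.predict_proba(x)[0, 0]
    return PremorbidMask((proba >= threshold).astype(np.uint8), muscle_label)
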