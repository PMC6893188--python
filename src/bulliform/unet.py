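"""U-net for bulliform column segmentation.

Classic encoder-decoder with skip connections: the contracting phase is
repeated units of two 3x3 convolutions and one 2x2 max-pool; the
expanding phase is repeated units of one 2x2 up-convolution (whose
output is concatenated with the matching-resolution encoder feature
map) and two 3x3 convolutions; a final 1x1 convolution produces one
logit per pixel (sigmoid probability of "bulliform").

Channel widths double at each contraction level starting from
``base_channels``.  All computation is float32 numpy (see :mod:`.nn`),
fully deterministic given the initialization seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import DTYPE, Adam, Conv3x3, MaxPool2, UpConv2x2, bce_with_logits, sigmoid


@dataclass
class UNetConfig:
    depth: int = 2
    base_channels: int = 8
    input_size: int = 480
    learning_rate: float = 5e-5
    epochs: int = 50
    batch_size: int = 2
    ensemble_size: int = 5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2**self.depth}"
            )
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class UNet:
    """One ensemble member. ``seed`` controls weight initialization."""

    def __init__(self, config: UNetConfig, seed: int | None = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        rng = np.random.default_rng(self.seed)
        d, b = config.depth, config.base_channels

        self.enc = []  # [(conv1, conv2, pool), ...]
        c_in = 1
        for lvl in range(d):
            c = b * 2**lvl
            self.enc.append((Conv3x3(c_in, c, rng), Conv3x3(c, c, rng), MaxPool2()))
            c_in = c
        cb = b * 2**d
        self.bottleneck = (Conv3x3(c_in, cb, rng), Conv3x3(cb, cb, rng))
        self.dec = []  # [(upconv, conv1, conv2), ...] from deepest to shallowest
        c_in = cb
        for lvl in reversed(range(d)):
            c = b * 2**lvl
            self.dec.append((UpConv2x2(c_in, c, rng), Conv3x3(2 * c, c, rng), Conv3x3(c, c, rng)))
            c_in = c
        self.head = Conv1x1(c_in, 1, rng)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) or (N, H, W, 1) float in [0,1] -> logits (N, H, W)."""
        if x.ndim == 3:
            x = x[..., None]
        h = x.astype(DTYPE)
        skips = []
        for conv1, conv2, pool in self.enc:
            h = conv2.forward(conv1.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h))
        self._skip_channels = []
        for (up, conv1, conv2), skip in zip(self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=-1)
            self._skip_channels.append(skip.shape[-1])
            h = conv2.forward(conv1.forward(h))
        z = self.head.forward(h)
        return z[..., 0]

    def backward(self, dz: np.ndarray) -> None:
        d = self.head.backward(dz[..., None])
        dskips = []
        for i in reversed(range(len(self.dec))):
            up, conv1, conv2 = self.dec[i]
            d = conv1.backward(conv2.backward(d))
            c_skip = self._skip_channels[i]
            dskips.append(d[..., :c_skip])
            d = up.backward(d[..., c_skip:])
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        # dskips was filled shallow -> deep, so dskips[i] matches enc[i]
        for i in reversed(range(len(self.enc))):
            conv1, conv2, pool = self.enc[i]
            d = pool.backward(d)
            d = d + dskips[i]
            d = conv1.backward(conv2.backward(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x))

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for i, (c1, c2, _) in enumerate(self.enc):
            yield f"enc{i}_c1", c1
            yield f"enc{i}_c2", c2
        yield "bot_c1", self.bottleneck[0]
        yield "bot_c2", self.bottleneck[1]
        for i, (up, c1, c2) in enumerate(self.dec):
            yield f"dec{i}_up", up
            yield f"dec{i}_c1", c1
            yield f"dec{i}_c2", c2
        yield "head", self.head

    def params(self) -> dict:
        return {f"{n}.{k}": v for n, lay in self._layers() for k, v in lay.params().items()}

    def grads(self) -> dict:
        return {f"{n}.{k}": v for n, lay in self._layers() for k, v in lay.grads().items()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params().values())

    def conv_param_count(self) -> int:
        """Parameters in 3x3/1x1 convolution layers only."""
        return sum(
            lay.n_params for _, lay in self._layers() if isinstance(lay, (Conv3x3, Conv1x1))
        )

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: Adam) -> float:
        z = self.forward_logits(x)
        loss, dz = bce_with_logits(z, y)
        self.backward(dz)
        opt.step(self.grads())
        return loss

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        z = self.forward_logits(x)
        return bce_with_logits(z, y)[0]

    # -- serialization ------------------------------------------------------
    def save(self, directory, name: str = "unet") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / f"{name}.npz", **self.params())
        sidecar = {"config": asdict(self.config), "seed": self.seed}
        (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory, name: str = "unet") -> "UNet":
        directory = Path(directory)
        sidecar = json.loads((directory / f"{name}.json").read_text())
        model = cls(UNetConfig(**sidecar["config"]), seed=sidecar["seed"])
        with np.load(directory / f"{name}.npz") as data:
            params = model.params()
            for k in params:
                params[k][...] = data[k]
        return model


class Conv1x1(Conv3x3):
    """1x1 convolution head (linear, no activation)."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.W = np.random.default_rng(rng.integers(2**31)).normal(
            0.0, np.sqrt(1.0 / c_in), size=(1, 1, c_in, c_out)
        ).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.relu = False
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W[0, 0] + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("nhwc,nhwf->cf", self._x, dout)[None, None].astype(DTYPE)
        self.db = dout.sum(axis=(0, 1, 2))
        dx = dout @ self.W[0, 0].T
        self._x = None
        return dx
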