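"""The 3D U-Net used to synthesize an undistorted b0.

Two input channels (normalized T1, normalized distorted b0), one output
channel (synthesized undistorted b0), encoder-decoder with skip
connections; every convolution is followed by instance normalization and
leaky rectification. Channels double at each encoder level; decoding
mirrors the encoder with nearest-neighbour upsampling and skip
concatenation, and a final 1x1x1 convolution maps to the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import AvgPool3d, Conv3d, InstanceNorm3d, Layer, LeakyReLU, Sequential, Upsample3d

__all__ = ["UNetConfig", "UNet3D"]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 2
    out_channels: int = 1
    levels: int = 3
    base_channels: int = 16
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.in_channels != 2 or self.out_channels != 1:
            raise ValueError("the synthesizer takes 2 input channels and emits 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not 0 <= self.leaky_slope < 1:
            raise ValueError("leaky_slope must be in [0, 1)")


def _block(cin: int, cout: int, slope: float, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv3d(cin, cout, 3, rng, slope),
        InstanceNorm3d(cout),
        LeakyReLU(slope),
        Conv3d(cout, cout, 3, rng, slope),
        InstanceNorm3d(cout),
        LeakyReLU(slope),
    )


class UNet3D:
    """Encoder-decoder volumetric synthesizer with skip connections."""

    def __init__(self, cfg: UNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C, L, s = cfg.base_channels, cfg.levels, cfg.leaky_slope
        self.enc = [
            _block(cfg.in_channels if l == 0 else C * 2 ** (l - 1), C * 2**l, s, rng)
            for l in range(L)
        ]
        self.pools = [AvgPool3d() for _ in range(L)]
        self.bottleneck = _block(C * 2 ** (L - 1), C * 2**L, s, rng)
        self.ups = [Upsample3d() for _ in range(L)]
        self.dec = [
            _block(C * 2**l + C * 2 ** (l + 1), C * 2**l, s, rng)
            for l in reversed(range(L))
        ]
        self.head = Conv3d(C, cfg.out_channels, 1, rng, s)
        self._layers: list[Layer] = (
            self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.head]
        )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        div = 2**self.cfg.levels
        if any(d % div for d in x.shape[1:]):
            raise ValueError(
                f"grid {x.shape[1:]} not divisible by 2^levels = {div}"
            )
        x = x.astype(np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = blk.forward(np.concatenate([skip, x], axis=0))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dx = self.head.backward(dy.astype(np.float32))
        dskips = []
        for blk, up, cs in zip(
            reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)
        ):
            d = blk.backward(dx)
            dskips.append(d[:cs])
            dx = up.backward(d[cs:])
        dx = self.bottleneck.backward(dx)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx) + dskip
            dx = blk.backward(dx)

    def zero_grad(self) -> None:
        for lyr in self._layers:
            lyr.zero_grad()

    # -- parameter access ---------------------------------------------------
    def _walk(self):
        def leaves(lyr: Layer):
            if isinstance(lyr, Sequential):
                for sub in lyr.layers:
                    yield from leaves(sub)
            elif lyr.params:
                yield lyr

        for i, lyr in enumerate(self._layers):
            for leaf in leaves(lyr):
                yield i, leaf

    def param_refs(self) -> list[tuple[dict, dict, str]]:
        return [
            (leaf.params, leaf.grads, k)
            for _i, leaf in self._walk()
            for k in sorted(leaf.params)
        ]

    def n_params(self) -> int:
        return sum(leaf.params[k].size for _i, leaf in self._walk() for k in leaf.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for j, (_i, leaf) in enumerate(self._walk()):
            for k in sorted(leaf.params):
                state[f"{j}.{k}"] = leaf.params[k].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for j, (_i, leaf) in enumerate(self._walk()):
            for k in sorted(leaf.params):
                arr = np.asarray(state[f"{j}.{k}"], dtype=np.float32)
                if arr.shape != leaf.params[k].shape:
                    raise ValueError(f"shape mismatch for parameter {j}.{k}")
                leaf.params[k][...] = arr

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights plus the architecture config as an .npz archive."""
        meta = np.array(
            [
                self.cfg.in_channels,
                self.cfg.out_channels,
                self.cfg.levels,
                self.cfg.base_channels,
            ],
            dtype=np.int64,
        )
        np.savez(
            str(path),
            __meta__=meta,
            __slope__=np.float64(self.cfg.leaky_slope),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(str(path)) as z:
            meta = z["__meta__"]
            cfg = UNetConfig(
                in_channels=int(meta[0]),
                out_channels=int(meta[1]),
                levels=int(meta[2]),
                base_channels=int(meta[3]),
                leaky_slope=float(z["__slope__"]),
            )
            net = cls(cfg, seed=0)
            net.load_state_dict({k: z[k] for k in z.files if not k.startswith("__")})
        return net
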