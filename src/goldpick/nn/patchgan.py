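"""PatchGAN discriminator: classifies overlapping patches as real or fake.

Input is the (micrograph, mask) pair stacked on the channel axis; output is
a logit map, one logit per receptive-field patch, averaged by the loss.
"""
from __future__ import annotations

import numpy as np

from .layers import Conv2d, InstanceNorm, LeakyReLU, Module

__all__ = ["PatchDiscriminator"]


class PatchDiscriminator:
    def __init__(
        self,
        in_channels: int = 2,
        base_filters: int = 64,
        n_strided: int = 2,
        init_rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = init_rng or np.random.default_rng(0)
        layers: list[Module] = [
            Conv2d(in_channels, base_filters, rng=rng, dtype=dtype),
            LeakyReLU(0.2),
        ]
        ch = base_filters
        for i in range(1, n_strided):
            layers += [
                Conv2d(ch, min(2**i, 8) * base_filters, rng=rng, dtype=dtype),
                InstanceNorm(min(2**i, 8) * base_filters, dtype=dtype),
                LeakyReLU(0.2),
            ]
            ch = min(2**i, 8) * base_filters
        layers += [
            Conv2d(ch, 2 * ch, stride=1, rng=rng, dtype=dtype),
            InstanceNorm(2 * ch, dtype=dtype),
            LeakyReLU(0.2),
            Conv2d(2 * ch, 1, stride=1, rng=rng, dtype=dtype),
        ]
        self.layers = layers

    def modules(self) -> list[Module]:
        return [m for m in self.layers if m.params]

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.params.items():
                out[f"m{i}.{k}"] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            m.load_state(
                {k.split(".", 1)[1]: v for k, v in state.items() if k.startswith(f"m{i}.")}
            )

    def zero_grad(self) -> None:
        for m in self.modules():
            m.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g
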