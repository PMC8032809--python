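"""U-Net generator: encoder-decoder with skip connections, pix2pix style.

For an input tile of side ``2**n_down`` the encoder halves the raster
``n_down`` times down to a 1x1 bottleneck; each decoder level upsamples by 2
and concatenates the same-scale encoder activation.  Channel schedule is
``base_filters * min(2**i, 8)``.  Normalization is per-instance; the first
encoder block, the bottleneck and the output block are unnormalized, and the
three innermost decoder levels use dropout (the generator's stochastic input
during training; inference runs with dropout off and is deterministic).
"""
from __future__ import annotations

import numpy as np

from .layers import (
    Conv2d,
    ConvTranspose2d,
    Dropout,
    InstanceNorm,
    LeakyReLU,
    Module,
    ReLU,
    Tanh,
)

__all__ = ["UNetGenerator"]


class UNetGenerator:
    def __init__(
        self,
        n_down: int = 8,
        base_filters: int = 64,
        in_channels: int = 1,
        out_channels: int = 1,
        dropout_rng: np.random.Generator | None = None,
        init_rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        if n_down < 2:
            raise ValueError("n_down must be >= 2")
        rng = init_rng or np.random.default_rng(0)
        drng = dropout_rng or np.random.default_rng(1)
        self.n_down = n_down
        self.dtype = dtype
        ch = [base_filters * min(2**i, 8) for i in range(n_down)]
        self.ch = ch

        self.enc_convs: list[Conv2d] = []
        self.enc_norms: list[InstanceNorm | None] = []
        self.enc_acts: list[LeakyReLU] = []
        prev = in_channels
        for i in range(n_down):
            self.enc_convs.append(Conv2d(prev, ch[i], rng=rng, dtype=dtype))
            # no norm on the first block or the bottleneck
            self.enc_norms.append(
                InstanceNorm(ch[i], dtype=dtype) if 0 < i < n_down - 1 else None
            )
            self.enc_acts.append(LeakyReLU(0.2))
            prev = ch[i]

        self.dec_convs: list[ConvTranspose2d] = []
        self.dec_norms: list[InstanceNorm] = []
        self.dec_drops: list[Dropout | None] = []
        self.dec_acts: list[ReLU] = []
        for i in range(n_down - 2, -1, -1):  # produce level-i feature maps
            c_in = ch[i + 1] if i == n_down - 2 else 2 * ch[i + 1]
            self.dec_convs.append(ConvTranspose2d(c_in, ch[i], rng=rng, dtype=dtype))
            self.dec_norms.append(InstanceNorm(ch[i], dtype=dtype))
            self.dec_drops.append(Dropout(0.5, drng) if i >= n_down - 4 else None)
            self.dec_acts.append(ReLU())
        self.out_act_in = ReLU()
        self.out_conv = ConvTranspose2d(2 * ch[0], out_channels, rng=rng, dtype=dtype)
        self.out_act = Tanh()
        self._skips: list[np.ndarray] | None = None

    # --- plumbing -------------------------------------------------------
    def modules(self) -> list[Module]:
        mods: list[Module] = []
        mods += self.enc_convs
        mods += [n for n in self.enc_norms if n is not None]
        mods += self.dec_convs
        mods += self.dec_norms
        mods += [self.out_conv]
        return mods

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

    # --- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        side = x.shape[2]
        if x.shape[2] != x.shape[3] or side % (2**self.n_down) != 0:
            raise ValueError(
                f"tile side {x.shape[2]}x{x.shape[3]} not divisible by 2^{self.n_down}"
            )
        skips: list[np.ndarray] = []
        h = x
        for i in range(self.n_down):
            if i > 0:
                h = self.enc_acts[i].forward(h, train)
            h = self.enc_convs[i].forward(h, train)
            if self.enc_norms[i] is not None:
                h = self.enc_norms[i].forward(h, train)
            skips.append(h)
        if train:
            self._skips = skips
        for j in range(len(self.dec_convs)):
            i = self.n_down - 2 - j
            h = self.dec_acts[j].forward(h, train)
            h = self.dec_convs[j].forward(h, train)
            h = self.dec_norms[j].forward(h, train)
            if self.dec_drops[j] is not None:
                h = self.dec_drops[j].forward(h, train)
            h = np.concatenate([skips[i], h], axis=1)
        h = self.out_act_in.forward(h, train)
        h = self.out_conv.forward(h, train)
        return self.out_act.forward(h, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(gy)
        g = self.out_conv.backward(g)
        g = self.out_act_in.backward(g)
        skip_grads: list[np.ndarray | None] = [None] * self.n_down
        for j in range(len(self.dec_convs) - 1, -1, -1):
            i = self.n_down - 2 - j
            c_skip = self._skips[i].shape[1]
            skip_grads[i] = g[:, :c_skip]
            g = g[:, c_skip:]
            if self.dec_drops[j] is not None:
                g = self.dec_drops[j].backward(g)
            g = self.dec_norms[j].backward(g)
            g = self.dec_convs[j].backward(g)
            g = self.dec_acts[j].backward(g)
        for i in range(self.n_down - 1, -1, -1):
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            if self.enc_norms[i] is not None:
                g = self.enc_norms[i].backward(g)
            g = self.enc_convs[i].backward(g)
            if i > 0:
                g = self.enc_acts[i].backward(g)
        return g
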