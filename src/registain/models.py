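"""Builders for the three networks: generator G, discriminator D, registration R.

G is an attention-gated U-Net mapping the 2-channel autofluorescence input to
a 3-channel H&E image in [0, 1]; D is a strided CNN classifier emitting one
probability per image; R is a plain U-Net taking the concatenated generator
output and raw target (6 channels) and predicting a raw 2-channel
displacement field, which is post-processed by :func:`registain.warp.postprocess_dvf`.

Exact layer widths/depths are configuration defaults — the architecture
contracts (shapes, determinism, differentiability), not specific weights,
are the tested surface.  The registration head is zero-initialised so the
predicted field starts at zero displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import CNNClassifier, UNet


@dataclass
class NetConfig:
    in_channels: int
    out_channels: int
    base_filters: int = 32
    depth: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.in_channels <= 0 or self.out_channels <= 0 or self.base_filters <= 0:
            raise ValueError("channel counts must be positive")


def build_generator(cfg: NetConfig | None = None) -> UNet:
    cfg = cfg or NetConfig(in_channels=2, out_channels=3)
    if cfg.in_channels != 2 or cfg.out_channels != 3:
        raise ValueError("generator maps 2 autofluorescence channels to RGB (3)")
    return UNet(
        in_ch=2, out_ch=3, base=cfg.base_filters, depth=cfg.depth,
        attention=True, final="sigmoid", seed=cfg.seed,
    )


def build_discriminator(cfg: NetConfig | None = None) -> CNNClassifier:
    cfg = cfg or NetConfig(in_channels=3, out_channels=1)
    if cfg.in_channels != 3:
        raise ValueError("discriminator consumes 3-channel RGB images")
    return CNNClassifier(in_ch=3, base=cfg.base_filters, depth=cfg.depth, seed=cfg.seed)


def build_registration_net(cfg: NetConfig | None = None) -> UNet:
    cfg = cfg or NetConfig(in_channels=6, out_channels=2)
    if cfg.in_channels != 6 or cfg.out_channels != 2:
        raise ValueError("registration net maps concat(I_VS, I_HS,raw) (6ch) to a 2-plane DVF")
    return UNet(
        in_ch=6, out_ch=2, base=cfg.base_filters, depth=cfg.depth,
        attention=False, final="none", seed=cfg.seed, zero_init_head=True,
    )
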