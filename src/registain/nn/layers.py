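"""Network building blocks: convolutional modules, U-Nets and a CNN classifier.

Parameter initialisation is driven entirely by an explicit ``numpy`` generator
so builds are deterministic given a seed and independent of any global RNG
state.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from . import tensor as T
from .tensor import Tensor


class Module:
    """Minimal container with recursive parameter discovery."""

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix=""):
        named = []
        for key, value in self.__dict__.items():
            path = f"{prefix}{key}"
            if isinstance(value, Tensor) and value.requires_grad:
                named.append((path, value))
            elif isinstance(value, Module):
                named.extend(value.named_parameters(path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(f"{path}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        named.append((f"{path}.{i}", item))
        return named

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, arr in state.items():
            own[name].data = np.array(arr, dtype=own[name].data.dtype, copy=True)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return Tensor(w.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, rng, stride=1, pad=None, bias=True, zero_init=False):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            self.weight = Tensor(np.zeros((out_ch, in_ch, k, k), np.float32), requires_grad=True)
        else:
            self.weight = _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by leaky ReLU."""

    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)

    def forward(self, x):
        return T.leaky_relu(self.c2(T.leaky_relu(self.c1(x))))


class AttentionGate(Module):
    """Additive attention gate weighting a skip connection by the decoder signal."""

    def __init__(self, gate_ch, skip_ch, inter_ch, rng):
        self.wg = Conv2d(gate_ch, inter_ch, 1, rng, pad=0)
        self.wx = Conv2d(skip_ch, inter_ch, 1, rng, pad=0)
        self.psi = Conv2d(inter_ch, 1, 1, rng, pad=0)

    def forward(self, gate, skip):
        att = T.sigmoid(self.psi(T.relu(self.wg(gate) + self.wx(skip))))
        return skip * att


class UNet(Module):
    """Encoder-decoder with skip connections, optionally attention-gated.

    ``depth`` down/upsampling levels on top of a stem block; channel widths
    double per level starting from ``base``.  Spatial dims must be divisible
    by 2**depth.
    """

    def __init__(self, in_ch, out_ch, base=8, depth=2, attention=False,
                 final="none", seed=0, zero_init_head=False):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.attention = attention
        self.final = final
        self.enc = [ConvBlock(in_ch if d == 0 else base * 2 ** (d - 1), base * 2 ** d, rng)
                    for d in range(depth)]
        self.bottleneck = ConvBlock(base * 2 ** (depth - 1), base * 2 ** depth, rng)
        self.up = []
        self.gates = []
        self.dec = []
        for d in reversed(range(depth)):
            ch_skip = base * 2 ** d
            ch_in = base * 2 ** (d + 1)
            self.up.append(Conv2d(ch_in, ch_skip, 3, rng))
            if attention:
                self.gates.append(AttentionGate(ch_skip, ch_skip, max(ch_skip // 2, 1), rng))
            self.dec.append(ConvBlock(2 * ch_skip, ch_skip, rng))
        self.head = Conv2d(base, out_ch, 1, rng, pad=0, zero_init=zero_init_head)

    def forward(self, x):
        H, W = x.shape[-2:]
        m = 2 ** self.depth
        if H % m or W % m:
            raise ValueError(f"input spatial dims {H}x{W} must be divisible by {m}")
        skips = []
        h = x
        for block in self.enc:
            h = block(h)
            skips.append(h)
            h = F.avg_pool2(h)
        h = self.bottleneck(h)
        for i, (up, dec) in enumerate(zip(self.up, self.dec)):
            h = T.leaky_relu(up(F.upsample_nearest2(h)))
            skip = skips[-(i + 1)]
            if self.attention:
                skip = self.gates[i](h, skip)
            h = dec(T.concatenate([skip, h], axis=1))
        h = self.head(h)
        if self.final == "sigmoid":
            h = T.sigmoid(h)
        return h


class CNNClassifier(Module):
    """Strided convolutional stack ending in one sigmoid probability per image."""

    def __init__(self, in_ch=3, base=8, depth=2, seed=0):
        rng = np.random.default_rng(seed)
        self.convs = []
        ch = in_ch
        for d in range(depth):
            out = base * 2 ** d
            self.convs.append(Conv2d(ch, out, 3, rng, stride=2, pad=1))
            ch = out
        self.headconv = Conv2d(ch, ch, 3, rng)
        self.fc_w = _he_init(rng, (ch, 1), ch)
        self.fc_b = Tensor(np.zeros(1, np.float32), requires_grad=True)

    def forward(self, x):
        h = x
        for conv in self.convs:
            h = T.leaky_relu(conv(h))
        h = T.leaky_relu(self.headconv(h))
        pooled = h.mean(axis=(2, 3))  # (B, C)
        return T.sigmoid(pooled @ self.fc_w + self.fc_b).reshape(-1)
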