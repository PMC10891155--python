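"""Alternating training of generator, discriminator and registration network.

Each training cycle performs ``update_ratio(t_D)`` generator steps (with the
registration and discriminator networks frozen; the target is the raw
histology warped by the current registration prediction), one discriminator
step (the raw target serves as the real image), and one registration step
(generator frozen; gradients flow through the differentiable warp into the
registration net).  The ratio decays as max(3, floor(12 - t_D/4000)) with
t_D the discriminator iteration count.  Disabling the registration network
(the ablation) uses the raw target directly and skips its updates.

Autofluorescence patches are standardised to zero mean / unit variance per
channel; RGB targets stay on the [0, 1] scale so the intensity semantics of
the losses and quality metrics remain interpretable.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import losses as L
from .image import PairedSample
from .models import NetConfig, build_discriminator, build_generator, build_registration_net
from .nn import Adam, Tensor, no_grad
from .warp import postprocess_dvf, warp_image


# ------------------------------------------------------------------ schedule
def update_ratio(t_d: int) -> int:
    """Generator updates per cycle: max(3, floor(12 - t_D / 4000))."""
    if t_d < 0:
        raise ValueError("t_D must be >= 0")
    return int(max(3, np.floor(12.0 - t_d / 4000.0)))


# -------------------------------------------------------------- data plumbing
def normalize_patch(patch: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """(x - mean) / max(SD, eps), per channel for (C, H, W); constant -> zeros.

    2-D input normalises over the whole array.
    """
    arr = np.asarray(patch, dtype=np.float32)
    if arr.ndim == 2:
        sd = arr.std()
        return (arr - arr.mean()) / max(float(sd), eps)
    mean = arr.mean(axis=(-2, -1), keepdims=True)
    sd = np.maximum(arr.std(axis=(-2, -1), keepdims=True), eps)
    return (arr - mean) / sd


def augment_pair(inp: np.ndarray, target: np.ndarray, rng: np.random.Generator):
    """Identical random flips (p=0.5 each) and 90-degree rotation of both arrays.

    Arrays are channel-first; the transform acts on the last two axes.
    """
    if inp.shape[-2:] != target.shape[-2:]:
        raise ValueError("input/target spatial dims differ")
    if rng.random() < 0.5:
        inp, target = inp[..., :, ::-1], target[..., :, ::-1]
    if rng.random() < 0.5:
        inp, target = inp[..., ::-1, :], target[..., ::-1, :]
    k = int(rng.integers(4))
    if k:
        inp = np.rot90(inp, k=k, axes=(-2, -1))
        target = np.rot90(target, k=k, axes=(-2, -1))
    return np.ascontiguousarray(inp), np.ascontiguousarray(target)


# ------------------------------------------------------------------- configs
@dataclass
class TrainConfig:
    lr_g: float = 1e-4
    lr_r: float = 1e-4
    lr_d: float = 1e-5
    batch_size: int = 4
    patch: int = 256
    max_cycles: int = 1000
    seed: int = 0
    use_registration_net: bool = True
    augment: bool = True
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    g_base: int = 32
    g_depth: int = 4
    d_base: int = 32
    d_depth: int = 3
    r_base: int = 32
    r_depth: int = 4
    val_fraction: float = 0.1
    val_every: int = 10
    include_adversarial_in_val: bool = False
    log_csv: Optional[str] = None
    init_generator_state: Optional[dict] = None  # warm-start for staged experiments
    freeze_generator: bool = False  # skip G updates (staged registration training)

    def __post_init__(self):
        if min(self.lr_g, self.lr_r, self.lr_d) <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainState:
    t_d: int = 0
    g_iters: int = 0
    r_iters: int = 0
    cycle: int = 0
    ratio_history: List[int] = field(default_factory=list)
    loss_history: List[dict] = field(default_factory=list)
    val_history: List[dict] = field(default_factory=list)
    best_val_lg: float = float("inf")
    best_cycle: int = -1


@dataclass
class TrainResult:
    generator: object
    discriminator: object
    registration_net: object
    state: TrainState
    config: TrainConfig
    best_generator_state: Optional[dict] = None

    def restore_best(self):
        """Load the checkpoint with the lowest validation L_G into the generator."""
        if self.best_generator_state is not None:
            self.generator.load_state_dict(self.best_generator_state)
        return self.generator


# ------------------------------------------------------------------- training
class _Batcher:
    def __init__(self, samples: Sequence[PairedSample], patch: int, rng, augment: bool = True):
        self.samples = list(samples)
        self.patch = patch
        self.rng = rng
        self.augment = augment

    def draw(self, batch_size: int):
        af_b, he_b = [], []
        idx = self.rng.integers(0, len(self.samples), size=batch_size)
        for i in idx:
            s = self.samples[i]
            af = s.af.transpose(2, 0, 1)  # (2, H, W)
            he = s.he_raw.transpose(2, 0, 1)  # (3, H, W)
            H, W = af.shape[-2:]
            p = self.patch
            if H > p or W > p:
                y = int(self.rng.integers(0, H - p + 1))
                x = int(self.rng.integers(0, W - p + 1))
                af, he = af[:, y : y + p, x : x + p], he[:, y : y + p, x : x + p]
            if self.augment:
                af, he = augment_pair(af, he, self.rng)
            af_b.append(normalize_patch(af))
            he_b.append(np.asarray(he, dtype=np.float32))
        return np.stack(af_b), np.stack(he_b)


def _predict_aligned_target(reg_net, vs_data: np.ndarray, he: np.ndarray, cfg: TrainConfig):
    """Registration forward + DVF post-processing + warp, without gradients."""
    from .nn.functional import bilinear_warp_np

    with no_grad():
        raw = reg_net(Tensor(np.concatenate([vs_data, he], axis=1)))
        dvf = postprocess_dvf(raw).data
        return bilinear_warp_np(he, dvf.astype(he.dtype)).astype(np.float32), dvf


def _generator_cost(vs, he_reg: np.ndarray, d_of_vs, cfg: TrainConfig, with_adv: bool = True):
    """Batched generator loss, mean over the batch; returns (Tensor/float, comps).

    Same arithmetic as :func:`registain.losses.generator_loss` applied per
    sample (per-sample adaptive BerHu delta), vectorised over the batch.
    """
    from .nn import tensor as T

    B = he_reg.shape[0]
    deltas = np.maximum(
        cfg.loss.delta_frac * he_reg.reshape(B, -1).std(axis=1), 1e-8
    ).astype(he_reg.dtype)[:, None, None, None]
    diff = (vs - he_reg) if isinstance(vs, Tensor) else Tensor(vs) - he_reg
    ad = diff.abs()
    quad = (ad ** 2 + deltas ** 2) * (0.5 / deltas)
    l_berhu = T.where(ad.data <= deltas, ad, quad).sum() * (1.0 / B)
    l_tv = L.tv(vs if isinstance(vs, Tensor) else Tensor(vs)) * (1.0 / B)
    comps = {"berhu": float(l_berhu.data), "tv": float(l_tv.data), "adv": 0.0}
    total = l_berhu + cfg.loss.alpha * l_tv
    if with_adv:
        adv = ((1.0 - d_of_vs) ** 2).mean() * cfg.loss.beta
        comps["adv"] = float(adv.data if isinstance(adv, Tensor) else adv)
        total = total + adv
    return total, comps


def train(dataset: Sequence[PairedSample], config: TrainConfig) -> TrainResult:
    """Run the alternating schedule; returns networks, state and best checkpoint.

    The best generator checkpoint minimises validation L_G (BerHu + TV by
    default; the adversarial term is included if configured).  Aborts with a
    diagnostic on divergent (non-finite) losses.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    n_val = int(round(config.val_fraction * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_set = [dataset[i] for i in perm[:n_val]]
    train_set = [dataset[i] for i in perm[n_val:]]
    if not train_set:
        train_set, val_set = list(dataset), []

    gen = build_generator(NetConfig(2, 3, config.g_base, config.g_depth, seed=config.seed))
    if config.init_generator_state is not None:
        gen.load_state_dict(config.init_generator_state)
    disc = build_discriminator(NetConfig(3, 1, config.d_base, config.d_depth, seed=config.seed + 1))
    reg_net = build_registration_net(NetConfig(6, 2, config.r_base, config.r_depth, seed=config.seed + 2))
    opt_g = Adam(gen.parameters(), lr=config.lr_g)
    opt_d = Adam(disc.parameters(), lr=config.lr_d)
    opt_r = Adam(reg_net.parameters(), lr=config.lr_r)

    batcher = _Batcher(train_set, config.patch, rng, augment=config.augment)
    state = TrainState()
    best_state = None
    log_rows = []

    def validation_lg():
        if not val_set:
            return None
        vals = []
        with no_grad():
            for s in val_set:
                af = normalize_patch(s.af.transpose(2, 0, 1))[None]
                he = s.he_raw.transpose(2, 0, 1).astype(np.float32)[None]
                vs = gen(Tensor(af)).data
                if config.use_registration_net:
                    he_reg, _ = _predict_aligned_target(reg_net, vs, he, config)
                else:
                    he_reg = he
                if config.include_adversarial_in_val:
                    d_vs = disc(Tensor(vs)).data
                    cost, _ = _generator_cost(Tensor(vs), he_reg, d_vs, config)
                else:
                    cost, _ = _generator_cost(Tensor(vs), he_reg, None, config, with_adv=False)
                vals.append(float(cost.data if isinstance(cost, Tensor) else cost))
        return float(np.mean(vals))

    def check_finite(name, value):
        if not np.isfinite(value):
            raise RuntimeError(
                f"divergent loss: {name}={value} at cycle {state.cycle} "
                f"(t_D={state.t_d}); aborting"
            )

    for cycle in range(config.max_cycles):
        state.cycle = cycle
        ratio = update_ratio(state.t_d)
        state.ratio_history.append(ratio)

        # ---- generator block (R and D frozen; no gradients into either)
        g_losses = {}
        d_params = disc.parameters()
        for p in d_params:  # only the gradient w.r.t. D's input is needed here
            p.requires_grad = False
        for _ in range(ratio if not config.freeze_generator else 0):
            af, he = batcher.draw(config.batch_size)
            vs = gen(Tensor(af))
            if config.use_registration_net:
                he_reg, _ = _predict_aligned_target(reg_net, vs.data, he, config)
            else:
                he_reg = he
            d_vs = disc(vs)  # graph passes through D; only G parameters step
            cost, comps = _generator_cost(vs, he_reg, d_vs, config)
            check_finite("L_G", float(cost.data))
            gen.zero_grad()
            cost.backward()
            opt_g.step()
            state.g_iters += 1
            g_losses = {"lg": float(cost.data), **comps}
        for p in d_params:
            p.requires_grad = True

        # ---- discriminator step (real = raw target)
        af, he = batcher.draw(config.batch_size)
        with no_grad():
            vs_data = gen(Tensor(af)).data
        d_vs = disc(Tensor(vs_data))
        d_real = disc(Tensor(he))
        d_cost = L.discriminator_loss(d_vs, d_real).mean()
        check_finite("L_D", float(d_cost.data))
        disc.zero_grad()
        d_cost.backward()
        opt_d.step()
        state.t_d += 1

        # ---- registration step (G frozen; gradients flow through the warp)
        r_loss_val = None
        if config.use_registration_net:
            af, he = batcher.draw(config.batch_size)
            with no_grad():
                vs_data = gen(Tensor(af)).data
            raw_dvf = reg_net(Tensor(np.concatenate([vs_data, he], axis=1)))
            dvf = postprocess_dvf(raw_dvf)
            he_reg = warp_image(Tensor(he), dvf)
            ncc_val = L.ncc(Tensor(vs_data), he_reg, k=config.loss.ncc_window,
                            stride=config.loss.ncc_stride, eps=config.loss.ncc_eps)
            if config.loss.reg_tv_reduction == "mean":
                tv_term = L.tv(dvf) * (1.0 / dvf.data.size)
            else:
                tv_term = L.tv(dvf) * (1.0 / he.shape[0])  # summed TV per image
            r_cost = 1.0 - ncc_val + tv_term
            check_finite("L_R", float(r_cost.data))
            reg_net.zero_grad()
            r_cost.backward()
            opt_r.step()
            state.r_iters += 1
            r_loss_val = float(r_cost.data)

        row = {"cycle": cycle, "t_d": state.t_d, "ratio": ratio,
               "ld": float(d_cost.data), "lr_loss": r_loss_val, **g_losses}
        state.loss_history.append(row)
        log_rows.append(row)

        # ---- validation / model selection
        last = cycle == config.max_cycles - 1
        if val_set and (cycle % config.val_every == 0 or last):
            vlg = validation_lg()
            state.val_history.append({"cycle": cycle, "val_lg": vlg})
            if vlg < state.best_val_lg:
                state.best_val_lg = vlg
                state.best_cycle = cycle
                best_state = copy.deepcopy(gen.state_dict())

    if config.log_csv and log_rows:
        keys = sorted({k for r in log_rows for k in r})
        with open(config.log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(log_rows)

    return TrainResult(gen, disc, reg_net, state, config, best_state)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path, result: TrainResult, which: str = "best") -> None:
    """Single-file archive: generator config + parameters + training counters."""
    import json

    cfg = result.config
    state = (
        result.best_generator_state
        if which == "best" and result.best_generator_state is not None
        else result.generator.state_dict()
    )
    meta = {
        "format": 1,
        "g_base": cfg.g_base,
        "g_depth": cfg.g_depth,
        "seed": cfg.seed,
        "t_d": result.state.t_d,
        "g_iters": result.state.g_iters,
        "r_iters": result.state.r_iters,
        "best_val_lg": result.state.best_val_lg,
        "best_cycle": result.state.best_cycle,
    }
    arrays = {f"param/{k}": v for k, v in state.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_generator(path):
    """Rebuild the generator recorded in a checkpoint and load its parameters."""
    import json

    npz = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(npz["__meta__"]).decode())
    gen = build_generator(
        NetConfig(2, 3, meta["g_base"], meta["g_depth"], seed=meta["seed"])
    )
    gen.load_state_dict(
        {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
    )
    return gen, meta


# ------------------------------------------------------------------ inference
def infer(
    generator,
    af_image: np.ndarray,
    tile: int = 2048,
    overlap: int = 64,
) -> np.ndarray:
    """Tiled inference with linear feather blending; returns (H, W, 3) uint8.

    The autofluorescence image is standardised per channel over the whole
    image (matching the training normalisation statistics' role), tiled with
    the given overlap, and the tile predictions are blended with a separable
    linear ramp.  Deterministic.
    """
    arr = np.asarray(af_image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected (H, W, 2) autofluorescence image, got {arr.shape}")
    H, W = arr.shape[:2]
    chw = normalize_patch(arr.transpose(2, 0, 1))
    depth = getattr(generator, "depth", 2)
    mult = 2 ** depth

    def forward(patch_chw):
        ph, pw = patch_chw.shape[-2:]
        py, px = (-ph) % mult, (-pw) % mult
        padded = np.pad(patch_chw, ((0, 0), (0, py), (0, px)), mode="edge")
        with no_grad():
            out = generator(Tensor(padded[None])).data[0]
        return out[:, :ph, :pw]

    if H <= tile and W <= tile:
        out = forward(chw)
        return np.clip(np.round(out.transpose(1, 2, 0) * 255.0), 0, 255).astype(np.uint8)

    step = tile - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than tile")
    acc = np.zeros((3, H, W), dtype=np.float64)
    wacc = np.zeros((H, W), dtype=np.float64)

    def ramp(n):
        w = np.ones(n)
        r = min(overlap, n)
        if r > 0:
            edge = (np.arange(1, r + 1)) / (r + 1)
            w[:r] = np.minimum(w[:r], edge)
            w[-r:] = np.minimum(w[-r:], edge[::-1])
        return np.maximum(w, 1e-3)

    ys = sorted({min(y, max(H - tile, 0)) for y in range(0, H, step)})
    xs = sorted({min(x, max(W - tile, 0)) for x in range(0, W, step)})
    for y in ys:
        for x in xs:
            th, tw = min(tile, H - y), min(tile, W - x)
            patch = chw[:, y : y + th, x : x + tw]
            pred = forward(patch)
            wgt = np.outer(ramp(th), ramp(tw))
            acc[:, y : y + th, x : x + tw] += pred * wgt
            wacc[y : y + th, x : x + tw] += wgt
    out = acc / wacc
    return np.clip(np.round(out.transpose(1, 2, 0) * 255.0), 0, 255).astype(np.uint8)
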