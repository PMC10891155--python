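"""Schedule, normalization, augmentation, short training smoke and inference."""

import numpy as np
import pytest

from registain import phantom as P
from registain import trainer as TR
from registain.models import NetConfig, build_generator

rng = np.random.default_rng(31)


# ---------------------------------------------------------------- schedule
def test_update_ratio_printed_values():
    assert TR.update_ratio(0) == 12
    assert TR.update_ratio(4000) == 11
    assert TR.update_ratio(48000) == 3


def test_update_ratio_non_increasing_with_floor():
    values = [TR.update_ratio(t) for t in range(0, 100_001, 500)]
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert min(values) == 3
    with pytest.raises(ValueError):
        TR.update_ratio(-1)


# ----------------------------------------------------------- normalization
def test_normalize_patch_hand_example():
    out = TR.normalize_patch(np.array([[0.0, 2.0], [0.0, 2.0]]))
    assert np.allclose(out, [[-1.0, 1.0], [-1.0, 1.0]])


def test_normalize_patch_constant_maps_to_zero():
    assert not TR.normalize_patch(np.full((4, 4), 7.0)).any()


def test_normalize_patch_standardizes_each_channel():
    x = rng.random((3, 16, 16)) * np.array([1, 10, 100])[:, None, None]
    out = TR.normalize_patch(x)
    assert np.abs(out.mean(axis=(1, 2))).max() < 1e-6
    assert np.abs(out.std(axis=(1, 2)) - 1).max() < 1e-5


# ------------------------------------------------------------ augmentation
def test_augment_preserves_pixel_alignment():
    g = np.random.default_rng(0)
    img = rng.random((2, 8, 8))
    a, b = TR.augment_pair(img, img.copy(), g)
    assert np.array_equal(a, b)


def test_augment_seeded_reproducible():
    img, tgt = rng.random((2, 8, 8)), rng.random((3, 8, 8))
    a1 = TR.augment_pair(img, tgt, np.random.default_rng(42))
    a2 = TR.augment_pair(img, tgt, np.random.default_rng(42))
    assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])


def test_augment_empirical_frequencies():
    """Independent p=0.5 flips composed with a uniform 90-degree rotation
    induce the uniform distribution over the 8 dihedral images; observe it."""
    g = np.random.default_rng(7)
    probe = np.arange(9.0).reshape(1, 3, 3)  # asymmetric under all 8 images
    variants = []
    for flip in (False, True):
        base = probe[..., :, ::-1] if flip else probe
        for k in range(4):
            variants.append(np.rot90(base, k=k, axes=(-2, -1)))
    n = 10_000
    counts = np.zeros(8)
    for _ in range(n):
        a, _ = TR.augment_pair(probe, probe.copy(), g)
        matches = [i for i, v in enumerate(variants) if np.array_equal(v, a)]
        assert len(matches) == 1
        counts[matches[0]] += 1
    assert np.allclose(counts / n, 0.125, atol=0.02)


def test_augment_applies_flip_and_rotation_identically():
    img = rng.random((2, 6, 6))
    tgt = rng.random((3, 6, 6))
    for seed in range(12):
        g = np.random.default_rng(seed)
        a, b = TR.augment_pair(img, tgt, g)
        # the same spatial op must relate input->a and target->b
        found = False
        for lr in (False, True):
            for ud in (False, True):
                for k in range(4):
                    ta = img[..., :, ::-1] if lr else img
                    ta = ta[..., ::-1, :] if ud else ta
                    ta = np.rot90(ta, k=k, axes=(-2, -1))
                    if np.array_equal(ta, a):
                        tb = tgt[..., :, ::-1] if lr else tgt
                        tb = tb[..., ::-1, :] if ud else tb
                        tb = np.rot90(tb, k=k, axes=(-2, -1))
                        if np.array_equal(tb, b):
                            found = True
        assert found


# ------------------------------------------------------------ short train
@pytest.fixture(scope="module")
def toy_dataset():
    pairs = []
    for i in range(8):
        s = P.generate_phantom(P.PhantomSpec(height=64, width=64, n_nuclei=8,
                                             nucleus_radius_range=(3.0, 5.0),
                                             background_fraction=0.15, seed=700 + i))
        mis = P.MisalignmentSpec(mode="smooth_random", amplitude=4.0,
                                 smoothness_scale=16.0, seed=800 + i)
        pairs.append(P.to_paired(s, mis))
    return pairs


@pytest.fixture(scope="module")
def short_run(toy_dataset):
    cfg = TR.TrainConfig(batch_size=2, patch=64, max_cycles=4, seed=9, lr_r=3e-3,
                         g_base=8, g_depth=2, d_base=8, d_depth=2, r_base=8, r_depth=2,
                         val_every=2)
    return TR.train(toy_dataset, cfg), cfg


def test_schedule_conservation(short_run):
    result, cfg = short_run
    state = result.state
    assert state.t_d == cfg.max_cycles
    assert state.g_iters == sum(state.ratio_history)
    assert state.r_iters == cfg.max_cycles


def test_best_checkpoint_tracks_min_validation(short_run):
    result, _ = short_run
    vals = [v["val_lg"] for v in result.state.val_history]
    assert result.state.best_val_lg == min(vals)
    assert result.best_generator_state is not None


def test_ablation_skips_registration_updates(toy_dataset):
    cfg = TR.TrainConfig(batch_size=2, patch=64, max_cycles=2, seed=9,
                         g_base=8, g_depth=2, d_base=8, d_depth=2, r_base=8, r_depth=2,
                         use_registration_net=False, val_every=1)
    result = TR.train(toy_dataset, cfg)
    assert result.state.r_iters == 0


def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        TR.train([], TR.TrainConfig())


def test_training_reproducible_given_seed(toy_dataset):
    cfg = TR.TrainConfig(batch_size=2, patch=64, max_cycles=2, seed=13,
                         g_base=8, g_depth=2, d_base=8, d_depth=2, r_base=8, r_depth=2,
                         val_every=1)
    r1 = TR.train(toy_dataset, cfg)
    r2 = TR.train(toy_dataset, cfg)
    s1, s2 = r1.generator.state_dict(), r2.generator.state_dict()
    for k in s1:
        assert np.array_equal(s1[k], s2[k]), k


# -------------------------------------------------------------- inference
def test_infer_single_tile_equals_direct_forward():
    from registain.nn import Tensor, no_grad

    gen = build_generator(NetConfig(2, 3, 8, 2, seed=4))
    af = rng.random((64, 64, 2)).astype(np.float32)
    out = TR.infer(gen, af, tile=64)
    chw = TR.normalize_patch(af.transpose(2, 0, 1))
    with no_grad():
        direct = gen(Tensor(chw[None])).data[0]
    direct8 = np.clip(np.round(direct.transpose(1, 2, 0) * 255), 0, 255).astype(np.uint8)
    assert np.array_equal(out, direct8)


def test_infer_deterministic():
    gen = build_generator(NetConfig(2, 3, 8, 2, seed=4))
    af = rng.random((96, 96, 2)).astype(np.float32)
    a = TR.infer(gen, af, tile=64, overlap=32)
    b = TR.infer(gen, af, tile=64, overlap=32)
    assert np.array_equal(a, b)


def test_infer_tiled_close_to_untiled():
    gen = build_generator(NetConfig(2, 3, 8, 2, seed=4))
    af = rng.random((96, 96, 2)).astype(np.float32)
    tiled = TR.infer(gen, af, tile=64, overlap=32)
    full = TR.infer(gen, af, tile=96)
    diff = np.abs(tiled.astype(float) - full.astype(float)).mean() / 255.0
    assert diff < 1.0 / 255.0


def test_infer_rejects_wrong_channel_count():
    gen = build_generator(NetConfig(2, 3, 8, 2, seed=4))
    with pytest.raises(ValueError):
        TR.infer(gen, np.zeros((64, 64, 3), np.float32))


# ------------------------------------------------------------- checkpoints
def test_checkpoint_roundtrip(tmp_path, short_run):
    result, _ = short_run
    path = tmp_path / "ckpt.npz"
    TR.save_checkpoint(path, result, which="best")
    gen, meta = TR.load_generator(path)
    ref = result.restore_best()
    s1, s2 = gen.state_dict(), ref.state_dict()
    for k in s1:
        assert np.array_equal(s1[k], s2[k])
    assert meta["t_d"] == result.state.t_d
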