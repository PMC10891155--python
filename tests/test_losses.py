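"""Loss functions vs independent naive-loop oracles and hand-computed values."""

import numpy as np
import pytest

from registain import losses as L
from registain.nn import Tensor

rng = np.random.default_rng(1234)


# ----------------------------------------------------------------- oracles
def berhu_oracle(a, b, delta):
    total = 0.0
    for d in np.abs(np.asarray(a, float) - b).ravel():
        total += d if d <= delta else (d * d + delta * delta) / (2 * delta)
    return total


def tv_oracle(a):
    a = np.asarray(a, float)
    total = 0.0
    for c in a.reshape((-1,) + a.shape[-2:]):
        H, W = c.shape
        for m in range(H - 1):
            for n in range(W):
                total += abs(c[m + 1, n] - c[m, n])
        for m in range(H):
            for n in range(W - 1):
                total += abs(c[m, n + 1] - c[m, n])
    return total


def ncc_oracle(a, b, k, stride=1, eps=1e-6):
    vals = []
    H, W = a.shape
    for i in range(0, H - k + 1, stride):
        for j in range(0, W - k + 1, stride):
            wa, wb = a[i : i + k, j : j + k], b[i : i + k, j : j + k]
            ca, cb = wa - wa.mean(), wb - wb.mean()
            cov = (ca * cb).mean()
            va = max((ca ** 2).mean(), 0.0)
            vb = max((cb ** 2).mean(), 0.0)
            vals.append(cov / (np.sqrt(va * vb) + eps))
    return float(np.mean(vals))


# ------------------------------------------------------------------- berhu
def test_berhu_hand_values():
    assert L.berhu(np.array([[1.0]]), np.array([[1.0]]), 1.0) == 0.0
    assert L.berhu(np.array([[0.5]]), np.array([[0.0]]), 1.0) == 0.5
    assert L.berhu(np.array([[3.0]]), np.array([[0.0]]), 1.0) == pytest.approx(5.0)


def test_berhu_matches_loop_oracle_on_random_instances():
    for _ in range(20):
        a = rng.normal(size=(9, 11))
        b = rng.normal(size=(9, 11))
        delta = float(rng.uniform(0.2, 2.0))
        assert L.berhu(a, b, delta) == pytest.approx(berhu_oracle(a, b, delta), rel=1e-12)


def test_berhu_continuous_and_smooth_at_delta():
    delta = 0.7
    below = L.berhu(np.array([[delta - 1e-6]]), np.zeros((1, 1)), delta)
    above = L.berhu(np.array([[delta + 1e-6]]), np.zeros((1, 1)), delta)
    assert abs(above - below) < 1e-5
    # first derivative also continuous: slope 1 on both sides of the boundary
    d_below = (L.berhu(np.array([[delta - 1e-6]]), np.zeros((1, 1)), delta)
               - L.berhu(np.array([[delta - 2e-6]]), np.zeros((1, 1)), delta)) / 1e-6
    d_above = (L.berhu(np.array([[delta + 2e-6]]), np.zeros((1, 1)), delta)
               - L.berhu(np.array([[delta + 1e-6]]), np.zeros((1, 1)), delta)) / 1e-6
    assert d_below == pytest.approx(1.0, abs=1e-3)
    assert d_above == pytest.approx(1.0, abs=1e-3)


def test_berhu_nonnegative_zero_iff_equal():
    a = rng.normal(size=(6, 6))
    assert L.berhu(a, a.copy(), 0.5) == 0.0
    assert L.berhu(a, a + 0.01, 0.5) > 0.0


def test_berhu_rejects_bad_inputs():
    with pytest.raises(ValueError):
        L.berhu(np.zeros((2, 2)), np.zeros((3, 3)), 1.0)
    with pytest.raises(ValueError):
        L.berhu(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)


# ---------------------------------------------------------------------- tv
def test_tv_hand_values():
    assert L.tv(np.full((5, 5), 3.0)) == 0.0
    assert L.tv(np.array([[0.0, 1.0], [0.0, 1.0]])) == 2.0
    # telescoping ramp: single row 0..L-1
    assert L.tv(np.arange(8.0)[None, :]) == 7.0


def test_tv_matches_loop_oracle_multichannel():
    a = rng.normal(size=(3, 7, 9))
    assert L.tv(a) == pytest.approx(tv_oracle(a), rel=1e-12)


# --------------------------------------------------------------------- ncc
def test_ncc_self_and_anticorrelation():
    a = rng.random((40, 40))
    assert L.ncc(a, a, k=20) == pytest.approx(1.0, abs=1e-4)
    assert L.ncc(a, -a + 7.0, k=20) == pytest.approx(-1.0, abs=1e-4)


@pytest.mark.parametrize("k,stride", [(20, 1), (20, 20), (7, 3)])
def test_ncc_matches_loop_oracle(k, stride):
    a = rng.random((40, 40))
    b = rng.random((40, 40))
    assert L.ncc(a, b, k=k, stride=stride) == pytest.approx(
        ncc_oracle(a, b, k, stride), abs=1e-9
    )


def test_ncc_affine_intensity_invariance():
    a = rng.random((30, 30))
    b = rng.random((30, 30))
    base = L.ncc(a, b, k=10)
    assert L.ncc(a, 3.0 * b + 2.0, k=10) == pytest.approx(base, abs=1e-4)
    assert L.ncc(0.5 * a - 1.0, b, k=10) == pytest.approx(base, abs=1e-4)


def test_ncc_constant_window_contributes_zero():
    a = np.zeros((8, 8))
    b = rng.random((8, 8))
    assert L.ncc(a, b, k=8) == pytest.approx(0.0, abs=1e-6)


def test_ncc_rejects_small_images():
    with pytest.raises(ValueError):
        L.ncc(np.zeros((10, 10)), np.zeros((10, 10)), k=20)


def test_ncc_strided_close_to_dense_on_stationary_texture(textured_pair):
    a, b = textured_pair
    dense = L.ncc(a, b, k=20, stride=1)
    strided = L.ncc(a, b, k=20, stride=20)
    assert abs(dense - strided) < 0.25  # sampling tolerance on a smooth texture


# -------------------------------------------------------------- composites
def test_generator_loss_components():
    vs = rng.random((3, 32, 32))
    hs = rng.random((3, 32, 32))
    cfg = L.LossConfig()
    total, comps = L.generator_loss(vs, hs, 0.3, cfg)
    delta = cfg.delta_frac * hs.std()
    expected = (
        berhu_oracle(vs, hs, delta)
        + cfg.alpha * tv_oracle(vs)
        + cfg.beta * (1 - 0.3) ** 2
    )
    assert total == pytest.approx(expected, rel=1e-9)
    assert comps["berhu"] + cfg.alpha * comps["tv"] + comps["adv"] == pytest.approx(total, rel=1e-9)


def test_generator_loss_perfect_output_leaves_only_tv():
    vs = rng.random((3, 16, 16))
    total, comps = L.generator_loss(vs, vs.copy(), 1.0)
    assert comps["berhu"] == 0.0 and comps["adv"] == 0.0
    assert total == pytest.approx(0.02 * L.tv(vs), rel=1e-9)


def test_generator_loss_adversarial_floor():
    z = np.zeros((3, 8, 8))
    total, _ = L.generator_loss(z, z, 0.0)
    assert total == pytest.approx(50.0)


def test_discriminator_loss_values():
    assert L.discriminator_loss(0.0, 1.0) == 0.0
    assert L.discriminator_loss(0.5, 0.5) == 0.5
    assert L.discriminator_loss(1.0, 0.0) == 2.0
    with pytest.raises(ValueError):
        L.discriminator_loss(1.5, 0.5)


def test_registration_loss_composition():
    vs = rng.random((3, 24, 24))
    dvf = rng.normal(size=(2, 24, 24))
    cfg = L.LossConfig(ncc_window=12)
    val = L.registration_loss(vs, vs.copy(), dvf, cfg)
    assert val == pytest.approx(1.0 - L.ncc(vs, vs, k=12) + L.tv(dvf), rel=1e-9)
    # perfectly matched images with a constant field give ~0
    const = np.full((2, 24, 24), 2.0)
    assert L.registration_loss(vs, vs.copy(), const, cfg) == pytest.approx(0.0, abs=1e-4)


def test_losses_equivariant_under_shared_flips():
    a = rng.random((3, 20, 20))
    b = rng.random((3, 20, 20))
    for op in (lambda x: x[..., ::-1, :], lambda x: x[..., :, ::-1],
               lambda x: np.rot90(x, axes=(-2, -1))):
        assert L.berhu(op(a), op(b), 0.5) == pytest.approx(L.berhu(a, b, 0.5), rel=1e-10)
        assert L.tv(op(a)) == pytest.approx(L.tv(a), rel=1e-10)
        assert L.ncc(op(a), op(b), k=10) == pytest.approx(L.ncc(a, b, k=10), abs=1e-10)


def test_losses_accept_tensors_and_match_numpy():
    a = rng.random((3, 24, 24)).astype(np.float64)
    b = rng.random((3, 24, 24)).astype(np.float64)
    assert float(L.berhu(Tensor(a), Tensor(b), 0.4).data) == pytest.approx(
        L.berhu(a, b, 0.4), rel=1e-9
    )
    assert float(L.tv(Tensor(a)).data) == pytest.approx(L.tv(a), rel=1e-9)
    assert float(L.ncc(Tensor(a), Tensor(b), k=12).data) == pytest.approx(
        L.ncc(a, b, k=12), abs=1e-6
    )
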