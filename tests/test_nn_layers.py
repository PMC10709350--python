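"""Layer mechanics: gradients vs finite differences, special-kernel identities,
parameter-count sharing, and input validation."""

import numpy as np
import pytest

from flairmatch.groups import ORDER
from flairmatch.nn import (
    SGD,
    AvgPool3d,
    Conv3d,
    CropPad,
    Dense,
    Dropout,
    GlobalAvgPool,
    GroupConv3d,
    LeakyReLU,
    LiftingConv3d,
    MaxPool3d,
    OrientationPool,
    ReLU,
    Sequential,
    Upsample3d,
)

RNG = np.random.default_rng(11)


def _numeric_vs_analytic(layer, x, check_params=True, eps=1e-3, tol=2e-2):
    """Compare backward() against central finite differences at random coords."""
    x = x.astype(np.float32)
    y = layer.forward(x)
    gy = RNG.normal(size=y.shape).astype(np.float32)
    for p in layer.parameters().values():
        p.grad[...] = 0.0
    gx = layer.backward(gy)
    assert gx.shape == x.shape

    i = tuple(RNG.integers(0, s) for s in x.shape)
    xp, xm = x.copy(), x.copy()
    xp[i] += eps
    xm[i] -= eps
    num = (np.sum(layer.forward(xp) * gy) - np.sum(layer.forward(xm) * gy)) / (2 * eps)
    assert abs(num - gx[i]) <= tol * max(1.0, abs(num))

    if check_params:
        for p in layer.parameters().values():
            j = tuple(RNG.integers(0, s) for s in p.value.shape)
            orig = p.value[j]
            p.value[j] = orig + eps
            up = np.sum(layer.forward(x) * gy)
            p.value[j] = orig - eps
            down = np.sum(layer.forward(x) * gy)
            p.value[j] = orig
            num = (up - down) / (2 * eps)
            assert abs(num - p.grad[j]) <= tol * max(1.0, abs(num))


@pytest.mark.parametrize("layer_fn,shape,params", [
    (lambda: Conv3d(2, 3, (3, 3, 3), rng=RNG), (2, 2, 6, 6, 4), True),
    (lambda: Conv3d(2, 2, (1, 1, 1), rng=RNG), (2, 2, 4, 4, 2), True),
    (lambda: LiftingConv3d(2, 2, (3, 3, 3), rng=RNG), (2, 2, 6, 6, 4), True),
    (lambda: GroupConv3d(2, 2, (3, 3, 3), rng=RNG), (2, 32, 6, 6, 4), True),
    (lambda: MaxPool3d(), (2, 2, 6, 6, 4), False),
    (lambda: AvgPool3d((2, 2, 2)), (2, 2, 6, 6, 4), False),
    (lambda: OrientationPool("max"), (2, 32, 4, 4, 2), False),
    (lambda: OrientationPool("mean"), (2, 32, 4, 4, 2), False),
    (lambda: GlobalAvgPool(), (2, 3, 4, 4, 2), False),
    (lambda: Dense(5, 3, rng=RNG), (4, 5), False),
    (lambda: Upsample3d(), (1, 2, 3, 3, 2), False),
    (lambda: CropPad((5, 3, 3)), (1, 2, 4, 4, 2), False),
    (lambda: ReLU(), (2, 3, 4, 4, 2), False),
    (lambda: LeakyReLU(0.1), (2, 3, 4, 4, 2), False),
], ids=["conv", "conv1x1", "lifting", "gconv", "maxpool", "avgpool", "opool-max",
        "opool-mean", "gap", "dense", "upsample", "croppad", "relu", "leaky"])
def test_backward_matches_finite_differences(layer_fn, shape, params):
    _numeric_vs_analytic(layer_fn(), RNG.normal(size=shape), check_params=params)


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        Conv3d(1, 1, (2, 2, 2))
    with pytest.raises(ValueError, match="odd"):
        LiftingConv3d(1, 1, (2, 2, 3))


def test_rectangular_inplane_kernel_rejected_for_equivariant_layers():
    with pytest.raises(ValueError, match="square"):
        LiftingConv3d(1, 1, (3, 1, 3))
    with pytest.raises(ValueError, match="square"):
        GroupConv3d(1, 1, (1, 3, 3))
    # plain conv has no such constraint
    Conv3d(1, 1, (3, 1, 3))


def test_lifting_pointwise_kernel_gives_identical_orientations(rng):
    """A 1x1x1 kernel is a fixed point of all 16 transforms, so every
    orientation channel must be identical."""
    lift = LiftingConv3d(2, 3, (1, 1, 1), rng=rng)
    x = rng.normal(size=(1, 2, 4, 4, 2)).astype(np.float32)
    y = lift.forward(x).reshape(1, 3, ORDER, 4, 4, 2)
    for o in range(1, ORDER):
        np.testing.assert_array_equal(y[:, :, o], y[:, :, 0])


def test_lifting_output_has_16_orientations(rng):
    lift = LiftingConv3d(2, 5, (3, 3, 3), rng=rng)
    y = lift.forward(rng.normal(size=(1, 2, 4, 4, 2)).astype(np.float32))
    assert y.shape[1] == 5 * ORDER


def test_group_conv_delta_identity_kernel_is_identity(rng):
    """Delta kernel at the center, only the identity-orientation tap nonzero,
    unit weight: output equals input."""
    gc = GroupConv3d(2, 2, (3, 3, 3), bias=False, rng=rng)
    w = np.zeros_like(gc.w.value)
    for c in range(2):
        w[c, c, 0, 1, 1, 1] = 1.0  # orientation 0 = identity
    gc.w.value[...] = w
    x = rng.normal(size=(1, 32, 4, 4, 2)).astype(np.float32)
    np.testing.assert_allclose(gc.forward(x), x, atol=1e-6)


def test_group_conv_rejects_wrong_channel_count(rng):
    gc = GroupConv3d(2, 2, (3, 3, 3), rng=rng)
    with pytest.raises(ValueError, match="channels"):
        gc.forward(rng.normal(size=(1, 31, 4, 4, 2)).astype(np.float32))


def test_parameter_counts_match_plain_convolution():
    """G-layer kernels are shared across orientations, not replicated: the
    base weight count equals a plain conv on the unfolded channels."""
    def n_weights(layer):
        return layer.w.value.size

    assert n_weights(LiftingConv3d(2, 8, (3, 3, 3))) == n_weights(Conv3d(2, 8, (3, 3, 3)))
    assert (n_weights(GroupConv3d(4, 8, (3, 3, 3)))
            == n_weights(Conv3d(4 * ORDER, 8, (3, 3, 3))))
    # bias is shared across orientations too
    assert LiftingConv3d(2, 8, (3, 3, 3)).b.value.size == 8
    assert GroupConv3d(4, 8, (3, 3, 3)).b.value.size == 8


def test_orientation_pool_permutation_invariance(rng):
    """Max/mean over the whole orientation axis cannot see a permutation."""
    x = rng.normal(size=(2, 2 * ORDER, 3, 3, 2)).astype(np.float32)
    perm = rng.permutation(ORDER)
    xp = x.reshape(2, 2, ORDER, 3, 3, 2)[:, :, perm].reshape(x.shape)
    for mode in ("max", "mean"):
        pool = OrientationPool(mode)
        np.testing.assert_allclose(pool.forward(xp), pool.forward(x), atol=1e-7)


def test_orientation_pool_constant_input(rng):
    pool = OrientationPool("max")
    x = np.full((1, ORDER, 3, 3, 2), 2.5, dtype=np.float32)
    np.testing.assert_array_equal(pool.forward(x), np.full((1, 1, 3, 3, 2), 2.5))


def test_maxpool_halves_and_crops_odd_dims(rng):
    x = rng.normal(size=(1, 1, 5, 4, 3)).astype(np.float32)
    y = MaxPool3d().forward(x)
    assert y.shape == (1, 1, 2, 2, 1)


def test_dropout_requires_rng_in_training():
    d = Dropout(0.5)
    x = np.ones((2, 3), dtype=np.float32)
    np.testing.assert_array_equal(d.forward(x, train=False), x)
    with pytest.raises(RuntimeError):
        d.forward(x, train=True)
    d.rng = np.random.default_rng(0)
    out = d.forward(x, train=True)
    assert set(np.unique(out)) <= {0.0, 2.0}


def test_sequential_parameter_namespace(rng):
    seq = Sequential([
        ("stage1", Sequential([("conv", Conv3d(1, 2, (1, 1, 1), rng=rng))])),
        ("fc", Dense(2, 1, rng=rng)),
    ])
    assert set(seq.parameters()) == {"stage1.conv.w", "stage1.conv.b", "fc.w", "fc.b"}


def test_sgd_nesterov_matches_reference_update():
    """One-parameter quadratic: compare against the textbook recursion."""
    from flairmatch.nn.layers import Parameter

    p = Parameter(np.array([1.0], dtype=np.float32))
    opt = SGD({"p": p}, lr=0.1, momentum=0.9, nesterov=True)
    w, v = 1.0, 0.0
    for _ in range(5):
        g = 2.0 * p.value[0]  # d/dw of w^2
        p.grad[...] = g
        opt.step()
        g_ref = 2.0 * w
        v = 0.9 * v + g_ref
        w -= 0.1 * (g_ref + 0.9 * v)
        assert np.isclose(p.value[0], w, atol=1e-6)
        opt.zero_grad()
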