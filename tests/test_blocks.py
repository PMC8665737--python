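"""Composite blocks: shape contracts, branch wiring, identity
initialization and its exact-identity property at epsilon = 0."""

import numpy as np
import pytest

from squigglecall import nn
from squigglecall.blocks import (
    CBlock,
    IdentityInitSpec,
    KSepConv1d,
    ResidualBlockBonito,
    ResidualBlockCompressed,
    glorot_init,
    identity_init,
    nearest_odd,
)
from squigglecall.conv_ops import swish


def _identity_bns(module):
    """Zero-epsilon identity batch norms so linear paths stay exact."""
    for name, val in vars(module).items():
        if isinstance(val, nn.BatchNorm1d):
            val.epsilon = 0.0
        elif isinstance(val, nn.Module):
            _identity_bns(val)
        elif isinstance(val, (list, tuple)):
            for item in val:
                if isinstance(item, nn.Module):
                    _identity_bns(item)


def test_nearest_odd():
    assert [nearest_odd(v) for v in (0.2, 1, 2, 3, 4.9, 5, 6)] == [1, 1, 3, 3, 5, 5, 7]


def test_c_block_is_activation_of_bn_of_conv(rng):
    blk = CBlock(1, 1, 1, conv_kind="full", activation=True)
    blk.conv.W.data[...] = 1.0
    _identity_bns(blk)
    x = np.array([[-1.0], [0.0], [2.0]])
    got = blk.forward(x[None])[0]
    np.testing.assert_allclose(got[:, 0], swish([-1.0, 0.0, 2.0]), atol=1e-12)

    no_act = CBlock(1, 1, 1, conv_kind="full", activation=False)
    no_act.conv.W.data[...] = 1.0
    _identity_bns(no_act)
    np.testing.assert_allclose(no_act.forward(x[None])[0], x, atol=1e-12)


def test_c_block_stride_reduces_length():
    blk = CBlock(1, 4, 9, stride=3)
    assert blk.forward(np.zeros((1, 12, 1))).shape == (1, 4, 4)


def test_bonito_block_zero_weights_gives_swish_zero(rng):
    blk = ResidualBlockBonito(3, 5, r=3)
    _identity_bns(blk)
    out = blk.forward(rng.normal(size=(1, 10, 3)))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)  # swish(0) = 0


def test_bonito_block_skip_path_isolation(rng):
    blk = ResidualBlockBonito(3, 5, r=3)
    glorot_init(blk, np.random.default_rng(0))
    _identity_bns(blk)
    # zero the main branch: its final sub-block conv and bias
    last = blk.sub[-1]
    last.conv.dw.W.data[...] = 0.0
    last.conv.dw.B.data[...] = 0.0
    last.conv.pw.W.data[...] = 0.0
    last.conv.pw.B.data[...] = 0.0
    x = rng.normal(size=(1, 8, 3))
    got = blk.forward(x)
    skip = blk.skip_bn.forward(blk.skip_pw.forward(x))
    np.testing.assert_allclose(got, skip * (1 / (1 + np.exp(-skip))), atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_residual_blocks_preserve_shape(seed):
    rng = np.random.default_rng(seed)
    c = int(rng.integers(2, 6))
    t = int(rng.integers(12, 40))
    x = rng.normal(size=(1, t, c))
    bonito = ResidualBlockBonito(c, 5, r=int(rng.integers(1, 4)))
    glorot_init(bonito, rng)
    assert bonito.forward(x).shape == (1, t, c)
    comp = ResidualBlockCompressed(c, 9, r=int(rng.integers(3, 6)), k=3, x=3, y=2)
    glorot_init(comp, rng)
    assert comp.forward(x).shape == (1, t, c)


def test_compressed_block_intermediate_shape():
    blk = ResidualBlockCompressed(4, 15, r=4, k=3, x=3, y=2)
    glorot_init(blk, np.random.default_rng(1))
    x = np.zeros((1, 30, 4))
    z = blk.compress.forward(x)
    assert z.shape == (1, 10, 8)  # (T/x, C*y)
    assert blk.forward(x).shape == (1, 30, 4)


def test_compressed_block_flop_increase_ratio():
    """Pointwise work per original sample in the compressed domain grows
    by y^2/x (= 4/3 at ratio 3:2) relative to the uncompressed block."""
    from squigglecall.conv_ops import count_params_and_flops

    c, t, x, y = 64, 300, 3, 2
    base = count_params_and_flops("pointwise", cin=c, cout=c, t=t)["flops"]
    compressed = count_params_and_flops(
        "pointwise", cin=c * y, cout=c * y, t=t // x
    )["flops"]
    assert compressed / base == pytest.approx(y**2 / x)


# -- identity initialization ---------------------------------------------

def test_identity_init_ksep_is_exact_identity_at_eps0(rng):
    conv = KSepConv1d(4, 4, depth=9, k=3)
    identity_init(conv, IdentityInitSpec(epsilon=0.0), np.random.default_rng(0))
    x = rng.normal(size=(1, 20, 4))
    np.testing.assert_array_equal(conv.forward(x), x)


def test_identity_init_sub_block_identity_through_bn(rng):
    blk = CBlock(4, 4, 9, conv_kind="k_blueprint_separable", k=3, activation=False)
    identity_init(blk, IdentityInitSpec(epsilon=0.0), np.random.default_rng(0))
    _identity_bns(blk)
    x = rng.normal(size=(1, 20, 4))
    np.testing.assert_allclose(blk.forward(x), x, atol=1e-12)


def test_identity_init_epsilon_structure():
    conv = KSepConv1d(6, 6, depth=9, k=3)
    identity_init(conv, IdentityInitSpec(epsilon=0.02), np.random.default_rng(3))
    w = conv.fat.W.data
    center = 3 // 2
    for d in range(3):
        if d != center:
            assert not w[:, d, :].any()  # off-center slices exactly zero
    assert np.max(np.abs(w[:, center, :] - np.eye(6))) <= 0.02
    dw = conv.dw.W.data
    assert dw[dw.shape[0] // 2].tolist() == [1.0] * 6
    assert not np.delete(dw, dw.shape[0] // 2, axis=0).any()


def test_identity_init_non_square_leading_diagonal():
    conv = KSepConv1d(4, 6, depth=3, k=3)
    identity_init(conv, IdentityInitSpec(epsilon=0.0), np.random.default_rng(0))
    w = conv.fat.W.data[:, 1, :]
    np.testing.assert_array_equal(w[:4, :4], np.eye(4))
    assert not w[4:].any()


def test_identity_init_whole_main_branch_x1_y1(rng):
    """With ε = 0, zero-epsilon BNs, x = y = 1 and the compression pair
    set to an exact inverse (identity) pair, the whole compressed main
    branch reproduces its input; with the skip zeroed the block output
    is swish(x)."""
    blk = ResidualBlockCompressed(3, 9, r=4, k=3, x=1, y=1,
                                  inner_activation=False)
    identity_init(blk, IdentityInitSpec(epsilon=0.0), np.random.default_rng(0))
    _identity_bns(blk)
    blk.compress.W.data[...] = np.eye(3)[:, None, :]
    blk.compress.B.data[...] = 0.0
    blk.decompress.W.data[...] = np.eye(3)[:, None, :]
    blk.decompress.B.data[...] = 0.0
    blk.skip_pw.W.data[...] = 0.0
    blk.skip_pw.B.data[...] = 0.0
    x = rng.normal(size=(1, 18, 3))

    main = blk.compress.forward(x)
    for sub in blk.inner:
        main = sub.forward(main)
    main = blk.pre_bn.forward(blk.pre_dw.forward(main))
    main = blk.post_bn.forward(blk.decompress.forward(main))
    np.testing.assert_allclose(main, x, atol=1e-12)

    out = blk.forward(x)
    np.testing.assert_allclose(out, x * (1 / (1 + np.exp(-x))), atol=1e-12)


def test_glorot_fallback_bound():
    blk = ResidualBlockBonito(8, 5, r=3)
    glorot_init(blk, np.random.default_rng(4))
    bound = IdentityInitSpec.glorot_bound(8, 8)
    for name, p in blk.named_parameters():
        if name.endswith(".W"):
            assert np.max(np.abs(p.data)) <= bound


def test_init_reproducible():
    a = ResidualBlockCompressed(4, 9, r=4)
    b = ResidualBlockCompressed(4, 9, r=4)
    identity_init(a, IdentityInitSpec(), np.random.default_rng(11))
    identity_init(b, IdentityInitSpec(), np.random.default_rng(11))
    for (na, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
        np.testing.assert_array_equal(pa.data, pb.data), na


def test_compressed_block_rejects_small_r():
    with pytest.raises(ValueError, match="R >= 3"):
        ResidualBlockCompressed(4, 9, r=2)
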