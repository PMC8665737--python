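"""Every convolution factorization against brute-force evaluation of its
defining sum, plus the closed-form parameter/flop accounting."""

import warnings

import numpy as np
import pytest

from squigglecall import conv_ops as co


# -- independent brute-force oracles (triple loops, no vectorization) -----

def bf_full_conv(x, w, b):
    t, cin = x.shape
    cout, d, _ = w.shape
    pad = d // 2
    xp = np.pad(x, ((pad, pad), (0, 0)))
    out = np.zeros((t, cout))
    for tt in range(t):
        for j in range(cout):
            acc = b[j]
            for dd in range(d):
                for i in range(cin):
                    acc += xp[tt + dd, i] * w[j, dd, i]
            out[tt, j] = acc
    return out


def bf_depthwise(x, w, b, dilation):
    t, c = x.shape
    depth = w.shape[0]
    pad = (depth // 2) * dilation
    xp = np.pad(x, ((pad, pad), (0, 0)))
    out = np.zeros((t, c))
    for tt in range(t):
        for j in range(c):
            acc = b[j]
            for dd in range(depth):
                acc += xp[tt + dd * dilation, j] * w[dd, j]
            out[tt, j] = acc
    return out


def bf_compress(x, w, b, stride):
    t, c = x.shape
    cy = w.shape[0]
    rem = (-t) % stride
    if rem:
        x = np.pad(x, ((0, rem), (0, 0)))
    ts = x.shape[0] // stride
    out = np.zeros((ts, cy))
    for s in range(ts):
        for j in range(cy):
            acc = b[j]
            for dd in range(stride):
                for i in range(c):
                    acc += x[s * stride + dd, i] * w[j, dd, i]
            out[s, j] = acc
    return out


def bf_decompress(z, w, b, stride):
    ts, cy = z.shape
    c = w.shape[0]
    out = np.zeros((ts * stride, c))
    for s in range(ts):
        for dd in range(stride):
            for j in range(c):
                acc = b[j]
                for i in range(cy):
                    acc += z[s, i] * w[j, dd, i]
                out[s * stride + dd, j] = acc
    return out


# -- worked examples ------------------------------------------------------

def test_full_conv_identity_and_bias():
    p = co.FullConvParams(np.ones((1, 1, 1)), np.zeros(1))
    np.testing.assert_allclose(
        co.full_conv([5.0, -2.0, 3.0], p)[:, 0], [5, -2, 3]
    )
    zero = co.FullConvParams(np.zeros((1, 3, 1)), np.array([7.0]))
    np.testing.assert_allclose(co.full_conv(np.zeros(4), zero)[:, 0], [7, 7, 7, 7])


def test_full_conv_padded_sum():
    p = co.FullConvParams(np.ones((1, 3, 1)), np.zeros(1))
    np.testing.assert_allclose(co.full_conv([1.0, 2.0, 3.0], p)[:, 0], [3, 6, 5])


def test_full_conv_rejects_even_depth_and_channel_mismatch():
    with pytest.raises(ValueError, match="odd"):
        co.FullConvParams(np.ones((1, 2, 1)), np.zeros(1))
    p = co.FullConvParams(np.ones((2, 3, 3)), np.zeros(2))
    with pytest.raises(ValueError, match="channels"):
        co.full_conv(np.ones((5, 2)), p)


def test_depthwise_identity_and_dilated_example():
    ident = co.DepthwiseParams(np.ones((1, 1)), np.zeros(1))
    np.testing.assert_allclose(
        co.depthwise_conv([1.0, 4.0], ident)[:, 0], [1, 4]
    )
    p = co.DepthwiseParams(np.ones((3, 1)), np.zeros(1), dilation=2)
    np.testing.assert_allclose(
        co.depthwise_conv([1.0, 2.0, 3.0, 4.0, 5.0], p)[:, 0], [4, 6, 9, 6, 8]
    )


def test_depthwise_equals_diagonal_full_conv(rng):
    x = rng.normal(size=(16, 4))
    w = rng.normal(size=(3, 4))
    b = rng.normal(size=4)
    dp = co.DepthwiseParams(w, b, dilation=1)
    wf = np.zeros((4, 3, 4))
    for j in range(4):
        wf[j, :, j] = w[:, j]
    fp = co.FullConvParams(wf, b)
    np.testing.assert_allclose(
        co.depthwise_conv(x, dp), co.full_conv(x, fp), atol=1e-9
    )


def test_pointwise_examples_and_full_conv_agreement(rng):
    ident = co.PointwiseParams(np.eye(3), np.zeros(3))
    x = rng.normal(size=(6, 3))
    np.testing.assert_allclose(co.pointwise_conv(x, ident), x)
    p = co.PointwiseParams(np.array([[1.0, 1.0]]), np.zeros(1))
    np.testing.assert_allclose(
        co.pointwise_conv(np.array([[3.0, 4.0]]), p), [[7.0]]
    )
    w = rng.normal(size=(5, 3))
    b = rng.normal(size=5)
    x = rng.normal(size=(8, 3))
    pw = co.pointwise_conv(x, co.PointwiseParams(w, b))
    full = co.full_conv(x, co.FullConvParams(w[:, None, :], b))
    np.testing.assert_allclose(pw, full, atol=1e-9)


def test_separable_is_the_composition(rng):
    x = rng.normal(size=(10, 3))
    dp = co.DepthwiseParams(rng.normal(size=(5, 3)), rng.normal(size=3))
    pp = co.PointwiseParams(rng.normal(size=(4, 3)), rng.normal(size=4))
    np.testing.assert_array_equal(
        co.separable_conv(x, dp, pp),
        co.pointwise_conv(co.depthwise_conv(x, dp), pp),
    )
    with pytest.raises(ValueError, match="undilated"):
        co.separable_conv(x, co.DepthwiseParams(np.ones((3, 3)), np.zeros(3), 2), pp)


@pytest.mark.parametrize("trial", range(10))
def test_factorized_ops_match_brute_force(trial):
    rng = np.random.default_rng(1000 + trial)
    t = int(rng.integers(4, 32))
    c = int(rng.integers(1, 8))
    cout = int(rng.integers(1, 8))
    d = int(rng.choice([1, 3, 5, 7]))
    dil = int(rng.integers(1, 4))
    x = rng.normal(size=(t, c))

    w, b = rng.normal(size=(cout, d, c)), rng.normal(size=cout)
    np.testing.assert_allclose(
        co.full_conv(x, co.FullConvParams(w, b)), bf_full_conv(x, w, b), atol=1e-9
    )
    wd, bd = rng.normal(size=(d, c)), rng.normal(size=c)
    np.testing.assert_allclose(
        co.depthwise_conv(x, co.DepthwiseParams(wd, bd, dil)),
        bf_depthwise(x, wd, bd, dil), atol=1e-9,
    )
    stride = int(rng.integers(1, 5))
    y = int(rng.integers(1, 4))
    wc, bc = rng.normal(size=(c * y, stride, c)), rng.normal(size=c * y)
    np.testing.assert_allclose(
        co.strided_compress_conv(x, wc, bc, stride),
        bf_compress(x, wc, bc, stride), atol=1e-9,
    )
    ts = int(rng.integers(1, 8))
    z = rng.normal(size=(ts, c * y))
    wt, bt = rng.normal(size=(c, stride, c * y)), rng.normal(size=c)
    np.testing.assert_allclose(
        co.transposed_decompress_conv(z, wt, bt, stride),
        bf_decompress(z, wt, bt, stride), atol=1e-9,
    )


@pytest.mark.parametrize("trial", range(8))
def test_k_separable_matches_two_stage_brute_force(trial):
    rng = np.random.default_rng(2000 + trial)
    k = int(rng.choice([1, 3, 5]))
    m = int(rng.choice([1, 3, 5]))  # depthwise depth D/k
    c, cout = int(rng.integers(1, 6)), int(rng.integers(1, 6))
    x = rng.normal(size=(int(rng.integers(8, 32)), c))
    fp = co.FatPointwiseParams(rng.normal(size=(cout, k, c)), rng.normal(size=cout))
    dp = co.DepthwiseParams(rng.normal(size=(m, cout)), rng.normal(size=cout), k)
    got = co.k_blueprint_separable_conv(x, fp, dp)
    z = bf_full_conv(x, fp.W, fp.B)
    want = bf_depthwise(z, dp.W, dp.B, k)
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_k1_reduces_to_blueprint_separable(rng):
    x = rng.normal(size=(32, 8))
    fp = co.FatPointwiseParams(rng.normal(size=(8, 1, 8)), rng.normal(size=8))
    dp = co.DepthwiseParams(rng.normal(size=(5, 8)), rng.normal(size=8), dilation=1)
    got = co.k_blueprint_separable_conv(x, fp, dp)
    blueprint = co.depthwise_conv(
        co.pointwise_conv(x, co.PointwiseParams(fp.W[:, 0, :], fp.B)), dp
    )
    np.testing.assert_allclose(got, blueprint, atol=1e-12)


def test_k_separable_receptive_field(rng):
    """Output at time t is exactly invariant to perturbations beyond the
    receptive radius (D−1)/2 and sensitive within ⌊(D−k)/2⌋."""
    k, m = 3, 5  # D = 15
    d = k * m
    c = 2
    t_len = 64
    fp = co.FatPointwiseParams(rng.normal(size=(c, k, c)), rng.normal(size=c))
    dp = co.DepthwiseParams(rng.normal(size=(m, c)), rng.normal(size=c), k)
    x = rng.normal(size=(t_len, c))
    base = co.k_blueprint_separable_conv(x, fp, dp)
    t0 = t_len // 2
    radius = (d - 1) // 2
    for dist, expect_change in [(radius + 1, False), (radius + 5, False),
                                ((d - k) // 2, True), (1, True), (0, True)]:
        x2 = x.copy()
        x2[t0 + dist] += 10.0
        out = co.k_blueprint_separable_conv(x2, fp, dp)
        changed = not np.array_equal(out[t0], base[t0])
        assert changed == expect_change, f"distance {dist}"


def test_k_separable_contract_errors(rng):
    x = rng.normal(size=(8, 2))
    fp = co.FatPointwiseParams(rng.normal(size=(2, 3, 2)), np.zeros(2))
    with pytest.raises(ValueError, match="dilation"):
        co.k_blueprint_separable_conv(
            x, fp, co.DepthwiseParams(np.ones((5, 2)), np.zeros(2), dilation=1)
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        co.k_blueprint_separable_conv(
            x, fp, co.DepthwiseParams(np.ones((2, 2)), np.zeros(2), dilation=3)
        )
    assert any("asymmetric" in str(w.message) for w in caught)


def test_compress_decompress_examples():
    w = np.ones((1, 3, 1))
    out = co.strided_compress_conv(np.arange(1.0, 7.0), w, np.zeros(1), 3)
    np.testing.assert_allclose(out[:, 0], [6, 15])
    # x=3, y=2 shape contract
    out = co.strided_compress_conv(
        np.ones((12, 4)), np.zeros((8, 3, 4)), np.zeros(8), 3
    )
    assert out.shape == (4, 8)
    # x=1, y=1, identity weights
    x = np.random.default_rng(0).normal(size=(5, 3))
    out = co.strided_compress_conv(x, np.eye(3)[:, None, :], np.zeros(3), 1)
    np.testing.assert_allclose(out, x)

    # decompression spreads each compressed sample over its x slots
    out = co.transposed_decompress_conv(
        np.array([[2.0], [5.0]]), np.ones((1, 3, 1)), np.zeros(1), 3
    )
    np.testing.assert_allclose(out[:, 0], [2, 2, 2, 5, 5, 5])
    out = co.transposed_decompress_conv(
        np.zeros((4, 2)), np.zeros((1, 3, 2)), np.array([2.0]), 3
    )
    np.testing.assert_allclose(out, 2.0)


def test_compress_decompress_round_trip_shape(rng):
    x = rng.normal(size=(14, 3))  # T not divisible by the stride
    w = rng.normal(size=(6, 3, 3))
    z = co.strided_compress_conv(x, w, rng.normal(size=6), 3)
    assert z.shape == (5, 6)
    back = co.transposed_decompress_conv(z, rng.normal(size=(3, 3, 6)),
                                         rng.normal(size=3), 3)
    assert back.shape[1] == 3 and back.shape[0] >= 14


def test_batch_norm_modes():
    ident = co.BatchNormParams.identity(1, epsilon=1e-12)
    x = np.array([[1.0], [2.0], [3.0]])
    np.testing.assert_allclose(co.batch_norm(x, ident, "infer"), x, atol=1e-9)

    p = co.BatchNormParams(np.array([2.0]), np.array([3.0]), np.array([1.0]),
                           np.array([1.0]), epsilon=1e-300)
    np.testing.assert_allclose(
        co.batch_norm(np.array([[0.0], [2.0]]), p, "infer")[:, 0], [1.0, 5.0]
    )

    rng = np.random.default_rng(5)
    x = rng.normal(2.0, 3.0, size=(200, 2))
    p = co.BatchNormParams(np.array([1.5, 0.5]), np.array([-1.0, 2.0]),
                           np.zeros(2), np.ones(2), epsilon=1e-12)
    y = co.batch_norm(x, p, "train")
    np.testing.assert_allclose(y.mean(axis=0), p.beta, atol=1e-6)
    np.testing.assert_allclose(y.var(axis=0), p.gamma**2, atol=1e-6)
    assert not np.allclose(p.running_mean, 0.0)  # EMA updated
    with pytest.raises(ValueError, match="mode"):
        co.batch_norm(x, p, "banana")


def test_swish_values():
    assert co.swish(0.0) == 0.0
    assert abs(co.swish(1.0) - 1 / (1 + np.exp(-1))) < 1e-12
    assert abs(co.swish(30.0) / 30.0 - 1.0) < 1e-9


# -- parameter / flop accounting -----------------------------------------

def test_count_examples():
    assert co.count_params_and_flops("full", cin=128, cout=128, depth=3)["params"] == 49152
    sep = co.count_params_and_flops("separable", cin=128, cout=128, depth=15, t=1000)
    assert sep["flops"] == 1000 * (15 * 128 + 128 * 128) == 18_304_000
    pw = co.count_params_and_flops("pointwise", cin=64, cout=32)
    full1 = co.count_params_and_flops("full", cin=64, cout=32, depth=1)
    assert pw == full1
    with pytest.raises(ValueError, match="unknown"):
        co.count_params_and_flops("quantum", cin=1)


def test_k_separable_param_count_and_ratio():
    ksep = co.count_params_and_flops(
        "k_blueprint_separable", cin=128, cout=128, depth=15, k=3
    )
    assert ksep["params"] == 128 * 3 * 128 + 5 * 128 == 49_792
    with_bias = co.count_params_and_flops(
        "k_blueprint_separable", cin=128, cout=128, depth=15, k=3, include_bias=True
    )
    assert with_bias["params"] == 49_792 + 256
    sep = co.count_params_and_flops("separable", cin=128, cout=128, depth=15)
    assert sep["params"] == 18_304
    ratio = ksep["params"] / sep["params"]
    assert 2.6 < ratio < 2.8  # "roughly k times" for k = 3


@pytest.mark.parametrize("trial", range(10))
def test_counts_match_stored_weight_enumeration(trial):
    rng = np.random.default_rng(3000 + trial)
    cin, cout = int(rng.integers(1, 16)), int(rng.integers(1, 16))
    k = int(rng.choice([1, 3, 5]))
    m = int(rng.choice([1, 3, 5]))
    d = k * m

    w_full = np.zeros((cout, d if d % 2 else d + 1, cin))
    assert co.count_params_and_flops(
        "full", cin=cin, cout=cout, depth=w_full.shape[1]
    )["params"] == w_full.size

    w_dw, w_pw = np.zeros((d, cin)), np.zeros((cout, cin))
    assert co.count_params_and_flops(
        "separable", cin=cin, cout=cout, depth=d
    )["params"] == w_dw.size + w_pw.size

    w_fat, w_dil = np.zeros((cout, k, cin)), np.zeros((m, cout))
    assert co.count_params_and_flops(
        "k_blueprint_separable", cin=cin, cout=cout, depth=d, k=k
    )["params"] == w_fat.size + w_dil.size
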