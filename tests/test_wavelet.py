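"""Haar transform pair, WTConv operator and the analytic FLOP formulas."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import correlate2d

import wmcdetr.nnkit as nn
from wmcdetr.errors import ArgumentError, ConfigError
from wmcdetr.nnkit import Tensor
from wmcdetr.wavelet import (WTConv2d, WTConvConfig, decompose, flops_bands,
                             flops_iwt, flops_wt, haar_dwt2, haar_idwt2,
                             reconstruct, wtconv2d)

RNG = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# Haar analysis/synthesis
# ---------------------------------------------------------------------------

def test_constant_map_decomposition():
    v = 3.5
    x = Tensor(np.full((1, 2, 4, 4), v))
    ll, lh, hl, hh = haar_dwt2(x)
    assert np.allclose(ll.numpy(), 2 * v)
    for band in (lh, hl, hh):
        assert np.allclose(band.numpy(), 0.0)
    # inverse of (LL=2v, zeros) is the constant v
    back = haar_idwt2((ll, lh, hl, hh))
    assert np.allclose(back.numpy(), v)


def test_single_block_coefficients():
    # 2x2 block [[1,2],[3,4]]: LL=5, (col-diff, row-diff, diag) = (-1, -2, 0)
    x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))
    ll, lh, hl, hh = haar_dwt2(x)
    assert ll.numpy().ravel()[0] == pytest.approx(5.0)
    assert lh.numpy().ravel()[0] == pytest.approx(-1.0)
    assert hl.numpy().ravel()[0] == pytest.approx(-2.0)
    assert hh.numpy().ravel()[0] == pytest.approx(0.0)


def test_matches_pywt_oracle():
    # orientation fixed against PyWavelets: (LL, LH, HL, HH) == (cA, cV, cH, cD)
    x = RNG.normal(size=(6, 8))
    ll, lh, hl, hh = [t.numpy()[0, 0] for t in haar_dwt2(Tensor(x[None, None]))]
    ca, (ch, cv, cd) = pywt.dwt2(x, "haar")
    assert np.allclose(ll, ca, atol=1e-6)
    assert np.allclose(lh, cv, atol=1e-6)
    assert np.allclose(hl, ch, atol=1e-6)
    assert np.allclose(hh, cd, atol=1e-6)


@pytest.mark.parametrize("size", [4, 6, 8, 16, 32, 64])
def test_perfect_reconstruction_and_energy(size):
    x = RNG.normal(size=(1, 3, size, size))
    levels = max(1, int(np.log2(size)) - 1)
    pyr = decompose(Tensor(x), levels)
    r = reconstruct(pyr).numpy()
    assert np.abs(r - x).max() < 1e-5
    e_in = (x ** 2).sum()
    e_sub = sum((b.numpy() ** 2).sum() for lvl in pyr.details for b in lvl)
    e_sub += (pyr.approx.numpy() ** 2).sum()
    assert e_sub == pytest.approx(e_in, rel=1e-6)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(h=st.integers(2, 16), w=st.integers(2, 16), seed=st.integers(0, 2 ** 16))
def test_reconstruction_property_any_even_shape(h, w, seed):
    """idwt(dwt(x)) == x and energy conservation for arbitrary even shapes."""
    x = np.random.default_rng(seed).normal(size=(1, 1, 2 * h, 2 * w))
    ll, lh, hl, hh = haar_dwt2(Tensor(x))
    back = haar_idwt2((ll, lh, hl, hh)).numpy()
    assert np.abs(back - x).max() < 1e-5 * max(1, np.abs(x).max())
    e_sub = sum((t.numpy() ** 2).sum() for t in (ll, lh, hl, hh))
    assert e_sub == pytest.approx((x ** 2).sum(), rel=1e-9)


def test_dwt_of_idwt_is_identity():
    subs = [Tensor(RNG.normal(size=(1, 2, 4, 4))) for _ in range(4)]
    rec = haar_idwt2(subs)
    back = haar_dwt2(rec)
    for s, b in zip(subs, back):
        assert np.allclose(s.numpy(), b.numpy(), atol=1e-6)


def test_zero_subbands_reconstruct_zero():
    z = [Tensor(np.zeros((1, 1, 2, 2)))] * 4
    assert np.allclose(haar_idwt2(z).numpy(), 0.0)


def test_dwt_errors():
    with pytest.raises(ArgumentError):
        haar_dwt2(Tensor(np.zeros((1, 1, 0, 0))))
    bad = [Tensor(np.zeros((1, 1, 2, 2)))] * 3 + [Tensor(np.zeros((1, 1, 4, 4)))]
    with pytest.raises(ArgumentError):
        haar_idwt2(bad)


def test_odd_input_reflect_padded():
    x = RNG.normal(size=(1, 1, 5, 7))
    ll, *_ = haar_dwt2(Tensor(x))
    assert ll.shape == (1, 1, 3, 4)


# ---------------------------------------------------------------------------
# brute-force oracle for WTConv: independent numpy/scipy implementation
# ---------------------------------------------------------------------------

def oracle_dwt(x):
    a, b = x[0::2, 0::2], x[0::2, 1::2]
    c, d = x[1::2, 0::2], x[1::2, 1::2]
    return ((a + b + c + d) / 2, (a - b + c - d) / 2,
            (a + b - c - d) / 2, (a - b - c + d) / 2)


def oracle_idwt(ll, lh, hl, hh):
    H, W = ll.shape
    out = np.zeros((2 * H, 2 * W))
    out[0::2, 0::2] = (ll + lh + hl + hh) / 2
    out[0::2, 1::2] = (ll - lh + hl - hh) / 2
    out[1::2, 0::2] = (ll + lh - hl - hh) / 2
    out[1::2, 1::2] = (ll - lh - hl + hh) / 2
    return out


def oracle_wtconv_channel(x, base_k, band_ks):
    """Single-channel WTConv by separable slicing + scipy correlation."""

    def cascade(x, lvl):
        ll, lh, hl, hh = oracle_dwt(x)
        conv = [correlate2d(band, k, mode="same")
                for band, k in zip((ll, lh, hl, hh), band_ks[lvl])]
        if lvl + 1 < len(band_ks):
            conv[0] = conv[0] + cascade(ll, lvl + 1)
        return oracle_idwt(*conv)

    return correlate2d(x, base_k, mode="same") + cascade(x, 0)


@pytest.mark.parametrize("size,levels,k", [(4, 1, 1), (4, 1, 3), (8, 2, 3), (8, 1, 3)])
def test_wtconv_matches_bruteforce_oracle(size, levels, k):
    c = 2
    cfg = WTConvConfig(channels=c, levels=levels, band_kernel=k, base_kernel=3)
    op = WTConv2d(cfg)
    x = RNG.normal(size=(1, c, size, size))
    out = op(Tensor(x)).numpy()
    for ch in range(c):
        base_k = op.base.weight.data[ch, 0]
        band_ks = [[op.bands[lvl].weight.data[band * c + ch, 0] for band in range(4)]
                   for lvl in range(levels)]
        ref = oracle_wtconv_channel(x[0, ch], base_k, band_ks)
        assert np.abs(out[0, ch] - ref).max() < 1e-5


def test_wtconv_zero_weights_gives_zero():
    cfg = WTConvConfig(channels=3, levels=2)
    op = WTConv2d(cfg)
    op.base.weight.data[:] = 0
    for b in op.bands:
        b.weight.data[:] = 0
    out = op(Tensor(RNG.normal(size=(1, 3, 8, 8)))).numpy()
    assert np.allclose(out, 0.0)


def test_wtconv_identity_path():
    cfg = WTConvConfig(channels=2, levels=1, band_kernel=3, base_kernel=3)
    op = WTConv2d(cfg)
    op.base.weight.data[:] = 0
    op.base.weight.data[:, 0, 1, 1] = 1.0   # delta kernel
    for b in op.bands:
        b.weight.data[:] = 0
    x = RNG.normal(size=(1, 2, 8, 8))
    assert np.allclose(op(Tensor(x)).numpy(), x, atol=1e-6)


def test_wtconv_scalar_band_on_constant():
    # l=1, k=1 band kernels all equal c_s, zero base, constant input v:
    # dwt -> scale -> idwt scales the constant by c_s (verified vs oracle)
    c_s, v = 0.75, 2.0
    cfg = WTConvConfig(channels=1, levels=1, band_kernel=1, base_kernel=1)
    op = WTConv2d(cfg)
    op.base.weight.data[:] = 0
    op.bands[0].weight.data[:] = c_s
    x = np.full((4, 4), v)
    out = op(Tensor(x[None, None])).numpy()[0, 0]
    ref = oracle_wtconv_channel(
        x, np.zeros((1, 1)), [[np.full((1, 1), c_s)] * 4])
    assert np.allclose(out, ref, atol=1e-6)
    assert np.allclose(out, c_s * v, atol=1e-6)


def test_wtconv_depth_error_names_level():
    cfg = WTConvConfig(channels=1, levels=4)
    op = WTConv2d(cfg)
    with pytest.raises(ConfigError, match="level"):
        op(Tensor(RNG.normal(size=(1, 1, 8, 8))))


def test_wtconv_functional_with_weights():
    cfg = WTConvConfig(channels=1, levels=1, band_kernel=1, base_kernel=1)
    w = {"base": np.zeros((1, 1, 1, 1)), "bands": [np.ones((4, 1, 1, 1))]}
    out = wtconv2d(np.full((1, 1, 4, 4), 2.0), cfg, w)
    assert np.allclose(out.numpy(), 2.0)


# ---------------------------------------------------------------------------
# FLOP formulas
# ---------------------------------------------------------------------------

def test_flops_worked_values():
    assert flops_wt(16, 64, 64, 2) == 16 * (16384 + 8192) == 393_216
    assert flops_bands(16, 16, 64, 64, 3, 1) == 2048 * 9 * 4 * 256 == 18_874_368
    assert flops_iwt(16, 64, 64, 2) == flops_wt(16, 64, 64, 2)


def test_flops_errors():
    for bad in (lambda: flops_wt(16, 64, 64, 0),
                lambda: flops_bands(16, 16, 64, 64, 3, 0),
                lambda: flops_iwt(16, 64, 64, 0)):
        with pytest.raises(ArgumentError):
            bad()


@pytest.mark.parametrize("levels,k", [(1, 3), (2, 3), (3, 3), (2, 5)])
def test_band_flops_below_equivalent_dense_conv(levels, k):
    c_in = c_out = 32
    h = w = 64
    keq = 2 ** levels * k
    dense = 2 * keq ** 2 * c_in * c_out * h * w
    assert flops_bands(c_in, c_out, h, w, k, levels) < dense


def test_band_flops_scaling():
    base = flops_bands(8, 8, 32, 32, 3, 1)
    assert flops_bands(8, 8, 32, 32, 6, 1) == 4 * base          # k^2
    assert flops_bands(16, 8, 32, 32, 3, 1) == 2 * base         # C_in
    assert flops_bands(8, 24, 32, 32, 3, 1) == 3 * base         # C_out
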