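"""Convolution, pooling and resampling primitives (numeric + meta modes).

conv2d uses im2col + BLAS matmul for dense convolutions and a windowed
einsum for the depthwise case.  Backward passes scatter gradients with a
short loop over kernel taps (k*k iterations, each fully vectorised).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, ensure, meta, add_flops, _node, _accum


def _out_size(size, k, stride, pad, dil):
    return (size + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _windows(xp, kh, kw, stride, dil, Ho, Wo):
    """View of padded input with shape (N, C, kh, kw, Ho, Wo)."""
    N, C, H, W = xp.shape
    sN, sC, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (N, C, kh, kw, Ho, Wo),
        (sN, sC, sH * dil, sW * dil, sH * stride, sW * stride), writeable=False)


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """2-D convolution over NCHW input.

    ``w`` has shape (C_out, C_in // groups, kh, kw); ``padding`` may be an
    int or an (ph, pw) pair (rectangular strip kernels).  FLOPs in meta
    mode: 2 * kh * kw * C_in * C_out * H_out * W_out / groups + bias adds.
    """
    x, w = ensure(x), ensure(w)
    if b is not None:
        b = ensure(b)
    N, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    assert C == Cg * groups, f"channel mismatch: {C} vs {Cg}*{groups}"
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    Ho = _out_size(H, kh, stride, ph, dilation)
    Wo = _out_size(W, kw, stride, pw, dilation)

    if x.is_meta or w.is_meta:
        macs = kh * kw * (C // groups) * Cout * Ho * Wo * N
        add_flops(2 * macs + (N * Cout * Ho * Wo if b is not None else 0))
        return meta((N, Cout, Ho, Wo))

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) \
        if (ph or pw) else x.data

    depthwise = groups == C and Cout == C and Cg == 1
    if depthwise:
        win = _windows(xp, kh, kw, stride, dilation, Ho, Wo)
        out = np.einsum("ncijhw,cij->nchw", win, w.data[:, 0], optimize=True)
        if b is not None:
            out = out + b.data[None, :, None, None]

        def bw(g):
            if w.requires_grad:
                gw = np.einsum("ncijhw,nchw->cij", win, g, optimize=True)
                _accum(w, gw[:, None])
            if b is not None and b.requires_grad:
                _accum(b, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i * dilation:i * dilation + Ho * stride:stride,
                            j * dilation:j * dilation + Wo * stride:stride] += \
                            g * w.data[None, :, 0, i, j, None, None]
                gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
                _accum(x, gx)

        parents = (x, w) if b is None else (x, w, b)
        return _node(out, parents, bw)

    if groups != 1:
        # grouped general case: dispatch per group (rare in this codebase)
        from .tensor import concat
        outs = []
        cs = C // groups
        for gidx in range(groups):
            outs.append(conv2d(x[:, gidx * cs:(gidx + 1) * cs], w[gidx * (Cout // groups):(gidx + 1) * (Cout // groups)],
                               None if b is None else b[gidx * (Cout // groups):(gidx + 1) * (Cout // groups)],
                               stride, padding, dilation, 1))
        return concat(outs, axis=1)

    win = _windows(xp, kh, kw, stride, dilation, Ho, Wo)
    cols = win.reshape(N, C * kh * kw, Ho * Wo)
    w2 = w.data.reshape(Cout, C * kh * kw)
    out = (w2 @ cols).reshape(N, Cout, Ho, Wo)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        gf = g.reshape(N, Cout, Ho * Wo)
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gf, cols, optimize=True)
            _accum(w, gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (w2.T @ gf).reshape(N, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * dilation:i * dilation + Ho * stride:stride,
                        j * dilation:j * dilation + Wo * stride:stride] += gcols[:, :, i, j]
            gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
            _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


def linear(x, w, b=None):
    """x (..., in) @ w.T (in, out) + b; w has shape (out, in)."""
    x, w = ensure(x), ensure(w)
    if b is not None:
        b = ensure(b)
    if x.is_meta or w.is_meta:
        out, inn = w.shape
        tokens = x.numel() // x.shape[-1]
        add_flops(2 * tokens * inn * out + (tokens * out if b is not None else 0))
        return meta(x.shape[:-1] + (out,))
    out_data = x.data @ w.data.T
    if b is not None:
        out_data += b.data

    def bw(g):
        if x.requires_grad:
            _accum(x, g @ w.data)
        if w.requires_grad:
            gf = g.reshape(-1, g.shape[-1])
            xf = x.data.reshape(-1, x.shape[-1])
            _accum(w, gf.T @ xf)
        if b is not None and b.requires_grad:
            _accum(b, g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bw)


def maxpool2d(x, kernel=3, stride=2, padding=1):
    x = ensure(x)
    N, C, H, W = x.shape
    Ho = _out_size(H, kernel, stride, padding, 1)
    Wo = _out_size(W, kernel, stride, padding, 1)
    if x.is_meta:
        return meta((N, C, Ho, Wo))
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    win = _windows(xp, kernel, kernel, stride, 1, Ho, Wo)
    flat = win.reshape(N, C, kernel * kernel, Ho, Wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        gxp = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        n, c, ho, wo = np.indices(arg.shape, sparse=False)
        rows = ho * stride + ki
        cols = wo * stride + kj
        np.add.at(gxp, (n, c, rows, cols), g)
        gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
        _accum(x, gx)

    return _node(out, (x,), bw)


def avg_pool2d(x, factor):
    """Non-overlapping average pooling by an integer factor."""
    x = ensure(x)
    N, C, H, W = x.shape
    if H % factor or W % factor:
        raise ValueError(f"spatial size {H}x{W} not divisible by pooling factor {factor}")
    from .tensor import mean
    r = x.reshape(N, C, H // factor, factor, W // factor, factor)
    return mean(r, axis=(3, 5))


def global_avg_pool(x):
    from .tensor import mean
    return mean(x, axis=(2, 3), keepdims=True)


def _bilinear_coeffs(out_size, in_size):
    """Half-pixel-centre source coordinates (align_corners=False)."""
    scale = in_size / out_size
    coords = (np.arange(out_size) + 0.5) * scale - 0.5
    coords = np.clip(coords, 0, in_size - 1)
    lo = np.floor(coords).astype(np.int64)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = coords - lo
    return lo, hi, frac.astype(np.float32)


def interpolate_bilinear(x, size):
    """Resize NCHW to ``size = (Ho, Wo)`` with half-pixel bilinear sampling."""
    x = ensure(x)
    N, C, H, W = x.shape
    Ho, Wo = size
    if x.is_meta:
        return meta((N, C, Ho, Wo))
    if (Ho, Wo) == (H, W):
        return _node(x.data.copy(), (x,), lambda g: _accum(x, g))
    ry_lo, ry_hi, fy = _bilinear_coeffs(Ho, H)
    rx_lo, rx_hi, fx = _bilinear_coeffs(Wo, W)
    d = x.data
    top = d[:, :, ry_lo][:, :, :, rx_lo] * (1 - fx) + d[:, :, ry_lo][:, :, :, rx_hi] * fx
    bot = d[:, :, ry_hi][:, :, :, rx_lo] * (1 - fx) + d[:, :, ry_hi][:, :, :, rx_hi] * fx
    out = top * (1 - fy)[:, None] + bot * fy[:, None]

    def bw(g):
        gx = np.zeros_like(d)
        gt = g * (1 - fy)[:, None]
        gb = g * fy[:, None]
        for gpart, rows in ((gt, ry_lo), (gb, ry_hi)):
            np.add.at(gx, (slice(None), slice(None), rows[:, None], rx_lo[None, :]),
                      gpart * (1 - fx))
            np.add.at(gx, (slice(None), slice(None), rows[:, None], rx_hi[None, :]),
                      gpart * fx)
        _accum(x, gx)

    return _node(out.astype(d.dtype), (x,), bw)


def point_sample(x, pts):
    """Bilinearly sample ``x`` (N, C, H, W) at ``pts`` (N, P, 2).

    Points are normalised to [0, 1] in (x, y) order with half-pixel centres;
    out-of-range samples contribute zero.  Differentiable in both arguments
    (needed so deformable-attention offsets receive gradients).
    """
    x, pts = ensure(x), ensure(pts)
    N, C, H, W = x.shape
    P = pts.shape[1]
    if x.is_meta or pts.is_meta:
        return meta((N, C, P))
    px = pts.data[..., 0] * W - 0.5
    py = pts.data[..., 1] * H - 0.5
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    fx = (px - x0).astype(x.data.dtype)
    fy = (py - y0).astype(x.data.dtype)
    # row-major (N*H*W, C) layout makes the 4 corner gathers contiguous
    rows = np.ascontiguousarray(
        np.swapaxes(x.data.reshape(N, C, H * W), 1, 2)).reshape(N * H * W, C)
    base = (np.arange(N) * H * W)[:, None]

    def gather(yy, xx):
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        idx = np.clip(yy, 0, H - 1) * W + np.clip(xx, 0, W - 1)
        vals = rows[(base + idx).reshape(-1)].reshape(N, P, C)
        vals = np.swapaxes(vals, 1, 2).copy()                      # (N, C, P)
        vals *= valid[:, None, :]
        return vals, valid, idx

    v00, m00, i00 = gather(y0, x0)
    v01, m01, i01 = gather(y0, x0 + 1)
    v10, m10, i10 = gather(y0 + 1, x0)
    v11, m11, i11 = gather(y0 + 1, x0 + 1)
    w00 = ((1 - fy) * (1 - fx))[:, None]
    w01 = ((1 - fy) * fx)[:, None]
    w10 = (fy * (1 - fx))[:, None]
    w11 = (fy * fx)[:, None]
    out = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11       # (N, C, P)

    def bw(g):
        if x.requires_grad:
            gt = np.swapaxes(g, 1, 2)                          # (N, P, C)
            acc = np.zeros((N * H * W, C), dtype=x.data.dtype)
            for m, idx, w in ((m00, i00, w00), (m01, i01, w01),
                              (m10, i10, w10), (m11, i11, w11)):
                upd = gt * np.swapaxes(w, 1, 2) * m[..., None]  # (N, P, C)
                np.add.at(acc, (base + idx).reshape(-1), upd.reshape(-1, C))
            gx = np.swapaxes(acc.reshape(N, H * W, C), 1, 2)
            _accum(x, gx.reshape(N, C, H, W).copy())
        if pts.requires_grad:
            gfx = (g * ((v01 - v00) * (1 - fy)[:, None] + (v11 - v10) * fy[:, None])).sum(1)
            gfy = (g * ((v10 - v00) * (1 - fx)[:, None] + (v11 - v01) * fx[:, None])).sum(1)
            gpts = np.stack([gfx * W, gfy * H], axis=-1)
            _accum(pts, gpts)

    return _node(out, (x, pts), bw)
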