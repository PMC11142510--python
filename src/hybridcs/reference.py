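"""Direct nested-loop 2-D/3-D convolutions: the oracle for the fast path.

These functions compute

    out[x, y, j]    = g( sum_{p,q,c} w[j, p, q, c] * v[x+p, y+q, c] + b[j] )
    out[x, y, z, j] = g( sum_{p,q,r,c} w[j, p, q, r, c]
                         * v[x+p, y+q, z*s+r, c] + b[j] )

exactly as written, one output element at a time.  They are deliberately
slow and structure-free so that the im2col/matmul layers in
:mod:`hybridcs.layers` can be validated against an implementation that
shares none of their machinery.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["conv2d_ref", "conv3d_ref"]


def _identity(x):
    return x


def conv2d_ref(v: np.ndarray, w: np.ndarray, b: np.ndarray,
               activation: Callable = _identity) -> np.ndarray:
    """Valid-mode 2-D multichannel convolution (cross-correlation form).

    Parameters
    ----------
    v : (H, W, C) input.
    w : (J, kh, kw, C) kernels, one per output feature j.
    b : (J,) biases.
    activation : elementwise nonlinearity g.
    """
    h, wid, c = v.shape
    j, kh, kw, cw = w.shape
    if cw != c:
        raise ValueError("kernel channel count does not match input")
    oh, ow = h - kh + 1, wid - kw + 1
    if oh < 1 or ow < 1:
        raise ValueError("kernel larger than input")
    out = np.zeros((oh, ow, j))
    for jj in range(j):
        for x in range(oh):
            for y in range(ow):
                acc = 0.0
                for p in range(kh):
                    for q in range(kw):
                        for cc in range(c):
                            acc += w[jj, p, q, cc] * v[x + p, y + q, cc]
                out[x, y, jj] = acc + b[jj]
    return activation(out)


def conv3d_ref(v: np.ndarray, w: np.ndarray, b: np.ndarray,
               spectral_stride: int = 1,
               activation: Callable = _identity) -> np.ndarray:
    """Valid-mode 3-D multichannel convolution with a spectral stride.

    Parameters
    ----------
    v : (H, W, D, C) input (D = spectral depth).
    w : (J, kh, kw, kd, C) kernels.
    b : (J,) biases.
    spectral_stride : stride along D.
    """
    h, wid, d, c = v.shape
    j, kh, kw, kd, cw = w.shape
    if cw != c:
        raise ValueError("kernel channel count does not match input")
    s = spectral_stride
    oh, ow = h - kh + 1, wid - kw + 1
    od = (d - kd) // s + 1
    if oh < 1 or ow < 1 or od < 1:
        raise ValueError("kernel larger than input")
    out = np.zeros((oh, ow, od, j))
    for jj in range(j):
        for x in range(oh):
            for y in range(ow):
                for z in range(od):
                    acc = 0.0
                    for p in range(kh):
                        for q in range(kw):
                            for r in range(kd):
                                for cc in range(c):
                                    acc += w[jj, p, q, r, cc] * \
                                        v[x + p, y + q, z * s + r, cc]
                    out[x, y, z, jj] = acc + b[jj]
    return activation(out)
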