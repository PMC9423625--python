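"""Numba inner loop for the windowed least-squares cost.

One evaluation resamples the reference at the (uniform) sub-pixel shift with
separable Catmull-Rom taps, correlates the result with the rasterised blur
kernel over the window, and accumulates the three weighted sums the quadratic
cost in T is built from.  ``fastmath`` only relaxes summation order; the
accumulated sums stay accurate to ~1e-12 relative.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def weighted_sums(sample, reference, gamma, kernel, cry, crx, sy, sx, by, bx, p):
    """Accumulate (sum G*I^2, sum G*I*M, sum G*M^2) over window and frames.

    ``sy, sx``: top-left of the window in the sample frames.
    ``by, bx``: top-left of the reference region touched by the shifted,
    blurred model; ``p`` is the side of the intermediate (shifted) patch,
    ``window + kernel - 1``.  Callers guarantee array bounds.
    """
    n = sample.shape[0]
    w = gamma.shape[0]
    ks = kernel.shape[0]
    s_ii = 0.0
    s_im = 0.0
    s_mm = 0.0
    tmp = np.empty((p + 3, p))
    patch = np.empty((p, p))
    for j in range(n):
        for y in range(p + 3):
            for x in range(p):
                v = 0.0
                for s in range(4):
                    v += crx[s] * reference[j, by + y, bx + x + s]
                tmp[y, x] = v
        for y in range(p):
            for x in range(p):
                v = 0.0
                for t in range(4):
                    v += cry[t] * tmp[y + t, x]
                patch[y, x] = v
        for y in range(w):
            for x in range(w):
                g = gamma[y, x]
                m = 0.0
                for a in range(ks):
                    for b in range(ks):
                        m += kernel[a, b] * patch[y + a, x + b]
                i_val = sample[j, sy + y, sx + x]
                s_ii += g * i_val * i_val
                s_im += g * i_val * m
                s_mm += g * m * m
    return s_ii, s_im, s_mm
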