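"""Brute-force Akima interpolation oracle.

Independent implementation of Akima's slope-weighting interpolation,
written directly from the published formulas (segment slopes, weighted
slope average with weights |m4-m3| and |m2-m1|, quadratic end extension,
Hermite cubic evaluation).  Used only as the dual-route oracle against the
package's spline; it shares no code with it.
"""

import numpy as np


def akima_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Akima's derivative at each node."""
    m = np.diff(y) / np.diff(x)
    ext = np.empty(m.size + 4)
    ext[2:-2] = m
    ext[1] = 2 * ext[2] - ext[3]
    ext[0] = 2 * ext[1] - ext[2]
    ext[-2] = 2 * ext[-3] - ext[-4]
    ext[-1] = 2 * ext[-2] - ext[-3]
    t = np.empty(x.size)
    for i in range(x.size):
        m1, m2, m3, m4 = ext[i : i + 4]
        w1, w2 = abs(m4 - m3), abs(m2 - m1)
        if w1 + w2 > 0:
            t[i] = (w1 * m2 + w2 * m3) / (w1 + w2)
        else:
            t[i] = 0.5 * (m2 + m3)
    return t


def _hermite(x, y, t, xq, deriv=False):
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2)
    out = np.empty(xq.size)
    for k, (q, i) in enumerate(zip(xq, idx)):
        h = x[i + 1] - x[i]
        s = q - x[i]
        mi = (y[i + 1] - y[i]) / h
        c = (3 * mi - 2 * t[i] - t[i + 1]) / h
        d = (t[i] + t[i + 1] - 2 * mi) / h**2
        if deriv:
            out[k] = t[i] + 2 * c * s + 3 * d * s**2
        else:
            out[k] = y[i] + t[i] * s + c * s**2 + d * s**3
    return out


def akima_eval(x, y, xq):
    """Spline values at query points inside the node range."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    return _hermite(x, y, akima_slopes(x, y), xq)


def akima_deriv(x, y, xq):
    """First-derivative values at query points inside the node range."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    return _hermite(x, y, akima_slopes(x, y), xq, deriv=True)
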