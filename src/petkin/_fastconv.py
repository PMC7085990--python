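"""Compiled inner loops for the piecewise-linear exponential convolution.

The math here mirrors :mod:`petkin.core` exactly: per-segment analytic
integrals of ``exp(-theta (t - s)) * C(s)`` for a linear segment, chained
by the stable recursion ``y[k+1] = y[k] * exp(-theta dt) + J[k]``.  When
numba is unavailable the callers fall back to the (slower) vectorised
log-domain implementation in :mod:`petkin.core`.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def conv_nodes(t: np.ndarray, c: np.ndarray, theta: float) -> np.ndarray:
    """exp(-theta t) (x) C at the sample nodes of a piecewise-linear curve."""
    n = t.shape[0]
    y = np.zeros(n)
    for k in range(n - 1):
        dt = t[k + 1] - t[k]
        x = theta * dt
        e = np.exp(-x)
        if x < 1e-4:
            p1 = 1.0 - x / 2.0 + x * x / 6.0
        else:
            p1 = (1.0 - e) / x
        if x < 1e-3:
            ps = 0.5 - x / 3.0 + x * x / 8.0
        else:
            ps = (1.0 - e * (1.0 + x)) / (x * x)
        j = dt * (c[k] * p1 + (c[k + 1] - c[k]) * (p1 - ps))
        y[k + 1] = y[k] * e + j
    return y


@njit(cache=True)
def frame_avg_conv(
    t: np.ndarray,
    c: np.ndarray,
    theta: float,
    seg: np.ndarray,
    dp: np.ndarray,
    cu: np.ndarray,
    cv: np.ndarray,
    icp: np.ndarray,
    durations: np.ndarray,
) -> np.ndarray:
    """Frame-averaged exp(-theta t) (x) C via the ODE identity.

    ``seg``/``dp``/``cu``/``cv`` locate the frame boundaries (starts then
    ends) inside the node grid; ``icp`` is the per-frame integral of C.
    """
    yn = conv_nodes(t, c, theta)
    nb = seg.shape[0]
    yb = np.empty(nb)
    for i in range(nb):
        d = dp[i]
        x = theta * d
        e = np.exp(-x)
        if x < 1e-4:
            p1 = 1.0 - x / 2.0 + x * x / 6.0
        else:
            p1 = (1.0 - e) / x
        if x < 1e-3:
            ps = 0.5 - x / 3.0 + x * x / 8.0
        else:
            ps = (1.0 - e * (1.0 + x)) / (x * x)
        part = d * (cu[i] * p1 + (cv[i] - cu[i]) * (p1 - ps))
        yb[i] = yn[seg[i]] * e + part
    nf = durations.shape[0]
    out = np.empty(nf)
    for i in range(nf):
        out[i] = (icp[i] - (yb[nf + i] - yb[i])) / (theta * durations[i])
    return out
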