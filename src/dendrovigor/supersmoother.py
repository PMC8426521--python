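"""Friedman's variable-span "super smoother".

Running local-linear smooths at three fixed spans (tweeter 0.05, midrange
0.2, woofer 0.5 of the data), leave-one-out residuals to pick the best span
at each point, optional bass enhancement pulling the selected span toward
the woofer, and a final pass that interpolates between the fixed-span
smooths at the locally selected span. Used here to detrend ring-width
series while preserving high-frequency (inter-annual) variability.
"""

from __future__ import annotations

import numpy as np

__all__ = ["supsmu", "local_linear_smooth"]

SPANS = (0.05, 0.2, 0.5)  # tweeter, midrange, woofer


def local_linear_smooth(x: np.ndarray, y: np.ndarray, span: float,
                        cv: bool = False):
    """Running local-linear fit over a symmetric nearest-neighbour window.

    Returns the smoothed values, and when ``cv`` also the absolute
    leave-one-out residuals |y_i − fit_(−i)(x_i)| obtained from the local
    leverage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    # windows below 5 points let a local line (near-)interpolate, which
    # degenerates the cross-validated span selection on short series
    j = int(min(n, max(5, round(span * n))))
    half = j // 2
    smo = np.empty(n)
    res = np.empty(n) if cv else None
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + j)
        lo = max(0, hi - j)
        xs = x[lo:hi]
        ys = y[lo:hi]
        m = hi - lo
        xbar = xs.mean()
        ybar = ys.mean()
        dx = xs - xbar
        sxx = float(dx @ dx)
        if sxx > 1e-12 * max(1.0, xbar * xbar):
            beta = float(dx @ (ys - ybar)) / sxx
        else:
            beta = 0.0
        xi = x[i]
        fit = ybar + beta * (xi - xbar)
        smo[i] = fit
        if cv:
            h = 1.0 / m + ((xi - xbar) ** 2 / sxx if sxx > 0 else 0.0)
            h = min(h, 1.0 - 1e-10)
            res[i] = abs(y[i] - fit) / (1.0 - h)
    if cv:
        return smo, res
    return smo


def supsmu(x, y, bass: float = 5.0) -> np.ndarray:
    """Friedman's super smoother.

    ``bass`` in [0, 10] controls smoothness enhancement; 5 corresponds to an
    intermediate degree of smoothing (larger values favour the widest span).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        return np.full(n, y.mean())
    if np.ptp(y) == 0:
        return y.copy()

    smooths = np.empty((3, n))
    cv_res = np.empty((3, n))
    for k, span in enumerate(SPANS):
        smooths[k], cv_res[k] = local_linear_smooth(x, y, span, cv=True)
    # smooth the CV residuals with the midrange span before comparing
    cv_smoothed = np.empty_like(cv_res)
    for k in range(3):
        cv_smoothed[k] = local_linear_smooth(x, cv_res[k], SPANS[1])
    best = np.argmin(cv_smoothed, axis=0)
    span_sel = np.array([SPANS[k] for k in best])

    if bass > 0:
        # bass enhancement: move selected spans toward the woofer when the
        # woofer's CV loss is nearly as good
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cv_smoothed[2] > 0,
                             cv_smoothed[best, np.arange(n)] / cv_smoothed[2],
                             1.0)
        ratio = np.clip(ratio, 0.0, 1.0)
        span_sel = span_sel + (SPANS[2] - span_sel) * ratio ** (10.0 - bass)

    # smooth the selected spans themselves, then interpolate between the
    # bracketing fixed-span smooths
    span_sel = local_linear_smooth(x, span_sel, SPANS[1])
    span_sel = np.clip(span_sel, SPANS[0], SPANS[2])
    result = np.empty(n)
    for i in range(n):
        s = span_sel[i]
        if s <= SPANS[1]:
            lo_k, hi_k = 0, 1
        else:
            lo_k, hi_k = 1, 2
        w = (s - SPANS[lo_k]) / (SPANS[hi_k] - SPANS[lo_k])
        result[i] = (1.0 - w) * smooths[lo_k, i] + w * smooths[hi_k, i]
    # final pass with the tweeter span to remove interpolation roughness
    return local_linear_smooth(x, result, SPANS[0])
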