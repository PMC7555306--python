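"""Small closed-form weighted least-squares helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    r_squared: float
    n: int


def weighted_line_fit(x, y, sigma=None) -> LineFit:
    """Fit y = a + b x by weighted least squares.

    sigma are per-point standard errors of y (None = unit weights).
    Parameter errors come from the inverse normal matrix, i.e. they assume
    the supplied sigma are correct rather than rescaling by the residual
    variance.  r_squared is the weighted coefficient of determination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two (x, y) pairs")
    if sigma is None:
        w = np.ones_like(x)
    else:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        w = 1.0 / sigma**2
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    delta = sw * sxx - sx * sx
    if delta <= 0:
        raise ValueError("degenerate x values")
    b = (sw * sxy - sx * sy) / delta
    a = (sxx * sy - sx * sxy) / delta
    a_err = np.sqrt(sxx / delta)
    b_err = np.sqrt(sw / delta)
    resid = y - (a + b * x)
    ss_res = (w * resid**2).sum()
    ybar = sy / sw
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LineFit(slope=float(b), intercept=float(a), slope_err=float(b_err),
                   intercept_err=float(a_err), r_squared=float(r2), n=len(x))
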