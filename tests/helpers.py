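"""Independent oracles used by the tests.

These deliberately re-derive results by brute force (explicit loops,
polyfit, root finding, textbook formulas) so that they share no code path
with the package implementations they check.
"""

import numpy as np
from scipy.optimize import brentq


def ols_r2(x, y):
    """Plain OLS line and R² via polyfit + residuals."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 1e-12 * max(abs(np.sum(y * y)), 1.0):
        r2 = 1.0 if np.sum(resid ** 2) <= 1e-12 * max(abs(np.sum(y * y)), 1.0) else 0.0
    else:
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def brute_force_band(x, y, band_width, start_t, stop_t, criterion="r2",
                     max_slope=None):
    """Exhaustively evaluate every candidate band [a, a + band_width]
    with a on the grid in [start_t, stop_t - band_width]; return
    (band_low, band_high, slope, intercept, r2) of the winner.

    Ties within 1e-9 break toward the lowest a, matching the published
    selection rule.
    """
    step = x[1] - x[0]
    w = int(round(band_width / step)) + 1
    best = None
    for i in range(len(x) - w + 1):
        a, b = x[i], x[i + w - 1]
        if a < start_t - 1e-9 or b > stop_t + 1e-9:
            continue
        slope, intercept, r2 = ols_r2(x[i:i + w], y[i:i + w])
        if max_slope is not None and not slope < max_slope:
            continue
        score = r2 if criterion == "r2" else slope
        if best is None or score > best[0] + 1e-9:
            best = (score, a, b, slope, intercept, r2)
    if best is None:
        return None
    return best[1:]


def numeric_lt(a1, a2, x0, p, d):
    """Root-find the damage temperature on the sigmoid directly.

    The power term is computed with a capped exponent so the bracket can
    be generous without overflowing for steep curves.
    """
    import math

    target = a1 - d * (a1 - a2)

    def f(x):
        z = min(p * math.log(x / x0), 700.0)
        return a2 + (a1 - a2) / (1.0 + math.exp(z)) - target

    return brentq(f, x0 * 1e-3, x0 * 1e3, xtol=1e-12, rtol=1e-15)


def pearson_formula(a, b):
    """Textbook Pearson correlation from raw sums."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
    den = np.sqrt(n * np.sum(a * a) - np.sum(a) ** 2) * \
        np.sqrt(n * np.sum(b * b) - np.sum(b) ** 2)
    return num / den
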