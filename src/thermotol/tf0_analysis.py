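"""PSII thermotolerance thresholds from T-F0 curves.

Basic fluorescence stays flat while the leaf heats, rises steeply once
PSII starts to be impaired, peaks, and may show a second peak at higher
temperature.  Three thresholds are extracted:

* ``T_c`` — intersection of a baseline line (best-R² 5 K band below the
  rise) with a rise line (3 K band of maximal positive slope below the
  first peak).  This replaces the traditional by-eye two-tangent
  construction.
* ``T_p`` — first prominent F0 maximum above T_c.
* ``T_pII`` — next prominent maximum above T_p, when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .dsc_analysis import (LineSegment, _best_band, _rolling_ols,
                           _stride_points, _uniform_step, _window_points,
                           intersect_lines)
from .errors import DetectionError
from .thermo_io import F0Curve, uniform_grid

_TOL = 1e-9
_MIN_SPAN_K = 15.0


@dataclass
class TF0Thresholds:
    sample_id: str
    species: str = ""
    t_c: float | None = None
    t_p: float | None = None
    t_pII: float | None = None
    baseline_line: LineSegment | None = None
    rise_line: LineSegment | None = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def ordered(self) -> bool:
        """T_c < T_p (< T_pII when present)."""
        if self.t_c is None or self.t_p is None:
            return False
        if not self.t_c < self.t_p:
            return False
        return self.t_pII is None or self.t_p < self.t_pII


def resample_f0(c: F0Curve, step: float = 0.1) -> F0Curve:
    """Linear interpolation of F0 onto a uniform temperature grid."""
    lo, hi = c.span
    if step <= 0 or step > hi - lo:
        raise ValueError(f"invalid resampling step {step} K for span {hi - lo:.3g} K")
    grid = uniform_grid(lo, hi, step)
    return F0Curve(sample_id=c.sample_id, species=c.species, temperature=grid,
                   f0=np.interp(grid, c.temperature, c.f0))


def _smooth(y: np.ndarray, window_k: float, step: float) -> np.ndarray:
    n = int(round(window_k / step))
    if n < 2:
        return y
    kernel = np.ones(n) / n
    pad = n // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="same")[pad:pad + y.size]
    return out


def _prepare(c: F0Curve, cfg: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = c.span
    if hi - lo < _MIN_SPAN_K:
        raise ValueError(f"T-F0 curve spans {hi - lo:.3g} K; "
                         f"at least {_MIN_SPAN_K} K is required")
    u = resample_f0(c, cfg.grid_step)
    y = u.f0
    if cfg.tf0_smooth_window > 0:
        y = _smooth(y, cfg.tf0_smooth_window, cfg.grid_step)
    return u.temperature, y


def _steepest_band(x, y, w: int, i_last: int) -> LineSegment:
    """Maximal-slope band, resolved toward low temperature.

    Among all windows starting at index <= ``i_last``, candidates whose
    slope lies within two standard errors of the steepest are treated as
    equivalent and the lowest-temperature one wins; this anchors the rise
    line at the onset of the rise instead of letting noise pick an
    arbitrary position along it.  Noise-free curves reduce to the plain
    lowest-start tie-break.
    """
    slope, intercept, r2 = _rolling_ols(x, y, w)
    cand = np.arange(0, i_last + 1)
    cand = cand[cand <= slope.size - 1]
    if cand.size == 0:
        raise DetectionError("no candidate rise band")
    i_best = int(cand[np.argmax(slope[cand])])
    xs, ys = x[i_best:i_best + w], y[i_best:i_best + w]
    resid = ys - (slope[i_best] * xs + intercept[i_best])
    var_x = np.sum((xs - xs.mean()) ** 2)
    se = np.sqrt(np.sum(resid ** 2) / max(w - 2, 1) / var_x)
    thresh = slope[i_best] - 2.0 * se - _TOL
    i = int(cand[np.argmax(slope[cand] >= thresh)])
    return LineSegment(slope=float(slope[i]), intercept=float(intercept[i]),
                       band_low=float(x[i]), band_high=float(x[i + w - 1]),
                       r_squared=float(np.clip(r2[i], 0.0, 1.0)), n_points=w)


def _prominent_peaks(x, y, frac):
    thresh = frac * float(y.max() - y.min())
    peaks, props = find_peaks(y, prominence=thresh)
    return peaks, props["prominences"], thresh


def detect_tc(c: F0Curve, config: AnalysisConfig | None = None
              ) -> tuple[float, LineSegment, LineSegment]:
    """T_c with its baseline and rise lines.

    Returns ``(t_c, baseline_line, rise_line)``; raises
    :class:`DetectionError` on flat curves without a qualifying rise.
    """
    cfg = config or AnalysisConfig()
    x, y = _prepare(c, cfg)
    step = _uniform_step(x)

    if float(y.max() - y.min()) <= 0:
        raise DetectionError("no F0 rise: curve is constant")
    # band searches stop at the first prominent peak; on monotone-rising
    # curves (no interior peak) the global maximum takes its place
    peaks, _, _ = _prominent_peaks(x, y, cfg.prominence_frac)
    i_peak = int(peaks[0]) if peaks.size else int(np.argmax(y))

    # the rise band is located first: on noisy curves the flat baseline
    # has near-zero R², so the baseline region must be delimited by the
    # rise geometrically rather than competing with it on R²
    w_rise = _window_points(cfg.tf0_rise_band, step)
    if i_peak + 1 < w_rise:
        raise DetectionError("first F0 peak too close to the curve start "
                             "for a rise band")
    rise = _steepest_band(x, y, w_rise, i_peak + 1 - w_rise)
    if rise.slope <= 0.0:
        raise DetectionError(f"no positive F0 rise (max band slope "
                             f"{rise.slope:.3g})")

    w_base = _window_points(cfg.tf0_baseline_band, step)
    i_last = int(np.searchsorted(x, rise.band_low + _TOL)) - w_base
    if i_last < 0:
        raise DetectionError("no room for a baseline band below the F0 rise")
    baseline = _best_band(x, y, w_base, 0, i_last,
                          _stride_points(None, step), criterion="r2")
    if rise.slope <= max(baseline.slope, 0.0):
        raise DetectionError(
            f"no rise exceeding the baseline slope "
            f"(rise {rise.slope:.3g} vs baseline {baseline.slope:.3g})")
    t_c = intersect_lines(baseline, rise, slope_tol=1e-9)
    if not x[0] <= t_c <= x[-1]:
        raise DetectionError(f"T_c estimate {t_c:.2f} °C outside the curve span")
    return t_c, baseline, rise


def detect_tp(c: F0Curve, t_c: float,
              config: AnalysisConfig | None = None) -> float:
    """First prominent F0 maximum above T_c."""
    cfg = config or AnalysisConfig()
    x, y = _prepare(c, cfg)
    peaks, _, thresh = _prominent_peaks(x, y, cfg.prominence_frac)
    above = peaks[x[peaks] > t_c + _TOL]
    if above.size == 0:
        raise DetectionError(
            f"no F0 peak above T_c = {t_c:.2f} °C with prominence >= {thresh:.3g}")
    return float(x[above[0]])


def detect_tpII(c: F0Curve, t_p: float,
                config: AnalysisConfig | None = None) -> float | None:
    """Next prominent F0 maximum above T_p; None when absent."""
    cfg = config or AnalysisConfig()
    x, y = _prepare(c, cfg)
    peaks, _, _ = _prominent_peaks(x, y, cfg.prominence_frac)
    above = peaks[x[peaks] > t_p + _TOL]
    if above.size == 0:
        return None
    return float(x[above[0]])


def analyze_f0_curve(c: F0Curve,
                     config: AnalysisConfig | None = None) -> TF0Thresholds:
    """Run the full T-F0 pipeline; failed stages leave fields None."""
    cfg = config or AnalysisConfig()
    res = TF0Thresholds(sample_id=c.sample_id, species=c.species)
    try:
        res.t_c, res.baseline_line, res.rise_line = detect_tc(c, cfg)
    except (DetectionError, ValueError) as exc:
        res.diagnostics.append(f"t_c: {exc}")
        return res
    try:
        res.t_p = detect_tp(c, res.t_c, cfg)
    except DetectionError as exc:
        res.diagnostics.append(f"t_p: {exc}")
        return res
    res.t_pII = detect_tpII(c, res.t_p, cfg)
    if res.t_pII is None:
        res.diagnostics.append("t_pII: no second peak (absent is a valid outcome)")
    if not res.ordered:
        res.diagnostics.append("threshold ordering t_c < t_p < t_pII violated")
    return res
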