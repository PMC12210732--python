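"""Critical-temperature extraction from normalized DSC thermograms.

The thermogram of a vital leaf during a constant-rate heating ramp shows an
initial shallow, near-linear endothermic decline, a steeper decline at
higher temperature, an endothermic dip (T_endo) and a pronounced exotherm
peak (T_exo).  Three parameters are derived per curve:

* ``T_exo`` — temperature of the most prominent heat-flow maximum at high
  temperature;
* ``T_endo`` — temperature of the most prominent heat-flow minimum below
  the exotherm's onset;
* ``T_init`` — intersection of two fitted lines: the best-R² 10 K band
  searched from 29 °C up to T_endo (the baseline decline), and the best-R²
  3 K band between the first band's upper edge and T_endo (the steep
  decline).

Curves from reheated (heat-killed) leaves lack the dip/peak signature and
are classified ``heat_killed`` when a single line fits the full span.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .errors import DataError, DegeneracyError, DetectionError
from .thermo_io import Thermogram, normalize_heat_flow, resample_uniform

_TOL = 1e-9  # °C slack for grid-index arithmetic and R² tie-breaking


class Vitality(enum.Enum):
    VITAL = "vital"
    HEAT_KILLED = "heat_killed"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LineSegment:
    """An ordinary-least-squares line fitted within a temperature band."""

    slope: float        # mW g-1 K-1
    intercept: float    # mW g-1, value at 0 °C
    band_low: float     # °C
    band_high: float    # °C
    r_squared: float
    n_points: int

    def __post_init__(self):
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be < band_high")
        if self.n_points < 3:
            raise ValueError("a line segment needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PeakResult:
    """A detected extremum with its prominence interval."""

    temperature: float       # °C
    prominence: float        # mW g-1
    index: int               # position on the resampled grid
    left_base_temperature: float
    left_base_index: int


@dataclass
class ThermalThresholds:
    """Full per-curve result of the DSC pipeline; absent stages are None."""

    sample_id: str
    species: str = ""
    t_init: float | None = None
    t_endo: float | None = None
    t_exo: float | None = None
    first_line: LineSegment | None = None
    second_line: LineSegment | None = None
    vitality: Vitality = Vitality.INDETERMINATE
    diagnostics: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return None not in (self.t_init, self.t_endo, self.t_exo)

    @property
    def ordered(self) -> bool:
        """T_init < T_endo < T_exo, defined only when all are present."""
        if not self.complete:
            return False
        return self.t_init < self.t_endo < self.t_exo


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def _uniform_step(x: np.ndarray) -> float:
    dx = np.diff(x)
    if dx.size == 0:
        raise DataError("curve has fewer than 2 points")
    step = dx[0]
    if not np.allclose(dx, step, rtol=0, atol=1e-6):
        raise DataError("curve must be on a uniform temperature grid "
                        "(use resample_uniform first)")
    return float(step)


def _rolling_ols(x: np.ndarray, y: np.ndarray, w: int):
    """OLS slope, intercept and R² for every length-``w`` window of (x, y).

    Windowed sums come from cumulative sums after centering, which keeps
    the arithmetic stable on long curves.  Flat windows (zero variance in
    y) get R² = 1 when the residual is also zero, else 0.
    """
    xc = x - x.mean()
    yc = y - y.mean()

    def winsum(a):
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[w:] - c[:-w]

    n = float(w)
    sx, sy = winsum(xc), winsum(yc)
    sxx, sxy, syy = winsum(xc * xc), winsum(xc * yc), winsum(yc * yc)
    var_x = sxx - sx * sx / n
    var_y = syy - sy * sy / n
    cov = sxy - sx * sy / n
    slope = cov / var_x
    ss_res = np.maximum(var_y - cov * cov / var_x, 0.0)
    scale = np.maximum(np.abs(syy), 1.0)
    flat = var_y <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / var_y
    r2 = np.where(flat, np.where(ss_res <= 1e-12 * scale, 1.0, 0.0), r2)
    r2 = np.clip(r2, 0.0, 1.0)
    # undo centering for the intercept (slope is unaffected)
    intercept = (sy - slope * sx) / n + y.mean() - slope * x.mean()
    return slope, intercept, r2


def _best_band(x, y, w: int, i_first: int, i_last: int, stride: int = 1,
               criterion: str = "r2", max_slope: float | None = None) -> LineSegment:
    """Best window of length ``w`` points starting in [i_first, i_last].

    ``criterion`` is ``"r2"`` (maximal R²) or ``"slope"`` (maximal slope).
    ``max_slope`` excludes candidates whose slope is not below it.
    Ties (within 1e-9) are broken toward the lowest start temperature.
    """
    slope, intercept, r2 = _rolling_ols(x, y, w)
    cand = np.arange(i_first, i_last + 1, stride)
    cand = cand[cand <= slope.size - 1]
    if max_slope is not None:
        cand = cand[slope[cand] < max_slope]
    if cand.size == 0:
        raise ValueError("no candidate band")
    score = r2[cand] if criterion == "r2" else slope[cand]
    best = score.max()
    i = int(cand[np.argmax(score >= best - _TOL)])
    return LineSegment(slope=float(slope[i]), intercept=float(intercept[i]),
                       band_low=float(x[i]), band_high=float(x[i + w - 1]),
                       r_squared=float(r2[i]), n_points=w)


def _window_points(band_width: float, step: float) -> int:
    w = int(round(band_width / step)) + 1
    if w < 3:
        raise ValueError(f"band width {band_width} K too narrow for grid step {step} K")
    return w


def _stride_points(step_arg: float | None, grid_step: float) -> int:
    if step_arg is None:
        return 1
    stride = step_arg / grid_step
    if abs(stride - round(stride)) > 1e-6 or round(stride) < 1:
        raise ValueError(f"search step {step_arg} K is not a positive multiple "
                         f"of the grid step {grid_step} K")
    return int(round(stride))


# ---------------------------------------------------------------------------
# band fits
# ---------------------------------------------------------------------------

def fit_first_line(t: Thermogram, t_endo: float, band_width: float = 10.0,
                   start: float = 29.0, step: float | None = None) -> LineSegment:
    """Best-R² ``band_width``-K line searched from ``start`` up to ``t_endo``.

    Candidate bands are [a, a + band_width] with a advancing by ``step``
    (default: the resampling grid step); the band with maximal R² wins,
    ties broken toward the lowest a.
    """
    if t_endo - start < band_width:
        raise ValueError(
            f"first-line fit needs t_endo - start >= {band_width} K; "
            f"got {t_endo} - {start} = {t_endo - start:.3g} K")
    x, y = t.temperature, t.heat_flow
    gstep = _uniform_step(x)
    w = _window_points(band_width, gstep)
    stride = _stride_points(step, gstep)
    i_first = int(np.searchsorted(x, start - _TOL))
    j_last = int(np.searchsorted(x, t_endo + _TOL, side="right")) - 1
    i_last = j_last - w + 1
    if i_last < i_first:
        raise ValueError(
            f"curve offers no {band_width} K band between {start} and {t_endo} °C")
    return _best_band(x, y, w, i_first, i_last, stride)


def fit_second_line(t: Thermogram, first: LineSegment, t_endo: float,
                    band_width: float = 3.0, step: float | None = None,
                    slope_tol: float = 1e-6) -> LineSegment:
    """Best-R² ``band_width``-K line between the first band's upper edge
    and ``t_endo``.

    The second line describes the steeper decline above the baseline, so
    candidate bands whose slope is not below the first line's slope (by at
    least ``slope_tol``) are excluded — intersecting a parallel line would
    be degenerate.
    """
    if t_endo - first.band_high < band_width:
        raise DetectionError(
            f"no admissible {band_width} K band between the first band's upper "
            f"edge ({first.band_high} °C) and t_endo ({t_endo} °C)")
    x, y = t.temperature, t.heat_flow
    gstep = _uniform_step(x)
    w = _window_points(band_width, gstep)
    stride = _stride_points(step, gstep)
    i_first = int(np.searchsorted(x, first.band_high - _TOL))
    j_last = int(np.searchsorted(x, t_endo + _TOL, side="right")) - 1
    i_last = j_last - w + 1
    if i_last < i_first:
        raise DetectionError("no admissible band for the second line")
    try:
        return _best_band(x, y, w, i_first, i_last, stride,
                          max_slope=first.slope - slope_tol)
    except ValueError:
        raise DetectionError("no admissible band steeper than the first line")


def intersect_lines(l1: LineSegment, l2: LineSegment,
                    slope_tol: float = 1e-6) -> float:
    """x-coordinate (°C) of the intersection of two fitted lines."""
    dslope = l1.slope - l2.slope
    if abs(dslope) < slope_tol:
        raise DegeneracyError(
            f"lines are near-parallel (|Δslope| = {abs(dslope):.3g} < {slope_tol})")
    return float((l2.intercept - l1.intercept) / dslope)


# ---------------------------------------------------------------------------
# peak / dip detection
# ---------------------------------------------------------------------------

def _prominence_threshold(y: np.ndarray, frac: float) -> float:
    return frac * float(y.max() - y.min())


def _wlen_points(x: np.ndarray, window_k: float) -> int | None:
    """find_peaks ``wlen``: prominence is measured against the signal
    within ``window_k`` K around the peak rather than the whole curve,
    which keeps the overall declining trend from inflating the
    prominence of small fluctuations."""
    if window_k is None or window_k <= 0:
        return None
    step = x[1] - x[0]
    w = int(round(window_k / step)) + 1
    return max(w, 3)


def detect_exotherm(t: Thermogram, search_min: float = 50.0,
                    prominence_frac: float = 0.05,
                    prominence_window: float = 10.0) -> PeakResult | None:
    """Most prominent heat-flow maximum at T ≥ ``search_min``; None if no
    maximum reaches the prominence threshold."""
    x, y = t.temperature, t.heat_flow
    if x[-1] < search_min:
        raise ValueError(f"curve ends at {x[-1]} °C, below the exotherm "
                         f"search region starting at {search_min} °C")
    thresh = _prominence_threshold(y, prominence_frac)
    peaks, props = find_peaks(y, prominence=thresh,
                              wlen=_wlen_points(x, prominence_window))
    keep = x[peaks] >= search_min - _TOL
    peaks, prom = peaks[keep], props["prominences"][keep]
    lbase = props["left_bases"][keep]
    if peaks.size == 0:
        return None
    i = int(np.argmax(prom))
    return PeakResult(temperature=float(x[peaks[i]]), prominence=float(prom[i]),
                      index=int(peaks[i]),
                      left_base_temperature=float(x[lbase[i]]),
                      left_base_index=int(lbase[i]))


def detect_endotherm(t: Thermogram, exo: PeakResult | None = None,
                     search_min: float = 40.0,
                     prominence_frac: float = 0.05,
                     prominence_window: float = 10.0) -> PeakResult:
    """Most prominent heat-flow minimum in the endotherm search region.

    With a detected exotherm the search is constrained to its left
    (at or below the left base of the exotherm's prominence interval);
    without one, to T ≥ ``search_min``.
    """
    x, y = t.temperature, t.heat_flow
    thresh = _prominence_threshold(y, prominence_frac)
    dips, props = find_peaks(-y, prominence=thresh,
                             wlen=_wlen_points(x, prominence_window))
    if exo is not None:
        keep = dips <= exo.left_base_index
    else:
        keep = x[dips] >= search_min - _TOL
    dips, prom = dips[keep], props["prominences"][keep]
    lbase = props["left_bases"][keep]
    if dips.size == 0:
        raise DetectionError(
            "no endotherm dip above the prominence threshold "
            f"({thresh:.3g} mW g-1); curve may be heat-killed")
    i = int(np.argmax(prom))
    return PeakResult(temperature=float(x[dips[i]]), prominence=float(prom[i]),
                      index=int(dips[i]),
                      left_base_temperature=float(x[lbase[i]]),
                      left_base_index=int(lbase[i]))


# ---------------------------------------------------------------------------
# classification and pipeline
# ---------------------------------------------------------------------------

def _full_span_r2(t: Thermogram) -> float:
    x, y = t.temperature, t.heat_flow
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def classify_vitality(t: Thermogram, config: AnalysisConfig | None = None) -> Vitality:
    """Vital when both dip and peak clear their prominence thresholds;
    heat-killed when neither does and one line fits the whole span."""
    cfg = config or AnalysisConfig()
    exo = detect_exotherm(t, cfg.search_min_exo, cfg.prominence_frac,
                          cfg.prominence_window)
    try:
        endo = detect_endotherm(t, exo, cfg.search_min_endo,
                                cfg.prominence_frac, cfg.prominence_window)
    except DetectionError:
        endo = None
    if exo is not None and endo is not None:
        return Vitality.VITAL
    if exo is None and endo is None and _full_span_r2(t) >= cfg.linearity_r2:
        return Vitality.HEAT_KILLED
    return Vitality.INDETERMINATE


def analyze_thermogram(t: Thermogram,
                       config: AnalysisConfig | None = None) -> ThermalThresholds:
    """Run the full DSC pipeline on one curve.

    Normalizes (if needed) and resamples, then detects the exotherm and
    endotherm, fits the two lines and intersects them.  Stages that fail on
    heat-killed-type curves leave their fields None and append a diagnostic
    message; nothing is silently defaulted.
    """
    cfg = config or AnalysisConfig()
    if not t.normalized:
        t = normalize_heat_flow(t)
    u = resample_uniform(t, cfg.grid_step)
    res = ThermalThresholds(sample_id=t.sample_id, species=t.species,
                            vitality=classify_vitality(u, cfg))

    exo = detect_exotherm(u, cfg.search_min_exo, cfg.prominence_frac,
                          cfg.prominence_window)
    if exo is not None:
        res.t_exo = exo.temperature
    else:
        res.diagnostics.append("exotherm: no peak above prominence threshold")

    try:
        endo = detect_endotherm(u, exo, cfg.search_min_endo,
                                cfg.prominence_frac, cfg.prominence_window)
        res.t_endo = endo.temperature
    except DetectionError as exc:
        res.diagnostics.append(f"endotherm: {exc}")
        return res

    try:
        res.first_line = fit_first_line(u, res.t_endo, cfg.band_width_first,
                                        cfg.band_start)
        res.second_line = fit_second_line(u, res.first_line, res.t_endo,
                                          cfg.band_width_second)
        res.t_init = intersect_lines(res.first_line, res.second_line,
                                     cfg.slope_tol)
    except (ValueError, DetectionError, DegeneracyError) as exc:
        res.diagnostics.append(f"line fit: {exc}")
        return res

    if not 25.0 <= res.t_init <= 65.0:
        res.diagnostics.append(
            f"t_init {res.t_init:.2f} °C outside the protocol window")
    if res.complete and not res.ordered:
        res.diagnostics.append("threshold ordering t_init < t_endo < t_exo violated")
    return res
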