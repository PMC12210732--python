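"""Synthetic curve generators with attached ground truth.

Each generator is a pure function of its truth record (which includes the
seed), producing the same curve on every call.  Shapes mimic the measured
curve classes:

* vital thermogram — continuous two-segment linear decline (breakpoint =
  the T_init ground truth) minus a Gaussian endotherm dip plus a Gaussian
  exotherm peak, plus homoscedastic Gaussian noise;
* reheat thermogram — a single noisy line, no dip/peak;
* T-F0 curve — flat baseline to the T_c truth, linear rise to a peak at
  T_p, decline to a plateau, optional second Gaussian peak at T_pII;
* viability assay — replicate Fv/Fm drawn around the damage sigmoid,
  clipped to [0, 1].

Because the dip/peak Gaussians sit on a sloped baseline, the extrema of
the composite analytic shape are displaced slightly from the Gaussian
centers; the displaced positions are exposed as ``t_endo_true`` /
``t_exo_true`` and are the reference for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .heat_tolerance import damage_sigmoid
from .thermo_io import F0Curve, Thermogram, ViabilityAssay, uniform_grid

DEFAULT_GRID_STEP = 0.1
DEFAULT_SPAN = (25.0, 65.0)


def _gauss(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermogramTruth:
    """Ground truth for a vital DSC curve (normalized units, mW g⁻¹).

    Defaults place the breakpoint, dip and peak inside the ranges reported
    for summer-active mountain-plant leaves (breakpoint ≈ 52 °C, endotherm
    ≈ 57.5 °C, exotherm ≈ 60.5 °C).
    """

    baseline_intercept: float = 0.0    # mW g-1 at t_min
    baseline_slope: float = -0.5       # mW g-1 K-1
    breakpoint: float = 52.0           # °C — the T_init ground truth
    post_slope: float = -3.0           # mW g-1 K-1
    endo_center: float = 57.5          # °C
    endo_depth: float = 30.0           # mW g-1
    endo_width: float = 0.6            # K
    exo_center: float = 60.5           # °C
    exo_height: float = 25.0           # mW g-1
    exo_width: float = 0.8             # K
    noise_sd: float = 0.5              # mW g-1 (2 % of the exotherm height)
    seed: int = 0
    fresh_mass: float = 20.0           # mg
    t_min: float = DEFAULT_SPAN[0]
    t_max: float = DEFAULT_SPAN[1]
    grid_step: float = DEFAULT_GRID_STEP
    ramp_rate: float = 1.0             # K min-1

    def __post_init__(self):
        if not self.t_min < self.breakpoint < self.endo_center < self.exo_center < self.t_max:
            raise ValueError("require t_min < breakpoint < endo_center < "
                             "exo_center < t_max")
        if self.endo_width <= 0 or self.exo_width <= 0:
            raise ValueError("peak widths must be positive")
        if self.endo_depth < 0 or self.exo_height < 0:
            raise ValueError("endo_depth and exo_height must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fresh_mass <= 0:
            raise ValueError("fresh_mass must be positive")

    def analytic_shape(self, t):
        """Noise-free normalized heat flow at temperature ``t``."""
        t = np.asarray(t, dtype=float)
        base = self.baseline_intercept + self.baseline_slope * (t - self.t_min)
        y_bp = (self.baseline_intercept
                + self.baseline_slope * (self.breakpoint - self.t_min))
        after = y_bp + self.post_slope * (t - self.breakpoint)
        y = np.where(t <= self.breakpoint, base, after)
        y = y - self.endo_depth * _gauss(t, self.endo_center, self.endo_width)
        y = y + self.exo_height * _gauss(t, self.exo_center, self.exo_width)
        return y

    @property
    def t_endo_true(self) -> float:
        """Location of the analytic minimum near the endotherm center."""
        w = self.endo_width
        res = optimize.minimize_scalar(
            lambda t: self.analytic_shape(float(t)),
            bounds=(self.endo_center - 2 * w, self.endo_center + 2 * w),
            method="bounded", options={"xatol": 1e-10})
        return float(res.x)

    @property
    def t_exo_true(self) -> float:
        """Location of the analytic maximum near the exotherm center."""
        w = self.exo_width
        res = optimize.minimize_scalar(
            lambda t: -self.analytic_shape(float(t)),
            bounds=(self.exo_center - 2 * w, self.exo_center + 2 * w),
            method="bounded", options={"xatol": 1e-10})
        return float(res.x)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_thermogram(truth: ThermogramTruth | None = None, *,
                        sample_id: str = "synthetic", species: str = "",
                        as_normalized: bool = False
                        ) -> tuple[Thermogram, ThermogramTruth]:
    """Generate a vital DSC curve from its ground truth.

    With ``as_normalized=False`` (default) the returned heat flow is raw
    mW (the normalized shape multiplied by the fresh mass in grams), so
    the full pipeline including normalization is exercised; with
    ``as_normalized=True`` the heat flow equals the analytic shape plus
    noise bit-exactly.
    """
    truth = truth or ThermogramTruth()
    grid = uniform_grid(truth.t_min, truth.t_max, truth.grid_step)
    rng = np.random.default_rng(truth.seed)
    y = truth.analytic_shape(grid)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=grid.size)
    if not as_normalized:
        y = y * (truth.fresh_mass / 1000.0)
    t = Thermogram(sample_id=sample_id, species=species,
                   fresh_mass=truth.fresh_mass,
                   time=(grid - truth.t_min) / truth.ramp_rate,
                   temperature=grid, heat_flow=y,
                   normalized=as_normalized, run_kind="initial")
    return t, truth


@dataclass(frozen=True)
class ReheatTruth:
    """Ground truth for a reheated (heat-killed) curve: one noisy line."""

    intercept: float = -2.0       # mW g-1 at t_min
    slope: float = -0.6           # mW g-1 K-1
    noise_sd: float = 0.1
    seed: int = 0
    fresh_mass: float = 20.0      # mg
    t_min: float = DEFAULT_SPAN[0]
    t_max: float = DEFAULT_SPAN[1]
    grid_step: float = DEFAULT_GRID_STEP
    ramp_rate: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.fresh_mass <= 0:
            raise ValueError("invalid reheat truth")

    def analytic_shape(self, t):
        t = np.asarray(t, dtype=float)
        return self.intercept + self.slope * (t - self.t_min)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_reheat_thermogram(truth: ReheatTruth | None = None, *,
                               sample_id: str = "synthetic-reheat",
                               species: str = "",
                               as_normalized: bool = False
                               ) -> tuple[Thermogram, ReheatTruth]:
    """Generate a heat-killed-type curve: linear decline, no dip/peak."""
    truth = truth or ReheatTruth()
    grid = uniform_grid(truth.t_min, truth.t_max, truth.grid_step)
    rng = np.random.default_rng(truth.seed)
    y = truth.analytic_shape(grid)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=grid.size)
    if not as_normalized:
        y = y * (truth.fresh_mass / 1000.0)
    t = Thermogram(sample_id=sample_id, species=species,
                   fresh_mass=truth.fresh_mass,
                   time=(grid - truth.t_min) / truth.ramp_rate,
                   temperature=grid, heat_flow=y,
                   normalized=as_normalized, run_kind="reheat")
    return t, truth


# ---------------------------------------------------------------------------
# T-F0 curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class F0Truth:
    """Ground truth for a T-F0 curve.

    Envelope: flat at ``baseline`` until ``t_c``; linear rise at
    ``rise_slope`` to the first peak at ``t_p``; decline at ``fall_slope``
    down to ``valley_level`` (then flat); plus an optional Gaussian second
    peak at ``t_pII``.
    """

    baseline: float = 100.0        # relative fluorescence units
    t_c: float = 43.0              # °C
    rise_slope: float = 40.0       # units K-1
    t_p: float = 52.0              # °C
    fall_slope: float = 60.0       # units K-1, magnitude
    valley_level: float = 250.0    # units
    t_pII: float | None = 58.5     # °C; None omits the second peak
    pII_height: float = 120.0      # units
    pII_width: float = 1.0         # K
    noise_sd: float = 0.0          # units
    seed: int = 0
    t_min: float = DEFAULT_SPAN[0]
    t_max: float = DEFAULT_SPAN[1]
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self):
        if not self.t_min < self.t_c < self.t_p < self.t_max:
            raise ValueError("require t_min < t_c < t_p < t_max")
        if self.t_pII is not None and not self.t_p < self.t_pII < self.t_max:
            raise ValueError("t_pII must lie in (t_p, t_max)")
        if self.rise_slope <= 0 or self.fall_slope <= 0:
            raise ValueError("rise_slope and fall_slope must be positive")
        if self.pII_width <= 0 or self.noise_sd < 0:
            raise ValueError("invalid width or noise")
        if self.valley_level >= self.peak_level:
            raise ValueError("valley_level must lie below the first peak")

    @property
    def peak_level(self) -> float:
        return self.baseline + self.rise_slope * (self.t_p - self.t_c)

    def analytic_shape(self, t):
        t = np.asarray(t, dtype=float)
        rise = self.baseline + self.rise_slope * (t - self.t_c)
        fall = np.maximum(self.valley_level,
                          self.peak_level - self.fall_slope * (t - self.t_p))
        y = np.where(t <= self.t_c, self.baseline,
                     np.where(t <= self.t_p, rise, fall))
        if self.t_pII is not None:
            y = y + self.pII_height * _gauss(t, self.t_pII, self.pII_width)
        return y

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_f0_curve(truth: F0Truth | None = None, *,
                      sample_id: str = "synthetic-f0", species: str = ""
                      ) -> tuple[F0Curve, F0Truth]:
    truth = truth or F0Truth()
    grid = uniform_grid(truth.t_min, truth.t_max, truth.grid_step)
    rng = np.random.default_rng(truth.seed)
    y = truth.analytic_shape(grid)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=grid.size)
    y = np.maximum(y, 0.0)
    return F0Curve(sample_id=sample_id, species=species,
                   temperature=grid, f0=y), truth


# ---------------------------------------------------------------------------
# viability assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayTruth:
    """Ground truth for a heat-tolerance assay: the sigmoid parameters,
    the target-temperature design and the replicate noise.

    The default design uses ten targets from 38 to 56 °C in 2 K steps plus
    a 65 °C full-damage sample and an unheated control.
    """

    a1: float = 0.8
    a2: float = 0.05
    x0: float = 50.0               # °C — the LT_50 ground truth
    p: float = 40.0
    temperatures: tuple[float, ...] = tuple(float(t) for t in range(38, 57, 2))
    replicates: int = 8
    noise_sd: float = 0.03
    seed: int = 0
    include_control: bool = True
    include_full_damage: bool = True
    full_damage_temp: float = 65.0

    def __post_init__(self):
        if not 0 <= self.a2 < self.a1 <= 1:
            raise ValueError("require 0 <= a2 < a1 <= 1")
        if self.p <= 0 or self.x0 <= 0:
            raise ValueError("p and x0 must be positive")
        if len(self.temperatures) < 2 or self.replicates < 1:
            raise ValueError("need >= 2 temperatures and >= 1 replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def expected(self, t):
        return damage_sigmoid(t, self.a1, self.a2, self.x0, self.p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["temperatures"] = list(self.temperatures)
        return d


def generate_viability_assay(truth: AssayTruth | None = None, *,
                             species: str = ""
                             ) -> tuple[ViabilityAssay, AssayTruth]:
    """Replicate Fv/Fm drawn around the damage sigmoid, clipped to [0, 1]."""
    truth = truth or AssayTruth()
    temps = list(truth.temperatures)
    if truth.include_full_damage:
        temps = temps + [truth.full_damage_temp]
    rng = np.random.default_rng(truth.seed)
    t_col, y_col, rep_col = [], [], []
    for t in temps:
        mu = float(truth.expected(t))
        draws = np.full(truth.replicates, mu)
        if truth.noise_sd > 0:
            draws = draws + rng.normal(0.0, truth.noise_sd, size=truth.replicates)
        draws = np.clip(draws, 0.0, 1.0)
        t_col.extend([t] * truth.replicates)
        y_col.extend(draws.tolist())
        rep_col.extend(range(1, truth.replicates + 1))
    control = float(np.clip(truth.a1, 0.0, 1.0)) if truth.include_control else None
    assay = ViabilityAssay(temperature=np.array(t_col), fvfm=np.array(y_col),
                           replicate=np.array(rep_col), control_fvfm=control,
                           species=species)
    return assay, truth
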