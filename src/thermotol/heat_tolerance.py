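"""Classical heat-tolerance analysis: sigmoid damage-curve fitting,
LT_10/LT_50 derivation and the 3-sample bootstrap.

The damage model is the four-parameter dose-response curve

    y(x) = A2 + (A1 - A2) / (1 + (x / x0)^p)

with y the viability score (Fv/Fm), x the target temperature, x0 the
inflection (LT_50), A1/A2 the upper/lower asymptotes and p the slope
parameter.  LT_d, the temperature causing a damage fraction d of the
curve's span, inverts the model in closed form:

    LT_d = x0 * (d / (1 - d))^(1/p)

Bootstrap: per repetition, ``per_temp`` replicates are drawn at every
target temperature (without replacement by default), the curve is refit,
and LT_10/LT_50 recorded; repeated ``reps`` times (250 in the reference
protocol, with 3 samples per temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import BootstrapError, DomainError, FitError
from .thermo_io import ViabilityAssay

_P_MAX = 500.0
_X0_MARGIN = 10.0  # K beyond the data span allowed for the inflection


def damage_sigmoid(x, a1: float, a2: float, x0: float, p: float):
    """Evaluate the damage curve at temperature ``x`` (°C, > 0).

    Computed in log space, ``(x/x0)^p = exp(p (ln x - ln x0))``, which is
    stable for large ``p``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("temperature must be positive")
    if x0 <= 0:
        raise DomainError("x0 must be positive")
    if not np.isfinite(p):
        raise DomainError("p must be finite")
    z = np.clip(p * (np.log(x) - np.log(x0)), -700.0, 700.0)
    return a2 + (a1 - a2) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SigmoidFit:
    a1: float            # upper asymptote (undamaged response)
    a2: float            # lower asymptote (full damage)
    x0: float            # °C, inflection = LT_50
    p: float             # slope parameter
    residual_sse: float
    converged: bool
    n_obs: int

    @property
    def degenerate(self) -> bool:
        """Flat curve: the two asymptotes collapse."""
        return abs(self.a1 - self.a2) < 1e-6

    def predict(self, x):
        return damage_sigmoid(x, self.a1, self.a2, self.x0, self.p)


def _fit_arrays(temps: np.ndarray, y: np.ndarray,
                init: tuple[float, float, float, float] | None = None) -> SigmoidFit:
    distinct = np.unique(temps)
    if distinct.size < 4:
        raise ValueError(f"sigmoid fit needs >= 4 distinct temperatures, "
                         f"got {distinct.size}")
    if init is None:
        a1_0, a2_0 = float(y.max()), float(y.min())
        mid = 0.5 * (a1_0 + a2_0)
        means = np.array([y[temps == t].mean() for t in distinct])
        x0_0 = float(distinct[np.argmin(np.abs(means - mid))])
        init = (a1_0, a2_0, x0_0, 30.0)
    lb = np.array([0.0, 0.0, distinct.min() - _X0_MARGIN, 1e-3])
    ub = np.array([2.0, 2.0, distinct.max() + _X0_MARGIN, _P_MAX])
    x_init = np.clip(np.asarray(init, dtype=float), lb + 1e-12, ub - 1e-12)

    def resid(theta):
        return damage_sigmoid(temps, *theta) - y

    res = optimize.least_squares(resid, x_init, bounds=(lb, ub), method="trf",
                                 xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                 max_nfev=5000)
    if not res.success:
        raise FitError(f"sigmoid fit did not converge: {res.message}",
                       diagnostics={"status": res.status, "nfev": res.nfev,
                                    "cost": float(res.cost)})
    a1, a2, x0, p = (float(v) for v in res.x)
    return SigmoidFit(a1=a1, a2=a2, x0=x0, p=p,
                      residual_sse=float(2.0 * res.cost), converged=True,
                      n_obs=int(y.size))


def fit_sigmoid(assay: ViabilityAssay,
                init: tuple[float, float, float, float] | None = None) -> SigmoidFit:
    """Nonlinear least-squares fit of the damage curve to an assay table.

    Default initialization: A1 = max response, A2 = min response, x0 = the
    target temperature whose mean response is nearest mid-span, p = 30.
    Bounds: A1, A2 in [0, 2]; x0 within the data span ± 10 K; p in (0, 500].
    """
    return _fit_arrays(assay.temperature, assay.fvfm, init)


def lt_from_fit(fit: SigmoidFit, damage_fraction: float) -> float:
    """Temperature causing damage fraction ``d`` of the fitted span.

    Inverts the damage curve at ``y = A1 - d (A1 - A2)`` in closed form;
    ``d = 0.5`` returns ``x0`` exactly.
    """
    d = damage_fraction
    if not 0.0 < d < 1.0:
        raise DomainError(f"damage fraction must be in (0, 1), got {d}")
    if not fit.converged:
        raise ValueError("cannot derive LT from a non-converged fit")
    if fit.p <= 0:
        raise ValueError(f"LT requires p > 0, got {fit.p}")
    if fit.a1 <= fit.a2:
        raise ValueError("LT requires a decreasing damage curve (A1 > A2)")
    return float(fit.x0 * (d / (1.0 - d)) ** (1.0 / fit.p))


@dataclass
class LTResult:
    lt10: float                    # °C, from the all-data point fit
    lt50: float                    # °C
    point_fit: SigmoidFit
    bootstrap_lt10: np.ndarray     # length reps; NaN marks failed fits
    bootstrap_lt50: np.ndarray
    ci95_lt10: tuple[float, float]
    ci95_lt50: tuple[float, float]
    seed: int | None
    n_failed: int
    reps: int
    per_temp: int

    @property
    def bootstrap_median_lt50(self) -> float:
        return float(np.nanmedian(self.bootstrap_lt50))

    @property
    def bootstrap_mean_lt50(self) -> float:
        return float(np.nanmean(self.bootstrap_lt50))

    @property
    def bootstrap_median_lt10(self) -> float:
        return float(np.nanmedian(self.bootstrap_lt10))

    @property
    def bootstrap_mean_lt10(self) -> float:
        return float(np.nanmean(self.bootstrap_lt10))


def bootstrap_lt(assay: ViabilityAssay, per_temp: int = 3, reps: int = 250,
                 seed: int | None = None, replace: bool = False,
                 damage_fractions: tuple[float, float] = (0.1, 0.5)) -> LTResult:
    """Resampling bootstrap of LT_10/LT_50.

    Each repetition draws ``per_temp`` replicates per target temperature
    (without replacement by default), refits the sigmoid and records the
    LT values.  Failed fits are stored as NaN and excluded from the
    percentile CIs; more than 50 % failures aborts.  Fully reproducible
    from ``seed``.
    """
    temps = assay.temperature
    y = assay.fvfm
    groups = [np.flatnonzero(temps == t) for t in assay.distinct_temperatures]
    if not replace:
        for g, t in zip(groups, assay.distinct_temperatures):
            if g.size < per_temp:
                raise ValueError(
                    f"temperature {t} °C has {g.size} replicates; "
                    f"{per_temp} needed for sampling without replacement")

    point = fit_sigmoid(assay)
    d_lo, d_hi = damage_fractions
    lt_lo_point = lt_from_fit(point, d_lo)
    lt_hi_point = lt_from_fit(point, d_hi)

    rng = np.random.default_rng(seed)
    boot_lo = np.full(reps, np.nan)
    boot_hi = np.full(reps, np.nan)
    n_failed = 0
    for r in range(reps):
        idx = np.concatenate([rng.choice(g, size=per_temp, replace=replace)
                              for g in groups])
        try:
            fit = _fit_arrays(temps[idx], y[idx])
            boot_lo[r] = lt_from_fit(fit, d_lo)
            boot_hi[r] = lt_from_fit(fit, d_hi)
        except (FitError, ValueError):
            n_failed += 1
    if n_failed > reps / 2:
        raise BootstrapError(
            f"{n_failed}/{reps} bootstrap repetitions failed to fit")

    def ci(a):
        ok = a[np.isfinite(a)]
        return (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))

    return LTResult(lt10=lt_lo_point, lt50=lt_hi_point, point_fit=point,
                    bootstrap_lt10=boot_lo, bootstrap_lt50=boot_hi,
                    ci95_lt10=ci(boot_lo), ci95_lt50=ci(boot_hi),
                    seed=seed, n_failed=n_failed, reps=reps, per_temp=per_temp)
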