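"""Curve data model, file I/O, normalization, resampling and aggregation.

Three curve/table types are handled:

* :class:`Thermogram` — a DSC trace (time, sample temperature, heat flow)
  for one leaf, with the leaf's fresh mass so heat flow can be normalized
  to mW per gram fresh weight.
* :class:`F0Curve` — basic chlorophyll fluorescence recorded against leaf
  temperature during a constant-rate ramp.
* :class:`ViabilityAssay` — a target-temperature × replicate Fv/Fm table
  from the classical heat-tolerance test.

Files are delimited text (comma or tab, auto-detected) with a header row.
Readers validate structural invariants and trim thermograms to the
protocol window (25–65 °C by default); writers emit full-precision text so
that read → write → read round-trips bit-identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, StateError

#: Observed fresh-mass range (mg) of leaf material in the reference protocol.
#: A soft plausibility check only — masses outside it trigger a warning.
MASS_RANGE_MG = (9.40, 33.46)

#: Protocol temperature window (°C) for trimming thermograms.
PROTOCOL_WINDOW = (25.0, 65.0)

_TIME_ALIASES = ("time", "t", "time_min", "minutes")
_TEMP_ALIASES = ("temperature", "temp", "sample_temperature", "t_sample", "temperature_c")
_FLOW_ALIASES = ("heat_flow", "heatflow", "flow", "heat_flow_mw", "hf")
_F0_ALIASES = ("f0", "fluorescence", "basic_fluorescence", "f_0")
_FVFM_ALIASES = ("fvfm", "fv_fm", "fv/fm", "response")
_REPL_ALIASES = ("replicate", "replicate_id", "rep", "sample")


# ---------------------------------------------------------------------------
# temperature program model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RampSegment:
    """One constant-rate segment of a temperature program."""

    start_temp: float  # °C
    end_temp: float    # °C
    rate: float        # K min-1, magnitude of the ramp rate

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("ramp rate must be positive")

    @property
    def duration_min(self) -> float:
        return abs(self.end_temp - self.start_temp) / self.rate


@dataclass(frozen=True)
class TemperatureProgram:
    """A sequence of ramp segments applied to one sample."""

    segments: tuple[RampSegment, ...]

    @classmethod
    def dsc_two_run(cls, start: float = 25.0, end: float = 65.0,
                    rate: float = 1.0, runs: int = 2) -> "TemperatureProgram":
        """The standard DSC protocol: heat ``start``→``end`` at ``rate``,
        cool back, and repeat for each run (the second run reheats the
        heat-killed sample under identical conditions)."""
        segs = []
        for _ in range(runs):
            segs.append(RampSegment(start, end, rate))
            segs.append(RampSegment(end, start, rate))
        return cls(tuple(segs))

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.segments)


# ---------------------------------------------------------------------------
# curve types
# ---------------------------------------------------------------------------

@dataclass
class Thermogram:
    """One leaf's DSC trace.

    ``heat_flow`` is in mW while ``normalized`` is False and in mW g⁻¹
    fresh weight afterwards.  ``run_kind`` distinguishes the initial
    heating of the vital leaf from the reheat of the heat-killed one.
    """

    sample_id: str
    species: str
    fresh_mass: float                 # mg
    time: np.ndarray                  # min
    temperature: np.ndarray           # °C
    heat_flow: np.ndarray             # mW or mW g-1
    normalized: bool = False
    run_kind: str = "initial"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.fresh_mass <= 0:
            raise ValueError(f"fresh_mass must be > 0 mg, got {self.fresh_mass}")
        if self.temperature.size == 0:
            raise DataError("thermogram has no points")
        if not (self.time.shape == self.temperature.shape == self.heat_flow.shape):
            raise DataError("time, temperature and heat_flow differ in length")
        if np.any(np.diff(self.temperature) <= 0):
            raise DataError("temperature must be strictly increasing after preprocessing")
        if self.run_kind not in ("initial", "reheat"):
            raise ValueError(f"run_kind must be 'initial' or 'reheat', got {self.run_kind!r}")

    @property
    def n_points(self) -> int:
        return int(self.temperature.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temperature[0]), float(self.temperature[-1])


@dataclass
class F0Curve:
    """Basic chlorophyll fluorescence against leaf temperature."""

    sample_id: str
    temperature: np.ndarray  # °C
    f0: np.ndarray           # relative fluorescence units
    species: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.temperature.size == 0:
            raise DataError("F0 curve has no points")
        if self.temperature.shape != self.f0.shape:
            raise DataError("temperature and F0 differ in length")
        if np.any(np.diff(self.temperature) <= 0):
            raise DataError("temperature must be strictly increasing")
        if np.any(self.f0 < 0):
            raise DataError("F0 must be non-negative")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temperature[0]), float(self.temperature[-1])


@dataclass
class ViabilityAssay:
    """Target-temperature × replicate Fv/Fm table from the heat test."""

    temperature: np.ndarray        # °C, one entry per record
    fvfm: np.ndarray               # dimensionless, [0, 1]
    replicate: np.ndarray          # replicate identifiers
    control_fvfm: float | None = None  # unheated reference, optional
    species: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fvfm = np.asarray(self.fvfm, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.temperature.shape != self.fvfm.shape:
            raise DataError("temperature and fvfm differ in length")
        if self.replicate.shape != self.temperature.shape:
            raise DataError("replicate and temperature differ in length")
        if np.any((self.fvfm < 0) | (self.fvfm > 1)):
            raise DataError("Fv/Fm values must lie in [0, 1]")
        if self.control_fvfm is not None and not 0 <= self.control_fvfm <= 1:
            raise DataError("control Fv/Fm must lie in [0, 1]")
        if np.unique(self.temperature).size < 2:
            raise DataError("at least 2 distinct target temperatures are required")

    @property
    def distinct_temperatures(self) -> np.ndarray:
        return np.unique(self.temperature)


@dataclass
class AggregateCurve:
    """Per-temperature mean ± sd of normalized heat flow across leaves."""

    temperature: np.ndarray  # rounded grid, °C
    mean: np.ndarray
    sd: np.ndarray           # NaN where n < 2
    n: np.ndarray

    def __post_init__(self):
        if np.any(self.n < 1):
            raise DataError("every aggregate bin must contain at least one value")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text file, auto-detecting comma vs tab.

    Uses the C parser with round-trip float precision so that values
    written by this package read back bit-identically.
    """
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _find_column(df: pd.DataFrame, aliases: Sequence[str], what: str,
                 path, required: bool = True) -> str | None:
    for name in aliases:
        if name in df.columns:
            return name
    if required:
        raise FormatError(
            f"{path}: no column for {what}; expected one of {list(aliases)}, "
            f"found {list(df.columns)}")
    return None


def read_thermogram(path: str | Path, fresh_mass: float, *,
                    sample_id: str | None = None, species: str = "",
                    run_kind: str = "initial", endo_up: bool = False,
                    window: tuple[float, float] = PROTOCOL_WINDOW,
                    columns: dict[str, str] | None = None) -> Thermogram:
    """Read a DSC trace from delimited text.

    Parameters
    ----------
    path:
        Delimited text file with header; columns mappable to
        time / temperature / heat flow (configurable via ``columns``).
    fresh_mass:
        Fresh mass of the leaf piece in mg.  Must be positive; values
        outside the observed plausibility range trigger a warning only.
    endo_up:
        If True the instrument records endothermic-positive heat flow and
        the sign is flipped on read; the package convention is exo-up.
    window:
        Protocol temperature window; points outside are trimmed.
    """
    if fresh_mass <= 0:
        raise ValueError(f"fresh_mass must be > 0 mg, got {fresh_mass}")
    if not MASS_RANGE_MG[0] <= fresh_mass <= MASS_RANGE_MG[1]:
        warnings.warn(
            f"fresh mass {fresh_mass} mg outside the plausible range "
            f"{MASS_RANGE_MG[0]}-{MASS_RANGE_MG[1]} mg", UserWarning, stacklevel=2)

    df = _read_table(path)
    colmap = {k: v.lower() for k, v in (columns or {}).items()}
    tcol = colmap.get("time") or _find_column(df, _TIME_ALIASES, "time", path)
    ccol = colmap.get("temperature") or _find_column(df, _TEMP_ALIASES, "temperature", path)
    fcol = colmap.get("heat_flow") or _find_column(df, _FLOW_ALIASES, "heat flow", path)
    for c in (tcol, ccol, fcol):
        if c not in df.columns:
            raise FormatError(f"{path}: configured column {c!r} not present")

    df = df[[tcol, ccol, fcol]].dropna().sort_values(tcol, kind="mergesort")
    # collapse exact duplicate temperatures (instrument oversampling)
    df = df.drop_duplicates(subset=ccol, keep="first")
    lo, hi = window
    df = df[(df[ccol] >= lo) & (df[ccol] <= hi)]
    if df.empty:
        raise DataError(f"{path}: no points inside the {lo}-{hi} °C window")

    flow = df[fcol].to_numpy(dtype=float)
    if endo_up:
        flow = -flow
    return Thermogram(
        sample_id=sample_id or Path(path).stem,
        species=species,
        fresh_mass=float(fresh_mass),
        time=df[tcol].to_numpy(dtype=float),
        temperature=df[ccol].to_numpy(dtype=float),
        heat_flow=flow,
        normalized=False,
        run_kind=run_kind,
    )


def read_f0_curve(path: str | Path, *, sample_id: str | None = None,
                  species: str = "",
                  columns: dict[str, str] | None = None) -> F0Curve:
    """Read an F0-vs-leaf-temperature curve from delimited text."""
    df = _read_table(path)
    colmap = {k: v.lower() for k, v in (columns or {}).items()}
    ccol = colmap.get("temperature") or _find_column(df, _TEMP_ALIASES, "temperature", path)
    fcol = colmap.get("f0") or _find_column(df, _F0_ALIASES, "F0", path)
    df = df[[ccol, fcol]].dropna().sort_values(ccol, kind="mergesort")
    df = df.drop_duplicates(subset=ccol, keep="first")
    return F0Curve(sample_id=sample_id or Path(path).stem, species=species,
                   temperature=df[ccol].to_numpy(dtype=float),
                   f0=df[fcol].to_numpy(dtype=float))


def read_viability_table(path: str | Path, *, species: str = "",
                         control_fvfm: float | None = None,
                         columns: dict[str, str] | None = None) -> ViabilityAssay:
    """Read a target-temperature × replicate Fv/Fm table."""
    df = _read_table(path)
    colmap = {k: v.lower() for k, v in (columns or {}).items()}
    ccol = colmap.get("temperature") or _find_column(df, _TEMP_ALIASES, "temperature", path)
    vcol = colmap.get("fvfm") or _find_column(df, _FVFM_ALIASES, "Fv/Fm", path)
    rcol = colmap.get("replicate") or _find_column(df, _REPL_ALIASES, "replicate",
                                                  path, required=False)
    df = df.dropna(subset=[ccol, vcol])
    if rcol is None:
        rep = df.groupby(ccol).cumcount().to_numpy()
    else:
        rep = df[rcol].to_numpy()
    fvfm = df[vcol].to_numpy(dtype=float)
    if np.any((fvfm < 0) | (fvfm > 1)):
        bad = fvfm[(fvfm < 0) | (fvfm > 1)][0]
        raise DataError(f"{path}: Fv/Fm value {bad} outside [0, 1]")
    return ViabilityAssay(temperature=df[ccol].to_numpy(dtype=float),
                          fvfm=fvfm, replicate=rep,
                          control_fvfm=control_fvfm, species=species)


# ---------------------------------------------------------------------------
# writers (full precision: read → write → read round-trips bit-identically)
# ---------------------------------------------------------------------------

def write_thermogram(t: Thermogram, path: str | Path) -> None:
    pd.DataFrame({"time": t.time, "temperature": t.temperature,
                  "heat_flow": t.heat_flow}).to_csv(path, index=False)


def write_f0_curve(c: F0Curve, path: str | Path) -> None:
    pd.DataFrame({"temperature": c.temperature, "f0": c.f0}).to_csv(path, index=False)


def write_viability_table(a: ViabilityAssay, path: str | Path) -> None:
    pd.DataFrame({"temperature": a.temperature, "replicate": a.replicate,
                  "fvfm": a.fvfm}).to_csv(path, index=False)


def write_aggregate(a: AggregateCurve, path: str | Path, *,
                    formatted: bool = False) -> None:
    """Write an aggregate curve; ``formatted=True`` rounds temperatures to 2
    decimals and flows to 4 significant digits for report output."""
    df = pd.DataFrame({"temperature": a.temperature, "mean": a.mean,
                       "sd": a.sd, "n": a.n})
    if formatted:
        df["temperature"] = df["temperature"].round(2)
        for col in ("mean", "sd"):
            df[col] = df[col].map(
                lambda v: float(f"{v:.4g}") if np.isfinite(v) else v)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def normalize_heat_flow(t: Thermogram) -> Thermogram:
    """Divide heat flow (mW) by fresh mass expressed in grams → mW g⁻¹."""
    if t.normalized:
        raise StateError(f"thermogram {t.sample_id!r} is already normalized")
    mass_g = t.fresh_mass / 1000.0
    return replace(t, heat_flow=t.heat_flow / mass_g, normalized=True)


def uniform_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Uniform grid of multiples of ``step`` covering [lo, hi] from the
    inside: ceil(lo) to floor(hi) in units of the step."""
    i0 = math.ceil(lo / step - 1e-9)
    i1 = math.floor(hi / step + 1e-9)
    return np.arange(i0, i1 + 1) * step


def resample_uniform(t: Thermogram, step: float = 0.1) -> Thermogram:
    """Linearly interpolate heat flow onto a uniform temperature grid.

    The grid runs from ``ceil(min T)`` to ``floor(max T)`` in steps of
    ``step`` K; values at grid points coinciding with input points are
    preserved.  Time is interpolated on the same grid.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = t.span
    if step > hi - lo:
        raise ValueError(f"step {step} K exceeds the curve span {hi - lo:.3g} K")
    grid = uniform_grid(lo, hi, step)
    if grid.size < 2:
        raise ValueError("resampling grid would contain fewer than 2 points")
    return replace(t,
                   time=np.interp(grid, t.temperature, t.time),
                   temperature=grid,
                   heat_flow=np.interp(grid, t.temperature, t.heat_flow))


def aggregate_curves(curves: Sequence[Thermogram], rounding: int = 1) -> AggregateCurve:
    """Pool normalized curves by temperature rounded to ``rounding`` decimals.

    Per bin: mean, sample sd (n−1 denominator; NaN where n < 2) and n of
    the normalized heat flow across curves.  Bins with no data are omitted.
    """
    if len(curves) == 0:
        raise ValueError("aggregate_curves requires at least one curve")
    frames = []
    for c in curves:
        if not c.normalized:
            raise StateError(f"curve {c.sample_id!r} must be normalized before pooling")
        frames.append(pd.DataFrame({
            "bin": np.round(c.temperature, rounding), "flow": c.heat_flow}))
    pooled = pd.concat(frames, ignore_index=True)
    g = pooled.groupby("bin")["flow"].agg(["mean", "std", "count"]).sort_index()
    return AggregateCurve(temperature=g.index.to_numpy(dtype=float),
                          mean=g["mean"].to_numpy(),
                          sd=g["std"].to_numpy(),
                          n=g["count"].to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class ManifestEntry:
    sample_id: str
    path: str
    species: str = ""
    fresh_mass: float | None = None   # mg, required for thermograms
    run_kind: str = "initial"


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a YAML run manifest: a list of sample records."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise FormatError(f"{path}: manifest must be a non-empty list of records")
    base = Path(path).parent
    entries = []
    for i, rec in enumerate(raw):
        if "sample_id" not in rec or "path" not in rec:
            raise FormatError(f"{path}: record {i} lacks sample_id/path")
        p = Path(rec["path"])
        if not p.is_absolute():
            p = base / p
        entries.append(ManifestEntry(
            sample_id=str(rec["sample_id"]), path=str(p),
            species=str(rec.get("species", "")),
            fresh_mass=rec.get("fresh_mass"),
            run_kind=str(rec.get("run_kind", "initial"))))
    return entries
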