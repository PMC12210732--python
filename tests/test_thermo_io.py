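import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_thermogram
from thermotol.errors import DataError, FormatError, StateError
from thermotol.thermo_io import (MASS_RANGE_MG, TemperatureProgram, Thermogram,
                                 ViabilityAssay, aggregate_curves,
                                 normalize_heat_flow, read_f0_curve,
                                 read_thermogram, read_viability_table,
                                 resample_uniform, uniform_grid,
                                 write_f0_curve, write_thermogram,
                                 write_viability_table)


class TestTemperatureProgram:
    def test_two_run_protocol_lasts_160_min(self):
        # 25→65→25 °C at 1 K/min, twice (initial run + reheat of the
        # heat-killed sample) = 4 × 40 min
        prog = TemperatureProgram.dsc_two_run(start=25.0, end=65.0, rate=1.0,
                                              runs=2)
        assert prog.total_duration_min == 160.0
        assert len(prog.segments) == 4

    def test_single_cycle(self):
        prog = TemperatureProgram.dsc_two_run(runs=1)
        assert prog.total_duration_min == 80.0

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            TemperatureProgram.dsc_two_run(rate=0.0)


class TestReadThermogram:
    def _write(self, path, df, sep=","):
        df.to_csv(path, index=False, sep=sep)

    def test_pass_through(self, tmp_path):
        p = tmp_path / "curve.csv"
        temps = np.linspace(25, 65, 81)
        df = pd.DataFrame({"time": np.arange(81.0), "temperature": temps,
                           "heat_flow": -0.1 * temps})
        self._write(p, df)
        t = read_thermogram(p, fresh_mass=20.0)
        assert t.n_points == 81
        np.testing.assert_array_equal(t.temperature, temps)
        np.testing.assert_array_equal(t.heat_flow, -0.1 * temps)
        assert not t.normalized and t.run_kind == "initial"

    def test_tab_delimited_autodetected(self, tmp_path):
        p = tmp_path / "curve.tsv"
        df = pd.DataFrame({"time": [0.0, 1, 2], "temperature": [30.0, 31, 32],
                           "heat_flow": [1.0, 2, 3]})
        self._write(p, df, sep="\t")
        t = read_thermogram(p, fresh_mass=20.0)
        assert t.n_points == 3

    def test_decreasing_temperature_is_data_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        self._write(p, pd.DataFrame({"time": [0.0, 1, 2],
                                     "temperature": [30.0, 29.0, 31.0],
                                     "heat_flow": [1.0, 2, 3]}))
        with pytest.raises(DataError):
            read_thermogram(p, fresh_mass=20.0)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        self._write(p, pd.DataFrame({"time": [0.0], "temperature": [30.0]}))
        with pytest.raises(FormatError):
            read_thermogram(p, fresh_mass=20.0)

    def test_small_mass_warns_but_reads(self, tmp_path):
        p = tmp_path / "curve.csv"
        self._write(p, pd.DataFrame({"time": [0.0, 1], "temperature": [30.0, 31],
                                     "heat_flow": [1.0, 2]}))
        with pytest.warns(UserWarning, match="fresh mass"):
            t = read_thermogram(p, fresh_mass=5.0)
        assert t.fresh_mass == 5.0

    def test_mass_in_observed_range_does_not_warn(self, tmp_path):
        p = tmp_path / "curve.csv"
        self._write(p, pd.DataFrame({"time": [0.0, 1], "temperature": [30.0, 31],
                                     "heat_flow": [1.0, 2]}))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            read_thermogram(p, fresh_mass=MASS_RANGE_MG[0])

    def test_nonpositive_mass_is_value_error(self, tmp_path):
        p = tmp_path / "curve.csv"
        self._write(p, pd.DataFrame({"time": [0.0], "temperature": [30.0],
                                     "heat_flow": [1.0]}))
        with pytest.raises(ValueError):
            read_thermogram(p, fresh_mass=0.0)

    def test_trim_to_protocol_window(self, tmp_path):
        p = tmp_path / "curve.csv"
        temps = np.linspace(20, 70, 51)
        self._write(p, pd.DataFrame({"time": np.arange(51.0),
                                     "temperature": temps,
                                     "heat_flow": np.zeros(51)}))
        t = read_thermogram(p, fresh_mass=20.0)
        assert t.temperature.min() >= 25.0
        assert t.temperature.max() <= 65.0

    def test_endo_up_negates(self, tmp_path):
        p = tmp_path / "curve.csv"
        self._write(p, pd.DataFrame({"time": [0.0, 1], "temperature": [30.0, 31],
                                     "heat_flow": [1.0, 2]}))
        t = read_thermogram(p, fresh_mass=20.0, endo_up=True)
        np.testing.assert_array_equal(t.heat_flow, [-1.0, -2.0])


class TestNormalize:
    def test_unit_identity(self):
        t = make_thermogram([30, 31], [2.0, 2.0], mass=1000.0, normalized=False)
        n = normalize_heat_flow(t)
        np.testing.assert_array_equal(n.heat_flow, [2.0, 2.0])
        assert n.normalized

    def test_hand_arithmetic(self):
        # 2 mW / 0.020 g = 100 mW/g
        t = make_thermogram([30, 31], [2.0, 2.0], mass=20.0, normalized=False)
        np.testing.assert_allclose(normalize_heat_flow(t).heat_flow, 100.0)

    def test_double_normalization_guarded(self):
        t = make_thermogram([30, 31], [2.0, 2.0], mass=20.0, normalized=False)
        n = normalize_heat_flow(t)
        with pytest.raises(StateError):
            normalize_heat_flow(n)

    def test_does_not_mutate_input(self):
        t = make_thermogram([30, 31], [2.0, 2.0], mass=20.0, normalized=False)
        normalize_heat_flow(t)
        assert not t.normalized
        np.testing.assert_array_equal(t.heat_flow, [2.0, 2.0])

    @given(c=st.floats(min_value=0.1, max_value=100.0,
                       allow_nan=False, allow_infinity=False))
    @settings(max_examples=30, deadline=None)
    def test_mass_scaling_is_linear(self, c):
        flow = np.array([1.5, -2.0, 3.25])
        t1 = make_thermogram([30, 31, 32], flow, mass=20.0, normalized=False)
        t2 = make_thermogram([30, 31, 32], flow, mass=20.0 * c, normalized=False)
        np.testing.assert_allclose(normalize_heat_flow(t2).heat_flow,
                                   normalize_heat_flow(t1).heat_flow / c,
                                   rtol=1e-12)


class TestResample:
    def test_linear_midpoint(self):
        t = make_thermogram([25.0, 25.2], [0.0, 2.0])
        r = resample_uniform(t, 0.1)
        np.testing.assert_allclose(r.temperature, [25.0, 25.1, 25.2])
        np.testing.assert_allclose(r.heat_flow, [0.0, 1.0, 2.0])

    def test_identity_on_uniform_grid(self):
        g = uniform_grid(25.0, 65.0, 0.1)
        t = make_thermogram(g, np.sin(g))
        r = resample_uniform(t, 0.1)
        np.testing.assert_array_equal(r.temperature, g)
        np.testing.assert_array_equal(r.heat_flow, np.sin(g))

    def test_preserves_coinciding_points(self):
        t = make_thermogram([25.0, 25.1, 25.35, 25.6], [1.0, 4.0, -2.0, 0.5])
        r = resample_uniform(t, 0.1)
        i = np.flatnonzero(np.isclose(r.temperature, 25.1))[0]
        assert r.heat_flow[i] == 4.0

    def test_step_larger_than_span_is_error(self):
        t = make_thermogram(np.linspace(25, 65, 100),
                            np.zeros(100))
        with pytest.raises(ValueError):
            resample_uniform(t, 50.0)


class TestAggregate:
    def test_single_curve(self, grid):
        t = make_thermogram(grid, np.cos(grid))
        a = aggregate_curves([t])
        np.testing.assert_allclose(a.mean, np.cos(grid))
        assert np.all(np.isnan(a.sd))
        assert np.all(a.n == 1)

    def test_two_constant_curves(self, grid):
        c1 = make_thermogram(grid, np.full(grid.size, 1.0))
        c2 = make_thermogram(grid, np.full(grid.size, 3.0))
        a = aggregate_curves([c1, c2])
        np.testing.assert_allclose(a.mean, 2.0)
        np.testing.assert_allclose(a.sd, math.sqrt(2.0))
        assert np.all(a.n == 2)

    def test_identical_curves_sd_zero(self, grid):
        t = make_thermogram(grid, np.sin(grid))
        a = aggregate_curves([t, t, t])
        np.testing.assert_allclose(a.sd, 0.0, atol=1e-13)
        np.testing.assert_allclose(a.mean, np.sin(grid))
        assert np.all(a.n == 3)

    def test_disjoint_ranges_union_bins(self):
        g1 = uniform_grid(25.0, 30.0, 0.1)
        g2 = uniform_grid(40.0, 45.0, 0.1)
        a = aggregate_curves([make_thermogram(g1, np.zeros(g1.size)),
                              make_thermogram(g2, np.ones(g2.size))])
        assert a.temperature.size == g1.size + g2.size
        assert np.all(a.n == 1)

    def test_unnormalized_rejected(self, grid):
        t = make_thermogram(grid, np.zeros(grid.size), normalized=False)
        with pytest.raises(StateError):
            aggregate_curves([t])

    def test_empty_input(self):
        with pytest.raises(ValueError):
            aggregate_curves([])


class TestF0AndViabilityIO:
    def test_f0_round_trip(self, tmp_path):
        p = tmp_path / "f0.csv"
        pd.DataFrame({"temperature": [30.0, 31.5, 33.0],
                      "f0": [100.0, 101.0, 140.0]}).to_csv(p, index=False)
        c = read_f0_curve(p)
        np.testing.assert_array_equal(c.temperature, [30.0, 31.5, 33.0])
        np.testing.assert_array_equal(c.f0, [100.0, 101.0, 140.0])

    def test_fvfm_out_of_range(self, tmp_path):
        p = tmp_path / "v.csv"
        pd.DataFrame({"temperature": [40.0, 42.0], "fvfm": [0.8, 1.3]}
                     ).to_csv(p, index=False)
        with pytest.raises(DataError):
            read_viability_table(p)

    def test_ten_targets_2k_spacing_accepted(self, tmp_path):
        # the reference design: ten targets, 2 K apart, 38-56 °C
        p = tmp_path / "v.csv"
        temps = np.repeat(np.arange(38.0, 57.0, 2.0), 6)
        pd.DataFrame({"temperature": temps,
                      "fvfm": np.linspace(0.8, 0.05, temps.size)}
                     ).to_csv(p, index=False)
        a = read_viability_table(p)
        assert a.distinct_temperatures.size == 10

    def test_viability_needs_two_temperatures(self):
        with pytest.raises(DataError):
            ViabilityAssay(temperature=np.array([40.0, 40.0]),
                           fvfm=np.array([0.5, 0.6]),
                           replicate=np.array([1, 2]))


class TestRoundTrips:
    """read → write → read must round-trip bit-identically."""

    def test_thermogram(self, tmp_path):
        rng = np.random.default_rng(0)
        temps = np.sort(rng.uniform(25, 65, 50))
        t = make_thermogram(temps, rng.normal(size=50), normalized=False)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_thermogram(t, p1)
        t1 = read_thermogram(p1, fresh_mass=t.fresh_mass)
        write_thermogram(t1, p2)
        t2 = read_thermogram(p2, fresh_mass=t.fresh_mass)
        np.testing.assert_array_equal(t1.temperature, t2.temperature)
        np.testing.assert_array_equal(t1.heat_flow, t2.heat_flow)
        np.testing.assert_array_equal(t1.time, t2.time)

    def test_f0(self, tmp_path):
        rng = np.random.default_rng(1)
        from thermotol.thermo_io import F0Curve
        c = F0Curve(sample_id="s", temperature=np.sort(rng.uniform(25, 65, 40)),
                    f0=np.abs(rng.normal(100, 30, 40)))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_f0_curve(c, p1)
        c1 = read_f0_curve(p1)
        write_f0_curve(c1, p2)
        c2 = read_f0_curve(p2)
        np.testing.assert_array_equal(c1.temperature, c2.temperature)
        np.testing.assert_array_equal(c1.f0, c2.f0)

    def test_viability(self, tmp_path):
        rng = np.random.default_rng(2)
        a = ViabilityAssay(temperature=np.repeat([40.0, 44, 48, 52], 3),
                           fvfm=rng.uniform(0, 1, 12),
                           replicate=np.tile([1, 2, 3], 4))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_viability_table(a, p1)
        a1 = read_viability_table(p1)
        write_viability_table(a1, p2)
        a2 = read_viability_table(p2)
        np.testing.assert_array_equal(a1.temperature, a2.temperature)
        np.testing.assert_array_equal(a1.fvfm, a2.fvfm)
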