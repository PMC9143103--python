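import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from mwtrack import (
    FrequencySweep,
    SweepMeasurement,
    TimeTrace,
    build_circular_array,
    group_delay,
    subtract_reference,
    system_fidelity_factor,
    to_time_domain,
)
from mwtrack.array_scene import Scene, simulate_reflection_sweep
from mwtrack.errors import (
    ConfigError,
    IncompatibleMeasurementError,
    UndefinedMetricError,
)


def _measurement(geom, sweep, spectra):
    return SweepMeasurement(geom, sweep, spectra)


class TestToTimeDomain:
    def test_delayed_spectrum_peaks_at_delay(self, geometry16, sweep):
        """Shift theorem: exp(-j*2*pi*f*tau) synthesises a pulse at tau."""
        tau = 1e-9
        spec = np.exp(-2j * np.pi * sweep.frequencies * tau)
        meas = _measurement(geometry16, sweep, np.tile(spec, (16, 1)))
        trace = to_time_domain(meas)[0]
        env = np.abs(hilbert(trace.samples))
        assert abs(env.argmax() / trace.fs - tau) <= 1.0 / trace.fs

    def test_flat_spectrum_no_taper_is_impulse_at_zero(self, geometry16, sweep):
        """With the band filling the grid and no taper the pulse energy
        concentrates at t = 0 (a band-limited impulse)."""
        meas = _measurement(
            geometry16, sweep, np.ones((16, sweep.n_points), dtype=complex)
        )
        trace = to_time_domain(meas, window=None, zero_pad_factor=1)[0]
        assert np.argmax(np.abs(trace.samples)) == 0

    def test_parseval(self, geometry16, sweep, rng):
        spec = rng.standard_normal((16, sweep.n_points)) + 1j * rng.standard_normal(
            (16, sweep.n_points)
        )
        meas = _measurement(geometry16, sweep, spec)
        traces = to_time_domain(meas, window=None, zero_pad_factor=2)
        # energy of the real signal equals (2*band energy)/n_fft (one-sided
        # spectrum, band strictly inside (0, fs/2))
        n_fft = traces[0].samples.size
        for m, tr in enumerate(traces):
            e_spec = 2 * np.sum(np.abs(spec[m]) ** 2) / n_fft
            assert tr.energy == pytest.approx(e_spec, rel=1e-9)

    def test_linearity(self, geometry16, sweep, rng):
        s1 = rng.standard_normal((16, sweep.n_points)) * (1 + 0j)
        s2 = rng.standard_normal((16, sweep.n_points)) * (1 + 0j)
        t1 = to_time_domain(_measurement(geometry16, sweep, s1))[0].samples
        t2 = to_time_domain(_measurement(geometry16, sweep, s2))[0].samples
        t12 = to_time_domain(_measurement(geometry16, sweep, s1 + s2))[0].samples
        assert np.allclose(t12, t1 + t2, atol=1e-12)

    def test_unknown_taper_rejected(self, geometry16, sweep):
        meas = _measurement(geometry16, sweep, np.ones((16, sweep.n_points), complex))
        with pytest.raises(ConfigError):
            to_time_domain(meas, window="not-a-window")

    def test_bad_zero_pad_rejected(self, geometry16, sweep):
        meas = _measurement(geometry16, sweep, np.ones((16, sweep.n_points), complex))
        with pytest.raises(ConfigError):
            to_time_domain(meas, zero_pad_factor=0)


class TestSubtractReference:
    def test_self_subtraction_is_zero(self, point_measurement):
        m = point_measurement([(10, 5, 1.0)])
        assert np.all(subtract_reference(m, m).spectra == 0)

    def test_recovers_added_component(self, geometry16, sweep):
        a = Scene().add_point(0, 0, 1.0)
        b = Scene().add_point(40, -20, 0.5)
        ma = simulate_reflection_sweep(a, geometry16, sweep)
        mab = simulate_reflection_sweep(a.union(b), geometry16, sweep)
        mb = simulate_reflection_sweep(b, geometry16, sweep)
        diff = subtract_reference(mab, ma)
        assert np.allclose(diff.spectra, mb.spectra, rtol=1e-12, atol=1e-13)

    def test_tumor_recovery_from_cranium_scenes(self, geometry16, sweep):
        """Subtracting the cranium-only sweep from cranium+tumor leaves the
        tumor's own spectra (forward-model linearity)."""
        from mwtrack import ellipse_shape, rectangle_shape

        cran = Scene(shapes=[ellipse_shape((0, 0), 64, 85, 0.3)])
        tum = Scene(shapes=[rectangle_shape((0, 26), 25, 25, 1.0)])
        m_cran = simulate_reflection_sweep(cran, geometry16, sweep)
        m_both = simulate_reflection_sweep(cran.union(tum), geometry16, sweep)
        m_tum = simulate_reflection_sweep(tum, geometry16, sweep)
        assert np.allclose(
            subtract_reference(m_both, m_cran).spectra, m_tum.spectra,
            rtol=1e-12, atol=1e-13,
        )

    def test_mismatched_grids_rejected(self, geometry16):
        s1 = FrequencySweep(1.2e9, 5e9, 20)
        s2 = FrequencySweep(1.2e9, 5e9, 21)
        m1 = _measurement(geometry16, s1, np.zeros((16, 20), complex))
        m2 = _measurement(geometry16, s2, np.zeros((16, 21), complex))
        with pytest.raises(IncompatibleMeasurementError):
            subtract_reference(m1, m2)


class TestGroupDelay:
    def test_pure_delay_is_flat(self):
        f = np.linspace(1.2e9, 5e9, 101)
        tau = 1e-9
        gd = group_delay(f, np.exp(-2j * np.pi * f * tau))
        assert np.allclose(gd[1:-1], tau, rtol=1e-9)

    def test_constant_phase_gives_zero(self):
        f = np.linspace(1e9, 2e9, 50)
        gd = group_delay(f, np.full(50, 0.3 - 0.4j))
        assert np.allclose(gd, 0.0, atol=1e-18)

    def test_phase_additivity(self):
        f = np.linspace(1.2e9, 5e9, 101)
        t1, t2 = 0.4e-9, 0.35e-9
        s = np.exp(-2j * np.pi * f * t1) * np.exp(-2j * np.pi * f * t2)
        gd = group_delay(f, s)
        assert np.allclose(gd[1:-1], t1 + t2, rtol=1e-9)


def _gaussian_pulse(fs, sigma=0.2e-9, n=512):
    t = (np.arange(n) - n / 2) / fs
    return np.exp(-(t**2) / (2 * sigma**2))


class TestSystemFidelityFactor:
    def test_scaled_delayed_replica_gives_one(self):
        fs = 40e9
        x = _gaussian_pulse(fs)
        y = 0.3 * np.roll(x, 37)
        sff = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(y, fs))
        assert sff == pytest.approx(1.0, abs=1e-9)

    def test_spectrally_disjoint_pulses_decorrelate(self):
        """Pulses in well-separated bands correlate to ~0 at every lag."""
        fs = 40e9
        env = _gaussian_pulse(fs, sigma=0.5e-9)
        t = (np.arange(env.size) - env.size / 2) / fs
        x = env * np.cos(2 * np.pi * 2e9 * t)
        y = env * np.cos(2 * np.pi * 8e9 * t)
        sff = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(y, fs))
        assert sff < 0.01

    def test_zero_energy_rejected(self):
        x = np.zeros(16); x[0] = 1.0
        with pytest.raises(UndefinedMetricError):
            system_fidelity_factor(TimeTrace(x, 1.0), TimeTrace(np.zeros(16), 1.0))

    def test_matches_brute_force_lag_scan(self):
        """Independent oracle: direct summation over every integer lag."""
        fs = 40e9
        x = _gaussian_pulse(fs)
        y = np.gradient(x)  # derivative pulse: distorted 'received' signal
        n = x.size
        best = 0.0
        for lag in range(-n + 1, n):
            if lag >= 0:
                s = float(np.sum(x[: n - lag] * y[lag:]))
            else:
                s = float(np.sum(x[-lag:] * y[: n + lag]))
            best = max(best, abs(s))
        expect = best / np.sqrt(np.sum(x**2) * np.sum(y**2))
        got = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(y, fs))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_symmetry(self, rng):
        fs = 40e9
        x = rng.standard_normal(128)
        y = rng.standard_normal(128)
        a = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(y, fs))
        b = system_fidelity_factor(TimeTrace(y, fs), TimeTrace(x, fs))
        assert a == pytest.approx(b, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_bounded_and_reflexive(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(64)
        fs = 1.0
        sff = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(x, fs))
        assert sff == pytest.approx(1.0, abs=1e-12)
        y = r.standard_normal(64)
        s = system_fidelity_factor(TimeTrace(x, fs), TimeTrace(y, fs))
        assert 0.0 <= s <= 1.0 + 1e-12

    def test_mismatched_fs_rejected(self):
        x = np.ones(8)
        from mwtrack.errors import DataError

        with pytest.raises(DataError):
            system_fidelity_factor(TimeTrace(x, 1.0), TimeTrace(x, 2.0))
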