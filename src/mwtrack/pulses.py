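"""Frequency-to-time conversion, reference subtraction, and pulse metrics.

The VNA-style measurement is a banded frequency sweep; imaging needs the
equivalent time-domain radar pulse per antenna.  The sweep band is tapered,
embedded into a zero-padded one-sided spectrum whose bin spacing equals the
sweep step, and inverse-transformed to a real pulse.  The resulting sample
rate is ``n_fft * df``; zero padding interpolates the pulse for sub-sample
peak placement downstream.

Pulse-quality metrics follow standard ultra-wideband practice: the group
delay is the negative phase derivative over frequency, and the system
fidelity factor (SFF) is the peak magnitude of the normalised
cross-correlation between the transmitted and received pulses — 1 for a
scaled, delayed replica, smaller under dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, hilbert

from .array_scene import FrequencySweep, SweepMeasurement
from .errors import (
    ConfigError,
    DataError,
    IncompatibleMeasurementError,
    UndefinedMetricError,
)

__all__ = [
    "TimeTrace",
    "to_time_domain",
    "subtract_reference",
    "group_delay",
    "system_fidelity_factor",
    "excitation_pulse",
    "default_time_window",
]


@dataclass
class TimeTrace:
    """A real time-domain pulse response with its sample rate."""

    samples: np.ndarray
    fs: float            # Hz
    t0: float = 0.0      # time of first sample, s

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError("fs must be positive")
        if not np.isfinite(s).all():
            raise DataError("trace samples must be finite")
        self.samples = s

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def energy(self) -> float:
        return float(np.sum(self.samples**2))


def _band_window(name: str | None, n: int) -> np.ndarray:
    """Taper over the swept band. 'hann' (default), 'rect'/'none', or any
    scipy.signal.get_window name."""
    if name is None or name in ("rect", "none", "boxcar"):
        return np.ones(n)
    try:
        return get_window(name, n, fftbins=False)
    except ValueError as exc:
        raise ConfigError(f"unknown taper name: {name!r}") from exc


def _band_bins(sweep: FrequencySweep) -> tuple[np.ndarray, int]:
    """Map the sweep grid onto inverse-FFT bins of spacing ``sweep.df``.

    Returns the bin index of each sweep point and the index of the top bin.
    Band edges that are integer multiples of the step map exactly;
    otherwise they are rounded to the nearest bin (error < df/2).
    """
    df = sweep.df
    idx = np.rint(sweep.frequencies / df).astype(int)
    if len(np.unique(idx)) != len(idx):
        raise DataError("sweep grid collapses onto duplicate FFT bins")
    return idx, int(idx[-1])


def to_time_domain(
    measurement: SweepMeasurement,
    window: str | None = "hann",
    zero_pad_factor: int = 4,
) -> list[TimeTrace]:
    """Convert each antenna's reflection spectrum to a real time pulse.

    The tapered band is placed at its physical frequencies in a one-sided
    spectrum of ``zero_pad_factor * 2 * i_top`` FFT bins (``i_top`` the top
    band bin), then inverse-transformed with ``irfft``.  The sample rate is
    ``n_fft * df``.
    """
    if zero_pad_factor < 1:
        raise ConfigError("zero_pad_factor must be >= 1")
    sweep = measurement.sweep
    idx, i_top = _band_bins(sweep)
    n_fft = int(zero_pad_factor) * 2 * i_top
    fs = n_fft * sweep.df
    taper = _band_window(window, sweep.n_points)
    full = np.zeros((measurement.spectra.shape[0], n_fft // 2 + 1), dtype=complex)
    full[:, idx] = measurement.spectra * taper[None, :]
    x = np.fft.irfft(full, n=n_fft, axis=1)
    return [TimeTrace(row, fs=fs, t0=0.0) for row in x]


def excitation_pulse(
    sweep: FrequencySweep,
    window: str | None = "hann",
    zero_pad_factor: int = 4,
) -> TimeTrace:
    """The band-limited wavelet of a unit (flat) spectrum over the band.

    This is the effective excitation pulse of the synthesised radar: every
    scatterer echo is a delayed copy of it.  Used to derive the default
    beamforming integration window.
    """
    import dataclasses as _dc

    from .array_scene import ArrayGeometry

    geom = ArrayGeometry(
        np.array([[1.0, 0.0], [-1.0, 0.0]]), diameter=2.0, eps_r=1.0
    )
    flat = SweepMeasurement(
        geom, sweep, np.ones((2, sweep.n_points), dtype=complex), label="excitation"
    )
    trace = to_time_domain(flat, window=window, zero_pad_factor=zero_pad_factor)[0]
    # centre the wavelet: the zero-delay pulse wraps around t=0
    n = trace.samples.size
    rolled = np.roll(trace.samples, n // 2)
    return _dc.replace(trace, samples=rolled, t0=-(n // 2) / trace.fs)


def default_time_window(
    sweep: FrequencySweep,
    window: str | None = "hann",
    zero_pad_factor: int = 4,
    percentage: float = 100.0,
    drop_db: float = 20.0,
) -> float:
    """Integration-window length (s) as a percentage of the excitation
    pulse's envelope duration above ``-drop_db`` of its peak."""
    pulse = excitation_pulse(sweep, window, zero_pad_factor)
    env = np.abs(hilbert(pulse.samples))
    above = np.nonzero(env >= env.max() * 10 ** (-drop_db / 20.0))[0]
    duration = (above[-1] - above[0] + 1) / pulse.fs
    return float(duration * percentage / 100.0)


def subtract_reference(
    measurement: SweepMeasurement, reference: SweepMeasurement
) -> SweepMeasurement:
    """Remove the static background: elementwise complex difference against
    a reference ('empty') acquisition on the identical grid."""
    if not measurement.compatible_with(reference):
        raise IncompatibleMeasurementError(
            "measurement and reference must share geometry and frequency grid"
        )
    return SweepMeasurement(
        measurement.geometry,
        measurement.sweep,
        measurement.spectra - reference.spectra,
        label=f"{measurement.label}-{reference.label}".strip("-"),
    )


def group_delay(frequencies: np.ndarray, spectrum: np.ndarray) -> np.ndarray:
    """Group delay ``-(1/2pi) * d(unwrapped phase)/df`` in seconds.

    Central differences at interior points, one-sided at the endpoints.
    A pure delay ``exp(-j*2*pi*f*tau)`` gives a flat ``tau``.
    """
    f = np.asarray(frequencies, dtype=float)
    s = np.asarray(spectrum, dtype=complex)
    if f.size < 3 or s.size != f.size:
        raise DataError("need >= 3 frequency points and matching spectrum")
    phase = np.unwrap(np.angle(s))
    return -np.gradient(phase, f) / (2 * np.pi)


def system_fidelity_factor(ts: TimeTrace, rs: TimeTrace) -> float:
    """Peak normalised cross-correlation magnitude between two pulses.

    ``SFF = max_tau | sum_t ts(t) rs(t+tau) | / sqrt(E_ts * E_rs)``,
    evaluated over all integer lags of the zero-padded cross-correlation.
    Equals 1 for a scaled and delayed replica; bounded in [0, 1] by
    Cauchy-Schwarz.
    """
    if not np.isclose(ts.fs, rs.fs):
        raise DataError("pulses must share a sample rate")
    e1, e2 = ts.energy, rs.energy
    if e1 <= 0 or e2 <= 0:
        raise UndefinedMetricError("SFF undefined for zero-energy pulses")
    xc = np.correlate(ts.samples, rs.samples, mode="full")
    return float(np.max(np.abs(xc)) / np.sqrt(e1 * e2))
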