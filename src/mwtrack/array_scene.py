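"""Circular antenna array geometry, scene description, and the synthetic
monostatic forward model.

The physical system this package models is a ring of ultra-wideband
antennas surrounding the region of interest.  Each antenna in turn acts as
a monostatic radar: it transmits a broadband signal and records the complex
reflection spectrum (the S11 parameter) over a frequency sweep.  Objects in
the scene appear as delayed echoes; for a point scatterer at round-trip
delay tau the noiseless reflection spectrum is ``a * exp(-j*2*pi*f*tau)``.

This module replaces the measurement hardware (VNA, switch network,
antennas) with an analytic point-scatterer forward model: scenes are
collections of point scatterers, optionally generated from parametric
shapes (circles, ellipses, rectangles) rendered as dense point sets.

Units: physical coordinates and distances are millimetres, frequencies Hz,
times seconds.  The background medium is homogeneous with relative
permittivity ``eps_r`` (propagation speed ``c/sqrt(eps_r)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as _C_VACUUM

from .errors import InvalidGeometryError, InvalidMediumError, DataError

__all__ = [
    "ArrayGeometry",
    "FrequencySweep",
    "Scene",
    "Shape",
    "SweepMeasurement",
    "build_circular_array",
    "simulate_reflection_sweep",
    "circle_shape",
    "ellipse_shape",
    "rectangle_shape",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Antenna ring: positions on a circle plus the background medium.

    Parameters
    ----------
    antenna_positions : ndarray, shape (n, 2)
        Antenna (x, y) coordinates in mm, on a circle centred at the origin.
    diameter : float
        Circle diameter in mm.
    eps_r : float
        Relative permittivity of the homogeneous background medium.
    """

    antenna_positions: np.ndarray
    diameter: float
    eps_r: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.antenna_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise InvalidGeometryError(
                "antenna_positions must be an (n>=2, 2) array of mm coordinates"
            )
        if self.diameter <= 0:
            raise InvalidGeometryError("diameter must be positive")
        if self.eps_r < 1:
            raise InvalidMediumError("eps_r must be >= 1")
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if not np.allclose(radii, self.diameter / 2.0, atol=1e-9):
            raise InvalidGeometryError(
                "all antennas must lie on the stated circle (within 1e-9 mm)"
            )
        object.__setattr__(self, "antenna_positions", pos)

    @property
    def n_antennas(self) -> int:
        return self.antenna_positions.shape[0]

    def distances_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Euclidean antenna-to-point distances.

        Parameters
        ----------
        points_mm : ndarray, shape (..., 2)

        Returns
        -------
        ndarray, shape (n_antennas, ...)
            Distance of each antenna to each point, mm.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        diff = self.antenna_positions[:, None, :] - pts[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])


@dataclass(frozen=True)
class FrequencySweep:
    """Uniform frequency grid of the reflection sweep (Hz)."""

    f_start: float
    f_stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.f_stop > self.f_start > 0):
            raise DataError("require f_stop > f_start > 0")
        if self.n_points < 2:
            raise DataError("n_points must be >= 2")

    @property
    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_stop, self.n_points)

    @property
    def df(self) -> float:
        """Frequency step of the uniform grid, Hz."""
        return (self.f_stop - self.f_start) / (self.n_points - 1)


#: Default sweep emulating the experimental antenna band (1.2-5 GHz).
#: 191 points give a 20 MHz step that divides both band edges, so the band
#: embeds exactly onto the inverse-FFT bin grid (50 ns unambiguous range).
DEFAULT_SWEEP = FrequencySweep(1.2e9, 5.0e9, 191)


@dataclass(frozen=True)
class Shape:
    """Parametric scene primitive rendered to a dense point set.

    ``reflectivity`` is the *aggregate* amplitude of the shape: it is
    divided uniformly over the rendered points so that the simulated return
    does not depend on the rendering density.
    """

    kind: str                      # 'circle' | 'ellipse' | 'rectangle'
    center: tuple[float, float]    # mm
    params: tuple[float, ...]      # semi-axes / half-sides, mm
    reflectivity: float = 1.0

    def render(self, arc_step_mm: float = 2.0) -> np.ndarray:
        """Render the outline to points; returns (n, 3) array x, y, amp."""
        cx, cy = self.center
        if self.kind == "circle":
            (r,) = self.params
            per = 2 * np.pi * r
            n = max(8, int(round(per / arc_step_mm)))
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            xy = np.c_[cx + r * np.cos(t), cy + r * np.sin(t)]
        elif self.kind == "ellipse":
            a, b = self.params
            # Ramanujan perimeter approximation; adequate for point budgeting
            per = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
            n = max(8, int(round(per / arc_step_mm)))
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            xy = np.c_[cx + a * np.cos(t), cy + b * np.sin(t)]
        elif self.kind == "rectangle":
            hx, hy = self.params
            pts = []
            for s in np.arange(-hx, hx, arc_step_mm):
                pts.append((cx + s, cy - hy))
                pts.append((cx - s, cy + hy))
            for s in np.arange(-hy, hy, arc_step_mm):
                pts.append((cx + hx, cy + s))
                pts.append((cx - hx, cy - s))
            xy = np.array(pts)
        else:
            raise DataError(f"unknown shape kind: {self.kind!r}")
        amp = np.full(len(xy), self.reflectivity / len(xy))
        return np.c_[xy, amp]


def circle_shape(center, radius_mm, reflectivity=1.0) -> Shape:
    return Shape("circle", tuple(center), (float(radius_mm),), reflectivity)


def ellipse_shape(center, semi_x_mm, semi_y_mm, reflectivity=1.0) -> Shape:
    return Shape("ellipse", tuple(center), (float(semi_x_mm), float(semi_y_mm)), reflectivity)


def rectangle_shape(center, width_mm, height_mm, reflectivity=1.0) -> Shape:
    return Shape(
        "rectangle", tuple(center), (float(width_mm) / 2, float(height_mm) / 2), reflectivity
    )


@dataclass
class Scene:
    """A collection of point scatterers and parametric shapes.

    ``scatterers`` holds explicit points as (x_mm, y_mm, amplitude) rows;
    ``shapes`` are rendered to points at ``arc_step_mm`` density when the
    scene is realised.
    """

    scatterers: list[tuple[float, float, float]] = field(default_factory=list)
    shapes: list[Shape] = field(default_factory=list)
    label: str = ""

    def add_point(self, x_mm: float, y_mm: float, reflectivity: float = 1.0) -> "Scene":
        if not np.isfinite([x_mm, y_mm, reflectivity]).all():
            raise DataError("scatterer coordinates and reflectivity must be finite")
        self.scatterers.append((float(x_mm), float(y_mm), float(reflectivity)))
        return self

    def add_shape(self, shape: Shape) -> "Scene":
        self.shapes.append(shape)
        return self

    def points(self, arc_step_mm: float = 2.0) -> np.ndarray:
        """All scatterers as an (n, 3) array of x, y, amplitude."""
        parts = []
        if self.scatterers:
            parts.append(np.asarray(self.scatterers, dtype=float))
        for sh in self.shapes:
            parts.append(sh.render(arc_step_mm))
        if not parts:
            return np.empty((0, 3))
        pts = np.vstack(parts)
        if not np.isfinite(pts).all():
            raise DataError("scene contains non-finite values")
        return pts

    def union(self, other: "Scene") -> "Scene":
        return Scene(
            scatterers=list(self.scatterers) + list(other.scatterers),
            shapes=list(self.shapes) + list(other.shapes),
            label=f"{self.label}+{other.label}".strip("+"),
        )


@dataclass
class SweepMeasurement:
    """Per-antenna complex reflection spectra over a common frequency grid."""

    geometry: ArrayGeometry
    sweep: FrequencySweep
    spectra: np.ndarray          # complex, [n_antennas, n_points]
    label: str = ""

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectra, dtype=complex)
        if spec.shape != (self.geometry.n_antennas, self.sweep.n_points):
            raise DataError(
                f"spectra shape {spec.shape} does not match geometry/sweep "
                f"({self.geometry.n_antennas}, {self.sweep.n_points})"
            )
        if not np.isfinite(spec).all():
            raise DataError("spectra must be finite")
        self.spectra = spec

    def compatible_with(self, other: "SweepMeasurement") -> bool:
        return (
            self.geometry.n_antennas == other.geometry.n_antennas
            and self.sweep.n_points == other.sweep.n_points
            and np.allclose(self.geometry.antenna_positions, other.geometry.antenna_positions)
            and np.isclose(self.geometry.eps_r, other.geometry.eps_r)
            and np.allclose(self.sweep.frequencies, other.sweep.frequencies)
        )


def build_circular_array(
    n_antennas: int, diameter_mm: float, eps_r: float = 1.0
) -> ArrayGeometry:
    """Place ``n_antennas`` equally spaced on a circle of ``diameter_mm``.

    Antenna k sits at angle ``k * 360/n`` degrees counterclockwise from the
    +x axis.  With 16 antennas on a 340 mm circle the angular spacing is
    22.5 degrees, matching the physical ring.
    """
    if n_antennas < 2:
        raise InvalidGeometryError("need at least 2 antennas")
    if diameter_mm <= 0:
        raise InvalidGeometryError("diameter must be positive")
    ang = 2 * np.pi * np.arange(n_antennas) / n_antennas
    pos = (diameter_mm / 2.0) * np.c_[np.cos(ang), np.sin(ang)]
    return ArrayGeometry(pos, float(diameter_mm), float(eps_r))


def propagation_speed_m_s(eps_r: float) -> float:
    """Wave speed in the background medium, ``c / sqrt(eps_r)`` (m/s)."""
    if eps_r < 1:
        raise InvalidMediumError("eps_r must be >= 1")
    return _C_VACUUM / np.sqrt(eps_r)


def simulate_reflection_sweep(
    scene: Scene,
    geometry: ArrayGeometry,
    sweep: FrequencySweep = DEFAULT_SWEEP,
    noise_sd: float = 0.0,
    seed: int | None = None,
    arc_step_mm: float = 2.0,
    spreading_loss: bool = False,
) -> SweepMeasurement:
    """Simulate the monostatic reflection sweep of ``scene``.

    For antenna m and frequency f the noiseless spectrum is::

        S_m(f) = sum_k a_k * exp(-j*2*pi*f * 2*d_mk / v)

    with ``d_mk`` the antenna-to-scatterer distance and ``v = c/sqrt(eps_r)``.
    The factor 2 is the monostatic round trip: the same antenna transmits
    and receives, so the echo travels out and back.

    Parameters
    ----------
    noise_sd : float
        Standard deviation of additive complex circular Gaussian noise per
        frequency point (total, i.e. real and imaginary parts each have
        ``noise_sd/sqrt(2)``).
    seed : int or None
        Required when ``noise_sd > 0``; drives a dedicated generator so
        equal seeds give bit-identical output.
    spreading_loss : bool
        If True, scale each echo by ``1/d**2`` (round-trip amplitude
        spreading).  Off by default: the delay model carries no amplitude
        term.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise DataError("a seed is required for noisy simulations")

    f = sweep.frequencies
    spectra = np.zeros((geometry.n_antennas, sweep.n_points), dtype=complex)
    pts = scene.points(arc_step_mm)
    if len(pts):
        d_m = geometry.distances_mm(pts[:, :2]) * 1e-3  # [M, K] metres
        v = propagation_speed_m_s(geometry.eps_r)
        tau = 2.0 * d_m / v                              # round-trip delay, s
        amp = pts[:, 2][None, :]
        if spreading_loss:
            with np.errstate(divide="ignore"):
                amp = amp / np.maximum(d_m, 1e-6) ** 2
        # [M, K, F] phase accumulation, summed over scatterers
        spectra = np.einsum(
            "mk,mkf->mf", amp, np.exp(-2j * np.pi * tau[:, :, None] * f[None, None, :])
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(spectra.shape) + 1j * rng.standard_normal(spectra.shape)
        spectra = spectra + noise_sd / np.sqrt(2.0) * noise
    return SweepMeasurement(geometry, sweep, spectra, label=scene.label)
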