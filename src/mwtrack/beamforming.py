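"""Delay-and-sum (DAS) and delay-multiply-and-sum (DMAS) image formation.

Both beamformers back-project the per-antenna radar pulses onto a physical
pixel grid.  For a pixel at position r0, antenna m's echo from r0 arrives
at the round-trip delay ``tau_m = 2*d_m / v`` (``d_m`` the antenna-pixel
distance, ``v = c/sqrt(eps_r)``).  DAS aligns the traces at those delays,
sums over antennas, squares, and integrates over a short window::

    I(r0) = sum_t [ sum_m X_m(t + tau_m(r0)) ]^2

DMAS instead sums the pairwise products of the aligned traces before
squaring, which rewards inter-channel coherence and suppresses incoherent
clutter::

    I(r0) = sum_t [ sum_{m<j} X_m(t + tau_m) * X_j(t + tau_j) ]^2

The pairwise sum is computed via the identity
``sum_{m<j} x_m x_j = (S^2 - Q) / 2`` with ``S = sum x_m``,
``Q = sum x_m^2``, which is algebraically exact and O(M) per sample.

Fractional delays use linear interpolation between samples by default
(nearest-sample mode available).  Both images are everywhere nonnegative;
scaling all traces by alpha scales DAS by alpha^2 and DMAS by alpha^4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import c as _C_VACUUM

from .array_scene import ArrayGeometry
from .errors import (
    DataError,
    IncompatibleInputError,
    InsufficientChannelsError,
    InvalidMediumError,
)
from .pulses import TimeTrace

__all__ = [
    "ImageGrid",
    "ReconstructionImage",
    "propagation_speed",
    "delay_index",
    "das_image",
    "dmas_image",
]


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid with a physical (mm) mapping.

    Convention: physical (0, 0) is at the grid centre; row 0 is the maximum
    y (the image 'top'), columns grow with x.  Pixel (row, col) has centre
    ``x = (col - (n_cols-1)/2) * col_pitch`` and
    ``y = ((n_rows-1)/2 - row) * row_pitch``.
    """

    n_rows: int
    n_cols: int
    row_pitch: float  # mm / pixel
    col_pitch: float  # mm / pixel

    def __post_init__(self) -> None:
        if self.row_pitch <= 0 or self.col_pitch <= 0:
            raise DataError("pixel pitches must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise DataError("grid must have at least one pixel")

    @classmethod
    def from_extent(cls, width_mm: float, height_mm: float, pitch_mm: float) -> "ImageGrid":
        """Square-pixel grid covering +-width/2 x +-height/2 around origin."""
        n_cols = int(round(width_mm / pitch_mm)) + 1
        n_rows = int(round(height_mm / pitch_mm)) + 1
        return cls(n_rows, n_cols, pitch_mm, pitch_mm)

    @property
    def origin_pixel(self) -> tuple[float, float]:
        """(row, col) of physical (0, 0); fractional for even dimensions."""
        return ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)

    @property
    def x_coords(self) -> np.ndarray:
        r0, c0 = self.origin_pixel
        return (np.arange(self.n_cols) - c0) * self.col_pitch

    @property
    def y_coords(self) -> np.ndarray:
        r0, c0 = self.origin_pixel
        return (r0 - np.arange(self.n_rows)) * self.row_pitch

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays X, Y of pixel-centre coordinates (mm)."""
        return np.meshgrid(self.x_coords, self.y_coords)


@dataclass
class ReconstructionImage:
    """A nonnegative intensity map on an :class:`ImageGrid`."""

    grid: ImageGrid
    intensity: np.ndarray
    algorithm: str            # 'DAS' | 'DMAS' | derived labels
    normalized: bool = False

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity, dtype=float)
        if img.shape != (self.grid.n_rows, self.grid.n_cols):
            raise DataError("intensity shape does not match grid")
        if (img < -1e-12).any():
            raise DataError("intensities must be nonnegative")
        self.intensity = np.clip(img, 0.0, None)

    def argmax_mm(self) -> tuple[float, float]:
        """Physical coordinates of the brightest pixel."""
        r, c = np.unravel_index(int(np.argmax(self.intensity)), self.intensity.shape)
        return float(self.grid.x_coords[c]), float(self.grid.y_coords[r])

    def replace_intensity(self, intensity: np.ndarray, **kw) -> "ReconstructionImage":
        return replace(self, intensity=intensity, **kw)


def propagation_speed(eps_r: float) -> float:
    """Propagation speed ``c / sqrt(eps_r)`` in m/s."""
    if eps_r < 1:
        raise InvalidMediumError("eps_r must be >= 1")
    return _C_VACUUM / np.sqrt(eps_r)


def delay_index(
    distance_mm: float | np.ndarray,
    eps_r: float,
    fs: float,
    one_way: bool = False,
) -> float | np.ndarray:
    """Fractional sample index of the echo from a point at ``distance_mm``.

    Round-trip by default (``2*d/v * fs``), matching monostatic reflection
    data; ``one_way=True`` gives the literal one-way delay.
    """
    d = np.asarray(distance_mm, dtype=float)
    if (d < 0).any():
        raise DataError("distance must be >= 0")
    v = propagation_speed(eps_r)
    factor = 1.0 if one_way else 2.0
    out = factor * (d * 1e-3) / v * fs
    return float(out) if np.isscalar(distance_mm) else out


def _trace_matrix(traces: list[TimeTrace]) -> tuple[np.ndarray, float]:
    fs = traces[0].fs
    n = traces[0].samples.size
    for t in traces:
        if not np.isclose(t.fs, fs) or t.samples.size != n:
            raise IncompatibleInputError("traces must share fs and length")
    return np.stack([t.samples for t in traces]), fs


def _delay_sums(
    traces: list[TimeTrace],
    geometry: ArrayGeometry,
    grid: ImageGrid,
    t_win: float,
    one_way: bool,
    interpolation: str,
    weights: np.ndarray | None,
    want_pairs: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Shared back-projection core.

    Returns the DAS accumulator ``sum_t S^2`` and, when ``want_pairs``,
    the DMAS accumulator ``sum_t ((S^2 - Q)/2)^2`` over the pixel grid.
    The window is centred on the aligned arrival: t runs over
    ``[-t_win/2, +t_win/2]`` around each pixel's delay, so the symmetric
    band-limited wavelet is integrated whole.
    """
    X, fs = _trace_matrix(traces)
    M = X.shape[0]
    if M != geometry.n_antennas:
        raise IncompatibleInputError(
            f"{M} traces for {geometry.n_antennas} antennas"
        )
    if t_win <= 0:
        raise DataError("t_win must be positive")
    if weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (M,):
            raise IncompatibleInputError("weights must have one entry per antenna")

    gx, gy = grid.pixel_centers()
    pts = np.c_[gx.ravel(), gy.ravel()]
    d = geometry.distances_mm(pts).T                       # [npix, M]
    idx = delay_index(d, geometry.eps_r, fs, one_way=one_way)
    N = X.shape[1]
    K = max(0, int(round(t_win * fs / 2.0)))
    ar = np.arange(M)[None, :]

    das_acc = np.zeros(pts.shape[0])
    dmas_acc = np.zeros(pts.shape[0]) if want_pairs else None

    if interpolation == "nearest":
        base = np.rint(idx).astype(int)
        frac = None
    elif interpolation == "linear":
        base = np.floor(idx).astype(int)
        frac = idx - base
    else:
        raise DataError(f"unknown interpolation mode: {interpolation!r}")

    for k in range(-K, K + 1):
        j = base + k
        if frac is None:
            ok = (j >= 0) & (j < N)
            jc = np.clip(j, 0, N - 1)
            vals = np.where(ok, X[ar, jc], 0.0)
        else:
            ok = (j >= 0) & (j < N - 1)
            jc = np.clip(j, 0, N - 2)
            vals = np.where(ok, (1.0 - frac) * X[ar, jc] + frac * X[ar, jc + 1], 0.0)
        vals = vals * w[None, :]
        S = vals.sum(axis=1)
        das_acc += S * S
        if want_pairs:
            Q = (vals * vals).sum(axis=1)
            pair = 0.5 * (S * S - Q)
            dmas_acc += pair * pair

    shape = (grid.n_rows, grid.n_cols)
    return das_acc.reshape(shape), (
        dmas_acc.reshape(shape) if want_pairs else None
    )


def das_image(
    traces: list[TimeTrace],
    geometry: ArrayGeometry,
    grid: ImageGrid,
    t_win: float,
    one_way: bool = False,
    interpolation: str = "linear",
    weights: np.ndarray | None = None,
) -> ReconstructionImage:
    """Delay-and-sum reconstruction (unit weights by default)."""
    das, _ = _delay_sums(
        traces, geometry, grid, t_win, one_way, interpolation, weights, want_pairs=False
    )
    return ReconstructionImage(grid, das, algorithm="DAS")


def dmas_image(
    traces: list[TimeTrace],
    geometry: ArrayGeometry,
    grid: ImageGrid,
    t_win: float,
    one_way: bool = False,
    interpolation: str = "linear",
    weights: np.ndarray | None = None,
) -> ReconstructionImage:
    """Delay-multiply-and-sum reconstruction over all unordered antenna
    pairs (M*(M-1)/2 products; signed, squared after summation)."""
    if geometry.n_antennas < 2 or len(traces) < 2:
        raise InsufficientChannelsError("DMAS needs at least 2 antenna channels")
    _, dmas = _delay_sums(
        traces, geometry, grid, t_win, one_way, interpolation, weights, want_pairs=True
    )
    return ReconstructionImage(grid, dmas, algorithm="DMAS")
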