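"""Differential tool tracking: per-position reconstruction, image
subtraction, binarization, and centroid extraction.

A long thin tool moving between two acquisitions leaves, after subtracting
the previous reconstruction from the current one, a single bright blob at
its new tip position; everything static (cranium, tumor, clutter) cancels.
The blob is thresholded at a luminance fraction of the normalised image
(0.8 by default, with >= semantics: a pixel exactly at the threshold is
white), the largest 8-connected white component is kept, and its unweighted
pixel centroid is mapped to physical millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .array_scene import ArrayGeometry, SweepMeasurement
from .beamforming import ImageGrid, ReconstructionImage, das_image, dmas_image
from .errors import (
    ConfigError,
    DataError,
    DegenerateImageError,
    IncompatibleInputError,
    NoDetectionError,
)
from .pulses import default_time_window, subtract_reference, to_time_domain

__all__ = [
    "PixelMapping",
    "TrackEstimate",
    "normalize_image",
    "differential_image",
    "binarize",
    "centroid_mm",
    "pixel_to_physical",
    "physical_to_pixel",
    "pixel_pitch_from_reference",
    "track_sequence",
]


@dataclass(frozen=True)
class PixelMapping:
    """Image-frame (row, col) to physical-frame (x, y) mapping.

    The image origin is its top-left corner; the physical frame is centred
    on the antenna system with y growing upward.  ``origin_pixel`` is the
    (row, col) — possibly fractional — where physical (0, 0) sits.
    """

    col_pitch: float   # mm / pixel
    row_pitch: float   # mm / pixel
    origin_pixel: tuple[float, float]

    def __post_init__(self) -> None:
        if self.col_pitch <= 0 or self.row_pitch <= 0:
            raise DataError("pixel pitches must be positive")

    @classmethod
    def for_grid(cls, grid: ImageGrid) -> "PixelMapping":
        return cls(grid.col_pitch, grid.row_pitch, grid.origin_pixel)


def pixel_to_physical(
    row: float, col: float, mapping: PixelMapping
) -> tuple[float, float]:
    """Map image (row, col) to physical (x, y) in mm; y grows upward."""
    r0, c0 = mapping.origin_pixel
    return ((col - c0) * mapping.col_pitch, (r0 - row) * mapping.row_pitch)


def physical_to_pixel(
    x_mm: float, y_mm: float, mapping: PixelMapping
) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_physical` (fractional pixels)."""
    r0, c0 = mapping.origin_pixel
    return (r0 - y_mm / mapping.row_pitch, c0 + x_mm / mapping.col_pitch)


def pixel_pitch_from_reference(
    real_dims_mm: tuple[float, float], pixel_dims: tuple[float, float]
) -> tuple[float, float]:
    """Per-axis mm/pixel pitches from a reference object of known physical
    and pixel extent (e.g. the imaged cranium): pitch = real / pixels.

    Returns (col_pitch, row_pitch) for (width, height) inputs.
    """
    (w_mm, h_mm), (w_px, h_px) = real_dims_mm, pixel_dims
    if w_mm <= 0 or h_mm <= 0:
        raise DataError("real dimensions must be positive")
    if w_px <= 0 or h_px <= 0:
        raise DataError("pixel dimensions must be positive")
    return (w_mm / w_px, h_mm / h_px)


def normalize_image(img: ReconstructionImage) -> ReconstructionImage:
    """Scale intensities so the global maximum is exactly 1."""
    peak = float(img.intensity.max())
    if peak <= 0:
        raise DegenerateImageError("cannot normalize an all-zero image")
    return img.replace_intensity(img.intensity / peak, normalized=True)


def differential_image(
    current: ReconstructionImage,
    previous: ReconstructionImage,
    negatives: str = "clip",
) -> ReconstructionImage:
    """Subtract the previous reconstruction from the current one.

    ``negatives`` controls the residue of the departed position, which is
    negative-valued: 'clip' (default) zeroes it, 'abs' keeps its magnitude,
    'none' shifts nothing and will fail the nonnegativity contract unless
    the difference happens to be nonnegative.  The result is normalised.
    """
    if current.grid != previous.grid:
        raise IncompatibleInputError("differential images require the same grid")
    diff = current.intensity - previous.intensity
    if negatives == "clip":
        diff = np.clip(diff, 0.0, None)
    elif negatives == "abs":
        diff = np.abs(diff)
    elif negatives != "none":
        raise ConfigError(f"unknown negatives mode: {negatives!r}")
    if diff.max() <= 0:
        raise DegenerateImageError("differential image has no positive content")
    out = ReconstructionImage(
        current.grid, diff, algorithm=f"{current.algorithm}-diff"
    )
    return normalize_image(out)


def binarize(img: ReconstructionImage, threshold: float = 0.8) -> np.ndarray:
    """Luminance thresholding of a normalised image.

    Pixels with luminance below ``threshold`` go black, the rest white
    (>= semantics, so the global maximum is always white).
    """
    if not img.normalized:
        img = normalize_image(img)
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("threshold must lie in [0, 1]")
    return img.intensity >= threshold


def centroid_mm(mask: np.ndarray, mapping: PixelMapping) -> tuple[float, float]:
    """Centroid (mm) of the largest 8-connected white component.

    Area ties are broken toward the component whose centroid is nearest the
    physical origin (the tool converges inward).  The centroid is the
    unweighted mean of the component's pixel centres.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoDetectionError("binary mask has no white pixels")
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)

    def sort_key(region):
        r, c = region.centroid
        x, y = pixel_to_physical(r, c, mapping)
        return (-region.area, float(np.hypot(x, y)))

    best = min(props, key=sort_key)
    return pixel_to_physical(*best.centroid, mapping)


@dataclass
class TrackEstimate:
    """Detected tool-tip coordinates for one acquisition position."""

    position_label: str
    detected_xy: tuple[float, float] | None
    algorithm: str
    threshold: float
    status: str = "ok"        # 'ok' | 'no-detection' | 'no-prior'

    @property
    def detected(self) -> bool:
        return self.status == "ok"


_ALGORITHMS = {"DAS": das_image, "DMAS": dmas_image}


def reconstruct(
    measurement: SweepMeasurement,
    algorithm: str,
    grid: ImageGrid,
    empty_ref: SweepMeasurement | None = None,
    t_win: float | None = None,
    window: str | None = "hann",
    zero_pad_factor: int = 4,
) -> ReconstructionImage:
    """One-stop reconstruction: reference subtraction, pulse synthesis,
    then DAS or DMAS image formation."""
    if algorithm not in _ALGORITHMS:
        raise ConfigError(f"unknown algorithm: {algorithm!r} (DAS or DMAS)")
    if empty_ref is not None:
        measurement = subtract_reference(measurement, empty_ref)
    traces = to_time_domain(measurement, window=window, zero_pad_factor=zero_pad_factor)
    if t_win is None:
        t_win = default_time_window(measurement.sweep, window, zero_pad_factor)
    return _ALGORITHMS[algorithm](traces, measurement.geometry, grid, t_win)


def track_sequence(
    measurements: list[SweepMeasurement],
    empty_ref: SweepMeasurement,
    algorithm: str = "DAS",
    threshold: float = 0.8,
    grid: ImageGrid | None = None,
    mapping: PixelMapping | None = None,
    labels: list[str] | None = None,
    t_win: float | None = None,
    window: str | None = "hann",
    zero_pad_factor: int = 4,
    negatives: str = "clip",
) -> list[TrackEstimate]:
    """Run the full navigation pipeline over an ordered acquisition list.

    For each position i >= 2: subtract the empty reference, synthesise the
    pulses, reconstruct, subtract the previous reconstruction, binarize,
    and extract the centroid.  The first position yields no estimate (there
    is no prior image to subtract).  A degenerate differential image or an
    empty mask is reported as a recoverable 'no-detection' for that
    position; the sequence continues.
    """
    if len(measurements) < 2:
        raise DataError("track_sequence needs at least 2 measurements")
    if grid is None:
        grid = ImageGrid.from_extent(250.0, 250.0, 1.0)
    if mapping is None:
        mapping = PixelMapping.for_grid(grid)
    if labels is None:
        labels = [f"p{i + 1}" for i in range(len(measurements))]

    estimates: list[TrackEstimate] = [
        TrackEstimate(labels[0], None, algorithm, threshold, status="no-prior")
    ]
    prev_img: ReconstructionImage | None = None
    for i, meas in enumerate(measurements):
        img = reconstruct(
            meas, algorithm, grid, empty_ref=empty_ref,
            t_win=t_win, window=window, zero_pad_factor=zero_pad_factor,
        )
        if i > 0:
            try:
                diff = differential_image(img, prev_img, negatives=negatives)
                xy = centroid_mm(binarize(diff, threshold), mapping)
                estimates.append(
                    TrackEstimate(labels[i], xy, algorithm, threshold)
                )
            except (DegenerateImageError, NoDetectionError):
                estimates.append(
                    TrackEstimate(
                        labels[i], None, algorithm, threshold, status="no-detection"
                    )
                )
        prev_img = img
    return estimates
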