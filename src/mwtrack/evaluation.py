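"""Error metrics and quantitative analyses for tracking performance.

The detection error is the Euclidean distance between detected and
reference coordinates.  Track-level summaries treat each axis
independently over a range of positions: with signed differences
``delta_i = detected_i - reference_i``, the mean error is the magnitude of
the mean signed difference, ``|mean(delta)|``, and the spread is the
sample standard deviation of the signed differences (n-1 denominator).
Report tables round half-up at 4 decimals; raw doubles are kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError, IncompleteRangeError
from .tracking import PixelMapping, binarize, centroid_mm, differential_image

__all__ = [
    "ErrorSummary",
    "detection_error",
    "error_summary",
    "summary_table",
    "relative_error",
    "fractional_bandwidth",
    "threshold_sweep",
    "threshold_sweep_image",
    "round_half_up",
]

Coords = dict[str, tuple[float, float]]


def round_half_up(value: float, decimals: int = 4) -> float:
    """Decimal round-half-up at ``decimals`` places.

    The double is first quantized at 12 decimals to recover the intended
    decimal value, so statistics whose exact decimal expansion ends in 5
    (e.g. a mean of 6.29675 whose float64 image is 6.296749999...) round
    up as a human computing in decimals would.
    """
    from decimal import ROUND_HALF_EVEN

    q = Decimal(1).scaleb(-decimals)
    snapped = Decimal(float(value)).quantize(
        Decimal(1).scaleb(-12), rounding=ROUND_HALF_EVEN
    )
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


def detection_error(
    detected: tuple[float, float], reference: tuple[float, float]
) -> float:
    """Euclidean distance (mm) between detected and reference coordinates."""
    (xd, yd), (xr, yr) = detected, reference
    if not np.isfinite([xd, yd, xr, yr]).all():
        raise DataError("coordinates must be finite")
    return float(np.hypot(xd - xr, yd - yr))


@dataclass(frozen=True)
class ErrorSummary:
    """Per-axis error statistics over a range of positions (mm)."""

    position_range: str
    mean_error_x: float   # |mean(detected_x - reference_x)|
    mean_error_y: float
    sd_x: float           # sample sd (n-1) of the signed x differences
    sd_y: float
    n: int

    def rounded(self, decimals: int = 4) -> "ErrorSummary":
        """Half-up-rounded copy for report output."""
        return ErrorSummary(
            self.position_range,
            round_half_up(self.mean_error_x, decimals),
            round_half_up(self.mean_error_y, decimals),
            round_half_up(self.sd_x, decimals),
            round_half_up(self.sd_y, decimals),
            self.n,
        )


def error_summary(
    detected: Coords, reference: Coords, labels: list[str], range_label: str = ""
) -> ErrorSummary:
    """Per-axis mean error and sd of detected vs reference over ``labels``.

    Each axis is summarised independently: the mean error is the magnitude
    of the mean signed difference (systematic bias), the sd the
    n-1-denominator standard deviation of the signed differences.
    """
    missing = [l for l in labels if l not in detected or l not in reference]
    if missing:
        raise IncompleteRangeError(f"labels missing from tracks: {missing}")
    if len(labels) < 2:
        raise DataError("need at least 2 positions for a sample sd")
    dx = np.array([detected[l][0] - reference[l][0] for l in labels])
    dy = np.array([detected[l][1] - reference[l][1] for l in labels])
    return ErrorSummary(
        position_range=range_label or f"{labels[0]} to {labels[-1]}",
        mean_error_x=float(abs(dx.mean())),
        mean_error_y=float(abs(dy.mean())),
        sd_x=float(dx.std(ddof=1)),
        sd_y=float(dy.std(ddof=1)),
        n=len(labels),
    )


def summary_table(
    detected_by_alg: dict[str, Coords],
    reference: Coords,
    ranges: dict[str, list[str]],
    decimals: int = 4,
) -> pd.DataFrame:
    """Error-summary table over several position ranges and algorithms.

    One row per range; per algorithm the columns are mean_error_x,
    mean_error_y, sd_x, sd_y, rounded half-up at ``decimals``.
    """
    rows = {}
    for rng_label, labels in ranges.items():
        row = {}
        for alg, det in detected_by_alg.items():
            s = error_summary(det, reference, labels, rng_label).rounded(decimals)
            row[f"{alg}_mean_error_x"] = s.mean_error_x
            row[f"{alg}_mean_error_y"] = s.mean_error_y
            row[f"{alg}_sd_x"] = s.sd_x
            row[f"{alg}_sd_y"] = s.sd_y
        rows[rng_label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "position_range"
    return df


def relative_error(mean_error_mm: float, dimension_mm: float) -> float:
    """Mean error as a percentage of a reference dimension."""
    if dimension_mm <= 0:
        raise DataError("dimension must be positive")
    return 100.0 * mean_error_mm / dimension_mm


def fractional_bandwidth(f_low_hz: float, f_high_hz: float) -> float:
    """Fractional bandwidth in percent: 100 * (f_high - f_low) / f_center.

    1.2-5 GHz gives 122.58%, conventionally reported as 123% at the
    3.1 GHz centre frequency.
    """
    if not (f_high_hz >= f_low_hz > 0):
        raise DataError("require f_high >= f_low > 0")
    center = (f_high_hz + f_low_hz) / 2.0
    return 100.0 * (f_high_hz - f_low_hz) / center


def threshold_sweep_image(
    diff_img,
    mapping: PixelMapping,
    reference_xy: tuple[float, float],
    thresholds: list[float],
) -> pd.DataFrame:
    """Detection error vs luminance threshold on one differential image.

    Re-binarizes and re-extracts the centroid at each threshold; a
    threshold yielding no detection is recorded with NaN coordinates and
    error, not raised.
    """
    from .errors import NoDetectionError

    rows = []
    for thr in thresholds:
        try:
            xy = centroid_mm(binarize(diff_img, thr), mapping)
            rows.append(
                {
                    "threshold": thr,
                    "x_mm": xy[0],
                    "y_mm": xy[1],
                    "detection_error_mm": detection_error(xy, reference_xy),
                }
            )
        except NoDetectionError:
            rows.append(
                {
                    "threshold": thr,
                    "x_mm": np.nan,
                    "y_mm": np.nan,
                    "detection_error_mm": np.nan,
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(
    current,
    previous,
    reference_xy: tuple[float, float],
    thresholds: list[float],
    algorithm: str = "DAS",
    grid=None,
    mapping: PixelMapping | None = None,
    empty_ref=None,
    **reconstruct_kw,
) -> pd.DataFrame:
    """Detection error vs threshold for a measurement pair.

    Reconstructs ``current`` and ``previous`` once, forms their
    differential image, then sweeps the binarization threshold.
    """
    from .beamforming import ImageGrid
    from .tracking import reconstruct

    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise DataError("thresholds must lie in (0, 1]")
    if grid is None:
        grid = ImageGrid.from_extent(250.0, 250.0, 1.0)
    if mapping is None:
        mapping = PixelMapping.for_grid(grid)
    img_cur = reconstruct(current, algorithm, grid, empty_ref=empty_ref, **reconstruct_kw)
    img_prev = reconstruct(previous, algorithm, grid, empty_ref=empty_ref, **reconstruct_kw)
    diff = differential_image(img_cur, img_prev)
    return threshold_sweep_image(diff, mapping, reference_xy, thresholds)
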