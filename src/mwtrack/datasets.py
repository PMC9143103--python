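"""Embedded benchmark data: tool coordinates from a robot-guided cranial
navigation experiment on a physical 16-antenna ring.

The benchmark recorded a surgical tool advancing along a straight line
toward a tumor phantom inside a 3-D-printed cranium (horizontal section
128 x 170 mm, tumor centre near (0, 26) mm).  At eight instants (p1..p8)
the microwave system produced differential DAS and DMAS reconstructions
whose centroids give the detected tool-tip coordinates, while the robot
arm's end-effector pose gives the reference coordinates.  p1 has no prior
image (no estimate) and the robot reference is unavailable for the tumor
row; p2 was still outside the sensing region and is excluded from error
summaries.

These tables serve as ground truth for the error-analysis routines in
:mod:`mwtrack.evaluation` and as the target trajectory replayed by the
synthetic demo.  All values in mm.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "benchmark_coordinates",
    "benchmark_detected",
    "benchmark_reference",
    "CRANIUM_DIMS_MM",
    "TUMOR_CENTER_MM",
    "TUMOR_SIDE_MM",
    "COL_PITCH_MM",
    "ROW_PITCH_MM",
    "IMAGE_DIMS_PX",
]

#: Physical cranium horizontal-section extents (width x, height y), mm.
CRANIUM_DIMS_MM = (128.0, 170.0)
#: Tumor phantom centre in the antenna frame, mm.
TUMOR_CENTER_MM = (0.0, 26.0)
#: Tumor phantom cube side, mm.
TUMOR_SIDE_MM = 25.0
#: Pixel pitches of the benchmark reconstructions (mm / pixel).
COL_PITCH_MM = 0.1922
ROW_PITCH_MM = 0.2255
#: Benchmark image dimensions (rows, cols).
IMAGE_DIMS_PX = (1300, 1301)

_TABLE = """\
position,das_x,das_y,dmas_x,dmas_y,robot_x,robot_y
tumor,-0.6342,26.1538,0.0961,26.3117,,
p2,80.6823,0.4284,111.0871,-13.9562,90.4000,96.2000
p3,47.4907,47.0544,47.4907,44.3263,67.0000,70.8000
p4,42.3399,37.4496,41.8595,36.3899,58.6000,61.7000
p5,36.3243,32.8501,36.1898,31.7679,45.8000,47.9000
p6,26.1574,25.5000,26.1189,24.0119,29.5000,30.2000
p7,17.7778,17.4735,17.8162,16.4589,19.6000,19.5000
p8,11.9544,10.9576,12.4925,10.5743,11.1000,10.4000
"""


def benchmark_coordinates() -> pd.DataFrame:
    """Full benchmark table: detected (DAS, DMAS) and robot coordinates."""
    return pd.read_csv(io.StringIO(_TABLE), index_col="position")


def benchmark_detected(algorithm: str) -> dict[str, tuple[float, float]]:
    """Detected tool-tip coordinates per position for 'DAS' or 'DMAS'."""
    alg = algorithm.lower()
    if alg not in ("das", "dmas"):
        raise ValueError("algorithm must be 'DAS' or 'DMAS'")
    df = benchmark_coordinates()
    return {
        lab: (float(row[f"{alg}_x"]), float(row[f"{alg}_y"]))
        for lab, row in df.iterrows()
        if lab != "tumor"
    }


def benchmark_reference() -> dict[str, tuple[float, float]]:
    """Robot-arm reference coordinates per position."""
    df = benchmark_coordinates().drop(index="tumor")
    return {
        lab: (float(row["robot_x"]), float(row["robot_y"]))
        for lab, row in df.iterrows()
    }
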