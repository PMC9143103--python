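"""File formats: Touchstone sweeps, geometry sidecars, bundles, exports.

Sweeps are interchanged as Touchstone files — the industry-standard text
format for VNA network-parameter data — one ``.s1p`` per antenna, plus a
YAML sidecar describing the array geometry, the sweep grid, and the
antenna file order.  A bundle is either a directory or a single ``.zip``
archive holding the same files.  The RI (real/imaginary) dialect is
written; RI, MA (magnitude/angle in degrees) and DB (dB-magnitude/angle)
dialects are read, with Hz/kHz/MHz/GHz frequency units.
"""

from __future__ import annotations

import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .array_scene import ArrayGeometry, FrequencySweep, SweepMeasurement
from .errors import DataError
from .pulses import TimeTrace

__all__ = [
    "read_touchstone",
    "write_touchstone",
    "read_sweep_bundle",
    "write_sweep_bundle",
    "write_traces_csv",
    "read_traces_csv",
    "export_image_png",
]

_UNIT_SCALE = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}
_SIDECAR = "geometry.yaml"


def _parse_touchstone_text(text: str, n_ports: int) -> tuple[np.ndarray, np.ndarray]:
    """Parse Touchstone text; returns (frequencies Hz, S11 complex)."""
    unit, fmt = "GHZ", "MA"  # Touchstone defaults
    rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line[1:].upper().split()
            for i, tok in enumerate(tokens):
                if tok in _UNIT_SCALE:
                    unit = tok
                elif tok in ("RI", "MA", "DB"):
                    fmt = tok
            continue
        try:
            rows.append([float(v) for v in line.split()])
        except ValueError as exc:
            raise DataError(f"malformed Touchstone data line: {raw!r}") from exc
    if not rows:
        raise DataError("Touchstone file contains no data")
    ncol = 1 + 2 * n_ports**2
    data = np.array([r[:ncol] for r in rows])
    if data.shape[1] < 3:
        raise DataError("Touchstone data rows need at least 3 columns")
    f = data[:, 0] * _UNIT_SCALE[unit]
    a, b = data[:, 1], data[:, 2]
    if fmt == "RI":
        s = a + 1j * b
    elif fmt == "MA":
        s = a * np.exp(1j * np.deg2rad(b))
    else:  # DB
        s = 10 ** (a / 20.0) * np.exp(1j * np.deg2rad(b))
    return f, s


def read_touchstone(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``.s1p``/``.s2p`` file; returns (frequencies Hz, S11)."""
    path = Path(path)
    n_ports = 2 if path.suffix.lower() == ".s2p" else 1
    return _parse_touchstone_text(path.read_text(), n_ports)


def _touchstone_text(frequencies: np.ndarray, s11: np.ndarray, comment: str = "") -> str:
    lines = []
    if comment:
        lines.append(f"! {comment}")
    lines.append("# HZ S RI R 50")
    for f, s in zip(frequencies, s11):
        lines.append(f"{f:.6f} {s.real:.12e} {s.imag:.12e}")
    return "\n".join(lines) + "\n"


def write_touchstone(
    path: str | Path, frequencies: np.ndarray, s11: np.ndarray, comment: str = ""
) -> None:
    """Write a one-port Touchstone file in the RI dialect (Hz)."""
    Path(path).write_text(_touchstone_text(frequencies, s11, comment))


def _sidecar_dict(measurement: SweepMeasurement, filenames: list[str]) -> dict:
    g, sw = measurement.geometry, measurement.sweep
    return {
        "label": measurement.label,
        "n_antennas": g.n_antennas,
        "diameter_mm": g.diameter,
        "eps_r": g.eps_r,
        "antenna_positions_mm": [[float(x), float(y)] for x, y in g.antenna_positions],
        "sweep": {"f_start_hz": sw.f_start, "f_stop_hz": sw.f_stop, "n_points": sw.n_points},
        "files": filenames,
    }


def write_sweep_bundle(path: str | Path, measurement: SweepMeasurement) -> None:
    """Write a sweep bundle: one ``.s1p`` per antenna + geometry sidecar.

    ``path`` ending in ``.zip`` produces a single-archive container;
    otherwise a directory is created.
    """
    path = Path(path)
    f = measurement.sweep.frequencies
    names = [f"ant{m:02d}.s1p" for m in range(measurement.geometry.n_antennas)]
    sidecar = yaml.safe_dump(_sidecar_dict(measurement, names), sort_keys=False)
    texts = [
        _touchstone_text(f, measurement.spectra[m], comment=f"antenna {m}")
        for m in range(len(names))
    ]
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(_SIDECAR, sidecar)
            for name, text in zip(names, texts):
                zf.writestr(name, text)
    else:
        path.mkdir(parents=True, exist_ok=True)
        (path / _SIDECAR).write_text(sidecar)
        for name, text in zip(names, texts):
            (path / name).write_text(text)


def read_sweep_bundle(path: str | Path) -> SweepMeasurement:
    """Read a sweep bundle (directory or ``.zip``) back into a measurement.

    Validates that every per-antenna file shares the sidecar's frequency
    grid and that no channel is missing.
    """
    path = Path(path)
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            if _SIDECAR not in zf.namelist():
                raise DataError(f"bundle is missing the {_SIDECAR} sidecar")
            meta = yaml.safe_load(zf.read(_SIDECAR))
            reader = {n: zf.read(n).decode() for n in zf.namelist() if n != _SIDECAR}
    elif path.is_dir():
        sidecar = path / _SIDECAR
        if not sidecar.exists():
            raise DataError(f"bundle is missing the {_SIDECAR} sidecar")
        meta = yaml.safe_load(sidecar.read_text())
        reader = {p.name: p.read_text() for p in path.iterdir() if p.name != _SIDECAR}
    else:
        raise DataError(f"bundle path not found: {path}")

    sweep = FrequencySweep(
        meta["sweep"]["f_start_hz"], meta["sweep"]["f_stop_hz"], meta["sweep"]["n_points"]
    )
    geom = ArrayGeometry(
        np.asarray(meta["antenna_positions_mm"], dtype=float),
        meta["diameter_mm"],
        meta.get("eps_r", 1.0),
    )
    missing = [n for n in meta["files"] if n not in reader]
    if missing:
        raise DataError(f"bundle is missing channel files: {missing}")
    grid = sweep.frequencies
    spectra = np.zeros((geom.n_antennas, sweep.n_points), dtype=complex)
    for m, name in enumerate(meta["files"]):
        n_ports = 2 if name.lower().endswith(".s2p") else 1
        f, s = _parse_touchstone_text(reader[name], n_ports)
        if f.size != grid.size or not np.allclose(f, grid, rtol=1e-9):
            raise DataError(f"frequency grid of {name} differs from the sidecar sweep")
        spectra[m] = s
    return SweepMeasurement(geom, sweep, spectra, label=meta.get("label", ""))


def write_traces_csv(path: str | Path, traces: list[TimeTrace]) -> None:
    """Columnar CSV of time traces: time_s, trace00, trace01, ..."""
    df = pd.DataFrame({"time_s": traces[0].times})
    for m, tr in enumerate(traces):
        df[f"trace{m:02d}"] = tr.samples
    df.to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[TimeTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise DataError("trace CSV needs at least 2 samples")
    fs = 1.0 / float(np.mean(np.diff(t)))
    return [
        TimeTrace(df[c].to_numpy(), fs=fs, t0=float(t[0]))
        for c in df.columns
        if c != "time_s"
    ]


def export_image_png(path: str | Path, image, cmap: str = "viridis") -> None:
    """Save a reconstruction as a normalised PNG with a YAML grid sidecar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = image.grid
    extent = [
        grid.x_coords[0], grid.x_coords[-1], grid.y_coords[-1], grid.y_coords[0],
    ]
    img = image.intensity
    peak = img.max()
    if peak > 0:
        img = img / peak
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, cmap=cmap, extent=extent, origin="upper")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(image.algorithm)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    meta = {
        "algorithm": image.algorithm,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "row_pitch_mm": grid.row_pitch,
        "col_pitch_mm": grid.col_pitch,
        "origin_pixel": list(grid.origin_pixel),
        "normalized": bool(image.normalized or peak > 0),
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
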