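"""Readers and writers for maps, tilt patterns and run configuration.

Quantitative outputs are 32-bit float TIFF (with a JSON sidecar carrying the
resolved configuration and axis metadata) or CSV.  PNG output is a log-scaled
8-bit preview for eyeballing only — it mirrors the logarithmic intensity
display customary for diffraction images and is never read back for numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .geometry import DMDGeometry
from .patterns import TiltPattern, make_pattern

__all__ = [
    "write_map",
    "read_map",
    "read_pattern",
    "write_pattern_ascii",
    "write_pattern_image",
    "load_config",
    "geometry_from_config",
]

MAP_FORMATS = ("tiff32", "csv", "png_log")


def write_map(
    data: np.ndarray,
    path: str | Path,
    fmt: str = "tiff32",
    *,
    axes: dict | None = None,
    config: dict | None = None,
) -> Path:
    """Write a 2-D map to disk.

    ``axes`` describes the grid (angle ranges, steps, units) and ``config``
    the resolved run configuration; both go into the JSON sidecar (tiff32) or
    the CSV header comment, so every artifact records how it was produced.
    """
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("write_map expects a 2-D array")
    if np.isinf(data).any():  # NaN is allowed (masked pixels), inf is not
        raise ValueError("map contains non-finite (inf) values")
    path = Path(path)
    meta = {"axes": axes or {}, "config": config or {}}

    if fmt == "tiff32":
        tifffile.imwrite(path, data.astype(np.float32))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    elif fmt == "csv":
        phi = (axes or {}).get("phi_deg")
        header_cols = (
            [f"{v:.6g}" for v in phi] if phi is not None else
            [str(i) for i in range(data.shape[1])]
        )
        lines = ["# " + json.dumps(meta), "theta\\phi," + ",".join(header_cols)]
        theta = (axes or {}).get("theta_deg")
        row_labels = (
            [f"{v:.6g}" for v in theta] if theta is not None else
            [str(i) for i in range(data.shape[0])]
        )
        for label, row in zip(row_labels, data):
            lines.append(label + "," + ",".join(f"{v:.9g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "png_log":
        finite = data[np.isfinite(data)]
        peak = finite.max() if finite.size else 1.0
        floor = peak * 1e-6 if peak > 0 else 1.0
        logimg = np.log10(np.clip(np.nan_to_num(data, nan=0.0), floor, None) / floor)
        span = logimg.max() or 1.0
        iio.imwrite(path, (255 * logimg / span).astype(np.uint8))
    else:
        raise ValueError(f"unknown map format {fmt!r}; choose from {MAP_FORMATS}")
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read back a tiff32 or csv map; returns ``(array, metadata)``."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return data, meta
    lines = path.read_text().strip().splitlines()
    meta = {}
    if lines and lines[0].startswith("#"):
        meta = json.loads(lines.pop(0)[1:].strip())
    rows = [[float(v) for v in line.split(",")[1:]] for line in lines[1:]]
    return np.asarray(rows), meta


def read_pattern(path: str | Path, geom: DMDGeometry | None = None) -> TiltPattern:
    """Read a tilt pattern from an ASCII 0/1 grid or a grayscale image.

    Images (PNG/PGM/...) are converted to grayscale and thresholded at 50%
    of their maximum; ASCII files hold one row of ``0``/``1`` characters per
    line.  If ``geom`` is given the dimensions are validated against it.
    """
    path = Path(path)
    if path.suffix.lower() in (".txt", ".pat", ".asc", ""):
        rows = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        if not rows or {c for row in rows for c in row} - {"0", "1"}:
            raise ValueError(f"{path} is not an ASCII 0/1 pattern grid")
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"{path} has ragged rows")
        states = np.array([[int(c) for c in row] for row in rows], dtype=np.uint8)
        pattern = TiltPattern(states)
    else:
        img = np.asarray(iio.imread(path), dtype=float)
        if img.ndim == 3:  # RGB(A) -> luma
            img = img[..., :3].mean(axis=-1)
        if img.ndim != 2:
            raise ValueError(f"{path} is not a binary-resolvable raster")
        ny, nx = img.shape
        pattern = make_pattern("from_image", nx, ny, image=img)
    if geom is not None:
        pattern.validate_for(geom)
    return pattern


def write_pattern_ascii(pattern: TiltPattern, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join("".join(str(v) for v in row) for row in pattern.states) + "\n")
    return path


def write_pattern_image(pattern: TiltPattern, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (pattern.states * 255).astype(np.uint8))
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def geometry_from_config(cfg: dict) -> DMDGeometry:
    """Build the device geometry from config keys (pitch_um, mirror_um, ...)."""
    defaults = DMDGeometry()
    return DMDGeometry(
        pitch_um=cfg.get("pitch_um", defaults.pitch_um),
        mirror_um=cfg.get("mirror_um", cfg.get("pitch_um", defaults.mirror_um)),
        tilt_deg=cfg.get("tilt_deg", defaults.tilt_deg),
        nx=cfg.get("nx", defaults.nx),
        ny=cfg.get("ny", defaults.ny),
    )
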