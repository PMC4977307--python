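"""Readers, writers, run configuration and pipeline orchestration.

Images: 8/16-bit grayscale PGM/PNG/TIFF, with the physical pixel size
taken from a JSON sidecar (``<image>.json`` with key
``pixel_size_mm``) or defaulting to 0.05 mm (50 um detectors).

Stacks: multi-page TIFF, or raw binary with a JSON sidecar declaring
``{"frames": ..., "rows": ..., "cols": ..., "fps": ..., "dtype": ...}``.

``run_pipeline`` drives the per-breast analysis (tiling,
classification, clustering) and writes CSV/JSON/PNG artefacts plus the
resolved configuration, so every run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .clusters import find_clusters
from .scales import DEFAULT_PIXEL_SIZE_MM
from .segmentation import (
    analyze_mammogram,
    render_class_map,
    summarize_breast,
    tile_thermogram,
)
from .wtmm2d import Image2D

__all__ = ["RunConfig", "read_image", "read_stack", "Stack", "run_pipeline"]

log = logging.getLogger("mfscreen")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Resolved analysis configuration; defaults are the published
    operating points (classification thresholds 0.45/0.55 on H and
    0.03 on c2, fit windows log2 a in [1,3] / 0.3-4 Hz)."""

    modality: str = "mammo"                  # 'mammo' | 'thermo'
    h_blue_below: float = 0.45
    h_red_above: float = 0.55
    c2_threshold: float = 0.03
    fit_window_mm: tuple[float, float] = (0.7, 2.8)
    fit_window_hz: tuple[float, float] = (0.3, 4.0)
    connectivity: str = "edge_or_corner"
    quality_r2: float = 0.98
    seed: int = 0
    output_dir: str = "mfscreen-out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ----------------------------------------------------------------------
def _sidecar(path: Path) -> dict:
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def read_image(path: str | Path) -> Image2D:
    """Read an 8/16-bit grayscale PGM/PNG/TIFF image.

    RGB input and unsupported bit depths are rejected; a missing
    sidecar leaves pixel_size at the 0.05 mm default (logged once).
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name}: RGB input not supported; convert to grayscale first"
        )
    # int32 appears for 16-bit PGM (PNM plugin); values are preserved
    if arr.dtype not in (np.uint8, np.uint16, np.int16, np.int32, np.float32, np.float64):
        raise ValueError(f"{path.name}: unsupported bit depth / dtype {arr.dtype}")
    meta = _sidecar(path)
    if "pixel_size_mm" in meta:
        pixel_size = float(meta["pixel_size_mm"])
    else:
        log.warning("%s: no sidecar pixel size; defaulting to %.3f mm",
                    path.name, DEFAULT_PIXEL_SIZE_MM)
        pixel_size = DEFAULT_PIXEL_SIZE_MM
    return Image2D(arr.astype(float), pixel_size=pixel_size)


def write_image(path: str | Path, image: Image2D | np.ndarray, dtype=np.uint16) -> None:
    """Write an image as 16-bit grayscale (values rescaled to the full
    range) with a JSON sidecar carrying the pixel size."""
    path = Path(path)
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    arr = (scaled * np.iinfo(dtype).max).astype(dtype)
    iio.imwrite(path, arr)
    if isinstance(image, Image2D):
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"pixel_size_mm": image.pixel_size})
        )


@dataclass
class Stack:
    """Lazily-indexed time-series stack (frames, rows, cols)."""

    data: np.ndarray
    sampling_rate: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        return np.asarray(self.data[:, row, col], dtype=float)


def read_stack(path: str | Path) -> Stack:
    """Read a thermogram-like stack: multi-page TIFF (sidecar supplies
    fps) or raw binary + JSON sidecar {frames, rows, cols, fps, dtype}.
    Frame-count mismatches are rejected with the byte counts."""
    path = Path(path)
    meta = _sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim != 3:
            raise ValueError(f"{path.name}: expected a multi-page TIFF stack")
        if "frames" in meta and meta["frames"] != data.shape[0]:
            raise ValueError(
                f"{path.name}: sidecar declares {meta['frames']} frames, file has {data.shape[0]}"
            )
        fps = float(meta.get("fps", 50.0))
        return Stack(data=data, sampling_rate=fps)
    required = {"frames", "rows", "cols", "fps", "dtype"}
    if not required <= meta.keys():
        raise ValueError(f"{path.name}: raw stack needs sidecar keys {sorted(required)}")
    dtype = np.dtype(meta["dtype"])
    expected = meta["frames"] * meta["rows"] * meta["cols"] * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{path.name}: expected {expected} bytes "
            f"({meta['frames']}x{meta['rows']}x{meta['cols']} {meta['dtype']}), found {actual}"
        )
    data = np.memmap(path, dtype=dtype, mode="r",
                     shape=(meta["frames"], meta["rows"], meta["cols"]))
    return Stack(data=data, sampling_rate=float(meta["fps"]))


def write_stack(path: str | Path, data: np.ndarray, sampling_rate: float) -> None:
    """Write a stack as multi-page TIFF plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"frames": int(data.shape[0]), "fps": sampling_rate})
    )


# ----------------------------------------------------------------------
def run_pipeline(config: RunConfig, inputs: dict, output_dir: str | Path | None = None) -> dict:
    """Run the per-breast pipeline on one input and write artefacts.

    ``inputs``: {'image': Image2D} for mammo, or
    {'stack': array, 'sampling_rate': float} for thermo; an optional
    'mask' and 'view' tag are honoured.  Returns a result bundle with
    the TileGrid, BreastSummary, ClusterSet and the output paths.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    view = inputs.get("view", "")

    if config.modality == "mammo":
        grid = analyze_mammogram(inputs["image"], mask=inputs.get("mask"))
        flagged = "yellow"
    elif config.modality == "thermo":
        grid = tile_thermogram(
            inputs["stack"],
            sampling_rate=inputs.get("sampling_rate", 50.0),
            mask=inputs.get("mask"),
        )
        flagged = "red"
    else:
        raise ValueError(f"unknown modality {config.modality!r}")

    summary = summarize_breast(grid, view=view)
    clusters = find_clusters(grid, connectivity=config.connectivity, label=flagged)

    tiles_csv = out / "tiles.csv"
    pd.DataFrame(grid.to_records()).to_csv(tiles_csv, index=False)
    summary_json = out / "summary.json"
    summary_json.write_text(json.dumps(summary.to_dict(), indent=2))
    clusters_csv = out / "clusters.csv"
    pd.DataFrame(
        [
            {"cluster": i, "size": len(c),
             "tiles": ";".join(f"{r},{cc}" for r, cc in sorted(c))}
            for i, c in enumerate(clusters.clusters)
        ]
    ).to_csv(clusters_csv, index=False)
    overlay_png = out / "class_map.png"
    iio.imwrite(overlay_png, render_class_map(grid))
    log.info("pipeline wrote %s", out)
    return {
        "grid": grid,
        "summary": summary,
        "clusters": clusters,
        "paths": {
            "tiles": tiles_csv, "summary": summary_json,
            "clusters": clusters_csv, "overlay": overlay_png,
            "config": out / "config.json",
        },
    }
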