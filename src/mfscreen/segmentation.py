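"""Tiling and per-tile classification of mammograms and thermograms.

Mammograms are divided into overlapping 360x360-pixel analysis windows
whose disjoint central 256x256 cores tile the image (stride 256,
corner-anchored); each window is analysed with the 2D WTMM restricted
to maxima lines rooted in its core, and the core is colour-coded by
the estimated Hurst exponent:

* blue   — anti-correlated roughness, H < 0.45 ("fatty")
* yellow — uncorrelated, 0.45 <= H <= 0.55 (the "risky" class)
* red    — long-range correlated, H > 0.55 ("dense")
* pink   — no convincing scaling

Thermogram stacks are divided into 8x8-pixel squares; the 64 per-pixel
series of each square are analysed with the 1D WTMM (averaged
partition functions) and classified monofractal (red) / multifractal
(blue) / no-scaling (white) by the intermittency coefficient c2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scales import ScaleGrid
from .spectra import ScalingSpectra
from .wtmm1d import WTMM1D
from .wtmm2d import Image2D, WTMM2D

__all__ = [
    "Tile",
    "TileGrid",
    "BreastSummary",
    "tile_mammogram",
    "classify_tile_mammo",
    "analyze_mammogram",
    "tile_thermogram",
    "summarize_breast",
    "breast_mask",
    "render_class_map",
]

#: Hurst thresholds of the mammographic colour code
H_BLUE_BELOW = 0.45
H_RED_ABOVE = 0.55

MAMMO_CORE = 256
MAMMO_WINDOW = 360
THERMO_TILE = 8
MIN_MASK_COVERAGE = 0.5

MAMMO_CLASSES = ("blue", "yellow", "red", "pink")
THERMO_CLASSES = ("red", "blue", "white")  # mono, multi, no scaling

CLASS_COLORS = {
    "blue": (60, 90, 220),
    "yellow": (235, 220, 60),
    "red": (220, 60, 60),
    "pink": (245, 170, 200),
    "white": (255, 255, 255),
    "none": (0, 0, 0),
}


@dataclass
class Tile:
    """One analysis tile: core placement plus its (clipped) window."""

    row: int                     # tile indices on the core grid
    col: int
    core: tuple[slice, slice]    # core extent in image coordinates
    window: tuple[slice, slice]  # clipped analysis window
    coverage: float = 1.0        # breast-mask fraction of the core


@dataclass
class TileGrid:
    """Classified tiles of one breast image or thermogram stack."""

    modality: str                          # 'mammo' | 'thermo'
    shape: tuple[int, int]                 # tile grid shape
    classes: np.ndarray                    # object array; 'none' = not analysed
    estimates: np.ndarray                  # H (mammo) or c2 (thermo); NaN if n/a
    quality: np.ndarray                    # min control-moment R^2
    tiles: list = field(default_factory=list, repr=False)

    def analyzed_mask(self) -> np.ndarray:
        return self.classes != "none"

    def class_mask(self, label: str) -> np.ndarray:
        return self.classes == label

    def counts(self) -> dict:
        out = {}
        labels = MAMMO_CLASSES if self.modality == "mammo" else THERMO_CLASSES
        for lab in labels:
            out[lab] = int((self.classes == lab).sum())
        return out

    def to_records(self) -> list[dict]:
        recs = []
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                if self.classes[r, c] == "none":
                    continue
                recs.append(
                    dict(
                        tile_row=r,
                        tile_col=c,
                        **{"class": str(self.classes[r, c])},
                        estimate=float(self.estimates[r, c]),
                        quality=float(self.quality[r, c]),
                    )
                )
        return recs


@dataclass
class BreastSummary:
    """Per-breast class counts: Nb + Nr + Ny + Nn = analysed tiles."""

    modality: str
    view: str
    counts: dict
    n_total: int

    @property
    def percentages(self) -> dict:
        if self.n_total == 0:
            return {k: float("nan") for k in self.counts}
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return dict(
            modality=self.modality,
            view=self.view,
            counts=self.counts,
            n_total=self.n_total,
            percentages=self.percentages,
        )


# ----------------------------------------------------------------------
def breast_mask(image: Image2D | np.ndarray) -> np.ndarray:
    """Foreground mask: Otsu threshold, largest connected component,
    holes filled.  User-supplied masks are accepted everywhere a mask
    is used, so this is only a convenience default."""
    from skimage.filters import threshold_otsu

    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, float)
    if np.ptp(px) == 0:
        return np.ones(px.shape, dtype=bool)
    mask = px > threshold_otsu(px)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.ones(px.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def tile_mammogram(
    image: Image2D | np.ndarray,
    mask: np.ndarray | None = None,
    core: int = MAMMO_CORE,
    window: int = MAMMO_WINDOW,
    offset: tuple[int, int] = (0, 0),
    min_coverage: float = MIN_MASK_COVERAGE,
) -> list[Tile]:
    """Corner-anchored tiling: disjoint exhaustive cores on a ``core``
    stride, each with an oversized centred analysis window (clipped at
    the image borders; the analysis mirror-pads the window).  Tiles
    whose core overlaps the mask by less than ``min_coverage`` are
    excluded."""
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    ny, nx = px.shape
    if ny < window or nx < window:
        raise ValueError(f"image {px.shape} smaller than one {window}x{window} tile")
    margin = (window - core) // 2
    tiles = []
    r0s = range(offset[0], ny - core + 1, core)
    c0s = range(offset[1], nx - core + 1, core)
    for i, r0 in enumerate(r0s):
        for j, c0 in enumerate(c0s):
            core_sl = (slice(r0, r0 + core), slice(c0, c0 + core))
            win_sl = (
                slice(max(r0 - margin, 0), min(r0 + core + margin, ny)),
                slice(max(c0 - margin, 0), min(c0 + core + margin, nx)),
            )
            cov = 1.0
            if mask is not None:
                cov = float(mask[core_sl].mean())
                if cov < min_coverage:
                    continue
            tiles.append(Tile(row=i, col=j, core=core_sl, window=win_sl, coverage=cov))
    return tiles


def classify_tile_mammo(spectra: ScalingSpectra) -> str:
    """Colour code from the Hurst estimate: blue iff H < 0.45, yellow
    iff 0.45 <= H <= 0.55, red iff H > 0.55, pink iff no scaling."""
    if not spectra.scaling_ok or not np.isfinite(spectra.hurst):
        return "pink"
    H = spectra.hurst
    if H < H_BLUE_BELOW:
        return "blue"
    if H <= H_RED_ABOVE:
        return "yellow"
    return "red"


def _pad_window_to(pixels: np.ndarray, window: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Mirror-pad a clipped border window back to full size; returns the
    padded array and the (row, col) shift applied to coordinates."""
    ny, nx = pixels.shape
    pr = window - ny
    pc = window - nx
    if pr == 0 and pc == 0:
        return pixels, (0, 0)
    return np.pad(pixels, ((pr, 0), (pc, 0)), mode="reflect"), (pr, pc)


def analyze_mammogram(
    image: Image2D | np.ndarray,
    mask: np.ndarray | None = None,
    grid: ScaleGrid | None = None,
    core: int = MAMMO_CORE,
    window: int = MAMMO_WINDOW,
    offset: tuple[int, int] = (0, 0),
    pixel_size: float | None = None,
) -> TileGrid:
    """Tile a mammogram-like image and classify every tile.

    Each tile's window is analysed with :class:`WTMM2D` (mirror
    boundary) with partition functions restricted to maxima lines
    rooted in the central core.
    """
    img = image if isinstance(image, Image2D) else Image2D(np.asarray(image))
    grid = grid or ScaleGrid.default_image()
    tiles = tile_mammogram(img, mask, core, window, offset)
    px = img.pixels
    ny, nx = px.shape
    nrows = len(range(offset[0], ny - core + 1, core))
    ncols = len(range(offset[1], nx - core + 1, core))
    classes = np.full((nrows, ncols), "none", dtype=object)
    estimates = np.full((nrows, ncols), np.nan)
    quality = np.full((nrows, ncols), np.nan)
    for t in tiles:
        win_px, (pr, pc) = _pad_window_to(px[t.window], window)
        model = WTMM2D(win_px, grid=grid, boundary="mirror")
        r_off = t.core[0].start - t.window[0].start + pr
        c_off = t.core[1].start - t.window[1].start + pc
        core_sl = (slice(r_off, r_off + core), slice(c_off, c_off + core))
        spectra = model.fit(core=core_sl)
        classes[t.row, t.col] = classify_tile_mammo(spectra)
        estimates[t.row, t.col] = spectra.hurst
        quality[t.row, t.col] = min(spectra.quality_r2.values())
    return TileGrid(
        modality="mammo", shape=(nrows, ncols), classes=classes,
        estimates=estimates, quality=quality, tiles=tiles,
    )


# ----------------------------------------------------------------------
def tile_thermogram(
    stack: np.ndarray,
    sampling_rate: float = 50.0,
    mask: np.ndarray | None = None,
    tile: int = THERMO_TILE,
    min_coverage: float = MIN_MASK_COVERAGE,
    frequency_window: tuple[float, float] = (0.3, 4.0),
    wavelet_order: int = 3,
) -> TileGrid:
    """Group per-pixel series into ``tile`` x ``tile`` squares and
    classify each square's dynamics (red = monofractal, blue =
    multifractal, white = no scaling).

    ``stack`` has shape (n_frames, rows, cols), n_frames >= 4096.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    nf, ny, nx = stack.shape
    if nf < 4096:
        raise ValueError("need at least 4096 frames")
    nrows, ncols = ny // tile, nx // tile
    classes = np.full((nrows, ncols), "none", dtype=object)
    estimates = np.full((nrows, ncols), np.nan)
    quality = np.full((nrows, ncols), np.nan)
    tiles = []
    for i in range(nrows):
        for j in range(ncols):
            sl = (slice(i * tile, (i + 1) * tile), slice(j * tile, (j + 1) * tile))
            cov = 1.0
            if mask is not None:
                cov = float(mask[sl].mean())
                if cov < min_coverage:
                    continue
            series = stack[:, sl[0], sl[1]].reshape(nf, -1).T.astype(float)
            if np.ptp(series) == 0:
                classes[i, j] = "white"
                tiles.append(Tile(row=i, col=j, core=sl, window=sl, coverage=cov))
                continue
            model = WTMM1D(
                series, sampling_rate=sampling_rate,
                frequency_window=frequency_window, wavelet_order=wavelet_order,
            )
            diag = model.diagnose()
            classes[i, j] = {
                "monofractal": "red", "multifractal": "blue", "no_scaling": "white",
            }[diag.label]
            estimates[i, j] = diag.c2
            quality[i, j] = min(diag.spectra.quality_r2.values())
            tiles.append(Tile(row=i, col=j, core=sl, window=sl, coverage=cov))
    return TileGrid(
        modality="thermo", shape=(nrows, ncols), classes=classes,
        estimates=estimates, quality=quality, tiles=tiles,
    )


# ----------------------------------------------------------------------
def summarize_breast(grid: TileGrid, view: str = "") -> BreastSummary:
    """Exact class counts and percentages over the analysed tiles."""
    counts = grid.counts()
    n_total = int(grid.analyzed_mask().sum())
    if n_total == 0:
        raise ValueError("empty tile grid: nothing analysed")
    return BreastSummary(modality=grid.modality, view=view, counts=counts, n_total=n_total)


def render_class_map(grid: TileGrid) -> np.ndarray:
    """RGB (uint8) rendering of the classified tile grid in the
    conventional colours."""
    rows, cols = grid.shape
    img = np.zeros((rows, cols, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            img[r, c] = CLASS_COLORS.get(str(grid.classes[r, c]), (0, 0, 0))
    return img
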