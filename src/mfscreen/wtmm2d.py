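"""2D WTMM analysis of rough surfaces (mammogram-like images).

The image is convolved with the dilated partial derivatives of an
isotropic Gaussian, giving at each scale the gradient vector field of
the smoothed image (its modulus and argument).  Edge-like points where
the modulus is locally maximal along the gradient direction form
connected *maxima chains*; the local maxima of the modulus along each
chain (WTMMM) are chained across scales into the WT skeleton, from
which partition functions and scaling spectra are computed.

The model class :class:`WTMM2D` wraps the full chain::

    res = WTMM2D(image).fit()
    res.hurst, res.c2, res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .partition import compute_partition_functions, default_q_grid
from .scales import DEFAULT_PIXEL_SIZE_MM, ScaleGrid
from .skeleton import Skeleton, link_maxima
from .spectra import ScalingSpectra, fit_scaling
from .wavelets import gradient_multipliers_2d

__all__ = [
    "Image2D",
    "WTSlice2D",
    "MaximaChain",
    "WTMM2D",
    "gradient_wavelet_transform",
    "extract_maxima_chains",
    "locate_wtmmm",
    "build_skeleton",
]

#: modulus maxima below this fraction of the per-scale peak modulus are
#: treated as numerical noise
MODULUS_FLOOR_REL = 1e-9
#: minimum number of pixels for a maxima chain to be kept
MIN_CHAIN_LENGTH = 4
#: mirror-padding radius, in units of the dilated kernel scale
PAD_RADIUS_SCALES = 5.0

_EIGHT_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Image2D:
    """Grayscale image with physical pixel size (mm); origin is the
    top-left corner, row-major, pixel centres at integer coordinates."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM
    origin: str = "upper-left"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("non-finite pixel values rejected")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class WTSlice2D:
    """Gradient-wavelet transform of one image at one scale."""

    scale: float                 # dimensionless a
    scale_pixels: float          # a * unit_scale
    w1: np.ndarray               # x (column) component
    w2: np.ndarray               # y (row) component
    modulus: np.ndarray = field(default=None)
    argument: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.modulus is None:
            self.modulus = np.hypot(self.w1, self.w2)
        if self.argument is None:
            arg = np.arctan2(self.w2, self.w1)
            arg[arg == -np.pi] = np.pi  # argument in (-pi, pi]
            self.argument = arg


@dataclass
class MaximaChain:
    """Ordered connected chain of modulus maxima at one scale."""

    scale: float
    points: np.ndarray           # (n, 2) sub-pixel (row, col)
    moduli: np.ndarray
    arguments: np.ndarray
    closed: bool

    def __len__(self) -> int:
        return len(self.moduli)


# ----------------------------------------------------------------------
# transform
# ----------------------------------------------------------------------
def _check_image_size(shape: tuple[int, int], grid: ScaleGrid) -> None:
    a_max_px = grid.scales[-1] * grid.unit_scale
    min_size = int(np.ceil(4.0 * a_max_px))
    if min(shape) < min_size:
        raise ValueError(
            f"image of shape {shape} too small for largest scale "
            f"a={grid.scales[-1]:g} ({a_max_px:g} px): need >= {min_size} px per side"
        )


def _padded_spectrum(pixels: np.ndarray, grid: ScaleGrid, boundary: str):
    ny, nx = pixels.shape
    if boundary == "periodic":
        pad = 0
        padded = pixels
    elif boundary == "mirror":
        a_max_px = grid.scales[-1] * grid.unit_scale
        pad = int(min(np.ceil(PAD_RADIUS_SCALES * a_max_px), min(ny, nx) - 1))
        padded = np.pad(pixels, pad, mode="reflect")
    else:
        raise ValueError("boundary must be 'mirror' or 'periodic'")
    return np.fft.rfft2(padded), padded.shape, pad


def _slice_at_scale(spec, pshape, pad, shape, grid: ScaleGrid, a: float) -> WTSlice2D:
    a_px = a * grid.unit_scale
    m1, m2 = gradient_multipliers_2d(pshape, a_px)
    w1 = np.fft.irfft2(spec * m1, s=pshape)
    w2 = np.fft.irfft2(spec * m2, s=pshape)
    ny, nx = shape
    sl = (slice(pad, pad + ny), slice(pad, pad + nx))
    return WTSlice2D(scale=a, scale_pixels=a_px, w1=w1[sl], w2=w2[sl])


def gradient_wavelet_transform(
    image: Image2D, grid: ScaleGrid | None = None, boundary: str = "mirror"
) -> list[WTSlice2D]:
    """Gradient-wavelet transform at every ladder scale.

    Returns one :class:`WTSlice2D` per scale (all held in memory; the
    model class streams instead).  The image must be at least 4 a_max
    pixels in each direction.
    """
    if not isinstance(image, Image2D):
        image = Image2D(np.asarray(image))
    grid = grid or ScaleGrid.default_image()
    _check_image_size(image.shape, grid)
    spec, pshape, pad = _padded_spectrum(image.pixels, grid, boundary)
    return [
        _slice_at_scale(spec, pshape, pad, image.shape, grid, a) for a in grid.scales
    ]


# ----------------------------------------------------------------------
# maxima chains / WTMMM
# ----------------------------------------------------------------------
def _bilinear(arr: np.ndarray, rr: np.ndarray, cc: np.ndarray, wrap: bool) -> np.ndarray:
    ny, nx = arr.shape
    r0 = np.floor(rr).astype(np.intp)
    c0 = np.floor(cc).astype(np.intp)
    fr = rr - r0
    fc = cc - c0
    r1 = r0 + 1
    c1 = c0 + 1
    if wrap:
        r0 %= ny; r1 %= ny; c0 %= nx; c1 %= nx
    else:
        np.clip(r0, 0, ny - 1, out=r0); np.clip(r1, 0, ny - 1, out=r1)
        np.clip(c0, 0, nx - 1, out=c0); np.clip(c1, 0, nx - 1, out=c1)
    return (
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0, c1] * (1 - fr) * fc
        + arr[r1, c0] * fr * (1 - fc)
        + arr[r1, c1] * fr * fc
    )


def _chain_mask(slice_: WTSlice2D, wrap: bool = False):
    """Canny-style non-maximum suppression: pixels where the modulus is
    locally maximal along the argument direction (bilinear sampling one
    pixel away on each side).  Returns (mask, m_minus, m_plus)."""
    mod, arg = slice_.modulus, slice_.argument
    ny, nx = mod.shape
    peak = mod.max()
    if peak <= 0:
        z = np.zeros_like(mod, dtype=bool)
        return z, mod, mod
    rows, cols = np.indices((ny, nx))
    uy = np.sin(arg)
    ux = np.cos(arg)
    m_plus = _bilinear(mod, rows + uy, cols + ux, wrap)
    m_minus = _bilinear(mod, rows - uy, cols - ux, wrap)
    # strict on the plus side so exact plateaus (edges between pixels)
    # keep a single pixel across the chain
    mask = (mod > m_plus) & (mod >= m_minus) & (mod > MODULUS_FLOOR_REL * peak)
    return mask, m_minus, m_plus


def _drop_short_chains(mask: np.ndarray, min_length: int = MIN_CHAIN_LENGTH) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    small = sizes < min_length
    small[0] = False
    return mask & ~small[labels]


def _shifted(arr, dr, dc, fill, wrap):
    out = np.roll(arr, (dr, dc), axis=(0, 1))
    if not wrap:
        if dr == 1:
            out[0, :] = fill
        elif dr == -1:
            out[-1, :] = fill
        if dc == 1:
            out[:, 0] = fill
        elif dc == -1:
            out[:, -1] = fill
    return out


def _local_maxima_2d(slice_: WTSlice2D, wrap: bool) -> tuple[np.ndarray, np.ndarray]:
    """WTMMM as strict 2D local maxima of the modulus (3x3 window).

    A modulus maximum along a maxima chain is simultaneously maximal
    across the chain (chain definition) and along it (WTMMM
    definition), i.e. a spatial local maximum of M; detecting them
    directly is robust to the fragmentation of discretised chains.
    Sub-pixel positions by separable quadratic interpolation.
    """
    mod = slice_.modulus
    peak = mod.max()
    if peak <= 0:
        return np.empty((0, 2)), np.empty(0)
    mode = "wrap" if wrap else "nearest"
    mx = ndimage.maximum_filter(mod, size=3, mode=mode)
    keep = (mod == mx) & (mod > MODULUS_FLOOR_REL * peak)
    # plateau guard: keep the lexicographically first pixel of any tie
    lab, n = ndimage.label(keep, structure=_EIGHT_CONN)
    if n and lab.max() != keep.sum():
        first = np.zeros(n + 1, dtype=bool)
        rr_, cc_ = np.nonzero(keep)
        out_keep = np.zeros_like(keep)
        for r_, c_ in zip(rr_, cc_):
            l_ = lab[r_, c_]
            if not first[l_]:
                first[l_] = True
                out_keep[r_, c_] = True
        keep = out_keep
    rr, cc = np.nonzero(keep)
    if rr.size == 0:
        return np.empty((0, 2)), np.empty(0)
    m0 = mod[rr, cc]
    ny, nx = mod.shape

    def refine(idx, lim, along_rows):
        lo = idx - 1
        hi = idx + 1
        if wrap:
            lo %= lim
            hi %= lim
        else:
            lo = np.clip(lo, 0, lim - 1)
            hi = np.clip(hi, 0, lim - 1)
        if along_rows:
            ml, mh = mod[lo, cc], mod[hi, cc]
        else:
            ml, mh = mod[rr, lo], mod[rr, hi]
        den = ml - 2 * m0 + mh
        d = np.where(np.abs(den) > 1e-30, 0.5 * (ml - mh) / den, 0.0)
        return np.clip(d, -0.5, 0.5)

    dr = refine(rr, ny, True)
    dc = refine(cc, nx, False)
    pos = np.stack([rr + dr, cc + dc], axis=1)
    return pos, m0


def extract_maxima_chains(
    slice_: WTSlice2D, min_length: int = MIN_CHAIN_LENGTH, wrap: bool = False
) -> list[MaximaChain]:
    """Connected maxima chains at one scale, with points ordered by a
    nearest-neighbour walk (closed flag set when the chain is a loop).

    A zero-modulus slice yields an empty list.
    """
    mask, m_minus, m_plus = _chain_mask(slice_, wrap)
    mask = _drop_short_chains(mask, min_length)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    chains: list[MaximaChain] = []
    mod, arg = slice_.modulus, slice_.argument
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        pts = list(zip(rr.tolist(), cc.tolist()))
        order, closed = _order_chain(pts)
        idx = np.array(order)
        r = rr[idx]
        c = cc[idx]
        chains.append(
            MaximaChain(
                scale=slice_.scale,
                points=np.stack([r, c], axis=1).astype(float),
                moduli=mod[r, c],
                arguments=arg[r, c],
                closed=closed,
            )
        )
    return chains


def _order_chain(pts: list[tuple[int, int]]) -> tuple[list[int], bool]:
    """Order chain pixels by walking from an endpoint (or from the
    lexicographically first pixel for a closed loop)."""
    index = {p: i for i, p in enumerate(pts)}
    nbrs: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pts}
    for (r, c) in pts:
        for dr, dc in _EIGHT_SHIFTS:
            q = (r + dr, c + dc)
            if q in index:
                nbrs[(r, c)].append(q)
    endpoints = sorted(p for p in pts if len(nbrs[p]) <= 1)
    closed = not endpoints
    start = endpoints[0] if endpoints else min(pts)
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in sorted(nbrs[cur]) if q not in visited]
        if not nxt:
            break
        cur = nxt[0]
        order.append(cur)
        visited.add(cur)
    # append stragglers (branched chains) deterministically
    for p in sorted(pts):
        if p not in visited:
            order.append(p)
            visited.add(p)
    return [index[p] for p in order], closed


def locate_wtmmm(chain: MaximaChain) -> list[tuple[np.ndarray, float]]:
    """Positions along a chain where the modulus is a strict local
    maximum w.r.t. both chain neighbours (circularly for closed
    chains).  Modulus plateaus keep one representative, chosen by
    largest modulus then lowest (row, col); 1-2 point chains return
    their maximum-modulus point."""
    m = chain.moduli
    n = len(m)
    if n <= 2 or np.all(m == m[0]):
        i = int(np.lexsort((chain.points[:, 1], chain.points[:, 0], -m))[0])
        return [(chain.points[i], float(m[i]))]

    def rank(i):  # tie-break key: larger modulus, then lower (row, col)
        return (-m[i], chain.points[i, 0], chain.points[i, 1])

    out = []
    idx = range(n) if chain.closed else range(1, n - 1)
    for i in idx:
        left = (i - 1) % n
        right = (i + 1) % n
        if rank(i) < rank(left) and rank(i) < rank(right):
            out.append((chain.points[i], float(m[i])))
    if not out:  # constant-modulus chain: single representative
        i = min(range(n), key=rank)
        out.append((chain.points[i], float(m[i])))
    return out


def build_skeleton(
    wtmmm_by_scale: list[tuple[np.ndarray, np.ndarray]], grid: ScaleGrid
) -> Skeleton:
    """Link per-scale WTMMM into maxima lines (fine to coarse,
    nearest-neighbour within the chaining radius)."""
    return link_maxima(wtmmm_by_scale, grid)


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------
class WTMM2D:
    """2D WTMM model for one image (or image tile).

    Parameters
    ----------
    image : Image2D or 2D array
    grid : ScaleGrid, optional
        Defaults to :meth:`ScaleGrid.default_image`.
    q_grid : array, optional
        Defaults to q in [-2, 5] step 0.25.
    boundary : 'mirror' or 'periodic'
        'periodic' suits spectrally synthesised (periodic) test
        surfaces and avoids padding cost.
    """

    def __init__(
        self,
        image,
        pixel_size: float = DEFAULT_PIXEL_SIZE_MM,
        grid: ScaleGrid | None = None,
        q_grid: np.ndarray | None = None,
        boundary: str = "mirror",
    ) -> None:
        self.image = image if isinstance(image, Image2D) else Image2D(np.asarray(image), pixel_size)
        self.grid = grid or ScaleGrid.default_image()
        self.q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
        self.boundary = boundary
        _check_image_size(self.image.shape, self.grid)

    # ------------------------------------------------------------------
    def wtmmm_by_scale(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-scale WTMMM (positions, moduli), streaming one transform
        slice at a time."""
        wrap = self.boundary == "periodic"
        spec, pshape, pad = _padded_spectrum(self.image.pixels, self.grid, self.boundary)
        out = []
        for a in self.grid.scales:
            sl = _slice_at_scale(spec, pshape, pad, self.image.shape, self.grid, a)
            out.append(_local_maxima_2d(sl, wrap))
        return out

    def build_skeleton(self) -> Skeleton:
        return build_skeleton(self.wtmmm_by_scale(), self.grid)

    def fit(
        self,
        core: tuple[slice, slice] | None = None,
        margin: float = 0.0,
        skeleton: Skeleton | None = None,
    ) -> ScalingSpectra:
        """Run the full pipeline and return the fitted spectra.

        ``core`` restricts the partition functions to maxima lines
        rooted inside the given (row_slice, col_slice) — the central
        256x256 part of a mammographic tile.  ``margin`` (pixels)
        instead excludes lines rooted within that distance of the
        image border; a scale-independent interior restriction that
        removes mirror-boundary contamination of whole-image analyses
        without distorting the line-count decay.
        """
        skeleton = skeleton or self.build_skeleton()
        root_filter = None
        if core is not None or margin > 0:
            ny, nx = self.image.shape
            rs, cs = core if core is not None else (slice(0, ny), slice(0, nx))
            r_lo, r_hi = max(rs.start, margin), min(rs.stop, ny - margin)
            c_lo, c_hi = max(cs.start, margin), min(cs.stop, nx - margin)
            rootpos = skeleton.positions[np.arange(skeleton.n_lines), skeleton.root]
            root_filter = (
                (rootpos[:, 0] >= r_lo) & (rootpos[:, 0] < r_hi)
                & (rootpos[:, 1] >= c_lo) & (rootpos[:, 1] < c_hi)
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pf = compute_partition_functions(skeleton, self.q_grid, root_filter)
            if np.all(pf.counts == 0):
                raise ValueError("empty skeleton")
            spectra = fit_scaling(pf, self.grid, support_dim=2, lognormal_q_range=(-1.0, 2.0))
        except (ValueError, np.linalg.LinAlgError):
            spectra = _degenerate_spectra(self.q_grid, self.grid, support_dim=2)
        return spectra


def _degenerate_spectra(q_grid, grid, support_dim) -> ScalingSpectra:
    nq = len(q_grid)
    nan = np.full(nq, np.nan)
    return ScalingSpectra(
        q_grid=np.asarray(q_grid, float),
        tau=nan.copy(), tau_se=nan.copy(), h_q=nan.copy(), d_q=nan.copy(),
        c0=np.nan, c1=np.nan, c2=np.nan, c2_raw=np.nan,
        hurst=np.nan, hurst_se=np.nan, hurst_residual=np.nan,
        quality_r2={0.0: 0.0, 1.0: 0.0, 2.0: 0.0},
        scaling_ok=False, support_dim=support_dim,
        fit_range=tuple(grid.fit_range),
    )
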