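"""Cross-scale chaining of modulus maxima into the WT skeleton.

At every scale of the ladder the transform yields a set of modulus
maxima (WTMM in 1D, WTMMM in 2D).  Maxima are linked from fine to
coarse scales by nearest-neighbour matching within a scale-dependent
chaining radius; the resulting *maxima lines* form the skeleton.  The
wavelet modulus followed along a line behaves as ``a^h`` where ``h`` is
the Holder exponent of the underlying singularity, which is what the
partition functions quantify.

Lines die when they fail to find a continuation or when they lose the
competition for a coarse maximum (line merging); the number of lines
crossing a scale therefore decays with ``a``, carrying the support
dimension of the singularity set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .scales import ScaleGrid

__all__ = ["MaximaLine", "Skeleton", "link_maxima", "chaining_radius"]


def chaining_radius(a: float, unit_scale: float) -> float:
    """Maximum positional jump (pixels/samples) allowed between
    consecutive scales: max(1.5, 0.3 * a * unit_scale)."""
    return max(1.5, 0.3 * a * unit_scale)


@dataclass(frozen=True)
class MaximaLine:
    """One maxima line: (scale, position, modulus) per crossed scale."""

    scales: np.ndarray          # strictly increasing subset of the ladder
    positions: np.ndarray       # (n, d) sub-pixel coordinates
    moduli: np.ndarray          # (n,) strictly positive WT moduli

    @property
    def root_position(self) -> np.ndarray:
        return self.positions[0]

    def __len__(self) -> int:
        return len(self.scales)


class Skeleton:
    """Set of maxima lines over a scale ladder, stored densely.

    Attributes
    ----------
    grid : ScaleGrid
    positions : ndarray, shape (L, S, d)
        NaN outside a line's lifetime.
    modulus : ndarray, shape (L, S)
    root, death : ndarray of int, shape (L,)
        First and last (inclusive) scale index of each line.
    """

    def __init__(
        self,
        grid: ScaleGrid,
        positions: np.ndarray,
        modulus: np.ndarray,
        root: np.ndarray,
        death: np.ndarray,
    ) -> None:
        self.grid = grid
        self.positions = positions
        self.modulus = modulus
        self.root = root
        self.death = death

    @property
    def n_lines(self) -> int:
        return self.modulus.shape[0]

    def alive(self, scale_index: int, root_max: int | None = None) -> np.ndarray:
        """Boolean mask of lines crossing ``scale_index`` (optionally
        restricted to lines rooted at/below ``root_max``)."""
        mask = (self.root <= scale_index) & (self.death >= scale_index)
        if root_max is not None:
            mask &= self.root <= root_max
        return mask

    def count_crossing(self, scale_index: int) -> int:
        return int(self.alive(scale_index).sum())

    def sup_modulus(self) -> np.ndarray:
        """Modulus with the supremum replacement: at scale ``a`` each
        line carries the supremum of its moduli at scales <= a.  This
        is the standard guard making the q < 0 partition functions
        well-behaved."""
        m = np.where(np.isnan(self.modulus), -np.inf, self.modulus)
        sup = np.maximum.accumulate(m, axis=1)
        out = np.where(np.isnan(self.modulus), np.nan, sup)
        return out

    def line(self, i: int) -> MaximaLine:
        sl = slice(self.root[i], self.death[i] + 1)
        return MaximaLine(
            scales=self.grid.scales[sl],
            positions=self.positions[i, sl],
            moduli=self.modulus[i, sl],
        )

    def __iter__(self):
        return (self.line(i) for i in range(self.n_lines))

    def __len__(self) -> int:
        return self.n_lines


def link_maxima(
    points_by_scale: list[tuple[np.ndarray, np.ndarray]],
    grid: ScaleGrid,
) -> Skeleton:
    """Link per-scale maxima into a :class:`Skeleton`.

    Parameters
    ----------
    points_by_scale : list of (positions, moduli)
        One entry per ladder scale; ``positions`` has shape (k, d)
        (d = 1 or 2), ``moduli`` shape (k,).
    grid : ScaleGrid

    Linking is greedy fine-to-coarse: active lines claim their nearest
    maximum at the next scale inside the chaining radius; a maximum can
    be claimed once (losers terminate, i.e. lines merge), and maxima
    left unclaimed root new lines at that scale.  Claims are processed
    in a deterministic order (distance, then larger modulus, then
    lexicographic position).
    """
    n_scales = grid.n_scales
    if len(points_by_scale) != n_scales:
        raise ValueError("need one maxima set per ladder scale")

    d = 1
    for pos, _ in points_by_scale:
        if len(pos):
            d = np.atleast_2d(pos).shape[1]
            break

    pos_rows: list[list[np.ndarray]] = []   # per line: per-scale positions
    mod_rows: list[list[float]] = []
    roots: list[int] = []
    active: list[int] = []                  # indices into pos_rows

    for j in range(n_scales):
        pts, mods = points_by_scale[j]
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        mods = np.asarray(mods, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, d)
        k = pts.shape[0]

        claimed = np.zeros(k, dtype=bool)
        if j > 0 and active and k:
            radius = chaining_radius(grid.scales[j], grid.unit_scale)
            cur_pos = np.array([pos_rows[i][-1] for i in active])
            cur_mod = np.array([mod_rows[i][-1] for i in active])
            tree = cKDTree(pts)
            kq = min(4, k)
            dist, idx = tree.query(cur_pos, k=kq)
            dist = np.atleast_2d(dist.reshape(len(active), kq))
            idx = np.atleast_2d(idx.reshape(len(active), kq))
            order = np.lexsort(
                tuple(cur_pos[:, c] for c in range(d - 1, -1, -1))
                + (-cur_mod, dist[:, 0])
            )
            survivors: list[int] = []
            for a_i in order:
                line = active[a_i]
                for cand in range(kq):
                    tgt = int(idx[a_i, cand])
                    if dist[a_i, cand] > radius:
                        break
                    if not claimed[tgt]:
                        claimed[tgt] = True
                        pos_rows[line].append(pts[tgt])
                        mod_rows[line].append(float(mods[tgt]))
                        survivors.append(line)
                        break
            active = survivors  # losers simply stop growing (death recorded by length)
        elif j > 0:
            active = []

        # maxima left unclaimed root new lines at this scale
        for t in range(k):
            if not claimed[t]:
                pos_rows.append([pts[t]])
                mod_rows.append([float(mods[t])])
                roots.append(j)
                active.append(len(pos_rows) - 1)

    return _pack(pos_rows, mod_rows, roots, grid, d)


def _pack(pos_rows, mod_rows, roots, grid, d):
    n_scales = grid.n_scales
    n_lines = len(pos_rows)
    positions = np.full((n_lines, n_scales, d), np.nan)
    modulus = np.full((n_lines, n_scales), np.nan)
    root = np.asarray(roots, dtype=int)
    death = np.empty(n_lines, dtype=int)
    for i in range(n_lines):
        n = len(mod_rows[i])
        death[i] = root[i] + n - 1
        positions[i, root[i] : root[i] + n] = np.asarray(pos_rows[i])
        modulus[i, root[i] : root[i] + n] = np.asarray(mod_rows[i])
    return Skeleton(grid, positions, modulus, root, death)
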