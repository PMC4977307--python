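"""Partition functions over the WT skeleton and Boltzmann weights.

The moment-q partition function over the maxima lines crossing scale a,

    Z(q, a) = sum_{l in L(a)} M(l, a)^q  ~  a^tau(q),

together with the expectation values obtained from the Boltzmann
weights W_hat(q, l, a) = M^q / Z(q, a),

    h(q, a) = sum_l ln M(l, a) W_hat(q, l, a),
    D(q, a) = sum_l W_hat ln W_hat = q h(q, a) - ln Z(q, a),

whose slopes vs. ln a give h(q) and D(q), the parametric form of the
singularity spectrum D(h).

A line enters L(a) iff it is rooted at or below the first fit-range
scale and is still alive at a; the modulus is the supremum-replaced one
(see Skeleton.sup_modulus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .scales import ScaleGrid
from .skeleton import Skeleton

__all__ = ["PartitionFunctionSet", "compute_partition_functions", "boltzmann_weights", "default_q_grid"]


def default_q_grid(q_min: float = -2.0, q_max: float = 5.0, step: float = 0.25) -> np.ndarray:
    n = int(round((q_max - q_min) / step)) + 1
    return np.linspace(q_min, q_max, n)


def boltzmann_weights(moduli: np.ndarray, q: float) -> np.ndarray:
    """Normalised weights M^q / Z for one (q, a); sums to 1."""
    logm = np.log(moduli)
    logw = q * logm - logsumexp(q * logm)
    return np.exp(logw)


@dataclass
class PartitionFunctionSet:
    """Z, h and D partition functions on a (q, a) grid.

    ``scale_indices`` are indices into ``grid.scales`` (the fit-range
    scales); ``line_moduli[j]`` holds the supremum-replaced moduli of
    the lines crossing the j-th of those scales, so the weights can be
    reconstructed exactly.
    """

    grid: ScaleGrid
    q_grid: np.ndarray
    scale_indices: np.ndarray
    log_z: np.ndarray            # natural log Z, shape (nq, ns)
    h_pf: np.ndarray             # shape (nq, ns)
    d_pf: np.ndarray             # shape (nq, ns)
    counts: np.ndarray           # lines crossing each scale, shape (ns,)
    line_moduli: list = field(default_factory=list, repr=False)
    n_averaged: int = 1          # number of signals averaged (1D tiles)

    @property
    def scales(self) -> np.ndarray:
        return self.grid.scales[self.scale_indices]

    @property
    def z(self) -> np.ndarray:
        return np.exp(self.log_z)

    @property
    def log2_z(self) -> np.ndarray:
        return self.log_z / np.log(2.0)


def compute_partition_functions(
    skeleton: Skeleton,
    q_grid: np.ndarray | None = None,
    root_filter: np.ndarray | None = None,
) -> PartitionFunctionSet:
    """Evaluate Z(q, a), h(q, a), D(q, a) over the fit-range scales.

    Parameters
    ----------
    skeleton : Skeleton
    q_grid : array, optional
        Defaults to q in [-2, 5] step 0.25.
    root_filter : bool array over lines, optional
        Extra eligibility mask (e.g. restrict to lines rooted inside a
        tile's central core).
    """
    grid = skeleton.grid
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)

    fit_idx = grid.fit_indices
    if fit_idx.size < 3:
        raise ValueError("fewer than 3 scales inside fit_range")

    # L(a) = lines alive at a; the count of crossing lines then decays
    # as a^-D, carrying the support dimension into tau(0)
    eligible = np.ones(skeleton.n_lines, dtype=bool)
    if root_filter is not None:
        eligible &= root_filter
    sup = skeleton.sup_modulus()

    # log-of-zero guard: drop lines whose supremum modulus vanishes
    with np.errstate(invalid="ignore"):
        zero_lines = eligible & np.any(np.nan_to_num(sup, nan=1.0) <= 0, axis=1)
    if zero_lines.any():
        warnings.warn(f"dropping {int(zero_lines.sum())} maxima lines with zero modulus")
        eligible &= ~zero_lines

    nq, ns = q_grid.size, fit_idx.size
    log_z = np.full((nq, ns), np.nan)
    h_pf = np.full((nq, ns), np.nan)
    d_pf = np.full((nq, ns), np.nan)
    counts = np.zeros(ns, dtype=int)
    line_moduli: list[np.ndarray] = []

    for jj, j in enumerate(fit_idx):
        alive = eligible & skeleton.alive(j)
        m = sup[alive, j]
        line_moduli.append(m)
        counts[jj] = m.size
        if m.size == 0:
            continue
        logm = np.log(m)
        ql = q_grid[:, None] * logm[None, :]          # (nq, k)
        lz = logsumexp(ql, axis=1)
        w = np.exp(ql - lz[:, None])
        log_z[:, jj] = lz
        h_pf[:, jj] = w @ logm
        d_pf[:, jj] = q_grid * h_pf[:, jj] - lz

    return PartitionFunctionSet(
        grid=grid,
        q_grid=q_grid,
        scale_indices=fit_idx,
        log_z=log_z,
        h_pf=h_pf,
        d_pf=d_pf,
        counts=counts,
        line_moduli=line_moduli,
    )


def average_partition_functions(parts: list[PartitionFunctionSet]) -> PartitionFunctionSet:
    """Arithmetic average of Z, h and D over several signals at fixed
    (q, a) — the per-tile averaging used for the 64 series of an 8x8
    thermogram square."""
    if not parts:
        raise ValueError("nothing to average")
    ref = parts[0]
    for p in parts[1:]:
        if p.q_grid.shape != ref.q_grid.shape or not np.allclose(p.q_grid, ref.q_grid):
            raise ValueError("q grids differ")
        if not np.array_equal(p.scale_indices, ref.scale_indices):
            raise ValueError("scale ladders differ")
    z = np.nanmean([p.z for p in parts], axis=0)
    h = np.nanmean([p.h_pf for p in parts], axis=0)
    d = np.nanmean([p.d_pf for p in parts], axis=0)
    counts = np.mean([p.counts for p in parts], axis=0)
    with np.errstate(divide="ignore"):
        log_z = np.log(z)
    return PartitionFunctionSet(
        grid=ref.grid,
        q_grid=ref.q_grid,
        scale_indices=ref.scale_indices,
        log_z=log_z,
        h_pf=h,
        d_pf=d,
        counts=counts,
        n_averaged=len(parts),
    )
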