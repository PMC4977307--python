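"""Scaling-exponent estimation: tau(q), h(q), D(q), log-normal fit,
Hurst exponent and the scaling-quality gate.

tau(q) is the slope of log2 Z(q, a) vs log2 a over the fit window;
h(q) and D(q) are the slopes of the corresponding expectation values
vs ln a, giving the singularity spectrum D(h) as a curve parametrised
by q.  A quadratic (log-normal) approximation

    tau(q) = -c0 + c1 q - c2 q^2 / 2

summarises the spectrum: c0 is the support dimension, c1 the most
frequent Holder exponent, and the intermittency coefficient c2 the
width of D(h) — c2 = 0 for monofractal scaling.  For monofractal rough
surfaces tau(q) = qH - 2 and D(h) collapses onto the point (H, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .partition import PartitionFunctionSet

__all__ = [
    "ScalingSpectra",
    "HurstEstimate",
    "NoScalingError",
    "fit_scaling",
    "estimate_hurst",
]

#: R^2 threshold of the log2 Z vs log2 a regressions at q = 0, 1, 2
#: below which a tile is flagged as showing no convincing scaling
QUALITY_R2_THRESHOLD = 0.98
#: alternative gate for control moments whose true slope is near zero
#: (where R^2 is uninformative): RMS deviation of log2 Z from the
#: fitted line, in log2 units
QUALITY_RESID_THRESHOLD = 0.05


class NoScalingError(RuntimeError):
    """Raised when an estimate is requested from spectra flagged as
    showing no scaling; callers map this to the pink/white class."""


@dataclass(frozen=True)
class HurstEstimate:
    value: float
    se: float
    residual: float          # weighted RMS deviation of tau(q) from the line
    q_range: tuple[float, float]

    def __float__(self) -> float:
        return self.value


@dataclass
class ScalingSpectra:
    """Results object carrying the fitted multifractal spectra.

    Produced by :func:`fit_scaling` (and by the ``fit`` methods of the
    WTMM model classes).  ``quality_r2`` maps the control moments
    q = 0, 1, 2 to the R^2 of their log-log regressions; ``scaling_ok``
    is False when any falls below :data:`QUALITY_R2_THRESHOLD`.
    """

    q_grid: np.ndarray
    tau: np.ndarray
    tau_se: np.ndarray
    h_q: np.ndarray
    d_q: np.ndarray
    c0: float
    c1: float
    c2: float
    c2_raw: float
    hurst: float
    hurst_se: float
    hurst_residual: float
    quality_r2: dict
    scaling_ok: bool
    support_dim: int
    fit_range: tuple[float, float]
    hurst_q_range: tuple[float, float] = (-1.0, 3.0)
    lognormal_q_range: tuple[float, float] = (-1.0, 2.0)
    counts: np.ndarray | None = field(default=None, repr=False)
    pf: PartitionFunctionSet | None = field(default=None, repr=False)

    # ------------------------------------------------------------------
    @property
    def flag(self) -> str:
        return "scaling" if self.scaling_ok else "no_scaling"

    def d_of_h(self) -> tuple[np.ndarray, np.ndarray]:
        """The singularity spectrum as the parametric curve (h(q), D(q))."""
        return self.h_q, self.d_q

    def legendre_residual(self, q_range: tuple[float, float] = (-1.0, 3.0)) -> float:
        """max_q |D(q) - (q h(q) - tau(q))| over the converged q window."""
        m = (self.q_grid >= q_range[0]) & (self.q_grid <= q_range[1])
        return float(np.nanmax(np.abs(self.d_q[m] - (self.q_grid[m] * self.h_q[m] - self.tau[m]))))

    def tau_records(self) -> list[tuple[float, float, float]]:
        return [(float(q), float(t), float(s)) for q, t, s in zip(self.q_grid, self.tau, self.tau_se)]

    def summary(self) -> str:
        lines = [
            "WTMM scaling spectra",
            "=" * 52,
            f"support dimension        {self.support_dim}",
            f"fit range (a)            [{self.fit_range[0]:g}, {self.fit_range[1]:g}]",
            f"scaling flag             {self.flag}",
            f"quality R^2 (q=0,1,2)    "
            + ", ".join(f"{q:g}: {r:.4f}" for q, r in sorted(self.quality_r2.items())),
            f"Hurst H                  {self.hurst:.4f} +/- {self.hurst_se:.4f}"
            f"  (rms nonlinearity {self.hurst_residual:.4f})",
            f"log-normal c0, c1, c2    {self.c0:.3f}, {self.c1:.3f}, {self.c2:.4f}",
            "-" * 52,
            "   q      tau(q)     se        h(q)      D(q)",
        ]
        for q, t, s, h, d in zip(self.q_grid, self.tau, self.tau_se, self.h_q, self.d_q):
            if abs(q - round(q)) < 1e-9:
                lines.append(f"{q:5.1f}  {t:9.4f}  {s:8.4f}  {h:8.4f}  {d:8.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot tau(q) with its linear (monofractal) fit and the D(h)
        spectrum; returns the two axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.6))
        ax1, ax2 = ax
        ax1.errorbar(self.q_grid, self.tau, yerr=self.tau_se, fmt="o", ms=3, label=r"$\tau(q)$")
        if np.isfinite(self.hurst):
            qq = np.array(self.hurst_q_range)
            off = -self.support_dim
            ax1.plot(qq, self.hurst * qq + off, "--", label=rf"$qH-{self.support_dim}$, $H$={self.hurst:.3f}")
        ax1.set_xlabel("q")
        ax1.set_ylabel(r"$\tau(q)$")
        ax1.legend(fontsize=8)
        ok = np.isfinite(self.h_q) & np.isfinite(self.d_q)
        ax2.plot(self.h_q[ok], self.d_q[ok], "o-", ms=3)
        ax2.set_xlabel("h")
        ax2.set_ylabel("D(h)")
        ax2.set_ylim(0, self.support_dim + 0.3)
        return ax1, ax2

    def to_dict(self) -> dict:
        return {
            "H": float(self.hurst),
            "H_se": float(self.hurst_se),
            "c0": float(self.c0),
            "c1": float(self.c1),
            "c2": float(self.c2),
            "tau": self.tau_records(),
            "quality": {str(k): float(v) for k, v in self.quality_r2.items()},
            "flag": self.flag,
        }


# ----------------------------------------------------------------------
def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares y = b + m x; returns (m, se_m, intercept)."""
    sw = np.sqrt(w)
    A = np.stack([np.ones_like(x), x], axis=1) * sw[:, None]
    coef, res, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    dof = max(x.size - 2, 1)
    resid = y * sw - A @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[1]), float(np.sqrt(cov[1, 1])), float(coef[0])


def _wls_quad(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    A = np.stack([np.ones_like(x), x, x**2], axis=1) * sw[:, None]
    coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    return coef  # [p0, p1, p2]


def fit_scaling(
    pf: PartitionFunctionSet,
    grid=None,
    support_dim: int = 2,
    hurst_q_range: tuple[float, float] = (-1.0, 3.0),
    lognormal_q_range: tuple[float, float] = (-1.0, 2.0),
    quality_threshold: float = QUALITY_R2_THRESHOLD,
) -> ScalingSpectra:
    """Regress the partition functions into scaling spectra.

    tau(q) from log2 Z vs log2 a (per-q OLS with standard errors);
    h(q), D(q) from the expectation values vs ln a; weighted linear
    tau-fit on ``hurst_q_range`` for H; weighted quadratic fit on
    ``lognormal_q_range`` for (c0, c1, c2), with c2 clipped at 0.
    """
    grid = pf.grid if grid is None else grid
    a = pf.scales
    if a.size < 3:
        raise ValueError("fewer than 3 scales in fit_range")
    log2a = np.log2(a)
    lna = np.log(a)
    q = pf.q_grid

    nq = q.size
    tau = np.full(nq, np.nan)
    tau_se = np.full(nq, np.nan)
    h_q = np.full(nq, np.nan)
    d_q = np.full(nq, np.nan)
    r2 = np.full(nq, np.nan)
    resid = np.full(nq, np.nan)
    log2z = pf.log2_z
    for i in range(nq):
        y = log2z[i]
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        res = stats.linregress(log2a[ok], y[ok])
        tau[i], tau_se[i] = res.slope, res.stderr
        r2[i] = res.rvalue**2
        resid[i] = float(np.sqrt(np.mean(
            (y[ok] - (res.intercept + res.slope * log2a[ok])) ** 2
        )))
        hres = stats.linregress(lna[ok], pf.h_pf[i, ok])
        h_q[i] = hres.slope
        dres = stats.linregress(lna[ok], pf.d_pf[i, ok])
        d_q[i] = dres.slope

    # quality gate on the control moments q = 0, 1, 2: power-law fit
    # accepted if R^2 is high or, for near-flat curves where R^2 is
    # uninformative, if the absolute residual is small
    quality = {}
    gate_ok = []
    for qc in (0.0, 1.0, 2.0):
        i = int(np.argmin(np.abs(q - qc)))
        quality[qc] = float(r2[i]) if np.isfinite(r2[i]) else 0.0
        ok_q = np.isfinite(r2[i]) and (
            r2[i] >= quality_threshold
            or (np.isfinite(resid[i]) and resid[i] <= QUALITY_RESID_THRESHOLD)
        )
        gate_ok.append(bool(ok_q))
    scaling_ok = all(gate_ok)

    # weights: inverse regression variance, floored for exact fits
    def weights(mask):
        se = tau_se[mask]
        floor = np.nanmax(se) * 1e-6 + 1e-12
        return 1.0 / (se**2 + floor**2)

    hm = (q >= hurst_q_range[0]) & (q <= hurst_q_range[1]) & np.isfinite(tau) & np.isfinite(tau_se)
    if hm.sum() >= 3:
        hurst, hurst_se, _ = _wls_line(q[hm], tau[hm], weights(hm))
        w = weights(hm)
        fitline = hurst * q[hm] + (np.average(tau[hm], weights=w) - hurst * np.average(q[hm], weights=w))
        hurst_resid = float(np.sqrt(np.average((tau[hm] - fitline) ** 2, weights=w)))
    else:
        hurst = hurst_se = hurst_resid = np.nan

    lm = (q >= lognormal_q_range[0]) & (q <= lognormal_q_range[1]) & np.isfinite(tau) & np.isfinite(tau_se)
    if lm.sum() >= 4:
        p0, p1, p2 = _wls_quad(q[lm], tau[lm], weights(lm))
        c0, c1 = -float(p0), float(p1)
        c2_raw = -2.0 * float(p2)
    else:
        c0 = c1 = c2_raw = np.nan
    c2 = float(np.clip(c2_raw, 0.0, None)) if np.isfinite(c2_raw) else np.nan

    return ScalingSpectra(
        q_grid=q,
        tau=tau,
        tau_se=tau_se,
        h_q=h_q,
        d_q=d_q,
        c0=c0,
        c1=c1,
        c2=c2,
        c2_raw=c2_raw,
        hurst=float(hurst),
        hurst_se=float(hurst_se),
        hurst_residual=float(hurst_resid),
        quality_r2=quality,
        scaling_ok=bool(scaling_ok),
        support_dim=support_dim,
        fit_range=tuple(grid.fit_range),
        hurst_q_range=tuple(hurst_q_range),
        lognormal_q_range=tuple(lognormal_q_range),
        counts=np.asarray(pf.counts),
        pf=pf,
    )


def estimate_hurst(spectra: ScalingSpectra) -> HurstEstimate:
    """Hurst exponent from the weighted linear tau(q) fit.

    Refuses (``NoScalingError``) when the spectra are flagged
    no_scaling; segmentation maps that refusal to the pink/white class.
    """
    if not spectra.scaling_ok:
        raise NoScalingError("spectra flagged no_scaling; Hurst estimate refused")
    return HurstEstimate(
        value=spectra.hurst,
        se=spectra.hurst_se,
        residual=spectra.hurst_residual,
        q_range=spectra.hurst_q_range,
    )


def modulus_collapse_ks(
    moduli_a: np.ndarray, a: float, moduli_b: np.ndarray, b: float, hurst: float
) -> float:
    """Kolmogorov-Smirnov distance between the distributions of raw
    WTMM moduli rescaled by a^H at two scales.  For monofractal
    scaling the rescaled pdfs collapse and the distance is small."""
    x = np.asarray(moduli_a) / a**hurst
    y = np.asarray(moduli_b) / b**hurst
    return float(stats.ks_2samp(x, y).statistic)
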