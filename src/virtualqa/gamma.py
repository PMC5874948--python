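"""2D gamma-index comparison of calculated and measured dose/CU grids.

The gamma index at a reference point r is the minimum over evaluated
positions r' of

    sqrt( (D_eval(r') - D_ref(r))^2 / (dose_tol(r))^2  +  |r' - r|^2 / dta^2 )

with dose_tol = dose_pct% of the local reference dose ("local" normalization,
the clinical default here) or of the global reference maximum.  A point passes
when gamma <= 1; the passing rate is the percentage of evaluated points
passing.  Only reference pixels at or above ``threshold_pct`` of the reference
maximum are evaluated.

The minimization searches a displacement lattice of pitch ``step_mm``
(default dta/10) out to ``search_radius_factor * dta``, sampling the evaluated
grid by bilinear interpolation, and prunes displacements whose distance term
alone already exceeds every pixel's current best gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DoseGrid", "GammaResult", "compute_gamma",
           "passing_rate_from_counts", "low_signal_flag", "GammaError"]


class GammaError(ValueError):
    pass


@dataclass
class DoseGrid:
    """A 2D dose (or CU) distribution: ``values[iy, ix]`` with pixel centers
    at origin + index * spacing (mm)."""

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")

    def axes(self):
        ny, nx = self.values.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing
        ys = self.origin[1] + np.arange(ny) * self.spacing
        return xs, ys


@dataclass
class GammaResult:
    gamma_values: np.ndarray        # per evaluated pixel (flat)
    evaluated_mask: np.ndarray      # boolean, reference-grid shaped
    passing_rate: float             # percent of evaluated pixels with gamma <= 1
    criterion: dict

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated_mask.sum())

    @property
    def n_failing(self) -> int:
        return int(np.count_nonzero(self.gamma_values > 1.0))


def _displacement_lattice(radius: float, step: float) -> np.ndarray:
    k = int(np.floor(radius / step))
    g = np.arange(-k, k + 1) * step
    dx, dy = np.meshgrid(g, g)
    d = np.column_stack([dx.ravel(), dy.ravel()])
    r = np.hypot(d[:, 0], d[:, 1])
    keep = r <= radius + 1e-12
    d, r = d[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return d[order], r[order]


def compute_gamma(reference: DoseGrid, evaluated: DoseGrid,
                  dose_pct: float = 3.0, dta_mm: float = 3.0,
                  threshold_pct: float = 10.0,
                  normalization: str = "local",
                  search_radius_factor: float = 3.0,
                  step_mm: float | None = None) -> GammaResult:
    """Gamma analysis of ``evaluated`` against ``reference``.

    ``step_mm`` overrides the displacement-lattice pitch (default dta/10);
    a fixed absolute step makes passing rates provably monotone when the
    criterion is loosened, since the loose lattice contains the tight one.
    """
    if dose_pct <= 0 or dta_mm <= 0 or threshold_pct <= 0:
        raise ValueError("dose_pct, dta_mm and threshold_pct must be > 0")
    if normalization not in ("local", "global"):
        raise ValueError(f"unknown normalization {normalization!r}")

    ref_max = reference.values.max()
    if ref_max <= 0:
        raise GammaError("reference grid is identically zero")
    mask = reference.values >= (threshold_pct / 100.0) * ref_max
    if not mask.any():
        raise GammaError("no pixels above threshold")

    xs_r, ys_r = reference.axes()
    iy, ix = np.nonzero(mask)
    px = xs_r[ix]
    py = ys_r[iy]
    d_ref = reference.values[mask]

    xs_e, ys_e = evaluated.axes()
    interp = RegularGridInterpolator(
        (ys_e, xs_e), evaluated.values, method="linear",
        bounds_error=False, fill_value=np.nan)

    if normalization == "local":
        denom = (dose_pct / 100.0) * d_ref
    else:
        denom = np.full_like(d_ref, (dose_pct / 100.0) * ref_max)

    step = step_mm if step_mm is not None else dta_mm / 10.0
    offsets, radii = _displacement_lattice(search_radius_factor * dta_mm, step)

    gamma_sq = np.full(d_ref.shape, np.inf)
    for (ox, oy), r in zip(offsets, radii):
        dist_term = (r / dta_mm) ** 2
        if dist_term >= gamma_sq.max():
            break  # offsets are radius-sorted: nothing can improve further
        d_eval = interp(np.column_stack([py + oy, px + ox]))
        valid = np.isfinite(d_eval)
        if not valid.any():
            continue
        g = np.full_like(gamma_sq, np.inf)
        g[valid] = ((d_eval[valid] - d_ref[valid]) / denom[valid]) ** 2 + dist_term
        np.minimum(gamma_sq, g, out=gamma_sq)

    if not np.all(np.isfinite(gamma_sq)):
        raise GammaError(
            "some reference pixels have no overlapping evaluated data")
    gamma = np.sqrt(gamma_sq)
    passing = 100.0 * float(np.count_nonzero(gamma <= 1.0)) / gamma.size
    return GammaResult(
        gamma_values=gamma,
        evaluated_mask=mask,
        passing_rate=passing,
        criterion={"dose_pct": dose_pct, "dta_mm": dta_mm,
                   "threshold_pct": threshold_pct,
                   "normalization": normalization},
    )


def passing_rate_from_counts(result: GammaResult) -> tuple[int, int]:
    """(D, y): evaluated-pixel and failing-pixel counts of a gamma result.

    Satisfies 100 * (1 - y/D) == result.passing_rate exactly.
    """
    return result.n_evaluated, result.n_failing


def low_signal_flag(reference: DoseGrid, cutoff: float = 0.3) -> bool:
    """Screen for beams dominated by low CU, where portal-dosimetry response
    errors make gamma unreliable: flags when the mean value of
    above-threshold pixels falls below ``cutoff`` (same unit as the grid)."""
    mask = reference.values >= 0.10 * reference.values.max()
    return bool(reference.values[mask].mean() < cutoff)
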