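"""Known-origin calibration: foliar isoscape → moth-tissue isoscape.

Larvae inherit the δ³⁴S of the foliage they eat, with negligible trophic
fractionation, so the moth isoscape is an affine rescaling of the foliar
one. The transfer is estimated by ordinary least squares of individual
moth δ³⁴S on the foliar-isoscape mean at each known-origin site (individual
moths, not site means, are the observations). Isoscape uncertainty and
regression scatter are combined in quadrature:

    mean' = a + b · mean
    σ'    = sqrt((b · σ)² + s_resid²)

The mask is unchanged by calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CalibrationFit", "fit_calibration", "calibrate_isoscape"]


@dataclass
class CalibrationFit:
    """An affine foliar→moth transfer with its regression diagnostics."""

    intercept: float      # ‰
    slope: float          # unitless
    residual_sd: float    # ‰, residual standard error
    n: int = 0
    r2: float = float("nan")
    se_intercept: float = float("nan")
    se_slope: float = float("nan")

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def apply(self, x):
        return self.intercept + self.slope * np.asarray(x, float)

    def inverse(self) -> "CalibrationFit":
        """The inverse affine map (diagnostics are not propagated)."""
        if self.slope == 0:
            raise ValueError("slope 0 has no inverse")
        return CalibrationFit(intercept=-self.intercept / self.slope,
                              slope=1.0 / self.slope, residual_sd=0.0)


def fit_calibration(moths: pd.DataFrame, iso) -> CalibrationFit:
    """OLS of individual moth δ³⁴S on the isoscape mean at each site cell.

    ``iso`` is an :class:`~isodrift.isoscape.Isoscape`. Every moth site
    must fall on a valid isoscape cell, and at least three distinct foliar
    (isoscape) values are required for a non-degenerate design.
    """
    grid = iso.mean
    if {"row", "col"}.issubset(moths.columns):
        rows = moths["row"].to_numpy(int)
        cols = moths["col"].to_numpy(int)
    else:
        rc = [grid.cell_of(la, lo) for la, lo in zip(moths["lat"], moths["lon"])]
        rows = np.array([r for r, _ in rc])
        cols = np.array([c for _, c in rc])
    on_valid = iso.valid[rows, cols]
    if not on_valid.all():
        bad = moths["site_id"].to_numpy()[~on_valid]
        raise ValueError(f"moth site(s) off the valid isoscape mask: {sorted(set(bad))[:5]}")
    x = grid.values[rows, cols]
    y = moths["d34S"].to_numpy(float)
    if len(np.unique(np.round(x, 9))) < 3:
        raise ValueError("fewer than 3 distinct foliar values: degenerate design")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return CalibrationFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        residual_sd=resid_sd, n=len(y), r2=float(res.rsquared),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
    )


def calibrate_isoscape(iso, cal: CalibrationFit):
    """Rescale a foliar isoscape into a moth isoscape (affine mean,
    quadrature σ); returns a new Isoscape on the same mask."""
    from .isoscape import Isoscape  # local import to avoid a module cycle

    mean = cal.intercept + cal.slope * iso.mean.values
    sigma = np.sqrt((cal.slope * iso.sigma.values) ** 2 + cal.residual_sd ** 2)
    return Isoscape(
        mean=iso.mean.like(mean, units=iso.mean.units),
        sigma=iso.sigma.like(sigma, units=iso.sigma.units),
        valid_mask=iso.valid_mask,
    )
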