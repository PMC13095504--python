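"""Covariate stacks: named rasters on a shared grid and land mask."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .raster import Raster

__all__ = ["CovariateStack", "COVARIATE_NAMES"]

#: The six environmental predictors of foliar δ³⁴S used throughout.
COVARIATE_NAMES = ("dist_coast", "sea_salt_dep", "dust_dep", "pet", "wind_speed", "aridity")


@dataclass
class CovariateStack:
    """Named covariate rasters sharing one grid geometry and nodata mask."""

    layers: Mapping[str, Raster]

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if not rasters:
            raise ValueError("empty covariate stack")
        first = rasters[0]
        for r in rasters[1:]:
            first.require_congruent(r, "covariate layer")
        masks = np.stack([r.mask for r in rasters])
        if not (masks == masks[0]).all():
            raise ValueError("covariate layers disagree on the nodata mask")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def __getitem__(self, name: str) -> Raster:
        if name not in self.layers:
            raise KeyError(f"missing covariate layer: {name!r}")
        return self.layers[name]

    def matrix(self, names, rows, cols) -> np.ndarray:
        """Covariate values of the containing cells, (n_points, n_names)."""
        return np.column_stack([self[n].values[rows, cols] for n in names])

    def subset(self, names) -> "CovariateStack":
        return CovariateStack({n: self[n] for n in names})
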