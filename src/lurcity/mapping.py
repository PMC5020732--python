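"""Render fitted regression models into concentration surfaces.

A fitted model is evaluated cell-wise on the predictor rasters, the
response transform is inverted back to ppb, and the surface is bounded
by the mapping rules used for exposure surfaces: a limit of prediction
(floor) equal to the minimum observed concentration divided by sqrt(2)
— the usual below-quantification convention — and a ceiling of 120% of
the maximum observed concentration.  The fractions of cells enlarged to
the floor and truncated to the ceiling are reported from the pre-clip
distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid
from .selection import LURModel, apply_ppv_transform, invert_response

__all__ = ["predict_surface", "clip_predictions", "MapResult"]


def predict_surface(model: LURModel, ppv_rasters: dict[str, RasterGrid],
                    y_observed: np.ndarray) -> RasterGrid:
    """Evaluate the model over the grid and back-transform to ppb.

    Cells where the transformed value has no consistent preimage (wrong
    branch of an even/negative power) come back NaN; ``clip_predictions``
    later raises them to the floor and counts them as enlarged.
    """
    template = None
    for term in model.terms:
        if term["name"] not in ppv_rasters:
            raise KeyError(f"no raster supplied for model term "
                           f"'{term['name']}'")
        template = ppv_rasters[term["name"]]
    if template is None:  # intercept-only model: need any raster for the grid
        template = next(iter(ppv_rasters.values()))
    t = np.full(template.shape, float(model.intercept))
    for term in model.terms:
        rast = ppv_rasters[term["name"]]
        vals = np.where(rast.nodata, 0.0, rast.values)
        t = t + term["coef"] * apply_ppv_transform(vals, term["transform"])
    ppb = invert_response(t, model.transform, np.asarray(y_observed, float))
    out = template.like(np.where(np.isfinite(ppb), ppb, 0.0),
                        nodata=~np.isfinite(ppb))
    return out


@dataclass
class MapResult:
    raster: RasterGrid
    floor: float
    ceiling: float
    fraction_enlarged: float
    fraction_truncated: float
    total_cells: int

    def summary(self) -> dict:
        return {"floor_ppb": self.floor, "ceiling_ppb": self.ceiling,
                "pct_enlarged": round(100 * self.fraction_enlarged, 1),
                "pct_truncated": round(100 * self.fraction_truncated, 1),
                "total_cells": self.total_cells}

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def clip_predictions(raster: RasterGrid, observed_min: float,
                     observed_max: float) -> MapResult:
    """Bound a prediction surface by the floor/ceiling rules.

    floor = observed_min / sqrt(2); ceiling = 1.2 * observed_max.  Cells
    below the floor (including non-invertible nodata cells) are raised to
    it; cells above the ceiling are truncated.  Fractions refer to the
    pre-clip distribution and sum with the untouched fraction to 1.
    """
    if observed_min <= 0:
        raise ValueError("observed_min must be positive")
    if observed_max <= observed_min:
        raise ValueError("observed_max must exceed observed_min")
    floor = observed_min / math.sqrt(2.0)
    ceiling = 1.2 * observed_max
    if floor >= ceiling:
        raise ValueError("floor >= ceiling: pathological observed range")
    vals = raster.values
    low = (vals < floor) | raster.nodata
    high = (vals > ceiling) & ~raster.nodata
    total = vals.size
    clipped = np.where(low, floor, np.where(high, ceiling, vals))
    out = RasterGrid(clipped, raster.origin, raster.cell_size)
    return MapResult(out, floor, ceiling,
                     float(low.sum()) / total, float(high.sum()) / total,
                     total)
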