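"""Seasonal stability of the predicted spatial pattern.

Samples random locations over the modelling domain and correlates the
annual, cooler-season and warmer-season prediction surfaces there.  The
correlation type follows a Shapiro-Wilk normality gate: Pearson when
both series of a pair pass, Spearman otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .raster import RasterGrid

__all__ = ["sample_locations", "correlate_predictions"]


def sample_locations(domain: RasterGrid, n: int = 1000,
                     seed: int = 0) -> list[tuple[float, float]]:
    """n distinct cell-centre locations, uniform over the unmasked cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    free = np.flatnonzero(~domain.nodata.ravel())
    if len(free) == 0:
        raise ValueError("empty domain")
    if n > len(free):
        raise ValueError(f"requested {n} locations but only {len(free)} "
                         "cells available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(free, size=n, replace=False)
    rows, cols = np.unravel_index(pick, domain.shape)
    x0, y0 = domain.origin
    cs = domain.cell_size
    return [(float(x0 + (c + 0.5) * cs), float(y0 - (r + 0.5) * cs))
            for r, c in zip(rows, cols)]


def correlate_predictions(maps: dict[str, RasterGrid], points,
                          alpha: float = 0.05):
    """Correlation matrix of map values at the sampled points.

    Returns (corr DataFrame, method DataFrame, values DataFrame).  Pearson
    is used for a pair only when both series pass the Shapiro-Wilk
    normality test at ``alpha``; otherwise Spearman.
    """
    labels = list(maps)
    grids = [maps[k].grid for k in labels]
    if any(g != grids[0] for g in grids):
        raise ValueError("all maps must share one grid")
    values = pd.DataFrame({k: maps[k].sample(points) for k in labels})
    normal = {}
    for k in labels:
        v = values[k].to_numpy()
        if np.ptp(v) == 0:
            raise ValueError(f"constant series '{k}': correlation undefined")
        normal[k] = stats.shapiro(v).pvalue >= alpha
    corr = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    method = pd.DataFrame("", index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if normal[a] and normal[b]:
                r = stats.pearsonr(values[a], values[b]).statistic
                m = "pearson"
            else:
                r = stats.spearmanr(values[a], values[b]).statistic
                m = "spearman"
            corr.loc[a, b] = corr.loc[b, a] = r
            method.loc[a, b] = method.loc[b, a] = m
    return corr, method, values
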