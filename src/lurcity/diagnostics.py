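"""Post-fit model diagnostics: leave-one-out coefficient stability and
global Moran's I spatial autocorrelation of residuals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["loocv_coefficient_stability", "morans_i",
           "StabilityReport", "MoranResult"]


@dataclass
class StabilityReport:
    """Per-coefficient spread over the n leave-one-out refits."""

    table: pd.DataFrame  # rows: intercept + terms; cols: min, max, mean, cv
    sign_consistent: bool

    def __str__(self) -> str:  # Table-style text report
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def loocv_coefficient_stability(design: pd.DataFrame,
                                variables: list[str],
                                response: np.ndarray) -> StabilityReport:
    """Refit the model with each observation left out and summarize each
    coefficient's min, max and coefficient of variation (sd/|mean|).
    A model is sign-consistent when every coefficient keeps one direction
    of effect across all refits."""
    from .selection import _design_matrix, _ols

    y = np.asarray(response, float)
    n = len(y)
    X = _design_matrix(design, variables)
    betas = np.empty((n, X.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        try:
            betas[i] = _ols(X[keep], y[keep])["beta"]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular refit when omitting row {design.index[i]}") from exc
    names = ["intercept"] + list(variables)
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.inf)
        cv = np.where(sd == 0, 0.0, cv)
    table = pd.DataFrame({"min": betas.min(axis=0), "max": betas.max(axis=0),
                          "mean": mean, "cv": cv}, index=names)
    coef_rows = table.iloc[1:] if len(variables) else table.iloc[:0]
    consistent = bool(((coef_rows["min"] > 0) | (coef_rows["max"] < 0)).all())
    return StabilityReport(table, consistent)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    weights: str
    p_method: str = "normal"

    def to_dict(self) -> dict:
        return {"I": self.I, "expected": self.expected,
                "variance": self.variance, "z": self.z,
                "p_value": self.p_value, "weights": self.weights,
                "p_method": self.p_method}


def _weight_matrix(coords: np.ndarray, scheme: str, k: int,
                   row_standardize: bool) -> np.ndarray:
    n = len(coords)
    d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                 coords[:, None, 1] - coords[None, :, 1])
    off = ~np.eye(n, dtype=bool)
    if scheme == "inverse_distance":
        if (d[off] == 0).any():
            raise ValueError("coincident points: inverse-distance weights "
                             "undefined; jitter the locations")
        W = np.zeros((n, n))
        W[off] = 1.0 / d[off]
    elif scheme == "knn":
        W = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(d[i])
            nearest = [j for j in order if j != i][:k]
            W[i, nearest] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {scheme}")
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def morans_i(residuals: np.ndarray, coords, weights: str = "inverse_distance",
             k: int = 4, row_standardize: bool = True,
             permutations: int = 0, seed: int = 0) -> MoranResult:
    """Global Moran's I of residuals at station locations.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    residuals.  The p-value uses the normal approximation under the
    randomization assumption (expectation -1/(n-1)); set ``permutations``
    for a permutation p-value instead.
    """
    z = np.asarray(residuals, float)
    n = len(z)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(z) == 0:
        raise ValueError("zero-variance residuals: Moran's I undefined")
    coords = np.asarray(coords, float)
    W = _weight_matrix(coords, weights, k, row_standardize)
    z = z - z.mean()
    s0 = W.sum()
    I = (n / s0) * (z @ W @ z) / (z @ z)
    EI = -1.0 / (n - 1)

    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    b2 = n * np.sum(z ** 4) / (np.sum(z ** 2) ** 2)
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - EI * EI
    zscore = (I - EI) / np.sqrt(var)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for b in range(permutations):
            zp = rng.permutation(z)
            sims[b] = (n / s0) * (zp @ W @ zp) / (zp @ zp)
        p = (1 + np.sum(np.abs(sims - EI) >= abs(I - EI))) / (permutations + 1)
        method = f"permutation({permutations})"
    else:
        p = 2 * stats.norm.sf(abs(zscore))
        method = "normal"
    scheme = weights + (":row" if row_standardize else "")
    return MoranResult(float(I), EI, float(var), float(zscore), float(p),
                       scheme, method)
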