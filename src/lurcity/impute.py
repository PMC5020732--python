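"""Multiple imputation of hourly station series by EM with bootstrapping.

Missing hours are filled under a joint multivariate-normal model over the
station columns plus fully-observed time covariates (hour-of-day and
day-of-year harmonics, month indicators).  Each of the (default 10)
imputation runs bootstraps the rows, fits the normal model by
expectation-maximization to convergence, and fills every missing cell
with its conditional mean plus a draw from the conditional distribution;
observed cells are never altered.  Station means are averaged across
runs, which is what the regressions downstream consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import WARMER_MONTHS

__all__ = ["em_bootstrap_impute", "seasonal_means", "time_covariates",
           "ImputationResult", "EMResult"]


def time_covariates(index: pd.DatetimeIndex) -> pd.DataFrame:
    """Harmonic + month-indicator encoding of measurement time."""
    hour = index.hour.to_numpy()
    doy = index.dayofyear.to_numpy()
    cov = {
        "sin_h": np.sin(2 * np.pi * hour / 24.0),
        "cos_h": np.cos(2 * np.pi * hour / 24.0),
        "sin_d": np.sin(2 * np.pi * doy / 365.0),
        "cos_d": np.cos(2 * np.pi * doy / 365.0),
    }
    for m in range(2, 13):  # January is the reference month
        cov[f"m{m:02d}"] = (index.month == m).astype(float)
    return pd.DataFrame(cov, index=index)


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    loglik: list[float]
    n_iter: int
    converged: bool


def _pattern_groups(miss: np.ndarray) -> dict[bytes, np.ndarray]:
    keys = np.packbits(miss, axis=1).tobytes()
    width = (miss.shape[1] + 7) // 8
    groups: dict[bytes, list[int]] = {}
    for i in range(miss.shape[0]):
        groups.setdefault(keys[i * width:(i + 1) * width], []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def em_mvn(Y: np.ndarray, tol: float = 1e-6, max_iter: int = 200,
           ridge: float = 1e-6) -> EMResult:
    """EM for a multivariate normal with values missing at random.

    Sufficient statistics are accumulated per missingness pattern; a tiny
    diagonal ridge (relative to the mean variance) keeps the observed
    sub-blocks invertible when columns are nearly collinear.  Convergence
    is declared when the relative change of the observed-data
    log-likelihood drops below ``tol``.
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    miss = np.isnan(Y)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    groups = _pattern_groups(miss)

    # starting values from available cases
    mu = np.nanmean(Y, axis=0)
    Yc = np.where(miss, mu, Y) - mu
    sigma = (Yc.T @ Yc) / n
    sigma += ridge * np.mean(np.diag(sigma)) * np.eye(p)

    logliks: list[float] = []
    converged = False
    for it in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        ll = 0.0
        for key, rows in groups.items():
            m = miss[rows[0]]
            o = ~m
            Yo = Y[rows][:, o]
            muo = mu[o]
            Soo = sigma[np.ix_(o, o)]
            ko = o.sum()
            try:
                L = np.linalg.cholesky(Soo)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(
                    Soo + 1e-8 * np.mean(np.diag(Soo)) * np.eye(ko))
            dev = Yo - muo
            solved = np.linalg.solve(L, dev.T)           # ko x r
            ll += (-0.5 * (solved ** 2).sum()
                   - len(rows) * (np.log(np.diag(L)).sum()
                                  + 0.5 * ko * np.log(2 * np.pi)))
            full = np.empty((len(rows), p))
            full[:, o] = Yo
            if m.any():
                B = np.linalg.solve(L.T, np.linalg.solve(L, sigma[np.ix_(o, m)]))
                cond_mean = mu[m] + dev @ B
                full[:, m] = cond_mean
                cond_cov = sigma[np.ix_(m, m)] - sigma[np.ix_(m, o)] @ B
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = len(rows) * cond_cov
                S2 += add
            S1 += full.sum(axis=0)
            S2 += full.T @ full
        mu = S1 / n
        sigma = S2 / n - np.outer(mu, mu)
        sigma += ridge * np.mean(np.diag(sigma)) * np.eye(p)
        logliks.append(ll)
        if it > 0 and abs(ll - logliks[-2]) <= tol * (abs(logliks[-2]) + 1e-12):
            converged = True
            break
    if not converged:
        raise RuntimeError(
            "EM did not converge within "
            f"{max_iter} iterations; log-likelihood trace: {logliks}")
    return EMResult(mu, sigma, logliks, len(logliks), True)


def _impute_once(Y: np.ndarray, fit: EMResult,
                 rng: np.random.Generator) -> np.ndarray:
    """Fill missing cells with conditional mean + a conditional draw."""
    out = Y.copy()
    miss = np.isnan(Y)
    for key, rows in _pattern_groups(miss).items():
        m = miss[rows[0]]
        if not m.any():
            continue
        o = ~m
        Soo = fit.cov[np.ix_(o, o)]
        L = np.linalg.cholesky(Soo)
        B = np.linalg.solve(L.T, np.linalg.solve(L, fit.cov[np.ix_(o, m)]))
        dev = Y[rows][:, o] - fit.mean[o]
        cond_mean = fit.mean[m] + dev @ B
        cond_cov = fit.cov[np.ix_(m, m)] - fit.cov[np.ix_(m, o)] @ B
        cond_cov = (cond_cov + cond_cov.T) / 2
        w, V = np.linalg.eigh(cond_cov)
        half = V * np.sqrt(np.clip(w, 0, None))
        draws = rng.standard_normal((len(rows), m.sum())) @ half.T
        out[np.ix_(rows, np.flatnonzero(m))] = cond_mean + draws
    return out


@dataclass
class ImputationResult:
    """Completed matrices per run plus run-averaged station means."""

    completed: list[pd.DataFrame]
    station_means: pd.Series        # averaged over runs, clipped at 0
    run_means: pd.DataFrame         # runs x stations
    fits: list[EMResult] = field(repr=False, default_factory=list)


def em_bootstrap_impute(matrix: pd.DataFrame,
                        covariates: pd.DataFrame | None = None,
                        n_runs: int = 10, seed: int = 0,
                        tol: float = 1e-6, max_iter: int = 200,
                        log_scale: bool = False) -> ImputationResult:
    """Multiple imputation of an hours x stations matrix.

    Each run: bootstrap the rows, fit the multivariate-normal EM on the
    bootstrap sample, then impute the *original* matrix from that fit
    with proper conditional draws.  Negative imputed concentrations are
    clipped to 0 when averaging station means.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 stations")
    obs_frac = matrix.notna().mean()
    if (obs_frac < 0.10).any():
        bad = obs_frac[obs_frac < 0.10].index.tolist()
        raise ValueError(f"stations with <10% observed data: {bad}")
    if covariates is None:
        covariates = time_covariates(matrix.index)
    stations = list(matrix.columns)
    vals = matrix.to_numpy(float)
    if log_scale:
        vals = np.log(np.where(np.isnan(vals), np.nan,
                               np.clip(vals, 1e-6, None)))
    Y = np.hstack([vals, covariates.to_numpy(float)])
    n = Y.shape[0]
    rng = np.random.default_rng(seed)

    completed, fits, run_means = [], [], []
    for run in range(n_runs):
        if np.isnan(vals).sum() == 0:
            filled = vals.copy()
            fit = None
        else:
            boot = rng.integers(0, n, size=n)
            fit = em_mvn(Y[boot], tol=tol, max_iter=max_iter)
            filled = _impute_once(Y, fit, rng)[:, :len(stations)]
        if log_scale:
            filled = np.exp(filled)
        obs_mask = matrix.notna().to_numpy()
        filled = np.where(obs_mask, matrix.to_numpy(float), filled)
        df = pd.DataFrame(filled, index=matrix.index, columns=stations)
        completed.append(df)
        if fit is not None:
            fits.append(fit)
        run_means.append(df.clip(lower=0).mean())
    run_means = pd.DataFrame(run_means)
    return ImputationResult(completed, run_means.mean(), run_means, fits)


def seasonal_means(result: ImputationResult,
                   warmer_months: tuple[int, ...] = WARMER_MONTHS,
                   ) -> pd.DataFrame:
    """Annual / cooler / warmer station means, averaged across runs.

    Requires a full-year hourly index; concentrations are clipped at 0
    before averaging.
    """
    idx = result.completed[0].index
    if len(idx) != 8760:
        raise ValueError("seasonal means require a full 8760-hour year")
    warm = idx.month.isin(warmer_months)
    rows = {"annual": [], "cooler": [], "warmer": []}
    for df in result.completed:
        c = df.clip(lower=0)
        rows["annual"].append(c.mean())
        rows["cooler"].append(c.loc[~warm].mean())
        rows["warmer"].append(c.loc[warm].mean())
    out = pd.DataFrame({k: pd.DataFrame(v).mean() for k, v in rows.items()})
    out.index.name = "station_id"
    return out
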