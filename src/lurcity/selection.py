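"""Constrained forward stepwise selection for land-use regression.

The model-building procedure: normalize the response as a power of its
logarithm, t(y) = (ln y)^p (Shapiro-Wilk gated); linearize each candidate
predictor against the transformed response with a log or power transform;
then add predictors one at a time, where a candidate is admissible only
if, in the model that includes it,

* every coefficient's sign agrees with its a-priori effect direction
  (account taken of whether t is order-preserving or order-reversing),
* every predictor has p < 0.1,
* the leave-one-out cross-validated R^2 strictly increases, and
* no variance inflation factor exceeds the threshold,

and the model never grows beyond ceil(sqrt(N)) terms.  Among admissible
candidates the one with the highest adjusted R^2 wins.  The selection
trace records every candidate evaluated at every step together with the
rule that rejected it, so accepted models can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RESPONSE_POWERS = (-4, -3, -2, -1, 2, 3)
PPV_TRANSFORMS = ("identity", "log", "p0.1", "p0.5", "p2")

__all__ = ["TransformSpec", "LURModel", "select_response_transform",
           "linearize_ppvs", "forward_select", "loocv_r2", "vif",
           "residual_normality", "fit_lur", "apply_ppv_transform",
           "transform_response", "invert_response"]


# ---------------------------------------------------------------------------
# transforms


@dataclass
class TransformSpec:
    """Response transform t(y) = (ln y)^power."""

    power: int = 1
    shapiro_p: float = np.nan
    candidate_p: dict[int, float] = field(default_factory=dict)
    normal: bool = True

    @property
    def label(self) -> str:
        return "Log y" if self.power == 1 else f"(Log y)^{self.power}"

    def monotone_sign(self, y: np.ndarray) -> int:
        """+1 if t is increasing over the observed response range.

        d/dy (ln y)^p = p (ln y)^{p-1} / y, so with ln y > 0 throughout
        the data the sign is sign(p); with ln y < 0 it is sign(p) times
        (-1)^{p-1}.
        """
        ly = np.log(np.asarray(y, float))
        if (ly > 0).all():
            return int(np.sign(self.power))
        if (ly < 0).all():
            return int(np.sign(self.power) * (-1) ** (self.power - 1))
        return 1 if self.power == 1 else 0  # not monotone across ln y = 0


def transform_response(y: np.ndarray, spec: TransformSpec) -> np.ndarray:
    y = np.asarray(y, float)
    if (y <= 0).any():
        raise ValueError("response must be strictly positive")
    return np.log(y) ** spec.power


def invert_response(t: np.ndarray, spec: TransformSpec,
                    y_observed: np.ndarray) -> np.ndarray:
    """Map transformed values back to concentration (ppb).

    For even or negative powers the real p-th root has branches; the one
    consistent with the observed response range is used (ln y > 0 when
    all observed y exceed 1).  Values with no consistent preimage come
    back as NaN for the caller to handle.
    """
    t = np.asarray(t, float)
    p = spec.power
    if p == 1:
        return np.exp(t)
    ly_obs = np.log(np.asarray(y_observed, float))
    positive_branch = (ly_obs > 0).all()
    if not positive_branch and not (ly_obs < 0).all():
        raise ValueError("observed responses straddle 1 ppb; the inverse "
                         "transform branch is ambiguous")
    with np.errstate(invalid="ignore"):
        if p % 2 == 0:
            root = np.where(t > 0, np.abs(t) ** (1.0 / p), np.nan)
            if not positive_branch:
                root = -root
        else:
            root = np.sign(t) * np.abs(t) ** (1.0 / p)
            ok = (root > 0) if positive_branch else (root < 0)
            root = np.where(ok, root, np.nan)
    return np.exp(root)


def select_response_transform(y: np.ndarray,
                              alpha: float = 0.05) -> TransformSpec:
    """Shapiro-Wilk gate on ln y; on failure pick the power of ln y that
    maximizes the Shapiro-Wilk p among the candidate exponents."""
    y = np.asarray(y, float)
    if len(y) < 8:
        raise ValueError("need at least 8 observations")
    if (y <= 0).any():
        raise ValueError("response must be strictly positive")
    ly = np.log(y)
    if np.ptp(ly) == 0:
        raise ValueError("constant response: normality test undefined")
    p_log = stats.shapiro(ly).pvalue
    if p_log >= alpha:
        return TransformSpec(1, p_log, {1: p_log}, True)
    cand = {1: p_log}
    for pw in RESPONSE_POWERS:
        t = ly ** pw
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        cand[pw] = stats.shapiro(t).pvalue
    best = max(cand, key=lambda k: cand[k])
    return TransformSpec(best, cand[best], cand, cand[best] >= alpha)


def apply_ppv_transform(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, float)
    if name == "identity":
        return x
    if name == "log":
        if (x > 0).all():
            return np.log(x)
        # zeros (or stray negatives) present: offset by the smallest
        # positive value so the transform stays finite
        pos = x[x > 0]
        eps = pos.min() if len(pos) else 1.0
        return np.log(np.clip(x, 0.0, None) + eps)
    if name.startswith("p"):
        return np.power(np.clip(x, 0, None), float(name[1:]))
    raise ValueError(f"unknown PPV transform {name}")


def linearize_ppvs(design: pd.DataFrame, t_response: np.ndarray,
                   columns: list[str] | None = None) -> dict[str, str]:
    """Choose, per predictor, the transform that best linearizes its
    relationship with the transformed response (max |Pearson r|); ties go
    to identity.  Zero-variance predictors are excluded (mapped to None).
    """
    t_response = np.asarray(t_response, float)
    out: dict[str, str] = {}
    for col in (columns or list(design.columns)):
        x = design[col].to_numpy(float)
        if np.ptp(x) == 0:
            out[col] = None
            continue
        best, best_r = "identity", -1.0
        for tr in PPV_TRANSFORMS:
            xt = apply_ppv_transform(x, tr)
            if not np.all(np.isfinite(xt)) or np.ptp(xt) == 0:
                continue
            r = abs(np.corrcoef(xt, t_response)[0, 1])
            if r > best_r + 1e-12:
                best, best_r = tr, r
        out[col] = best
    return out


# ---------------------------------------------------------------------------
# linear-model machinery


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept-first design; returns a dict of fit quantities."""
    n, k = X.shape
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular design matrix")
    XtXi = np.linalg.inv(XtX)
    beta = XtXi @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for this model size")
    s2 = resid @ resid / dof
    se = np.sqrt(np.clip(np.diag(XtXi) * s2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    tss = np.sum((y - y.mean()) ** 2)
    rss = resid @ resid
    r2 = 1 - rss / tss if tss > 0 else np.nan
    adj = 1 - (1 - r2) * (n - 1) / dof if tss > 0 else np.nan
    hat = np.einsum("ij,jk,ik->i", X, XtXi, X)
    return {"beta": beta, "se": se, "pvalues": pvals, "resid": resid,
            "r2": r2, "adj_r2": adj, "hat": hat, "dof": dof, "rss": rss}


def _design_matrix(design: pd.DataFrame, variables: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(design))]
                        + [design[v].to_numpy(float) for v in variables])
    return X


def loocv_r2(design: pd.DataFrame, variables: list[str],
             response: np.ndarray) -> float:
    """Leave-one-out R^2 = 1 - PRESS/TSS via the hat-matrix shortcut
    (PRESS residual e_i / (1 - h_ii)); may be negative."""
    y = np.asarray(response, float)
    X = _design_matrix(design, variables)
    if len(y) <= X.shape[1]:
        raise ValueError("LOOCV needs n > number of parameters")
    fit = _ols(X, y)
    denom = 1.0 - fit["hat"]
    if (denom <= 1e-10).any():
        raise np.linalg.LinAlgError("leverage 1: LOOCV undefined")
    press = np.sum((fit["resid"] / denom) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant response")
    return 1.0 - press / tss


def vif(design: pd.DataFrame, variables: list[str]) -> dict[str, float]:
    """Variance inflation factors, 1/(1 - R^2_j) from regressing each
    predictor on the others; a single predictor has VIF 1 by convention.
    Exact collinearity reports +inf."""
    if len(variables) < 2:
        return {v: 1.0 for v in variables}
    out = {}
    for v in variables:
        others = [w for w in variables if w != v]
        yv = design[v].to_numpy(float)
        X = _design_matrix(design, others)
        try:
            r2 = _ols(X, yv)["r2"]
        except np.linalg.LinAlgError:
            out[v] = np.inf
            continue
        out[v] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def residual_normality(residuals: np.ndarray, alpha: float = 0.05):
    """Shapiro-Wilk on residuals; returns (statistic, p, flagged)."""
    r = np.asarray(residuals, float)
    if len(r) < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(r) == 0 or np.allclose(r, 0):
        raise ValueError("degenerate (zero-variance) residuals")
    res = stats.shapiro(r)
    return res.statistic, res.pvalue, res.pvalue < alpha


# ---------------------------------------------------------------------------
# the stepwise algorithm


@dataclass
class LURModel:
    """A fitted land-use regression model with its audit trail."""

    label: str
    transform: TransformSpec
    terms: list[dict]            # name, transform, coef, se, pvalue
    intercept: float
    r2: float
    adj_r2: float
    loocv_r2: float
    rmse_ppb: float
    max_vif: tuple[str, float] | None
    shapiro_stat: float
    shapiro_p: float
    normality_flag: bool
    trace: list[dict]
    n: int
    cap: int
    ppv_transforms: dict[str, str] = field(default_factory=dict)

    @property
    def term_names(self) -> list[str]:
        return [t["name"] for t in self.terms]

    def equation(self) -> str:
        parts = [f"{self.intercept:.3g}"]
        for t in self.terms:
            parts.append(f"{'+' if t['coef'] >= 0 else '-'} "
                         f"{abs(t['coef']):.2g} x {t['display']}")
        resp = self.label or "t(y)"
        return f"{self.transform.label.replace('y', resp)} = " + " ".join(parts)

    def to_dict(self) -> dict:
        d = {"label": self.label,
             "response_power": self.transform.power,
             "intercept": self.intercept, "terms": self.terms,
             "r2": self.r2, "adj_r2": self.adj_r2,
             "loocv_r2": self.loocv_r2, "rmse_ppb": self.rmse_ppb,
             "max_vif": list(self.max_vif) if self.max_vif else None,
             "shapiro_stat": self.shapiro_stat, "shapiro_p": self.shapiro_p,
             "normality_flag": self.normality_flag, "n": self.n,
             "cap": self.cap, "equation": self.equation(),
             "ppv_transforms": self.ppv_transforms, "trace": self.trace}
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)


def _display_name(name: str, transform: str) -> str:
    if transform == "identity":
        return name
    if transform == "log":
        return f"log({name})"
    return f"({name})^{transform[1:]}"


def forward_select(design: pd.DataFrame, response: np.ndarray,
                   priors: dict[str, int], alpha_p: float = 0.1,
                   vif_max: float = 5.0, cap: int | None = None,
                   response_sign: int = 1, label: str = "",
                   transform: TransformSpec | None = None,
                   ppv_transforms: dict[str, str] | None = None,
                   y_ppb: np.ndarray | None = None) -> LURModel:
    """Forward selection under sign / p-value / LOOCV / VIF constraints.

    ``design`` holds the (already transformed) candidate predictors;
    ``response`` the transformed response; ``response_sign`` +1/-1 states
    whether the response transform preserves or reverses order, so sign
    priors can be checked on the model scale.  ``cap`` defaults to
    ceil(sqrt(n)).  Returns the fitted model with the full selection
    trace; if no candidate is admissible at step one, an intercept-only
    model is returned (with trace), not an error.
    """
    y = np.asarray(response, float)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 observations")
    if cap is None:
        cap = int(np.ceil(np.sqrt(n)))
    if cap < 1:
        raise ValueError("cap must be >= 1")
    candidates = [c for c in design.columns
                  if np.ptp(design[c].to_numpy(float)) > 0]
    included: list[str] = []
    trace: list[dict] = []
    current_loocv = loocv_r2(design, [], y)

    while len(included) < cap:
        survivors = []
        for cand in candidates:
            if cand in included:
                continue
            trial = included + [cand]
            entry = {"step": len(included) + 1, "candidate": cand,
                     "model": list(trial)}
            try:
                fit = _ols(_design_matrix(design, trial), y)
            except (np.linalg.LinAlgError, ValueError) as exc:
                entry["status"] = f"rejected: singular fit ({exc})"
                trace.append(entry)
                continue
            coefs = dict(zip(trial, fit["beta"][1:]))
            pvals = dict(zip(trial, fit["pvalues"][1:]))
            bad_sign = [v for v in trial
                        if priors.get(v, 0) != 0 and response_sign != 0
                        and np.sign(coefs[v]) != priors[v] * response_sign]
            if bad_sign:
                entry["status"] = f"rejected: sign contradicts prior ({bad_sign})"
                trace.append(entry)
                continue
            bad_p = [v for v in trial if not pvals[v] < alpha_p]
            if bad_p:
                entry["status"] = f"rejected: p >= {alpha_p} ({bad_p})"
                trace.append(entry)
                continue
            try:
                cv = loocv_r2(design, trial, y)
            except np.linalg.LinAlgError:
                entry["status"] = "rejected: LOOCV undefined (leverage 1)"
                trace.append(entry)
                continue
            if not cv > current_loocv:
                entry["status"] = (f"rejected: LOOCV R^2 {cv:.4f} does not "
                                   f"exceed {current_loocv:.4f}")
                trace.append(entry)
                continue
            vifs = vif(design, trial)
            worst = max(vifs, key=lambda v: vifs[v])
            if vifs[worst] >= vif_max:
                entry["status"] = (f"rejected: VIF {vifs[worst]:.2f} "
                                   f"({worst}) >= {vif_max}")
                trace.append(entry)
                continue
            entry["status"] = "admissible"
            entry.update(adj_r2=fit["adj_r2"], loocv_r2=cv,
                         max_vif=vifs[worst])
            trace.append(entry)
            survivors.append((fit["adj_r2"], -vifs[worst],
                              -candidates.index(cand), cand, fit, cv, vifs))
        if not survivors:
            break
        survivors.sort(reverse=True)
        _, _, _, best, fit, cv, vifs = survivors[0]
        included.append(best)
        current_loocv = cv
        trace.append({"step": len(included), "candidate": best,
                      "status": "accepted", "model": list(included),
                      "loocv_r2": cv, "adj_r2": fit["adj_r2"]})

    # final fit + diagnostics
    fit = _ols(_design_matrix(design, included), y)
    vifs = vif(design, included)
    max_v = (max(vifs.items(), key=lambda kv: kv[1]) if vifs else None)
    if len(included) > 0 and np.ptp(fit["resid"]) > 0:
        sw_stat, sw_p, flagged = residual_normality(fit["resid"])
    else:
        sw_stat, sw_p, flagged = np.nan, np.nan, False
    tspec = transform or TransformSpec(1)
    ptr = ppv_transforms or {}
    terms = []
    for i, v in enumerate(included):
        terms.append({"name": v, "transform": ptr.get(v, "identity"),
                      "display": _display_name(v, ptr.get(v, "identity")),
                      "coef": float(fit["beta"][i + 1]),
                      "se": float(fit["se"][i + 1]),
                      "pvalue": float(fit["pvalues"][i + 1])})
    if y_ppb is not None:
        pred_ppb = invert_response(
            _design_matrix(design, included) @ fit["beta"], tspec, y_ppb)
        ok = np.isfinite(pred_ppb)
        rmse = float(np.sqrt(np.mean((np.asarray(y_ppb)[ok]
                                      - pred_ppb[ok]) ** 2)))
    else:
        rmse = float(np.sqrt(np.mean(fit["resid"] ** 2)))
    return LURModel(label=label, transform=tspec, terms=terms,
                    intercept=float(fit["beta"][0]), r2=float(fit["r2"]),
                    adj_r2=float(fit["adj_r2"]),
                    loocv_r2=float(current_loocv), rmse_ppb=rmse,
                    max_vif=(max_v[0], float(max_v[1])) if max_v else None,
                    shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
                    normality_flag=bool(flagged), trace=trace, n=n, cap=cap,
                    ppv_transforms={v: ptr.get(v, "identity")
                                    for v in included})


def fit_lur(design: pd.DataFrame, response: pd.Series | np.ndarray,
            priors: dict[str, int], alpha_p: float = 0.1,
            vif_max: float = 5.0, cap: int | None = None,
            label: str = "", linearize: bool = True) -> LURModel:
    """End-to-end model fit: response transform selection, predictor
    linearization, then constrained forward selection."""
    y = np.asarray(response, float)
    cols = [c for c in design.columns if c not in ("x", "y")]
    tspec = select_response_transform(y)
    ty = transform_response(y, tspec)
    if linearize:
        tmap = linearize_ppvs(design[cols], ty)
    else:
        tmap = {c: "identity" for c in cols}
    tdesign = pd.DataFrame(
        {c: apply_ppv_transform(design[c].to_numpy(float), tmap[c])
         for c in cols if tmap[c] is not None}, index=design.index)
    return forward_select(tdesign, ty, priors, alpha_p=alpha_p,
                          vif_max=vif_max, cap=cap,
                          response_sign=tspec.monotone_sign(y), label=label,
                          transform=tspec, ppv_transforms=tmap, y_ppb=y)
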