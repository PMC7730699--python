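"""Partial least squares regression (NIPALS) with grouped cross-validation.

The model is built statsmodels-style: ``PLSRegression(endog, exog)`` holds
the data, ``fit(n_components)`` returns a ``PLSResults`` with coefficients
on the original scale, and ``cross_val_pls`` runs leave-one-group-out
cross-validation over a ladder of latent-variable counts, picking the count
that minimises RMSECV.

Conventions
-----------
R² uses the n−1 variance convention: R² = 1 − MSE / Var(y, ddof=1).  With
this convention the residual prediction deviation RPD = SD(y) / RMSECV
satisfies RPD = sqrt(1 / (1 − R²CV)) exactly.  Negative R²CV values are
legal (cross-validated predictions worse than the mean) and are reported,
not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge while extracting a latent variable."""


def _nipals(X, y, n_components, tol, max_iter):
    """NIPALS deflation on centred/scaled data.

    Returns weights W, x-loadings P, y-loadings q (all per component).  For
    a single response the power iteration converges in one step; the loop is
    kept for generality and guards against pathological non-convergence.
    Extraction stops early (zero-padding the remaining components) if the
    residual X–y covariance vanishes.
    """
    X = X.copy()
    y = y.copy().astype(float)
    n, p = X.shape
    x_scale = np.linalg.norm(X)
    y_scale = np.linalg.norm(y)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        # stop once the residual X–y covariance is numerically exhausted
        if norm <= max(tol * max(x_scale * y_scale, 1.0), 1e-30):
            break
        if np.linalg.norm(X) <= 1e-12 * max(x_scale, 1.0):
            break  # X fully deflated; remaining components are noise
        # for a single response the NIPALS power iteration has the exact
        # fixed point w ∝ X'y, so the weight is available in one step; the
        # finite-iteration contract still guards against degeneracy
        w = cov / norm
        for _ in range(max_iter):
            t = X @ w
            tt = t @ t
            if tt == 0.0 or not np.isfinite(tt):
                break
            q_a = (y @ t) / tt
            w_new = X.T @ (y * q_a)
            nrm = np.linalg.norm(w_new)
            if nrm == 0.0 or not np.isfinite(nrm):
                break
            w_new /= nrm
            # the weight vector is defined up to sign
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) <= max(
                tol, 64 * np.finfo(float).eps * x_scale * y_scale / norm
            ):
                w = w_new
                break
            w = w_new
        else:
            raise ConvergenceError(
                f"NIPALS did not converge within {max_iter} iterations at "
                f"latent variable {a + 1}"
            )
        # sign convention: largest-magnitude weight element positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = X @ w
        tt = t @ t
        if tt == 0.0:
            break
        p_vec = X.T @ t / tt
        q_a = (y @ t) / tt
        X = X - np.outer(t, p_vec)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_vec, q_a
        used += 1
    return W[:, :used], P[:, :used], q[:used], used


@dataclass
class PLSResults:
    """Fitted PLS regression: coefficients, fit statistics, summary table."""

    model: "PLSRegression"
    n_components: int
    coef: np.ndarray          # original-scale slope coefficients
    intercept: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    fittedvalues: np.ndarray = field(init=False)
    r2: float = field(init=False)
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        self.fittedvalues = self.predict(self.model.exog)
        resid = self.model.endog - self.fittedvalues
        self.rmse = float(np.sqrt(np.mean(resid**2)))
        var = float(np.var(self.model.endog, ddof=1))
        self.r2 = 1.0 - self.rmse**2 / var if var > 0 else np.nan

    def predict(self, exog: np.ndarray) -> np.ndarray:
        return np.asarray(exog, dtype=float) @ self.coef + self.intercept

    def summary(self) -> str:
        lines = [
            "PLS regression (NIPALS)",
            f"  observations:       {self.model.nobs}",
            f"  predictors:         {self.model.exog.shape[1]}",
            f"  latent variables:   {self.n_components}",
            f"  R2 (training):      {self.r2:.4f}",
            f"  RMSEC:              {self.rmse:.4f}",
        ]
        return "\n".join(lines)


class PLSRegression:
    """Single-response partial least squares regression model.

    Parameters
    ----------
    endog : 1-D array
        Response vector.
    exog : 2-D array
        Predictor matrix (observations × features).
    scale : bool
        Autoscale predictor columns (centre, unit SD) before extraction;
        the response is always centred.  Constant predictor columns are
        tolerated (their scale is left at 1) since spectra routinely carry
        dead channels after truncation.
    """

    def __init__(self, endog, exog, *, scale: bool = True):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog have different numbers of rows")
        self.scale = scale
        self.nobs = self.endog.size

    def fit(
        self, n_components: int, *, tol: float = 1e-10, max_iter: int = 500
    ) -> PLSResults:
        n, p = self.exog.shape
        if n_components > min(n - 1, p):
            raise ValueError(
                f"n_components = {n_components} exceeds min(n-1, p) = {min(n - 1, p)}"
            )
        x_mean = self.exog.mean(axis=0)
        if self.scale:
            x_sd = self.exog.std(axis=0, ddof=1)
            x_sd[x_sd == 0.0] = 1.0
        else:
            x_sd = np.ones(p)
        y_mean = self.endog.mean()
        Xs = (self.exog - x_mean) / x_sd
        ys = self.endog - y_mean
        W, P, q, used = _nipals(Xs, ys, n_components, tol, max_iter)
        if used == 0:
            coef_s = np.zeros(p)
        else:
            coef_s = W @ np.linalg.solve(P.T @ W, q)
        coef = coef_s / x_sd
        intercept = y_mean - x_mean @ coef
        return PLSResults(self, used if used else n_components, coef, float(intercept), W, P, q)


# ---------------------------------------------------------------------------
# Regression quality metrics
# ---------------------------------------------------------------------------

@dataclass
class PLSCVResults:
    """Cross-validated PLS quality record.

    Mirrors the columns of a model-quality table: training R² and RMSEC from
    the final refit on all rows, cross-validated R²CV / RMSECV at the
    selected latent-variable count, RPD = SD(y)/RMSECV, plus the full
    RMSECV-vs-LV curve and the assembled CV predictions.
    """

    n_components: int
    r2_tr: float
    rmsec: float
    r2_cv: float
    rmsecv: float
    rpd: float
    n_obs: int
    rmsecv_curve: np.ndarray
    cv_predictions: np.ndarray
    final_fit: PLSResults

    def summary(self) -> str:
        return (
            "Cross-validated PLS regression\n"
            f"  observations:     {self.n_obs}\n"
            f"  latent variables: {self.n_components} "
            f"(RMSECV minimum over 1..{len(self.rmsecv_curve)})\n"
            f"  R2 train / CV:    {self.r2_tr:.4f} / {self.r2_cv:.4f}\n"
            f"  RMSEC / RMSECV:   {self.rmsec:.4f} / {self.rmsecv:.4f}\n"
            f"  RPD:              {self.rpd:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "n_latent": int(self.n_components),
            "R2Tr": float(self.r2_tr),
            "RMSEC": float(self.rmsec),
            "R2CV": float(self.r2_cv),
            "RMSECV": float(self.rmsecv),
            "RPD": float(self.rpd),
            "n_obs": int(self.n_obs),
        }


def regression_metrics(
    y: np.ndarray, yhat_train: np.ndarray, yhat_cv: np.ndarray
) -> dict:
    """RMSEC/RMSECV, training and CV R², and RPD for given predictions."""
    y = np.asarray(y, dtype=float)
    if y.size != len(yhat_train) or y.size != len(yhat_cv):
        raise ValueError("predictions must have the same length as y")
    var = float(np.var(y, ddof=1))
    if var == 0.0:
        raise ValueError("zero-variance response: R2 and RPD are undefined")
    rmsec = float(np.sqrt(np.mean((y - yhat_train) ** 2)))
    rmsecv = float(np.sqrt(np.mean((y - yhat_cv) ** 2)))
    sd = float(np.sqrt(var))
    return {
        "rmsec": rmsec,
        "rmsecv": rmsecv,
        "r2_tr": 1.0 - rmsec**2 / var,
        "r2_cv": 1.0 - rmsecv**2 / var,
        "rpd": sd / rmsecv if rmsecv > 0 else np.inf,
    }


def _group_folds(groups: np.ndarray) -> list[np.ndarray]:
    groups = np.asarray(groups)
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def cross_val_pls(
    endog,
    exog,
    groups,
    max_components: int = 10,
    *,
    scale: bool = True,
    leakage_safe: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSCVResults:
    """Leave-one-group-out cross-validated PLS with LV selection.

    For every latent-variable count 1..max_components a full round of
    grouped cross-validation is run (all observations of one group held out
    together, e.g. all scans of one preparation unit); the count with the
    lowest RMSECV is selected and the model refit on all rows at that count.

    With ``leakage_safe`` (default) predictor scaling is fitted inside each
    training fold; otherwise the full matrix is scaled once, matching a
    pretreat-everything-first workflow.
    """
    y = np.asarray(endog, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    folds = _group_folds(groups)
    if len(folds) < 2:
        raise ValueError("grouped cross-validation needs at least two groups")
    for f in folds:
        if f.size == y.size:
            raise ValueError("a single group covers the whole data set")
    smallest_train = y.size - max(f.size for f in folds)
    cap = min(max_components, smallest_train - 1, X.shape[1], len(folds) - 1)
    if cap < 1:
        raise ValueError("not enough observations per fold for even one LV")
    if not leakage_safe:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=0)) / sd if scale else X
    cv_pred = np.zeros((cap, y.size))
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        model = PLSRegression(
            y[train_mask], X[train_mask], scale=scale and leakage_safe
        )
        for a in range(1, cap + 1):
            res = model.fit(a, tol=tol, max_iter=max_iter)
            cv_pred[a - 1, test_idx] = res.predict(X[test_idx])
    rmsecv_curve = np.sqrt(np.mean((cv_pred - y) ** 2, axis=1))
    best = int(np.argmin(rmsecv_curve))  # ties: fewest latent variables
    final = PLSRegression(y, X, scale=scale and leakage_safe).fit(
        best + 1, tol=tol, max_iter=max_iter
    )
    m = regression_metrics(y, final.fittedvalues, cv_pred[best])
    return PLSCVResults(
        n_components=best + 1,
        r2_tr=m["r2_tr"],
        rmsec=m["rmsec"],
        r2_cv=m["r2_cv"],
        rmsecv=m["rmsecv"],
        rpd=m["rpd"],
        n_obs=y.size,
        rmsecv_curve=rmsecv_curve,
        cv_predictions=cv_pred[best].copy(),
        final_fit=final,
    )
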