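"""Linear discriminant analysis with pooled covariance and k-fold validation.

Classification of botanical origin from high-dimensional instrument blocks:
when there are at least as many features as observations, the data are first
compressed to PCA scores (fitted on the training rows only) retaining 99% of
the variance, capped at n_obs − n_classes components, and the pooled
within-class covariance gets a small ridge if singular.  Recognition is the
macro-averaged training accuracy of a refit on all rows; prediction the
macro-averaged stratified k-fold cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import PCAResults, fit_pca


@dataclass
class LDAFit:
    """A fitted pooled-covariance discriminant model."""

    classes: np.ndarray
    means: np.ndarray            # class × feature (possibly compressed space)
    cov_inv: np.ndarray
    log_priors: np.ndarray
    root_vectors: np.ndarray     # feature × root discriminant axes
    root_variance_pct: np.ndarray
    compressor: PCAResults | None
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def _project(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_sd
        if self.compressor is not None:
            Z = self.compressor.transform(Z)
        return Z

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = self._project(X)
        # linear discriminant score per class
        S = Z @ self.cov_inv @ self.means.T
        S -= 0.5 * np.einsum("ij,jk,ik->i", self.means, self.cov_inv, self.means)
        return S + self.log_priors

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]

    def root_scores(self, X: np.ndarray) -> np.ndarray:
        """Observation scores on the discriminant axes ("roots")."""
        Z = self._project(X)
        return (Z - Z.mean(axis=0)) @ self.root_vectors


@dataclass
class LDAResult:
    """Cross-validated LDA quality record.

    ``recognition_pct`` is the macro-averaged per-class training accuracy of
    the model refit on all rows; ``prediction_pct`` the macro-averaged
    cross-validated accuracy.  Confusion matrices are class × class counts
    (rows = true class).
    """

    classes: np.ndarray
    recognition_pct: float
    prediction_pct: float
    confusion_train: pd.DataFrame
    confusion_cv: pd.DataFrame
    root_scores: np.ndarray
    root_variance_pct: np.ndarray
    n_folds: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"LDA ({self.n_folds}-fold stratified CV, seed {self.seed})",
            f"  recognition (training): {self.recognition_pct:.2f}%",
            f"  prediction (CV):        {self.prediction_pct:.2f}%",
            "  CV confusion matrix (rows = true):",
        ]
        lines.append(self.confusion_cv.to_string())
        return "\n".join(lines)


def _fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    *,
    compress: bool | str = "auto",
    variance_pct: float = 99.0,
    ridge: float = 1e-8,
    standardize: bool = True,
) -> LDAFit:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    k = classes.size
    n, p = X.shape
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
    else:
        mean, sd = np.zeros(p), np.ones(p)
    Z = (X - mean) / sd

    do_compress = compress is True or (compress == "auto" and p >= n)
    compressor = None
    if do_compress:
        cap = max(n - k, 1)
        full = fit_pca(Z)
        cum = np.cumsum(full.explained_variance_pct)
        need = int(np.searchsorted(cum, variance_pct) + 1)
        n_keep = min(need, cap, full.n_components)
        compressor = fit_pca(Z, n_keep)
        Z = compressor.transform(Z)

    d = Z.shape[1]
    means = np.vstack([Z[y_idx == j].mean(axis=0) for j in range(k)])
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    grand = Z.mean(axis=0)
    for j in range(k):
        Zi = Z[y_idx == j] - means[j]
        Sw += Zi.T @ Zi
        Sb += (y_idx == j).sum() * np.outer(means[j] - grand, means[j] - grand)
    Sw /= max(n - k, 1)
    # ridge if the pooled covariance is singular or near-singular
    tr = np.trace(Sw)
    if tr <= 0:
        tr = 1.0
    try:
        if np.linalg.cond(Sw) > 1e12:
            raise np.linalg.LinAlgError
        cov_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.inv(Sw + ridge * tr * np.eye(d))
    priors = np.bincount(y_idx, minlength=k) / n
    # discriminant axes: eigenvectors of Sw^-1 Sb, ordered by eigenvalue
    evals, evecs = np.linalg.eig(cov_inv @ Sb)
    order = np.argsort(evals.real)[::-1][: max(k - 1, 1)]
    roots = evecs[:, order].real
    lam = np.clip(evals[order].real, 0.0, None)
    root_pct = 100.0 * lam / lam.sum() if lam.sum() > 0 else np.zeros_like(lam)
    return LDAFit(
        classes, means, cov_inv, np.log(priors), roots, root_pct,
        compressor, mean, sd,
    )


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment per row, stratified by class, shuffled by seed."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for c in pd.unique(y):
        idx = np.flatnonzero(np.asarray(y) == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def _confusion(classes, y_true, y_pred) -> pd.DataFrame:
    M = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        M.loc[t, p] += 1
    return M


def _macro_accuracy(conf: pd.DataFrame) -> float:
    per_class = [
        conf.loc[c, c] / conf.loc[c].sum() for c in conf.index if conf.loc[c].sum()
    ]
    return 100.0 * float(np.mean(per_class))


def cross_val_lda(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 3,
    seed: int = 42,
    *,
    compress: bool | str = "auto",
    standardize: bool = True,
) -> LDAResult:
    """LDA with stratified k-fold cross-validation.

    PCA compression (when active) and column standardisation are fitted on
    the training folds only, so no held-out information leaks into the
    classifier.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    small = classes[counts < n_folds]
    if small.size:
        raise ValueError(
            f"classes with fewer members than folds ({n_folds}): {small.tolist()}"
        )
    full = _fit_lda(X, y, compress=compress, standardize=standardize)
    train_pred = full.predict(X)
    conf_tr = _confusion(classes, y, train_pred)

    assignment = _stratified_folds(y, n_folds, seed)
    cv_pred = np.empty(len(y), dtype=object)
    for f in range(n_folds):
        test = assignment == f
        fit = _fit_lda(X[~test], y[~test], compress=compress, standardize=standardize)
        cv_pred[test] = fit.predict(X[test])
    conf_cv = _confusion(classes, y, cv_pred)

    return LDAResult(
        classes=classes,
        recognition_pct=_macro_accuracy(conf_tr),
        prediction_pct=_macro_accuracy(conf_cv),
        confusion_train=conf_tr,
        confusion_cv=conf_cv,
        root_scores=full.root_scores(X),
        root_variance_pct=full.root_variance_pct,
        n_folds=n_folds,
        seed=seed,
    )
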