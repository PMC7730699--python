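"""Block-specific signal pretreatment.

NIR spectra: Savitzky-Golay smoothing, multiplicative scatter correction
(MSC) and truncation to the informative wavelength range.  E-tongue:
additive per-session drift correction.  E-nose: Fisher-ratio sensor
selection.  All blocks: column autoscaling with train/apply separation so
held-out data never leaks into the fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .blocks import SensorBlock, SpectralBlock


@dataclass(frozen=True)
class ScalerState:
    """Per-column mean and standard deviation fitted on a training matrix."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------

def _savgol_matrix(X: np.ndarray, window: int, polyorder: int, deriv: int) -> np.ndarray:
    """SG filtering of each row; edges fit the polynomial on the truncated
    asymmetric window (no padding, no fabricated samples)."""
    n = X.shape[1]
    half = window // 2
    coeffs = savgol_coeffs(window, polyorder, deriv=deriv, use="dot")
    out = np.empty_like(X, dtype=float)
    # interior: plain correlation with the central-window coefficients
    for i in range(half, n - half):
        out[:, i] = X[:, i - half : i + half + 1] @ coeffs
    # edges: least-squares polynomial on whatever part of the window exists
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi) - i  # centred abscissa
        V = np.vander(t, polyorder + 1, increasing=True)
        # polynomial coefficients for all rows at once: (order+1) × n_rows
        beta, *_ = np.linalg.lstsq(V, X[:, lo:hi].T, rcond=None)
        out[:, i] = beta[deriv] * _factorial(deriv)
    return out


def _factorial(k: int) -> float:
    out = 1.0
    for j in range(2, k + 1):
        out *= j
    return out


def savgol_smooth(
    block: SpectralBlock,
    window: int = 21,
    polyorder: int = 2,
    deriv: int = 0,
) -> SpectralBlock:
    """Savitzky-Golay smoothing of every spectrum in the block.

    Each point is replaced by the value (or ``deriv``-th derivative, in
    sample units) of the local least-squares polynomial of order
    ``polyorder`` over a centred window of ``window`` points.  The defaults
    (window 21, order 2, no derivative) reduce instrument noise while
    leaving locally quadratic signal untouched.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > block.X.shape[1]:
        raise ValueError(
            f"window ({window}) exceeds the number of wavelengths "
            f"({block.X.shape[1]})"
        )
    if deriv > polyorder:
        raise ValueError("derivative order cannot exceed the polynomial order")
    return block.with_data(_savgol_matrix(block.X, window, polyorder, deriv))


# ---------------------------------------------------------------------------
# Multiplicative scatter correction
# ---------------------------------------------------------------------------

def msc_correct(
    block: SpectralBlock,
    reference: np.ndarray | str = "mean",
) -> tuple[SpectralBlock, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r (x ≈ a·r + b by least
    squares) and replaced by (x − b) / a, removing per-spectrum multiplicative
    gain and additive offset.  The default reference is the column mean of
    the block; the reference actually used is returned so that held-out
    spectra can be corrected with the training reference.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be a spectrum or 'mean'")
        ref = block.X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (block.X.shape[1],):
        raise ValueError(
            f"reference length {ref.shape} does not match the "
            f"{block.X.shape[1]} wavelengths"
        )
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0.0:
        raise ValueError("constant reference spectrum: MSC slope is undefined")
    Xc = block.X - block.X.mean(axis=1, keepdims=True)
    slope = (Xc @ rc) / denom
    if np.any(slope == 0.0):
        raise ValueError("a spectrum is uncorrelated with the reference (zero slope)")
    intercept = block.X.mean(axis=1) - slope * ref.mean()
    corrected = (block.X - intercept[:, None]) / slope[:, None]
    return block.with_data(corrected), ref


def truncate_range(
    block: SpectralBlock, low_nm: float = 950.0, high_nm: float = 1650.0
) -> SpectralBlock:
    """Keep wavelengths in the closed interval [low_nm, high_nm]."""
    if low_nm > high_nm:
        raise ValueError(f"low_nm ({low_nm}) must not exceed high_nm ({high_nm})")
    keep = (block.wavelengths >= low_nm) & (block.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(
            f"no wavelengths in [{low_nm}, {high_nm}]; block covers "
            f"{block.wavelengths[0]:.1f}–{block.wavelengths[-1]:.1f} nm"
        )
    return block.with_data(block.X[:, keep], block.wavelengths[keep])


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------

def autoscale_fit(train: np.ndarray, column_names=None) -> ScalerState:
    """Fit per-column mean/SD (n−1 denominator) on a training matrix."""
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = (
            [column_names[j] for j in bad] if column_names is not None else bad.tolist()
        )
        raise ValueError(f"constant training columns cannot be autoscaled: {names}")
    return ScalerState(mean, sd)


def autoscale_fit_apply(
    train: np.ndarray, apply_to: np.ndarray | None = None, column_names=None
) -> tuple[np.ndarray, np.ndarray | None, ScalerState]:
    """Autoscale a training matrix and transform held-out rows with its state.

    Training columns come out with mean 0 and unit SD; ``apply_to`` (if
    given) is transformed with the training means and SDs, not its own.
    """
    state = autoscale_fit(train, column_names)
    scaled_train = state.apply(train)
    scaled_apply = None if apply_to is None else state.apply(apply_to)
    return scaled_train, scaled_apply, state


# ---------------------------------------------------------------------------
# E-tongue drift correction
# ---------------------------------------------------------------------------

def drift_correct_etongue(block: SensorBlock) -> SensorBlock:
    """Additive correction relative to all samples.

    Sensor signals age between measurement sessions.  Because every session
    measures the same sample set comparably, a session's mean signal over
    all samples estimates the session's additive drift: for each sensor the
    session mean is re-centred onto that sensor's grand mean, which removes
    any additive per-session offset exactly while preserving within-session
    contrasts between samples.
    """
    sessions = block.meta["session_id"].to_numpy()
    unique = pd.unique(sessions)
    if unique.size == 1:
        warnings.warn(
            "single-session block: no drift to correct, returning unchanged",
            stacklevel=2,
        )
        return block.with_data(block.X.copy())
    grand = block.X.mean(axis=0)
    X = block.X.copy()
    for s in unique:
        mask = sessions == s
        X[mask] -= X[mask].mean(axis=0) - grand
    return block.with_data(X)


# ---------------------------------------------------------------------------
# E-nose sensor selection by discrimination power
# ---------------------------------------------------------------------------

def discrimination_power(
    block: SensorBlock, labels: np.ndarray | None = None
) -> pd.Series:
    """Fisher ratio (between-class SS / within-class SS) per sensor.

    A sensor that separates classes strongly relative to its within-class
    spread scores high; a perfectly constant sensor scores 0; a perfect
    separator with zero within-class variance scores +inf.
    """
    y = block.meta["class_label"].to_numpy() if labels is None else np.asarray(labels)
    if len(y) != block.n_obs:
        raise ValueError("labels length does not match the number of observations")
    classes = pd.unique(y)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    grand = block.X.mean(axis=0)
    ssb = np.zeros(block.X.shape[1])
    ssw = np.zeros(block.X.shape[1])
    for c in classes:
        Xi = block.X[y == c]
        mi = Xi.mean(axis=0)
        ssb += Xi.shape[0] * (mi - grand) ** 2
        ssw += ((Xi - mi) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = ssb / ssw
    score[(ssw == 0.0) & (ssb == 0.0)] = 0.0
    score[(ssw == 0.0) & (ssb > 0.0)] = np.inf
    return pd.Series(score, index=block.sensor_ids, name="fisher_ratio")


def select_sensors_by_discrimination(
    block: SensorBlock, labels: np.ndarray | None = None, k: int = 20
) -> SensorBlock:
    """Keep the k sensors with the highest Fisher ratio.

    Ties are broken by lexical sensor-id order so the selection is
    deterministic.
    """
    if k > len(block.sensor_ids):
        raise ValueError(
            f"k = {k} exceeds the number of sensors ({len(block.sensor_ids)})"
        )
    scores = discrimination_power(block, labels)
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    return block.subset_sensors(order[:k])
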