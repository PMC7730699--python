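"""In-memory containers for instrument data blocks.

A block couples a numeric feature matrix (observations × features) with
per-row metadata. ``SpectralBlock`` carries a strictly increasing wavelength
axis (NIR absorbance spectra); ``SensorBlock`` carries named sensor channels
(e-nose, e-tongue); ``FusedBlock`` is the column-wise concatenation of
aligned blocks, remembering which columns came from which source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Metadata columns required on every instrument block.
SPECTRAL_META = ("sample_id", "class_label", "replicate_id", "scan_index")
SENSOR_META = ("sample_id", "class_label", "replicate_id", "session_id")


def _check_meta(meta: pd.DataFrame, required: tuple[str, ...], n_rows: int) -> None:
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if len(meta) != n_rows:
        raise ValueError(
            f"metadata has {len(meta)} rows but the matrix has {n_rows}"
        )


@dataclass
class SpectralBlock:
    """Observations × wavelength absorbance matrix with per-row metadata.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength axis in nm, strictly increasing, one entry per column.
    X : 2-D array
        Absorbance values, no missing entries.
    meta : DataFrame
        One row per observation with columns ``sample_id``, ``class_label``,
        ``replicate_id`` and ``scan_index``.
    """

    wavelengths: np.ndarray
    X: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (observations × wavelengths)")
        if self.wavelengths.size != self.X.shape[1]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths but X has "
                f"{self.X.shape[1]} columns"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        _check_meta(self.meta, SPECTRAL_META, self.X.shape[0])
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def with_data(self, X: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectralBlock":
        """Copy of the block with a new matrix (and optionally new axis)."""
        wl = self.wavelengths if wavelengths is None else wavelengths
        return SpectralBlock(wl, X, self.meta.copy())


@dataclass
class SensorBlock:
    """Observations × named-sensor signal matrix with session metadata."""

    sensor_ids: list[str]
    X: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sensor_ids = [str(s) for s in self.sensor_ids]
        if len(set(self.sensor_ids)) != len(self.sensor_ids):
            dupes = sorted({s for s in self.sensor_ids if self.sensor_ids.count(s) > 1})
            raise ValueError(f"duplicate sensor ids: {dupes}")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (observations × sensors)")
        if len(self.sensor_ids) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.sensor_ids)} sensor ids but X has "
                f"{self.X.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        _check_meta(self.meta, SENSOR_META, self.X.shape[0])
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def with_data(self, X: np.ndarray, sensor_ids: list[str] | None = None) -> "SensorBlock":
        ids = list(self.sensor_ids) if sensor_ids is None else list(sensor_ids)
        return SensorBlock(ids, X, self.meta.copy())

    def subset_sensors(self, ids: list[str]) -> "SensorBlock":
        """Restrict the block to the given sensors, in the given order."""
        index = {s: j for j, s in enumerate(self.sensor_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sensors: {missing}")
        cols = [index[s] for s in ids]
        return SensorBlock(list(ids), self.X[:, cols], self.meta.copy())


@dataclass
class FusedBlock:
    """Column-wise concatenation of aligned instrument blocks.

    ``block_slices`` maps each source block name to the slice of columns it
    occupies; together the slices cover every column exactly once.  When the
    fused matrix has been autoscaled, ``column_mean``/``column_sd`` hold the
    scaling state so individual blocks can be recovered on original scale.
    """

    X: np.ndarray
    meta: pd.DataFrame
    feature_names: list[str]
    block_slices: dict[str, slice]
    column_mean: np.ndarray | None = None
    column_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        covered = np.zeros(self.X.shape[1], dtype=int)
        for sl in self.block_slices.values():
            covered[sl] += 1
        if not np.all(covered == 1):
            raise ValueError("block slices must cover every column exactly once")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X columns")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def block_view(self, name: str, *, original_scale: bool = False) -> np.ndarray:
        """Columns of one source block, optionally undoing the autoscaling."""
        sl = self.block_slices[name]
        V = self.X[:, sl]
        if original_scale:
            if self.column_mean is None or self.column_sd is None:
                raise ValueError("fused block carries no scaling state")
            V = V * self.column_sd[sl] + self.column_mean[sl]
        return V
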