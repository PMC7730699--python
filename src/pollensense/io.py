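"""Readers and writers for the block CSV dialects.

All block files are UTF-8 comma-separated with '.' decimals.  Instrument
blocks use a header row of metadata columns followed by feature columns:
NIR features are wavelengths in nm (serialised with one decimal), e-nose /
e-tongue features are sensor id strings.  Writes are atomic (temp file then
rename), so a failed write never leaves a partial file behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blocks import SensorBlock, SpectralBlock

KINDS = ("nir", "etongue", "enose", "sensory", "colour")

_META_COLS = {
    "nir": ["sample_id", "class", "replicate", "scan"],
    "etongue": ["sample_id", "class", "replicate", "session"],
    "enose": ["sample_id", "class", "replicate", "session"],
}
_SENSORY_COLS = ["panellist", "session", "sample", "attribute", "score"]
_COLOUR_COLS = ["sample_id", "replicate", "L", "a", "b"]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file in the same directory."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_to_csv_atomic(frame: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, frame.to_csv(index=False))


def write_block(block, path: str | Path, kind: str) -> None:
    """Serialise a block to its CSV dialect."""
    if kind == "nir":
        frame = block.meta.rename(
            columns={"class_label": "class", "replicate_id": "replicate", "scan_index": "scan"}
        )[["sample_id", "class", "replicate", "scan"]].copy()
        features = pd.DataFrame(
            block.X, columns=[f"{w:.1f}" for w in block.wavelengths]
        )
    elif kind in ("etongue", "enose"):
        frame = block.meta.rename(
            columns={"class_label": "class", "replicate_id": "replicate", "session_id": "session"}
        )[["sample_id", "class", "replicate", "session"]].copy()
        features = pd.DataFrame(block.X, columns=list(block.sensor_ids))
    elif kind == "sensory":
        _frame_to_csv_atomic(block[_SENSORY_COLS], path)
        return
    elif kind == "colour":
        _frame_to_csv_atomic(block[_COLOUR_COLS], path)
        return
    else:
        raise ValueError(f"unknown block kind {kind!r}; expected one of {KINDS}")
    _frame_to_csv_atomic(pd.concat([frame, features], axis=1), path)


def _numeric_features(raw: pd.DataFrame, feature_cols: list[str], path) -> np.ndarray:
    X = np.empty((len(raw), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, data row {row + 1}"
            )
        X[:, j] = converted.to_numpy()
    return X


def read_block(path: str | Path, kind: str):
    """Parse a block CSV into its typed container, validating the dialect."""
    path = Path(path)
    if kind not in KINDS:
        raise ValueError(f"unknown block kind {kind!r}; expected one of {KINDS}")
    raw = pd.read_csv(path, dtype=str)
    if kind == "sensory":
        missing = [c for c in _SENSORY_COLS if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing sensory columns {missing}")
        out = raw.copy()
        for col in ("panellist", "session"):
            out[col] = pd.to_numeric(out[col]).astype(int)
        out["score"] = pd.to_numeric(out["score"])
        return out[_SENSORY_COLS]
    if kind == "colour":
        missing = [c for c in _COLOUR_COLS if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing colour columns {missing}")
        out = raw.copy()
        out["replicate"] = pd.to_numeric(out["replicate"]).astype(int)
        for col in ("L", "a", "b"):
            out[col] = pd.to_numeric(out[col])
        return out[_COLOUR_COLS]

    # pandas mangles duplicate headers (ZZ, ZZ.1), so check the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sensor ids {dupes}")

    meta_cols = _META_COLS[kind]
    missing = [c for c in meta_cols if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    feature_cols = [c for c in raw.columns if c not in meta_cols]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns found")
    X = _numeric_features(raw, feature_cols, path)
    if kind == "nir":
        try:
            wavelengths = np.array([float(c) for c in feature_cols])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric wavelength header: {exc}") from None
        if np.any(np.diff(wavelengths) <= 0):
            raise ValueError(f"{path}: wavelength header must be strictly increasing")
        meta = pd.DataFrame(
            {
                "sample_id": raw["sample_id"],
                "class_label": raw["class"],
                "replicate_id": pd.to_numeric(raw["replicate"]).astype(int),
                "scan_index": pd.to_numeric(raw["scan"]).astype(int),
            }
        )
        return SpectralBlock(wavelengths, X, meta)
    if len(set(feature_cols)) != len(feature_cols):
        dupes = sorted({c for c in feature_cols if feature_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicate sensor ids {dupes}")
    meta = pd.DataFrame(
        {
            "sample_id": raw["sample_id"],
            "class_label": raw["class"],
            "replicate_id": pd.to_numeric(raw["replicate"]).astype(int),
            "session_id": pd.to_numeric(raw["session"]).astype(int),
        }
    )
    return SensorBlock(feature_cols, X, meta)


def load_config(path: str | Path) -> dict:
    """Load a YAML study configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg
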