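"""Low-level multi-sensor fusion and the two-round PLSR workflow.

The fused matrix is the column-wise concatenation of the pretreated NIR,
e-tongue and e-nose blocks aligned on the NIR observations (each preparation
unit's e-tongue rows are matched or averaged, its single e-nose row is
repeated), autoscaled after concatenation.  Regression models are built in
two rounds: cross-validated predictions of the first round are screened for
outliers per sample with a median ± 1.5·IQR whisker rule, flagged rows are
dropped, and the model is rebuilt on the retained rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import FusedBlock, SensorBlock, SpectralBlock
from .pls import PLSCVResults, cross_val_pls


@dataclass
class OutlierReport:
    """Rows flagged by the prediction-based boxplot rule.

    ``bounds`` maps each sample group to its whisker interval
    [median − 1.5·IQR, median + 1.5·IQR]; values exactly on a whisker are
    retained.
    """

    flagged: np.ndarray
    bounds: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.size)


def align_blocks(
    nir: SpectralBlock, etongue: SensorBlock, enose: SensorBlock
) -> FusedBlock:
    """Pair the three blocks observation-wise and concatenate columns.

    The NIR observations define the row basis.  For each preparation unit
    (sample, replicate): e-tongue rows are paired with the NIR scans in
    acquisition order when the counts match, otherwise the unit's e-tongue
    average is used for every NIR row; the unit's single e-nose row is
    repeated across all its NIR rows.  The fused matrix is autoscaled after
    concatenation (state kept on the block).
    """
    def unit_key(meta: pd.DataFrame):
        return list(zip(meta["sample_id"], meta["replicate_id"]))

    nir_units = unit_key(nir.meta)
    for name, block in (("e-tongue", etongue), ("e-nose", enose)):
        missing = set(nir.meta["sample_id"]) - set(block.meta["sample_id"])
        extra = set(block.meta["sample_id"]) - set(nir.meta["sample_id"])
        if missing or extra:
            raise ValueError(
                f"sample mismatch with {name} block: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    et_index: dict = {}
    for i, key in enumerate(unit_key(etongue.meta)):
        et_index.setdefault(key, []).append(i)
    en_index: dict = {}
    for i, key in enumerate(unit_key(enose.meta)):
        en_index.setdefault(key, []).append(i)

    nir_counts: dict = {}
    for key in nir_units:
        nir_counts[key] = nir_counts.get(key, 0) + 1

    et_rows = np.empty((nir.n_obs, etongue.X.shape[1]))
    en_rows = np.empty((nir.n_obs, enose.X.shape[1]))
    seen: dict = {}
    for i, key in enumerate(nir_units):
        if key not in et_index:
            raise ValueError(f"unit {key} missing from the e-tongue block")
        if key not in en_index:
            raise ValueError(f"unit {key} missing from the e-nose block")
        if len(en_index[key]) != 1:
            raise ValueError(
                f"e-nose must have exactly one row per unit, unit {key} has "
                f"{len(en_index[key])}"
            )
        pos = seen.get(key, 0)
        seen[key] = pos + 1
        rows = et_index[key]
        if len(rows) == nir_counts[key]:
            et_rows[i] = etongue.X[rows[pos]]
        else:
            et_rows[i] = etongue.X[rows].mean(axis=0)
        en_rows[i] = enose.X[en_index[key][0]]

    X = np.hstack([nir.X, et_rows, en_rows])
    p1, p2, p3 = nir.X.shape[1], et_rows.shape[1], en_rows.shape[1]
    slices = {
        "nir": slice(0, p1),
        "etongue": slice(p1, p1 + p2),
        "enose": slice(p1 + p2, p1 + p2 + p3),
    }
    names = (
        [f"{w:.1f}" for w in nir.wavelengths]
        + list(etongue.sensor_ids)
        + list(enose.sensor_ids)
    )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    meta = nir.meta[["sample_id", "class_label", "replicate_id"]].copy()
    return FusedBlock((X - mean) / sd, meta, names, slices, mean, sd)


def detect_prediction_outliers(
    predictions: np.ndarray,
    groups: np.ndarray,
    *,
    whisker: str = "median",
    k_iqr: float = 1.5,
) -> OutlierReport:
    """Boxplot screening of model predictions within each sample group.

    With the default ``whisker='median'`` convention the whiskers sit at
    median ± k·IQR; ``whisker='tukey'`` uses the classic quartile ± k·IQR
    fences instead.  Values exactly on a whisker are retained.  Groups with
    fewer than 3 observations are skipped with a warning.
    """
    predictions = np.asarray(predictions, dtype=float)
    groups = np.asarray(groups)
    flagged: list[int] = []
    bounds: dict = {}
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 3:
            warnings.warn(
                f"group {g!r} has fewer than 3 observations; skipped",
                stacklevel=2,
            )
            continue
        vals = predictions[idx]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        if whisker == "median":
            lo, hi = med - k_iqr * iqr, med + k_iqr * iqr
        elif whisker == "tukey":
            lo, hi = q1 - k_iqr * iqr, q3 + k_iqr * iqr
        else:
            raise ValueError("whisker must be 'median' or 'tukey'")
        bounds[g] = (float(lo), float(hi))
        flagged.extend(idx[(vals < lo) | (vals > hi)].tolist())
    return OutlierReport(np.array(sorted(flagged), dtype=int), bounds)


def two_round_plsr(
    endog,
    exog,
    groups,
    max_components: int = 10,
    *,
    sample_groups=None,
    whisker: str = "median",
    scale: bool = True,
    leakage_safe: bool = True,
) -> tuple[PLSCVResults, OutlierReport, PLSCVResults]:
    """Cross-validated PLSR with prediction-based outlier removal.

    Round 1 fits on all rows; its cross-validated predictions are screened
    per sample with the whisker rule; round 2 refits on the retained rows.
    Returns (round-2 result, outlier report, round-1 result); the round-2
    record carries the retained observation count.
    """
    y = np.asarray(endog, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    groups = np.asarray(groups)
    sg = groups if sample_groups is None else np.asarray(sample_groups)
    round1 = cross_val_pls(
        y, X, groups, max_components, scale=scale, leakage_safe=leakage_safe
    )
    report = detect_prediction_outliers(round1.cv_predictions, sg, whisker=whisker)
    if report.n_flagged == 0:
        return round1, report, round1
    keep = np.ones(y.size, dtype=bool)
    keep[report.flagged] = False
    emptied = [g for g in pd.unique(sg) if not np.any(keep[sg == g])]
    if emptied:
        raise ValueError(
            f"outlier removal would empty sample group(s) {emptied}; aborting"
        )
    round2 = cross_val_pls(
        y[keep], X[keep], groups[keep], max_components,
        scale=scale, leakage_safe=leakage_safe,
    )
    return round2, report, round1
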