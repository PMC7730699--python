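"""Full-study orchestration: preprocessing, classification and regression
for every instrument block and for their low-level fusion.

``run_full_study`` wires the whole pipeline together: generate (or accept)
the blocks, pretreat each one the block-specific way, build per-block LDA
classification models, run two-round cross-validated PLSR for all 18
sensory and 5 colour attributes per block and on the fused matrix, and
collect everything in a serialisable report.  Given the same configuration
and seed the report is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import SpectralBlock
from .fusion import align_blocks, two_round_plsr
from .lda import LDAResult, cross_val_lda
from .preprocess import (
    drift_correct_etongue,
    msc_correct,
    savgol_smooth,
    select_sensors_by_discrimination,
    truncate_range,
)
from .synthetic import ALL_ATTRIBUTES, StudyConfig, SyntheticStudy, generate_study


@dataclass
class StudyReport:
    """Bundle of classification and regression results for one study run."""

    seed: int
    lda: dict[str, LDAResult]
    plsr: pd.DataFrame            # tidy: block × attribute quality metrics
    n_obs_per_block: dict[str, int]
    config: StudyConfig = field(repr=False, default=None)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "seed": self.seed,
            "lda": {
                name: {
                    "recognition_pct": round(res.recognition_pct, 6),
                    "prediction_pct": round(res.prediction_pct, 6),
                    "confusion_cv": res.confusion_cv.to_dict(),
                }
                for name, res in self.lda.items()
            },
            "plsr": [
                {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
                for row in self.plsr.to_dict(orient="records")
            ],
            "n_obs_per_block": self.n_obs_per_block,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def preprocess_nir(
    nir: SpectralBlock,
    *,
    window: int = 21,
    polyorder: int = 2,
    low_nm: float = 950.0,
    high_nm: float = 1650.0,
) -> SpectralBlock:
    """Standard NIR pretreatment: SG smoothing, MSC, range truncation."""
    smoothed = savgol_smooth(nir, window=window, polyorder=polyorder)
    corrected, _ = msc_correct(smoothed, "mean")
    return truncate_range(corrected, low_nm, high_nm)


def _unit_labels(meta: pd.DataFrame) -> np.ndarray:
    return np.array(
        [f"{s}|{r}" for s, r in zip(meta["sample_id"], meta["replicate_id"])]
    )


def _attribute_vector(study: SyntheticStudy, attribute: str, meta: pd.DataFrame) -> np.ndarray:
    """Per-observation regression target: the unit-level attribute value."""
    values = study.truth.attribute_values.set_index(["sample_id", "replicate_id"])
    return np.array(
        [
            values.loc[(s, r), attribute]
            for s, r in zip(meta["sample_id"], meta["replicate_id"])
        ]
    )


def run_full_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    *,
    max_components: int = 12,
    lda_folds: int = 3,
    lda_seed: int = 42,
    attributes: tuple[str, ...] | None = None,
    study: SyntheticStudy | None = None,
) -> StudyReport:
    """Run classification and regression on every block and the fusion.

    Per-block pretreatment: NIR gets SG smoothing + MSC + 950–1650 nm
    truncation; the e-tongue gets additive session-drift correction; the
    e-nose keeps its 20 most discriminating sensors.  LDA uses stratified
    3-fold cross-validation; PLSR uses leave-one-preparation-unit-out
    cross-validation in two rounds with prediction-based outlier removal.
    """
    if study is None:
        study = generate_study(config, seed)
    config = study.config
    attributes = ALL_ATTRIBUTES if attributes is None else attributes

    nir = preprocess_nir(study.nir)
    etongue = drift_correct_etongue(study.etongue)
    enose = select_sensors_by_discrimination(
        study.enose, k=min(20, len(study.enose.sensor_ids))
    )
    fused = align_blocks(nir, etongue, enose)

    blocks: dict[str, tuple[np.ndarray, pd.DataFrame]] = {
        "nir": (nir.X, nir.meta),
        "etongue": (etongue.X, etongue.meta),
        "enose": (enose.X, enose.meta),
        "fused": (fused.X, fused.meta),
    }

    lda_results = {
        name: cross_val_lda(
            X, meta["class_label"].to_numpy(), n_folds=lda_folds, seed=lda_seed
        )
        for name, (X, meta) in blocks.items()
    }

    rows = []
    for name, (X, meta) in blocks.items():
        groups = _unit_labels(meta)
        samples = meta["sample_id"].to_numpy()
        for attribute in attributes:
            y = _attribute_vector(study, attribute, meta)
            result, report, _ = two_round_plsr(
                y, X, groups, max_components, sample_groups=samples
            )
            rows.append(
                {
                    "block": name,
                    "attribute": attribute,
                    "r2_tr": result.r2_tr,
                    "rmsec": result.rmsec,
                    "r2_cv": result.r2_cv,
                    "rmsecv": result.rmsecv,
                    "rpd": result.rpd,
                    "n_latent": result.n_components,
                    "n_obs": result.n_obs,
                    "n_outliers_removed": report.n_flagged,
                }
            )
    plsr = pd.DataFrame(rows)
    return StudyReport(
        seed=seed,
        lda=lda_results,
        plsr=plsr,
        n_obs_per_block={name: X.shape[0] for name, (X, _) in blocks.items()},
        config=config,
    )
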