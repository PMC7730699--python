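"""Published summary statistics for the five-origin bee pollen study.

These are the printed measurement summaries the pipeline treats as inputs:
mean CIELAB coordinates per botanical origin, the quantitative descriptive
sensory profile (panel mean ± SD per sample), and the model-quality tables
(R²Tr, RMSEC, R²CV, RMSECV, RPD, latent variables, n) of the single-block
and fused PLSR models. The synthetic-data generator targets these summaries;
the acceptance checks recompute derived quantities from them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Botanical origins, in fixed study order.
CLASS_NAMES = (
    "lakeshore bulrush",
    "sunflower",
    "red clover",
    "rapeseed",
    "spiny plumeless thistle",
)

#: The two polyfloral samples (both contain Carduus acanthoides pollen);
#: the only pair the e-tongue is expected to confuse.
POLYFLORAL_PAIR = ("lakeshore bulrush", "spiny plumeless thistle")

# ---------------------------------------------------------------------------
# Colour: mean (L*, a*, b*) and SDs per sample, and the printed derived values
# ---------------------------------------------------------------------------

COLOUR_MEANS: dict[str, tuple[float, float, float]] = {
    "lakeshore bulrush": (59.6, 6.0, 44.2),
    "sunflower": (58.1, 12.2, 64.5),
    "red clover": (50.7, 5.8, 40.7),
    "rapeseed": (66.3, 0.9, 54.6),
    "spiny plumeless thistle": (33.4, 15.6, 17.1),
}

COLOUR_SDS: dict[str, tuple[float, float, float]] = {
    "lakeshore bulrush": (0.4, 0.1, 0.9),
    "sunflower": (0.2, 0.1, 0.2),
    "red clover": (0.4, 0.1, 0.4),
    "rapeseed": (0.5, 0.2, 0.4),
    "spiny plumeless thistle": (0.3, 0.2, 0.3),
}

#: Printed chroma C*ab and hue angle h_ab per sample.
PRINTED_CHROMA_HUE: dict[str, tuple[float, float]] = {
    "lakeshore bulrush": (44.6, 82.3),
    "sunflower": (65.6, 79.3),
    "red clover": (41.1, 81.9),
    "rapeseed": (54.6, 89.1),
    "spiny plumeless thistle": (23.1, 47.6),
}

#: Printed pairwise colour differences (delta_E, delta_C, delta_h).
#: Note: in the published rapeseed–thistle cell the delta_C and delta_h lines
#: appear in swapped order; recomputation from the printed means fixes the
#: assignment (delta_C = 31.46, delta_h = 41.5).
PRINTED_COLOUR_DIFFS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("lakeshore bulrush", "sunflower"): (21.28, 21.03, 3.0),
    ("lakeshore bulrush", "red clover"): (9.57, 3.50, 0.4),
    ("lakeshore bulrush", "rapeseed"): (13.38, 10.00, 6.8),
    ("lakeshore bulrush", "spiny plumeless thistle"): (38.90, 21.46, 34.7),
    ("sunflower", "red clover"): (25.73, 24.53, 2.6),
    ("sunflower", "rapeseed"): (17.12, 11.03, 9.8),
    ("sunflower", "spiny plumeless thistle"): (53.56, 42.49, 31.7),
    ("red clover", "rapeseed"): (21.46, 13.50, 7.2),
    ("red clover", "spiny plumeless thistle"): (30.86, 17.96, 34.3),
    ("rapeseed", "spiny plumeless thistle"): (52.01, 31.46, 41.5),
}

# ---------------------------------------------------------------------------
# Sensory: 18-attribute quantitative descriptive profile, mean ± SD per sample
# (panel of 14 assessors × 2 sessions, 0–100 scale; n = 28 per cell)
# ---------------------------------------------------------------------------

SENSORY_ATTRIBUTES = (
    "brightness",
    "colour hue",
    "homogeneity of surface",
    "global odour intensity",
    "sweet odour intensity",
    "sour odour intensity",
    "floral odour intensity",
    "hay odour intensity",
    "global taste intensity",
    "sweet taste intensity",
    "sour taste intensity",
    "floral taste intensity",
    "hay taste intensity",
    "off-taste intensity",
    "aftertaste intensity",
    "hardness",
    "cohesiveness",
    "mouthcoating",
)

#: attribute -> ((means per class), (sds per class)), class order = CLASS_NAMES
SENSORY_SUMMARY: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "brightness": ((45.5, 29.6, 68.9, 11.5, 84.3), (3.9, 3.7, 2.1, 2.0, 3.5)),
    "colour hue": ((40.9, 23.9, 61.7, 11.4, 94.1), (2.7, 2.4, 2.0, 2.0, 1.9)),
    "homogeneity of surface": ((62.9, 64.5, 80.8, 85.6, 81.3), (3.0, 5.1, 1.7, 3.5, 1.9)),
    "global odour intensity": ((85.6, 63.8, 70.0, 88.0, 86.5), (3.4, 2.9, 3.4, 3.2, 3.4)),
    "sweet odour intensity": ((63.0, 67.0, 56.7, 71.3, 82.4), (3.0, 2.8, 2.7, 2.6, 2.2)),
    "sour odour intensity": ((17.3, 5.5, 6.0, 10.4, 7.1), (3.2, 1.7, 2.1, 1.1, 2.5)),
    "floral odour intensity": ((11.8, 6.3, 3.2, 8.7, 2.8), (2.4, 2.3, 2.8, 1.8, 2.7)),
    "hay odour intensity": ((20.3, 11.7, 2.8, 14.8, 2.4), (3.7, 2.9, 2.5, 2.5, 2.0)),
    "global taste intensity": ((87.8, 92.0, 83.3, 81.8, 79.8), (3.9, 2.8, 4.1, 3.8, 2.8)),
    "sweet taste intensity": ((86.2, 64.4, 72.8, 68.4, 84.1), (4.8, 3.5, 5.0, 2.8, 3.9)),
    "sour taste intensity": ((7.4, 14.4, 47.7, 69.1, 63.4), (3.5, 3.6, 4.1, 2.4, 5.5)),
    "floral taste intensity": ((5.5, 5.5, 8.3, 9.0, 8.3), (2.8, 3.0, 2.3, 1.8, 3.3)),
    "hay taste intensity": ((4.4, 15.5, 7.6, 4.0, 4.8), (1.6, 3.0, 2.5, 2.6, 0.6)),
    "off-taste intensity": ((42.3, 64.6, 32.8, 32.5, 0.0), (5.5, 5.6, 4.6, 5.8, 0.0)),
    "aftertaste intensity": ((0.1, 0.0, 0.0, 0.0, 0.4), (0.4, 0.0, 0.4, 0.0, 1.3)),
    "hardness": ((10.5, 8.4, 11.0, 13.4, 18.4), (1.0, 2.3, 1.8, 2.0, 3.6)),
    "cohesiveness": ((10.4, 8.9, 12.1, 5.9, 74.6), (0.8, 3.3, 2.3, 2.0, 5.9)),
    "mouthcoating": ((76.8, 86.8, 35.9, 63.8, 71.0), (3.4, 3.6, 4.8, 2.5, 4.1)),
}

#: Observations per sample-attribute cell (14 panellists × 2 sessions).
SENSORY_N_PER_CELL = 28

# ---------------------------------------------------------------------------
# Published PLSR model-quality tables per instrument block and for the fusion
# rows: (attribute, R2Tr, RMSEC, R2CV, RMSECV, RPD, n_latent, n_obs)
# ---------------------------------------------------------------------------

_Q = [
    # NIR (950–1650 nm after Savitzky-Golay + MSC)
    ("nir", "brightness", 0.81, 11.53, 0.54, 17.75, 1.49, 3, 58),
    ("nir", "colour hue", 0.85, 11.14, 0.70, 15.87, 1.84, 3, 58),
    ("nir", "homogeneity of surface", 0.98, 1.26, 0.85, 3.53, 2.62, 5, 57),
    ("nir", "global odour intensity", 0.90, 3.15, 0.49, 7.08, 1.41, 5, 59),
    ("nir", "sweet odour intensity", 0.06, 8.47, -0.25, 9.75, 0.90, 1, 63),
    ("nir", "sour odour intensity", 0.59, 2.49, 0.14, 3.61, 1.09, 3, 57),
    ("nir", "floral odour intensity", 0.95, 0.70, 0.75, 1.62, 2.03, 5, 55),
    ("nir", "hay odour intensity", 0.96, 1.28, 0.84, 2.75, 2.48, 5, 56),
    ("nir", "global taste intensity", 0.95, 0.95, 0.75, 2.19, 2.03, 5, 59),
    ("nir", "sweet taste intensity", 0.61, 5.11, 0.20, 7.33, 1.13, 3, 61),
    ("nir", "sour taste intensity", 0.96, 5.11, 0.67, 14.20, 1.75, 5, 55),
    ("nir", "floral taste intensity", 0.96, 0.30, 0.84, 0.62, 2.50, 4, 61),
    ("nir", "hay taste intensity", 0.77, 2.08, 0.20, 3.91, 1.13, 4, 61),
    ("nir", "off-taste intensity", 0.95, 4.83, 0.74, 10.64, 2.00, 5, 58),
    ("nir", "aftertaste intensity", 0.84, 0.05, 0.70, 0.07, 1.84, 3, 61),
    ("nir", "hardness", 0.95, 0.81, 0.69, 1.97, 1.80, 5, 59),
    ("nir", "cohesiveness", 0.95, 6.17, 0.68, 15.39, 1.79, 5, 58),
    ("nir", "mouthcoating", 0.66, 10.34, 0.52, 12.36, 1.45, 1, 65),
    ("nir", "L*", 0.94, 2.76, 0.80, 4.90, 2.27, 4, 57),
    ("nir", "a*", 0.85, 1.78, 0.50, 3.57, 1.42, 4, 55),
    ("nir", "b*", 0.94, 4.28, 0.65, 9.94, 1.71, 5, 59),
    ("nir", "delta_C", 0.78, 6.92, 0.59, 9.43, 1.58, 3, 61),
    ("nir", "delta_h", 0.93, 3.68, 0.61, 8.96, 1.61, 5, 58),
    # e-nose (method 4, 20 most discriminating sensors)
    ("enose", "brightness", 0.66, 15.38, 0.44, 19.44, 1.39, 2, 15),
    ("enose", "colour hue", 0.65, 17.42, 0.42, 22.12, 1.36, 2, 15),
    ("enose", "homogeneity of surface", 0.69, 5.23, 0.00, 9.22, 1.03, 2, 15),
    ("enose", "global odour intensity", 0.74, 5.02, 0.62, 6.25, 1.69, 2, 15),
    ("enose", "sweet odour intensity", 0.68, 4.86, 0.53, 5.85, 1.52, 2, 15),
    ("enose", "sour odour intensity", 0.56, 2.88, 0.37, 3.46, 1.31, 2, 15),
    ("enose", "floral odour intensity", 0.72, 1.79, 0.27, 2.84, 1.21, 2, 15),
    ("enose", "hay odour intensity", 0.87, 2.46, 0.26, 5.52, 1.21, 2, 15),
    ("enose", "global taste intensity", 0.49, 3.17, 0.27, 3.76, 1.21, 2, 15),
    ("enose", "sweet taste intensity", 0.92, 2.39, 0.89, 2.81, 3.16, 2, 15),
    ("enose", "sour taste intensity", 0.48, 18.20, -0.06, 26.65, 1.00, 2, 15),
    ("enose", "floral taste intensity", 0.58, 1.00, 0.06, 1.52, 1.07, 2, 15),
    ("enose", "hay taste intensity", 0.78, 2.02, 0.69, 2.39, 1.86, 2, 15),
    ("enose", "off-taste intensity", 0.62, 12.87, 0.38, 16.55, 1.31, 2, 15),
    ("enose", "aftertaste intensity", 0.67, 0.08, 0.49, 0.09, 1.45, 2, 15),
    ("enose", "hardness", 0.54, 2.31, 0.32, 2.81, 1.25, 2, 15),
    ("enose", "cohesiveness", 0.61, 16.33, 0.41, 20.12, 1.34, 2, 15),
    ("enose", "mouthcoating", 0.97, 2.91, 0.87, 5.66, 2.88, 2, 15),
    ("enose", "L*", 0.68, 6.38, 0.50, 8.25, 1.46, 2, 15),
    ("enose", "a*", 0.81, 2.26, 0.62, 3.15, 1.69, 2, 15),
    ("enose", "b*", 0.76, 7.84, 0.61, 9.92, 1.65, 2, 15),
    ("enose", "delta_C", 0.79, 6.45, 0.67, 8.14, 1.79, 2, 15),
    ("enose", "delta_h", 0.62, 9.04, 0.41, 11.14, 1.35, 2, 15),
    # e-tongue (drift-corrected, 7 sensors)
    ("etongue", "brightness", 0.68, 14.91, 0.22, 22.88, 1.14, 5, 46),
    ("etongue", "colour hue", 0.44, 21.84, 0.09, 27.56, 1.06, 3, 43),
    ("etongue", "homogeneity of surface", 0.73, 4.87, 0.54, 6.26, 1.49, 4, 50),
    ("etongue", "global odour intensity", 0.95, 2.31, 0.91, 3.02, 3.32, 4, 47),
    ("etongue", "sweet odour intensity", 0.76, 4.39, 0.58, 5.83, 1.55, 4, 45),
    ("etongue", "sour odour intensity", 0.78, 1.92, 0.57, 2.67, 1.54, 5, 49),
    ("etongue", "floral odour intensity", 0.66, 1.97, 0.16, 3.05, 1.11, 5, 47),
    ("etongue", "hay odour intensity", 0.54, 4.75, 0.16, 6.37, 1.11, 4, 45),
    ("etongue", "global taste intensity", 0.85, 1.71, 0.61, 2.69, 1.62, 5, 51),
    ("etongue", "sweet taste intensity", 0.88, 2.96, 0.77, 4.11, 2.10, 4, 44),
    ("etongue", "sour taste intensity", 0.65, 14.47, 0.43, 18.40, 1.34, 4, 51),
    ("etongue", "floral taste intensity", 0.90, 0.46, 0.85, 0.57, 2.61, 4, 44),
    ("etongue", "hay taste intensity", 0.98, 0.55, 0.97, 0.69, 5.94, 4, 44),
    ("etongue", "off-taste intensity", 0.88, 6.96, 0.68, 10.88, 1.80, 5, 49),
    ("etongue", "aftertaste intensity", 0.50, 0.09, 0.04, 0.12, 1.03, 3, 44),
    ("etongue", "hardness", 0.83, 1.34, 0.66, 1.87, 1.74, 5, 49),
    ("etongue", "cohesiveness", 0.59, 16.76, 0.21, 22.94, 1.14, 4, 45),
    ("etongue", "mouthcoating", 0.98, 2.16, 0.97, 3.20, 5.42, 4, 44),
    ("etongue", "L*", 0.62, 6.46, 0.00, 10.27, 1.01, 5, 46),
    ("etongue", "a*", 0.72, 2.67, 0.56, 3.32, 1.53, 3, 41),
    ("etongue", "b*", 0.77, 7.57, 0.44, 11.73, 1.35, 5, 46),
    ("etongue", "delta_C", 0.72, 7.64, 0.46, 10.47, 1.37, 3, 45),
    ("etongue", "delta_h", 0.67, 7.62, 0.14, 12.00, 1.09, 5, 46),
    # fused NIR + e-nose + e-tongue (low-level concatenation)
    ("fused", "brightness", 0.99, 2.14, 0.96, 4.61, 5.06, 5, 70),
    ("fused", "colour hue", 0.97, 4.80, 0.90, 9.08, 3.20, 5, 70),
    ("fused", "homogeneity of surface", 0.99, 0.77, 0.98, 1.40, 6.67, 5, 70),
    ("fused", "global odour intensity", 0.99, 1.09, 0.96, 2.05, 4.82, 5, 70),
    ("fused", "sweet odour intensity", 0.98, 1.21, 0.94, 2.13, 3.99, 5, 70),
    ("fused", "sour odour intensity", 0.98, 0.66, 0.94, 1.07, 4.09, 5, 70),
    ("fused", "floral odour intensity", 0.97, 0.58, 0.91, 1.02, 3.34, 5, 70),
    ("fused", "hay odour intensity", 0.97, 1.15, 0.91, 2.03, 3.42, 5, 70),
    ("fused", "global taste intensity", 0.99, 0.46, 0.96, 0.90, 4.95, 5, 70),
    ("fused", "sweet taste intensity", 0.99, 0.87, 0.96, 1.69, 5.12, 5, 70),
    ("fused", "sour taste intensity", 0.99, 2.45, 0.97, 4.41, 5.65, 5, 70),
    ("fused", "floral taste intensity", 0.99, 0.14, 0.97, 0.24, 6.25, 4, 70),
    ("fused", "hay taste intensity", 0.99, 0.47, 0.96, 0.88, 4.92, 5, 70),
    ("fused", "off-taste intensity", 0.98, 2.96, 0.93, 5.62, 3.73, 5, 70),
    ("fused", "aftertaste intensity", 0.80, 0.06, 0.55, 0.09, 1.49, 3, 70),
    ("fused", "hardness", 0.98, 0.51, 0.92, 0.94, 3.61, 5, 70),
    ("fused", "cohesiveness", 0.97, 4.87, 0.89, 8.72, 2.98, 5, 70),
    ("fused", "mouthcoating", 0.99, 0.81, 0.99, 1.43, 12.10, 5, 70),
    ("fused", "L*", 0.96, 2.14, 0.88, 3.85, 2.89, 5, 70),
    ("fused", "a*", 0.97, 0.91, 0.90, 1.57, 3.27, 5, 70),
    ("fused", "b*", 0.98, 2.41, 0.91, 4.63, 3.44, 5, 70),
    ("fused", "delta_C", 0.98, 1.99, 0.92, 3.91, 3.64, 5, 70),
    ("fused", "delta_h", 0.96, 2.77, 0.88, 4.92, 2.93, 5, 70),
]


def model_quality_table() -> pd.DataFrame:
    """Published PLSR quality metrics for all blocks as a tidy DataFrame."""
    return pd.DataFrame(
        _Q,
        columns=[
            "block", "attribute", "r2_tr", "rmsec", "r2_cv", "rmsecv",
            "rpd", "n_latent", "n_obs",
        ],
    )


def sensory_summary_frame() -> pd.DataFrame:
    """Sensory profile summaries as a tidy (attribute, sample, mean, sd) frame."""
    rows = []
    for attr, (means, sds) in SENSORY_SUMMARY.items():
        for cls, m, s in zip(CLASS_NAMES, means, sds):
            rows.append((attr, cls, m, s))
    return pd.DataFrame(rows, columns=["attribute", "sample", "mean", "sd"])


def colour_means_array() -> np.ndarray:
    """Mean (L*, a*, b*) per class as a 5 × 3 array in CLASS_NAMES order."""
    return np.array([COLOUR_MEANS[c] for c in CLASS_NAMES])
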