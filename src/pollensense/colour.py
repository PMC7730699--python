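"""CIELAB colour characterisation and pairwise colour differences.

Instrument readings are taken as given (L*, a*, b*) coordinates.  Chroma
C*ab and hue angle h_ab are the polar coordinates of (a*, b*); the total
colour difference ΔE*ab between two coordinates is their Euclidean distance,
categorised against the perceptibility thresholds 1.5 / 3.0 / 6.0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: ΔE*ab perceptibility categories; intervals are closed on the left, so a
#: difference of exactly 1.5 is already "perceptible", 6.0 already "huge".
CATEGORY_THRESHOLDS = ((6.0, "huge"), (3.0, "well perceptible"), (1.5, "perceptible"))


@dataclass(frozen=True)
class ColourCoordinate:
    """A CIELAB point: lightness L* in [0, 100], signed a* and b* axes."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        vals = (self.L_star, self.a_star, self.b_star)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("colour coordinates must be finite")
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L_star}")


@dataclass(frozen=True)
class ColourSummary:
    """Chroma C*ab (colourfulness) and hue angle h_ab in degrees, [0, 360)."""

    chroma: float
    hue_deg: float


@dataclass(frozen=True)
class ColourDifference:
    """ΔE*ab, ΔC*ab, Δh_ab between two CIELAB points, with perceptibility."""

    delta_E: float
    delta_C: float
    delta_h: float
    category: str


def derive_chroma_hue(c: ColourCoordinate) -> ColourSummary:
    """Polar form of (a*, b*): chroma and hue angle.

    The achromatic point a* = b* = 0 has no defined hue; it is reported as
    0° by convention.
    """
    chroma = math.hypot(c.a_star, c.b_star)
    if chroma == 0.0:
        return ColourSummary(0.0, 0.0)
    hue = math.degrees(math.atan2(c.b_star, c.a_star)) % 360.0
    return ColourSummary(chroma, hue)


def categorise_delta_e(delta_E: float) -> str:
    """Perceptibility class of a ΔE*ab value (closed-left intervals)."""
    for threshold, name in CATEGORY_THRESHOLDS:
        if delta_E >= threshold:
            return name
    return "not perceptible"


def colour_difference(c1: ColourCoordinate, c2: ColourCoordinate) -> ColourDifference:
    """Pairwise colour difference between two CIELAB coordinates.

    ΔE*ab is the Euclidean distance in (L*, a*, b*); ΔC*ab the absolute
    chroma difference; Δh_ab the absolute hue-angle difference taken the
    short way around the circle (min(d, 360 − d), in degrees).
    """
    delta_E = math.sqrt(
        (c1.L_star - c2.L_star) ** 2
        + (c1.a_star - c2.a_star) ** 2
        + (c1.b_star - c2.b_star) ** 2
    )
    s1, s2 = derive_chroma_hue(c1), derive_chroma_hue(c2)
    delta_C = abs(s1.chroma - s2.chroma)
    d = abs(s1.hue_deg - s2.hue_deg)
    delta_h = min(d, 360.0 - d)
    return ColourDifference(delta_E, delta_C, delta_h, categorise_delta_e(delta_E))


def pairwise_colour_table(
    samples: Mapping[str, ColourCoordinate] | Sequence[tuple[str, ColourCoordinate]],
) -> pd.DataFrame:
    """All pairwise colour differences between named mean coordinates.

    Returns one row per unordered pair (upper triangle of the difference
    matrix) with columns ``pair``, ``sample_1``, ``sample_2``, ``delta_E``,
    ``delta_C``, ``delta_h`` and ``category``.
    """
    items = list(samples.items()) if isinstance(samples, Mapping) else list(samples)
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("sample names must be unique")
    if len(items) < 2:
        raise ValueError("at least two samples are required")
    rows = []
    for (n1, c1), (n2, c2) in itertools.combinations(items, 2):
        d = colour_difference(c1, c2)
        rows.append(
            {
                "pair": f"{n1} vs {n2}",
                "sample_1": n1,
                "sample_2": n2,
                "delta_E": d.delta_E,
                "delta_C": d.delta_C,
                "delta_h": d.delta_h,
                "category": d.category,
            }
        )
    return pd.DataFrame(rows)


def summarise_colour_observations(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean L*, a*, b* with derived chroma and hue.

    ``observations`` follows the colour CSV dialect: columns ``sample_id``,
    ``replicate``, ``L``, ``a``, ``b``.
    """
    grouped = observations.groupby("sample_id", sort=False)[["L", "a", "b"]].mean()
    out = grouped.copy()
    out["chroma"] = np.hypot(grouped["a"], grouped["b"])
    out["hue_deg"] = np.degrees(np.arctan2(grouped["b"], grouped["a"])) % 360.0
    return out
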