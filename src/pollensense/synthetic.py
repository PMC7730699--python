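"""Synthetic five-origin bee pollen study generator.

No public data exist for the study this package models, so every stage of
the pipeline is exercised on synthetic blocks that carry the statistical
structure the analysis assumes:

* colour observations drawn around the published per-origin CIELAB means/SDs;
* NIR transmission spectra (900–1700 nm, 3 nm step) dominated by water
  bands, with class-dependent absorption amplitudes concentrated at 1364 and
  1450 nm, multiplicative scatter, baseline offsets and white noise;
* a 7-sensor e-tongue block with additive per-session drift shared by all
  samples in a session;
* an e-nose sensor pool in which 20 informative sensors carry graded
  class separation (Fisher ratio) and the rest are noise;
* a sensory long table built from the published panel means with additive
  assessor effects;
* per-preparation-unit attribute targets generated as noisy linear functions
  of latent factors expressed one-per-block, so that fusing blocks is
  genuinely more informative than any single block.

All randomness flows through one master seed; sub-streams are spawned
deterministically, so equal seeds give byte-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .blocks import SensorBlock, SpectralBlock

#: e-tongue sensor identifiers (Astree food-application set).
ETONGUE_SENSORS = ("ZZ", "JE", "JB", "HA", "CA", "BB", "GA")

#: e-nose sensors named in the study narrative; kept among the informative
#: pool so generated blocks look like real Kovats-index-labelled channels.
NAMED_ENOSE_SENSORS = (
    "516.65-2A", "686.62-1A", "793.68-2A", "592.01-2A",
    "998.58-1A", "1046.00-1A", "444.97-1A",
)

#: attributes predicted by the regression stage: the 18 sensory descriptors
#: plus the five colour parameters.
COLOUR_ATTRIBUTES = ("L*", "a*", "b*", "delta_C", "delta_h")
ALL_ATTRIBUTES = reference.SENSORY_ATTRIBUTES + COLOUR_ATTRIBUTES


@dataclass
class StudyConfig:
    """Design constants and noise scales of the synthetic study.

    The defaults reproduce the study geometry: 5 botanical classes × 3
    preparation units, 5 consecutive NIR scans per unit (n = 75 spectra), 4
    e-tongue sessions, one e-nose row per unit (method 4), a 14-assessor ×
    2-session panel and 10 colour readings per sample.  Separation scales
    are set so the qualitative outcomes of the real study emerge: NIR and
    e-nose classes are fully separable, while the two polyfloral classes
    (which share Carduus acanthoides pollen) sit close in e-tongue space and
    are the only confusable pair.
    """

    class_names: tuple[str, ...] = reference.CLASS_NAMES
    n_replicates: int = 3
    nir_scans_per_replicate: int = 5
    etongue_sessions: int = 4
    sensory_panellists: int = 14
    sensory_sessions: int = 2
    colour_obs_per_class: int = 10

    # NIR block
    wl_start: float = 900.0
    wl_stop: float = 1700.0
    wl_step: float = 3.0
    nir_noise_sd: float = 0.002
    nir_gain_range: tuple[float, float] = (0.9, 1.1)
    nir_offset_range: tuple[float, float] = (-0.04, 0.04)
    nir_class_scale: float = 1.0      # multiplies the class band-amplitude patterns
    nir_latent_scale: float = 1.0     # multiplies the per-unit 1364/1450 nm loading

    # e-tongue block (signal units ~ mV)
    etongue_noise_sd: float = 1.0
    etongue_drift_sd: float = 3.0
    etongue_pair_separation: float = 4.0   # polyfloral pair centre distance
    etongue_far_separation: float = 12.0   # everyone else
    etongue_latent_scale: float = 3.5

    # e-nose block
    enose_n_sensors: int = 59
    enose_n_informative: int = 20
    enose_signal_scale: float = 14.0
    enose_noise_sd: float = 0.5
    enose_latent_scale: float = 0.8

    # sensory panel
    assessor_sd: float = 2.0

    # attribute targets: per-unit latent contribution and noise, both as
    # fractions of the between-class SD of the attribute
    attribute_latent_frac: float = 0.55
    attribute_noise_frac: float = 0.03

    def __post_init__(self) -> None:
        counts = (
            self.n_replicates, self.nir_scans_per_replicate,
            self.etongue_sessions, self.sensory_panellists,
            self.sensory_sessions, self.colour_obs_per_class,
            self.enose_n_sensors, self.enose_n_informative,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be positive")
        if self.enose_n_informative > self.enose_n_sensors:
            raise ValueError("cannot have more informative sensors than sensors")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_units(self) -> int:
        return self.n_classes * self.n_replicates

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop, self.wl_step)


@dataclass
class GroundTruth:
    """Everything needed to verify recovery of the generated structure."""

    unit_meta: pd.DataFrame            # one row per preparation unit
    latent: np.ndarray                 # units × 3 (NIR, e-tongue, e-nose factors)
    attribute_values: pd.DataFrame     # units × 23 regression targets
    attribute_weights: pd.DataFrame    # 23 × 3 latent weights
    attribute_class_means: pd.DataFrame
    etongue_drift: np.ndarray          # sessions × sensors
    etongue_drift_free: np.ndarray     # block matrix without drift
    informative_sensors: list[str]
    nir_band_centers: np.ndarray
    outlier_rows: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    colour: pd.DataFrame
    nir: SpectralBlock
    etongue: SensorBlock
    enose: SensorBlock
    sensory: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

_NIR_BAND_CENTERS = np.array([1163.0, 1364.0, 1415.0, 1450.0, 1495.0])
_NIR_BAND_WIDTHS = np.array([24.0, 26.0, 20.0, 28.0, 22.0])
# class band-amplitude geometry: four orthonormal contrasts across the five
# classes (so the centred class means span the full 4-D class space and any
# attribute profile is linearly representable from the spectra), with the
# first contrast — loading mainly on the 1364/1450 nm water bands — carrying
# most of the between-class variance
_CLASS_CONTRASTS = np.array(
    [
        [-2.0, -1.0, 0.0, 1.0, 2.0],
        [2.0, -1.0, -2.0, -1.0, 2.0],
        [-1.0, 2.0, 0.0, -2.0, 1.0],
        [1.0, -4.0, 6.0, -4.0, 1.0],
    ]
)
_CLASS_CONTRASTS /= np.linalg.norm(_CLASS_CONTRASTS, axis=1, keepdims=True)
_BAND_LOADINGS = np.array(
    [
        # bands:  1163    1364    1415    1450    1495
        [0.009, 0.068, 0.011, 0.059, 0.013],   # dominant water-band contrast
        [0.026, 0.009, 0.018, 0.007, 0.022],
        [0.018, 0.007, 0.027, 0.005, 0.016],
        [0.014, 0.005, 0.016, 0.007, 0.027],
    ]
)
# per-unit latent loading in band space: the direction of the 5-band space
# orthogonal to all four class contrasts (so within-class latent variation
# never masquerades as class signal), scaled to a water-band-sized amplitude
def _orthogonal_complement(basis: np.ndarray, seed_vec: np.ndarray) -> np.ndarray:
    v = seed_vec.astype(float).copy()
    for row in basis:
        u = row / np.linalg.norm(row)
        v -= (v @ u) * u
    return v / np.linalg.norm(v)


_BAND_LATENT = 0.035 * _orthogonal_complement(
    _BAND_LOADINGS, np.array([0.0, 1.0, 0.0, -0.75, 0.0])
)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _unit_meta(config: StudyConfig) -> pd.DataFrame:
    rows = [
        (cls, cls, rep)
        for cls in config.class_names
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "class_label", "replicate_id"])


def _water_base(wl: np.ndarray) -> np.ndarray:
    def g(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    return 0.15 + g(1450.0, 55.0, 1.1) + g(1190.0, 70.0, 0.25) + g(975.0, 45.0, 0.08)


def _band_shapes(wl: np.ndarray) -> np.ndarray:
    return np.exp(
        -0.5 * ((wl[None, :] - _NIR_BAND_CENTERS[:, None]) / _NIR_BAND_WIDTHS[:, None]) ** 2
    )


def _etongue_centers(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Class centres in 7-sensor space: the polyfloral pair sits close along
    one axis, each monofloral class far away along its own axis, so the
    centred class geometry spans 4 dimensions (any attribute profile is
    linearly representable) while the pair stays hard to tell apart."""
    raw = rng.normal(size=(7, 4))
    Q, _ = np.linalg.qr(raw)  # orthonormal 4-D embedding in sensor space
    far = config.etongue_far_separation
    d = config.etongue_pair_separation
    coords = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],   # lakeshore bulrush
            [0.0, far, 0.0, 0.0],   # sunflower
            [0.0, 0.0, far, 0.0],   # red clover
            [0.0, 0.0, 0.0, far],   # rapeseed
            [d, 0.0, 0.0, 0.0],     # spiny plumeless thistle
        ]
    )
    return 40.0 + coords @ Q.T


def generate_colour(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cls in config.class_names:
        mu = np.array(reference.COLOUR_MEANS[cls])
        sd = np.array(reference.COLOUR_SDS[cls])
        obs = rng.normal(mu, sd, size=(config.colour_obs_per_class, 3))
        obs[:, 0] = np.clip(obs[:, 0], 0.0, 100.0)
        for r, (L, a, b) in enumerate(obs, start=1):
            rows.append((cls, r, L, a, b))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "L", "a", "b"])


def generate_nir_spectra(
    config: StudyConfig,
    rng: np.random.Generator,
    latent_nir: np.ndarray | None = None,
) -> SpectralBlock:
    """NIR block: water-dominated base plus class-weighted absorption bands.

    Per-unit latent variation loads on the 1364/1450 nm bands; every scan
    gets its own multiplicative gain, additive offset and white noise, so
    multiplicative scatter correction has real work to do.
    """
    meta_units = _unit_meta(config)
    if latent_nir is None:
        latent_nir = rng.normal(size=config.n_units)
    wl = config.wavelengths
    base = _water_base(wl)
    shapes = _band_shapes(wl)
    class_amp = config.nir_class_scale * (_CLASS_CONTRASTS.T @ _BAND_LOADINGS)
    rows, meta_rows = [], []
    for u, unit in meta_units.iterrows():
        c = config.class_names.index(unit["class_label"])
        amp = class_amp[c] + config.nir_latent_scale * _BAND_LATENT * latent_nir[u]
        clean = base + amp @ shapes
        for scan in range(1, config.nir_scans_per_replicate + 1):
            gain = rng.uniform(*config.nir_gain_range)
            offset = rng.uniform(*config.nir_offset_range)
            noise = rng.normal(0.0, config.nir_noise_sd, size=wl.size)
            rows.append(gain * clean + offset + noise)
            meta_rows.append(
                (unit["sample_id"], unit["class_label"], unit["replicate_id"], scan)
            )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "class_label", "replicate_id", "scan_index"]
    )
    return SpectralBlock(wl, np.vstack(rows), meta)


def generate_etongue_with_drift(
    config: StudyConfig,
    rng: np.random.Generator,
    latent_et: np.ndarray | None = None,
) -> tuple[SensorBlock, np.ndarray, np.ndarray]:
    """E-tongue block with additive per-session drift.

    The same drift vector is added to every observation of a session, which
    is exactly the structure the additive correction removes.  Only the
    identifiable part of session drift matters (an offset common to every
    session is indistinguishable from signal), so the drift vectors are
    centred across sessions and the measurement noise is centred within
    each session; the additive correction then recovers the drift-free
    matrix exactly.  Returns (block, drift matrix, drift-free matrix).
    """
    meta_units = _unit_meta(config)
    if latent_et is None:
        latent_et = rng.normal(size=config.n_units)
    centers = _etongue_centers(config, rng)
    # latent direction orthogonal to the class-centre geometry, so unit-level
    # chemistry variation does not blur the class separation
    span = centers - centers.mean(axis=0)
    latent_dir = _orthogonal_complement(span[1:], rng.normal(size=7))
    latent_dir *= config.etongue_latent_scale
    drift = rng.normal(0.0, config.etongue_drift_sd, size=(config.etongue_sessions, 7))
    drift -= drift.mean(axis=0)
    class_idx = [config.class_names.index(c) for c in meta_units["class_label"]]
    structural = centers[class_idx] + np.outer(latent_et, latent_dir)
    rows, clean_rows, meta_rows = [], [], []
    for session in range(1, config.etongue_sessions + 1):
        noise = rng.normal(0.0, config.etongue_noise_sd, size=(config.n_units, 7))
        noise -= noise.mean(axis=0)
        clean = structural + noise
        clean_rows.append(clean)
        rows.append(clean + drift[session - 1])
        for _, unit in meta_units.iterrows():
            meta_rows.append(
                (unit["sample_id"], unit["class_label"], unit["replicate_id"], session)
            )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "class_label", "replicate_id", "session_id"]
    )
    block = SensorBlock(list(ETONGUE_SENSORS), np.vstack(rows), meta)
    return block, drift, np.vstack(clean_rows)


def _enose_sensor_ids(config: StudyConfig, rng: np.random.Generator) -> list[str]:
    ids = list(NAMED_ENOSE_SENSORS)[: config.enose_n_sensors]
    while len(ids) < config.enose_n_sensors:
        ki = rng.uniform(400.0, 1600.0)
        column = rng.choice(["1A", "2A"])
        candidate = f"{ki:.2f}-{column}"
        if candidate not in ids:
            ids.append(candidate)
    return ids


def generate_enose(
    config: StudyConfig,
    rng: np.random.Generator,
    latent_en: np.ndarray | None = None,
) -> tuple[SensorBlock, list[str]]:
    """E-nose block: one row per preparation unit (method 4 protocol).

    The first ``enose_n_informative`` sensors carry class-dependent signal
    with linearly graded strength (so their Fisher ratios are graded); the
    remaining sensors are pure noise.
    """
    meta_units = _unit_meta(config)
    if latent_en is None:
        latent_en = rng.normal(size=config.n_units)
    ids = _enose_sensor_ids(config, rng)
    k = config.enose_n_informative
    grades = 1.0 - 0.6 * np.arange(k) / max(k - 1, 1)
    pattern = rng.normal(size=(config.n_classes, k))  # class signature per sensor
    strength = config.enose_signal_scale * grades
    # latent loading orthogonal to the class signatures (see e-tongue)
    latent_load = _orthogonal_complement(
        pattern * strength, rng.normal(size=k)
    ) * config.enose_latent_scale * np.sqrt(k)
    rows = np.empty((config.n_units, config.enose_n_sensors))
    for u, unit in meta_units.iterrows():
        c = config.class_names.index(unit["class_label"])
        informative = strength * pattern[c] + latent_load * latent_en[u]
        noise = rng.normal(0.0, config.enose_noise_sd, size=config.enose_n_sensors)
        rows[u] = 50.0 + noise
        rows[u, :k] += informative
    meta = meta_units.copy()
    meta["session_id"] = 1
    block = SensorBlock(ids, rows, meta)
    return block, ids[:k]


def generate_sensory(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long sensory table: published sample means + additive assessor
    effects + panel noise, truncated to the 0–100 scale."""
    rows = []
    for attr in reference.SENSORY_ATTRIBUTES:
        means, sds = reference.SENSORY_SUMMARY[attr]
        assessor_effect = rng.normal(
            0.0, config.assessor_sd, size=config.sensory_panellists
        )
        for p in range(1, config.sensory_panellists + 1):
            for session in range(1, config.sensory_sessions + 1):
                for cls, mu, sd in zip(config.class_names, means, sds):
                    score = mu + assessor_effect[p - 1] + rng.normal(0.0, sd)
                    rows.append((p, session, cls, attr, float(np.clip(score, 0.0, 100.0))))
    return pd.DataFrame(
        rows, columns=["panellist", "session", "sample", "attribute", "score"]
    )


def _attribute_class_means(config: StudyConfig) -> pd.DataFrame:
    """Class-level target values: the published sensory means plus the five
    colour parameters (ΔC, Δh taken relative to the pooled mean colour)."""
    data = {}
    for attr in reference.SENSORY_ATTRIBUTES:
        data[attr] = list(reference.SENSORY_SUMMARY[attr][0])
    lab = reference.colour_means_array()
    chroma = np.hypot(lab[:, 1], lab[:, 2])
    hue = np.degrees(np.arctan2(lab[:, 2], lab[:, 1])) % 360.0
    data["L*"] = lab[:, 0].tolist()
    data["a*"] = lab[:, 1].tolist()
    data["b*"] = lab[:, 2].tolist()
    data["delta_C"] = np.abs(chroma - chroma.mean()).tolist()
    data["delta_h"] = np.abs(hue - hue.mean()).tolist()
    return pd.DataFrame(data, index=list(config.class_names))


def _attribute_targets(
    config: StudyConfig, rng: np.random.Generator, latent: np.ndarray,
    unit_meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    class_means = _attribute_class_means(config)
    weights = {}
    values = {}
    for attr in ALL_ATTRIBUTES:
        mu = class_means[attr].to_numpy()
        spread = np.std(mu, ddof=1)
        w = rng.uniform(0.65, 1.0, size=3) * rng.choice([-1.0, 1.0], size=3)
        w /= np.linalg.norm(w)
        weights[attr] = w
        unit_mu = np.array(
            [mu[list(config.class_names).index(c)] for c in unit_meta["class_label"]]
        )
        noise = rng.normal(0.0, config.attribute_noise_frac * spread, size=config.n_units)
        values[attr] = (
            unit_mu + config.attribute_latent_frac * spread * (latent @ w) + noise
        )
    weights_df = pd.DataFrame(weights, index=["nir", "etongue", "enose"]).T
    values_df = pd.DataFrame(values)
    values_df.insert(0, "sample_id", unit_meta["sample_id"].to_numpy())
    values_df.insert(1, "replicate_id", unit_meta["replicate_id"].to_numpy())
    return values_df, weights_df, class_means


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study, all blocks plus ground truth."""
    config = config or StudyConfig()
    rngs = _spawn(seed, 7)
    (rng_latent, rng_colour, rng_nir, rng_et, rng_en, rng_sens, rng_attr) = rngs
    unit_meta = _unit_meta(config)
    latent = rng_latent.normal(size=(config.n_units, 3))

    colour = generate_colour(config, rng_colour)
    nir = generate_nir_spectra(config, rng_nir, latent[:, 0])
    etongue, drift, drift_free = generate_etongue_with_drift(
        config, rng_et, latent[:, 1]
    )
    enose, informative = generate_enose(config, rng_en, latent[:, 2])
    sensory = generate_sensory(config, rng_sens)
    values, weights, class_means = _attribute_targets(
        config, rng_attr, latent, unit_meta
    )
    truth = GroundTruth(
        unit_meta=unit_meta,
        latent=latent,
        attribute_values=values,
        attribute_weights=weights,
        attribute_class_means=class_means,
        etongue_drift=drift,
        etongue_drift_free=drift_free,
        informative_sensors=list(informative),
        nir_band_centers=_NIR_BAND_CENTERS.copy(),
    )
    return SyntheticStudy(
        config=config, seed=seed, colour=colour, nir=nir,
        etongue=etongue, enose=enose, sensory=sensory, truth=truth,
    )
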