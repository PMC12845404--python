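"""Seeded synthetic-data generators with known ground truth.

The county-year generator emulates the structure of the study dataset
(22 districts/counties x 5 growing seasons, monthly April--October values of
5 Sentinel-2 bands, 11 FLDAS environmental variables and 2 vegetation
indices, plus planting area and a kg/mu yield label) without any external
download.  Every channel follows a smooth seasonal bump with per-record
random amplitude and per-county phase; the yield is a *documented linear
function* of the per-channel seasonal means plus planting area and Gaussian
noise, so parameter-recovery tests have a closed-form least-squares oracle:

    yield = intercept + sum_c w_c * mean_t(channel_c) + w_area * area + eps,
    eps ~ N(0, noise_sd^2).

Scenario and image-tensor generators provide ground-truthed fixtures for the
proportional-correction and detection-block modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import CorrectionScenario, GroundSample
from .features import (CHANNELS, MONTHS, N_CHANNELS, N_MONTHS,
                       FeatureSequenceRecord)

# per-channel (base level, seasonal amplitude) in native units
_CHANNEL_SHAPE = {
    "B2": (0.05, 0.02), "B4": (0.08, 0.04), "B8": (0.25, 0.15),
    "B11": (0.20, 0.06), "B12": (0.15, 0.05),
    "Evap_tavg": (2.0, 2.0), "LWdown_f_tavg": (300.0, 40.0),
    "Psurf_f_tavg": (85.0, 1.0), "Rainf_f_tavg": (1.5, 2.0),
    "SoilMoi00_10cm_tavg": (0.22, 0.10), "SoilMoi10_40cm_tavg": (0.25, 0.08),
    "SoilTemp00_10cm_tavg": (285.0, 12.0), "SoilTemp10_40cm_tavg": (284.0, 10.0),
    "SWdown_f_tavg": (220.0, 60.0), "Tair_f_tavg": (283.0, 12.0),
    "Wind_f_tavg": (2.5, 1.0),
    "NDVI": (0.30, 0.45), "EVI": (0.25, 0.40),
}

# default linear effect of each channel's seasonal mean on yield (kg/mu per
# native unit); vegetation indices dominate, soil/weather contribute, and
# every channel carries some signal so all 18 are exercised
_DEFAULT_WEIGHTS = {
    "B2": -150.0, "B4": -250.0, "B8": 300.0, "B11": -180.0, "B12": -120.0,
    "Evap_tavg": 12.0, "LWdown_f_tavg": 0.8, "Psurf_f_tavg": 5.0,
    "Rainf_f_tavg": 18.0, "SoilMoi00_10cm_tavg": 250.0,
    "SoilMoi10_40cm_tavg": 180.0, "SoilTemp00_10cm_tavg": 2.0,
    "SoilTemp10_40cm_tavg": 1.5, "SWdown_f_tavg": 0.5, "Tair_f_tavg": 3.0,
    "Wind_f_tavg": -15.0,
    "NDVI": 2500.0, "EVI": 1200.0,
}
_DEFAULT_INTERCEPT = -3540.0  # chosen so yields land around 1000-1500 kg/mu
_DEFAULT_AREA_WEIGHT = 0.002  # kg/mu per mu of county planting area


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_counties: int = 22
    years: tuple = (2019, 2020, 2021, 2022, 2023)
    months: tuple = tuple(MONTHS)
    seed: int = 0
    noise_sd: float = 10.0  # kg/mu; ~5% of the deterministic yield sd
    effect_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    intercept: float = _DEFAULT_INTERCEPT
    area_weight: float = _DEFAULT_AREA_WEIGHT

    def validate(self):
        if self.n_counties < 2:
            raise SyntheticConfigError("need at least 2 counties")
        if len(self.months) < 2:
            raise SyntheticConfigError("need at least 2 months")
        if tuple(self.months) != tuple(MONTHS):
            raise SyntheticConfigError("month grid must be April..October")
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be non-negative")
        if set(self.effect_weights) != set(CHANNELS):
            raise SyntheticConfigError("effect_weights must cover all channels")


@dataclass
class GroundTruth:
    """Recomputable generative truth for a generated dataset."""

    intercept: float
    effect_weights: dict
    area_weight: float
    noise: np.ndarray  # per-record yield noise draws, generation order

    def true_yield(self, record: FeatureSequenceRecord) -> float:
        """Deterministic (noise-free) yield implied by a record's features."""
        means = record.temporal.mean(axis=0)
        y = self.intercept + self.area_weight * record.planting_area
        for ci, ch in enumerate(CHANNELS):
            y += self.effect_weights[ch] * means[ci]
        return float(y)


def _seasonal_bump(phase: float) -> np.ndarray:
    """Smooth one-peak growing-season shape over the month grid, in [0, 1]."""
    t = (np.arange(N_MONTHS) + 0.5) / N_MONTHS
    return np.sin(np.pi * np.clip(t - phase, 0.0, 1.0)) ** 2


def generate_county_dataset(cfg: SyntheticConfig
                            ) -> tuple[list[FeatureSequenceRecord], GroundTruth]:
    """One record per (county, year), reproducible bit-for-bit per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ndvi_i, evi_i = CHANNELS.index("NDVI"), CHANNELS.index("EVI")

    county_phase = rng.uniform(-0.08, 0.08, size=(cfg.n_counties, N_CHANNELS))
    county_area = rng.uniform(20_000.0, 80_000.0, size=cfg.n_counties)
    # counties differ systematically in canopy vigor (vegetation amplitude)
    county_vigor = rng.uniform(0.8, 1.2, size=cfg.n_counties)

    records, noises = [], []
    for county in range(cfg.n_counties):
        for year in cfg.years:
            amp_scale = rng.uniform(0.5, 1.5, size=N_CHANNELS)
            amp_scale[ndvi_i] *= county_vigor[county]
            amp_scale[evi_i] *= county_vigor[county]
            temporal = np.empty((N_MONTHS, N_CHANNELS))
            for ci, ch in enumerate(CHANNELS):
                base, amp = _CHANNEL_SHAPE[ch]
                bump = _seasonal_bump(county_phase[county, ci])
                temporal[:, ci] = base + amp * amp_scale[ci] * bump
            # indices stay within their physical ranges by construction
            temporal[:, ndvi_i] = np.clip(temporal[:, ndvi_i], -1.0, 1.0)
            area = float(county_area[county] * rng.uniform(0.95, 1.05))
            # the unit draw is always consumed so that datasets with
            # different noise_sd share identical features per seed
            eps = float(rng.normal(0.0, 1.0)) * cfg.noise_sd
            rec = FeatureSequenceRecord(county=county, year=year,
                                        planting_area=area, temporal=temporal,
                                        yield_label=0.0)
            truth = GroundTruth(cfg.intercept, cfg.effect_weights,
                                cfg.area_weight, np.empty(0))
            rec.yield_label = truth.true_yield(rec) + eps
            records.append(rec)
            noises.append(eps)
    gt = GroundTruth(cfg.intercept, dict(cfg.effect_weights), cfg.area_weight,
                     np.asarray(noises))
    return records, gt


def generate_correction_scenario(seed: int, bias: float) -> CorrectionScenario:
    """A ground-sampled orchard whose model predictions carry a uniform
    multiplicative bias: predicted = true / bias for both the sampling area
    and the whole orchard, so exact proportional correction recovers truth."""
    if not bias > 0:
        raise ValueError("bias must be positive")
    rng = np.random.default_rng(seed)
    true_orchard = float(rng.uniform(1200.0, 1800.0))
    true_sample = float(true_orchard * rng.uniform(0.9, 1.1))

    # build an integer-count ground sample consistent with true_sample
    n_trees = 30
    weight = 0.25  # kg per fruit, empirical
    counts = rng.integers(80, 160, size=n_trees)
    area = float(counts.sum() * weight / true_sample)  # mu
    sample = GroundSample(fruit_counts=counts.tolist(),
                          single_fruit_weight=weight, sampling_area=area)

    return CorrectionScenario(
        y_pre_sample=true_sample / bias,
        y_true_sample=true_sample,
        y_pre=true_orchard / bias,
        true_orchard_yield=true_orchard,
        ground_sample=sample,
    )


def generate_feature_maps(batch: int, channels: int, height: int, width: int,
                          seed: int) -> np.ndarray:
    """Standard-normal image-feature tensor [B, C, H, W], seeded."""
    for d in (batch, channels, height, width):
        if d < 1:
            raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((batch, channels, height, width))
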