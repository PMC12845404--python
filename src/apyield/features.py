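"""Feature-sequence assembly and dataset splitting.

A county-year sample couples three *statistical* features (county code, year
code, planting area in mu) with a ``[7 months x 18 channels]`` temporal block
spanning the April--October growing season.  Channel order is fixed:

* 5 Sentinel-2 surface-reflectance bands: B2, B4, B8, B11, B12
* 11 FLDAS environmental variables (evapotranspiration, radiation fluxes,
  surface pressure, precipitation rate, soil moisture/temperature at two
  depths, air temperature, wind speed)
* 2 vegetation indices: NDVI, EVI

Monthly values are median composites over all valid within-month
observations.  Yields are kg/mu (1 mu ~= 666.67 m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPECTRAL_CHANNELS = ["B2", "B4", "B8", "B11", "B12"]
ENV_CHANNELS = [
    "Evap_tavg", "LWdown_f_tavg", "Psurf_f_tavg", "Rainf_f_tavg",
    "SoilMoi00_10cm_tavg", "SoilMoi10_40cm_tavg",
    "SoilTemp00_10cm_tavg", "SoilTemp10_40cm_tavg",
    "SWdown_f_tavg", "Tair_f_tavg", "Wind_f_tavg",
]
VI_CHANNELS = ["NDVI", "EVI"]
CHANNELS = SPECTRAL_CHANNELS + ENV_CHANNELS + VI_CHANNELS
MONTHS = [4, 5, 6, 7, 8, 9, 10]  # April..October
N_MONTHS = len(MONTHS)
N_CHANNELS = len(CHANNELS)
GROUP_SLICES = {  # channel grouping used by the regression network
    "spectral": slice(0, 5),
    "environmental": slice(5, 16),
    "vegetation": slice(16, 18),
}


class MissingDataError(ValueError):
    pass


class UndefinedIndexError(ValueError):
    """A vegetation-index denominator vanished; the record must be flagged."""


@dataclass
class FeatureSequenceRecord:
    """One county-year sample."""

    county: int
    year: int
    planting_area: float  # mu, > 0
    temporal: np.ndarray  # [N_MONTHS, N_CHANNELS]
    yield_label: float | None = None  # kg/mu; None for prediction-only
    source: str = "orig"  # provenance tag: orig|noise|mixup|tvae

    def __post_init__(self):
        self.temporal = np.asarray(self.temporal, dtype=float)
        if self.temporal.shape != (N_MONTHS, N_CHANNELS):
            raise ValueError(
                f"temporal block must be {(N_MONTHS, N_CHANNELS)}, "
                f"got {self.temporal.shape}")
        if not self.planting_area > 0:
            raise ValueError("planting_area must be positive")
        ndvi = self.temporal[:, CHANNELS.index("NDVI")]
        if np.any(np.abs(ndvi) > 1 + 1e-9):
            raise ValueError("NDVI outside [-1, 1]")

    def copy(self, **changes) -> "FeatureSequenceRecord":
        out = replace(self, **changes)
        if "temporal" not in changes:
            out.temporal = self.temporal.copy()
        return out


@dataclass
class SplitResult:
    train_ids: list
    val_ids: list
    test_ids: list

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split ids must be pairwise disjoint")


@dataclass
class CodeBook:
    """Dense integer ids assigned in first-seen order (persistable)."""

    codes: dict = field(default_factory=dict)

    def encode(self, key) -> int:
        if key not in self.codes:
            self.codes[key] = len(self.codes)
        return self.codes[key]

    def lookup(self, key) -> int:
        return self.codes[key]

    def __len__(self):
        return len(self.codes)


# ---------------------------------------------------------------------------
# operations

def median_composite(values, valid=None) -> float:
    """Monthly median composite over the valid observations.

    Even counts use the mean of the two central values. Raises
    :class:`MissingDataError` when no valid observation remains.
    """
    arr = np.asarray(values, dtype=float)
    if valid is None:
        mask = np.isfinite(arr)
    else:
        mask = np.asarray(valid, dtype=bool) & np.isfinite(arr)
    kept = arr[mask]
    if kept.size == 0:
        raise MissingDataError("no valid observation in compositing window")
    return float(np.median(kept))


def compute_vi(b2: float, b4: float, b8: float) -> tuple[float, float]:
    """NDVI and EVI from blue/red/NIR surface reflectance.

    NDVI = (B8-B4)/(B8+B4); EVI = 2.5*(B8-B4)/(B8 + 6*B4 - 7.5*B2 + 1).
    """
    for v in (b2, b4, b8):
        if not np.isfinite(v):
            raise UndefinedIndexError("non-finite reflectance")
    den_ndvi = b8 + b4
    if den_ndvi == 0:
        raise UndefinedIndexError("NDVI denominator is zero")
    ndvi = (b8 - b4) / den_ndvi
    den_evi = b8 + 6.0 * b4 - 7.5 * b2 + 1.0
    if den_evi == 0:
        raise UndefinedIndexError("EVI denominator is zero")
    evi = 2.5 * (b8 - b4) / den_evi
    return float(ndvi), float(evi)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_counts(n: int) -> tuple[int, int, int]:
    """8:1:1 image-set split: val = test = round-half-up(n/10), train = rest."""
    if n < 10:
        raise ValueError("need n >= 10 for an 8:1:1 split")
    val = _round_half_up(n / 10)
    test = val
    return n - val - test, val, test


def temporal_split(records, test_year: int, seed: int = 0,
                   train_frac: float = 0.8) -> SplitResult:
    """Hold out one calendar year; shuffle the rest 8:2 into train/val."""
    test_ids = [i for i, r in enumerate(records) if r.year == test_year]
    rest = [i for i, r in enumerate(records) if r.year != test_year]
    if not test_ids:
        raise ValueError(f"no records in test year {test_year}")
    if len(rest) < 5:
        raise ValueError("too few records outside the test year")
    rng = np.random.default_rng(seed)
    rest = list(np.array(rest)[rng.permutation(len(rest))])
    n_train = _round_half_up(train_frac * len(rest))
    return SplitResult(train_ids=[int(i) for i in rest[:n_train]],
                       val_ids=[int(i) for i in rest[n_train:]],
                       test_ids=test_ids)


# ---------------------------------------------------------------------------
# CSV schema (long form): one row per (county, year, month)

def records_to_frames(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long feature table + per-(county, year) label table."""
    feat_rows, label_rows = [], []
    for r in records:
        for mi, month in enumerate(MONTHS):
            row = {"county": r.county, "year": r.year, "month": month}
            row.update({ch: r.temporal[mi, ci] for ci, ch in enumerate(CHANNELS)})
            feat_rows.append(row)
        label_rows.append({
            "county": r.county, "year": r.year,
            "planting_area_mu": r.planting_area,
            "yield_kg_per_mu": r.yield_label if r.yield_label is not None else np.nan,
            "source_stage": r.source,
        })
    return pd.DataFrame(feat_rows), pd.DataFrame(label_rows)


def frames_to_records(features: pd.DataFrame,
                      labels: pd.DataFrame) -> list[FeatureSequenceRecord]:
    """Inverse of :func:`records_to_frames`; missing months are an error."""
    out = []
    feat_g = features.groupby(["county", "year"], sort=False)
    for _, lab in labels.iterrows():
        key = (lab["county"], lab["year"])
        try:
            block = feat_g.get_group(key)
        except KeyError:
            raise MissingDataError(f"no feature rows for county-year {key}")
        block = block.set_index("month")
        if sorted(block.index) != MONTHS:
            raise MissingDataError(f"incomplete months for county-year {key}")
        temporal = block.loc[MONTHS, CHANNELS].to_numpy(dtype=float)
        y = lab["yield_kg_per_mu"]
        out.append(FeatureSequenceRecord(
            county=int(lab["county"]), year=int(lab["year"]),
            planting_area=float(lab["planting_area_mu"]),
            temporal=temporal,
            yield_label=None if pd.isna(y) else float(y),
            source=str(lab.get("source_stage", "orig"))))
    return out


def write_dataset(records, features_path, labels_path):
    feats, labels = records_to_frames(records)
    feats.to_csv(features_path, index=False)
    labels.to_csv(labels_path, index=False)


def read_dataset(features_path, labels_path) -> list[FeatureSequenceRecord]:
    return frames_to_records(pd.read_csv(features_path), pd.read_csv(labels_path))
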