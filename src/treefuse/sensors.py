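"""Tabular preprocessing for per-tree sensor and biometric records.

Raw records arrive as a CSV keyed by tree ID with continuous environmental
channels (soil moisture, temperature, humidity, gas concentrations, AQI),
continuous biometrics (height, canopy width, crown density, bark damage,
leaf colour deviation, root exposure) and categorical metadata (species,
urban zone).  The pipeline imputes missing values (mean / mode), one-hot
encodes categoricals, z-scores continuous features and regression targets
with statistics fit on the training split only, aligns records to images by
tree ID, and splits 80/20 with class stratification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "SensorSchema",
    "StandardizationStats",
    "default_schema",
    "impute_missing",
    "one_hot_encode",
    "fit_standardization",
    "apply_standardization",
    "invert_target_standardization",
    "encode_features",
    "align_by_tree_id",
    "stratified_split",
]

CONTINUOUS_SENSOR_COLUMNS = [
    "Soil_Moisture_%",
    "Ambient_Temperature_C",
    "Humidity_%",
    "CO2_ppm",
    "PM2.5_ug_m3",
    "NO2_ppb",
    "O3_ppb",
    "Air_Quality_Index",
]

BIOMETRIC_COLUMNS = [
    "height_m",
    "canopy_width_m",
    "crown_density",
    "bark_damage_score",
    "leaf_color_deviation",
    "root_exposure_score",
]

SPECIES = [
    "Platanus orientalis",
    "Acer negundo",
    "Fraxinus pennsylvanica",
    "Morus alba",
    "Ulmus pumila",
    "Populus alba",
    "Ailanthus altissima",
    "Robinia pseudoacacia",
    "Tilia cordata",
    "Salix babylonica",
    "Elaeagnus angustifolia",
    "Juglans regia",
]

URBAN_ZONES = ["residential", "park", "roadside", "industrial"]


@dataclass(frozen=True)
class SensorSchema:
    """Column layout of the sensor table.

    ``continuous_columns`` and the categorical column set must be disjoint;
    the encoded feature width is ``len(continuous) + sum(len(vocab))``.
    """

    continuous_columns: tuple[str, ...]
    categorical_columns: dict[str, tuple[str, ...]]
    id_column: str = "tree_id"

    def __post_init__(self):
        overlap = set(self.continuous_columns) & set(self.categorical_columns)
        if overlap:
            raise ValueError(f"columns both continuous and categorical: {overlap}")
        for name, vocab in self.categorical_columns.items():
            if len(vocab) == 0:
                raise ValueError(f"empty vocabulary for {name!r}")

    @property
    def encoded_width(self) -> int:
        return len(self.continuous_columns) + sum(
            len(v) for v in self.categorical_columns.values())

    @property
    def feature_columns(self) -> list[str]:
        return list(self.continuous_columns) + list(self.categorical_columns)


def default_schema() -> SensorSchema:
    """Reference schema: 8 sensor channels + 6 biometrics + species + zone.

    Encoded width 14 + 12 + 4 = 30.  Contextual metadata (coordinates,
    planting year, road proximity) is deliberately not part of the model
    feature set.
    """
    return SensorSchema(
        continuous_columns=tuple(CONTINUOUS_SENSOR_COLUMNS + BIOMETRIC_COLUMNS),
        categorical_columns={
            "species": tuple(SPECIES),
            "urban_zone": tuple(URBAN_ZONES),
        },
    )


@dataclass
class StandardizationStats:
    """Per-column z-score statistics, fit on the training split only.

    Standard deviations use the population convention (divide by n) so the
    fit set has exactly unit variance.  Target statistics cover the two gas
    regression targets.
    """

    feature_mean: dict[str, float]
    feature_sd: dict[str, float]
    target_mean: dict[str, float]
    target_sd: dict[str, float]

    def __post_init__(self):
        for name, sd in {**self.feature_sd, **self.target_sd}.items():
            if not sd > 0:
                raise ValueError(f"standard deviation for {name!r} must be > 0")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StandardizationStats":
        with open(path) as fh:
            return cls(**json.load(fh))


def impute_missing(table: pd.DataFrame, schema: SensorSchema) -> pd.DataFrame:
    """Fill missing continuous values with the column mean of observed
    values and missing categoricals with the most frequent category.

    A column with no observed value at all is a hard error, as is a schema
    column absent from the table.
    """
    out = table.copy()
    for col in schema.continuous_columns:
        if col not in out.columns:
            raise KeyError(f"missing required column {col!r}")
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.notna().sum() == 0:
            raise ValueError(f"column {col!r} is entirely missing")
        out[col] = vals.fillna(vals.mean())
    for col in schema.categorical_columns:
        if col not in out.columns:
            raise KeyError(f"missing required column {col!r}")
        vals = out[col]
        if vals.notna().sum() == 0:
            raise ValueError(f"column {col!r} is entirely missing")
        mode = vals.mode(dropna=True).iloc[0]
        out[col] = vals.fillna(mode)
    return out


def one_hot_encode(table: pd.DataFrame, schema: SensorSchema,
                   allow_unknown: bool = False) -> np.ndarray:
    """Encode the categorical columns as concatenated indicator blocks.

    Each categorical expands to a block of length ``len(vocabulary)`` with
    exactly one 1.  Out-of-vocabulary values raise under the default strict
    policy; with ``allow_unknown=True`` they produce an all-zeros block.
    """
    blocks = []
    for col, vocab in schema.categorical_columns.items():
        index = {v: i for i, v in enumerate(vocab)}
        block = np.zeros((len(table), len(vocab)), dtype=np.float64)
        for row, value in enumerate(table[col].to_numpy()):
            if value in index:
                block[row, index[value]] = 1.0
            elif not allow_unknown:
                raise ValueError(
                    f"value {value!r} not in vocabulary of {col!r}")
        blocks.append(block)
    return np.concatenate(blocks, axis=1) if blocks else np.zeros((len(table), 0))


def fit_standardization(train_table: pd.DataFrame, schema: SensorSchema,
                        target_columns=("O2_rate", "CO2_rate"),
                        drop_zero_variance: bool = False) -> StandardizationStats:
    """Fit z-score statistics on the training split.

    Zero-variance continuous columns are a hard error in strict mode; with
    ``drop_zero_variance=True`` they are excluded from the statistics (and
    thus from the encoded features) instead.
    """
    fmean, fsd = {}, {}
    for col in schema.continuous_columns:
        vals = train_table[col].to_numpy(dtype=np.float64)
        sd = float(vals.std())  # population convention
        if sd == 0.0:
            if drop_zero_variance:
                continue
            raise ValueError(f"column {col!r} has zero variance on the fit set")
        fmean[col] = float(vals.mean())
        fsd[col] = sd
    tmean, tsd = {}, {}
    for col in target_columns:
        if col not in train_table.columns:
            continue
        vals = train_table[col].to_numpy(dtype=np.float64)
        sd = float(vals.std())
        if sd == 0.0:
            raise ValueError(f"target {col!r} has zero variance on the fit set")
        tmean[col] = float(vals.mean())
        tsd[col] = sd
    return StandardizationStats(fmean, fsd, tmean, tsd)


def apply_standardization(table: pd.DataFrame,
                          stats: StandardizationStats) -> pd.DataFrame:
    """z-score every column covered by ``stats`` (features and targets)."""
    out = table.copy()
    for col, m in stats.feature_mean.items():
        out[col] = (out[col].to_numpy(dtype=np.float64) - m) / stats.feature_sd[col]
    for col, m in stats.target_mean.items():
        if col in out.columns:
            out[col] = (out[col].to_numpy(dtype=np.float64) - m) / stats.target_sd[col]
    return out


def invert_target_standardization(values: np.ndarray, target: str,
                                  stats: StandardizationStats) -> np.ndarray:
    """Map z-scored gas predictions back to original units."""
    return np.asarray(values) * stats.target_sd[target] + stats.target_mean[target]


def encode_features(table: pd.DataFrame, schema: SensorSchema,
                    stats: StandardizationStats,
                    allow_unknown: bool = False) -> np.ndarray:
    """Standardized continuous block followed by one-hot categorical blocks.

    The result has ``schema.encoded_width`` columns (fewer only if zero-
    variance columns were dropped at fit time) and no missing entries.
    """
    cont_cols = [c for c in schema.continuous_columns if c in stats.feature_mean]
    cont = np.stack([
        (table[c].to_numpy(dtype=np.float64) - stats.feature_mean[c])
        / stats.feature_sd[c]
        for c in cont_cols
    ], axis=1) if cont_cols else np.zeros((len(table), 0))
    cats = one_hot_encode(table, schema, allow_unknown=allow_unknown)
    return np.concatenate([cont, cats], axis=1)


def align_by_tree_id(image_manifest: pd.DataFrame, sensor_table: pd.DataFrame,
                     id_column: str = "tree_id"):
    """Pair images and sensor rows on tree ID.

    Returns ``(paired, dropped_ids)`` where ``paired`` is the inner join and
    ``dropped_ids`` is a sorted list of IDs present in only one source.
    Duplicate IDs within either source are a hard error.
    """
    for name, df in (("image manifest", image_manifest),
                     ("sensor table", sensor_table)):
        dup = df[id_column][df[id_column].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate tree IDs in {name}: {sorted(set(dup))}")
    img_ids = set(image_manifest[id_column])
    sen_ids = set(sensor_table[id_column])
    dropped = sorted(img_ids.symmetric_difference(sen_ids))
    paired = image_manifest.merge(sensor_table, on=id_column, how="inner")
    return paired, dropped


def stratified_split(table: pd.DataFrame, label_column: str = "health_class",
                     test_fraction: float = 0.2, seed: int = 0):
    """Deterministic stratified train/test partition.

    Per-class test counts match ``round(test_fraction * class_count)`` to
    within one sample.  Every class must have at least two members.
    """
    counts = table[label_column].value_counts()
    if (counts < 2).any():
        small = sorted(counts[counts < 2].index)
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    train_idx, test_idx = train_test_split(
        np.arange(len(table)), test_size=test_fraction,
        stratify=table[label_column].to_numpy(), random_state=seed)
    return (table.iloc[np.sort(train_idx)].reset_index(drop=True),
            table.iloc[np.sort(test_idx)].reset_index(drop=True))
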