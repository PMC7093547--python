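"""Per-recording feature battery for AHI estimation.

Each cleaned channel is summarised by four families of descriptors:

* time-domain moments of the amplitude histogram (M1t–M4t),
* spectral measures inside the channel's OSA-related band — amplitude
  moments M1f–M4f, Shannon spectral entropy SE, median frequency MF,
  Wootters distance WD, amplitude extrema MA/mA and relative power PR,
* non-linear measures — sample entropy, central tendency measure and
  Lempel–Ziv complexity,
* conventional clinical indices — ODI3/ODI4, minimum saturation, CT90
  for oximetry and the respiratory disturbance index RDI for airflow.

The default registry keeps 21 oximetry features and 17 airflow features
(38 for the dual-channel set).  Average saturation equals M1t of the
cleaned SpO2 trace and is therefore not listed twice; the airflow mean
M1t is essentially zero after high-pass-free zero-phase filtering of a
zero-mean oscillation and is likewise dropped from the default airflow
registry.  Both registries are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nonlinear, spectral
from ._stats import four_moments
from .events import (
    detect_airflow_events,
    detect_desaturations,
    oximetric_indices,
    respiratory_disturbance_index,
)
from .signals import AirflowSignal, OximetrySignal, Recording

__all__ = [
    "DEFAULT_SPO2_FEATURES",
    "DEFAULT_AF_FEATURES",
    "FeatureTable",
    "time_moments",
    "spo2_features",
    "airflow_features",
    "extract_features",
    "build_feature_table",
]

DEFAULT_SPO2_FEATURES: tuple[str, ...] = (
    "M1t", "M2t", "M3t", "M4t",
    "M1f", "M2f", "M3f", "M4f",
    "SE", "MF", "WD", "MA", "mA", "PR",
    "SampEn", "CTM", "LZC",
    "ODI3", "ODI4", "Sat_MIN", "CT90",
)

DEFAULT_AF_FEATURES: tuple[str, ...] = (
    "M2t", "M3t", "M4t",
    "M1f", "M2f", "M3f", "M4f",
    "SE", "MF", "WD", "MA", "mA", "PR",
    "SampEn", "CTM", "LZC",
    "RDI",
)

TARGET_COLUMN = "reference_ahi"

#: epoch length for epoch-averaged sample entropy, seconds
SAMPEN_EPOCH_S = 1200.0
#: CTM radius for oximetry, in %SpO2
CTM_RHO_SPO2 = 1.0
#: CTM radius for airflow, as a fraction of the series SD
CTM_RHO_AF_SD_FRACTION = 0.25


def time_moments(x: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Mean, unbiased variance, skewness, kurtosis (+ degenerate flag)."""
    return four_moments(x)


def _spectral_block(x: np.ndarray, fs: float, band: spectral.SpectralBand) -> dict[str, float]:
    psd = spectral.estimate_psd(x, fs)
    out = spectral.band_stats(psd, band)
    out["SE"] = spectral.spectral_entropy(psd, band)
    out["MF"] = spectral.median_frequency(psd, band)
    out["WD"] = spectral.wootters_distance(psd, band)
    return out


def spo2_features(spo2: OximetrySignal) -> dict[str, float]:
    """The full oximetry feature family of one cleaned recording."""
    x = spo2.valid_samples()
    m1, m2, m3, m4, _ = four_moments(x)
    feats = {"M1t": m1, "M2t": m2, "M3t": m3, "M4t": m4}
    feats.update(_spectral_block(x, spo2.fs, spectral.SPO2_BAND))
    feats["SampEn"] = nonlinear.sample_entropy(
        x, m=1, fs=spo2.fs, epoch_seconds=SAMPEN_EPOCH_S
    )
    feats["CTM"] = nonlinear.central_tendency_measure(x, rho=CTM_RHO_SPO2)
    feats["LZC"] = nonlinear.lempel_ziv_complexity(x)
    desats3 = detect_desaturations(spo2, drop_pct=3.0)
    desats4 = detect_desaturations(spo2, drop_pct=4.0)
    indices = oximetric_indices(spo2, desats3, desats4)
    feats.update(indices)
    feats["Sat_AVG"] = indices["Sat_AVG"]  # alias of M1t up to masking
    return feats


def airflow_features(af: AirflowSignal) -> dict[str, float]:
    """The full airflow feature family of one cleaned recording."""
    x = af.valid_samples()
    m1, m2, m3, m4, _ = four_moments(x)
    feats = {"M1t": m1, "M2t": m2, "M3t": m3, "M4t": m4}
    feats.update(_spectral_block(x, af.fs, spectral.AIRFLOW_BAND))
    sd = float(np.std(x, ddof=1))
    feats["SampEn"] = nonlinear.sample_entropy(
        x, m=1, fs=af.fs, epoch_seconds=SAMPEN_EPOCH_S
    )
    feats["CTM"] = nonlinear.central_tendency_measure(
        x, rho=CTM_RHO_AF_SD_FRACTION * sd if sd > 0 else 1.0
    )
    feats["LZC"] = nonlinear.lempel_ziv_complexity(x)
    events = detect_airflow_events(af)
    feats["RDI"] = respiratory_disturbance_index(events, af.valid_seconds / 3600.0)
    return feats


def extract_features(
    rec: Recording,
    spo2_registry: tuple[str, ...] = DEFAULT_SPO2_FEATURES,
    af_registry: tuple[str, ...] = DEFAULT_AF_FEATURES,
) -> dict[str, float]:
    """One named feature row for a cleaned recording.

    Column names are channel-prefixed (``spo2_``/``af_``).  Raises if
    any requested feature is undefined (NaN) — such rows must not reach
    selection or regression.
    """
    if not (rec.spo2.processed and rec.airflow.processed):
        raise ValueError(
            f"recording {rec.id} has not been preprocessed; "
            "run preprocess_recording first"
        )
    row: dict[str, float] = {}
    if spo2_registry:
        values = spo2_features(rec.spo2)
        for name in spo2_registry:
            row[f"spo2_{name}"] = values[name]
    if af_registry:
        values = airflow_features(rec.airflow)
        for name in af_registry:
            row[f"af_{name}"] = values[name]
    bad = [k for k, v in row.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"undefined features for recording {rec.id}: {bad}")
    return row


@dataclass
class FeatureTable:
    """Per-recording feature rows plus the reference AHI target.

    Backed by a DataFrame whose last column is ``reference_ahi``; the
    index holds recording identifiers.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if TARGET_COLUMN not in self.df.columns:
            raise ValueError(f"missing {TARGET_COLUMN} column")
        feats = self.df.drop(columns=[TARGET_COLUMN])
        if feats.isna().any().any():
            raise ValueError("missing values in feature rows")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c != TARGET_COLUMN]

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.df[TARGET_COLUMN]

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.df[list(columns) + [TARGET_COLUMN]].copy())

    def rows(self, index) -> "FeatureTable":
        return FeatureTable(self.df.iloc[index].copy())


def build_feature_table(
    records: list[Recording],
    spo2_registry: tuple[str, ...] = DEFAULT_SPO2_FEATURES,
    af_registry: tuple[str, ...] = DEFAULT_AF_FEATURES,
) -> FeatureTable:
    """Extract features for a cohort of cleaned recordings."""
    rows = {}
    for rec in records:
        row = extract_features(rec, spo2_registry, af_registry)
        row[TARGET_COLUMN] = np.nan if rec.reference_ahi is None else rec.reference_ahi
        rows[rec.id] = row
    return FeatureTable(pd.DataFrame.from_dict(rows, orient="index"))
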