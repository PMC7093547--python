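"""Reading and writing the pipeline's on-disk formats.

Signals travel as per-channel wide CSV (one value per line, a one-line
``# fs=<Hz>`` header) tied together by a small JSON manifest per
recording, or as EDF (European Data Format) for real recordings.  The
EDF reader is deliberately minimal — plain header parsing plus int16
record decoding — because each channel must keep its native sampling
rate (oximetry and nasal pressure are digitised at very different
rates, and resampling to a common grid at read time would corrupt the
preprocessing contracts).  Channel discovery in EDF uses configurable
label regexes to absorb vendor naming variance.

Feature tables and event annotations are plain CSV round-tripped
through pandas.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_AF_FEATURES,
    DEFAULT_SPO2_FEATURES,
    TARGET_COLUMN,
    FeatureTable,
)
from .signals import (
    AirflowSignal,
    EventKind,
    OximetrySignal,
    Recording,
    RespiratoryEvent,
    RespiratoryEventSet,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
    "write_events",
    "read_events",
    "read_edf_channels",
    "SPO2_LABEL_PATTERN",
    "AIRFLOW_LABEL_PATTERN",
]

SPO2_LABEL_PATTERN = r"SpO2|SaO2"
AIRFLOW_LABEL_PATTERN = r"Flow|Pres|Cannula"


# ---------------------------------------------------------------- CSV signals

def _write_channel_csv(path: Path, samples: np.ndarray, fs: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        np.savetxt(fh, samples, fmt="%.6g")


def _read_channel_csv(path: Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().strip()
        m = re.match(r"#\s*fs=([0-9.eE+-]+)", header)
        if not m:
            raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
        fs = float(m.group(1))
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return samples, fs


def write_recording(rec: Recording, directory) -> Path:
    """Write a recording as two channel CSVs plus a JSON manifest.

    Samples invalidated by preprocessing are written as NaN and become
    the invalid mask again on read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spo2_file = f"{rec.id}_spo2.csv"
    af_file = f"{rec.id}_airflow.csv"
    spo2_out = np.where(rec.spo2.valid_mask, rec.spo2.samples, np.nan)
    af_out = np.where(rec.airflow.valid_mask, rec.airflow.samples, np.nan)
    _write_channel_csv(directory / spo2_file, spo2_out, rec.spo2.fs)
    _write_channel_csv(directory / af_file, af_out, rec.airflow.fs)
    manifest = {
        "id": rec.id,
        "spo2": spo2_file,
        "airflow": af_file,
        "reference_ahi": rec.reference_ahi,
        "trt_seconds": rec.trt_seconds,
        "processed": {"spo2": rec.spo2.processed, "airflow": rec.airflow.processed},
    }
    path = directory / f"{rec.id}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def _read_recording_csv(manifest_path: Path) -> Recording:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    spo2_samples, spo2_fs = _read_channel_csv(base / manifest["spo2"])
    af_samples, af_fs = _read_channel_csv(base / manifest["airflow"])
    processed = manifest.get("processed", {})
    spo2 = OximetrySignal(
        samples=np.nan_to_num(spo2_samples, nan=100.0),
        fs=spo2_fs,
        valid_mask=np.isfinite(spo2_samples),
        processed=bool(processed.get("spo2", False)),
    )
    airflow = AirflowSignal(
        samples=np.nan_to_num(af_samples, nan=0.0),
        fs=af_fs,
        valid_mask=np.isfinite(af_samples),
        processed=bool(processed.get("airflow", False)),
    )
    return Recording(
        id=manifest["id"],
        spo2=spo2,
        airflow=airflow,
        reference_ahi=manifest.get("reference_ahi"),
        trt_seconds=manifest.get("trt_seconds"),
    )


# ------------------------------------------------------------------ EDF input

def _ascii(buf: bytes) -> str:
    return buf.decode("ascii", errors="replace").strip()


def read_edf_channels(path) -> dict[str, tuple[np.ndarray, float]]:
    """Parse an EDF file into ``{label: (physical_samples, fs)}``.

    Handles the standard continuous EDF layout: 256-byte fixed header,
    per-signal header arrays, then int16 data records scaled to
    physical units per channel.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(_ascii(fixed[236:244]))
        record_s = float(_ascii(fixed[244:252]))
        n_sig = int(_ascii(fixed[252:256]))
        if n_sig < 1 or record_s <= 0:
            raise ValueError(f"{path}: malformed EDF header")

        def _field(width: int) -> list[str]:
            raw = fh.read(width * n_sig)
            return [_ascii(raw[i * width : (i + 1) * width]) for i in range(n_sig)]

        labels = _field(16)
        _field(80)  # transducer
        _field(8)  # physical dimension
        phys_min = [float(v) for v in _field(8)]
        phys_max = [float(v) for v in _field(8)]
        dig_min = [int(v) for v in _field(8)]
        dig_max = [int(v) for v in _field(8)]
        _field(80)  # prefiltering
        spr = [int(v) for v in _field(8)]  # samples per record
        _field(32)  # reserved

        payload = np.frombuffer(fh.read(), dtype="<i2")
    per_record = sum(spr)
    if n_records < 0:  # unknown length: infer from payload
        n_records = payload.size // per_record
    payload = payload[: n_records * per_record].reshape(n_records, per_record)
    out: dict[str, tuple[np.ndarray, float]] = {}
    offset = 0
    for i, label in enumerate(labels):
        block = payload[:, offset : offset + spr[i]].reshape(-1).astype(float)
        offset += spr[i]
        dig_span = dig_max[i] - dig_min[i]
        if dig_span != 0:
            scale = (phys_max[i] - phys_min[i]) / dig_span
            block = phys_min[i] + (block - dig_min[i]) * scale
        out[label] = (block, spr[i] / record_s)
    return out


def _read_recording_edf(
    path: Path,
    spo2_pattern: str = SPO2_LABEL_PATTERN,
    airflow_pattern: str = AIRFLOW_LABEL_PATTERN,
) -> Recording:
    channels = read_edf_channels(path)

    def _find(pattern: str, what: str) -> tuple[np.ndarray, float]:
        for label, data in channels.items():
            if re.search(pattern, label, flags=re.IGNORECASE):
                return data
        raise ValueError(
            f"{path}: no channel matching {what} pattern {pattern!r} "
            f"(labels: {sorted(channels)})"
        )

    spo2_samples, spo2_fs = _find(spo2_pattern, "SpO2")
    af_samples, af_fs = _find(airflow_pattern, "airflow")
    return Recording(
        id=path.stem,
        spo2=OximetrySignal(samples=spo2_samples, fs=spo2_fs),
        airflow=AirflowSignal(samples=af_samples, fs=af_fs),
    )


def read_recording(path, format: str | None = None, **kwargs) -> Recording:
    """Load a recording from a CSV manifest or an EDF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        return _read_recording_edf(path, **kwargs)
    raise ValueError(f"unknown format: {format}")


# ------------------------------------------------------------- feature tables

def _canonical_columns() -> set[str]:
    base_spo2 = set(DEFAULT_SPO2_FEATURES) | {"M1t", "Sat_AVG"}
    base_af = set(DEFAULT_AF_FEATURES) | {"M1t"}
    cols = {f"spo2_{name}" for name in base_spo2}
    cols |= {f"af_{name}" for name in base_af}
    cols.add(TARGET_COLUMN)
    return cols


def write_feature_table(table: FeatureTable, path) -> None:
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.df.to_csv(path, index_label="id")


def read_feature_table(path, allowed_columns: set[str] | None = None) -> FeatureTable:
    """Read a feature CSV, rejecting unknown columns.

    ``allowed_columns`` defaults to the canonical channel-prefixed
    feature vocabulary plus the reference-AHI target.
    """
    df = pd.read_csv(path, index_col="id")
    allowed = allowed_columns if allowed_columns is not None else _canonical_columns()
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ValueError(f"{path}: unknown feature columns {unknown}")
    return FeatureTable(df)


# ---------------------------------------------------------- event annotations

def write_events(events: RespiratoryEventSet, path) -> None:
    rows = [
        {
            "kind": ev.kind.value,
            "onset_s": ev.onset_s,
            "duration_s": ev.duration_s,
            "depth": ev.depth,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["kind", "onset_s", "duration_s", "depth"]).to_csv(
        path, index=False
    )


def read_events(path) -> RespiratoryEventSet:
    df = pd.read_csv(path)
    return RespiratoryEventSet(
        RespiratoryEvent(
            kind=EventKind(row.kind),
            onset_s=float(row.onset_s),
            duration_s=float(row.duration_s),
            depth=float(row.depth),
        )
        for row in df.itertuples()
    )
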