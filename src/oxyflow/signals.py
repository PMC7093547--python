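"""Core domain types for dual-channel sleep-apnoea screening.

Two channels drive the whole pipeline: arterial oxygen saturation from
pulse oximetry (SpO2, percent) and airflow from a nasal prong pressure
transducer (arbitrary units).  Both are modelled as uniformly sampled
series with a per-sample validity mask so that preprocessing can
invalidate artefactual stretches without re-indexing time.

Severity grading follows the conventional apnoea–hypopnoea index (AHI)
cut-offs of 5, 15 and 30 events/h.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "UniformSignal",
    "OximetrySignal",
    "AirflowSignal",
    "Recording",
    "EventKind",
    "RespiratoryEvent",
    "RespiratoryEventSet",
    "SeverityClass",
    "SEVERITY_THRESHOLDS",
    "severity_of",
    "severity_labels",
    "split_train_test",
]

#: AHI thresholds (events/h) separating No-OSA / mild / moderate / severe.
SEVERITY_THRESHOLDS = (5.0, 15.0, 30.0)


class SeverityClass(enum.IntEnum):
    """Four-class OSA severity grade derived from the AHI."""

    NO_OSA = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return _SEVERITY_LABELS[int(self)]


_SEVERITY_LABELS = ("No-OSA", "mild", "moderate", "severe")


def severity_labels() -> tuple[str, ...]:
    """Canonical ordering of the four severity class labels."""
    return _SEVERITY_LABELS


def severity_of(ahi: float) -> SeverityClass:
    """Grade an AHI (events/h) on the half-open bins [0,5), [5,15), [15,30), [30, inf).

    Raises ``ValueError`` for negative or non-finite input.
    """
    ahi = float(ahi)
    if not np.isfinite(ahi) or ahi < 0:
        raise ValueError(f"AHI must be finite and >= 0, got {ahi}")
    if ahi < SEVERITY_THRESHOLDS[0]:
        return SeverityClass.NO_OSA
    if ahi < SEVERITY_THRESHOLDS[1]:
        return SeverityClass.MILD
    if ahi < SEVERITY_THRESHOLDS[2]:
        return SeverityClass.MODERATE
    return SeverityClass.SEVERE


@dataclass
class UniformSignal:
    """A uniformly sampled channel with per-sample validity flags.

    Parameters
    ----------
    samples : array of float
        Channel values (units depend on the subclass).
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Offset of the first sample from the recording start, seconds.
    valid_mask : bool array or None
        Per-sample validity.  ``None`` means all samples valid.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    valid_mask: np.ndarray | None = None
    #: set by the preprocessing stage so filtering is applied only once
    processed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.samples.shape:
                raise ValueError("valid_mask must match samples in shape")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Nominal recorded span, seconds."""
        return self.samples.size / self.fs

    @property
    def valid_seconds(self) -> float:
        """Time covered by samples still marked valid, seconds."""
        return float(np.count_nonzero(self.valid_mask)) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from the recording start."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def valid_samples(self) -> np.ndarray:
        return self.samples[self.valid_mask]

    def copy(self) -> "UniformSignal":
        return replace(
            self, samples=self.samples.copy(), valid_mask=self.valid_mask.copy()
        )


@dataclass
class OximetrySignal(UniformSignal):
    """SpO2 series in percent saturation (physiological range 50–100 after cleaning)."""


@dataclass
class AirflowSignal(UniformSignal):
    """Nasal-prong-pressure airflow in arbitrary units."""


class EventKind(enum.Enum):
    APNEA = "apnoea"
    HYPOPNEA = "hypopnoea"
    DESATURATION = "desaturation"


#: apnoeas/hypopnoeas must last at least this long (AASM scoring convention)
MIN_RESPIRATORY_EVENT_S = 10.0


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored interval on one channel.

    ``depth`` is the percent SpO2 drop for desaturations and the
    fractional airflow amplitude reduction (0–1) for apnoeas/hypopnoeas.
    Intervals are half-open: ``[onset_s, onset_s + duration_s)``.
    """

    kind: EventKind
    onset_s: float
    duration_s: float
    depth: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if (
            self.kind in (EventKind.APNEA, EventKind.HYPOPNEA)
            and self.duration_s < MIN_RESPIRATORY_EVENT_S
        ):
            raise ValueError(
                f"{self.kind.value} events must last >= {MIN_RESPIRATORY_EVENT_S} s"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


class RespiratoryEventSet:
    """Ordered collection of respiratory/desaturation events."""

    def __init__(self, events: Iterable[RespiratoryEvent] = ()) -> None:
        self.events: list[RespiratoryEvent] = sorted(events, key=lambda e: e.onset_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[RespiratoryEvent]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def of_kind(self, *kinds: EventKind) -> "RespiratoryEventSet":
        return RespiratoryEventSet(e for e in self.events if e.kind in kinds)

    @property
    def n_respiratory(self) -> int:
        """Apnoeas plus hypopnoeas (the AHI numerator)."""
        return sum(
            1 for e in self.events if e.kind in (EventKind.APNEA, EventKind.HYPOPNEA)
        )


@dataclass
class Recording:
    """One night: both channels plus the reference AHI label when known."""

    id: str
    spo2: OximetrySignal
    airflow: AirflowSignal
    reference_ahi: float | None = None
    trt_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.trt_seconds is None:
            self.trt_seconds = max(self.spo2.duration_s, self.airflow.duration_s)
        if not self.trt_seconds > 0:
            raise ValueError("trt_seconds must be > 0")
        if self.reference_ahi is not None and self.reference_ahi < 0:
            raise ValueError("reference_ahi must be >= 0 when present")


def split_train_test(
    records: Sequence, train_fraction: float
) -> tuple[list, list]:
    """Chronological split: the first ``floor(n * train_fraction)`` items train.

    No shuffling — mirrors a prospective design where the first consecutive
    patients form the training set and the remainder the held-out test set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    records = list(records)
    if not records:
        raise ValueError("cannot split an empty record list")
    n_train = int(np.floor(len(records) * train_fraction))
    return records[:n_train], records[n_train:]
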