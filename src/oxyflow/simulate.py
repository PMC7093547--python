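"""Synthetic overnight polysomnography generator with scripted ground truth.

Each simulated night is a pair of signals driven by one shared list of
respiratory events:

* **Airflow** — a quasi-periodic breathing oscillation (~0.25 Hz) whose
  amplitude is multiplicatively reduced during each event: by at least
  90% for apnoeas and by 30–90% for hypopnoeas, with short cosine ramps
  at the event edges.
* **SpO2** — a ~94% baseline with slow drift, from which each event
  subtracts a desaturation pulse lagging the airflow reduction by
  15–30 s: a linear fall over the event span followed by an exponential
  resaturation.  Desaturation depth grows with event duration (longer
  obstructions desaturate deeper), is jittered, and lies in 3–12%.
  The output is quantised to 0.1% like a real oximeter.

Event onsets follow a renewal process scaled to tile the simulated
sleep period exactly, so the realised event count — and hence the
ground-truth AHI over sleep time — is exact by construction.  Note the
deliberate asymmetry reproduced from clinical practice: the true AHI is
defined over *sleep* time while all downstream indices divide by valid
*recording* time, so automated indices slightly underestimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signals import (
    AirflowSignal,
    EventKind,
    OximetrySignal,
    Recording,
    RespiratoryEvent,
    RespiratoryEventSet,
)

__all__ = [
    "SimulationConfig",
    "SimulatedRecording",
    "simulate_recording",
    "simulate_cohort",
    "inject_artifacts",
    "STUDY_SEVERITY_MIX",
]

#: severity-class prevalences of the reference clinical cohort
STUDY_SEVERITY_MIX = (0.063, 0.226, 0.234, 0.477)

#: AHI ranges (events/h) drawn uniformly within each severity class
SEVERITY_AHI_RANGES = ((0.0, 5.0), (5.0, 15.0), (15.0, 30.0), (30.0, 70.0))

MIN_EVENT_GAP_S = 5.0


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults emulate the target cohort."""

    target_ahi: float = 20.0
    trt_minutes: float = 450.0
    sleep_efficiency: float = 0.87
    apnoea_fraction: float = 0.2
    duration_median_s: float = 22.4
    duration_min_s: float = 10.0
    duration_max_s: float = 90.0
    duration_sigma: float = 0.4
    desat_lag_s: tuple[float, float] = (15.0, 30.0)
    desat_depth_pct: tuple[float, float] = (3.0, 12.0)
    baseline_spo2: float = 94.0
    breath_freq_hz: float = 0.25
    fs_spo2: float = 75.0
    fs_airflow: float = 250.0
    noise_sd: dict = field(default_factory=lambda: {"spo2": 0.2, "airflow": 0.05})
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sleep_efficiency <= 1:
            raise ValueError("sleep_efficiency must be in (0, 1]")
        if not 0 <= self.apnoea_fraction <= 1:
            raise ValueError("apnoea_fraction must be in [0, 1]")
        if self.duration_min_s < 10.0:
            raise ValueError("duration_min_s must be >= 10 s")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")

    @property
    def sleep_seconds(self) -> float:
        return self.trt_minutes * 60.0 * self.sleep_efficiency


@dataclass
class SimulatedRecording:
    """A generated night plus its scripted truth."""

    recording: Recording
    truth_events: RespiratoryEventSet
    true_ahi: float
    sleep_seconds: float


def _draw_durations(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated log-normal event durations with the configured median."""
    out = np.empty(n)
    mu = np.log(cfg.duration_median_s)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, cfg.duration_sigma, size=2 * (n - filled))
        keep = draw[(draw >= cfg.duration_min_s) & (draw <= cfg.duration_max_s)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _script_events(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[RespiratoryEvent], float, float]:
    """Draw event kinds, durations and onsets tiling the sleep period."""
    trt_s = cfg.trt_minutes * 60.0
    sleep_s = cfg.sleep_seconds
    sleep_start = 0.5 * (trt_s - sleep_s)
    n = int(round(cfg.target_ahi * sleep_s / 3600.0))
    if n == 0:
        return [], sleep_start, sleep_s
    durations = _draw_durations(cfg, n, rng)
    occupied = float(durations.sum()) + n * MIN_EVENT_GAP_S
    if occupied > 0.98 * sleep_s:
        mean_block = float(durations.mean()) + MIN_EVENT_GAP_S
        max_ahi = 0.98 * 3600.0 / mean_block
        raise ValueError(
            f"target AHI {cfg.target_ahi} infeasible: events cannot fit without "
            f"overlap (maximum feasible ~{max_ahi:.0f} events/h)"
        )
    free = sleep_s - occupied
    raw_gaps = rng.exponential(1.0, size=n + 1)
    gaps = MIN_EVENT_GAP_S + raw_gaps / raw_gaps.sum() * free
    gaps[0] -= MIN_EVENT_GAP_S  # no enforced gap before the first event
    is_apnoea = rng.random(n) < cfg.apnoea_fraction
    events = []
    cursor = sleep_start
    for i in range(n):
        cursor += gaps[i]
        kind = EventKind.APNEA if is_apnoea[i] else EventKind.HYPOPNEA
        depth = rng.uniform(0.9, 1.0) if is_apnoea[i] else rng.uniform(0.3, 0.9)
        events.append(
            RespiratoryEvent(
                kind=kind, onset_s=cursor, duration_s=float(durations[i]), depth=depth
            )
        )
        cursor += durations[i]
    return events, sleep_start, sleep_s


def _cosine_window(n: int, ramp: int) -> np.ndarray:
    """Unit plateau with half-cosine edges of ``ramp`` samples."""
    w = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        edge = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ramp)))
        w[:ramp] = edge
        w[-ramp:] = edge[::-1]
    return w


def _synth_airflow(cfg: SimulationConfig, events, rng: np.random.Generator) -> np.ndarray:
    fs = cfg.fs_airflow
    n = int(round(cfg.trt_minutes * 60.0 * fs))
    t = np.arange(n) / fs
    # breathing carrier with gentle phase and amplitude wander
    phase = 2.0 * np.pi * cfg.breath_freq_hz * t + 0.4 * np.sin(
        2.0 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi)
    )
    amplitude = 1.0 + 0.15 * np.sin(2.0 * np.pi * t / 900.0 + rng.uniform(0, 2 * np.pi))
    modulation = np.ones(n)
    ramp = int(round(2.0 * fs))
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        i1 = min(int(round(ev.end_s * fs)), n)
        if i1 <= i0:
            continue
        w = _cosine_window(i1 - i0, ramp)
        modulation[i0:i1] *= 1.0 - ev.depth * w
    x = amplitude * modulation * np.sin(phase)
    x += rng.normal(0.0, cfg.noise_sd.get("airflow", 0.05), size=n)
    return x


def _desat_pulse(duration_s: float, depth: float, fs: float, tau_s: float = 15.0) -> np.ndarray:
    """Linear fall over the event span, exponential resaturation after it."""
    n_fall = max(int(round(duration_s * fs)), 1)
    n_rec = int(round(3.0 * tau_s * fs))
    fall = np.linspace(0.0, depth, n_fall)
    rec = depth * np.exp(-np.arange(n_rec) / (tau_s * fs))
    return np.concatenate([fall, rec])


def _synth_spo2(cfg: SimulationConfig, events, rng: np.random.Generator) -> np.ndarray:
    fs = cfg.fs_spo2
    n = int(round(cfg.trt_minutes * 60.0 * fs))
    t = np.arange(n) / fs
    lo, hi = cfg.desat_depth_pct
    span = cfg.duration_max_s - cfg.duration_min_s
    x = cfg.baseline_spo2 + 0.4 * np.sin(
        2.0 * np.pi * t / 3600.0 + rng.uniform(0, 2 * np.pi)
    )
    for ev in events:
        lag = rng.uniform(*cfg.desat_lag_s)
        frac = (ev.duration_s - cfg.duration_min_s) / span
        depth = float(np.clip(lo + frac * (hi - lo) + rng.normal(0.0, 0.5), lo, hi))
        pulse = _desat_pulse(ev.duration_s, depth, fs)
        i0 = int(round((ev.onset_s + lag) * fs))
        i1 = min(i0 + pulse.size, n)
        if i1 <= i0:
            continue
        x[i0:i1] -= pulse[: i1 - i0]
    x += rng.normal(0.0, cfg.noise_sd.get("spo2", 0.2), size=n)
    return np.round(np.clip(x, 0.0, 100.0), 1)


def simulate_recording(cfg: SimulationConfig, rec_id: str = "sim") -> SimulatedRecording:
    """Generate one night of paired SpO2/airflow with scripted events."""
    rng = np.random.default_rng(cfg.seed)
    events, _, sleep_s = _script_events(cfg, rng)
    airflow = _synth_airflow(cfg, events, rng)
    spo2 = _synth_spo2(cfg, events, rng)
    truth = RespiratoryEventSet(events)
    true_ahi = 3600.0 * truth.n_respiratory / sleep_s
    rec = Recording(
        id=rec_id,
        spo2=OximetrySignal(samples=spo2, fs=cfg.fs_spo2),
        airflow=AirflowSignal(samples=airflow, fs=cfg.fs_airflow),
        reference_ahi=true_ahi,
        trt_seconds=cfg.trt_minutes * 60.0,
    )
    return SimulatedRecording(
        recording=rec, truth_events=truth, true_ahi=true_ahi, sleep_seconds=sleep_s
    )


def _draw_target_ahi(ahi_law, rng: np.random.Generator) -> float:
    """Sample a target AHI from a distribution spec.

    Supported specs: a number (constant), ``("uniform", lo, hi)``, or
    ``("mixture", probs)`` with four class probabilities over the
    severity bins (class first, then uniform AHI within the bin).
    """
    if isinstance(ahi_law, (int, float)):
        return float(ahi_law)
    kind = ahi_law[0]
    if kind == "uniform":
        return float(rng.uniform(ahi_law[1], ahi_law[2]))
    if kind == "mixture":
        probs = np.asarray(ahi_law[1], dtype=float)
        if probs.size != 4 or probs.min() < 0:
            raise ValueError("mixture spec needs 4 non-negative class probabilities")
        probs = probs / probs.sum()
        cls = int(rng.choice(4, p=probs))
        lo, hi = SEVERITY_AHI_RANGES[cls]
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown AHI distribution spec: {ahi_law!r}")


def simulate_cohort(
    n: int,
    ahi_law=("mixture", STUDY_SEVERITY_MIX),
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> list[SimulatedRecording]:
    """Generate ``n`` independent nights with AHIs drawn from ``ahi_law``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = cfg if cfg is not None else SimulationConfig()
    master = np.random.SeedSequence(seed)
    law_rng = np.random.default_rng(master.spawn(1)[0])
    child_seeds = master.generate_state(n)
    out = []
    for i in range(n):
        target = _draw_target_ahi(ahi_law, law_rng)
        cfg_i = replace(base, target_ahi=target, seed=int(child_seeds[i] % (2**31)))
        out.append(simulate_recording(cfg_i, rec_id=f"sim-{i:04d}"))
    return out


def inject_artifacts(
    rec: Recording, kind: str, rate_per_hour: float, seed: int = 0
) -> tuple[Recording, list[dict]]:
    """Contaminate a recording with probe/sensor artefacts.

    ``spo2_spike``: excursions of <= 2 s to implausible values below 50%
    (movement artefact).  ``airflow_dropout``: 30–300 s flatline
    segments (sensor disconnection).  Returns the modified recording and
    the injected intervals as annotations.
    """
    if rate_per_hour < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    annotations: list[dict] = []
    spo2 = rec.spo2.copy()
    airflow = rec.airflow.copy()
    hours = rec.trt_seconds / 3600.0
    n_art = rng.poisson(rate_per_hour * hours)
    for _ in range(n_art):
        if kind == "spo2_spike":
            dur = rng.uniform(0.5, 2.0)
            onset = rng.uniform(0.0, max(rec.trt_seconds - dur, 0.0))
            i0 = int(round(onset * spo2.fs))
            i1 = min(i0 + max(int(round(dur * spo2.fs)), 1), spo2.samples.size)
            spo2.samples[i0:i1] = rng.uniform(20.0, 45.0)
        elif kind == "airflow_dropout":
            dur = rng.uniform(30.0, 300.0)
            onset = rng.uniform(0.0, max(rec.trt_seconds - dur, 0.0))
            i0 = int(round(onset * airflow.fs))
            i1 = min(i0 + max(int(round(dur * airflow.fs)), 1), airflow.samples.size)
            airflow.samples[i0:i1] = 0.0
        else:
            raise ValueError(f"unknown artifact kind: {kind}")
        annotations.append(
            {"kind": kind, "onset_s": float(onset), "duration_s": float(dur)}
        )
    out = Recording(
        id=rec.id,
        spo2=spo2,
        airflow=airflow,
        reference_ahi=rec.reference_ahi,
        trt_seconds=rec.trt_seconds,
    )
    return out, annotations
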