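"""Desaturation and airflow-event detection plus the conventional indices.

Oximetry: a desaturation is a fall of at least 3% (or 4%) below a
running baseline — the maximum saturation over the preceding two
minutes, frozen while an event is in progress — ending on recovery to
within 1% of that baseline.  The per-hour counts are the ODI3/ODI4.

Airflow: respiratory events are amplitude reductions of the breathing
envelope relative to a 120-s local reference amplitude (frozen during
events).  A drop below 70% of the reference lasting at least 10 s is an
event; if the envelope also spends 10 s below 10% it is scored as an
apnoea, otherwise as a hypopnoea.  The per-hour count is the RDI.

All per-hour indices divide by valid (post-cleaning) recording time,
not sleep time — the systematic source of slight underestimation of
sleep-time-based reference indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter1d

from .signals import (
    AirflowSignal,
    EventKind,
    OximetrySignal,
    RespiratoryEvent,
    RespiratoryEventSet,
)

__all__ = [
    "detect_desaturations",
    "oximetric_indices",
    "detect_airflow_events",
    "respiratory_disturbance_index",
]

BASELINE_WINDOW_S = 120.0
RECOVERY_MARGIN_PCT = 1.0
MIN_EVENT_S = 10.0
MERGE_GAP_S = 10.0

ENVELOPE_WINDOW_S = 10.0
APNEA_THRESHOLD = 0.10
HYPOPNEA_THRESHOLD = 0.70


@njit(cache=False)
def _desat_state_machine(
    x, valid, fs, drop, win_s, recovery_margin, min_dur_s
):  # pragma: no cover - exercised via detect_desaturations
    n = x.shape[0]
    win = int(round(win_s * fs))
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    depths = np.empty(n, dtype=np.float64)
    n_ev = 0
    in_event = False
    baseline = x[0]
    start = 0
    nadir = 0.0
    for i in range(n):
        if not valid[i]:
            if in_event:  # an artefact gap aborts the ongoing event
                in_event = False
            continue
        if not in_event:
            # running baseline: causal max over the previous window
            lo = i - win
            if lo < 0:
                lo = 0
            b = x[lo]
            for k in range(lo + 1, i + 1):
                if valid[k] and x[k] > b:
                    b = x[k]
            baseline = b
            if x[i] <= baseline - drop:
                in_event = True
                start = i
                nadir = x[i]
        else:
            if x[i] < nadir:
                nadir = x[i]
            if x[i] >= baseline - recovery_margin:
                if (i - start) / fs >= min_dur_s:
                    starts[n_ev] = start
                    ends[n_ev] = i
                    depths[n_ev] = baseline - nadir
                    n_ev += 1
                in_event = False
    if in_event and (n - start) / fs >= min_dur_s:
        starts[n_ev] = start
        ends[n_ev] = n
        depths[n_ev] = baseline - nadir
        n_ev += 1
    return starts[:n_ev], ends[:n_ev], depths[:n_ev]


def _merge_close(events: list[RespiratoryEvent], gap_s: float) -> list[RespiratoryEvent]:
    if not events:
        return events
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if ev.kind == prev.kind and ev.onset_s - prev.end_s < gap_s:
            merged[-1] = RespiratoryEvent(
                kind=prev.kind,
                onset_s=prev.onset_s,
                duration_s=ev.end_s - prev.onset_s,
                depth=max(prev.depth, ev.depth),
            )
        else:
            merged.append(ev)
    return merged


def detect_desaturations(spo2: OximetrySignal, drop_pct: float = 3.0) -> RespiratoryEventSet:
    """Detect oxygen desaturations of at least ``drop_pct`` percent."""
    if drop_pct <= 0:
        raise ValueError("drop_pct must be > 0")
    starts, ends, depths = _desat_state_machine(
        np.ascontiguousarray(spo2.samples, dtype=np.float64),
        np.ascontiguousarray(spo2.valid_mask),
        float(spo2.fs),
        float(drop_pct),
        BASELINE_WINDOW_S,
        RECOVERY_MARGIN_PCT,
        MIN_EVENT_S,
    )
    events = [
        RespiratoryEvent(
            kind=EventKind.DESATURATION,
            onset_s=spo2.t0 + s / spo2.fs,
            duration_s=(e - s) / spo2.fs,
            depth=d,
        )
        for s, e, d in zip(starts, ends, depths)
    ]
    return RespiratoryEventSet(_merge_close(events, MERGE_GAP_S))


def oximetric_indices(
    spo2: OximetrySignal,
    desats3: RespiratoryEventSet,
    desats4: RespiratoryEventSet,
) -> dict[str, float]:
    """ODI3/ODI4 (events per valid hour), Sat_MIN, Sat_AVG and CT90."""
    hours = spo2.valid_seconds / 3600.0
    if hours <= 0:
        raise ValueError("no valid SpO2 time")
    vals = spo2.valid_samples()
    return {
        "ODI3": len(desats3) / hours,
        "ODI4": len(desats4) / hours,
        "Sat_MIN": float(np.min(vals)),
        "Sat_AVG": float(np.mean(vals)),
        "CT90": 100.0 * float(np.count_nonzero(vals < 90.0)) / vals.size,
    }


@njit(cache=False)
def _airflow_state_machine(
    env, valid, fs, win_s, hypo_thr, apnea_thr, min_dur_s
):  # pragma: no cover - exercised via detect_airflow_events
    n = env.shape[0]
    win = int(round(win_s * fs))
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    kinds = np.empty(n, dtype=np.int64)  # 0 = apnoea, 1 = hypopnoea
    depths = np.empty(n, dtype=np.float64)
    n_ev = 0

    ring = np.empty(win, dtype=np.float64)
    # seed the reference with the opening two minutes
    seed = min(win, n)
    for i in range(seed):
        ring[i] = env[i]
    for i in range(seed, win):
        ring[i] = env[seed - 1]
    ring_sum = ring.sum()
    pos = 0

    in_event = False
    start = 0
    min_env = 0.0
    apnea_run = 0
    apnea_time = 0
    ref = ring_sum / win
    for i in range(n):
        if not valid[i]:
            if in_event:
                in_event = False
            continue
        ref = ring_sum / win
        if not in_event:
            if env[i] < hypo_thr * ref and ref > 0:
                in_event = True
                start = i
                min_env = env[i]
                apnea_run = 1 if env[i] < apnea_thr * ref else 0
                apnea_time = apnea_run
            else:
                ring_sum += env[i] - ring[pos]
                ring[pos] = env[i]
                pos = (pos + 1) % win
        else:
            if env[i] < min_env:
                min_env = env[i]
            if env[i] < apnea_thr * ref:
                apnea_run += 1
                if apnea_run > apnea_time:
                    apnea_time = apnea_run
            else:
                apnea_run = 0
            if env[i] >= hypo_thr * ref:
                dur = (i - start) / fs
                if dur >= min_dur_s:
                    starts[n_ev] = start
                    ends[n_ev] = i
                    kinds[n_ev] = 0 if apnea_time / fs >= min_dur_s else 1
                    depths[n_ev] = 1.0 - min_env / ref
                    n_ev += 1
                in_event = False
    if in_event and (n - start) / fs >= min_dur_s:
        starts[n_ev] = start
        ends[n_ev] = n
        kinds[n_ev] = 0 if apnea_time / fs >= min_dur_s else 1
        depths[n_ev] = 1.0 - min_env / ref
        n_ev += 1
    return starts[:n_ev], ends[:n_ev], kinds[:n_ev], depths[:n_ev]


def breathing_envelope(af: AirflowSignal, window_s: float = ENVELOPE_WINDOW_S) -> np.ndarray:
    """Moving amplitude envelope: sqrt(2) x RMS over a ~2-breath window."""
    x = af.samples - float(np.mean(af.samples[af.valid_mask]))
    win = max(int(round(window_s * af.fs)), 2)
    meansq = uniform_filter1d(x * x, size=win, mode="nearest")
    return np.sqrt(2.0 * np.maximum(meansq, 0.0))


def detect_airflow_events(af: AirflowSignal) -> RespiratoryEventSet:
    """Score apnoeas/hypopnoeas from airflow amplitude reductions."""
    env = breathing_envelope(af)
    starts, ends, kinds, depths = _airflow_state_machine(
        np.ascontiguousarray(env, dtype=np.float64),
        np.ascontiguousarray(af.valid_mask),
        float(af.fs),
        BASELINE_WINDOW_S,
        HYPOPNEA_THRESHOLD,
        APNEA_THRESHOLD,
        MIN_EVENT_S,
    )
    events = [
        RespiratoryEvent(
            kind=EventKind.APNEA if k == 0 else EventKind.HYPOPNEA,
            onset_s=af.t0 + s / af.fs,
            duration_s=(e - s) / af.fs,
            depth=min(max(d, 0.0), 1.0),
        )
        for s, e, k, d in zip(starts, ends, kinds, depths)
    ]
    return RespiratoryEventSet(events)


def respiratory_disturbance_index(events: RespiratoryEventSet, valid_hours: float) -> float:
    """Respiratory events per valid hour of airflow recording."""
    if valid_hours <= 0:
        raise ValueError("valid_hours must be > 0")
    return len(events) / valid_hours
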