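# Methods

Model, assumptions, parameter defaults and numerical choices behind
`oxyflow`. All defaults live in the named module constants quoted
here and can be overridden per call or via `PipelineConfig`.

## Problem model

A subject's overnight recording consists of two channels: blood oxygen
saturation (SpO₂, percent) and nasal-pressure airflow (arbitrary
units, zero-mean oscillation at the breathing frequency). The target
is the apnoea–hypopnoea index (AHI): respiratory events (apnoeas,
≥ 90 % airflow reduction; hypopnoeas, ≥ 30 % reduction with
desaturation) per hour of sleep, scored events lasting at least 10 s.
Severity classes are half-open bins of the AHI at 5, 15 and 30
events/h: No-OSA [0, 5), mild [5, 15), moderate [15, 30), severe
[30, ∞).

The estimator is regression-first: predict the continuous AHI, then
threshold the estimate for any categorical decision. This keeps a
single model consistent across the three clinical cut-offs.

## Preprocessing (`oxyflow.preprocess`)

- Analysis rates: SpO₂ 3 Hz (`SPO2_ANALYSIS_FS`), airflow 5 Hz
  (`AIRFLOW_ANALYSIS_FS`). Oximetric dynamics of interest live below
  ~0.05 Hz and respiratory dynamics below ~1 Hz, so these rates keep
  all usable content while shrinking native 75/250 Hz streams ~25–50×.
- Airflow is low-passed at 1.2 Hz with a 4th-order zero-phase
  Butterworth filter (`sosfiltfilt`) before decimation, suppressing
  cardiogenic and sensor noise without phase distortion.
- Resampling uses polyphase filtering (`scipy.signal.resample_poly`)
  with `padtype="line"`: SpO₂ sits on a large DC offset (~95 %), and
  the default zero padding would inject an edge transient that the
  desaturation detector scores as a night-long event.
- SpO₂ artifact rules: physiological range clip (values outside
  [50, 100] % invalid), transient deep drops (slope above 4 %/s
  bracketing an excursion shorter than 30 s) masked as probe
  artifacts, genuine desaturations (slower, longer) kept.
- Airflow artifact rules: flatlined windows (moving SD below 1 % of
  the global SD for ≥ 30 s) and rail saturation (≥ 5 s at the extreme
  value) invalidated.
- Recordings with less than 4 h of simultaneously valid signal
  (`MIN_VALID_HOURS`) are rejected — shorter nights make the per-hour
  AHI estimate unstable.

## Features (`oxyflow.features`)

38 defaults: 21 oximetry, 17 airflow, channel-prefixed (`spo2_`,
`af_`).

- Time-domain histogram moments M1t–M4t (mean, unbiased variance,
  skewness, kurtosis). Airflow M1t is excluded from the default
  registry (zero-mean by construction); average saturation equals
  SpO₂ M1t and is not listed twice.
- Spectral block inside the channel's OSA band — SpO₂ 0.014–0.033 Hz,
  airflow 0.025–0.050 Hz, i.e. the 30–70 s periodicity of recurrent
  events: amplitude moments M1f–M4f, Shannon spectral entropy SE,
  median frequency MF, Wootters distance WD between the normalised
  spectrum and the uniform one, band extrema MA/mA and relative band
  power PR. PSDs come from Welch's method with frequency resolution
  ≤ 1 mHz.
- Non-linear: sample entropy (m = 1, tolerance r = 0.25 × sample SD,
  averaged over 20-min epochs to bound the O(n²) template match and
  track non-stationarity), central tendency measure (radius 1 %SpO₂
  for oximetry, 0.25 × SD for airflow) and Lempel–Ziv complexity
  (median-binarised sequence, LZ76 phrase count normalised by
  n/log₂ n). SampEn and LZ76 inner loops are numba-compiled; both are
  property-tested against literal-definition oracles.
- Clinical indices: ODI3/ODI4 (desaturations ≥ 3 %/≥ 4 % per valid
  hour), minimum saturation, CT90 (fraction of time below 90 %) for
  SpO₂; respiratory disturbance index (RDI) for airflow.

Event detectors are explicit state machines: desaturation scoring
uses a 120 s moving baseline, ≥ 10 s below baseline − drop, recovery
within 1 % of baseline, events merged across gaps < 10 s; airflow
events use a 10 s RMS breathing envelope with apnoea/hypopnoea
thresholds at 10 %/70 % of the local baseline envelope.

## Feature selection (`oxyflow.selection`)

Fast correlation-based filter (FCBF) on features discretised by
Fayyad–Irani MDL partitioning against the severity class. Relevance
and redundancy are both measured by symmetrical uncertainty
SU(x, y) = 2·I(x; y)/(H(x) + H(y)). A feature is kept if no
already-kept feature predicts it better than it predicts the target.
Stability: FCBF runs on `B = 1000` bootstrap resamples of the
training set; features selected more often than the mean selection
count across all candidates form the final subset. Selection is
restricted to the channel set of each model variant.

## Regression (`oxyflow.regression`)

RBF support-vector regression (scikit-learn `SVR`) on standardised
features (train-set mean/SD). The grid is C ∈ {10⁻³ … 10⁴} (8
decades) × kernel width σ ∈ {10⁻² … 10³} ∪ {20, 50, 100, 150, 200,
250, 300, 500} (13 distinct values; γ = 1/(2σ²)), ε = 0.1.
Hyperparameters maximise ICC(2,1) between leave-one-out predictions
and the reference AHI on the training set — optimising agreement, not
squared error, because the downstream decisions are agreement-based.
Predictions are clamped at 0 (an AHI cannot be negative). Constant
features are dropped with a warning before standardisation.

## Evaluation (`oxyflow.evaluation`)

- ICC(2,1), two-way random effects, absolute agreement — verified
  against `pingouin` in the test suite.
- Bland–Altman bias and 95 % limits of agreement; folded-CDF
  ("mountain") curves.
- Four-class confusion matrix, Cohen's kappa, overall accuracy.
- Binary screening at each cut-off: Se, Sp, PPV, NPV, LR+, LR−,
  accuracy, AUC.
- Uncertainty: percentile bootstrap over test subjects (`B = 1000`
  default, minimum 100).
- Feasibility: the minimum LR+ for a 95 % post-test probability at
  the observed prevalence (`required_lr_plus`), and avoidable-PSG
  fractions for two triage protocols (`triage_fractions`):
  conservative sends everyone except predicted-severe to PSG;
  extended also trusts predicted-No-OSA discharges.

## Synthetic generator (`oxyflow.simulate`)

Scope: produce physiologically plausible dual-channel recordings with
known ground truth for end-to-end testing and parameter recovery —
not a patient-level digital twin.

- Night structure: total recording time 450 min, sleep efficiency
  0.87, the sleep period centred in the recording.
- Events: a renewal process tiles the sleep period exactly; the event
  count is `round(AHI × sleep_h)`, so the realised AHI matches the
  target up to rounding. Durations are lognormal (median 22.4 s,
  σ = 0.4) truncated to [10, 90] s; inter-event gaps ≥ 5 s; 20 %
  apnoeas (depth 0.9–1.0) vs hypopnoeas (0.3–0.9).
- Airflow: 0.25 Hz breathing carrier with slow amplitude modulation
  and phase jitter; each event multiplies the envelope by
  1 − depth with cosine-ramped edges.
- SpO₂: baseline 94 % minus one desaturation pulse per event, lagged
  15–30 s (circulatory delay), depth 3–12 % growing with event
  duration, exponential resaturation (τ = 15 s); quantised to 0.1 %
  like a real oximeter. Feasibility is checked: a target AHI whose
  events cannot fit the night raises.
- Optional artifact injection (`inject_artifacts`): probe spikes,
  sensor dropouts — used to test that cleaning recovers the
  uncorrupted indices.
- Cohort AHI laws: constant, uniform, or the severity mixture
  matching the benchmark test-set prevalences.
- Determinism: every stochastic step derives from a single integer
  seed (< 2³¹) through `numpy.random.default_rng`; identical configs
  give bit-identical recordings.

## Pipeline defaults (`oxyflow.pipeline`)

`PipelineConfig`: 160 recordings, chronological 60/40 train/test
split, severity-mixture AHI law, `selection_B = 1000`,
`eval_B = 1000`, three model variants (`spo2`, `airflow`, `dual`).
Simulated studies in the test suite shrink only the cohort size,
night length (never below the 4 h gate) and bootstrap counts; no
scientific parameter is altered for speed.

## Problem sizes and runtime

On one CPU: feature extraction ≈ 2.4 s per recording (SampEn and LZC
dominate; numba-compiled), 1000-replicate bootstrap FCBF on 100 × 21
features ≈ 13 s, the 104-point LOO grid search at n = 100 ≈ 13 s. A
full 160-recording study runs in about 8 minutes.
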