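# oxyflow

Dual-channel machine-learning screening of obstructive sleep apnoea
(OSA) from at-home recordings of blood oxygen saturation (SpO₂) and
nasal-pressure airflow.

## The problem

OSA severity is graded by the apnoea–hypopnoea index (AHI, respiratory
events per hour of sleep) measured with in-lab polysomnography (PSG),
an expensive and scarce test. `oxyflow` implements a screening
pipeline that estimates the AHI from just two channels that can be
recorded unattended at home, then grades patients into the four
standard severity classes (No-OSA < 5, mild 5–15, moderate 15–30,
severe ≥ 30 events/h) and evaluates how many confirmatory PSGs a
triage protocol based on those estimates could avoid.

## The pipeline

1. **Preprocessing** — resampling to analysis rates (SpO₂ 3 Hz,
   airflow 5 Hz after a 1.2 Hz zero-phase low-pass), artifact masking
   (out-of-range values, transient spikes, flatlined sensors) and a
   minimum-valid-duration gate.
2. **Feature extraction** — 38 features per recording (21 oximetry,
   17 airflow): histogram moments, in-band spectral descriptors
   (moments, Shannon entropy, median frequency, Wootters distance,
   relative power, extrema), non-linear measures (sample entropy,
   central tendency measure, Lempel–Ziv complexity) and clinical
   indices (ODI3/ODI4, minimum saturation, CT90, RDI).
3. **Feature selection** — fast correlation-based filter (FCBF) on
   MDL-discretised features, wrapped in a 1000-replicate bootstrap;
   features selected more often than the mean count are kept.
4. **Regression** — RBF support-vector regression of the AHI, with
   the hyperparameter grid tuned by leave-one-out cross-validation
   maximising the intraclass correlation coefficient ICC(2,1).
5. **Evaluation** — ICC with bootstrap CIs, Bland–Altman and mountain
   plots, four-class confusion/kappa/accuracy, binary screening
   metrics at the 5/15/30 events/h cut-offs, likelihood-ratio
   feasibility thresholds and avoidable-PSG triage fractions.

Three model variants are trained side by side: oximetry-only,
airflow-only and dual-channel (joint feature set).

Because raw clinical recordings cannot be redistributed, the package
includes a physiology-inspired synthetic PSG generator
(`oxyflow.simulate`): a renewal process of apnoeas/hypopnoeas with
lognormal durations, coupled lagged desaturation pulses on a quantised
SpO₂ channel and amplitude-modulated breathing on the airflow channel.
The generator provides ground-truth AHI for end-to-end parameter
recovery studies. Published benchmark confusion matrices from a
96-patient clinical validation are bundled (`oxyflow.reference`) so
the evaluation layer's headline statistics can be recomputed exactly.

## Worked example

```python
from oxyflow import PipelineConfig, SimulationConfig, run_screening_study

cfg = PipelineConfig(
    n_recordings=14,          # simulated cohort, chronological 60/40 split
    selection_B=25,           # bootstrap replicates for FCBF (1000 default)
    eval_B=100,               # bootstrap replicates for CIs
    seed=3,
    simulator=SimulationConfig(fs_spo2=3.0, fs_airflow=5.0, trt_minutes=270.0),
)
result = run_screening_study(cfg)
for name, info in result.models.items():
    print(name, round(info["test_icc"], 3), info["selected_features"])
```

Output (deterministic for the seed; about 45 s on one CPU):

```
spo2 0.965 ['spo2_CT90', 'spo2_CTM', 'spo2_SE']
airflow 0.991 ['af_CTM', 'af_M3f']
dual 0.99 ['af_CTM', 'spo2_CTM', 'af_M3f', 'af_M4f']
```

`result.report` holds the full evaluation block per model (ICC with
CI, Bland–Altman statistics, confusion matrix, kappa, binary screening
rows at each cut-off, avoidable-PSG fractions); `result.save(path)`
serialises everything to JSON.

The same pipeline is scriptable step by step from the command line:

```bash
oxyflow simulate --n 10 --seed 6 --out raw/
oxyflow preprocess raw/ --out clean/
oxyflow extract clean/ --out features.csv
oxyflow select features.csv --model dual -B 1000 --out selection.json
oxyflow train features.csv --selection selection.json --out model.json
oxyflow predict model.json features.csv --out preds.csv
oxyflow evaluate preds.csv --name dual --out report.json
```

`oxyflow run-all --seed 0 --out study.json` runs the whole study in
one shot; `--config config.yaml` overrides any `PipelineConfig` or
simulator field.

## Layout

- `src/oxyflow/` — the package (`preprocess`, `features`, `spectral`,
  `nonlinear`, `events`, `selection`, `regression`, `evaluation`,
  `simulate`, `pipeline`, `cli`, `io`, `reference`).
- `tests/` — unit, property-based and acceptance tests.
- `docs/methods.md` — model assumptions, parameter defaults and
  numerical choices.
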