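# relapsekit

Digital phenotyping of psychotic disorders from consumer wearables asks two
questions: do patients and healthy controls differ in long-term biosignal
statistics, and can a patient's own baseline flag an impending or ongoing
relapse? `relapsekit` implements the full computational pipeline for both,
for researchers who want to study, stress-test or extend the methodology
without access to a private clinical cohort:

* a **synthetic cohort generator** producing multi-day raw streams
  (triaxial accelerometer/gyroscope at 20 Hz, a 5 Hz RR-interval readout
  that repeats the latest beat, step counts, sleep diaries), relapse
  annotations with low/moderate/severe severities, and spectrogram-slice
  "interview sessions" — with controllable standardized group effects and
  relapse perturbation magnitudes;
* **preprocessing** of 5-min windows: readout de-duplication, RR range
  filtering to [300, 2000] ms, missed-pulse interpolation, 90%/270 s
  truncation, motion-window repair (>50 missing samples rejected,
  nearest-neighbour fill, first 5940 samples) and wavelet denoising, and
  288×10 day tensors with the 10-hour gap rule;
* **features**: short-time energy of the motion norm, Lomb–Scargle LF/HF
  band powers (percent of LF+HF) and ratio, sample entropy, Higuchi and
  multiscale morphological-cover fractal dimensions, Poincaré SD1/SD2,
  mean HR/RR, time-of-day encodings, daily steps and sleep/wake ratio;
* **group statistics**: 28 per-subject aggregates per state, two-tailed
  Mann–Whitney U tests with Benjamini–Hochberg FDR control, median (IQR)
  tables, Shapiro–Wilk-gated balance checks;
* **anomaly detection**: FNN / 1-D CNN / attention-GRU / transformer
  autoencoders over day-tensor sub-sequences, CAE/CVAE for 128×64 log-mel
  slices and a 1-D CVAE for 5×30 hourly HRV tensors (all on an in-package
  numpy autodiff engine), train-on-normal 5-fold protocol with
  Mahalanobis anomaly scores
  `a(i) = (e(i) − μ)ᵀ Σ⁻¹ (e(i) − μ)` fitted on held-out normal error
  vectors, KL-divergence probes, day averaging, ROC/PR-AUC evaluation,
  severity analysis, temporal pooling and additive/multiplicative fusion.

See `docs/methods.md` for the models, assumptions and parameter defaults.

## Worked example

Plant a +2.0 SD shift in activity-energy variability and a −1.5 SD shift
in short-term HRV (SD1) in the patient group, then ask the statistics
stage what it finds:

```python
from relapsekit.synthetic import CohortConfig
from relapsekit.pipeline import trait_summaries
from relapsekit.group_stats import group_comparison

cfg = CohortConfig(n_controls=15, n_patients=15, days_per_subject=1, seed=7,
                   effect_sizes={"ste_acc_std": 2.0, "sd1_mean": -1.5})
summaries = trait_summaries(cfg, n_awake=32, n_sleep=8)   # 28 aggregates/subject
table = group_comparison(summaries, state="awake")
print(table[table.p_adj < 0.05].to_string(index=False))
```

prints (columns abridged):

```
    feature  control_median  patient_median  p_raw  p_adj  significant
ste_acc_std          0.9046          1.3735 0.0012 0.0340         True
```

The planted activity-variability effect survives FDR control
(BH-adjusted p = 0.034 across the 28-feature family), while the milder
SD1 shift echoes sub-threshold through the correlated HRV features — with
28 tests and 15 subjects per group, a 1.5 SD single-feature effect is
near the detectability edge, which is exactly the behaviour the
calibration suite quantifies.

Detection side: simulate ten patients with 4-day moderate relapses at
anomaly magnitude 2.0, train personalized 1-D CNN autoencoders under the
5-fold train-on-normal protocol, and report median day-level AUCs:

```python
from relapsekit.synthetic import CohortConfig, RelapseSpec
from relapsekit.pipeline import cohort_day_records
from relapsekit.evaluation import run_experiment
from relapsekit.models import ModelConfig

cfg = CohortConfig(0, 10, 14, prodrome_days=2, seed=11,
                   relapses=[RelapseSpec(i, 10, 4, "moderate", anomaly_magnitude=2.0)
                             for i in range(10)])
days = cohort_day_records(cfg, stride=2)
res = run_experiment(days, scheme="personalized", architecture="cnn",
                     seed=5, input_hours=8,
                     model_config=ModelConfig(cnn_filters=(8, 16, 32, 64)))
print(res[["patient_id", "roc_auc", "pr_auc"]].tail(3).to_string(index=False))
```

```
patient_id  roc_auc  pr_auc
      P008   1.0000  1.0000
      P009   1.0000  1.0000
    MEDIAN   0.9375  0.9750
```

A median day-level ROC-AUC of 0.94 against the planted relapses; the same
run with `anomaly_magnitude=0.0` gives 0.50, confirming the scores carry
no spurious signal.

There is also a CLI for file-based runs:

```bash
relapsekit simulate --config cohort.yaml --out data/
relapsekit features --data data/ --out feat/ --mode full
relapsekit stats    --features feat/ --out stats/
relapsekit detect-eval --features feat/ --out det/ --architecture cnn
```

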