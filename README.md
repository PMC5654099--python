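# pafentropy

Screening for **paroxysmal atrial fibrillation (PAF)** from short
single-lead ECG records, using the multi-scale wavelet α-entropy of heart
rate variability (HRV).

PAF is intermittent: between episodes the ECG can look nearly normal, so
screening hinges on subtle beat-to-beat irregularity rather than overt
morphology. This package implements the full recognition chain:

1. **ECG conditioning** — zero-phase 5–15 Hz Butterworth band-pass;
2. **QRS detection** — Pan-Tompkins (derivative → squaring →
   moving-window integration → adaptive dual thresholds with search-back),
   with detections snapped back onto raw-signal R peaks;
3. **HRV extraction** — RR intervals, artifact rejection, cubic-spline
   resampling to a uniform 2 Hz tachogram `f(t)`;
4. **Feature extraction** — 8-level db8 discrete wavelet transform; for
   each detail level `j` the coefficient-energy distribution
   `p_jk = D_jk² / Σ_k D_jk²` is summarized by the α-order generalized
   (Tsallis) entropy

   `H_j(α) = (1 − Σ_k p_jk^α) / (α − 1)`,   `H_j(1) = −Σ_k p_jk log p_jk`;

5. **Classification** — per-scale Welch t-tests pick the three most
   discriminative scales; a linear soft-margin SVM is evaluated by
   stratified, record-grouped fivefold cross-validation repeated many
   times, reporting mean ± SD of correct rate, sensitivity and
   specificity. The order α is chosen by an exhaustive sweep (0.1–5.0,
   step 0.1).

A seeded synthetic-data module generates normal-sinus, distant-from-PAF
and PAF-like tachograms (and ECG with exact ground-truth R peaks), so the
entire pipeline is testable without any database download.

## Worked example

```python
import pafentropy as pe

records = pe.make_benchmark(seed=1)          # 25 PAF / 25 distant / 50 normal
signals = [pe.resample_uniform(pe.clean_rr(r)) for r in records
           if r.label in ("PAF", "NORMAL")]
fm = pe.features_from_signals(signals, positive_label="PAF", alpha=0.3)
print(pe.per_scale_ttest(fm).chosen)
report = pe.repeated_cv(fm, folds=5, repeats=20, seed=0)
print(f"{report.mean_correct_rate:.2f} +/- {report.std_correct_rate:.2f} %")
```

prints

```
(1, 3, 4)
100.00 +/- 0.00 %
```

i.e. scales D1, D3 and D4 are the most class-separating on this draw of
the benchmark, and the cross-validated correct rate on the synthetic
PAF-vs-normal task is 100% (the default generator effect sizes make the
classes strongly separable; sensitivity is the detected fraction of PAF
records, specificity the fraction of normal records passed).

The `examples/` directory holds one short script per capability
(detection scoring, entropy features, benchmark classification, α sweep);
each prints its numbers with a line of interpretation. A thin CLI wraps
the same library:

```sh
paf simulate --class paf --seed 7 --out rec.csv --ecg rec_ecg.csv
paf preprocess --ecg rec_ecg.csv --fs 128 --out peaks.csv
paf extract --peaks peaks.csv --fs 128 --out hrv.csv
paf train-eval --features features.csv --folds 5 --repeats 100 --seed 17
```

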