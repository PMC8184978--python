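# bdews

Early-warning signals and spectral periodicity analysis of wrist actigraphy
for anticipating mood-episode transitions in bipolar disorder.

Bipolar-I patients cycle between euthymic periods and manic or depressive
episodes.  Complex-systems theory predicts that near a tipping point a
system shows *critical slowing down*, visible as rising variance, kurtosis
and autocorrelation in its output.  Continuous 1-minute actigraphy is a
low-burden, objective readout of the rest/activity system, so rolling-window
statistics of activity counts are candidate early-warning signals (EWS) for
upcoming episodes, and the spectrum of the activity rhythm can flag the
collapse of the normal 24-h cycle into atypical 12-h or 4-h rhythms.

`bdews` implements that analysis as a tested, reusable pipeline for
researchers working with minute-epoch actigraphy and weekly symptom scales
(ASRM, IDS-SR):

* **Indicators** — per 7-day window, stepped by 1 day, on the linearly
  detrended minute series: sample variance, raw Pearson kurtosis m₄/m₂²,
  and the autocorrelation at lag 720 min (12 h), the day/night-contrast
  statistic that sits near −1 for a strong 24-h rhythm and drifts toward 0
  as the rhythm deregulates.
* **Trend tests** — Mann-Kendall over the four pre-onset weeks of each
  indicator series: S = Σ_{i<j} sign(x_j − x_i), ties-corrected Var(S),
  continuity-corrected z, tau-a = S/(n(n−1)/2), two-sided p; Fisher's
  method (−2 Σ ln p ~ χ²_{2k}) pools p-values across patients per
  indicator.
* **Spectral indices** — unsmoothed FFT periodogram per window; the
  harmonic ratio power(12-h)/power(24-h) with WARN (ratio ≥ 0.9) and
  SWITCH (dominant period ≠ 24 h, covering 1440/n for n ≤ 6) events.
* **Episode rules** — manic onset at the first week opening ≥ 2 consecutive
  weeks with ASRM > 5; depressive onset at ≥ 3 consecutive weeks with
  IDS-SR > 25; pre-onset and euthymic analysis intervals derived from the
  onset.
* **Synthetic patients** — a seeded cosinor-plus-truncated-noise generator
  with injectable pre-transition signatures (linear variance ramp, rhythm
  switch) and matching symptom series, so the whole pipeline is testable
  without patient data.

## Worked example

Simulate a patient whose depressive episode at day 70 is preceded by a
28-day ramp of the epoch noise (×4 at onset), then run the full analysis:

```python
from bdews import (CircadianParams, TransitionSpec, simulate_patient,
                   analyze_patient, combine_group)
from bdews.pipeline import patient_report_frame

params = CircadianParams(n_days=120, seed=11)
spec = TransitionSpec(onset_day=70, ramp_days=28, variance_gain=4.0,
                      episode_type="depressive")
activity, symptoms, _ = simulate_patient(params, spec)
report = analyze_patient(activity, symptoms)
print(patient_report_frame(report).to_string(index=False))
```

```
 id episode_type indicator        z      tau  n            p sig direction
sim   depressive  variance 7.408695 0.994709 28 1.275484e-13  **  increase
sim   depressive  kurtosis 7.448208 1.000000 28 9.461668e-14  **  increase
sim   depressive    acf720 7.448208 1.000000 28 9.461668e-14  **  increase
```

Each row is one indicator's Mann-Kendall test over its n = 28 daily
pre-onset values (window end days 42–69): all three indicators rise almost
monotonically (tau ≈ 1) as the injected noise ramp inflates the window
variance and kurtosis and dilutes the day/night contrast, so acf-720 climbs
from its euthymic ≈ −0.89 toward 0 — each a significant (`**`, p ≤ 0.01)
pre-onset trend.  `combine_group([report, ...])` then Fisher-combines the
p-values per indicator across patients and tallies how many patients show
any, or all three, significant EWS.

The same pipeline runs from the shell on delimited text tables
(`timestamp,counts` and `week_start_date,asrm,ids_sr`):

```bash
bdews simulate --config sim.yaml --out data/p1/
bdews analyze --activity data/p1/activity.csv --symptoms data/p1/symptoms.csv --out out/p1/
bdews group --reports out/ --out group.csv
```

`analyze` writes `patient_report.csv` (the table above), `ews_series.csv`
(daily indicator values) and `ratio_series.csv` (harmonic ratio, dominant
period and WARN/SWITCH events per day).

## Reference data

`bdews.datasets` ships the published per-patient results of the motivating
eight-patient, 180-day actigraphy study (Mann-Kendall z/tau/n/p per
indicator, and euthymic-vs-episode mean activity), whose raw recordings
were never deposited.  They serve as inputs for group-level computations:
Fisher-combining each indicator's eight published p-values gives a combined
p < 0.001 for variance, kurtosis and acf-720 alike, and the p ≤ 0.05 /
tau-sign rule reproduces the published tallies (7/8 patients with at least
one significant EWS, 2/8 with all three, 4/8 with a significant acf-720
decrease).

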