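# Methods

`bdews` implements a within-patient pipeline for anticipating bipolar mood
episodes from continuous wrist actigraphy: rolling-window early-warning
signals (EWS) tested for pre-onset monotonic trends, and spectral
periodicity indices that flag rest/activity-rhythm transitions.  This note
records the models, estimator conventions, defaults and numerical choices,
and what the synthetic generator does and does not emulate.

## Data model

Minute-epoch activity counts are held on a contiguous, uniformly spaced
grid with an explicit validity mask (`ActivitySeries`).  Zeros are real
observations (sleep); off-wrist time is *missing*, never zero.  Timestamps
are local wall-clock time; daylight-saving duplications or gaps in
wall-clock time are rejected rather than resolved, because every rhythm
statistic below assumes uniform spacing.  Weekly ASRM (0–20) and IDS-SR
(0–84) self-reports are held per week start date, exactly 7 days apart
(`QuestionnaireSeries`).

## Episode definitions

* **Manic onset** — first week opening a run of ≥ 2 consecutive weeks with
  ASRM > 5.
* **Depressive onset** — first week opening a run of ≥ 3 consecutive weeks
  with IDS-SR > 25.

Thresholds are strict (exactly 5 / 25 does not qualify) and a missing week
breaks a run.  Only the first transition is analysed.  Onset is dated to
the first day of the first qualifying week — the finest resolution weekly
instruments permit.  If both criteria first qualify in the same week the
case is refused with an error: weekly data cannot order the two onsets and
the choice is clinical, not statistical.

The **pre-onset interval** is the four weeks `[onset − 28 d, onset)`
(truncated at day 0 for early transitions).  The **euthymic reference**
interval is either supplied explicitly or derived as the longest run of
weeks with ASRM ≤ 5 *and* IDS-SR ≤ 25 ending before the pre-onset interval;
the thresholds make the published exclusion of "not evidently euthymic"
reference periods operational, and a configuration override is available
when clinical judgement differs.

## Detrending and windowing

EWS are sensitive to slow drifts, so the full minute series is reduced to
residuals from one ordinary-least-squares line (time in minutes as
regressor, fitted on valid epochs) before windowing.  Detrending is global,
once, not per window.

Windows are 7 days long (10 080 epochs — every window contains a full
weekend, levelling weekday/weekend contrast), stepped by 1 day, and only
full windows are emitted.  A window is labelled by the day it **ends**, so
the indicator dated day *d* uses only data observed before *d*, and a
four-week pre-onset span yields n = 28 daily values.  Windows with fewer
than 90 % valid epochs are flagged unusable (`min_completeness = 0.9`; the
missingness rule is this package's choice — the source analyses state
none).  Day indices are 0-based and all intervals half-open.

## Early-warning indicators

Computed per usable window on the detrended residuals:

| indicator | estimator | convention |
|---|---|---|
| variance | Σ(x−x̄)²/(n−1) | sample variance |
| kurtosis | m₄/m₂², central moments with denominator n | raw Pearson kurtosis (Gaussian → 3, lower bound 1), *not* excess — the two differ by a constant shift, which no trend test can see |
| acf-720 | mean pairwise product / mean squared deviation (below) | day/night-contrast autocorrelation at a 12-h lag |

The acf estimator centres both terms of every lagged pair on the
full-window mean and normalizes the *mean* cross product by the *mean*
squared deviation:

    r(L) = [ Σ_pairs (x_t − x̄)(x_{t+L} − x̄) / #pairs ] / [ Σ_valid (x_t − x̄)² / #valid ]

Per-term (rather than raw-sum) normalization makes a pure 1440-min tone
score exactly −1 at lag 720 and +1 at lag 1440 irrespective of the partial
final cycle a 7-day window leaves; the raw-sum convention would bias the
7-day value to ≈ −0.93.  Under missingness, only pairs with both epochs
valid enter the numerator (pairwise complete).  Because the pair subset's
variance can slightly exceed the full-window variance, the result is
clipped to [−1, 1].  A strongly day/night-contrasted rhythm sits near −1;
deregulation (restless nights, inactive days, or a 12-h rhythm) pulls it
toward 0 or positive values — so *any* systematic drift, not only an
increase, is informative, and direction is reported alongside the test.

Variance and kurtosis under masking equal their values on the compacted
(invalid-deleted) window; all three indicators are invariant to positive
affine maps of the input except variance, which scales as a².

## Trend testing and group combination

Each indicator's pre-onset daily series is tested with the Mann-Kendall
test: S = Σ_{i<j} sign(x_j − x_i), ties-corrected
Var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18, continuity-corrected normal
deviate z = (S∓1)/√Var(S) (z = 0 at S = 0, giving p = 1 for flat series),
two-sided p, and classical tau-a = S/(n(n−1)/2).  Tau-a (not tau-b) is the
convention consistent with the published per-patient tables: tau = 0.444 at
n = 28 implies S = 168 and a no-ties z of 3.299, within 1 % of the printed
3.319.  Missing values are dropped preserving order; at least 3 values are
required, else the row is reported untestable.  Direction is derived
strictly from sign(S); the published table prints "increase" beside three
negative-z kurtosis rows (patients 3, 4, 15), which this package treats as
a typesetting inconsistency rather than a convention to reproduce.

Group evidence per indicator pools one p-value per patient with Fisher's
method, χ² = −2 Σ ln p on 2k degrees of freedom, in its standard form.
Significance labelling matches the published table note: `**` for p ≤ 0.01,
`*` for p ≤ 0.05.

The rolling 1-day step makes consecutive indicator values share 6/7 of
their data; the Mann-Kendall p-values on overlapping windows are therefore
anti-conservative as absolute error rates.  The package reports them as the
published analysis does, and calibrates the type-I error strictly on
non-overlapping windows (see below).  Autocorrelation-robust MK variants
and block-bootstrap nulls are deliberately out of scope.

## Spectral periodicity

Per rolling window (raw counts, not detrended): the mean is removed, and an
unsmoothed, untapered FFT periodogram is computed on the natural grid k/N
cycles/min, scaled one-sided so the ordinates sum to N·var (Parseval).
Missing epochs are filled with the window mean for the FFT only — a plain
periodogram cannot mask — and sub-completeness windows are skipped.

Because 10 080 is an exact multiple of 1440, the 24-h fundamental and its
harmonics n/1440 (n = 2..6) fall on bins and their powers are read off
without leakage.  The **harmonic ratio** is power(12-h bin) / power(24-h
bin); a vanishing fundamental (< 1e−12 of total power) reports +inf.  The
**dominant period** is the argmax over {1440/n : n = 1..6} — restricted to
harmonics to cover the observed 12-h and 4-h phenomena while excluding
leakage-driven spurious dominants; sub-fundamental (48-h) rhythms are out
of scope.  Event logic: WARN at the first window with ratio ≥ 0.9, SWITCH
at the first window whose dominant period leaves 1440 min (or ratio ≥ 1.0).
Raising a threshold can only delay or suppress its event.

Spectra reuse the 7-day/1-day windows; a 7-day window puts the fundamental
exactly on bin 7.  With a mid-window rhythm switch, whole post-switch days
contribute coherently to the new bin, so the dominant period flips once the
window majority is post-switch — a day-60 switch is flagged at an end day
in [60, 67], typically 64.

## Mean-activity comparisons

Weekly means are taken on raw counts (detrended means are 0 by
construction) over valid epochs: the euthymic reference is the first 7 days
of the euthymic interval; "before episode" is the 7 days ending at onset;
"during episode" (post-hoc variant) the first 7 days from onset.  The label
(more/less/equal) follows the sign of the difference.

## Synthetic generator

The generator emulates the study conditions the analysis assumes, not real
actigraphy in full.  Baseline model: counts = mesor + amplitude·cos(2π(t −
acrophase)/1440) + ε, ε ~ N(0, noise_sd²), truncated at zero.  Defaults —
180 days, mesor 100, amplitude 80, noise_sd 20 counts/min, acrophase 15:00
— give daytime activity in the 100–200 counts/min range of the published
euthymic means, near-zero troughs at night with occasional truncation
(hence mildly heteroscedastic non-negative counts), and a noise-to-rhythm
ratio (noise_sd = amplitude/4) under which the baseline acf-720 sits near
−0.89 and harmonic ratios stay ≪ 1.

Signatures are injected by reconstructing the deterministic mean curve from
the generating parameters (which is why `inject_transition_signature` takes
them explicitly), rescaling residuals by a noise gain that ramps linearly
from 1 to `variance_gain` over `ramp_days` ending at onset — linear because
a monotone ramp is exactly the alternative Mann-Kendall targets — and, for
rhythm transitions, replacing the 1440-min cosine with one at the target
period (same amplitude, 720 min for the 12-h phenomenon, 240 min for the
4-h one) from `switch_day` onward.  The calibrated detection scenario is
gain 4 over a 28-day ramp.  Symptom series draw euthymic baselines strictly
below both thresholds (ASRM 0–4, IDS-SR 8–20) and, when an episode is
specified, a qualifying run (ASRM 8–15 or IDS-SR 30–45) starting exactly at
the onset week, so ground-truth onsets round-trip through the detector.

Not emulated: sleep architecture and naps, weekday/weekend structure,
medication effects, seasonal drift, device artefacts, and autocorrelated
epoch noise.  Passing tests therefore demonstrate the estimators' and
tests' behaviour under the assumed signal model, not performance on real
recordings — in particular the null-calibration results do not bound false
positive rates in clinical data, where epoch noise is serially dependent.

## Calibration experiments and problem sizes

The shipped checks use scales chosen to estimate each rate precisely while
keeping the whole suite fast: brute-force Mann-Kendall oracle on 1 000
random tied vectors (lengths 3–30); type-I error on 20 000 i.i.d. Gaussian
series of length 28 (band [0.04, 0.06]; the continuity correction makes the
test mildly conservative, ~0.046 observed); detection power over 100
generator seeds (49-day recordings, onset day 42 → n = 28); strict null
rejection over 1 000 seeds of 196-day recordings cut into 28
*non-overlapping* windows (band [0.03, 0.08] per indicator); and 25 null
seeds for the zero-false-SWITCH check.

## Known limitations

* Weekly symptom resolution dates onsets no finer than the week start.
* The pre-onset n depends on the window-labelling convention; end-day
  labelling (used here) yields n = 14 for a day-21 onset where a start-day
  convention would yield more.
* Overlapping-window MK p-values are anti-conservative (see above).
* The harmonic-ratio series reacts to any rhythm disturbance, including the
  end of a euthymic period — it is an instability index, not an
  episode-onset-specific predictor.
* Mean-filled missing epochs bias periodogram power slightly toward zero at
  all frequencies; windows are skipped below 90 % completeness to bound
  this.
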