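# stare — automated alternate-cover-test strabismus screening

`stare` implements an automated, eye-tracking-based alternate cover test for
screening of strabismus (ocular misalignment), for researchers evaluating
headset-based vision-screening pipelines and for anyone who needs the
accompanying biostatistics (ROC screening evaluation, Bland–Altman method
agreement) on their own cohort data.

## The measurement

During the test each eye is alternately occluded for 1 s over a 60-s run
while the subject fixates a distant target and an eye tracker samples both
eyes' horizontal gaze position at 120 Hz. A strabismic eye deviates under
cover and snaps back (refixates) when uncovered, so each eye's horizontal
trace is a square-wave-like signal with a 2-s period whose step height grows
with the deviation. The package measures it by linear least squares of a
fixed-period sinusoid per eye:

    x(t) = a + b sin(2πt/T) + c cos(2πt/T),    T = 2 s (fixed)

with amplitude √(b² + c²) — the fundamental Fourier component of the
refixation square wave (an ideal square wave of peak-to-peak D fits
amplitude 2D/π). The fit is closed-form, deterministic, and indifferent to
samples dropped during blinks.

Amplitudes in millimetres are converted to deviations in prism dioptres
(1 PD deflects light 1 cm at 1 m; angle θ = arctan(PD/100)) through a
calibration curve fitted on control runs in which prisms of known strength
(0–40 PD) induce the deviation. Cohort-level screening performance is then
evaluated with ROC/AUC (Mann–Whitney, ties = ½), a jittered-ROC robustness
simulation, AUC versus test duration, Bland–Altman limits of agreement with
percentile-bootstrap CIs (N = 20,000), Pearson correlation, and the
prevalence-based minimum referral specificity.

Because clinical recordings of this kind are rarely shareable, the package
includes a synthetic binocular gaze simulator (`stare.occlusion_sim`) that
generates traces with the same statistical structure: square-wave
refixations with saccadic latency and main-sequence dynamics, Gaussian
tracker noise, and blink dropouts.

## Worked example

Simulate a subject with a true 15 PD horizontal deviation, calibrate on
simulated controls, and estimate the deviation from the trace:

```sh
stare simulate --deviation-pd 15 --seed 7 --out trace.csv
stare calibrate --runs cal_runs.csv --out cal.json   # control_id,prism_pd,amplitude_mm
stare fit --trace trace.csv --calibration cal.json
```

which prints

```json
{
  "deviation_pd": 15.61221819062151,
  "amplitude_mm": 1.0312883221505038,
  "eye_policy": "mean_of_eyes",
  "extrapolated": false,
  "amplitude_left_mm": 1.0316070611722647,
  "amplitude_right_mm": 1.0309695831287429,
  "rms_residual_left_mm": 0.46081771773158337,
  "rms_residual_right_mm": 0.4508718258223297,
  "gaps": [[18.833333333333332, 0.20000000000000237]]
}
```

The two eyes' fitted refixation amplitudes (≈1.03 mm each) are averaged and
mapped through the calibration slope (0.0661 mm/PD on these simulated
controls) to an estimated deviation of 15.6 PD — within 1 PD of the true
simulated 15 PD. The `gaps` entry records a 0.2-s blink dropout that was
excised before fitting; `extrapolated` would flag amplitudes beyond the
calibrated range. The same battery runs on real cohort tables via
`stare evaluate --cohort cohort.csv`, and `stare screen` executes the whole
synthetic study (calibration → estimation → evaluation) from one config.

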