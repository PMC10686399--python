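# Methods

## The model

An alternate cover test dissociates the two eyes: while one eye is covered
it drifts to its deviated position, and on uncovering it makes a refixation
saccade back to the target; meanwhile the newly covered fellow eye deviates.
Under a strict 1-s/1-s alternation both eyes therefore trace antiphase
square-wave-like signals with a 2-s period, with step height equal to the
pupil-plane displacement of the deviation. The package's core measurement
exploits the fixed periodicity: each eye's raw horizontal trace x(t) is fit
by ordinary least squares to

    x(t) = a + b sin(2πt/T) + c cos(2πt/T),    T = cycle period (2 s)

and the response amplitude is √(b² + c²), the amplitude of the fundamental
at the occlusion frequency. Phase and offset are free nuisance parameters;
the sin/cos basis makes the fit closed-form (no optimiser, no seed
sensitivity) and it needs no resampling, so blink-dropped samples are simply
absent from the design matrix. For an ideal square wave of peak-to-peak D
the fundamental has amplitude 2D/π; saccadic dynamics round the wave's
corners and shave ~1–2% off that, which the calibration absorbs.

Assumptions: the subject holds fixation (no nystagmus, no large head slip
relative to the headset); the deviation is constant over the run; only the
horizontal channel is analysed. The method quantifies magnitude, not
direction (eso vs exo), and does not distinguish manifest from latent
deviations.

## Units and geometry

Deviation is reported in prism dioptres (PD): 1 PD deflects light 1 cm at
1 m, so a deviation of d PD is a rotation θ = arctan(d/100). The tracker
reports pupil position in millimetres; a rotation θ about the eye's centre
moves the tracked pupil by r·sin θ, where r is the rotation-centre-to-pupil
distance (`eye_radius`, default 11 mm — a representative adult value; axial
length and vertex distance vary between subjects, which is exactly the
mm-to-PD conversion error the calibration step exists to absorb, and the
reason extreme eyes can be grossly over- or under-estimated).

## Calibration

Control runs with prisms of known strength give (prism_pd, amplitude_mm)
pairs; per-strength means across controls are fitted by one of three
monotone forms — `linear_through_origin` (default; zero deviation must give
zero refixation, and it is the simplest invertible choice), `affine`, or
`power`. A fitted curve that is not strictly increasing on the calibrated
range (e.g. from flat amplitudes) is rejected rather than inverted. New
subjects are scored by combining the two per-eye amplitudes (default: their
mean; `left`, `right` and `max` policies are available — which combination a
clinical deployment should use is genuinely open) and applying the
calibration inverse, clamped at 0; amplitudes above the calibrated range are
flagged `extrapolated` but still scored, since large deviations are the
cases a screen must not miss.

With defaults the generative small-angle slope is (2/π)·r/100 ≈ 0.070 mm/PD;
a linear-through-origin fit over the full 0–40 PD grid lands slightly lower
(≈0.066) because r·sin(arctan(d/100)) saturates mildly at large d.

## The synthetic generator

`occlusion_sim` emulates a 120 Hz binocular tracker over a 60-s test with
1-s alternate occlusion (right eye covered first): the covered eye sits at
its deviated position, transitions follow a cover change after a 200-ms
latency (±20 ms Gaussian jitter per saccade) with a sigmoidal (smoothstep)
position profile of main-sequence duration (21 ms + 2.2 ms/deg); per-sample
Gaussian tracker noise of 0.3 mm (≈0.1–0.15° at typical geometry, mid-range
of consumer-tracker accuracy specs once averaged) and ~4 blinks/min of
100–300 ms dropout are superimposed. All randomness flows from one seed.

What it does **not** emulate — and hence what passing tests do and do not
show about real data: inter-subject variability in gain (axial length,
headset fit), fixation instability, drift, latent components that emerge
gradually under dissociation, and non-Gaussian tracker artefacts. Synthetic
cohorts therefore separate cleanly: the synthetic screening AUC of 1.0 and
the sub-PD Bland–Altman limits of agreement characterise the *pipeline's*
statistical machinery under ideal subjects, not clinical performance, where
between-subject amplitude variation dominates the error budget. The jitter
sigma inferred from synthetic controls is correspondingly tiny (~0.03 PD),
so the jittered AUC stays at 1.0; on real cohorts the same code, fed a
realistic control SD, degrades the AUC as intended.

## Screening statistics

* ROC/AUC: scores are the estimated deviations; AUC is the Mann–Whitney
  probability (ties ½) via scikit-learn, cross-checked in the tests against
  a brute-force pairwise count. "Sensitivity at 100% specificity" uses the
  smallest threshold strictly above every negative score; positives tied
  with the top negative count as misses (deterministic and conservative).
* Jittered ROC: each of `n_sims` (default 1000) simulations adds i.i.d.
  Gaussian noise (SD = sample SD of the negative/control estimates unless
  given) to **every** subject's estimate, clamps at 0 (estimates are
  non-negative by construction), and recomputes the ROC; the mean ROC is
  formed by vertical averaging of sensitivity on a fixed 1001-point FPR
  grid. σ = 0 short-circuits to the raw ROC exactly.
* Duration analysis: deviations are re-estimated from the first N seconds of
  each trace, keeping whole 2-s cycles only (an N-s window keeps ⌊N/2⌋
  cycles — partial cycles bias the fixed-period fit), then the AUC is
  recomputed per window (default N = 2, 4, …, 60).
* Bland–Altman: differences are estimate − reference (positive bias =
  overestimation); bias, limits of agreement bias ± 1.96·SD (n−1), and the
  coefficient of repeatability 1.96·SD each get 95% percentile-bootstrap CIs
  (default 20,000 resamples, seeded). Outlier exclusion is manual and
  explicit (an id list); no automated rejection rule is applied.
* Referral arithmetic: at prevalence p and sensitivity se, false-positive
  referrals outnumber true positives once specificity falls below
  s\* = 1 − se·p/(1 − p); at p = 1.93% and se = 1 this is 98.03%, i.e. 98%
  to the nearest percent. Reported exact and rounded.

## Numerical choices and degenerate inputs

* The sine fit via `numpy.linalg.lstsq`; an all-constant trace yields
  amplitude 0 (not an error). Less than one full cycle of recording raises.
* Amplitude has a positive noise floor even at zero true deviation (the
  Rayleigh-type bias of √(b²+c²) under noise; it shrinks as samples
  accumulate), so any screening threshold must sit above that floor; the
  duration analysis quantifies the effect.
* Invalid samples are dropped, never interpolated; a gap is logged when
  consecutive retained samples are separated by more than `max_gap` (default
  0.2 s) beyond one nominal sample interval.
* Whole-cycle windowing uses `floor(window / period) * period` with samples
  strictly before that time.
* Per-stage seeds in the pipeline derive from the global seed via
  `numpy.random.SeedSequence.spawn`, keeping every report regenerable from
  its config.

## Study-scale defaults

The synthetic study mirrors the screening-feasibility design the package
models: 7 controls calibrated at {0, 1, 2, 3, 5, 6, 12, 15, 30, 40} PD; a
validation cohort of those 7 controls, 2 vertical-only patients (negatives —
the screen targets horizontal misalignment) and 17 horizontal-strabismus
patients drawn uniformly from 5–40 PD, alternating eso/exo; 60-s runs at
120 Hz; 20,000 bootstrap resamples; 1000 jitter simulations. These sizes run
the whole acceptance pipeline in a few seconds.

## Known limitations

Vertical and torsional deviations, nystagmus waveforms, vergence/
accommodation effects and manifest-vs-latent differentiation are out of
scope. The CSV trace format is the sole ingest path; device-specific binary
logs are not parsed. The calibration's functional form beyond the three
provided families, and the best eye-combination policy, remain open choices
exposed as parameters.
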