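# Methods

This note documents the models, the synthetic-data conditions, and the
numerical choices behind `opmpipe`, and states what the tests do and do
not demonstrate about real recordings.

## Head model and forward fields

The head is a homogeneous conducting sphere (scalp radius 0.09 m, source
shell 0.07 m, origin at the sphere centre; x through the preauricular
axis, y through the nasion, z up).  The magnetic field of a current
dipole inside a conducting sphere has the Sarvas closed form; two exact
properties anchor the test suite: a radially oriented dipole produces no
external field, and the radial component of the external field equals
that of the primary current alone (Biot–Savart), independent of volume
currents.  Both are verified to machine precision against independent
implementations.

A sphere is used instead of a realistic boundary-element head because it
admits closed-form fields and therefore exact oracles; the cost is that
"normal to the cortical surface" degenerates to the radial direction,
which is magnetically silent.  Source orientations are therefore
tangential, along the local anterior–posterior direction — emulating
sulcal-bank generators, which dominate MEG anyway.

**Sensor array.**  13 radial magnetometers at idealized 10-05 sites
(FC1, C1, CP1, FC3, C3, CP3, FC5, C5, CP5, FC7, C7, CP7, C9 — modified
combinatorial nomenclature, so FC7≡FT7, C7≡T7, CP7≡TP7, C9≡T9) at
scalp + 1 cm standoff, plus three reference magnetometers with mutually
orthogonal axes 0.37 m superior, posterior and left of the vertex.  The
10-05 angles come from the classic arc-division construction on the unit
sphere (C row at 18° steps from the vertex; FC/CP rows by great-circle
interpolation between the midline points and the 10% circumferential
circle), not from an anatomical template: the geometry is exactly
reproducible and needs no co-registration chain.

**Source grid and ROIs.**  A 6 × 20 grid on the source shell under the
array: six contiguous equal-width anterior→posterior strips named
superior precentral sulcus, precentral gyrus, central sulcus,
postcentral gyrus, postcentral sulcus, superior parietal lobule.  The
strip band spans +35°…−25° around the C sensor row so that the
postcentral-gyrus strip lies directly beneath the row — the array
targets the postcentral hand area — which also reproduces the expected
sensitivity ordering (maximal in the gyri beneath the sensors, lowest in
the superior parietal lobule at the posterior edge of coverage).

**Sensitivity maps** are lead-field column norms for a 1 A·m source;
ROI sensitivity is the mean over member vertices, with SD across
subject-specific lead fields when several are supplied.

## Synthetic sessions

The generator plants the responses the analysis is designed to measure;
its defaults are the study conditions, chosen once:

| quantity | default | basis |
|---|---|---|
| protocols | 300 events, ISI 1–1.4 s; 80 events, ISI 5.6–7.6 s | protocol definition |
| sampling | 1000 Hz | system bandwidth |
| SEF lobes | 20/35/60 ms, σ = 5/8/12 ms, −4/+2/+4 nA·m | latencies from the component definitions; amplitudes calibrated (below) |
| SEF source | postcentral-gyrus vertex between C5 and C7, orientation sign −1 | places the negative N20m lobe over the medial peri-rolandic channels |
| mu source | central sulcus, 10 Hz, 8 nA·m, ERD depth 0.5 (0.2–0.4 s) | ERD window definition; depth > beta so mu ERD dominates |
| beta ERD source | central sulcus, 21 Hz, 6 nA·m, depth 0.3 | |
| beta ERS source | precentral gyrus, 21 Hz, 6 nA·m, gain 0.3 (0.5–1.0 s) | rebound is anterior to the ERD focus |
| subject variability | latency jitter SD 1 ms; amplitude jitter 20 % | keeps grand-average latencies nominal with realistic spread |
| sensor noise | 10 fT/√Hz white | within the magnetometers' < 20 fT/√Hz rating; see below |
| interference | 30 pT RMS per cardinal axis, 4 Hz bandwidth, filtered random walk | compact passively shielded environment |
| gradient remainder | 5 % of the interference at a 10 cm reference distance | makes HFC imperfect, as in real data |
| line fields | 1 / 0.5 / 0.3 pT at 60 / 120 / 180 Hz, homogeneous AC | |
| artifact | 10 ms white burst at 10 × sensor-noise RMS around each event | stimulus-current artifact |

Oscillatory sources are unit-RMS band-limited (2 Hz) random-phase
carriers multiplied by an envelope that is 1 at baseline, ×(1 − depth)
in each event's ERD window and ×(1 + gain) in each ERS window, smoothed
over 0.1 s.  Short-protocol sessions carry unmodulated rhythms: the ERS
window extends 1.0 s past the stimulus and would collide with the next
event at the short protocol's minimum ISI — which is exactly why long
ISIs are required to measure the rebound.

**Calibration.**  The SEF and rhythm amplitudes are not measured
quantities; they were calibrated once so that the default cohort's
sensor-level N20m SNR lands in the single-digit-to-low-twenties band
reported for compact partial-coverage systems (seed 1: mean 12.9, median
11.8, range 7.6–22.2) and epoch rejection sits at a few percent.  The
sensor-noise density (10 fT/√Hz) was likewise chosen so that the two
fixed conventions — artifact at 10 × sensor-noise RMS and epoch
rejection at 5 pT peak-to-peak — are mutually consistent; at the rated
maximum of 20 fT/√Hz the artifact burst alone would trip the rejection
threshold in most epochs.

**What the generator does not emulate:** distributed background brain
activity (the only "brain noise" is the three planted rhythms, so
baseline variance is focal rather than spread over the array), head
movement, sensor calibration errors, cross-axis projections, or
non-stationary interference.  Passing recovery tests therefore shows the
pipeline is correct and self-consistent, not that real data of this
quality would yield the same statistics.

## Preprocessing

Order: notch → band-pass → bad channels → reference regression → HFC.

- Filters: second-order IIR notches (Q = 30) at 60/120/180 Hz and a
  4th-order Butterworth band-pass 3–150 Hz, both applied
  forward–backward.  Zero phase is mandatory because component latency
  is the headline measurement; a symmetric pulse's peak sample is
  provably unshifted.
- Bad channels: Welch amplitude spectra (2 s Hann, 50 % overlap), band
  mean over 120–145 Hz, z-scored across scalp channels, flag z > 2.0,
  single pass.  References are never flagged.
- Reference regression: each scalp channel is regressed on the three
  reference time courses plus intercept (OLS); the residual replaces the
  channel.  (The alternative direction — references as dependent
  variables — yields residuals for the references, not the channels, and
  is not what "reference-adjusted channel time courses" can mean.)
- HFC: model matrix N = scalp orientation vectors; projector
  P = I − NN⁺ with a rank-revealing pseudo-inverse (singular values
  below 1e-8 of the largest treated as zero; reduced rank proceeds with
  a warning).  Per-source attenuation 1 − ‖P lⱼ‖/‖lⱼ‖ is recorded when a
  lead field is supplied.  On this 13-channel single-axis array the mean
  attenuation is substantially higher than for a synthetic 64-channel
  whole-cap array — the partial-coverage penalty the with/without-HFC
  comparison quantifies.
- After HFC the reference channels are dropped: they are consumed by the
  regression and would otherwise dominate epoch rejection with their
  retained interference.

## Epoching and rejection

Epochs are −0.2…+0.5 s (short) and −1.2…+5.2 s (long), sample 0 aligned
to the event, both endpoints included (701 and 6401 samples at 1 kHz);
baselines −0.2…−0.1 s and −1.0…−0.5 s are subtracted per epoch and
channel.  Visual artifact screening is replaced by an automated
any-channel peak-to-peak threshold, default 5 pT on preprocessed data;
on the default cohort this rejects ≈ 4 % of epochs.  For induced-power
analysis the inter-trial average is subtracted from every epoch.

## Time-frequency analysis

Complex Morlet wavelets, 3–40 Hz in 1 Hz steps, cycles = f/3 (a
constant-duration wavelet: temporal SD = 1/(6π) s ≈ 53 ms at every
frequency), L2-normalized, Gaussian SD in time = cycles/(2πf).  Power is
the squared magnitude; the first and last 0.2 s are trimmed against edge
artifacts; no zero-padding (immaterial behind the trim).  Baseline
correction is log10(power / mean baseline power) per frequency — base 10
is declared in the output metadata since "logarithm" alone is ambiguous.
Band averages use inclusive endpoints, so 15 Hz belongs to both mu
(8–15 Hz) and beta (15–30 Hz), exactly as the printed ranges overlap.

## Source estimation

Minimum norm with identity source covariance (no depth weighting, no
noise normalization), fixed tangential orientations, restricted to the
six-ROI patch:

    K = Lᵀ (L Lᵀ + λ² C̃)⁻¹

with λ² = 1/SNR², SNR = 3 by default, and C̃ the baseline noise
covariance (pooled over epochs, 10 % diagonal loading) rescaled so
trace(C̃) = trace(LLᵀ) — making λ² a dimensionless knob.  The same
operator is applied to evoked (short protocol) and per-epoch (long
protocol) data.  Each ROI is summarized by the first principal component
of its vertex time courses (SVD of the time-centred block), sign-aligned
with the ROI mean time course.

Two caveats are documented rather than hidden.  First, minimum-norm
point spread on a 13-channel array is wide: localization claims are read
off at the vertex level (ROI label of the argmax vertex of
time-integrated |activity| in the early-component window), which
recovers the planted ROI within one strip in all default-cohort
subjects.  Second, the first-PC sign rule is unstable in ROIs where the
point-spread pattern changes sign across vertices, so cross-ROI
comparisons of PC amplitudes are not a localization measure.

## Statistics

- Peak windows: 10 ms a-priori windows centred on 20/35/60 ms; within
  each, the refined window is ±1 ms around the grand-average peak
  (extremum of |trace| over the supplied traces); a peak on the window
  boundary is recorded as a warning.  Test direction per ROI follows the
  sign of its grand-average early component; the later components are
  tested in the opposite direction.
- Bayes factors: one-tailed paired t-tests with the JZS prior — a
  Cauchy(0, r = √2/2) on the standardized effect size, truncated to the
  tested side and renormalized (doubled half-Cauchy).  BF10 is computed
  by adaptive quadrature of the noncentral-t likelihood over the effect
  size (relative tolerance 1e-10, well inside the 1e-8 contract); the
  effect-size parameterization makes one-sided truncation a simple
  interval restriction, and its equivalence to the usual g-integral is
  covered by a fine-grid quadrature oracle and an independent package in
  the tests.  The prior-mass identity BF(left) + BF(right) = 2·BF(two)
  holds by construction and is asserted to 1e-6.
- SNR: |mean(refined peak window) − mean(baseline window)| / SD of the
  baseline samples, on each subject's evoked trace; the per-subject
  summary is the maximum over sensors or ROIs.  The SD is taken over
  time samples of the evoked trace (not over trials).
- Best-sensor latency report: the early SEF component is a negative
  deflection by definition, and a tangential dipole always projects both
  field lobes onto the array, so the "best sensor" is the
  cohort-mean-max-SNR channel among those whose grand-average early
  deflection is negative; latencies are then the window extrema of the
  grand-average trace at that sensor.
- HFC impact: the analysis is repeated with HFC omitted, reusing the
  identical bad channels and epoch selections; per-subject with/without
  ratios of response magnitudes and maximum SNR are tabulated with grand
  medians.

## Problem sizes and determinism

The default cohort is 12 subjects × (300-event short + 80-event long)
sessions — the protocol-defined sizes; a full `run_full` takes a few
minutes on one CPU, and the evoked-only acceptance computation well
under a minute per cohort.  Every random draw descends from
(seed, subject id, protocol) through a counter-based generator, so
sessions are byte-identical across runs and CSV outputs are reproducible
bit for bit; the config hash is recorded in every output directory.

## Known limitations

- The sphere + idealized-layout geometry reproduces the *structure* of
  the analysis, not any individual anatomy; absolute field magnitudes
  depend on the invented source amplitudes.
- Bad-channel z-scoring with 13 statistically identical channels flags
  ~1 channel per session by chance (z > 2 across a small sample); this
  mirrors the single-pass criterion rather than a defect, but it means
  grand averages run on the intersection of surviving channels.
- The Bayes-table pattern across ROIs depends on the PC sign stability
  discussed above; only the planted-effect directions and BF > 1 claims
  are treated as recovery criteria.
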