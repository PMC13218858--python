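# Methods

## Scope and model of the analysis

The package implements an event-based analysis of five-channel peripheral
physiology (ECG, EDA, RSP, EMG, skin temperature; 1000 Hz) comparing an
active condition (GamePlay) against a passive one (GameWatch). The analysis
unit is the 10 s window inside annotated emotional-challenge events; windows
never straddle event boundaries and never overlap (10 s offset), avoiding
statistical dependence between adjacent feature frames. Two endpoints are
computed:

1. **Group comparison** — window features are averaged within each event,
   event estimates are averaged per participant, and the two groups are
   compared feature-by-feature with pooled-variance t-tests (Cohen's *d*,
   95% CI of the mean difference), corrected with Benjamini–Hochberg FDR
   within the physiological family.
2. **Condition discrimination** — L2-regularized logistic regression on
   window-level feature vectors under participant-wise 10-fold
   cross-validation (all windows of a participant share a fold), with
   modality ablations (full 80 features / without EMG, 63 / without EMG and
   EDA, 51) and a single-feature screen (full-data logistic β with Wald *p*,
   BH-FDR corrected within the screen; CV accuracy on the shared folds).

Because real participant recordings of this kind are not shareable, the
package ships a synthetic-data generator as a first-class, tested module; it
defines the cohort every end-to-end test runs on.

## Preprocessing

Processing order per channel: z-score over the **full recording** (removing
individual differences in level and gain), then filtering, then detection.
All filters are zero-phase forward–backward 2nd-order Butterworth, so
fiducial timing is unshifted; the filter family and order are the package's
choice (only cutoffs are externally prescribed).

* **ECG** — baseline estimated by a median-filter cascade (200 ms then
  600 ms) and subtracted; QRS complexes (~80 ms) are narrower than the first
  window and survive within a few percent. Beats are found with a
  Pan-Tompkins detector: 5–15 Hz band-pass, derivative, squaring, 150 ms
  moving-window integration, adaptive dual thresholds (SPKI/NPKI running
  estimates, 0.125 update), 200 ms refractory, and RR-based search-back at
  1.66× the running-average RR with a half threshold. Thresholds are
  initialized from the upper/lower quartiles of candidate-peak heights over
  the record: QRS and noise peaks are bimodal, and the quartile init is
  immune to the zero-phase filter's edge transient, which can exceed true
  QRS peaks several-fold and would poison a learning-phase maximum.
  Detections are refined to the local raw-ECG maximum within ±50 ms.
* **EDA** — 0.02 Hz high-pass removes tonic baseline; the high-passed signal
  is additionally split once per recording into LF (0.02–0.5 Hz), HF
  (0.5–1 Hz) and VHF (>1 Hz) components for the time-domain event counts.
  Filtering whole recordings rather than 10 s windows keeps the 0.02 Hz edge
  well-conditioned (its transient outlasts a window).
* **RSP** — 0.1–5 Hz band-pass; cycles are segmented from the alternating
  extrema sequence, and a candidate cycle is accepted only if its exhaled
  excursion (peak minus following trough) reaches 65% of the running median
  excursion. This operationalizes a proprietary exhaled-volume acceptance
  rule as a relative threshold; the fraction is configurable
  (`exhale_frac`). Depth is peak minus onset trough; period is
  onset-to-onset.
* **EMG** — decimated to 32 Hz behind a 16 Hz anti-aliasing filter
  (polyphase resampling); output length is floor(n·32/1000).
* **TEMP** — z-scored only.

## Features (80)

See `docs/features.md` for the canonical list. Notable conventions:

* **ECG spectra** — the RR tachogram (interval assigned to the closing
  beat) is cubic-spline resampled at 8 Hz over a 32 s frame centered on
  each 10 s window, clipped at event edges, mean-removed and zero-padded to
  256 samples; band powers are one-sided sums of squared FFT magnitudes
  over VLF/LF/HF (0–0.04/0.04–0.15/0.15–0.4 Hz), PSD is power over
  bandwidth, and total power is the band sum by construction. Frames with
  under 16 s of beat coverage yield missing values.
* **"sam" counts** — time-domain counts are local maxima of the
  band-limited EDA with prominence ≥ θ_t (default 0.05 z-units);
  frequency-domain counts are FFT bins of the window whose power exceeds
  θ_f (default 0.1) times the largest in-band bin. Both thresholds are
  configurable.
* **EMG wavelet energies** — 6-level Daubechies-5 DWT with *periodized*
  boundaries, so the transform is orthogonal and the sub-band energies
  (d1…d6, a6) sum to the window energy to machine precision; this energy
  conservation is asserted at 1e-6 relative. Symmetric padding was
  considered and rejected because edge coefficients inflate energy by ~1%
  at 320-sample windows, destroying the conservation identity.
* **Missing values** — windows with <3 beats, <2 breath cycles,
  insufficient tachogram coverage or zero EMG energy carry NaN; statistics
  exclude them pairwise, classification mean-imputes with training-fold
  means only.

## Classification choices

Regularization strength C = 1.0 on standardized features (stabilizes an
80-feature model on a few hundred windows; configurable). Accuracy is
pooled over windows (total correct / total windows), not averaged over
folds. Standardization and imputation are computed inside each training
fold, so no held-out participant's statistics ever touch its own test
windows. Fold assignment is a seeded, condition-stratified round-robin: one
condition deals folds 0,1,…, the other k−1,k−2,…, balancing size and class
mix (28 participants → eight folds of 3, two of 2). In the single-feature
screen, a fit with non-converged optimization or Wald SE above 1e3
(perfect separation) reports the likelihood-ratio *p* instead of the Wald
*p*.

## The synthetic generator

Each condition is a `ConditionProfile` (JSON-editable; shipped defaults
encode the study-scale group physiology: GamePlay with higher mean heart
rate 78.09 vs. 74.16 bpm with between-participant SDs 6.82/11.06, lower RR
jitter 0.04 vs. 0.06 s, shallower event-period breathing depth 1.12 vs.
1.29, more phasic EDA events 20 vs. 12.6 per minute with larger amplitude,
a larger event-period temperature elevation 0.48 vs. 0.26 z-units, and a
slightly smaller fine-band EMG fraction). Channels:

* **ECG** — P-QRS-T template (sum of Gaussians, R amplitude 1.0) placed at
  integrate-and-fire beat times (mean RR = 60/HR, jitter `rr_within_sd`),
  plus respiratory-band and very slow baseline wander and white noise.
  R-amplitude jitter is coupled to RR jitter (2.5×), reflecting shared
  autonomic drive; the profile has no separate amplitude-variability field.
* **EDA** — smooth tonic drift (AR(1) low-passed at 0.05 Hz — tonic skin
  conductance has essentially no power above a few hundredths of a Hz, and
  an unfiltered AR(1) tail would contaminate the 0.5–1 Hz phasic band) plus
  bi-exponential SCR kernels (0.75 s rise, 2.0 s decay) at Poisson times
  with log-normal amplitudes.
* **RSP** — per-breath sinusoidal half-cycles with jittered periods; depth
  follows a smooth event-modulation envelope from a common pre-event
  reference (1.5) to the profile's event-period depth, so the event-period
  depth relative to the participant's own z-score baseline differs by
  condition.
* **EMG** — noise split between a <1 Hz and a 1–16 Hz component per
  `emg_fine_fraction`, amplitude-scaled by `emg_total_energy_scale`
  (energy exactly quadratic in the scale).
* **TEMP** — event-modulated offset plus an Ornstein–Uhlenbeck fluctuation
  (τ = 10 s) and a sensor-noise floor whose scale varies log-normally
  between participants (placement and gain differ), so noise-derived
  features are not artificially identical within a group.

All randomness flows from one integer seed through per-channel
`SeedSequence` substreams; identical seeds give bit-identical recordings
(channels are rounded to the 1e-5 precision of the plain-text signal files
so disk round trips are exact). Ground truth records true beat, SCR and
breath-onset times, so detectors are scored against the generator, never
against themselves.

**What the generator does not emulate:** cardiorespiratory coupling, motion
artifacts, ectopic beats, real EMG bandwidth (20–450 Hz content above the
32 Hz-referenced band is irrelevant post-decimation and is not generated),
distinct physiology for the two narrative endings, or realistic session
lengths (default 300 s per participant, not ~50 min). Passing tests
demonstrate the pipeline's correctness and calibration on signals with this
structure; they do not certify accuracy figures on real recordings — the
reference study's accuracies were computed on non-shareable data and are
treated as schema, not targets.

Two reported group-difference directions are structurally unrecoverable
under full-recording z-scoring with the given profile fields: total EMG
energy (a pure amplitude scale cancels under normalization) and temperature
first-difference variability (both conditions share the fluctuation drive).
Direction tests therefore cover heart rate, mean RR, R-amplitude spread,
phasic EDA counts, breathing depth and temperature level.

## Problem sizes and calibration checks

Monte-Carlo checks run at desk scale, sized by a-priori power arithmetic:
type-I calibration uses 50 null cohorts (identical profiles, 8 per group,
120 s) and expects a 5% ± 2-point false-positive rate; chance-level CV uses
20 window-level label shuffles of one cohort (0.50 ± 0.05); direction
recovery uses 10 cohorts of 50 per group at 120 s — with the configured
between-participant heart-rate spreads the group effect is d ≈ 0.4, so
smaller cohorts would make a sharp ≥90% sign-recovery check underpowered —
and the multimodal-vs-single-feature comparison is paired over the same
cohorts.

## Degenerate inputs and tie-breaks

Constant signals z-score to zeros; flat respiration yields an empty cycle
series (not an error); fewer than two detected beats raises "insufficient
beats"; constant features are flagged degenerate in group comparison and
skipped in the screen; a training fold with one class raises rather than
silently reporting chance. Annotation intervals are half-open in samples,
so adjacent events partition the signal without sharing a sample;
overlapping annotations are rejected, not merged.
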