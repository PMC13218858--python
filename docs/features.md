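# Canonical feature inventory (80)

One row per feature, in canonical column order. Windows are 10 s wide with
a 10 s offset inside annotated events; statistics marked *Diff* are taken
on first-order differences.

## ECG (31)

| Feature | Definition |
|---|---|
| RR mean / std / mad / median / min / max | statistics of in-window RR intervals (s) |
| bpm | mean of per-beat instantaneous rates 60/RR_i |
| RRdiff mean / std / mad | statistics of successive RR differences |
| RMSSD | root mean square of successive RR differences |
| pNN20 / pNN50 | fraction of \|ΔRR\| > 20 ms / 50 ms |
| R mean / std / mad | statistics of R-peak amplitudes (normalized ECG) |
| Rdiff mean / std | statistics of successive R-amplitude differences |
| pwr VLF / LF / HF / TP | band power of the 8 Hz-resampled RR tachogram, 32 s / 256-sample FFT frame; bands 0–0.04 / 0.04–0.15 / 0.15–0.4 Hz; TP = VLF+LF+HF |
| psd VLF / LF / HF / TP | band power / bandwidth |
| LF/HF ratio | pwr LF / pwr HF |
| LF norm / HF norm | LF/(LF+HF), HF/(LF+HF) |
| peak-freq LF / HF | frequency of the largest in-band FFT magnitude |

## RSP (12)

| Feature | Definition |
|---|---|
| val mean / std / mad | per-cycle depth (peak − onset trough) |
| prd mean / std / mad | per-cycle period (onset-to-onset, s) |
| Diffval mean / std | successive depth differences |
| Diffprd mean / std | successive period differences |
| breath rate | accepted cycles per minute |
| duty ratio | mean inhale time / period |

## TEMP (8)

temp mean / std / mad / min / max; temp Diff mean / std / mad — statistics
of the z-scored in-window temperature and its sample-to-sample differences.

## EDA (12)

For each band LF (0.02–0.5 Hz), HF (0.5–1 Hz), VHF (>1 Hz):

| Feature | Definition |
|---|---|
| *band* time sam | count of local maxima of the band-limited signal with prominence ≥ θ_t (default 0.05 z-units) |
| *band* frq sam | count of in-band FFT bins with power > θ_f × max in-band bin (default θ_f = 0.1) |
| *band* frq pwr | summed in-band FFT power of the window |
| *band* frq psd | band power / bandwidth |

## EMG (17)

6-level Daubechies-5 DWT (periodized) of the 32 Hz signal; sub-bands
d1 (8–16 Hz), d2 (4–8), d3 (2–4), d4 (1–2), d5 (0.5–1), d6 (0.25–0.5),
a6 (0–0.25 Hz).

| Feature | Definition |
|---|---|
| Total Eng | Σ sub-band energies = window sum of squares |
| d1…d6, a6 Eng | sum of squared coefficients per sub-band |
| d1…d6, a6 Eng% | sub-band energy / Total Eng |
| 1-2 level Eng% | Eng%(d1) + Eng%(d2) |
| 5-6 level (7) Eng% | Eng%(d5) + Eng%(d6) + Eng%(a6) |
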