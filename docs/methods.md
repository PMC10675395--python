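# Methods

## Problem and pipeline

`eegfatigue` classifies operator alertness into three states — *normal*,
*critical* and *fatigue* — from 32-channel scalp EEG. Ground truth comes
from Karolinska Sleepiness Scale (KSS) self-ratings collected every 10
minutes; the mapping is KSS 1–5 → normal, 6–8 → critical, 9 → fatigue.
The pipeline is

1. **Preprocessing** — wavelet denoising, 1–75 Hz zero-phase band-pass,
   downsampling to 200 Hz, truncation into non-overlapping 60 s epochs,
   KSS carry-forward labelling.
2. **Spectral features** — per channel, an AR(10) model fitted by the Burg
   method; the parametric PSD is reduced to absolute band power and
   relative PSD (RPSD) in the delta (0–4), theta (4–7), alpha (8–13) and
   beta (14–30 Hz) bands.
3. **Topographic rendering** — RPSD values are placed on a 9×9 grid via an
   azimuthal equidistant projection of the electrode positions and
   rendered as 72×72 maps; delta/theta/alpha maps stack into a 72×72×3
   image.
4. **Classification** — a compact convolutional network
   (conv3×3×16 – ReLU – pool2 – conv3×3×32 – ReLU – pool2 – FC128 – FC3,
   softmax) trained with Adam on cross-entropy, evaluated by stratified
   75/25 splits and 10-fold cross-validation with one-vs-rest metrics and
   ROC/AUC.

## Spectral estimation

The Burg recursion minimises the summed forward and backward
prediction-error power over reflection coefficients, orders 1…p; the final
prediction-error power doubles as the innovation-variance estimate. The
spectrum is evaluated as a one-sided density
`P(f) = (2/fs)·σ²_p / |1 + Σ a_k e^(−2πifk/fs)|²` on a 0–100 Hz grid with
0.25 Hz steps, so its rectangle-rule integral over [0, Nyquist]
approximates the signal variance (checked to 10% in tests).

Band powers use the rectangle rule over half-open intervals [low, high),
so the shared 4 Hz delta/theta edge counts once. The RPSD denominator is
the continuous 1–30 Hz span of the four analysis bands (the 7–8 Hz
theta–alpha gap *is* in the denominator); RPSD numerators are clipped to
that span, which makes every ratio land in [0, 1] and gives delta an
effective 1 Hz lower edge — consistent with the 1 Hz high-pass anyway.

The default order is fixed at p = 10. `select_order_aic` implements
`AIC(p) = n·ln(ê_p) + 2p` with ties to the smaller order; note AIC's
well-known overselection: on strong AR(2) data it returns exactly 2 in
roughly three quarters of realizations and a slightly larger order
otherwise — it essentially never underfits.

## Montage and rendering choices

Electrode coordinates come from the bundled standard 10–20 positions,
recentred on a least-squares sphere fit, left/right symmetrised (14
homologous pairs, 4 midline channels), rotated so Cz is the exact pole,
and polar-angle–compressed into the upper hemisphere (realistic head
geometry puts temporal electrodes slightly below the equator plane). The
acquisition montage names "C7"/"C8" ship verbatim but sit at the standard
T7/T8 coordinates.

Rendering: electrodes snap injectively to nearest cells of a 9×9 lattice
over the bounding square of the projected disk (conflicts would move the
later channel to its nearest free cell; the standard montage has none).
Empty cells are filled by inverse-distance-squared interpolation from the
electrode cells, the grid is upsampled ×8 bicubically, masked to the head
disk (radius = max projected radius + 5%), and min–max normalised per
image; a constant map renders as 0.5. How four bands map onto three image
channels is a genuine design gap; the default drops beta — the band that
changes least with fatigue — and an "rgb" mode renders a single band
through a perceptual colormap instead.

## The synthetic generator

Each channel is a sum of unit-variance band-limited noise components
(white noise through 4th-order zero-phase Butterworth band-passes, with
generous padding trimmed so the slow delta-band edge transients never
reach the output), scaled by a base amplitude (δ 4.0, θ 3.0, α 3.0, β 1.5
µV, a coarse 1/f shape) times a per-state gain:

| state    | delta | theta | alpha | beta |
|----------|-------|-------|-------|------|
| normal   | 1.0   | 1.0   | 1.0   | 1.0  |
| critical | 1.3   | 1.4   | 0.85  | 1.0  |
| fatigue  | 1.7   | 1.9   | 0.6   | 1.0  |

The delta gains sit close to theta's on purpose: RPSD is a power *share*,
and the theta-driven growth of the 1–30 Hz denominator (~×2.3 in fatigue)
would swallow a small absolute delta increase — the relative delta power
would stay flat instead of rising as the fatigue signature requires.

plus unit-variance broadband noise, raised-cosine blink transients
(0.3–0.5 s, 5× background SD, ~15/min) on Fp1/Fp2/AF3/AF4, and 50 Hz
mains pickup (0.5 µV). Gain *directions* follow the drowsiness-EEG
literature (delta/theta up, alpha down, beta flat); the magnitudes are
synthetic conventions, since real data constrain only the direction.

The state effects carry an anterior–posterior spatial profile:
`gain_eff(ch) = 1 + (gain − 1)(1 + tilt·y)` with y the channel's
normalised front–back coordinate and tilt +0.5/+0.6/−0.6/0 for
delta/theta/alpha/beta. This mirrors the regional physiology of fatigue
(fronto-central theta rise, occipital alpha suppression) and is also what
makes the rendered maps classifiable at all: per-image min–max
normalisation deliberately discards absolute level, so a spatially uniform
effect would be invisible in the images. The scalp-mean effect direction
per band is unchanged by the tilt.

What the generator does **not** emulate: dipole/forward-model topography
and volume conduction (channels are statistically independent),
inter-subject variability, non-stationarity within an epoch, real artifact
morphology beyond blinks and mains. Passing tests therefore demonstrate
that the pipeline recovers the structure this generator plants — a
parameter-recovery result, not a claim about accuracy on recorded EEG.

## Training and evaluation

Defaults: Adam at 1e-3, batch 32, 50 epochs, seeded He initialisation;
regularization options are L1/L2 (1e-4), dropout 0.5 on FC128, and early
stopping (patience 5 on a 10% validation split). All randomness — weight
init, shuffling, dropout masks, splits — flows from integer seeds, and
training is bitwise reproducible. The network (~1.33M parameters) is
implemented directly in numpy with im2col convolutions; exact gradients
are verified against finite differences in the test suite. Max-pooling
routes tied maxima to the earlier element — a deterministic subgradient.

Metrics are computed one-vs-rest per class (accuracy, precision,
sensitivity, F1) with unweighted macro averages, 0/0 denominators map to 0
with a logged warning, and AUC is the trapezoidal one-vs-rest area
(equal to the normalised Mann–Whitney statistic; tested against a
brute-force pairwise oracle).

## Evaluation problem sizes

The reference experiments (`eegfatigue.benchmarks`, used by
`scripts/acceptance.py` and the acceptance tests) use a corpus of 300
epochs per state (60 s, 500 Hz) run through the full pipeline, 10-fold
stratified cross-validation with 6 training epochs per fold — the loss
plateaus well before that on this corpus — and 50 AR(2) realizations of
40,000 samples for the spectral cross-check (long enough that the
periodogram oracle's band sums are noise-free relative to the tolerance).
A full acceptance run takes roughly a quarter of an hour on one CPU.

## Known limitations

* The published 8-layer architecture is under-documented upstream; the
  stack here is a faithful reconstruction consistent with the stated
  input size, padding, activation and pooling, not a replica.
* EDF files are read (via mne) but not written — the simulator's on-disk
  format is a text matrix + JSON sidecar.
* Per-subject ROC curves are supported through the `subject_id` field,
  but the simulator does not model subjects, so the shipped experiments
  pool epochs.
* No ICA artifact rejection, re-referencing or bad-channel interpolation;
  the upstream description specifies none.
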