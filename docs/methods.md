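# Methods

This note records the models, conventions and numerical choices behind
`hifumap`, and what the synthetic study conditions do and do not establish.

## Coordinate and container conventions

Stacks are `frames[t, row, col]` with row = axial/depth and col = lateral,
0-based pixel-center indices. Frame `t` occurs at
`time_origin_s + t / frame_rate_hz` on a shared experiment clock; the
canonical timeline has optical mapping from 0 s, ultrasound imaging from
4 s (11 frames/s), and the ablation exposure at 4.5–8.5 s. On disk, stacks
are multi-page TIFF with a JSON sidecar for acquisition metadata (frame
rate, pixel spacing, RF sample rate, ablation window); histology is
PNG/TIFF RGB, masks 0/255 PNG, tables CSV. Round-trips are lossless at the
stored dtype.

## Parametric ultrasound maps

The envelope is the magnitude of the per-A-line analytic signal (Hilbert
transform over the full line, no tapering; edge samples retained). The dB
maps use `GS = 20·log10(A/ref)` and `IBS = 10·log10(⟨A²⟩_w/ref²)` with
`ref` = the maximum envelope over the pre-ablation baseline frames (the
convention fixes the arbitrary linear gain; any other positive reference
only shifts both maps by a constant). Zero amplitudes clamp to −60 dB.

Rayleigh α̂ and log-normal (µ̂, σ̂) are the closed-form MLEs over the
sliding window; σ̂ uses strictly positive samples (zeros excluded and
counted) and emits NaN sentinels when fewer than two remain. The window
anchors at its center and *shrinks at the frame border*, so all four maps
share the source frame's shape and pixel alignment. Consequence: border
pixels average fewer samples and are noisier; the detection pipeline
therefore scores only the full-window interior (see ROC below). Windows
overlap (stride 1), so neighboring estimates are correlated — fine for
mapping, but statistical tests on map values must subsample at
non-overlapping positions.

Goodness of fit uses 45 equal-width bins on [0, max]: adjusted R² of the
MLE pdf against the normalized histogram, Pearson χ² on counts, and
`dof = bins − params − 1` (43 for Rayleigh, 42 for log-normal).

## Temporal-evolution maps

Transient `|ΔX|_t`, cumulative `ΔX_c` (signed and absolute, versus the
average of all frames before ablation onset), and the per-pixel running
maximum `|ΔX|_max` of `|ΔX_c|`. The extrema map is normalized by **one
global constant per sequence** (its maximum over all pixels and frames):
per-frame normalization would break per-pixel monotonicity and make a
single dimensionless threshold meaningless. When a threshold trained on
one cohort is applied to a *new* sequence, the training scale is carried
over (raw extrema divided by the trained constant). Normalizing a
no-lesion sequence by its own noise maximum would stretch pure noise to
[0, 1] and defeat any fixed threshold; carrying the trained scale keeps
the units commensurate. The transient convention is absolute (detection
maps); a signed variant exists for analysis (its time sum telescopes).

## Optical-mapping feature extraction

Pipeline: 3×3 spatial binning → ΔF = (F − F̄)/F̄ per pixel → zero-phase
FIR low-pass at 100 Hz → drift correction → per-cycle features. A literal
1–100 Hz band-pass (`preprocess`) is provided and verified (DC rejection
< 0.01%, 10 Hz gain within 1%), but the default measurement path removes
sub-hertz drift in the *time domain* instead: with 1000 ms pacing the AP
fundamental lies exactly on a 1 Hz high-pass edge, and zero-phase
filtering there distorts repolarization by tens of milliseconds. Drift
fits (linear, a + b·ln(1+t), cubic; best residual wins) use the diastolic
samples — the last 10% of each pacing cycle — so the paced waveform is
untouched.

Per cycle and pixel: activation = arg-max of the central-difference
derivative with parabolic sub-frame refinement; plateau amplitude = median
of samples in the top quarter of the range (robust to filter ringing at
the upstroke corner and unbiased under noise, unlike a raw maximum);
diastole = median of the last 10% of the cycle; APD_f = time from
activation to the repolarization crossing of `diastole + (1−f)·APA`, where
the crossing is the mean of the first-below and last-above linear
interpolations — the symmetric pair cancels the early bias a noisy
first-crossing rule has on shallow tails, and reduces to the exact
crossing on clean traces. Non-positive APDs (crossing before activation:
noise-dominated cycles) become NaN. APA is normalized by the mean
amplitude over the cycles inside the 1–4 s baseline window, so
ΔAPA = APA − 1. Conduction velocity comes from a least-squares plane fit
of activation time over a 5×5 neighborhood, `v = ∇T/|∇T|²` in mm/ms;
gradients implying speeds above 5 mm/ms (near-simultaneous activation)
and windows touching the border or containing NaN are masked.

## Histology segmentation and registration

RGB → L\*a\*b\*; 2-class k-means on (a\*, b\*) with fixed seeding;
lesion = the paler (higher mean L\*) class by default, overridable for
stains where the prior differs. Labels are regularized by an Ising-prior
ICM sweep (4-neighborhood, pairwise weight β = 1.0 by default, unary =
normalized squared centroid distance, synchronous updates until stable,
≤ 10 sweeps) followed by a radius-1 morphological closing. Energy ties
keep the current label (within a float tolerance), so a clean two-color
labeling is a fixed point and noiseless phantoms are recovered exactly.
Registration fits a similarity transform (rotation, isotropic scale,
translation) to fiducial landmark pairs by least squares; the carved
fiducial is rigid, so affine freedom is unjustified. Masks resample
nearest-neighbor, intensity images bilinearly.

## ROC machinery

Scores are oriented lesion-positive (−ΔAPA, normalized extrema). Curves
group tied scores; the trapezoid AUC then equals the Mann–Whitney
pair-counting statistic exactly (ties count ½), which the tests verify
against a brute-force oracle. The operating threshold maximizes Youden's
J with ties broken toward higher specificity and is reported as the
midpoint between the retained score and the next distinct score below, so
`score ≥ threshold` reproduces the operating point and falls mid-gap for
separated clusters. Pixel non-independence is deliberately ignored in
curve construction; leave-one-out across subjects is the unit of
uncertainty (per-fold threshold trained on the pooled remainder,
evaluated held-out). The Kruskal–Wallis utility computes H from pooled
mid-ranks with tie correction and a χ² tail.

The three-band ΔAPA classifier uses bounds (−0.43, −0.19) by default:
below −0.43 = lesion-grade amplitude loss, between = detectable
non-lesion change, above = unchanged.

## Synthetic study conditions

**Speckle phantom.** Envelope amplitudes are drawn i.i.d. per pixel from
the configured law — log-normal (µ0 = 0, σ0 = 0.3) by default, Rayleigh
optional — rather than via scatterer-field convolution: the detectors use
only first-order envelope statistics, and direct sampling makes ground
truth exact. Inside the lesion ellipse the parameters ramp linearly from
identity at ablation onset (4.5 s) to the final shift (σ×1.8, µ+0.4) at
ablation end (8.5 s); defaults are 200×80 px at 11 frames/s, 51 frames
from 4 s, so ~6 baseline frames precede onset. What this omits: spatial
speckle correlation from the imaging PSF, attenuation, motion, and any
non-monotone "boiling"/gas-body dynamics — so passing tests establish
estimator and detector correctness under the assumed statistics, not
robustness to those physical effects.

**AP movie.** F = drift(t)·[F₀ + A₀·APA(x,y;cycle)·V(t − activation)] +
noise, with V a half-cosine upstroke (8 ms; max normalized slope
π/(2u) ≈ 0.196/ms), flat plateau, and exponential repolarization whose
plateau duration and time constant are solved so APD50 = 160 ms and
APD80 = 200 ms hold simultaneously (τ = ΔAPD/ln 2.5). Plane-wave
activation at 0.5 mm/ms on 250 µm pixels; one cycle per 1000 ms pacing
period, no arrhythmic beats. Lesion effects (APA×0.2, APD50×0.67,
APD80×0.79, upstroke rate×0.58) are evaluated on the linear ramp at each
cycle's stimulus time. Drift is multiplicative (linear −0.003/s plus a
0.02-amplitude exponential, τ = 8 s); noise is additive white with
sd = 0.005 against a 5% fractional AP amplitude (20 dB amplitude SNR).
Ground-truth maps are computed from the config, never from the rendered
frames. Omitted: dye washout heterogeneity beyond the per-pixel
normalization, motion, photon scattering from depth (which in real data
contaminates in-lesion optical signals).

**Histology phantom.** Pale lesion / dark-red background class colors with
Gaussian color noise and a configurable fraction of single-pixel class
outliers to exercise the MRF step. **ΔAPA phantom.** Three-zone mean field
(lesion core −0.5, border rim −0.31, background 0) plus N(0, 0.1) pixel
noise; the banded classifier is evaluated on the 3×3-binned map — the
binning the optical pipeline itself applies — against the partition of
the mean field.

## Problem sizes and test design

Tests and the acceptance script run scaled-down instances of the same
conditions: speckle phantoms 60×40 px with a 7×5 estimation window, AP
movies 40×40 px over 12 s (3 baseline, 4 ablation, ~3.5 recovery
cycles). The 7×5 window was chosen so that *single-frame* parameter maps
remain imperfect detectors — the regime of the real measurement, where
cumulative AUC ≈ 0.75-class performance makes the ordering
extrema ≥ cumulative ≥ transient meaningful; with very large windows all
per-frame detectors saturate and the comparison degenerates into ties.
Cohort analyses use 13 subjects. Noisy-recovery tolerances are asserted on
medians across pixels (cycle-averaged over the baseline window);
per-frame AUC monotonicity is asserted up to twice the chance-level
Hanley–McNeil standard error, the resolution below which a stochastic
AUC estimate cannot be ordered. The upstroke-slowing ratio under noise is
quantified in a configuration that preserves AP amplitude: at 80%
amplitude loss the lesion upstroke derivative lies below the sensor noise
floor and no estimator can recover it — consistent with the caution that
in-lesion optical signals are unreliable in real preparations.

## Known limitations

* Monotone lesion kinetics only; transient gas-body fluctuation is not
  modeled, so the extrema map's advantage over the final cumulative map is
  smaller here than on real exposures where signals fluctuate and recover.
* The speckle phantom is spatially white; window-level estimator variance
  on real (PSF-correlated) speckle is larger at equal window size.
* ICM is a local optimizer of the Ising energy; heavy label noise beyond
  ~10% can leave residual clusters (the closing step absorbs small ones).
* ROC curves treat pixels as exchangeable; all spatial uncertainty is
  deferred to the leave-one-out subject level.
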