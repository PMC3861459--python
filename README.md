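# hifumap

Spatiotemporally correlated analysis of thermal ablation lesions in
transmural cardiac tissue: parametric ultrasound imaging of first-order
speckle statistics, optical-mapping electrophysiology, histology lesion
segmentation, and ROC-based detection thresholds — with synthetic-data
generators that make the whole chain testable end to end.

## The problem

During high-intensity focused ultrasound (HIFU) or RF ablation of cardiac
arrhythmias, the operator needs to know — *while ablating* — whether the
lesion has become transmural and whether the surrounding tissue's action
potentials (APs) have changed irreversibly. Conventional B-mode ultrasound
shows almost no lesion contrast, but the *statistics* of the backscattered
envelope change as tissue coagulates, and optical mapping shows the
electrophysiological footprint: loss of AP amplitude (APA), shortening of
APD50/APD80, AP triangulation, slower upstrokes, altered conduction.

This package implements that analysis chain for users who work with
envelope/RF image sequences, voltage-dye fluorescence movies, and stained
section photographs — and, because such datasets are rarely shareable, it
ships generators that emulate them with exact ground truth.

## The statistics at the core

For an envelope image sequence A(x, y; t), a sliding window (default
100×13 px) yields four per-pixel parametric maps:

* grayscale `GS = 20·log10(A/A_ref)` [dB],
* integrated backscatter `IBS = 10·log10(⟨A²⟩_w / A_ref²)` [dB],
* Rayleigh scale MLE `α̂ = sqrt(Σ Aᵢ² / 2N)`,
* log-normal shape MLE `σ̂ = sqrt((1/N)·Σ (ln Aᵢ − µ̂)²)`.

Each map sequence X(x, y; t) is then turned into three temporal-evolution
images: transient change `|ΔX|_t = |X(t) − X(t−1)|`, cumulative change
`ΔX_c = X(t) − X̄_baseline` against the pre-ablation average, and the
cumulative extrema `|ΔX|_max(t) = max_{t'≤t} |ΔX_c(t')|`, normalized to
[0, 1]. The extrema map integrates the whole exposure history and is the
best lesion detector of the family.

On the electrophysiology side, ΔF/F traces are extracted per pixel,
drift-corrected on diastolic samples, and reduced to per-cycle activation
time (arg-max of dΔF/dt), APD50/APD80 (time from activation to 50%/80%
repolarization), APA and its change ΔAPA versus the pre-ablation mean,
the triangulation ratio APD50/APD80, maximum upstroke rate, and
conduction-velocity vectors ∇T/|∇T|² from a local plane fit.

Score maps are linked to lesion ground truth (segmented from histology by
L\*a\*b\* k-means + Markov-random-field smoothing, co-registered through
fiducial landmarks) via ROC curves, Youden-optimal thresholds, and
leave-one-out cross-validation across subjects.

## Worked example

```bash
python examples/01_speckle_lesion_detection.py
```

prints

```
envelope sequence: 51 frames of (60, 40), t = 4.00–8.55 s, ablation 4.5–8.5 s
baseline σ̂ ≈ 0.289, final σ̂ inside lesion ≈ 0.540 (the lesion broadens the amplitude distribution)
|Δσ|_max lesion detection: AUC = 0.995, Youden threshold = 0.520 (sens 0.98 / spec 0.97)
per-frame AUC rises 0.42 → 1.00 across the ablation window — detectability grows as the lesion forms.
```

The phantom's lesion ramps its log-normal shape parameter from 0.3 to 0.54
across a 4 s exposure; the windowed σ̂ maps pick this up, and the
cumulative-extrema detector separates lesion from background pixels almost
perfectly, with its per-frame AUC growing as the lesion forms and
plateauing once the exposure ends. The other examples cover the MLE
estimators and goodness of fit (`02`), EP feature recovery from an AP movie
(`03`), histology segmentation and landmark registration (`04`), and
cohort-level threshold training with leave-one-out validation and null
safety (`05`). A thin CLI (`hifumap simulate|usparam|tmaps|epmap|segment|roc`)
exposes the same steps for batch use on TIFF/PNG/CSV artifacts.

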