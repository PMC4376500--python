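# Methods

## Overview

The package implements an oriented, illumination-robust texture descriptor
for breast-ultrasound (BUS) region-of-interest images, together with the
classification protocol used to evaluate it. The premise is clinical:
benign breast tumors tend to present regular, sharply delimited,
homogeneous hypoechoic regions, while malignant tumors present irregular,
blurred, angular borders and heterogeneous internal echoes. That is
*structural* information, and local Fourier **phase** carries structure in
a way that is independent of the gray-scale range of the scanner.

The pipeline is:

1. **Oriented phase congruency (PC).** A bank of log-Gabor quadrature
   filters (S scales × O orientations) produces local amplitude
   `A_{s,o}` and phase `φ_{s,o}` at every pixel. Per orientation the PC
   map is

       PC_o = W_o · ⌊Σ_s A_{s,o} Δφ_{s,o} − T_o⌋ / (Σ_s A_{s,o} + ε)

   with `Δφ = cos(φ − φ̄_o) − |sin(φ − φ̄_o)|` the phase-deviation measure
   relative to the amplitude-weighted mean phase, `W_o` a sigmoid weight
   on the fraction of scales contributing energy
   (`W_o = 1/(1 + exp(α(c − s_o)))`, `s_o = (Σ_s A_s / (A_max + η))/S`),
   `T_o` a noise floor, `⌊·⌋` zeroing of negatives. `PC_o ∈ [0, 1]`,
   large at edges/ridges regardless of contrast.
2. **Pattern encoding.** Each `PC_o` map is encoded with
   rotation-invariant uniform local binary patterns (riu2: P circular
   neighbors thresholded at the center; uniform patterns map to their bit
   count, all others to a single bucket, P+2 codes total) weighted by the
   local neighbor variance (LBPV). The (P+2)-bin histograms are
   L1-normalized per orientation and concatenated: the **PCBP**
   descriptor, 10·O = 80 features at defaults.
3. **Classification.** Features scaled per feature to [−1, 1] on training
   data, RBF-SVM with (C, γ) chosen by grid search under stratified
   10-fold CV, evaluated by leave-one-out CV, by 500-replicate
   out-of-bag bootstrap, and by the cross-contrast scheme (train on
   original images, test on gray-scale-transformed copies).

## Parameters

| parameter | default | meaning |
|---|---|---|
| S | 6 | filter scales |
| O | 8 | orientations, axes at o·π/O |
| λ_min | 3 px | smallest filter wavelength |
| mult | 2.1 | wavelength multiplier between scales |
| σ_onf | 0.55 | radial log-Gaussian bandwidth ratio (~2 octaves) |
| angular spread | 1.2 | angular σ = (π/O)/1.2 |
| c, α | 0.4, 10 | spread-sigmoid cut-off and gain |
| η, ε | 1e-4 | division guards in s_o and PC_o |
| k_noise | 2 | noise threshold at mean + k·σ of the estimated noise energy |
| P, R | 8, 1 | LBP neighbors and radius (P=24, R=3 for the plain-LBP baseline) |
| C, γ grid | 2^{−5..15}, 2^{−15..3}, step 2² | SVM candidates (half-step grid available) |

The PC-specific constants (c, α, η, ε, S, O, P, R) are the reference
configuration for this descriptor; λ_min, mult, σ_onf and the angular
spread are the standard log-Gabor defaults of the widely used PC
implementation, since no single canonical values exist. All are exposed
in `PCBPParams`.

**Noise compensation.** `T_o` is estimated per orientation from the
median amplitude of the smallest-scale filter (Rayleigh-distributed under
Gaussian noise; σ = median/√(ln 4)), extrapolated over scales by the
geometric 1/mult amplitude fall-off, with the threshold at mean +
k_noise·σ of the implied noise-energy distribution. `k_noise = 0`
disables compensation and yields *exact* invariance to linear gray-scale
maps; with compensation on, invariance is still exact for linear maps
because images are min-max normalized to [0, 1] before filtering (which
also fixes the intensity scale that η, ε and T_o assume).

## Numerical choices

- `A·Δφ` is evaluated in the dot/cross-product form
  `(e·ē + o·ō) − |e·ō − o·ē|` with `(ē, ō)` the unit vector along the
  summed quadrature response — algebraically identical to the
  trigonometric form, stable where amplitude ≈ 0, no arctangents.
- The floor `⌊·⌋` and the weight `W_o` are applied to the *summed*
  energy, with `T_o` subtracted once from the sum (the convention of the
  reference PC method); `PC_o ∈ [0, 1]` follows from `Δφ ≤ 1`, `W_o < 1`.
- Filtering is frequency-domain multiplication (periodic boundary),
  images at native size; each radial filter carries a Butterworth
  low-pass (cutoff 0.45, order 15) against Nyquist ringing and is zeroed
  at DC.
- Off-grid LBP neighbors are bilinearly interpolated; offsets within
  1e-9 of an integer are snapped, so e.g. the four axial R=1 neighbors
  are read exactly. The tie rule is s(x ≥ 0) = 1. Differences below
  ~8 ULP of the operand scale are treated as ties and variances below the
  corresponding square as zero, so constant maps yield empty histograms
  rather than floating-point dust.
- Only pixels with a complete circular neighborhood contribute (no
  padding); an all-zero histogram is left unnormalized.
- Constant feature columns scale to 0 in the [−1, 1] scaler; scaling is
  refitted inside every resampling loop (LOO folds, CV folds, bootstrap
  replicates) so no test information leaks into the scaler.
- Grid-search ties break toward smaller C, then smaller γ. Caveat: on
  synthetic data where *every* grid point ties at perfect CV accuracy,
  this selects a maximally regularized model that can behave like a
  majority vote under the one-case class imbalance of LOO; realistic
  feature tables do not produce such universal ties.
- Bootstrap replicates whose out-of-bag set lacks a class are redrawn and
  counted (probability is negligible at n ≈ 138).
- ROC scores are SVM decision-function values; ties count one half
  (trapezoidal AUC). Metrics with zero denominators are reported as NaN,
  never silently 0. Malignant is the positive class.
- LOO experiments default to selecting (C, γ) once on the full table and
  holding them fixed, matching the protocol that fixes grid-searched
  parameters across experiments; fully nested per-fold selection is
  available (`loo_cv(nested_grid=True)`).

## Synthetic phantoms

No public BUS ROI database accompanies this problem, so the generator
emulates the two classes at ROI scale (sizes sampled in 82–330 ×
104–473 px):

- **benign** — centered ellipse (random axes/tilt), tumor mean 0.25–0.35
  vs background 0.55–0.65, border blurred with σ_edge 1–2 px;
- **malignant** — radius modulated by 3–8 random-phase sinusoidal lobes
  (amplitude 15–30 % of radius) plus a second harmonic, σ_edge 3–5 px,
  interior perturbed by a smoothed Gaussian heterogeneity field
  (amplitude 0.15–0.30);
- both multiplied by unit-mean correlated Rayleigh speckle (magnitude of
  smoothed complex Gaussian noise, correlation length 1.5 px), clipped to
  [0, 1].

Every phantom is fully determined by its seed; dataset-level seeds derive
per-image seeds recorded in the manifest.

**What the phantoms do and do not show.** They reproduce the *structural*
class contrasts (border regularity, border sharpness, interior
homogeneity) under multiplicative speckle, which is what the descriptor
claims to measure, and they make the full pipeline testable end to end.
They are not physical ultrasound simulations: no point-spread anisotropy,
attenuation, shadowing or posterior enhancement, and the intensity
statistics are not calibrated against clinical ROIs (none are published
for the original database). Passing the phantom study shows the pipeline
separates the intended morphology under speckle; it does not certify
clinical performance.

## Design choices where the design was open

- Histograms are L1-normalized *per orientation block* before
  concatenation (global vs per-block was open); per-block keeps every
  orientation's mass comparable.
- The plain-LBP baseline uses count-weighted (not variance-weighted) riu2
  histograms on the raw gray image — it is a comparator, not a PCBP
  variant.
- Transform defaults for the robustness experiment: CI to the full [0, 1]
  range, γ = 0.5, HE with 256 bins; all configurable (the families, not
  specific parameter values, define the experiment).
- The cross-contrast experiment is leave-one-out: each held-out case is
  scored by a model trained on the *original* descriptors of the
  remaining cases, once per database, so the Origin report and the
  transformed-database reports are directly comparable case by case.

## Problem sizes used in the shipped experiments

The test suite runs the classification study at 60 + 60 phantoms with
default descriptor parameters (≈ 3–4 minutes total), the permutation-null
check at n = 100, and the PC range check over 50 images; the acceptance
script recomputes the structural quantities (pattern-code counts, metric
worked examples, PC range) over 50 images in well under a minute. The
bootstrap evaluator defaults to B = 500 replicates in the CLI; tests use
smaller B since they assert protocol properties, not clinical effect
sizes.

## Known limitations

- riu2 monotone-intensity invariance is exact only for on-grid neighbor
  offsets; bilinear interpolation does not commute with nonlinear
  monotone maps (the effect is confined to interpolated samples near
  ties).
- With noise compensation on (k_noise = 2), nonlinear gray-scale
  transforms change the speckle amplitude statistics and hence T_o, so
  overall-PC maps of transformed images differ more than in the
  k_noise = 0 regime; the descriptor (variance-weighted, normalized)
  remains stable in practice, which is what the cross-contrast study
  measures.
- Phase congruency under periodic filtering sees the image as a torus:
  strong fictitious edges appear where opposite borders differ. ROIs are
  used at native size without windowing; conclusions near the image
  border should be treated accordingly.
- The grid-search tie-break pathology described above.
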