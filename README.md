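# pcbp — phase congruency-based binary patterns for breast-ultrasound texture classification

Distinguishing benign from malignant breast tumors in B-mode ultrasound
relies on structural cues — border regularity, border sharpness,
homogeneity of the internal echoes — that are easily distorted by the
gray-scale settings of the scanner. `pcbp` implements a texture
descriptor built on local Fourier **phase**, which carries exactly that
structural information while being invariant to monotone changes of
image contrast, and the full protocol for evaluating it as a classifier
input.

It is intended for researchers in ultrasound computer-aided diagnosis
who need an illumination-robust texture representation of tumor
regions-of-interest, and a reproducible evaluation harness around it.

## Method

For an ROI image `I`, a log-Gabor quadrature filter bank (S = 6 scales ×
O = 8 orientations) yields local amplitude `A_{s,o}` and phase `φ_{s,o}`.
The oriented phase congruency at orientation *o* is

```
PC_o(i,j) = W_o(i,j) ⌊Σ_s A_{s,o}(i,j) Δφ_{s,o}(i,j) − T_o⌋ / (Σ_s A_{s,o}(i,j) + ε)
```

with `Δφ = cos(φ − φ̄_o) − |sin(φ − φ̄_o)|`, `W_o` a sigmoid weight on the
spread of filter response over scales, `T_o` a noise floor and `⌊·⌋`
zeroing of negatives; `PC_o ∈ [0, 1]` peaks at edges and ridges
regardless of contrast. Each `PC_o` map is encoded with
rotation-invariant uniform local binary patterns (`riu2`, P = 8 neighbors
at radius R = 1, P + 2 = 10 codes) whose histogram bins accumulate the
local neighbor variance (LBPV). The per-orientation histograms are
L1-normalized and concatenated into the 80-dimensional **PCBP**
descriptor. Classification uses an RBF-SVM (features scaled to [−1, 1],
(C, γ) by grid search under 10-fold CV), evaluated by leave-one-out CV,
out-of-bag bootstrap, and a cross-contrast scheme that trains on original
images and tests on contrast-improved (CI), gamma-corrected (GC) and
histogram-equalized (HE) copies.

Because the clinical database this design targets is not public, the
package ships a seeded phantom generator: benign phantoms are regular
blurred-edge ellipses with homogeneous interiors, malignant phantoms are
spiculated blobs with blurrier borders and heterogeneous interiors, both
under correlated Rayleigh speckle. See `docs/methods.md` for the model,
parameter meanings and limitations.

## Worked example

```python
from pcbp import make_dataset, extract_dataset, grid_search_svm, loo_cv

dataset = make_dataset(60, 60, seed=7)            # 120 labelled phantoms
table = extract_dataset(dataset.images, labels=dataset.labels)
X = table.filter(like="pcbp_").to_numpy(float)    # 120 x 80 features
config = grid_search_svm(X, table["label"], seed=0)
scores, report = loo_cv(X, table["label"], config)
print(f"selected C={config.C:g}, gamma={config.gamma:g} "
      f"(10-fold CV accuracy {config.cv_accuracy:.3f})")
print(f"LOO-CV: AUC={report.auc:.3f}  ACC={report.acc:.3f}  MCC={report.mcc:.3f}")
```

prints

```
selected C=2, gamma=0.03125 (10-fold CV accuracy 0.883)
LOO-CV: AUC=0.939  ACC=0.892  MCC=0.789
```

i.e. the grid search settles on a moderately regularized SVM, and the
descriptor separates the two phantom morphologies with a leave-one-out
AUC of 0.939: the held-out decision scores rank malignant above benign
phantoms in 93.9 % of cross-class pairs. Phantom studies are stochastic;
different master seeds give AUCs varying by several points around this
value.

The same pipeline is available from the shell:

```sh
pcbp simulate --out db --n-benign 69 --n-malignant 69 --seed 0
pcbp extract --manifest db/manifest.csv --images-dir db --out features.csv
pcbp evaluate --features features.csv --mode loo --out results/
pcbp cross-contrast --manifest db/manifest.csv --images-dir db --out results/cc/
```

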