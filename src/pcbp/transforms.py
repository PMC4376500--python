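"""Gray-scale transforms and the cross-contrast train/test scheme.

Ultrasound gray levels depend on adjustable scanner settings, so a texture
descriptor intended for clinical use must tolerate monotone gray-scale
changes.  Three transform families are provided, all operating on
[0, 1]-normalized float images:

* contrast improvement (CI) — affine remapping onto a target range;
* gamma correction (GC) — power-law remapping ``out = in ** gamma``;
* histogram equalization (HE) — CDF-based remapping that spreads the
  intensity distribution over the full range.

The cross-contrast experiment trains the classifier on descriptors of the
original images only and evaluates it on each transformed database,
quantifying how much of the classification performance survives the
gray-scale change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from pcbp.descriptor import PCBPParams, compute_pcbp
from pcbp.evaluation import (
    SVMConfig,
    _as_binary_labels,
    _fit_svm,
    _report_from_scores,
    grid_search_svm,
)

__all__ = [
    "TransformSpec",
    "contrast_improve",
    "gamma_correct",
    "hist_equalize",
    "apply_transform",
    "cross_contrast_experiment",
]


@dataclass(frozen=True)
class TransformSpec:
    """A named gray-scale transform with its parameters.

    kind is one of ``identity``, ``contrast_improve``, ``gamma_correct``,
    ``hist_equalize``; params supplies ``lo``/``hi`` (CI), ``gamma`` (GC)
    or ``bins`` (HE).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        kinds = ("identity", "contrast_improve", "gamma_correct", "hist_equalize")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}, got {self.kind!r}")
        if self.kind == "contrast_improve":
            lo = self.params.get("lo", 0.0)
            hi = self.params.get("hi", 1.0)
            if not lo < hi:
                raise ValueError("contrast_improve requires lo < hi")
        if self.kind == "gamma_correct" and self.params.get("gamma", 0.5) <= 0:
            raise ValueError("gamma must be > 0")
        if self.kind == "hist_equalize" and self.params.get("bins", 256) < 2:
            raise ValueError("bins must be >= 2")


def contrast_improve(image: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine gray-scale remap sending input min -> lo and max -> hi."""
    image = np.asarray(image, dtype=float)
    if lo >= hi:
        raise ValueError("lo must be < hi")
    imin, imax = image.min(), image.max()
    if imin == imax:
        raise ValueError("constant image: contrast improvement is undefined")
    return lo + (image - imin) * (hi - lo) / (imax - imin)


def gamma_correct(image: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """Power-law remap ``out = in ** gamma`` of a [0, 1] image."""
    image = np.asarray(image, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("gamma correction expects values in [0, 1]")
    return image**gamma


def hist_equalize(image: np.ndarray, bins: int = 256) -> np.ndarray:
    """Histogram equalization via the empirical CDF (monotone non-decreasing)."""
    image = np.asarray(image, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if image.min() == image.max():
        return np.full_like(image, 0.5)
    return exposure.equalize_hist(image, nbins=bins)


def apply_transform(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.kind == "identity":
        return np.asarray(image, dtype=float)
    if spec.kind == "contrast_improve":
        return contrast_improve(
            image, spec.params.get("lo", 0.0), spec.params.get("hi", 1.0)
        )
    if spec.kind == "gamma_correct":
        return gamma_correct(image, spec.params.get("gamma", 0.5))
    return hist_equalize(image, spec.params.get("bins", 256))


def default_transforms() -> dict[str, TransformSpec]:
    """The CI/GC/HE databases at representative settings."""
    return {
        "CI": TransformSpec("contrast_improve", {"lo": 0.0, "hi": 1.0}),
        "GC": TransformSpec("gamma_correct", {"gamma": 0.5}),
        "HE": TransformSpec("hist_equalize", {"bins": 256}),
    }


def cross_contrast_experiment(
    images,
    labels,
    transforms: dict[str, TransformSpec] | None = None,
    params: PCBPParams | None = None,
    config: SVMConfig | None = None,
    seed: int = 0,
):
    """Train on original-image features, test on gray-scale-transformed ones.

    Runs leave-one-out over the cases: for each held-out case the feature
    scaler and SVM are fitted on the *original* descriptors of the remaining
    cases, then the held-out case is scored once per database (Origin plus
    each transform).  Returns ``{database_name: EvalReport}`` with the
    Origin report first.

    If ``config`` is None the SVM parameters are chosen once by 10-fold
    grid search on the original-image features.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    y = _as_binary_labels(labels)
    if len(images) != y.size:
        raise ValueError("number of images and labels differ")
    if params is None:
        params = PCBPParams()
    if transforms is None:
        transforms = default_transforms()

    features = {"Origin": np.vstack([compute_pcbp(im, params).values for im in images])}
    for name, spec in transforms.items():
        features[name] = np.vstack(
            [compute_pcbp(apply_transform(im, spec), params).values for im in images]
        )

    if config is None:
        config = grid_search_svm(features["Origin"], y, seed=seed)

    n = y.size
    scores = {name: np.empty(n) for name in features}
    preds = {name: np.empty(n, dtype=int) for name in features}
    for i in range(n):
        train = np.delete(np.arange(n), i)
        model = _fit_svm(features["Origin"][train], y[train], config)
        for name, X in features.items():
            s = model.decision_function(X[i : i + 1])[0]
            scores[name][i] = s
            preds[name][i] = int(s > 0)

    return {
        name: _report_from_scores(y, scores[name], preds[name]) for name in features
    }
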