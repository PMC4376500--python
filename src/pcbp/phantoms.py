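"""Synthetic breast-ultrasound speckle phantoms.

The clinical database this pipeline targets is not publicly deposited, so
the generator emulates its two tumor classes at region-of-interest scale:

* **benign** — a centered regular ellipse with a smooth, sharply defined
  border and homogeneous hypoechoic interior;
* **malignant** — an irregular blob whose radius is perturbed by low-order
  sinusoidal lobes (angular "spiculation"), with a more blurred border and
  a heterogeneous interior echo pattern.

Both classes are multiplied by a correlated Rayleigh speckle field, the
standard surrogate for fully developed ultrasound speckle.  Image sizes are
sampled within the ROI range of real clinical crops (82-330 rows by
104-473 columns).  All randomness is driven by explicit seeds, so datasets
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "Phantom",
    "PhantomDataset",
    "speckle_field",
    "make_phantom",
    "make_dataset",
    "boundary_band",
    "DEFAULT_SIZE_RANGE",
]

#: default ROI size range: ((min_rows, max_rows), (min_cols, max_cols))
DEFAULT_SIZE_RANGE = ((82, 330), (104, 473))


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one phantom deterministically.

    Intensities are on the [0, 1] scale; the tumor is hypoechoic (darker
    than background).  ``edge_sigma`` is the Gaussian blur (pixels) applied
    to the ideal two-level image, modelling border sharpness.  The
    irregularity/heterogeneity fields are zero for benign specs.
    """

    class_label: str
    rows: int
    cols: int
    tumor_mean: float = 0.30
    background_mean: float = 0.60
    edge_sigma: float = 1.5
    irregularity: float = 0.0  # radius modulation amplitude (fraction of radius)
    n_lobes: int = 0  # sinusoidal lobe count of the modulation
    heterogeneity: float = 0.0  # interior echo inhomogeneity amplitude
    speckle_strength: float = 1.0
    speckle_corr: float = 1.5  # speckle correlation length, pixels
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in ("benign", "malignant"):
            raise ValueError("class_label must be 'benign' or 'malignant'")
        if self.rows < 16 or self.cols < 16:
            raise ValueError("phantom must be at least 16x16 pixels")
        if self.class_label == "benign" and (
            self.irregularity != 0 or self.heterogeneity != 0
        ):
            raise ValueError("benign specs must have zero irregularity/heterogeneity")
        if not 0 <= self.tumor_mean <= 1 or not 0 <= self.background_mean <= 1:
            raise ValueError("mean echogenicities must lie in [0, 1]")
        if self.edge_sigma < 0 or self.speckle_corr < 1:
            raise ValueError("edge_sigma >= 0 and speckle_corr >= 1 required")


@dataclass
class Phantom:
    image: np.ndarray  # float in [0, 1]
    tumor_mask: np.ndarray  # bool, ideal (pre-blur) tumor support
    spec: PhantomSpec


@dataclass
class PhantomDataset:
    images: list
    labels: list
    masks: list
    manifest: pd.DataFrame


def speckle_field(
    rows: int,
    cols: int,
    correlation_length: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Unit-mean multiplicative Rayleigh speckle field.

    The magnitude of circular complex Gaussian noise is Rayleigh
    distributed; smoothing the complex field before taking the magnitude
    introduces spatial correlation on the requested length scale.  The
    field is divided by its sample mean, so it is exactly unit mean.
    """
    if correlation_length < 1:
        raise ValueError("correlation length must be >= 1 pixel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    re = rng.standard_normal((rows, cols))
    im = rng.standard_normal((rows, cols))
    if correlation_length > 1:
        sigma = correlation_length / 2.0
        re = ndimage.gaussian_filter(re, sigma, mode="wrap")
        im = ndimage.gaussian_filter(im, sigma, mode="wrap")
    field = np.hypot(re, im)
    return field / field.mean()


def _radius_modulation(theta: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    """Angular boundary perturbation for malignant phantoms, peak-normalized."""
    if spec.irregularity == 0 or spec.n_lobes == 0:
        return np.zeros_like(theta)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    mod = np.sin(spec.n_lobes * theta + phase1) + 0.5 * np.sin(
        (spec.n_lobes + 3) * theta + phase2
    )
    return spec.irregularity * mod / np.abs(mod).max()


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom image and its ideal tumor-support mask."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols

    # tumor axes: scaled to the ROI so the lesion fills its center
    a = 0.5 * cols * rng.uniform(0.45, 0.62)
    b = 0.5 * rows * rng.uniform(0.45, 0.62)
    tilt = rng.uniform(0.0, np.pi)

    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx - (cols - 1) / 2.0
    y = yy - (rows - 1) / 2.0
    xr = x * np.cos(tilt) + y * np.sin(tilt)
    yr = -x * np.sin(tilt) + y * np.cos(tilt)
    rho = np.hypot(xr / a, yr / b)  # elliptical radius, boundary near 1
    theta = np.arctan2(yr, xr)

    boundary = 1.0 + _radius_modulation(theta, spec, rng)
    mask = rho <= boundary

    base = np.where(mask, spec.tumor_mean, spec.background_mean).astype(float)
    if spec.heterogeneity > 0:
        texture = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), 6.0, mode="reflect"
        )
        texture *= spec.heterogeneity / (3.0 * texture.std())
        base = np.where(mask, np.clip(base + texture, 0.02, 0.98), base)
    if spec.edge_sigma > 0:
        base = ndimage.gaussian_filter(base, spec.edge_sigma, mode="reflect")

    speckle = speckle_field(rows, cols, spec.speckle_corr, rng)
    image = base * (1.0 + spec.speckle_strength * (speckle - 1.0))
    return Phantom(image=np.clip(image, 0.0, 1.0), tumor_mask=mask, spec=spec)


def boundary_band(mask: np.ndarray, width: int = 3) -> np.ndarray:
    """Band of ``width`` pixels straddling the mask boundary on both sides."""
    return ndimage.binary_dilation(mask, iterations=width) & ~ndimage.binary_erosion(
        mask, iterations=width
    )


def _sample_spec(label: str, rng: np.random.Generator, size_range, seed: int) -> PhantomSpec:
    (rmin, rmax), (cmin, cmax) = size_range
    rows = int(rng.integers(rmin, rmax + 1))
    cols = int(rng.integers(cmin, cmax + 1))
    common = dict(
        rows=rows,
        cols=cols,
        tumor_mean=float(rng.uniform(0.25, 0.35)),
        background_mean=float(rng.uniform(0.55, 0.65)),
        seed=seed,
    )
    if label == "benign":
        return PhantomSpec(
            class_label="benign",
            edge_sigma=float(rng.uniform(1.0, 2.0)),
            **common,
        )
    return PhantomSpec(
        class_label="malignant",
        edge_sigma=float(rng.uniform(3.0, 5.0)),
        irregularity=float(rng.uniform(0.15, 0.30)),
        n_lobes=int(rng.integers(3, 9)),
        heterogeneity=float(rng.uniform(0.15, 0.30)),
        **common,
    )


def make_dataset(
    n_benign: int = 69,
    n_malignant: int = 69,
    seed: int = 0,
    size_range=DEFAULT_SIZE_RANGE,
) -> PhantomDataset:
    """Generate a labelled phantom database with a manifest.

    Per-image seeds and spec parameters are drawn deterministically from
    the master seed, so the same call reproduces the same images bit for
    bit.  The default 69 + 69 split mirrors a balanced 138-case database.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one phantom per class")
    master = np.random.default_rng(seed)
    images, labels, masks, rows = [], [], [], []
    for k in range(n_benign + n_malignant):
        label = "benign" if k < n_benign else "malignant"
        img_seed = int(master.integers(0, 2**31 - 1))
        spec = _sample_spec(label, master, size_range, img_seed)
        phantom = make_phantom(spec)
        images.append(phantom.image)
        labels.append(label)
        masks.append(phantom.tumor_mask)
        rows.append(
            {
                "id": f"{label}_{k:04d}",
                "label": label,
                "rows": spec.rows,
                "cols": spec.cols,
                "seed": img_seed,
            }
        )
    return PhantomDataset(
        images=images, labels=labels, masks=masks, manifest=pd.DataFrame(rows)
    )
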