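"""Assembly of the PCBP texture descriptor and the plain-LBP baseline.

The phase congruency-based binary pattern (PCBP) descriptor of an image is
formed by computing the O oriented phase-congruency maps, encoding each map
with a variance-weighted rotation-invariant uniform LBP histogram (P + 2
bins), L1-normalizing each histogram, and concatenating them in orientation
order.  Under the default configuration (S = 6 scales, O = 8 orientations,
P = 8 neighbors at radius R = 1) this yields an 80-dimensional feature
vector per image.

The plain-LBP baseline (P = 24, R = 3, count-weighted riu2 histogram on the
raw gray image, 26 bins) is provided as a comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pcbp.patterns import NeighborhoodSpec, lbpv_histogram, riu2_histogram
from pcbp.pc import build_log_gabor_bank, oriented_pc

__all__ = [
    "PCBPParams",
    "PCBPDescriptor",
    "compute_pcbp",
    "compute_lbp_baseline",
    "extract_dataset",
    "ExtractionError",
]


@dataclass(frozen=True)
class PCBPParams:
    """Full configuration of the PCBP descriptor.

    The defaults are the reference configuration: six filter scales, eight
    orientations, an 8-neighbor radius-1 LBP neighborhood, weighting-sigmoid
    cut-off 0.4 with gain 10, and eta = epsilon = 1e-4.
    """

    n_scales: int = 6
    n_orientations: int = 8
    n_neighbors: int = 8
    radius: float = 1.0
    wavelength_min: float = 3.0
    mult: float = 2.1
    sigma_onf: float = 0.55
    angular_spread: float = 1.2
    cutoff: float = 0.4
    gain: float = 10.0
    eta: float = 1e-4
    epsilon: float = 1e-4
    k_noise: float = 2.0
    normalize_input: bool = True

    @property
    def n_features(self) -> int:
        """Descriptor length: (P + 2) bins per orientation."""
        return (self.n_neighbors + 2) * self.n_orientations

    def neighborhood(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(self.n_neighbors, self.radius)

    def with_updates(self, **kwargs) -> "PCBPParams":
        return replace(self, **kwargs)


@dataclass
class PCBPDescriptor:
    """Concatenated per-orientation LBPV histograms of one image."""

    values: np.ndarray
    params: PCBPParams = field(repr=False)

    def __len__(self) -> int:
        return self.values.size

    def orientation_block(self, o: int) -> np.ndarray:
        """The (P + 2)-bin histogram of orientation channel ``o``."""
        k = self.params.n_neighbors + 2
        return self.values[o * k : (o + 1) * k]


def compute_pcbp(image: np.ndarray, params: PCBPParams | None = None) -> PCBPDescriptor:
    """Compute the PCBP descriptor of a 2-D gray image.

    Pipeline: oriented phase congruency -> per-orientation LBPV histogram
    (L1-normalized) -> concatenation in orientation order.
    """
    if params is None:
        params = PCBPParams()
    image = np.asarray(image, dtype=float)
    bank = build_log_gabor_bank(
        image.shape[0],
        image.shape[1],
        n_scales=params.n_scales,
        n_orientations=params.n_orientations,
        wavelength_min=params.wavelength_min,
        mult=params.mult,
        sigma_onf=params.sigma_onf,
        angular_spread=params.angular_spread,
    )
    stack = oriented_pc(
        image,
        bank,
        cutoff=params.cutoff,
        gain=params.gain,
        eta=params.eta,
        epsilon=params.epsilon,
        k_noise=params.k_noise,
        normalize=params.normalize_input,
    )
    spec = params.neighborhood()
    blocks = [
        lbpv_histogram(stack.pc[o], spec, normalize=True).bins
        for o in range(params.n_orientations)
    ]
    return PCBPDescriptor(values=np.concatenate(blocks), params=params)


def compute_lbp_baseline(
    image: np.ndarray, n_neighbors: int = 24, radius: float = 3.0
) -> np.ndarray:
    """Plain-LBP baseline: normalized riu2 occurrence histogram on the raw
    gray image (length P + 2; 26 features at the default P = 24, R = 3)."""
    spec = NeighborhoodSpec(n_neighbors, radius)
    return riu2_histogram(np.asarray(image, dtype=float), spec, normalize=True).bins


class ExtractionError(RuntimeError):
    """Raised when any image in a batch fails; carries per-image causes."""

    def __init__(self, failures: dict):
        self.failures = failures
        detail = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"feature extraction failed for {len(failures)} image(s): {detail}")


def extract_dataset(
    images,
    params: PCBPParams | None = None,
    ids=None,
    labels=None,
    descriptor: str = "pcbp",
) -> pd.DataFrame:
    """Feature table for a list of images: one descriptor row per image.

    Columns are ``image_id``, ``label`` then ``pcbp_0 ... pcbp_{D-1}`` (or
    ``lbp_0 ...`` for the baseline).  If any image fails, an
    :class:`ExtractionError` naming every failing image is raised; partial
    tables are never returned.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    if params is None:
        params = PCBPParams()
    if ids is None:
        ids = [f"img_{k:04d}" for k in range(len(images))]
    if labels is None:
        labels = [""] * len(images)
    if not (len(ids) == len(labels) == len(images)):
        raise ValueError("images, ids and labels must have equal length")

    if descriptor == "pcbp":
        prefix, width = "pcbp", params.n_features
        fn = lambda img: compute_pcbp(img, params).values
    elif descriptor in ("lbp", "lbp24"):
        prefix, width = "lbp", 26
        fn = lambda img: compute_lbp_baseline(img)
    else:
        raise ValueError(f"unknown descriptor {descriptor!r}")

    rows, failures = [], {}
    for img_id, label, img in zip(ids, labels, images):
        try:
            rows.append(fn(img))
        except Exception as exc:  # noqa: BLE001 - reported per image
            failures[img_id] = repr(exc)
    if failures:
        raise ExtractionError(failures)

    table = pd.DataFrame(
        np.vstack(rows), columns=[f"{prefix}_{k}" for k in range(width)]
    )
    table.insert(0, "label", list(labels))
    table.insert(0, "image_id", list(ids))
    return table
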