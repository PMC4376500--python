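"""Rotation-invariant uniform local binary patterns and LBPV histograms.

A local binary pattern (LBP) thresholds the ``P`` circular neighbors of a
pixel at the center value and reads the comparison results as a ``P``-bit
code.  Restricting to *uniform* patterns (at most two 0/1 transitions
around the circle) and mapping each uniform pattern to its count of set
bits — all others to a single non-uniform bucket ``P + 1`` — yields the
rotation-invariant uniform (``riu2``) code with exactly ``P + 2`` distinct
values.

The LBP-variance (LBPV) histogram accumulates, in each pattern's bin, the
local variance of the neighborhood instead of a unit count, so that
high-contrast micro-structures contribute proportionally more.  Applied to
oriented phase-congruency maps these histograms form the building blocks of
the PCBP descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeighborhoodSpec",
    "PatternMaps",
    "LBPVHistogram",
    "sample_neighbors",
    "initial_code",
    "uniformity",
    "riu2_code",
    "local_variance",
    "pattern_maps",
    "lbpv_histogram",
    "riu2_histogram",
]

# offsets within this distance of an integer are snapped, so that e.g. the
# four axial neighbors at R=1 are read without interpolation
_SNAP_TOL = 1e-9


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling neighborhood: ``n_neighbors`` points at ``radius``.

    Neighbor ``p`` sits at angle ``2*pi*p / P`` on the circle, starting on
    the positive column axis and proceeding counter-clockwise in image
    coordinates (row offset ``-R*sin``, column offset ``+R*cos``).
    """

    n_neighbors: int = 8
    radius: float = 1.0

    def __post_init__(self):
        if self.n_neighbors < 4:
            raise ValueError("n_neighbors must be >= 4")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def n_codes(self) -> int:
        """Number of distinct riu2 codes: P + 2."""
        return self.n_neighbors + 2

    def offsets(self) -> np.ndarray:
        """(P, 2) array of (row, col) offsets, near-integers snapped."""
        p = np.arange(self.n_neighbors)
        ang = 2.0 * np.pi * p / self.n_neighbors
        off = np.stack([-self.radius * np.sin(ang), self.radius * np.cos(ang)], axis=1)
        rounded = np.round(off)
        snap = np.abs(off - rounded) < _SNAP_TOL
        off[snap] = rounded[snap]
        return off

    @property
    def margin(self) -> int:
        """Border width (pixels) lacking a complete neighborhood."""
        return int(np.ceil(self.radius))


@dataclass
class PatternMaps:
    """Per-pixel riu2 codes and local variances for one 2-D map.

    ``riu2`` and ``var`` have the dimensions of the input map; only pixels
    where ``valid_mask`` is True carry a complete circular neighborhood
    (no padding is used — border values are zero and must be ignored).
    """

    riu2: np.ndarray  # int codes in {0..P+1}
    var: np.ndarray  # non-negative local variances
    valid_mask: np.ndarray  # bool
    spec: NeighborhoodSpec


@dataclass
class LBPVHistogram:
    """Variance-weighted pattern histogram of length P + 2."""

    bins: np.ndarray
    n_neighbors: int
    radius: float
    normalized: bool


def _bilinear_at(image: np.ndarray, i: float, j: float) -> float:
    i0, j0 = int(np.floor(i)), int(np.floor(j))
    ti, tj = i - i0, j - j0
    if ti == 0 and tj == 0:
        return float(image[i0, j0])
    i1 = min(i0 + 1, image.shape[0] - 1)
    j1 = min(j0 + 1, image.shape[1] - 1)
    return float(
        (1 - ti) * (1 - tj) * image[i0, j0]
        + (1 - ti) * tj * image[i0, j1]
        + ti * (1 - tj) * image[i1, j0]
        + ti * tj * image[i1, j1]
    )


def sample_neighbors(
    image: np.ndarray, i: int, j: int, spec: NeighborhoodSpec
) -> np.ndarray:
    """The P circular neighbor values around pixel (i, j).

    Off-grid positions are bilinearly interpolated; positions that fall
    exactly on the grid are read directly.  The center must be at least
    ``spec.margin`` pixels from every border.
    """
    image = np.asarray(image, dtype=float)
    m = spec.margin
    if not (m <= i < image.shape[0] - m and m <= j < image.shape[1] - m):
        raise IndexError(
            f"center ({i}, {j}) lacks a complete radius-{spec.radius} "
            f"neighborhood in a {image.shape} map"
        )
    return np.array([_bilinear_at(image, i + di, j + dj) for di, dj in spec.offsets()])


def initial_code(g_c: float, neighbors: np.ndarray) -> int:
    """Plain LBP code: sum of s(g_p - g_c) * 2^p with s(x) = 1 iff x >= 0."""
    bits = (np.asarray(neighbors, dtype=float) >= g_c).astype(np.int64)
    return int((bits << np.arange(bits.size)).sum())


def uniformity(bits: np.ndarray) -> int:
    """Number of 0/1 transitions around the circular bit sequence."""
    bits = np.asarray(bits).astype(np.int64)
    return int(np.abs(bits - np.roll(bits, 1)).sum())


def riu2_code(g_c: float, neighbors: np.ndarray) -> int:
    """Rotation-invariant uniform code: bit count if uniform, else P + 1."""
    bits = (np.asarray(neighbors, dtype=float) >= g_c).astype(np.int64)
    if uniformity(bits) <= 2:
        return int(bits.sum())
    return bits.size + 1


def local_variance(neighbors: np.ndarray) -> float:
    """Population variance (1/P normalization) of the P neighbor values."""
    g = np.asarray(neighbors, dtype=float)
    return float(np.mean((g - g.mean()) ** 2))


def _neighbor_stack(image: np.ndarray, spec: NeighborhoodSpec) -> np.ndarray:
    """(P, H, W) stack of neighbor values over the valid interior window.

    Each neighbor offset is constant over the image, so bilinear sampling
    reduces to a fixed 4-tap blend of shifted views — exact and fast.
    """
    m = spec.margin
    rows, cols = image.shape
    h, w = rows - 2 * m, cols - 2 * m
    out = np.empty((spec.n_neighbors, h, w))
    for p, (di, dj) in enumerate(spec.offsets()):
        i0, j0 = int(np.floor(di)), int(np.floor(dj))
        ti, tj = di - i0, dj - j0
        base_i, base_j = m + i0, m + j0

        def window(a: int, b: int) -> np.ndarray:
            return image[base_i + a : base_i + a + h, base_j + b : base_j + b + w]

        if ti == 0 and tj == 0:
            out[p] = window(0, 0)
        else:
            out[p] = (
                (1 - ti) * (1 - tj) * window(0, 0)
                + (1 - ti) * tj * window(0, 1)
                + ti * (1 - tj) * window(1, 0)
                + ti * tj * window(1, 1)
            )
    return out


def pattern_maps(image: np.ndarray, spec: NeighborhoodSpec) -> PatternMaps:
    """riu2 code map and local-variance map for every interior pixel."""
    image = np.asarray(image, dtype=float)
    m = spec.margin
    if image.ndim != 2 or min(image.shape) < 2 * m + 1:
        raise ValueError(
            f"map of shape {image.shape} too small for radius {spec.radius}"
        )
    neighbors = _neighbor_stack(image, spec)
    center = image[m : image.shape[0] - m, m : image.shape[1] - m]

    # differences below the rounding error of the bilinear blend are ties;
    # without this, a constant map yields spurious codes and variances
    tol = 8 * np.finfo(float).eps * np.maximum(
        np.abs(center), np.abs(neighbors).max(axis=0)
    )
    bits = (neighbors - center >= -tol).astype(np.int64)
    transitions = np.abs(bits - np.roll(bits, 1, axis=0)).sum(axis=0)
    codes = np.where(transitions <= 2, bits.sum(axis=0), spec.n_neighbors + 1)

    mean = neighbors.mean(axis=0)
    var = ((neighbors - mean) ** 2).mean(axis=0)
    var[var <= tol**2] = 0.0

    riu2 = np.zeros(image.shape, dtype=np.int64)
    var_full = np.zeros(image.shape)
    valid = np.zeros(image.shape, dtype=bool)
    sl = (slice(m, image.shape[0] - m), slice(m, image.shape[1] - m))
    riu2[sl] = codes
    var_full[sl] = var
    valid[sl] = True
    return PatternMaps(riu2=riu2, var=var_full, valid_mask=valid, spec=spec)


def lbpv_histogram(
    image: np.ndarray, spec: NeighborhoodSpec, normalize: bool = True
) -> LBPVHistogram:
    """Variance-weighted riu2 histogram (LBPV) of a 2-D map.

    Bin ``k`` accumulates the local variance of every valid pixel whose
    riu2 code equals ``k``; with ``normalize`` the bins are divided by
    their total mass (an all-zero histogram is left untouched).
    """
    maps = pattern_maps(image, spec)
    bins = np.bincount(
        maps.riu2[maps.valid_mask],
        weights=maps.var[maps.valid_mask],
        minlength=spec.n_codes,
    ).astype(float)
    if normalize:
        total = bins.sum()
        if total > 0:
            bins = bins / total
    return LBPVHistogram(
        bins=bins,
        n_neighbors=spec.n_neighbors,
        radius=spec.radius,
        normalized=normalize,
    )


def riu2_histogram(
    image: np.ndarray, spec: NeighborhoodSpec, normalize: bool = True
) -> LBPVHistogram:
    """Count-based riu2 occurrence histogram (the plain-LBP statistic)."""
    maps = pattern_maps(image, spec)
    bins = np.bincount(maps.riu2[maps.valid_mask], minlength=spec.n_codes).astype(float)
    if normalize:
        total = bins.sum()
        if total > 0:
            bins = bins / total
    return LBPVHistogram(
        bins=bins,
        n_neighbors=spec.n_neighbors,
        radius=spec.radius,
        normalized=normalize,
    )
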