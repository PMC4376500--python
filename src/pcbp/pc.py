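"""Oriented phase congruency via a log-Gabor quadrature filter bank.

Phase congruency (PC) is a dimensionless measure of how well the local
Fourier components of an image agree in phase at each pixel.  It is maximal
at step edges and ridges and, unlike gradient magnitude, is invariant to
linear changes of image contrast, which makes it attractive for ultrasound
images whose gray-scale range depends on scanner settings.

The local frequency information is obtained from a bank of log-Gabor filters
in quadrature: for each scale ``s`` and orientation ``o`` the image is
filtered with a complex analytic filter whose real and imaginary parts are
the even- and odd-symmetric members of the pair.  Writing ``e`` and ``o``
for those responses, the local amplitude is ``A = sqrt(e^2 + o^2)`` and the
local phase is ``atan2(o, e)``.  Per orientation the oriented phase
congruency is

    PC_o(i,j) = W_o(i,j) * max(sum_s A_{s,o} * dphi_{s,o} - T_o, 0)
                / (sum_s A_{s,o} + epsilon)

where ``dphi`` is a phase-deviation measure combining the cosine and the
(absolute) sine of the deviation from the amplitude-weighted mean phase,
``W_o`` is a sigmoid weighting that penalizes responses concentrated in a
narrow range of frequencies, and ``T_o`` is an orientation-specific noise
compensation term estimated from the smallest-scale filter response.
Every PC_o value lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogGaborBank",
    "QuadratureResponse",
    "OrientedPCStack",
    "build_log_gabor_bank",
    "quadrature_responses",
    "spread_weight",
    "noise_threshold",
    "oriented_pc",
    "overall_pc",
    "normalize_image",
]

#: Butterworth low-pass applied to every radial filter to suppress ringing
#: from frequencies near the Nyquist boundary (cutoff as a fraction of the
#: Nyquist frequency, filter order).
_LOWPASS_CUTOFF = 0.45
_LOWPASS_ORDER = 15


@dataclass(frozen=True)
class LogGaborBank:
    """A frequency-domain bank of S x O complex-analytic log-Gabor filters.

    Each transfer function is real and non-negative with zero DC response;
    filtering an image with it (multiply in the frequency domain, inverse
    transform) yields the complex quadrature response whose real/imaginary
    parts are the even/odd filter outputs.
    """

    rows: int
    cols: int
    n_scales: int
    n_orientations: int
    wavelength_min: float
    mult: float
    sigma_onf: float
    angular_spread: float
    #: transfer[s][o], each of shape (rows, cols), unshifted FFT layout
    transfer: tuple = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def wavelength(self, s: int) -> float:
        """Center wavelength (pixels) of scale ``s`` (0-based)."""
        return self.wavelength_min * self.mult**s

    def orientation_angle(self, o: int) -> float:
        """Filter-axis angle of orientation channel ``o`` (0-based).

        Channel ``o`` sits at angle ``o * pi / O``; channel 0 responds
        maximally to intensity variation along image columns, i.e. to
        vertical edges.
        """
        return o * np.pi / self.n_orientations


@dataclass
class QuadratureResponse:
    """Even/odd quadrature filter outputs with amplitude and phase.

    All stacks have shape (S, O, rows, cols); ``a_max`` has shape
    (O, rows, cols) and holds the per-orientation maximum amplitude over
    scales.
    """

    even: np.ndarray
    odd: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    a_max: np.ndarray


@dataclass
class OrientedPCStack:
    """Per-orientation phase congruency maps and their by-products."""

    pc: np.ndarray  # (O, rows, cols), values in [0, 1]
    weights: np.ndarray  # (O, rows, cols), frequency-spread weights W_o
    noise_t: np.ndarray  # (O,) noise compensation terms T_o
    params: dict

    @property
    def n_orientations(self) -> int:
        return self.pc.shape[0]


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Affinely map an image onto [0, 1]; a constant image maps to zeros.

    Performed before filtering so that the small constants (eta, epsilon)
    and the noise threshold operate on a fixed intensity scale, and so that
    any linear gray-scale transform of the input leaves the result
    unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo = image.min()
    rng = image.max() - lo
    if rng == 0:
        return np.zeros_like(image)
    return (image - lo) / rng


def build_log_gabor_bank(
    rows: int,
    cols: int,
    n_scales: int = 6,
    n_orientations: int = 8,
    wavelength_min: float = 3.0,
    mult: float = 2.1,
    sigma_onf: float = 0.55,
    angular_spread: float = 1.2,
) -> LogGaborBank:
    """Construct the S x O log-Gabor transfer functions for an image size.

    Parameters
    ----------
    rows, cols
        Target image dimensions in pixels (>= 8 each).
    n_scales, n_orientations
        Number of filter scales S and orientations O.
    wavelength_min
        Wavelength of the smallest-scale filter, in pixels (>= 2).
    mult
        Scaling factor between successive filter wavelengths (> 1).
    sigma_onf
        Ratio of the radial Gaussian sigma (on the log-frequency axis) to
        the filter center frequency; 0.55 gives about two octaves of
        bandwidth.
    angular_spread
        Ratio controlling the angular Gaussian width: the angular sigma is
        ``(pi / O) / angular_spread``.
    """
    if rows < 8 or cols < 8:
        raise ValueError(f"image dimensions must be >= 8, got {rows}x{cols}")
    if n_scales < 1 or n_orientations < 1:
        raise ValueError("n_scales and n_orientations must be >= 1")
    if wavelength_min < 2:
        raise ValueError("wavelength_min must be >= 2 pixels")
    if mult <= 1:
        raise ValueError("mult must be > 1")

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC sample is zeroed below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    lowpass = 1.0 / (1.0 + (radius / _LOWPASS_CUTOFF) ** (2 * _LOWPASS_ORDER))

    radial = []
    log_sigma = np.log(sigma_onf)
    for s in range(n_scales):
        f0 = 1.0 / (wavelength_min * mult**s)
        g = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma**2))
        g *= lowpass
        g[0, 0] = 0.0
        radial.append(g)

    theta_sigma = (np.pi / n_orientations) / angular_spread
    spreads = []
    for o in range(n_orientations):
        angle = o * np.pi / n_orientations
        # angular distance on the circle between each frequency sample's
        # direction and the filter axis
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta**2) / (2.0 * theta_sigma**2)))

    transfer = tuple(
        tuple(radial[s] * spreads[o] for o in range(n_orientations))
        for s in range(n_scales)
    )
    return LogGaborBank(
        rows=rows,
        cols=cols,
        n_scales=n_scales,
        n_orientations=n_orientations,
        wavelength_min=wavelength_min,
        mult=mult,
        sigma_onf=sigma_onf,
        angular_spread=angular_spread,
        transfer=transfer,
    )


def _filtered(image_fft: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Complex quadrature response of one filter (frequency-domain product)."""
    return np.fft.ifft2(image_fft * transfer)


def quadrature_responses(image: np.ndarray, bank: LogGaborBank) -> QuadratureResponse:
    """Even/odd responses, amplitude and phase for every (scale, orientation).

    The filtering is periodic (frequency-domain multiplication).  Intended
    for inspection and testing; :func:`oriented_pc` streams the same
    responses orientation by orientation to bound memory.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != bank.shape:
        raise ValueError(f"image shape {image.shape} != bank shape {bank.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    S, O = bank.n_scales, bank.n_orientations
    image_fft = np.fft.fft2(image)
    even = np.empty((S, O) + image.shape)
    odd = np.empty_like(even)
    for s in range(S):
        for o in range(O):
            resp = _filtered(image_fft, bank.transfer[s][o])
            even[s, o] = resp.real
            odd[s, o] = resp.imag
    amplitude = np.hypot(even, odd)
    phase = np.arctan2(odd, even)
    return QuadratureResponse(
        even=even,
        odd=odd,
        amplitude=amplitude,
        phase=phase,
        a_max=amplitude.max(axis=0),
    )


def spread_weight(
    amplitudes: np.ndarray, cutoff: float = 0.4, gain: float = 10.0, eta: float = 1e-4
) -> np.ndarray:
    """Frequency-spread weighting W_o for one orientation.

    ``amplitudes`` is the (S, rows, cols) stack of filter amplitudes at one
    orientation.  The spread fraction ``s_o = (sum_s A_s / (A_max + eta)) / S``
    is near 1 when all scales respond equally (a true step edge) and near
    1/S when a single scale dominates; the sigmoid
    ``W = 1 / (1 + exp(gain * (cutoff - s_o)))`` suppresses the latter.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim != 3 or amplitudes.shape[0] < 1:
        raise ValueError("amplitudes must be an (S, rows, cols) stack")
    if eta <= 0:
        raise ValueError("eta must be positive")
    S = amplitudes.shape[0]
    spread = (amplitudes.sum(axis=0) / (amplitudes.max(axis=0) + eta)) / S
    return 1.0 / (1.0 + np.exp(gain * (cutoff - spread)))


def noise_threshold(
    smallest_scale_amplitude: np.ndarray,
    n_scales: int,
    mult: float,
    k_noise: float = 2.0,
) -> float:
    """Orientation-specific noise compensation term T_o.

    Under additive Gaussian image noise the amplitude response of a single
    quadrature filter is Rayleigh distributed.  The Rayleigh scale is
    estimated robustly from the median amplitude of the *smallest-scale*
    filter (whose pass-band carries the least signal energy relative to
    noise), extrapolated to the total noise energy summed over scales using
    the geometric amplitude fall-off ``1/mult`` per scale, and the
    threshold is set ``k_noise`` standard deviations above the mean of the
    implied noise-energy distribution.

    ``k_noise = 0`` disables compensation entirely (returns 0.0), which is
    the exactly contrast-invariant regime.
    """
    if k_noise == 0:
        return 0.0
    if k_noise < 0:
        raise ValueError("k_noise must be >= 0")
    amp = np.asarray(smallest_scale_amplitude, dtype=float)
    # median of Rayleigh(sigma) is sigma * sqrt(ln 4)
    tau = np.median(amp) / np.sqrt(np.log(4.0))
    inv_m = 1.0 / mult
    total_tau = tau * (1.0 - inv_m**n_scales) / (1.0 - inv_m)
    noise_mean = total_tau * np.sqrt(np.pi / 2.0)
    noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
    return float(noise_mean + k_noise * noise_sigma)


def oriented_pc(
    image: np.ndarray,
    bank: LogGaborBank,
    cutoff: float = 0.4,
    gain: float = 10.0,
    eta: float = 1e-4,
    epsilon: float = 1e-4,
    k_noise: float = 2.0,
    normalize: bool = True,
) -> OrientedPCStack:
    """Compute the O oriented phase-congruency maps of an image.

    The amplitude-weighted phase deviation ``A * dphi`` is evaluated in the
    numerically stable dot/cross-product form

        A*dphi = (e*mean_e + o*mean_o) - |e*mean_o - o*mean_e|

    where ``(mean_e, mean_o)`` is the unit vector along the summed
    quadrature response over scales, which is algebraically identical to
    ``A * (cos(phi - mean_phi) - |sin(phi - mean_phi)|)`` but avoids
    arctangents and is well behaved where the amplitude vanishes.

    With ``normalize=True`` (default) the image is first affinely mapped
    onto [0, 1]; together with ``k_noise`` this fixes the intensity scale
    of eta, epsilon and T_o, and makes the output exactly invariant to
    linear gray-scale transforms of the input.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != bank.shape:
        raise ValueError(f"image shape {image.shape} != bank shape {bank.shape}")
    if normalize:
        image = normalize_image(image)
    elif not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    S, O = bank.n_scales, bank.n_orientations
    image_fft = np.fft.fft2(image)

    pc = np.empty((O,) + image.shape)
    weights = np.empty_like(pc)
    noise_t = np.empty(O)
    for o in range(O):
        even = np.empty((S,) + image.shape)
        odd = np.empty_like(even)
        for s in range(S):
            resp = _filtered(image_fft, bank.transfer[s][o])
            even[s] = resp.real
            odd[s] = resp.imag
        amplitude = np.hypot(even, odd)
        sum_a = amplitude.sum(axis=0)
        sum_e = even.sum(axis=0)
        sum_o = odd.sum(axis=0)

        # unit mean-phase vector; epsilon guards the zero-energy case
        x_energy = np.hypot(sum_e, sum_o) + epsilon
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy

        energy = (
            even * mean_e + odd * mean_o - np.abs(even * mean_o - odd * mean_e)
        ).sum(axis=0)

        t_o = noise_threshold(amplitude[0], S, bank.mult, k_noise)
        energy = np.maximum(energy - t_o, 0.0)

        w_o = spread_weight(amplitude, cutoff, gain, eta)
        pc[o] = w_o * energy / (sum_a + epsilon)
        weights[o] = w_o
        noise_t[o] = t_o

    # guard against tiny negative round-off; values cannot exceed 1 since
    # energy <= sum_a pointwise and w_o < 1
    np.clip(pc, 0.0, None, out=pc)
    params = {
        "cutoff": cutoff,
        "gain": gain,
        "eta": eta,
        "epsilon": epsilon,
        "k_noise": k_noise,
        "n_scales": S,
        "n_orientations": O,
        "normalize": normalize,
    }
    return OrientedPCStack(pc=pc, weights=weights, noise_t=noise_t, params=params)


def overall_pc(stack: OrientedPCStack) -> np.ndarray:
    """Sum of the oriented PC maps over orientations (values in [0, O])."""
    return stack.pc.sum(axis=0)
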