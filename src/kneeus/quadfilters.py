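"""Frequency-domain quadrature filter banks.

Three families are built directly on the FFT grid:

* 2D Log-Gabor bank — Gaussian on a log radial-frequency axis times an
  angular Gaussian, one transfer per (scale, orientation). The angular term
  is single-sided (centered on the orientation vector, not on the
  orientation axis), so the inverse transform of ``spectrum * transfer`` is
  the analytic (even + i*odd) response.
* ASSD band-pass — isotropic alpha-scale-space-derivative transfer
  ``H(w) ~ w * exp(-t * w**(2*alpha))``, the quadrature pair generator for
  the monogenic signal.
* Riesz kernels — ``(i*u1/|u|, i*u2/|u|)``, the 2D Hilbert-transform pair.

All transfers are real, non-negative, zero at DC and peak-normalized to 1.
Frequencies are in cycles per pixel (Nyquist = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


class FilterParameterError(ValueError):
    pass


@dataclass(frozen=True)
class EnhancementParams:
    """Log-Gabor bank geometry and the noise-threshold multiplier.

    ``min_wavelength_px`` and ``scale_multiplier`` define a geometric series
    of center frequencies ``omega0 = 1 / (min_wavelength * mult**s)``;
    ``kappa_ratio`` is k/omega0, the radial bandwidth ratio (0.25 is roughly
    two octaves); angular spread ``sigma_phi = delta_phi / s_angular`` with
    ``delta_phi = pi / n_orientations``. ``noise_sd_mult`` is the number of
    standard deviations above the mean noise energy used for the threshold
    Tr, estimated independently per orientation.
    """

    n_scales: int = 2
    n_orientations: int = 6
    min_wavelength_px: float = 25.0
    scale_multiplier: float = 1.55
    kappa_ratio: float = 0.25
    s_angular: float = 1.2
    noise_sd_mult: float = 3.0
    epsilon: float = 1e-4

    def __post_init__(self):
        if self.n_scales < 1 or self.n_orientations < 1:
            raise FilterParameterError("need at least one scale and one orientation")
        if not (0 < self.kappa_ratio < 1):
            raise FilterParameterError("kappa_ratio must be in (0, 1)")
        if not self.epsilon > 0:
            raise FilterParameterError("epsilon must be positive")
        for w in self.omega0_per_scale():
            if not (0 < w < 0.5):
                raise FilterParameterError(
                    f"center frequency {w:.4f} cycles/px outside (0, Nyquist)"
                )

    def omega0_per_scale(self) -> tuple[float, ...]:
        return tuple(
            1.0 / (self.min_wavelength_px * self.scale_multiplier**s)
            for s in range(self.n_scales)
        )

    @property
    def delta_phi(self) -> float:
        return np.pi / self.n_orientations

    @property
    def sigma_phi(self) -> float:
        return self.delta_phi / self.s_angular

    def orientations(self) -> tuple[float, ...]:
        return tuple(r * self.delta_phi for r in range(self.n_orientations))


@dataclass(frozen=True)
class FilterBank:
    """Per-(scale, orientation) real frequency-domain transfer grids."""

    transfer: np.ndarray  # (n_scales, n_orient, H, W), real, >= 0, DC = 0
    kind: str  # "log_gabor" | "assd"

    @property
    def n_scales(self) -> int:
        return self.transfer.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.transfer.shape[1]


@dataclass(frozen=True)
class FilterResponse:
    """Even (real) and odd (imaginary) quadrature responses per (scale, orientation)."""

    even: np.ndarray  # (n_scales, n_orient, H, W)
    odd: np.ndarray


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial frequency and the two Cartesian frequency components.

    u1 varies along columns (lateral), u2 along rows (depth); cycles/px.
    """
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    u1 = np.broadcast_to(fc, shape).copy()
    u2 = np.broadcast_to(fr, shape).copy()
    radius = np.hypot(u1, u2)
    return radius, u1, u2


def build_log_gabor_bank(shape: tuple[int, int], params: EnhancementParams) -> FilterBank:
    """2D Log-Gabor bank on the FFT grid of ``shape``.

    Radial term ``exp(-(log(w/w0))**2 / (2*log(kappa)**2))`` with
    kappa = kappa_ratio; single-sided angular term
    ``exp(-dphi**2 / (2*sigma_phi**2))`` with the angle difference computed
    through sin/cos so there is no 2*pi seam. DC is exactly zero.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise FilterParameterError(f"shape {shape} too small (need >= 8x8)")
    radius, u1, u2 = _freq_grids(shape)
    radius[0, 0] = 1.0  # avoid log(0); DC reset below
    theta = np.arctan2(u2, u1)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    log_k2 = np.log(params.kappa_ratio) ** 2
    bank = np.empty((params.n_scales, params.n_orientations) + tuple(shape))
    for s, w0 in enumerate(params.omega0_per_scale()):
        radial = np.exp(-(np.log(radius / w0) ** 2) / (2.0 * log_k2))
        radial[0, 0] = 0.0
        for r, phi0 in enumerate(params.orientations()):
            # full angular difference in (-pi, pi]: keeps the filter one-sided
            dphi = np.abs(np.arctan2(
                sin_t * np.cos(phi0) - cos_t * np.sin(phi0),
                cos_t * np.cos(phi0) + sin_t * np.sin(phi0),
            ))
            angular = np.exp(-(dphi**2) / (2.0 * params.sigma_phi**2))
            tf = radial * angular
            peak = tf.max()
            if peak > 0:
                tf = tf / peak
            bank[s, r] = tf
    return FilterBank(transfer=bank, kind="log_gabor")


def apply_bank(image: np.ndarray, bank: FilterBank) -> FilterResponse:
    """Filter ``image`` with every transfer; even = real, odd = imag part.

    Linear in the input. The transfers are single-sided in frequency, so the
    complex inverse transform is the analytic signal along each orientation.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != bank.transfer.shape[2:]:
        raise ValueError(
            f"image shape {image.shape} does not match bank {bank.transfer.shape[2:]}"
        )
    spectrum = np.fft.fft2(image)
    resp = np.fft.ifft2(spectrum[None, None] * bank.transfer, axes=(-2, -1))
    return FilterResponse(even=resp.real.copy(), odd=resp.imag.copy())


def assd_transfer(radius: np.ndarray, alpha: float, t: float) -> np.ndarray:
    """Un-normalized isotropic ASSD band-pass ``w * exp(-t * w**(2*alpha))``."""
    return radius * np.exp(-t * radius ** (2.0 * alpha))


def assd_peak_frequency(alpha: float, t: float) -> float:
    """Analytic argmax of the ASSD transfer: ``(1/(2*alpha*t))**(1/(2*alpha))``."""
    return (1.0 / (2.0 * alpha * t)) ** (1.0 / (2.0 * alpha))


def assd_t_for_wavelength(alpha: float, wavelength_px: float) -> float:
    """Scale parameter t that puts the transfer peak at 1/wavelength cycles/px."""
    w = 1.0 / wavelength_px
    return 1.0 / (2.0 * alpha * w ** (2.0 * alpha))


def build_assd_filter(
    shape: tuple[int, int], alpha: float = 1.5, t_scales=(None,)
) -> FilterBank:
    """Isotropic ASSD band-pass bank, one transfer per scale (orientation axis = 1).

    ``t_scales`` holds the positive scale parameters t; each transfer is
    peak-normalized to 1 and zero at DC.
    """
    if alpha < 0.5:
        raise FilterParameterError("alpha must be >= 0.5")
    ts = [assd_t_for_wavelength(alpha, 25.0) if t is None else float(t) for t in t_scales]
    if any(t <= 0 for t in ts):
        raise FilterParameterError("t_scales must be positive")
    radius, _, _ = _freq_grids(shape)
    bank = np.empty((len(ts), 1) + tuple(shape))
    for s, t in enumerate(ts):
        tf = assd_transfer(radius, alpha, t)
        tf[0, 0] = 0.0
        peak = tf.max()
        if peak > 0:
            tf = tf / peak
        bank[s, 0] = tf
    return FilterBank(transfer=bank, kind="assd")


def riesz_kernels(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Frequency responses of the Riesz transform pair.

    Returns ``(H1, H2) = (i*u1/|u|, i*u2/|u|)`` with DC set to 0;
    ``|H1|**2 + |H2|**2 == 1`` at every non-DC bin.
    """
    radius, u1, u2 = _freq_grids(shape)
    radius[0, 0] = 1.0
    h1 = 1j * u1 / radius
    h2 = 1j * u2 / radius
    h1[0, 0] = 0.0
    h2[0, 0] = 0.0
    return h1, h2
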