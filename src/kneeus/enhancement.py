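"""Cartilage-interface enhancement.

The enhanced image is a signed phase-symmetry measure accumulated over a
Log-Gabor quadrature bank: per scale and orientation the numerator collects
``max(0, (even - odd) - Tr)`` — signed responses, no absolute values, so
ridge polarity is kept — and the denominator is the total local energy
``sum sqrt(even**2 + odd**2) + eps``. Tr is a noise floor estimated
independently per orientation from the smallest-scale energy under a
Rayleigh speckle model. Because both numerator and threshold scale linearly
with intensity, the result is (approximately) invariant to global intensity
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BModeImage
from .quadfilters import (
    EnhancementParams,
    FilterResponse,
    apply_bank,
    build_log_gabor_bank,
)
from ._util import minmax_normalize

# Rayleigh(sigma): median = sigma*sqrt(2 ln 2), mean = sigma*sqrt(pi/2),
# sd = sigma*sqrt(2 - pi/2)
_RAYLEIGH_MEDIAN = np.sqrt(2.0 * np.log(2.0))
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)
_RAYLEIGH_SD = np.sqrt(2.0 - np.pi / 2.0)


@dataclass(frozen=True)
class EnhancedImage:
    """USE map in [0, 1] plus the parameter snapshot that produced it."""

    values: np.ndarray
    params_used: EnhancementParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_noise_threshold(
    response: FilterResponse, orientation: int, mult: float
) -> float:
    """Noise threshold Tr for one orientation.

    The smallest-scale local energy ``sqrt(e**2 + o**2)`` is dominated by
    speckle noise, whose amplitude is Rayleigh distributed; its scale is
    estimated robustly from the median. Tr = mean + mult*sd of that implied
    noise energy distribution.
    """
    e = response.even[0, orientation]
    o = response.odd[0, orientation]
    if e.size == 0:
        raise ValueError("empty filter response")
    energy = np.hypot(e, o)
    sigma = np.median(energy) / _RAYLEIGH_MEDIAN
    return float(sigma * (_RAYLEIGH_MEAN + mult * _RAYLEIGH_SD))


def enhance_cartilage(image: BModeImage, params: EnhancementParams | None = None) -> EnhancedImage:
    """Phase-symmetry cartilage/bone-interface enhancement of a B-mode frame.

    Returns USE in [0, 1] (min-max rescaled); zero on constant inputs.
    """
    if params is None:
        params = EnhancementParams()
    pixels = image.pixels
    if min(pixels.shape) < params.min_wavelength_px / 2:
        raise ValueError(
            f"image {pixels.shape} smaller than half the largest filter wavelength "
            f"({params.min_wavelength_px}px)"
        )
    bank = build_log_gabor_bank(pixels.shape, params)
    resp = apply_bank(pixels, bank)

    numerator = np.zeros_like(pixels)
    denominator = np.zeros_like(pixels)
    for r in range(params.n_orientations):
        tr = compute_noise_threshold(resp, r, params.noise_sd_mult)
        for s in range(params.n_scales):
            e = resp.even[s, r]
            o = resp.odd[s, r]
            numerator += np.maximum((e - o) - tr, 0.0)
            denominator += np.hypot(e, o)
    use = numerator / (denominator + params.epsilon)
    use = np.clip(use, 0.0, 1.0)
    return EnhancedImage(values=minmax_normalize(use), params_used=params)
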