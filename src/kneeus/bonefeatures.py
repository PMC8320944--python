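"""Bone-selective local-phase features: LPT, LPE, LwPA and their product LP.

The cartilage-enhanced image highlights every interface; these features
single out the bone surface. A depth ramp first down-weights shallow
soft-tissue lines (bone sits deep, under the cartilage). The local-phase
tensor (LPT) responds to ridge-like symmetric structure through Hessian and
gradient/Laplacian products; the monogenic signal of the band-passed LPT
yields the local-phase energy (LPE, even-dominant structure) and the local
weighted mean phase angle (LwPA, a scale-invariant phase measure). Their
pointwise product LP is high only on compact, deep, ridge-like structure —
the bone surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .enhancement import EnhancedImage
from .quadfilters import build_assd_filter, assd_t_for_wavelength, riesz_kernels
from ._util import minmax_normalize


@dataclass(frozen=True)
class BoneFeatureParams:
    """ASSD band-pass scales, depth-ramp power, and numeric guards.

    ``assd_wavelengths_px`` place the ASSD transfer peaks (two scales by
    default, matching the Log-Gabor series); ``ramp_power`` is the exponent
    p of the normalized depth ramp ``(row/(NR-1))**p`` (p=0 disables depth
    weighting); ``lwpa_symmetric_denominator`` selects whether both Riesz
    components enter the LwPA denominator (the orientation-independent
    form) or only the first.
    """

    assd_alpha: float = 1.5
    assd_wavelengths_px: tuple[float, ...] = (25.0, 38.75)
    ramp_power: float = 2.0
    epsilon: float = 1e-4
    deriv_sigma_px: float = 1.0
    lwpa_symmetric_denominator: bool = True
    pad_px: int = 32  # reflect padding before FFT filtering (kills wrap-around)

    def __post_init__(self):
        if len(self.assd_wavelengths_px) < 1:
            raise ValueError("need at least one ASSD scale")
        if self.ramp_power < 0:
            raise ValueError("ramp_power must be >= 0")

    def assd_t_scales(self) -> tuple[float, ...]:
        return tuple(
            assd_t_for_wavelength(self.assd_alpha, w) for w in self.assd_wavelengths_px
        )


@dataclass(frozen=True)
class PhaseFeatureSet:
    """Co-registered LPT / LPE / LwPA / LP maps plus monogenic intermediates."""

    lpt: np.ndarray  # >= 0
    lpe: np.ndarray  # >= 0
    lwpa: np.ndarray  # in [0, 1] (arctan remapped)
    lp: np.ndarray  # in [0, 1]
    usm: np.ndarray  # (3, n_scales, H, W) monogenic triple
    phi: np.ndarray  # instantaneous phase of the tensor responses


def _pad_reflect(arr: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad: even along depth, odd along the lateral axis.

    Odd reflection continues sloped structures (the bone curve) across the
    lateral borders instead of mirroring them into a spurious V-ridge; along
    depth, plain reflection avoids sign-flipped ghosts at the transducer
    face and the depth end.
    """
    if pad <= 0:
        return arr
    arr = np.pad(arr, ((pad, pad), (0, 0)), mode="reflect")
    return np.pad(arr, ((0, 0), (pad, pad)), mode="reflect", reflect_type="odd")


def _crop(arr: np.ndarray, pad: int, shape: tuple[int, int]) -> np.ndarray:
    if pad == 0:
        return arr
    return arr[pad : pad + shape[0], pad : pad + shape[1]]


def distance_mask(image: EnhancedImage, params: BoneFeatureParams | None = None) -> np.ndarray:
    """Band-pass the enhanced image and weight it by a normalized depth ramp.

    ``ramp(row) = (row/(NR-1))**p`` is 0 at the transducer face and 1 at the
    bottom row, so deep structure (bone) is emphasized over shallow
    soft-tissue interfaces. The band-pass is the smallest-scale isotropic
    Log-Gabor radial transfer.
    """
    if params is None:
        params = BoneFeatureParams()
    use = image.values
    n_rows = use.shape[0]
    padded = _pad_reflect(use, params.pad_px)
    # isotropic radial band-pass at the smallest ASSD wavelength
    bank = build_assd_filter(
        padded.shape, alpha=params.assd_alpha, t_scales=params.assd_t_scales()[:1]
    )
    bandpassed = _crop(
        np.fft.ifft2(np.fft.fft2(padded) * bank.transfer[0, 0]).real,
        params.pad_px,
        use.shape,
    )
    ramp = (np.arange(n_rows, dtype=float) / (n_rows - 1)) ** params.ramp_power
    return bandpassed * ramp[:, None]


def compute_lpt(
    usdb: np.ndarray, sigma_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Local-phase tensor of the depth-masked image.

    The symmetric response is the trace of the Hessian outer product,
    ``Uxx**2 + 2*Uxy**2 + Uyy**2``; the asymmetric response is the trace of
    the symmetrized gradient x Laplacian-gradient product,
    ``-(Ux*Lx + Uy*Ly)`` with ``L = laplacian(U)``. Both are quadratic in
    the input, so LPT scales as c**2 under intensity scaling while the
    instantaneous phase ``phi = atan2(Todd, Teven)`` is unchanged.
    Derivatives are centered differences after Gaussian pre-smoothing.
    Returns ``(lpt, phi)`` with lpt floored at 0.
    """
    u = gaussian_filter(np.asarray(usdb, dtype=float), sigma_px)
    uy, ux = np.gradient(u)
    uyy, uyx = np.gradient(uy)
    uxy, uxx = np.gradient(ux)
    t_even = uxx**2 + 2.0 * uxy**2 + uyy**2
    lap = uxx + uyy
    ly, lx = np.gradient(lap)
    t_odd = -(ux * lx + uy * ly)
    phi = np.arctan2(t_odd, t_even)
    lpt = np.maximum(np.hypot(t_even, t_odd) * np.cos(phi), 0.0)
    return lpt, phi


def compute_monogenic(lpt: np.ndarray, params: BoneFeatureParams | None = None) -> np.ndarray:
    """Monogenic triple of the ASSD-band-passed LPT, per scale.

    Returns an array ``usm[0..2, scale]``: the band-passed signal and its
    two Riesz components. Linear in the input.
    """
    if params is None:
        params = BoneFeatureParams()
    lpt = np.asarray(lpt, dtype=float)
    padded = _pad_reflect(lpt, params.pad_px)
    bank = build_assd_filter(padded.shape, alpha=params.assd_alpha, t_scales=params.assd_t_scales())
    h1, h2 = riesz_kernels(padded.shape)
    spectrum = np.fft.fft2(padded)
    n_sc = bank.n_scales
    usm = np.empty((3, n_sc) + lpt.shape)
    for s in range(n_sc):
        band = spectrum * bank.transfer[s, 0]
        usm[0, s] = _crop(np.fft.ifft2(band).real, params.pad_px, lpt.shape)
        usm[1, s] = _crop(np.fft.ifft2(band * h1).real, params.pad_px, lpt.shape)
        usm[2, s] = _crop(np.fft.ifft2(band * h2).real, params.pad_px, lpt.shape)
    return usm


def compute_lpe(usm: np.ndarray) -> np.ndarray:
    """Local-phase energy: per-scale ``|USM1| - sqrt(USM2**2 + USM3**2)``
    summed over scales and floored at 0 (even-dominant, phase-congruent
    structure; odd structure such as step edges scores ~0)."""
    per_scale = np.abs(usm[0]) - np.hypot(usm[1], usm[2])
    return np.maximum(per_scale.sum(axis=0), 0.0)


def compute_lwpa(usm: np.ndarray, symmetric: bool = True) -> np.ndarray:
    """Local weighted mean phase angle, remapped from (-pi/2, pi/2) to [0, 1].

    ``arctan2(sum_sc USM1, sqrt(sum_sc USM2**2 + sum_sc USM3**2))`` —
    exactly invariant to positive rescaling of the input triple; where both
    arguments vanish the angle is 0 (0.5 after remap). With
    ``symmetric=False`` only the first Riesz component enters the
    denominator (the orientation-dependent variant).
    """
    s1 = usm[0].sum(axis=0)
    s2 = (usm[1] ** 2).sum(axis=0)
    s3 = (usm[2] ** 2).sum(axis=0)
    denom = np.sqrt(s2 + s3) if symmetric else np.sqrt(s2)
    angle = np.arctan2(s1, denom)
    return (angle + np.pi / 2.0) / np.pi


def compute_lp(lpt: np.ndarray, lpe: np.ndarray, lwpa: np.ndarray) -> np.ndarray:
    """Final local-phase bone image: product of the min-max normalized factors."""
    if not (lpt.shape == lpe.shape == lwpa.shape):
        raise ValueError("feature maps must share one shape")
    return minmax_normalize(lpt) * minmax_normalize(lpe) * minmax_normalize(lwpa)


def compute_phase_features(
    image: EnhancedImage, params: BoneFeatureParams | None = None
) -> PhaseFeatureSet:
    """Full bone-feature chain: depth mask -> LPT -> monogenic -> LPE/LwPA -> LP."""
    if params is None:
        params = BoneFeatureParams()
    usdb = distance_mask(image, params)
    lpt, phi = compute_lpt(usdb, sigma_px=params.deriv_sigma_px)
    usm = compute_monogenic(lpt, params)
    lpe = compute_lpe(usm)
    lwpa = compute_lwpa(usm, symmetric=params.lwpa_symmetric_denominator)
    lp = compute_lp(lpt, lpe, lwpa)
    return PhaseFeatureSet(lpt=lpt, lpe=lpe, lwpa=lwpa, lp=lp, usm=usm, phi=phi)
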