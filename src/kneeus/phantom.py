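"""Synthetic knee-ultrasound phantoms with exact ground truth.

The phantom emulates the transverse suprapatellar view of the femoral
condyle: speckled soft tissue near the transducer, a monotonous hypoechoic
cartilage band of known thickness, a bright curved (parabolic) bone ridge
directly below it, and an acoustic shadow under the bone. Every phantom
carries its generating bone curve and cartilage mask, so each pipeline
stage can be validated without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .io import BModeImage
from ._util import round_half_up

#: Healthy femoral cartilage thickness range reported from cadaver studies, mm.
CARTILAGE_THICKNESS_RANGE_MM = (1.69, 2.55)
#: Mean knee-cartilage thickness (MKT) from the same cadaver literature, mm.
MEAN_CARTILAGE_THICKNESS_MM = 2.16


class PhantomGeometryError(ValueError):
    """Raised when the requested bone/cartilage geometry leaves the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one synthetic B-mode frame.

    The bone surface is a parabola in depth: ``depth(col) = apex_depth_mm +
    curvature_mm * ((col - center)/half_width)**2``. Intensities are on the
    [0, 1] normalized B-mode scale; ``cartilage_mean < tissue_mean`` (the
    cartilage band is hypoechoic) and ``bone_brightness > tissue_mean``.
    ``speckle_scale`` in [0, 1] blends a unit-mean multiplicative Rayleigh
    speckle field (0 = noise free, 1 = fully developed speckle).

    Three appearance features emulate the artefacts of clinical knee scans
    (each can be disabled): a specular synovial interface echo at the top
    of the cartilage band (``interface_brightness``), wavy hyperechoic
    soft-tissue layers above the cartilage (``n_tissue_layers``), and a
    smooth lateral contrast-degradation field emulating transducer
    misalignment (``align_min`` = worst-column contrast fraction; 1
    disables it).
    """

    rows: int = 160
    cols: int = 120
    spacing_mm: float = 0.15
    apex_depth_mm: float = 14.0
    curvature_mm: float = 3.0
    cartilage_thickness_mm: float = MEAN_CARTILAGE_THICKNESS_MM
    bone_brightness: float = 0.95
    tissue_mean: float = 0.45
    cartilage_mean: float = 0.12
    shadow_decay: float = 0.15
    speckle_scale: float = 0.5
    psf_sigma_px: float = 1.0
    ridge_sigma_px: float = 2.0
    interface_brightness: float = 0.85
    interface_sigma_px: float = 1.5
    n_tissue_layers: int = 3
    align_min: float = 0.7
    rng_seed: int = 0

    def __post_init__(self):
        if not (1.0 <= self.cartilage_thickness_mm <= 4.0):
            raise PhantomGeometryError(
                f"cartilage_thickness_mm {self.cartilage_thickness_mm} outside [1, 4]"
            )
        if not self.cartilage_mean < self.tissue_mean:
            raise PhantomGeometryError("cartilage must be hypoechoic: cartilage_mean < tissue_mean")
        if not self.bone_brightness > self.tissue_mean:
            raise PhantomGeometryError("bone ridge must be brighter than tissue")
        if not (0 < self.shadow_decay < 1):
            raise PhantomGeometryError("shadow_decay must be in (0, 1)")
        if not (0 <= self.speckle_scale <= 1):
            raise PhantomGeometryError("speckle_scale must be in [0, 1]")
        if not (0 < self.align_min <= 1):
            raise PhantomGeometryError("align_min must be in (0, 1]")
        if self.interface_brightness and not (
            self.cartilage_mean < self.interface_brightness <= self.bone_brightness
        ):
            raise PhantomGeometryError(
                "interface echo must be brighter than cartilage, dimmer than bone"
            )

    def bone_rows(self) -> np.ndarray:
        """Sub-pixel bone-surface row per column (depth / spacing)."""
        cols = np.arange(self.cols)
        center = (self.cols - 1) / 2.0
        half = max(center, 1.0)
        depth = self.apex_depth_mm + self.curvature_mm * ((cols - center) / half) ** 2
        return depth / self.spacing_mm


@dataclass(frozen=True)
class GroundTruth:
    """Generating geometry of a phantom: true bone rows, cartilage mask, thickness."""

    bone_rows: np.ndarray  # sub-pixel, one value per column
    cartilage_mask: np.ndarray  # bool grid, strictly above the bone surface
    thickness_mm: float


def generate_phantom(spec: PhantomSpec) -> tuple[BModeImage, GroundTruth]:
    """Render one phantom. Deterministic given ``spec.rng_seed``.

    Construction order: piecewise-constant tissue/cartilage background,
    shadow attenuation below the bone curve, Gaussian-profile bone ridge +
    interface echo + tissue layers (max-blended), lateral misalignment
    field, unit-mean Rayleigh speckle, PSF blur, clip to [0, 1]. With the
    appearance features disabled and ``speckle_scale = psf_sigma_px = 0``
    the output is piecewise constant plus the bone ridge.
    """
    bone = spec.bone_rows()
    thick_px = spec.cartilage_thickness_mm / spec.spacing_mm
    if np.any(bone + 3 * spec.ridge_sigma_px >= spec.rows - 1):
        raise PhantomGeometryError("bone curve (with ridge support) leaves the image bottom")
    if np.any(bone - thick_px - 2 <= 0):
        raise PhantomGeometryError("cartilage band leaves the image top")

    rr = np.arange(spec.rows)[:, None].astype(float)
    bone_r = bone[None, :]
    rng = np.random.default_rng(spec.rng_seed)

    img = np.full((spec.rows, spec.cols), spec.tissue_mean)

    # hypoechoic cartilage band directly above the bone surface
    bone_px = round_half_up(bone)[None, :]
    height_px = int(round_half_up(thick_px))
    in_band = (rr >= bone_px - height_px) & (rr < bone_px)
    img[in_band] = spec.cartilage_mean

    # acoustic shadow below the ridge support
    below = rr > bone_r + 2 * spec.ridge_sigma_px
    img[below] *= spec.shadow_decay

    # bright bone ridge with Gaussian cross-section along depth
    overlay = spec.bone_brightness * np.exp(
        -((rr - bone_r) ** 2) / (2.0 * spec.ridge_sigma_px**2)
    )

    # specular synovial interface echo at the top of the band
    band_top = bone_r - thick_px
    if spec.interface_brightness > 0:
        echo = spec.interface_brightness * np.exp(
            -((rr - band_top) ** 2) / (2.0 * spec.interface_sigma_px**2)
        )
        overlay = np.maximum(overlay, echo)

    # wavy hyperechoic soft-tissue layers well above the cartilage
    for _ in range(spec.n_tissue_layers):
        depth0 = rng.uniform(0.15, 0.75) * (band_top.min() - 8.0)
        wave = gaussian_filter1d(rng.standard_normal(spec.cols), 25.0)
        wave = 3.0 * wave / (np.abs(wave).max() + 1e-12)
        center = depth0 + wave
        bright = rng.uniform(0.55, 0.7)
        sigma = rng.uniform(1.0, 2.0)
        layer = bright * np.exp(-((rr - center[None, :]) ** 2) / (2.0 * sigma**2))
        layer[rr > band_top - 5.0] = 0.0  # layers never invade the band
        overlay = np.maximum(overlay, layer)

    img = np.maximum(img, overlay)

    # smooth lateral contrast degradation (transducer misalignment / gain)
    if spec.align_min < 1.0:
        g = gaussian_filter1d(rng.standard_normal(spec.cols), 20.0)
        g = (g - g.min()) / (g.max() - g.min() + 1e-12)
        g = g * (1.0 - spec.align_min) + spec.align_min
        img = spec.tissue_mean + g[None, :] * (img - spec.tissue_mean)

    # unit-mean multiplicative Rayleigh speckle, blended by speckle_scale
    if spec.speckle_scale > 0:
        rayleigh = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=img.shape)
        img = img * (1.0 + spec.speckle_scale * (rayleigh - 1.0))

    if spec.psf_sigma_px > 0:
        img = gaussian_filter(img, spec.psf_sigma_px)

    img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        bone_rows=bone,
        cartilage_mask=in_band,
        thickness_mm=spec.cartilage_thickness_mm,
    )
    return BModeImage(img, spacing_mm=spec.spacing_mm), truth


def phantom_suite(
    n: int,
    thickness_range_mm: tuple[float, float] = CARTILAGE_THICKNESS_RANGE_MM,
    rng_seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[BModeImage, GroundTruth]]:
    """Generate ``n`` phantoms with varied thickness, bone depth and curvature.

    Thickness is sampled uniformly in ``thickness_range_mm``; apex depth and
    curvature are jittered around the base spec so the suite covers a range
    of plausible condyle geometries. Reproducible for a fixed ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n):
        thick = float(rng.uniform(*thickness_range_mm))
        apex = base.apex_depth_mm + float(rng.uniform(-2.0, 2.0))
        curv = base.curvature_mm * float(rng.uniform(0.5, 1.5))
        spec = replace(
            base,
            cartilage_thickness_mm=thick,
            apex_depth_mm=apex,
            curvature_mm=curv,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out
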