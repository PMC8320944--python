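"""B-mode image container and plain-text configuration I/O.

A B-mode ultrasound frame is stored depth-major: row 0 is the transducer
face, row index increases with depth, column index is lateral position.
Intensities are normalized to [0, 1] at load time so every threshold in the
pipeline lives on a machine-independent scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

DEFAULT_SPACING_MM = 0.15  # linear-array knee protocol, mm per pixel


class ImageFormatError(ValueError):
    """Raised for color, non-finite or too-small input images."""


@dataclass(frozen=True)
class BModeImage:
    """2D B-mode frame: ``pixels[row, col]`` with row 0 at the transducer.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, normalized to [0, 1] by the loaders.
    spacing_mm : float
        Isotropic physical pixel spacing in mm.
    """

    pixels: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageFormatError(
                f"expected 2D grayscale image, got {px.ndim} dimensions"
            )
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ImageFormatError(f"image too small: {px.shape} (need >= 32x32)")
        if not np.all(np.isfinite(px)):
            raise ImageFormatError("image contains non-finite values")
        if px.min() < 0:
            raise ImageFormatError("image contains negative intensities")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


def load_image(path, spacing_mm: float = DEFAULT_SPACING_MM) -> BModeImage:
    """Load an 8/16-bit grayscale PNG or TIFF as a BModeImage.

    Intensities are divided by the format's maximum representable value
    (255 or 65535), giving pixels in [0, 1].
    """
    path = Path(path)
    raw = iio.imread(path)
    if raw.ndim == 3:
        # allow trivially-gray RGB (all channels equal), reject true color
        if raw.shape[2] in (3, 4) and np.all(raw[..., :3].max(axis=2) == raw[..., :3].min(axis=2)):
            raw = raw[..., 0]
        else:
            raise ImageFormatError(f"{path}: color image; expected grayscale")
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ImageFormatError(f"{path}: unsupported dtype {raw.dtype}")
    return BModeImage(raw.astype(float) / scale, spacing_mm=spacing_mm)


def save_image(path, values: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float grid as 8- or 16-bit grayscale PNG/TIFF."""
    values = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        iio.imwrite(Path(path), np.round(values * 255).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(Path(path), np.round(values * 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def config_to_dict(config) -> dict:
    """Serialize a (possibly nested) dataclass config to plain dict."""
    return dataclasses.asdict(config)


def save_config(path, config) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config_dict(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
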