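"""Channel encoding of dual-contrast scans into network-ready RGB images.

The microscope produces two co-registered label-free contrasts: a
photoacoustic remote sensing (PARS) channel carrying nucleus (hematoxylin-like)
contrast, and a UV back-scatter channel carrying stroma/cytoplasm
(eosin-like) contrast.  For style transfer these are packed into an RGB
array -- PARS on red, scattering on green, blue unused -- and complemented so
that empty regions render paper-white like a brightfield slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DualChannelImage",
    "RGBImage",
    "to_network_input",
    "normalize_channels",
    "to_model_tensor",
    "from_model_tensor",
]


def _check_unit_range(arr: np.ndarray, name: str) -> None:
    if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
        raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class DualChannelImage:
    """Co-registered PARS + scattering intensity rasters, both in [0, 1].

    pixel_spacing is in nanometres (≈250 nm for 400x-equivalent sampling).
    """

    pars: np.ndarray
    scatter: np.ndarray
    pixel_spacing: float = 250.0

    def __post_init__(self) -> None:
        self.pars = np.asarray(self.pars, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if self.pars.shape != self.scatter.shape:
            raise ValueError(
                f"channel shape mismatch: {self.pars.shape} vs {self.scatter.shape}"
            )
        if self.pars.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        _check_unit_range(self.pars, "pars")
        _check_unit_range(self.scatter, "scatter")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pars.shape


@dataclass
class RGBImage:
    """An RGB raster with values in [0, 1] and square pixels (spacing in nm)."""

    rgb: np.ndarray
    pixel_spacing: float = 250.0

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must have shape (H, W, 3)")
        _check_unit_range(self.rgb, "rgb")

    @classmethod
    def from_channels(
        cls, r: np.ndarray, g: np.ndarray, b: np.ndarray, pixel_spacing: float = 250.0
    ) -> "RGBImage":
        return cls(np.stack([r, g, b], axis=-1), pixel_spacing)

    @property
    def r(self) -> np.ndarray:
        return self.rgb[..., 0]

    @property
    def g(self) -> np.ndarray:
        return self.rgb[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.rgb[..., 2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rgb.shape


def to_network_input(dual: DualChannelImage) -> RGBImage:
    """Encode a dual-channel image as the complemented RGB network input.

    PARS forms the red channel and scattering the green channel; blue is
    unused.  The complement is then taken, so blank regions appear white as
    in true brightfield H&E and nuclei appear as dark (cyan-tinged) features:

        r = 1 - pars,  g = 1 - scatter,  b = 1.
    """
    r = 1.0 - dual.pars
    g = 1.0 - dual.scatter
    b = np.ones_like(dual.pars)
    return RGBImage.from_channels(r, g, b, dual.pixel_spacing)


def from_network_input(img: RGBImage) -> DualChannelImage:
    """Invert :func:`to_network_input` (complement is an involution on R, G)."""
    return DualChannelImage(1.0 - img.r, 1.0 - img.g, img.pixel_spacing)


def normalize_channels(
    pars_raw: np.ndarray,
    scatter_raw: np.ndarray,
    percentile_clip: float = 99.9,
    pixel_spacing: float = 250.0,
) -> DualChannelImage:
    """Scale raw detector amplitudes into [0, 1] with upper-percentile clipping.

    Each channel is independently clipped at its ``percentile_clip`` level and
    divided by that level, which is monotone and order preserving below the
    clip point.  A constant raster carries no contrast and maps to zeros
    (with a warning).
    """

    def _one(raw: np.ndarray, name: str) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if raw.size == 0:
            raise ValueError(f"{name} raster is empty")
        if np.ptp(raw) == 0:
            warnings.warn(
                f"{name} raster is constant; normalizing to all-zeros", stacklevel=3
            )
            return np.zeros_like(raw)
        top = np.percentile(raw, percentile_clip)
        if top <= 0:
            warnings.warn(
                f"{name} percentile level is non-positive; normalizing to zeros",
                stacklevel=3,
            )
            return np.zeros_like(raw)
        return np.clip(raw, 0.0, top) / top

    return DualChannelImage(
        _one(pars_raw, "pars"), _one(scatter_raw, "scatter"), pixel_spacing
    )


def to_model_tensor(img: RGBImage) -> np.ndarray:
    """[0,1] HxWx3 image -> (3,H,W) tensor in [-1,1] (tanh model boundary)."""
    return np.transpose(img.rgb * 2.0 - 1.0, (2, 0, 1)).astype(float)


def from_model_tensor(t: np.ndarray, pixel_spacing: float = 250.0) -> RGBImage:
    """(3,H,W) tensor in [-1,1] -> [0,1] RGBImage, clipping tiny overshoot."""
    rgb = np.clip((np.transpose(t, (1, 2, 0)) + 1.0) / 2.0, 0.0, 1.0)
    return RGBImage(rgb, pixel_spacing)
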