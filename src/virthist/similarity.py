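"""Quantitative similarity of registered virtual / true H&E image pairs.

Three complementary metrics: multi-scale SSIM computed per channel in the
YCbCr color space and combined as 0.8*SSIM_Y + 0.1*SSIM_Cb + 0.1*SSIM_Cr,
PSNR pooled over the RGB channels, and the Pearson correlation coefficient
of the grayscale luminance.  Each metric can be evaluated on raw images or
after an identical Gaussian low-pass simulating a reduced optical
resolution (2 um by default), which discounts fine contrast/focus
differences between modalities and characterizes gross morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .encode import RGBImage

__all__ = [
    "SimilarityConfig", "SimilarityReport",
    "ssim_single", "ms_ssim", "ms_ssim_color",
    "psnr_rgb", "pcc_luminance",
    "lpf_to_resolution", "radial_power_spectrum",
    "rgb_to_ycbcr", "score_pairs",
]

# canonical 5-scale MS-SSIM exponents
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_LUMA = np.array([0.299, 0.587, 0.114])
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SimilarityConfig:
    """Channel weights, blur target and PSNR peak convention."""

    ycbcr_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)
    lpf_target_resolution: float = 2.0     # μm
    native_resolution: float = 0.39        # μm (optical)
    pixel_spacing: float = 250.0           # nm
    psnr_peak: float = 1.0
    lpf_convention: str = "fwhm"           # or "quadrature"

    def __post_init__(self) -> None:
        if abs(sum(self.ycbcr_weights) - 1.0) > 1e-9:
            raise ValueError("YCbCr channel weights must sum to 1")
        if self.lpf_target_resolution * 1000.0 <= self.pixel_spacing:
            raise ValueError("target resolution must exceed the native sampling")


@dataclass
class SimilarityReport:
    ms_ssim: float
    psnr_db: float
    pcc: float
    variant: str = "raw"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.ms_ssim <= 1.0 + 1e-9:
            raise ValueError("MS-SSIM out of range")
        if not -1.0 - 1e-9 <= self.pcc <= 1.0 + 1e-9:
            raise ValueError("PCC out of range")


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Full-range BT.601 RGB -> YCbCr, all channels in [0, 1]."""
    y = rgb @ _LUMA
    cb = (rgb[..., 2] - y) * 0.564 + 0.5
    cr = (rgb[..., 0] - y) * 0.713 + 0.5
    return np.stack([y, cb, cr], axis=-1)


def _gaussian_window_stats(img: np.ndarray, sigma: float, truncate: float = 3.5):
    mu = gaussian_filter(img, sigma, truncate=truncate)
    musq = gaussian_filter(img * img, sigma, truncate=truncate)
    var = musq - mu * mu
    return mu, var


def _ssim_cs_maps(a, b, data_range=1.0, sigma=1.5, k1=0.01, k2=0.03):
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, var_a = _gaussian_window_stats(a, sigma)
    mu_b, var_b = _gaussian_window_stats(b, sigma)
    cov = gaussian_filter(a * b, sigma, truncate=3.5) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def ssim_single(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Single-scale SSIM with an 11-tap Gaussian window (sigma 1.5)."""
    lum, cs = _ssim_cs_maps(a, b, data_range)
    return float(np.mean(lum * cs))


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x2 average pooling (truncating odd edges)."""
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def ms_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Multi-scale SSIM of two single-channel images.

    Uses the canonical 5-scale pyramid (2x average-pool between scales) with
    contrast-structure terms at the coarse scales and the full SSIM at the
    finest retained scale.  If the images are too small for 5 scales, fewer
    are used and the exponents renormalized (flagged with a warning).
    """
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    n_scales = len(_MSSSIM_WEIGHTS)
    min_dim = min(a.shape)
    feasible = max(1, min(n_scales, int(np.log2(min_dim / 11)) + 1))
    if feasible < n_scales:
        warnings.warn(
            f"image too small for 5 MS-SSIM scales; using {feasible}",
            stacklevel=2,
        )
    weights = _MSSSIM_WEIGHTS[:feasible]
    weights = weights / weights.sum()
    vals = []
    x, y = a.astype(float), b.astype(float)
    for s in range(feasible):
        lum, cs = _ssim_cs_maps(x, y, data_range)
        if s == feasible - 1:
            vals.append(np.mean(lum * cs))
        else:
            vals.append(np.mean(cs))
            x, y = _downsample2(x), _downsample2(y)
    vals = np.array(vals)
    signs = np.sign(vals)
    return float(np.prod(signs * np.abs(vals) ** weights))


def ms_ssim_color(
    a: RGBImage | np.ndarray,
    b: RGBImage | np.ndarray,
    cfg: SimilarityConfig | None = None,
) -> float:
    """Weighted YCbCr multi-scale SSIM of a registered color pair.

    Channels that are constant in both images carry no structural
    information and are excluded, with the remaining weights renormalized
    (they sum to one).  For grayscale pairs (R=G=B) both chroma channels
    are identically 0.5, so the result reduces exactly to the
    single-channel (luma) MS-SSIM.
    """
    cfg = cfg or SimilarityConfig()
    ra = a.rgb if isinstance(a, RGBImage) else np.asarray(a, dtype=float)
    rb = b.rgb if isinstance(b, RGBImage) else np.asarray(b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("image shapes must match")
    ya = rgb_to_ycbcr(ra)
    yb = rgb_to_ycbcr(rb)
    w = np.array(cfg.ycbcr_weights, dtype=float)
    live = np.array([
        np.ptp(ya[..., c]) > 1e-9 or np.ptp(yb[..., c]) > 1e-9 for c in range(3)
    ])
    if not live.any():
        return 1.0 if np.allclose(ra, rb) else ms_ssim(ya[..., 0], yb[..., 0])
    w = np.where(live, w, 0.0)
    w = w / w.sum()
    return float(sum(
        w[c] * ms_ssim(ya[..., c], yb[..., c]) for c in range(3) if live[c]
    ))


def psnr_rgb(
    a: RGBImage | np.ndarray,
    b: RGBImage | np.ndarray,
    peak: float = 1.0,
) -> float:
    """PSNR in dB with MSE pooled over all three channels.

    Identical images yield ``inf`` (serialized downstream as a sentinel).
    """
    ra = a.rgb if isinstance(a, RGBImage) else np.asarray(a, dtype=float)
    rb = b.rgb if isinstance(b, RGBImage) else np.asarray(b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("image shapes must match")
    mse = float(np.mean((ra - rb) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


def pcc_luminance(a: RGBImage | np.ndarray, b: RGBImage | np.ndarray) -> float:
    """Pearson correlation of the two images' luminance pixel vectors."""
    ra = a.rgb if isinstance(a, RGBImage) else np.asarray(a, dtype=float)
    rb = b.rgb if isinstance(b, RGBImage) else np.asarray(b, dtype=float)
    la = (ra @ _LUMA if ra.ndim == 3 else ra).ravel()
    lb = (rb @ _LUMA if rb.ndim == 3 else rb).ravel()
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        raise ValueError("undefined correlation: zero-variance luminance")
    return float(np.corrcoef(la, lb)[0, 1])


def lpf_to_resolution(
    img: RGBImage | np.ndarray,
    cfg: SimilarityConfig | None = None,
) -> np.ndarray:
    """Gaussian low-pass simulating a reduced optical resolution.

    The blur FWHM equals the target resolution (``fwhm`` convention) or the
    quadrature difference ``sqrt(target^2 - native^2)`` (``quadrature``
    convention), converted to pixels at the configured spacing.  Both
    images of a pair must be filtered identically.
    """
    cfg = cfg or SimilarityConfig()
    arr = img.rgb if isinstance(img, RGBImage) else np.asarray(img, dtype=float)
    target_um = cfg.lpf_target_resolution
    if cfg.lpf_convention == "quadrature":
        target_um = float(np.sqrt(target_um ** 2 - cfg.native_resolution ** 2))
    elif cfg.lpf_convention != "fwhm":
        raise ValueError("lpf_convention must be 'fwhm' or 'quadrature'")
    sigma_px = target_um * _FWHM_TO_SIGMA / (cfg.pixel_spacing / 1000.0)
    if arr.ndim == 3:
        return np.stack(
            [gaussian_filter(arr[..., c], sigma_px) for c in range(arr.shape[-1])],
            axis=-1,
        )
    return gaussian_filter(arr, sigma_px)


def gaussian_mtf(spatial_freq_per_um: float, cfg: SimilarityConfig | None = None) -> float:
    """Transfer-function value of the low-pass blur at a spatial frequency.

    For a Gaussian with real-space sigma s (μm), the MTF is
    ``exp(-2 pi^2 s^2 f^2)``.
    """
    cfg = cfg or SimilarityConfig()
    target_um = cfg.lpf_target_resolution
    if cfg.lpf_convention == "quadrature":
        target_um = float(np.sqrt(target_um ** 2 - cfg.native_resolution ** 2))
    s = target_um * _FWHM_TO_SIGMA
    return float(np.exp(-2.0 * np.pi ** 2 * s ** 2 * spatial_freq_per_um ** 2))


def radial_power_spectrum(img: np.ndarray, n_bins: int | None = None):
    """Radially averaged DFT magnitude, normalized to the DC value.

    Returns (radii, profile) where radii are in cycles/pixel-extent units
    (bin index) and profile[0] == 1.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expects a single-channel image")
    f = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    h, w = img.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    n_bins = n_bins or (min(h, w) // 2)
    bins = np.clip(r.astype(int), 0, n_bins)
    prof = np.bincount(bins.ravel(), weights=f.ravel(), minlength=n_bins + 1)
    counts = np.bincount(bins.ravel(), minlength=n_bins + 1)
    prof = prof[:n_bins] / np.maximum(counts[:n_bins], 1)
    dc = prof[0] if prof[0] != 0 else 1.0
    return np.arange(n_bins), prof / dc


def score_pairs(
    pairs,
    cfg: SimilarityConfig | None = None,
    lpf: bool = True,
) -> pd.DataFrame:
    """Batch similarity report over (id, virtual, true) image pairs.

    Returns a tidy DataFrame (pair id, variant, ms_ssim, psnr_db, pcc) with
    a raw row per pair and, when ``lpf`` is set, a low-pass-filtered row.
    Summaries (e.g. medians per variant) can be taken directly from it.
    """
    cfg = cfg or SimilarityConfig()
    rows = []
    for pid, a, b in pairs:
        ra = a.rgb if isinstance(a, RGBImage) else np.asarray(a, dtype=float)
        rb = b.rgb if isinstance(b, RGBImage) else np.asarray(b, dtype=float)
        rows.append((pid, "raw", ms_ssim_color(ra, rb, cfg),
                     psnr_rgb(ra, rb, cfg.psnr_peak), pcc_luminance(ra, rb)))
        if lpf:
            fa = lpf_to_resolution(ra, cfg)
            fb = lpf_to_resolution(rb, cfg)
            rows.append((pid, "lpf", ms_ssim_color(fa, fb, cfg),
                         psnr_rgb(fa, fb, cfg.psnr_peak), pcc_luminance(fa, fb)))
    return pd.DataFrame(rows, columns=["pair", "variant", "ms_ssim", "psnr_db", "pcc"])
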