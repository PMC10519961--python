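"""Seeded tissue phantoms: every input the pipeline consumes, with ground truth.

The phantom emulates the structure of dual-contrast label-free tissue scans:
elliptical nuclei with strong PARS (absorption) contrast on a near-zero
background, and band-limited stromal texture in the scattering channel that
dims inside nuclei.  Default geometry follows breast-tissue scale at 250 nm
pixel spacing: mean nucleus radius 3.0 μm gives a mean cross-sectional area
of ~28 μm², in the range typical of H&E morphometry.

Also generated here: a paired deterministic pseudo-H&E rendering (a Beer-
Lambert colorization that stands in for the true-stain image domain in
unpaired training), synthetic raw scan streams on a sinusoidal trajectory,
and rater tables for reader-study statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

from .encode import DualChannelImage, RGBImage
from .scan_recon import ScanStream, _QUAD_ORDER

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "TrajectorySpec",
    "make_dual_channel",
    "make_pseudo_he",
    "make_scan_stream",
    "make_rater_table",
    "HEMATOXYLIN_OD",
    "EOSIN_OD",
]

# optical-density (absorbance) unit vectors of the two stains, RGB order
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.072, 0.990, 0.105])


@dataclass
class PhantomSpec:
    """Geometry and noise of a synthetic dual-contrast tissue image.

    Lengths are physical: pixel_spacing in nm, nucleus radii and texture
    scale in μm.  Identical specs (same seed) produce bit-identical outputs.
    """

    width: int = 256
    height: int = 256
    pixel_spacing: float = 250.0           # nm/px
    n_nuclei: int = 40
    nucleus_radius_mean: float = 3.0       # μm
    nucleus_radius_sd: float = 0.5         # μm
    nucleus_eccentricity_range: tuple[float, float] = (0.0, 0.8)
    min_separation: float = 1.5            # μm between nucleus boundaries
    stroma_texture_scale: float = 2.0      # μm
    noise_sd: float = 0.02                 # intensity fraction
    nucleus_intensity_range: tuple[float, float] = (0.7, 1.0)
    edge_softness: float = 0.5             # px Gaussian on the PARS channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.nucleus_eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must lie in [0, 1)")

    @property
    def px_per_um(self) -> float:
        return 1000.0 / self.pixel_spacing


@dataclass
class PhantomTruth:
    """Ground truth of a rendered phantom: centers (x, y) px, areas μm²,
    and an integer label mask (0 = background, k = nucleus k)."""

    nucleus_centers: np.ndarray
    nucleus_areas: np.ndarray
    labels_mask: np.ndarray

    def __post_init__(self) -> None:
        n_labels = len(np.unique(self.labels_mask)) - (1 if (self.labels_mask == 0).any() else 0)
        if len(self.nucleus_centers) != n_labels:
            raise ValueError("center count must equal distinct nonzero labels")
        if np.any(self.nucleus_areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def count(self) -> int:
        return len(self.nucleus_centers)


def _sample_nuclei(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse parameters (px units)."""
    ppu = spec.px_per_um
    placed = []  # (cx, cy, a, b, theta) with a >= b, px
    max_tries = 2000 * max(spec.n_nuclei, 1)
    tries = 0
    while len(placed) < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place requested nuclei; reduce n_nuclei or separation"
            )
        r_um = rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd)
        if r_um < 0.5:
            continue
        lo, hi = spec.nucleus_eccentricity_range
        ecc = rng.uniform(lo, hi)
        axis_ratio = np.sqrt(1.0 - ecc ** 2)       # b/a
        a = r_um * ppu / axis_ratio ** 0.5         # preserve area = pi r^2
        b = r_um * ppu * axis_ratio ** 0.5
        theta = rng.uniform(0, np.pi)
        margin = a + 2.0
        if 2 * margin >= min(spec.width, spec.height):
            continue
        cx = rng.uniform(margin, spec.width - 1 - margin)
        cy = rng.uniform(margin, spec.height - 1 - margin)
        sep_px = spec.min_separation * ppu
        ok = True
        for (px_, py_, pa, _pb, _th) in placed:
            if np.hypot(cx - px_, cy - py_) < a + pa + sep_px:
                ok = False
                break
        if ok:
            placed.append((cx, cy, a, b, theta))
    return placed


def make_dual_channel(spec: PhantomSpec) -> tuple[DualChannelImage, PhantomTruth]:
    """Render a dual-contrast phantom and its ground truth.

    The PARS channel is bright inside nuclei (per-nucleus intensity drawn
    from ``nucleus_intensity_range``) and near zero elsewhere; the scattering
    channel carries band-limited stromal texture that is attenuated inside
    nuclei.  Gaussian noise of ``noise_sd`` is added to both channels and
    intensities are clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    nuclei = _sample_nuclei(spec, rng)
    centers = []
    areas = []
    pars = np.zeros((spec.height, spec.width))
    for k, (cx, cy, a, b, theta) in enumerate(nuclei, start=1):
        rr, cc = _draw_ellipse(cy, cx, b, a, shape=labels.shape, rotation=theta)
        labels[rr, cc] = k
        pars[rr, cc] = rng.uniform(*spec.nucleus_intensity_range)
        centers.append((cx, cy))
        areas.append(len(rr) * (spec.pixel_spacing / 1000.0) ** 2)
    if spec.edge_softness > 0:
        pars = gaussian_filter(pars, spec.edge_softness)

    # band-limited eosin-like texture, dimmer inside nuclei
    sigma_px = spec.stroma_texture_scale * spec.px_per_um
    texture = gaussian_filter(rng.standard_normal(labels.shape), sigma_px)
    t_span = np.ptp(texture)
    if t_span > 0:
        texture = (texture - texture.min()) / t_span
    scatter = 0.3 + 0.4 * texture
    scatter[labels > 0] *= 0.3

    if spec.noise_sd > 0:
        pars = pars + rng.normal(0, spec.noise_sd, pars.shape)
        scatter = scatter + rng.normal(0, spec.noise_sd, scatter.shape)
    dual = DualChannelImage(
        np.clip(pars, 0, 1), np.clip(scatter, 0, 1), spec.pixel_spacing
    )
    truth = PhantomTruth(
        np.array(centers).reshape(-1, 2), np.array(areas), labels
    )
    return dual, truth


def make_pseudo_he(
    dual: DualChannelImage,
    hematoxylin_strength: float = 1.0,
    eosin_strength: float = 0.8,
) -> RGBImage:
    """Deterministic Beer-Lambert colorization of a dual-channel image.

    Treats the PARS channel as hematoxylin concentration and the scattering
    channel as eosin concentration; transmitted brightfield intensity is
    ``10**(-OD)`` per RGB channel.  An all-zero input therefore renders as a
    uniform white (brightfield background); pure PARS structures take the
    blue-purple hematoxylin hue and stroma renders pink.  This is a pure
    function with no randomness, used as the paired stand-in target domain
    for unpaired training and as a forward model in stain-separation tests.
    """
    od = (
        dual.pars[..., None] * (hematoxylin_strength * HEMATOXYLIN_OD)
        + dual.scatter[..., None] * (eosin_strength * EOSIN_OD)
    )
    rgb = np.power(10.0, -od)
    return RGBImage(np.clip(rgb, 0.0, 1.0), dual.pixel_spacing)


@dataclass
class TrajectorySpec:
    """Sinusoidal fast-axis / linear slow-axis scan trajectory.

    The fast (x) axis sweeps 0..extent as ``x(t) = X/2 (1 - cos(2π f t))``;
    the slow (y) axis moves linearly over the scan duration.  Pulses fire at
    the pulse repetition rate ``prr``; detector samples at ``sample_rate``.
    """

    fast_freq: float = 20.0        # Hz
    prr: float = 20_000.0          # pulses/s
    sample_rate: float = 200_000.0  # samples/s
    duration: float = 1.0          # s
    counts_per_um: float = 10.0
    pulse_window: int = 5          # samples of the rendered pulse response

    def __post_init__(self) -> None:
        if self.sample_rate < 2 * self.prr:
            raise ValueError("sample_rate must comfortably exceed the PRR")


def _quadrature_states(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.array(_QUAD_ORDER)
    phase = np.mod(counts, 4)
    return order[phase, 0], order[phase, 1]


def make_scan_stream(
    dual: DualChannelImage,
    trajectory: TrajectorySpec,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ScanStream:
    """Simulate a continuous acquisition stream over a dual-channel image.

    Per-pulse sample values are bilinear reads of the image at the stage
    position of the excitation event; the PARS trace renders a short
    triangular response whose apex equals the read value, and the scattering
    trace holds the peak over the same window.  Encoder quadrature states are
    emitted for every sample.  The number of pulses is
    ``floor(duration * prr)``.
    """
    rng = np.random.default_rng(seed)
    h, w = dual.shape
    spacing_um = dual.pixel_spacing / 1000.0
    extent_x = (w - 1) * spacing_um
    extent_y = (h - 1) * spacing_um

    n_samples = int(np.floor(trajectory.duration * trajectory.sample_rate))
    t = np.arange(n_samples) / trajectory.sample_rate
    x_um = extent_x / 2.0 * (1.0 - np.cos(2 * np.pi * trajectory.fast_freq * t))
    y_um = extent_y * t / trajectory.duration

    cpu = trajectory.counts_per_um
    # the encoder must not skip counts between samples
    max_step = np.max(np.abs(np.diff(x_um))) * cpu if n_samples > 1 else 0.0
    if max_step >= 1.0:
        raise ValueError(
            "trajectory undersampled: encoder would skip counts; "
            "raise sample_rate or lower fast_freq"
        )
    x_counts = np.floor(x_um * cpu + 0.5).astype(int)
    y_counts = np.floor(y_um * cpu + 0.5).astype(int)
    ex_a, ex_b = _quadrature_states(x_counts)
    ey_a, ey_b = _quadrature_states(y_counts)

    n_pulses = int(np.floor(trajectory.duration * trajectory.prr))
    markers = np.floor(np.arange(n_pulses) / trajectory.prr * trajectory.sample_rate).astype(int)
    markers = markers[markers < n_samples]

    pars_trace = np.zeros(n_samples)
    scat_trace = np.zeros(n_samples)

    # sample the image at the *encoder-quantized* position so that
    # reconstruction from decoded positions is consistent
    def _bilinear(img: np.ndarray, xu: float, yu: float) -> float:
        xf = np.clip(xu / spacing_um, 0, w - 1)
        yf = np.clip(yu / spacing_um, 0, h - 1)
        x0, y0 = int(np.floor(xf)), int(np.floor(yf))
        x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
        fx, fy = xf - x0, yf - y0
        return float(
            img[y0, x0] * (1 - fx) * (1 - fy)
            + img[y0, x1] * fx * (1 - fy)
            + img[y1, x0] * (1 - fx) * fy
            + img[y1, x1] * fx * fy
        )

    win = trajectory.pulse_window
    ramp = np.linspace(0.2, 1.0, win)  # apex at the last window sample
    for m in markers:
        xq = x_counts[m] / cpu
        yq = y_counts[m] / cpu
        v_pars = _bilinear(dual.pars, xq, yq)
        v_scat = _bilinear(dual.scatter, xq, yq)
        end = min(m + win, n_samples)
        pars_trace[m:end] = np.maximum(pars_trace[m:end], v_pars * ramp[: end - m])
        scat_trace[m:end] = np.maximum(scat_trace[m:end], v_scat)
    if noise_sd > 0:
        pars_trace = pars_trace + rng.normal(0, noise_sd, n_samples)

    return ScanStream(
        pulse_markers=markers,
        pars_trace=pars_trace,
        scatter_trace=scat_trace,
        encoder_x_a=ex_a,
        encoder_x_b=ex_b,
        encoder_y_a=ey_a,
        encoder_y_b=ey_b,
        sample_rate=trajectory.sample_rate,
        counts_per_um=cpu,
    )


def make_rater_table(
    n_items: int,
    n_raters: int,
    truth_labels: np.ndarray,
    error_rates: np.ndarray | float,
    seed: int = 0,
):
    """Simulate a reader study: per-rater binary calls with known error rates.

    ``truth_labels`` are the gold diagnoses (True = malignant); each rater's
    virtual-image call flips each truth independently with that rater's
    error rate.  Calls on the true images are error-free (raters read the
    gold standard correctly), matching a study design in which consensus on
    true images defines ground truth.  With zero error rates all calls equal
    the truth.
    """
    from .readerstats import RaterTable

    truth = np.asarray(truth_labels, dtype=bool)
    if len(truth) != n_items:
        raise ValueError("truth_labels length must equal n_items")
    err = np.broadcast_to(np.asarray(error_rates, dtype=float), (n_raters,))
    if np.any(err < 0) or np.any(err > 1):
        raise ValueError("error_rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    virtual = np.empty((n_raters, n_items), dtype=bool)
    for r in range(n_raters):
        flips = rng.random(n_items) < err[r]
        virtual[r] = truth ^ flips
    true_calls = np.tile(truth, (n_raters, 1))
    return RaterTable(
        item_ids=np.arange(n_items),
        gold=truth,
        virtual_calls=virtual,
        true_calls=true_calls,
    )
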