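"""Unpaired stain style transfer: CycleGAN model, training, and inference.

Two generators map between the domain X of encoded label-free images and
the domain Y of brightfield H&E images; two 70x70 PatchGAN discriminators
judge realism.  Training minimizes the least-squares adversarial losses
together with a heavily weighted (lambda = 150) L1 cycle-consistency term
and an identity term at half the cycle weight:

    L_tot = L_adv(G_UV, D_UV) + L_adv(G_HE, D_HE)
          + lambda * L_cyc + 0.5 * lambda * L_ident

Generators follow the canonical residual layout: a 7x7 stem, two stride-2
downsampling convolutions, nine residual blocks (two 3x3 convolutions
each), two fractionally-strided upsampling convolutions, and a 7x7 tanh
head.  Every convolution uses reflection padding, instance normalization
and ReLU (tanh at the output).  Because the networks are fully
convolutional, arbitrarily large images can be translated at inference and
the parameter count is independent of the input size.

Discriminator updates draw from a 50-image history buffer of generated
examples rather than only the newest one, which damps oscillation.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .encode import RGBImage, from_model_tensor, to_model_tensor

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossWeights", "TrainConfig",
    "ImageBuffer", "DomainSets", "PatchSet", "CycleGAN",
    "build_generator", "build_discriminator", "discriminator_receptive_field",
    "adversarial_loss_d", "adversarial_loss_g", "cycle_loss", "identity_loss",
    "l1_loss", "total_loss", "prepare_patches", "learning_rate_at",
    "train", "infer", "stitch_strips",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Residual generator: 9 blocks of two convolutions by default."""

    n_res_blocks: int = 9
    base_width: int = 64
    padding_mode: str = "reflection"
    norm: str = "instance"
    output_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.n_res_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.padding_mode != "reflection" or self.norm != "instance" \
                or self.output_activation != "tanh":
            raise ValueError("unsupported generator variant")


@dataclass
class DiscriminatorSpec:
    """70x70 PatchGAN: maps 256x256 inputs to a 30x30 score array."""

    patch_receptive_field: int = 70
    base_width: int = 64
    leaky_slope: float = 0.2
    first_layer_norm: bool = False

    def __post_init__(self) -> None:
        if self.patch_receptive_field != 70:
            raise ValueError("only the 70x70 PatchGAN layout is implemented")


@dataclass
class LossWeights:
    """Cycle weight lambda and the identity factor (identity weight = 0.5*lambda)."""

    lambda_cyc: float = 150.0
    identity_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_cyc <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class TrainConfig:
    """Adam(0.5, 0.999), batch 1, lr 2e-4 held for ``epochs_const`` epochs
    then decayed linearly to zero over ``epochs_decay`` epochs."""

    batch_size: int = 1
    adam_betas: tuple[float, float] = (0.5, 0.999)
    lr: float = 2e-4
    epochs_const: int = 100
    epochs_decay: int = 100
    buffer_size: int = 50
    seed: int = 0
    max_iterations: int | None = None   # cap total updates (smoke runs)

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs_const, self.epochs_decay,
               self.buffer_size) <= 0 or self.lr <= 0:
            raise ValueError("training config values must be positive")


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Linear decay policy: constant for epochs_const, then linear to zero.

    Epochs are 1-based; e.g. epoch 150 of a 100+100 schedule gives
    ``lr * (1 - 50/100)``.
    """
    if epoch <= cfg.epochs_const:
        return cfg.lr
    frac = (epoch - cfg.epochs_const) / cfg.epochs_decay
    return cfg.lr * max(0.0, 1.0 - frac)


class ImageBuffer:
    """History buffer of generated images for discriminator updates.

    While filling, each query stores and returns its input.  Once full, with
    probability 1/2 the new image is returned unchanged; otherwise a
    uniformly chosen stored image is returned and replaced by the new one.
    """

    def __init__(self, capacity: int = 50, rng: np.random.Generator | None = None):
        self.capacity = capacity
        self.images: list[np.ndarray] = []
        self.rng = rng or np.random.default_rng(0)

    def __len__(self) -> int:
        return len(self.images)

    def query(self, image: np.ndarray) -> np.ndarray:
        if len(self.images) < self.capacity:
            self.images.append(image)
            return image
        if self.rng.random() < 0.5:
            return image
        idx = int(self.rng.integers(self.capacity))
        out = self.images[idx]
        self.images[idx] = image
        return out


@dataclass
class PatchSet:
    """Disjoint train/val/test patch arrays, each (N, 3, H, W) in [-1, 1]."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class DomainSets:
    """Unpaired training domains X (encoded scans) and Y (H&E patches)."""

    X: PatchSet
    Y: PatchSet


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def build_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> nnet.Sequential:
    """ResNet generator mapping (3, H, W) in [-1,1] to same shape in [-1,1].

    H and W must be divisible by 4 (two stride-2 stages); :func:`infer` pads
    and crops automatically for other sizes.
    """
    rng = rng or np.random.default_rng(0)
    w = spec.base_width
    layers: list[nnet.Layer] = [
        nnet.ReflectionPad2d(3),
        nnet.Conv2d(3, w, 7, 1, rng=rng),
        nnet.InstanceNorm2d(),
        nnet.ReLU(),
        nnet.ReflectionPad2d(1),
        nnet.Conv2d(w, 2 * w, 3, 2, rng=rng),
        nnet.InstanceNorm2d(),
        nnet.ReLU(),
        nnet.ReflectionPad2d(1),
        nnet.Conv2d(2 * w, 4 * w, 3, 2, rng=rng),
        nnet.InstanceNorm2d(),
        nnet.ReLU(),
    ]
    for _ in range(spec.n_res_blocks):
        body = nnet.Sequential([
            nnet.ReflectionPad2d(1),
            nnet.Conv2d(4 * w, 4 * w, 3, 1, rng=rng),
            nnet.InstanceNorm2d(),
            nnet.ReLU(),
            nnet.ReflectionPad2d(1),
            nnet.Conv2d(4 * w, 4 * w, 3, 1, rng=rng),
            nnet.InstanceNorm2d(),
        ])
        layers.append(nnet.ResidualBlock(body))
    layers += [
        nnet.ConvTranspose2d(4 * w, 2 * w, 3, 2, 1, 1, rng=rng),
        nnet.InstanceNorm2d(),
        nnet.ReLU(),
        nnet.ConvTranspose2d(2 * w, w, 3, 2, 1, 1, rng=rng),
        nnet.InstanceNorm2d(),
        nnet.ReLU(),
        nnet.ReflectionPad2d(3),
        nnet.Conv2d(w, 3, 7, 1, rng=rng),
        nnet.Tanh(),
    ]
    return nnet.Sequential(layers)


# (kernel, stride) ladder of the PatchGAN; receptive field works out to 70
_PATCHGAN_LADDER = [(4, 2), (4, 2), (4, 2), (4, 1), (4, 1)]


def build_discriminator(spec: DiscriminatorSpec, rng: np.random.Generator | None = None) -> nnet.Sequential:
    """70x70 PatchGAN mapping (3, 256, 256) to a (1, 30, 30) score array."""
    rng = rng or np.random.default_rng(0)
    d = spec.base_width
    widths = [3, d, 2 * d, 4 * d, 8 * d, 1]
    layers: list[nnet.Layer] = []
    for i, (k, s) in enumerate(_PATCHGAN_LADDER):
        layers.append(nnet.ZeroPad2d(1))
        layers.append(nnet.Conv2d(widths[i], widths[i + 1], k, s, rng=rng))
        last = i == len(_PATCHGAN_LADDER) - 1
        if not last:
            if i > 0 or spec.first_layer_norm:
                layers.append(nnet.InstanceNorm2d())
            layers.append(nnet.LeakyReLU(spec.leaky_slope))
    return nnet.Sequential(layers)


def discriminator_receptive_field(ladder=None) -> int:
    """Receptive field of one output element, from the (kernel, stride) ladder."""
    ladder = ladder or _PATCHGAN_LADDER
    rf, jump = 1, 1
    for k, s in ladder:
        rf += (k - 1) * jump
        jump *= s
    return rf


def patch_score(d_out: np.ndarray) -> float:
    """Scalar classification = arithmetic mean of the patch score array."""
    return float(np.mean(d_out))


# ---------------------------------------------------------------------------
# losses (value + gradient helpers)
# ---------------------------------------------------------------------------

def _mse(a: np.ndarray, target: float) -> float:
    return float(np.mean((a - target) ** 2))


def l1_loss(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError("shape mismatch in L1 loss")
    return float(np.mean(np.abs(a - b)))


def adversarial_loss_d(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """LSGAN discriminator objective: real -> 1, fake -> 0 (sum of both terms)."""
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("empty batch")
    return _mse(real_scores, 1.0) + _mse(fake_scores, 0.0)


def adversarial_loss_g(fake_scores: np.ndarray) -> float:
    """LSGAN generator objective: drive D(fake) -> 1."""
    if fake_scores.size == 0:
        raise ValueError("empty batch")
    return _mse(fake_scores, 1.0)


def cycle_loss(x: np.ndarray, g_forward, g_backward) -> float:
    """Mean absolute error between x and its round-trip reconstruction."""
    return l1_loss(g_backward(g_forward(x)), x)


def identity_loss(y: np.ndarray, g_forward) -> float:
    """L1 between a target-domain image and the generator applied to it."""
    return l1_loss(g_forward(y), y)


@dataclass
class LossParts:
    adv_uv: float
    adv_he: float
    cyc: float
    ident: float


def total_loss(parts: LossParts, weights: LossWeights | None = None) -> float:
    """Weighted total: adv_uv + adv_he + lambda*cyc + 0.5*lambda*ident."""
    weights = weights or LossWeights()
    vals = [parts.adv_uv, parts.adv_he, parts.cyc, parts.ident]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite loss component")
    lam = weights.lambda_cyc
    return (
        parts.adv_uv + parts.adv_he
        + lam * parts.cyc
        + weights.identity_factor * lam * parts.ident
    )


# ---------------------------------------------------------------------------
# patch preparation
# ---------------------------------------------------------------------------

_DIHEDRAL = [
    lambda p: p,
    lambda p: np.rot90(p, 1, axes=(1, 2)),
    lambda p: np.rot90(p, 2, axes=(1, 2)),
    lambda p: np.rot90(p, 3, axes=(1, 2)),
    lambda p: p[:, ::-1, :],
    lambda p: np.rot90(p, 1, axes=(1, 2))[:, ::-1, :],
    lambda p: np.rot90(p, 2, axes=(1, 2))[:, ::-1, :],
    lambda p: np.rot90(p, 3, axes=(1, 2))[:, ::-1, :],
]


def prepare_patches(
    wsi_image: RGBImage | np.ndarray,
    patch: int = 256,
    stride: int | None = None,
    augment: bool = False,
    jitter: int = 0,
    split: tuple[int, int, int] = (80, 10, 10),
    seed: int = 0,
) -> PatchSet:
    """Tile a large image into patches with optional augmentation and split.

    A sliding window of size ``patch`` and step ``stride`` (default: patch,
    i.e. non-overlapping) tiles the image; with ``augment`` each patch
    receives a random element of the dihedral group (rotations/reflections)
    and positional jitter up to ``jitter`` pixels where room allows.  Patch
    indices are then shuffled into disjoint train/val/test sets in ``split``
    proportion (percent).
    """
    rgb = wsi_image.rgb if isinstance(wsi_image, RGBImage) else np.asarray(wsi_image)
    h, w = rgb.shape[:2]
    if h < patch or w < patch:
        raise ValueError("image is smaller than the patch size")
    if sum(split) != 100:
        raise ValueError("split percentages must sum to 100")
    stride = stride or patch
    rng = np.random.default_rng(seed)
    tensor = np.transpose(rgb * 2.0 - 1.0, (2, 0, 1))
    patches = []
    for i in range(0, h - patch + 1, stride):
        for j in range(0, w - patch + 1, stride):
            ii, jj = i, j
            if augment and jitter > 0:
                ii = int(np.clip(i + rng.integers(-jitter, jitter + 1), 0, h - patch))
                jj = int(np.clip(j + rng.integers(-jitter, jitter + 1), 0, w - patch))
            p = tensor[:, ii:ii + patch, jj:jj + patch]
            if augment:
                p = _DIHEDRAL[int(rng.integers(8))](p)
            patches.append(np.ascontiguousarray(p))
    patches = np.stack(patches)
    n = len(patches)
    order = rng.permutation(n)
    n_train = int(n * split[0] / 100)
    n_val = int(n * split[1] / 100)
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return PatchSet(patches[idx_train], patches[idx_val], patches[idx_test])


# ---------------------------------------------------------------------------
# model container, training, inference
# ---------------------------------------------------------------------------

class TrainingDivergedError(RuntimeError):
    def __init__(self, model: "CycleGAN", iteration: int):
        self.model = model
        self.iteration = iteration
        super().__init__(f"non-finite loss at iteration {iteration}")


class CycleGAN:
    """Two generators + two discriminators + loss weights."""

    def __init__(
        self,
        gen_spec: GeneratorSpec | None = None,
        disc_spec: DiscriminatorSpec | None = None,
        weights: LossWeights | None = None,
        seed: int = 0,
    ):
        self.gen_spec = gen_spec or GeneratorSpec()
        self.disc_spec = disc_spec or DiscriminatorSpec()
        self.weights = weights or LossWeights()
        rng = np.random.default_rng(seed)
        self.G_HE = build_generator(self.gen_spec, rng)   # X -> Y_hat
        self.G_UV = build_generator(self.gen_spec, rng)   # Y -> X_hat
        self.D_HE = build_discriminator(self.disc_spec, rng)
        self.D_UV = build_discriminator(self.disc_spec, rng)
        self.trained = False

    def nets(self):
        return [self.G_HE, self.G_UV, self.D_HE, self.D_UV]

    # -- single-file checkpoint container (compressed npz) ------------------
    def save(self, path) -> None:
        arrays = {}
        for net_name, net in zip(("G_HE", "G_UV", "D_HE", "D_UV"), self.nets()):
            for i, layer in enumerate(net.named_layers()):
                for pname, val in layer.params.items():
                    arrays[f"{net_name}/{i}/{pname}"] = val
        meta = dict(
            n_res_blocks=self.gen_spec.n_res_blocks,
            gen_width=self.gen_spec.base_width,
            disc_width=self.disc_spec.base_width,
            lambda_cyc=self.weights.lambda_cyc,
            identity_factor=self.weights.identity_factor,
            trained=int(self.trained),
        )
        np.savez_compressed(path, __meta__=np.array(list(meta.items()), dtype=object),
                            **arrays)

    @classmethod
    def load(cls, path) -> "CycleGAN":
        data = np.load(path, allow_pickle=True)
        meta = dict(data["__meta__"])
        model = cls(
            GeneratorSpec(n_res_blocks=int(meta["n_res_blocks"]),
                          base_width=int(meta["gen_width"])),
            DiscriminatorSpec(base_width=int(meta["disc_width"])),
            LossWeights(float(meta["lambda_cyc"]), float(meta["identity_factor"])),
        )
        for net_name, net in zip(("G_HE", "G_UV", "D_HE", "D_UV"), model.nets()):
            for i, layer in enumerate(net.named_layers()):
                for pname in layer.params:
                    layer.params[pname] = data[f"{net_name}/{i}/{pname}"]
        model.trained = bool(int(meta["trained"]))
        return model


def _g_update(model: CycleGAN, x, y, opt, lam, idf):
    """One generator step; returns the Eq-style loss bookkeeping."""
    G_HE, G_UV, D_HE, D_UV = model.G_HE, model.G_UV, model.D_HE, model.D_UV
    fake_y, tape_gy = G_HE.forward(x)
    rec_x, tape_rx = G_UV.forward(fake_y)
    fake_x, tape_gx = G_UV.forward(y)
    rec_y, tape_ry = G_HE.forward(fake_x)
    idt_y, tape_iy = G_HE.forward(y)
    idt_x, tape_ix = G_UV.forward(x)
    s_fake_y, tape_dy = D_HE.forward(fake_y)
    s_fake_x, tape_dx = D_UV.forward(fake_x)

    adv_he = _mse(s_fake_y, 1.0)
    adv_uv = _mse(s_fake_x, 1.0)
    cyc = l1_loss(rec_x, x) + l1_loss(rec_y, y)
    ident = l1_loss(idt_y, y) + l1_loss(idt_x, x)

    opt.zero_grad()
    # adversarial branches (gradients flow into generators through frozen Ds)
    d_s_fy = 2.0 * (s_fake_y - 1.0) / s_fake_y.size
    d_s_fx = 2.0 * (s_fake_x - 1.0) / s_fake_x.size
    g_fy = D_HE.backward(d_s_fy, tape_dy)
    g_fx = D_UV.backward(d_s_fx, tape_dx)
    # cycle branches
    d_rec_x = lam * np.sign(rec_x - x) / rec_x.size
    d_rec_y = lam * np.sign(rec_y - y) / rec_y.size
    g_fy = g_fy + G_UV.backward(d_rec_x, tape_rx)
    g_fx = g_fx + G_HE.backward(d_rec_y, tape_ry)
    # identity branches
    d_idt_y = idf * lam * np.sign(idt_y - y) / idt_y.size
    d_idt_x = idf * lam * np.sign(idt_x - x) / idt_x.size
    G_HE.backward(d_idt_y, tape_iy)
    G_UV.backward(d_idt_x, tape_ix)
    # into the generators that produced the fakes
    G_HE.backward(g_fy, tape_gy)
    G_UV.backward(g_fx, tape_gx)
    # discriminator grads from this pass are discarded (not stepped)
    for dnet in (D_HE, D_UV):
        dnet.zero_grad()
    opt.step()
    return LossParts(adv_uv=adv_uv, adv_he=adv_he, cyc=cyc, ident=ident), fake_x, fake_y


def _d_update(dnet, real, fake, opt):
    """LSGAN discriminator step (0.5 factor per the standard recipe)."""
    s_real, tape_r = dnet.forward(real)
    s_fake, tape_f = dnet.forward(fake)
    loss = 0.5 * adversarial_loss_d(s_real, s_fake)
    opt.zero_grad()
    dnet.backward(0.5 * 2.0 * (s_real - 1.0) / s_real.size, tape_r)
    dnet.backward(0.5 * 2.0 * s_fake / s_fake.size, tape_f)
    opt.step()
    return loss


def train(
    model: CycleGAN,
    data: DomainSets,
    cfg: TrainConfig,
    callback=None,
) -> tuple[CycleGAN, "np.recarray"]:
    """Alternating generator/discriminator optimization on unpaired sets.

    Per iteration: one generator Adam step (adversarial + cycle + identity
    branches), then one Adam step per discriminator using buffer-mediated
    fake examples.  The per-iteration loss history records each component
    and the weighted total.  Supports fine-tuning: pass a model loaded from
    a checkpoint (patch sizes may differ; the parameter count is unchanged).
    """
    X, Y = data.X.train, data.Y.train
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("both training domains must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    buf_he = ImageBuffer(cfg.buffer_size, np.random.default_rng(cfg.seed + 1))
    buf_uv = ImageBuffer(cfg.buffer_size, np.random.default_rng(cfg.seed + 2))

    opt_g = nnet.Adam([model.G_HE, model.G_UV], cfg.lr, cfg.adam_betas)
    opt_d_he = nnet.Adam(model.D_HE, cfg.lr, cfg.adam_betas)
    opt_d_uv = nnet.Adam(model.D_UV, cfg.lr, cfg.adam_betas)

    lam = model.weights.lambda_cyc
    idf = model.weights.identity_factor
    iters_per_epoch = max(len(X), len(Y))
    total_epochs = cfg.epochs_const + cfg.epochs_decay
    history = []
    it = 0
    done = False
    for epoch in range(1, total_epochs + 1):
        lr = learning_rate_at(epoch, cfg)
        opt_g.lr = opt_d_he.lr = opt_d_uv.lr = lr
        xi = rng.permutation(len(X))
        yi = rng.permutation(len(Y))
        for step in range(iters_per_epoch):
            x = X[xi[step % len(xi)]]
            y = Y[yi[step % len(yi)]]
            parts, fake_x, fake_y = _g_update(model, x, y, opt_g, lam, idf)
            d_he_loss = _d_update(model.D_HE, y, buf_he.query(fake_y), opt_d_he)
            d_uv_loss = _d_update(model.D_UV, x, buf_uv.query(fake_x), opt_d_uv)
            tot = total_loss(parts, model.weights)
            if not np.isfinite(tot):
                raise TrainingDivergedError(model, it)
            history.append((it, epoch, parts.adv_uv, parts.adv_he, parts.cyc,
                            parts.ident, tot, d_he_loss, d_uv_loss))
            if callback is not None:
                callback(it, parts, tot)
            it += 1
            if cfg.max_iterations is not None and it >= cfg.max_iterations:
                done = True
                break
        if done:
            break
    model.trained = True
    hist = np.rec.fromrecords(
        history,
        names="iteration,epoch,adv_uv,adv_he,cyc,ident,total,d_he,d_uv",
    )
    return model, hist


def infer(g_he: nnet.Sequential, rgb: RGBImage, trained: bool = True) -> RGBImage:
    """Translate an encoded image to virtual H&E (deterministic).

    Input sizes not divisible by 4 are reflection-padded and cropped back.
    """
    if not trained:
        warnings.warn("generator is untrained; output is style-less", stacklevel=2)
    x = to_model_tensor(rgb)
    _, h, w = x.shape
    ph = (-h) % 4
    pw = (-w) % 4
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    y = g_he(x)
    if ph or pw:
        y = y[:, :h, :w]
    return from_model_tensor(y, rgb.pixel_spacing)


def stitch_strips(
    g_he,
    large_image: RGBImage,
    overlap: int = 256,
    memory_budget_px: int = 1 << 20,
) -> RGBImage:
    """Translate a tall image in horizontal strips with linear blending.

    The image is cut into horizontal strips whose height fits the pixel
    budget; consecutive strips share ``overlap`` rows in which the output is
    ``w * upper + (1 - w) * lower`` with ``w`` falling linearly from 1 to 0
    across the central half of the overlap.  The outer quarter of the
    overlap at each cut edge carries zero weight, so border effects of any
    operator whose receptive field is at most half the overlap are fully
    discarded and the stitched result equals single-pass inference there.
    Weights sum to one everywhere (no vertical seams).  An image shorter
    than one strip is translated in a single pass.  ``g_he`` may be a
    generator network or any image-to-image callable on (3, H, W) tensors.
    """
    rgb = large_image.rgb
    h, w = rgb.shape[:2]
    strip_h = max(overlap * 2, int(memory_budget_px // max(w, 1)))
    strip_h = min(strip_h, h)
    strip_h -= strip_h % 4
    if strip_h <= overlap and strip_h < h:
        raise ValueError("overlap must be smaller than the strip height")

    def _run(tile: np.ndarray) -> np.ndarray:
        img = RGBImage(tile, large_image.pixel_spacing)
        out = infer(g_he, img) if isinstance(g_he, nnet.Sequential) else \
            from_model_tensor(g_he(to_model_tensor(img)), img.pixel_spacing)
        return out.rgb

    if strip_h >= h:
        return RGBImage(_run(rgb), large_image.pixel_spacing)

    step = strip_h - overlap
    starts = list(range(0, max(h - strip_h, 0) + 1, step))
    if starts[-1] + strip_h < h:
        starts.append(h - strip_h)

    margin = overlap // 4
    t = np.arange(overlap)
    rise = np.clip((t - margin + 0.5) / max(overlap - 2 * margin, 1), 0.0, 1.0)

    acc = np.zeros_like(rgb)
    wacc = np.zeros((h, 1, 1))
    for a in starts:
        b = a + strip_h
        out = _run(rgb[a:b])
        wt = np.ones(strip_h)
        if a > 0:
            wt[:overlap] = rise
        if b < h:
            wt[-overlap:] = 1.0 - rise
        acc[a:b] += out * wt[:, None, None]
        wacc[a:b, 0, 0] += wt
    return RGBImage(np.clip(acc / wacc, 0.0, 1.0), large_image.pixel_spacing)
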