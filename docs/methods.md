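# Methods

This note documents the models and numerical choices behind `virthist`:
what each stage assumes, which parameters matter, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Scan reconstruction

The acquisition model is a continuously sampled stream (no per-pulse
triggering): PARS and peak-held scattering traces plus quadrature encoder
bits for a sinusoidal fast axis and a linear slow axis. Decoding follows
the standard A-quad-B state machine (forward order 00→01→11→10, four counts
per cycle); a transition in which both bits flip is physically impossible
at an adequate sample rate and raises an error carrying the sample index
rather than guessing a direction. The encoder counts-per-micrometre factor
and the post-pulse peak window are not physical constants of the method and
are exposed as configuration (defaults: 10 counts/μm, 5-sample window).

Gridding uses natural-neighbor (Sibson) interpolation, computed by
Watson's local retriangulation on a `scipy.spatial.Delaunay`
triangulation: the triangles whose circumcircle contains the query point
form the insertion cavity, and each natural neighbor's weight is the
Voronoi area it cedes to the query, assembled from cavity circumcenters
and the circumcenters of the new triangles on the cavity boundary. Sibson
interpolation reproduces data-site values exactly and is exact for affine
fields inside the convex hull; both properties are verified in the tests
against direct evaluation and against a brute-force pixel-counting Voronoi
oracle. Queries that land exactly on a hull edge are degenerate for the
area construction and fall back to barycentric-linear interpolation, which
coincides with the Sibson limit there. A `method="linear"` fallback (same
triangulation) is provided for speed; samples recorded at identical
positions are averaged before triangulation; pixels outside the hull take
a configurable fill value. Pixel centers sit at `x0 + i*spacing` (0-based).

## Channel encoding

The network input packs PARS into red and scattering into green, leaves
blue unused, and takes the complement so empty regions render white like a
brightfield slide: `r = 1-pars, g = 1-scatter, b = 1`. The complement is an
involution on the two live channels, so no information is lost. Raw
detector amplitudes are normalized per channel by clipping at an upper
percentile (default 99.9) and dividing by that level — monotone and
order-preserving; a constant raster maps to zeros with a warning. At the
model boundary images are rescaled to [-1, 1] to match the tanh output.

## Stain transfer

Generators are the canonical residual image-translation layout: 7×7
stride-1 stem, two stride-2 3×3 downsampling convolutions, nine residual
blocks of two 3×3 convolutions, two fractionally-strided 3×3 upsampling
convolutions, 7×7 head. Reflection padding, instance normalization (no
affine parameters) and ReLU follow every convolution except the tanh
output. Discriminators are 70×70 PatchGANs: kernels (4,4,4,4,4) with
strides (2,2,2,1,1), leaky-ReLU slope 0.2, no normalization in the first
layer; a 256×256 input maps to a 30×30 score array whose arithmetic mean
is the image-level score. Exact kernel/stride annotations are not dictated
by the architecture constraints alone; the canonical layout above is the
one consistent with every stated constraint (30×30 map, 70 px receptive
field, fully-convolutional in both directions).

The total objective is

    L_tot = L_adv(G_UV, D_UV) + L_adv(G_H&E, D_H&E) + λ·L_cyc + 0.5·λ·L_ident

with least-squares adversarial losses (real→1, fake→0), L1 cycle and
identity terms, and λ = 150 — a deliberately heavy cycle weight that
preserves tissue morphology and confines the GAN to style. Optimization is
Adam(β₁=0.5, β₂=0.999), batch size 1, learning rate 2·10⁻⁴ for 100 epochs
then linearly decayed to zero over 100 more. Discriminator updates draw
fakes from a 50-image history buffer: while filling, the buffer stores and
returns each image; once full, with probability ½ the new image is used
directly, otherwise a uniformly chosen stored image is returned and
replaced. Weight init is N(0, 0.02²); all RNGs are seeded.

The layer stack (convolutions via BLAS tensor contractions, transposed
convolutions, padding, instance norm, activations, Adam) is implemented
directly in NumPy with manual backpropagation; every layer's input and
parameter gradients are verified against central finite differences at
1e-6 tolerance. Each forward pass returns an explicit tape so one
generator can appear several times in the cycle-consistency graph.

**Smoke-scale study conditions.** Full convergence training is far outside
desk scale; the package's training validation is a descent test: 200
iterations on 64×64 phantom patches with base width 8, three residual
blocks and width-8 discriminators, asserting that the median total loss
over the last 20 iterations is below the first 20. This demonstrates that
the coupled optimization is wired correctly (losses, buffers, schedules,
gradients), not that the smoke model produces realistic stains.

**Stitching.** Large images are translated in horizontal strips sized to a
pixel budget, sharing `overlap` rows. Blending weights ramp linearly
across the central half of the overlap and are zero in the outer quarter
at each cut edge, so the weights sum to one everywhere and the rows
nearest a cut — the only rows a local operator computes differently than
in a single pass — carry no weight. Stitched output therefore equals
single-pass inference exactly for operators whose receptive field is at
most half the overlap. Instance normalization is global over the spatial
extent, so a generator is not strictly local and stitched output can
deviate slightly near strip boundaries; the 256-pixel default overlap
makes this visually negligible (no seams), and the exactness guarantee is
asserted with a genuinely local operator.

## Registration cascade

Stage 1 maximizes normalized cross-correlation over integer shifts in a
bounded window (default: a quarter of the image side), ties broken toward
the smallest shift. Stage 2 maximizes Mattes mutual information (50 bins,
10% random sampling per evaluation, seeded) under an affine transform with
a (1+1)-evolution strategy for 1000 evaluations; the mutation radius is
1.5 px for translations and 0.01 units for the linear part, imposed
through optimizer parameter scales (without this scaling the matrix
entries mutate at pixel magnitudes and the search stalls). Stage 3 runs
Thirion's demons, 100 iterations at each of 3 pyramid levels
(coarse-to-fine shrink 4/2/1), smoothing the accumulated displacement
field with a Gaussian of σ = 2.0 px after each iteration — the common
reading of an "accumulated field smoothing" parameter; warps are applied
with cubic (B-spline) resampling. Metrics are evaluated on BT.601
luminance; transforms are applied to full RGB. Stages 2–3 use SimpleITK.

Cascade diagnostics report luminance MSE over the central region (12.5%
margin excluded per side): resampling fills border wedges with a constant,
which otherwise dominates the metric; the production workflow instead
carries 64 padding pixels into registration and crops to 256×256 after.
On 20 seeded phantoms perturbed by shift + rotation + smooth warp, the
cascade improves monotonically (demons < coarse < unregistered in every
case; the affine stage improves the median). When the perturbation is
dominated by the non-rigid warp, the affine stage occasionally treads
water — the demons stage recovers it.

## Similarity metrics

MS-SSIM uses the standard 5-scale pyramid (2× average pooling) with the
canonical per-scale exponents, an 11-tap Gaussian window (σ = 1.5),
K₁ = 0.01, K₂ = 0.03; contrast-structure terms at coarse scales and the
full SSIM at the finest retained scale. Images smaller than the 5-scale
minimum use fewer scales with renormalized exponents (warned). Color
scoring converts to full-range BT.601 YCbCr and combines channels as
0.8·Y + 0.1·Cb + 0.1·Cr; channels constant in both images carry no
structural information and are excluded with weight renormalization, which
makes gray pairs reduce exactly to the luma MS-SSIM. PSNR pools MSE over
RGB with peak 1.0 (identical images report infinity); PCC is computed on
luminance. The resolution-degradation low-pass is a Gaussian whose FWHM
equals the target resolution (default 2 μm at 250 nm pixel spacing); the
quadrature-subtraction convention `sqrt(target² - native²)` is available
behind a flag. The radially averaged DFT magnitude profile (DC-normalized)
supports spatial-frequency comparisons.

## Nuclear morphometrics

Stain separation converts to optical density (−log₁₀ of transmittance) and
estimates the two stain vectors blindly: tissue pixels (OD norm > 0.15)
are projected onto the plane of the two leading singular vectors and the
1st/99th percentile angular extremes are taken as the stain directions;
the vector with the larger relative blue absorbance is hematoxylin, and
concentrations come from least squares. Fixed published H&E vectors are
available as a fallback. On forward-model mixtures of known vectors the
hematoxylin concentrations are recovered within a few percent of full
scale.

Segmentation smooths with a Gaussian derived from the threshold-smoothing
scale (1.35 on the source tool's scale, ≈1.0 px σ; the tool defines scale
1.3488 ≡ σ 1 px), thresholds at global Otsu × correction factor (default
0.8, clamped to [0.1, 1.0]), fills holes, declumps by the shape method
(watershed on the negated distance transform, seeded at distance maxima
with minima suppression at half the minimum object diameter), and discards
objects outside the 15–50 px equivalent-diameter range or touching the
border. The two filter rules are per-object and order-independent.
Measurements: area = pixel count × spacing²; eccentricity from the
second-moment equivalent ellipse; compactness = perimeter²/(4π·area)
(≥ 1, circle = 1); internuclear distance = Euclidean nearest-neighbor
centroid distance. Compactness and eccentricity definitions are
swappable, as morphometry conventions vary between tools.

On noise-free phantoms the pipeline recovers the exact nucleus count, and
the validation uses correction factor 1.0 — the unbiased threshold for
binary-contrast objects, whereas 0.8 is a tuning for real H&E. A global
threshold cannot be unbiased for every object when nuclear intensities
vary: a bright nucleus's edge crossing moves slightly outward and a dim
one's inward (a fraction of a pixel), so per-nucleus area errors are
typically under 2% with occasional small, dim nuclei near 6%; validation
asserts the 95th percentile under 5% over several phantoms.

## Reader statistics

Rates use malignant as the positive class; zero-denominator rates are
reported as missing rather than zero. The "mean" summary is the unweighted
arithmetic mean of *unrounded* per-rater rates (not pooled counts) — the
two conventions differ in the second decimal and the unpooled one is the
internally consistent choice; rounding is half-up to two decimals at
reporting time only. Consensus calls are per-item majorities with ties
broken toward malignant (conservative for margin assessment;
configurable). Cohen's kappa uses marginal-product chance agreement and is
defined as 1 when both raters are constant and identical; Fleiss' kappa
uses the standard category-proportion formulation and is defined as 1 when
a single category is used throughout. Both are validated against
statsmodels and invariant to label swapping.

The stain-quality comparison uses a right-tailed Wilcoxon rank-sum test
with the exact null distribution, enumerated by a subset-sum dynamic
program over rank subsets (verified against exhaustive enumeration for all
m+n ≤ 12 and against `scipy.stats.mannwhitneyu(method="exact")`). Tied
pooled values are refused with guidance to pre-average scores over raters
— per-image inter-rater means both reduce observer variability and remove
integer-score ties. No multiple-comparison correction is applied (three
planned comparisons).

The reference reader tables bundled with `readerstats` reconstruct
per-rater calls from published per-rater confusion counts at n = 24
(10 malignant) for breast with five raters and n = 32 (20 malignant) for
prostate with three; the item-level assignment of errors is chosen so the
majority vote also reproduces the published consensus statistics.
True-image readings are taken as the gold standard itself — exact for the
breast study (unanimous readings) and an approximation for prostate.

## Phantoms: what they emulate, and what passing tests show

The phantom renders elliptical nuclei (area-preserving eccentricity up to
0.8, mean radius 3 μm ⇒ ≈28 μm² mean area, per-nucleus intensity
0.7–1.0) with rejection-sampled minimum separation, over band-limited
stromal texture (Gaussian-filtered noise at a 2 μm scale, attenuated
inside nuclei), with optional Gaussian noise, at 250 nm pixel spacing.
The pseudo-H&E rendering is a deterministic Beer–Lambert colorization
with published absorbance vectors — it serves as the unpaired target
domain and as the forward model for stain-separation tests. All
generators are bit-reproducible under a seed.

Phantoms contain no optical point-spread function, no acoustic physics,
no chromatin texture, no touching-cell pathology, and no staining
variability. Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover known ground truth under controlled
conditions — not that the pipeline reaches any particular fidelity on
clinical tissue, which depends on data the phantoms do not model.

## Problem sizes used in validation

Registration validation runs on 128×128 textured phantoms (20 perturbed
pairs for the cascade statistics); segmentation recovery on 256×256
phantoms with 12 nuclei each; natural-neighbor exactness on ≤200-point
scattered sets against a 25×25 grid; smoke training on 64×64 patches for
200 iterations. These sizes were chosen to exercise every code path at
desk scale while keeping the whole validation suite runnable in minutes
on a single CPU.
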