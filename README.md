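# virthist

Label-free virtual H&E histology, end to end: from raw dual-contrast
ultraviolet scan streams to realistic virtual hematoxylin-and-eosin images
via unpaired style transfer, together with the quantitative validation
suite used to judge such images — registration, color similarity metrics,
nuclear morphometrics, and reader-study statistics.

## Who this is for

Researchers building or evaluating slide-free histology systems in which an
ultraviolet photoacoustic remote sensing (UV-PARS) channel provides
nucleus (hematoxylin-like) contrast and a peak-held UV back-scatter channel
provides stroma/cytoplasm (eosin-like) contrast. The package reproduces the
full computational pipeline of such a system on synthetic tissue phantoms
with known ground truth, so every stage can be exercised and verified
without access to clinical scan data.

## The pipeline

1. **Scan reconstruction** (`scan_recon`). Acquisition is a continuous
   stream: per-pulse PARS maxima, peak-held scattering samples, and A-quad-B
   encoder states of a sinusoidal fast axis and linear slow axis. Quadrature
   decoding recovers stage positions; per-pulse trace maxima are associated
   with the position of each excitation event; the scattered points are
   mapped onto a Cartesian grid by natural-neighbor (Sibson) interpolation
   on a Delaunay triangulation — exact at data sites and for affine fields.
2. **Encoding** (`encode`). PARS → red, scattering → green, blue unused;
   the complement is taken so blank regions render brightfield-white:
   r = 1 − PARS, g = 1 − scatter, b = 1.
3. **Stain transfer** (`stain_transfer`). A CycleGAN with two ResNet
   generators (9 residual blocks, reflection padding, instance norm, tanh
   output) and two 70×70 PatchGAN discriminators (256×256 → 30×30 score
   array), trained on unpaired domains with the least-squares adversarial
   loss and a heavily weighted cycle-consistency term:

       L_tot = L_adv(G_UV, D_UV) + L_adv(G_H&E, D_H&E) + λ·L_cyc + 0.5·λ·L_ident,   λ = 150

   Adam(0.5, 0.999), batch 1, lr 2·10⁻⁴ constant for 100 epochs then
   linearly decayed for 100 more; discriminators update from a 50-image
   history buffer. Large images are translated in overlapping horizontal
   strips re-stitched with linear blending. The networks are implemented
   directly in NumPy with manual backpropagation, sized for CPU-scale runs.
4. **Validation** (`registration`, `similarity`, `nuclei`, `readerstats`).
   Virtual/true pairs are co-registered (NCC coarse shift → Mattes mutual
   information affine via a (1+1)-evolution strategy → Thirion demons) and
   scored with YCbCr-weighted multi-scale SSIM (0.8/0.1/0.1), RGB PSNR, and
   luminance Pearson correlation, raw and after a 2 μm Gaussian low-pass.
   Nuclei are recovered by stain separation (Macenko unmixing in optical
   density), Otsu thresholding with shape-method declumping, and measured
   (area, eccentricity, compactness, internuclear distance). Reader studies
   are summarized by sensitivity/specificity/PPV/NPV/accuracy per rater,
   their means and consensus calls, Cohen's and Fleiss' kappa, and a
   right-tailed *exact* Wilcoxon rank-sum test for stain-quality scores.
5. **Phantoms** (`phantom`). A seeded generator emulates all inputs:
   dual-channel images with elliptical nuclei and band-limited stromal
   texture, a deterministic Beer–Lambert pseudo-H&E rendering, synthetic
   scan streams, and rater tables — each with exact ground truth.

## Worked example

```python
import numpy as np
from virthist import phantom, nuclei
from virthist.readerstats import concordance_report, example_breast_table

# segment nuclei in a rendered phantom and compare with ground truth
spec = phantom.PhantomSpec(width=256, height=256, n_nuclei=12,
                           noise_sd=0.0, edge_softness=0.0, seed=3)
dual, truth = phantom.make_dual_channel(spec)
he = phantom.make_pseudo_he(dual)
hema = nuclei.separate_hematoxylin(he.rgb)
mask = nuclei.segment_nuclei(hema, nuclei.SegmentationParams(correction_factor=1.0))
records = nuclei.measure_nuclei(mask, pixel_spacing=250.0)
print(len(records), truth.count, round(float(np.median([r.area for r in records])), 1))

# reader-study statistics of the reference breast table (24 images, 5 raters)
print(concordance_report(example_breast_table()).rounded()["mean"])
```

prints

```
12 12 27.3
{'sensitivity': 0.96, 'specificity': 0.91, 'ppv': 0.89, 'npv': 0.97, 'accuracy': 0.93}
```

— all 12 nuclei are recovered, the median cross-sectional nuclear area is
27.3 μm² (phantom nuclei are drawn at a 3 μm mean radius, ≈ 28 μm²), and
the mean diagnostic rates over the five raters match the reference reader
study to two decimals.

A command-line interface mirrors the library
(`virthist phantom|reconstruct|encode|train|infer|stitch|register|similarity|nuclei|readerstats|run`);
`virthist run --config cfg.yaml` executes any subset of stages and writes a
manifest of content hashes for reproducibility audits.

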