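# discmorph

Objective morphometry of the internal composition of lumbar intervertebral
discs (IVDs) from transverse T2-weighted images.

The proteoglycan-rich nucleus pulposus (NP) appears hyperintense on T2
against the darker annulus fibrosus (AF) ring. The fraction of the disc's
transverse cross-sectional area occupied by the nucleus,

```
Ratio_NP-to-CSA = 100 · CSA_NP / CSA_IVD   [%]
```

is a key geometric input for finite-element models of spinal loading, yet it
is hard to measure consistently by hand: the NP/AF boundary is blurred, and
manual tracings of it are poorly repeatable. `discmorph` implements an
objective measurement protocol built around two computer-assisted
segmentation algorithms, for researchers in spine biomechanics and
musculoskeletal image analysis:

* **Fuzzy C-means (FCM)** — soft clustering of the cropped disc image
  minimizing `J = Σᵢ Σⱼ uᵢⱼᵐ ‖cᵢ − xⱼ‖²` subject to `Σᵢ uᵢⱼ = 1`; the
  brightest cluster, cleaned by morphological opening, is the nucleus.
* **Seeded region growing (RG)** — best-first aggregation from seeds placed
  near the NP boundary: the frontier pixel closest to the running region
  mean `mean₂ = (mean₁·size + point)/(size + 1)` is absorbed while the
  difference stays below a threshold `maxdis` (default 0.06 on normalized
  [0, 1] intensities).

Around the two segmentation kernels the package provides: manual-contour
I/O and K-means cropping to the traced IVD, elliptic-Fourier smoothing of
the NP outline (order 1 = ellipse/oval, order 4 admits the kidney shape of
lower-lumbar discs), area and ratio computation with physical pixel
spacing, and the statistics used to validate such protocols (Pearson
correlation with interpretation bands, paired t tests, absolute error,
ICC(2,1), split-plot gender × spinal-level ANOVA, Tukey HSD).

Because no scan data ships with the package, a **synthetic disc phantom
generator** produces oval- or kidney-shaped discs with a darker AF ring, a
brighter NP, a blurred NP/AF transition, noise, and an exactly known
ground-truth ratio — every pipeline stage is testable end to end.

## Worked example

```python
from discmorph import (PhantomSpec, generate_phantom, measure_np,
                       normalize_intensity, dice_coefficient)

spec = PhantomSpec(shape_template="kidney", kidney_indent_depth=0.25,
                   np_target_ratio=0.40, rng_seed=7)
ph = generate_phantom(spec)
img = normalize_intensity(ph.image.pixels, spec.pixel_spacing_mm)

print(f"true NP-to-CSA ratio: {ph.true_ratio_percent:.1f}%")
for method in ("fcm", "rg"):
    seg = measure_np(img, ph.ivd_contour_true, method, seed=3)
    d = dice_coefficient(seg.np_mask, ph.np_mask_true)
    r = seg.record
    print(f"{method:3s}: CSA_NP={r.csa_np:.1f} mm2  CSA_IVD={r.csa_ivd:.1f} mm2  "
          f"ratio={r.ratio_percent:.1f}%  Dice={d:.3f}")
```

prints

```
true NP-to-CSA ratio: 40.0%
fcm: CSA_NP=667.5 mm2  CSA_IVD=1671.1 mm2  ratio=39.9%  Dice=0.994
rg : CSA_NP=600.4 mm2  CSA_IVD=1671.1 mm2  ratio=35.9%  Dice=0.946
```

A kidney-shaped phantom with a true ratio of 40.0% is measured at 39.9% by
the FCM pipeline and 35.9% by the RG pipeline (areas in mm² from the
0.69 × 0.69 mm pixel spacing). Both recover the nucleus shape well (Dice
0.99 / 0.95); region growing systematically stops slightly inside the
blurred NP/AF transition band, a behavior discussed in
[docs/methods.md](docs/methods.md).

The same pipeline runs from the shell over batches of real images:

```sh
discmorph phantom --seed 7 --out demo/
discmorph segment-rg demo/image.png --contour demo/contour.json --auto-seed --out demo/np_rg.png
discmorph ratio --np demo/np_rg.png --ivd-contour demo/contour.json --method rg --out demo/ratios.csv
discmorph run manifest.csv --methods fcm,rg --seed 1 --out results/
```

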