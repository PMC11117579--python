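# Methods

This note documents the measurement model implemented by `discmorph`, the
choices made where the protocol left the design open, and what the
synthetic phantom suite can and cannot show about real scan data.

## Measurement chain

One transverse disc image and one manually traced outer IVD contour enter;
one `RatioRecord` per segmentation method leaves.

1. **Normalization.** Raw intensities are linearly rescaled to [0, 1]
   (min → 0, max → 1; a constant image maps to zeros). This makes every
   intensity threshold in the chain — cluster distances and the
   region-growing `maxdis` — scale-free across scanners and file formats.
2. **Contour rasterization.** The traced contour (an ordered (row, col)
   vertex list) is rasterized by the even-odd rule evaluated at pixel
   centers; pixel centers sit at integer coordinates, 0-based. The enclosed
   pixel count defines CSA_IVD. Self-intersecting polygons are rejected.
3. **K-means crop.** The image is cut to the contour's bounding box; a
   Lloyd K-means with k-means++ seeding (k = 3: surrounding tissue /
   annulus / nucleus intensity populations) summarizes the intensity
   structure, and all pixels outside the traced contour are zeroed. The
   contour — not the clustering — is the authoritative disc boundary; the
   cropped "disc-only" image retains AF + NP on a zeroed background.
4. **Segmentation** (next two sections) produces a binary NP mask.
5. **Outline regularization** (optional, on by default): the mask boundary
   is extracted exactly and refitted with a truncated elliptic-Fourier
   curve, then re-rasterized and intersected with the disc mask.
6. **Morphometry.** `CSA = pixel count × row_spacing × col_spacing` (mm²)
   when spacing is known, else px²; the ratio `100·CSA_NP/CSA_IVD` is
   independent of spacing by construction.

## Fuzzy C-means stage

The solver minimizes `J(U, C) = Σᵢ Σⱼ uᵢⱼᵐ dᵢⱼ²` with `dᵢⱼ = ‖cᵢ − xⱼ‖` by
alternating the centroid update `cᵢ = Σⱼ uᵢⱼᵐ xⱼ / Σⱼ uᵢⱼᵐ` and the
membership update `uᵢⱼ = 1 / Σₖ (dᵢⱼ/dₖⱼ)^{2/(m−1)}` from a seeded random
row-normalized initialization. A pixel coinciding with a center is crisply
assigned to it (the limit of the update). Iteration stops when `J` or its
change drops below `tol`; hitting `max_iter` flags the partition
unconverged instead of raising. `J` is non-increasing across iterations
(alternating minimization), and each membership row sums to 1 — both are
asserted by the test suite at every iteration. The membership matrix is
stored objects × clusters.

Defaults: `c = 3`, `m = 2` (the conventional fuzziness), `tol = 1e-5` on
`|ΔJ|`, `max_iter = 100` (convergence is typically reached in ~20
iterations on disc images).

**Clustering domain.** The pipeline clusters the *whole* cropped disc-only
image, zeroed surroundings included, so the three clusters are background /
AF / NP. The brightest-centroid cluster (the nucleus is T2-hyperintense) is
then restricted to the disc mask and cleaned by a disk opening plus
largest-4-connected-component selection ("interference cluster" removal).
This choice is deliberate: clustering only the in-disc pixels makes c = 3
fragile on nearly bimodal disc histograms — FCM then splits the NP
intensity peak in two and the brightest-centroid rule can collapse onto a
noise tail. With the background population present, the three centers are
well separated under every blur/noise regime we generate, and the hardened
NP/AF boundary lands essentially at the half-intensity contour, making the
FCM ratio estimate nearly unbiased on phantoms (|error| ≤ 0.5 points across
blur 0–1 px and noise sd 0–0.03).

## Region-growing stage

Growth is best-first: among all frontier pixels (the "Seeds" stack), the
one minimizing |gray − region mean| is absorbed if that difference is
≤ `maxdis`; its 4-neighbors join the frontier; the mean is updated
incrementally as `mean₂ = (mean₁·size + point)/(size + 1)` (kept equal to
the batch mean to 1e-12, verified at every acceptance). Ties break by
smallest (row, col), making runs fully deterministic. The frontier is one
persistent set across seed restarts: growth ends only when every remaining
frontier difference exceeds `maxdis` and no seeds remain, so pixels
rejected under an earlier mean are reconsidered when later seeds shift it.
Growth is confined to the disc mask, so the nucleus cannot leak outside the
traced IVD. The acceptance test is `≤ maxdis` (not `<`).

Seeds: placed near the NP boundary, where the gray value is noticeably
lower than at the NP center — central seeds give a high initial mean and
can stall immediately. The automatic proposal thresholds disc pixels at the
midpoint of the two brightest k = 3 K-means centers, takes the largest
component as a provisional nucleus, erodes once, and spaces 5 seeds evenly
(by angle) around the eroded boundary. Five seeds (the count is a package
choice; one is configurable) make the noisy cold start robust: a single
seed's four neighbors can all exceed `maxdis` by chance.

`maxdis` defaults to 0.06 on the normalized scale — the stricter of the two
values commonly compared (0.1 over-grows into the annulus). Cleanup:
closing then opening with a radius-2 disk, largest 4-connected component,
hole filling.

**Known bias.** On phantoms with a flat-intensity nucleus, the running mean
converges near the NP core value, so growth stops at the intensity contour
`mean − maxdis` — roughly 1 px inside the half-intensity (true) boundary
for a 1 px blur. This yields a systematic underestimate of ≈ 4 ratio
points at the default phantom conditions, while FCM is nearly unbiased
there; the two methods consequently disagree more on phantoms than they
would on real discs, whose internal NP texture and intensity gradient keep
the running mean lower. The phantom deliberately does not model such
internal gradients (see below), so this gap is a property of the study
conditions, not a tunable defect.

## Contour extraction and elliptic-Fourier smoothing

The mask boundary is the exact outline of the union of unit pixel squares
(a pixel is the square of side 1 centered on its integer coordinates), so
`mask → contour → mask` round-trips exactly and a one-pixel mask yields a
unit square of area 1. For smoothing, the closed boundary is resampled
uniformly in arc length (512 points), each coordinate is least-squares
regressed on the trigonometric basis {1, cos kt, sin kt}ₖ≤H, and the fitted
curve is emitted at 128 vertices. The models are nested, so the residual is
non-increasing in H. Order 1 is always an ellipse (hence convex); the
default order 4 follows the posterior concavity of kidney-shaped
lower-lumbar discs while removing pixel jaggedness — on phantom suites the
enclosed area changes by well under 5%, i.e. the step regularizes rather
than reshapes. No published parametric family exists for this protocol
step; the elliptic-Fourier descriptor was chosen because it spans the
oval→kidney continuum with few parameters. Note that under arc-length
parametrization an eccentric ellipse is not exactly order 1, so the order-1
fit reproduces mildly eccentric ellipses to sub-pixel accuracy but not
arbitrarily elongated ones.

## Synthetic phantom

The phantom emulates a transverse T2 slice of one disc: background tissue
0.10, AF ring 0.35, NP 0.75 (on [0, 1]; the hyperintensity ordering
background < AF < NP is enforced), Gaussian blur σ = 1 px for the fuzzy
NP/AF transition, additive Gaussian noise sd 0.02 clipped to [0, 1],
pixel spacing 0.69 × 0.69 mm. The outer shape is an ellipse (semi-axes
42 × 30 px by default); the kidney template scales the posterior half
radially by `1 − depth·cos²θ`, a single-parameter concavity. The nucleus is
a scaled, optionally offset copy of the outer curve; the scale is bisected
until the pixel-count ratio is within 2 points of the requested target
(30–50% is the physiological range), which guarantees nesting and ratio
control. The true ratio is *defined* from the emitted masks, so it is
exact. Everything is deterministic given the seed.

Not modeled, deliberately: 3-D geometry, Rician noise, bias fields,
internal NP texture or radial intensity gradients, and partial-volume
anisotropy. Passing the phantom suite therefore demonstrates correctness of
the algorithms and their implementation under controlled contrast — it does
not certify accuracy on clinical scans, where the NP/AF contrast, texture
and artifacts differ (the RG bias discussed above is one concrete
consequence).

## Statistics layer

* **Pearson correlation bands**: Excellent > 0.810, Good [0.61, 0.809],
  Moderate [0.410, 0.609], Fair [0.210, 0.409], Poor < 0.209. The printed
  band edges leave tiny gaps (0.809–0.810 etc.); a value falling in a gap
  is assigned to the lower band so the classification is total. (These are
  the conventional cutpoints; note 0.549 is "Moderate" under them.)
* **Paired t**: `t = mean(d)/(sd(d)/√n)`, df = n−1, two-sided. Identical
  pairs give t = 0, p = 1; constant nonzero differences are flagged
  degenerate rather than reported as infinite evidence.
* **Absolute error**: `100·|x−y|/x` — relative to the *first* measurement,
  hence deliberately asymmetric.
* **ICC(2,1)**: two-way random effects, absolute agreement, single rater,
  from the classical mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`. Chosen as the standard
  repeatability form; other forms can be computed from the same table.
* **Split-plot ANOVA**: gender between subjects, spinal level within,
  subject nested in gender as the between-stratum error. The between
  stratum is computed on subject means; the within stratum uses partial
  (type III, sum-to-zero coding) sums of squares via model comparison with
  subject fixed effects absorbing all between-subject variation, so
  unequal group sizes are handled; every subject must be measured at every
  level (missing cells raise with a listing). Under a 2000-replicate null
  simulation all three F tests hold their nominal 0.05 level.
* **Tukey HSD**: studentized-range tests on all group pairs with pooled
  within-group variance and Tukey–Kramer standard errors for unequal n;
  with two groups it reduces exactly to the pooled two-sample t test. No
  additional global multiplicity correction is applied.
* **Simulator**: `simulate_ratio_table` draws subject effects
  N(0, 6²) around a 38% baseline with N(0, 2²) measurement noise over four
  lumbar levels (L1/L2–L4/L5) — magnitudes chosen to match healthy-cohort
  NP-to-CSA variability — with configurable gender/level effects for power
  and calibration studies.

## Numerical conventions and degenerate inputs

Coordinates are 0-based (row, col) with pixel centers at integers,
everywhere. K-means and hard FCM assignment break ties toward the lower
cluster index; the NP cluster tie-breaks the same way. Region-growing ties
break by (row, col). Empty masks, empty fuzzy clusters, contours that
self-intersect or enclose no pixels, discs with no intensity contrast, and
ratio denominators of zero all raise typed exceptions
(`InvalidSpecError`, `SegmentationError`, `ContourError`) rather than
propagating garbage. If a segmentation ever emits NP pixels outside the
IVD (only possible with the domain restriction disabled), the area step
intersects with the IVD mask and warns.

## Problem sizes

The bundled studies are sized for a desktop run: 50 phantoms of 96 × 128 px
for the recovery study, 8 × 8 images for the 100-instance region-growing
oracle suite, n ≤ 50 scalar instances for the FCM oracle suite, and 12
subjects × 4 levels × 2000 replicates for the ANOVA null calibration.
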