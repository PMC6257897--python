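# Methods

## Model

The pipeline treats leukocyte identification as three nested decisions:
*which pixels are nucleus*, *which nucleus fragments are one cell*, and
*which of the five normal classes the cell is*.

**Pixel classification.** A single color prototype p̄ — the mean of
labeled nucleus pixels — stands in for the nucleus color distribution.
Pixel similarity is the Gaussian radial basis function E = exp(−D/α) of
the Euclidean color distance D between the pixel and p̄. With α = 255
(the range of an 8-bit channel) the activation decays to 1/e at one
full channel range of distance. Thresholding E at cutoff τ is exactly
thresholding D at −α·ln τ; both parameterizations are exposed
(`RBFParams`, `segmentation.d_threshold`). This is deliberately the
simplest radial-basis classifier — one prototype, fixed width, no
trained weights — and the same machinery is reused for cytoplasm color
matching in classification, so the whole system has a single similarity
primitive.

**Working color space.** Segmentation runs on the YCbCr image by
default; the conversion is full-range BT.601 (the JPEG convention,
appropriate since smear captures are typically JPEGs), computed in
floating point, rounded half away from zero and clipped. Studio-range
BT.601 is available as a variant. The reference pixel must be fit in
the same space as the image it is compared to; the pipeline converts
its RGB reference automatically. On the synthetic palette the
nucleus/background YCbCr separation is ≈ 152, versus a decision radius
of ≈ 91 at the default τ = 0.70 — pixel labels are therefore stable to
many σ of the default noise.

**Morphology.** Platelets stain like nuclei but are far smaller;
objects with area < 1500 px at the 1200×1600 reference resolution are
discarded (the threshold scales with relative pixel count at other
resolutions, and exactly-1500-px objects are kept). The surviving mask
is dilated by the discrete radius-3 Euclidean disk (29-pixel footprint)
to recover the rim eroded by thresholding, then interior holes — pale
chromatin gaps — are filled. Order is fixed: threshold → label →
remove-small → dilate → fill → relabel. Descriptors come from
scikit-image's `regionprops`; the perimeter is its weighted
contour-length estimator, and solidity is pixel area over the pixel
count of the rasterized convex hull (verified in tests against an
independent lattice-point hull oracle).

**Fragment merging.** Polymorphonuclear cells, neutrophils especially,
segment into separate lobes. Region pairs whose centroids are strictly
closer than 115 px are joined; cells are the connected components of
this proximity graph (transitive closure, order-invariant, verified
against a union-find oracle). The merge radius is a length, so it
scales with the linear image dimension √(H·W / 1200·1600), unlike the
area filter which scales with pixel count.

**Classification.** The branch rule encodes the
polymorphonuclear/mononuclear dichotomy: ≥ 2 merged lobes, or minimum
lobe solidity below 0.90, marks a cell polymorphonuclear. The 0.90
default sits between observed lobed-nucleus solidities (≈ 0.78) and
compact ones (≈ 0.97). Within a branch the sampled cytoplasm color is
matched to per-class prototypes by the same RBF similarity; ties break
in fixed branch order. Cytoplasm is sampled on the **RGB** image over
an annulus between dilations of the cell's nucleus mask by the inner
(3 px) and outer (15 px) radii, excluding pixels claimed by any other
cell's nucleus or annulus; if nothing remains the sampler falls back to
the padded bounding-box margin. Annulus radii scale with linear image
dimension. An optional nucleus-area tie-breaker for
lymphocyte-vs-monocyte exists but is off by default: it fires only when
the two prototype activations nearly tie (window 0.02), and the default
prototypes are far enough apart that it stays inert on clear colors.

**Agreement statistics.** R² is the squared Pearson correlation of the
13 per-individual count pairs for one class. Identical vectors score
1.0 by the perfect-agreement convention — necessary because an
identical constant pair (the basophil columns of the packaged table)
has zero variance and an undefined Pearson r, yet plainly represents
perfect agreement; a constant vector against a *different* vector
raises instead. Bland–Altman limits are mean ± 1.96·sd of the paired
differences with the n−1 sd. The per-individual-totals R² and the
Bland–Altman mean difference are reported but not asserted against any
external value: published overall figures for this kind of study often
depend on pairing choices that cannot be reconstructed from per-class
tables.

## Synthetic generator

`leukocount.synthetic` renders exactly the features the pipeline keys
on: dark purple nuclei (RGB 80/40/110) and platelets in the same
tonality, class-specific cytoplasm halos equal to the classifier's
default prototypes, a pale pink background (228/200/192), and
independent per-channel Gaussian noise (default sd 4, clipped) — small
relative to the ≈ 150 nucleus/background separation, as in-focus
stained smears are high-contrast. Nuclei are disks or chains of disk
lobes: overlapping chains (spacing < 2r) render connected scalloped
nuclei whose solidity strictly decreases with lobe count; wider spacing
renders disjoint fragments whose areas (r = 24 → 1809 px) each survive
the platelet filter and whose centroid spacing (64–70 px) falls inside
the merge threshold. Mononuclear classes are single compact disks
(lymphocyte r = 26, monocyte r = 32). Cytoplasm halos extend ≥ 20 px
beyond the nucleus so the sampling annulus stays on-halo. The default
composition sampler draws from adult reference frequencies
(neutrophil 62%, lymphocyte 30%, monocyte 5.3%, eosinophil 2.3%,
basophil 0.4%); placement is uniform rejection sampling with a
separation that keeps every cross-cell lobe pair beyond the merge
threshold and halos disjoint. Cell geometry is independent of the seed,
which drives only platelet placement and noise — so recipes differing
only in seed share identical ground truth.

What the generator does **not** emulate: red-cell texture, touching or
overlapping cells, stain and illumination variability, focus blur,
smudge cells, and pathological morphologies. Passing the synthetic
suite therefore demonstrates that the implementation honors its own
contracts (exact segmentation under separated colors, correct merging,
correct rule firing, exact counts), not that the rule thresholds
transfer to real smears — on real data the reference pixel, cutoff and
prototypes must be fit per staining protocol via `fit-reference` and
the config file.

## Numerical choices

- Conversion/rounding: float64 throughout, round half away from zero,
  clip to [0, 255]; forward+inverse YCbCr round-trips within ±1 per
  channel over the 8-bit cube.
- Thresholds: activation cutoff inclusive (E ≥ τ); area filter
  inclusive (area ≥ threshold kept); merge strictly below (d < 115
  merges, d = 115 does not).
- Determinism: component labels in raster discovery order; merge groups
  ordered by smallest member label; detection order follows group
  order; all stochastic code uses `numpy.random.default_rng` with
  explicit seeds.
- Degenerate inputs: empty masks yield empty labelings, descriptor
  lists and zero counts; an annulus emptied by exclusion falls back to
  bounding-box margin sampling before raising.

## Problem sizes

The end-to-end suite used by the tests and the acceptance script runs
50 images at 1200×1600 with 12 cells and 10 platelets each (≈ 600
cells; ≈ 1.5 s/image), enough for every common class to appear dozens
of times while basophils (0.4%) appear in low single digits across the
suite — mirroring their scarcity in real differentials.

## Known limitations

- A single color prototype cannot represent multimodal nucleus
  staining; heavily variable stains would need per-batch reference
  refitting.
- Basophils are decided purely by cytoplasm color in the
  polymorphonuclear branch; real basophil granulation obscures the
  nucleus and stains close to it, so the synthetic basophil halo is a
  stylization chosen to remain outside the segmentation radius.
- Touching nuclei are not split (no watershed); clustered fields are
  out of scope, as is any diagnostic interpretation of the counts.
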