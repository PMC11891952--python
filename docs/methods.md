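# Methods

This note documents the models, conventions and parameter choices behind
`aponecv`, and what its validation does and does not demonstrate.

## Imaging model and preprocessing

The pipeline assumes wide-field/spinning-disk fluorescence images of
adherent cells taken with a low-NA air objective (validated configuration:
10×, NA 0.3, refractive index 1.0), two fluorescence channels excited at
488 nm (6-CF, green) and 561 nm (AnnCy3, red), plus a transmitted-light
plane that is carried through but not used by the computation.

**Background subtraction.** The background of each channel is estimated as
the grayscale opening of the image by a non-flat ball structuring element
(height `sqrt(r² − x² − y²)`) and subtracted, clipping at zero — the
rolling-ball model of a smooth background varying on scales larger than a
cell. Radii: 50 px (green), 30 px (red); the red radius is smaller because
punctate red signal has finer structure. For radii ≤ 20 px the opening is
exact; larger radii use the classic shrink/open/enlarge speed-up
(block-minimum downscale by 4, or 8 above radius 40, opening at the reduced
radius, bilinear enlargement, with the enlarged estimate clamped to lie
under the image). The default radii take the fast path; the approximation
error is a fraction of the noise floor for backgrounds that are smooth at
the block scale.

**PSF and deconvolution.** The channel PSF is the in-focus Airy intensity
pattern `I(r) = [2·J1(v)/v]²`, `v = 2π·NA·r·Δx/λ`, sampled on the pixel
grid in a 63×63 window and normalised to unit sum. The lateral Rayleigh
resolution is `0.61·λ/NA` (in pixels after division by the pixel spacing
Δx). Δx is a calibration the user should always supply; the package default
is 650 nm/px — a 6.5 µm camera pixel behind the validated 10× objective,
the common sCMOS geometry. Deconvolution is non-negative Richardson–Lucy:
`x ← x · (K^T ⊛ (y / (K ⊛ x)))`, initialised at the observed image, with
edge-replicated padding so flux is approximately conserved (within 5% in
tests). Iteration stops at `max_iterations` (default 10) or when the
relative L2 change of the estimate between iterations drops below
`termination_change` (default 0.010). A `wiener_gamma` damping factor
(update scaled by `1/(1+γ)`) exists but defaults to 0 (off). Processing is
entirely 2-D; the `lowpass_z` setting is accepted for configuration
compatibility and ignored.

**Smoothing.** A 3×3 uniform mean filter, applied twice by the pipeline;
edge pixels average their in-bounds neighbours only, so borders are not
darkened before thresholding.

## Thresholding

All three auto-threshold algorithms operate on a 256-bin histogram and
return a bin index; pixels strictly above the mapped intensity are
foreground (both dyes are bright on dark). 8-bit images bin directly;
16-bit images are min–max scaled into the 256 bins and the chosen bin is
mapped back to source intensity units. Min–max scaling (rather than a fixed
0–65535 range) is what makes histogram-shape methods meaningful on sparse
16-bit fluorescence data; it is documented here because it affects
reproducibility across acquisitions with different dynamic range.

* **Intermeans ("Default", mode C green).** From the histogram midpoint,
  iterate `t ← round((mean below t + mean above t)/2)` (round half up)
  until stable. Suits the clearly bimodal histogram of a green-dominant
  control field.
* **Otsu (mode TR green).** Exhaustive maximisation of between-class
  variance over the 255 cut points, ties broken to the lowest index. Used
  for treated samples where the green class has shrunk.
* **Triangle (red, both modes).** A line is drawn from the histogram peak
  to the furthest occupied tail bin; the threshold is the bin of maximum
  perpendicular distance *below* that line (mirror, compute, un-mirror when
  the long tail is on the left; a flat histogram returns its lowest
  occupied bin). Suits the red channel's background peak with a long dim
  tail of punctate signal.

A per-channel manual threshold override exists as an escape hatch for
low-SNR data; see Limitations.

## Watershed splitting

Fused cells are split on the Euclidean distance transform: regional maxima
(merged by h-maxima with tolerance 0.5, so plateau or near-equal maxima
seed one basin) flood the inverted distance map; dividing lines become
background. Because a 1-px line blocks only 4-connectivity, pixels where
two basins would still touch diagonally are peeled off so the split is
effective under the package-wide convention of 8-connected foreground and
4-connected background — with the guard that peeling never erases a basin
outright. Watershed runs on the green mask in both modes and on the red
mask in mode C only: punctate treated-sample red signal does not optically
fuse cells, and splitting it would fragment genuine necrotic accumulations.

## Particle analysis

Particles are 8-connected components. Area is the pixel count with interior
holes filled at measurement time ("include holes"); intensity statistics
(mean, integrated density = mean × area) are taken over the same pixels on
the deconvolved reference plane.

**Perimeter convention.** The outer boundary is the crack polygon (traced
between pixel corners, clockwise, region kept to the right). Its length is
corner-weighted: each counted 90° corner shortens the staircase by
`2 − √2`, and corners on a 1-px staircase are counted on alternate vertices
only, so a 45° staircase measures exactly `√2` per step. Closed forms under
this convention: a 10×10 square measures `40 − 4(2−√2) ≈ 37.66`
(circularity ≈ 0.886), a 1×10 line `22 − 3(2−√2)` (circularity ≈ 0.31),
and rasterised disks score ≈ 0.89–0.90 and rise with radius. The raw crack
length was rejected because it is biased high for curved outlines — a
digital disk would score `≈ π²/16 ≈ 0.62` regardless of radius, which would
misclassify ideally round cells under the strictest gate in use
(circularity ≥ 0.6). Circularity is `min(1, 4π·A/P²)`.

**Gates.** Per class and mode (size in px², validated for a 10× air
objective):

| class | mode C | mode TR |
| --- | --- | --- |
| Merge (apoptotic) | circ 0.2–1, size 100–∞ | circ 0.1–1, size 50–∞ |
| AnnCy3-only (necrotic) | circ 0.3–1, size 100–∞ | circ 0.3–1, size 100–∞ |
| 6-CF-only (viable) | circ 0.2–1, size 100–∞ | circ 0.6–1, size 100–∞ |

The 100↔50 size switch for including more or less dim signal is a plain
configuration edit (`--size-min-*` flags), not a code change. Edge-touching
particles are excluded. Accepted particles are numbered 1..count in raster
order and drawn coloured-and-numbered in the overlay; rejected ones are
white and unnumbered — the overlay is the user's audit trail for gate
choices.

## Classification logic

`Merge = G AND R` is dilated once (3×3) before being subtracted from both
channel masks: the dilation over-covers the apoptotic halos so that thin
green or red fringes — which arise because the two channels threshold at
different levels — do not survive subtraction as spurious fragments. The
merge mask is eroded back (3×3, outside-the-image treated as foreground so
border objects are not eaten) before its particles are counted. The three
masks (viable, necrotic, dilated merge) are pairwise disjoint by
construction and asserted on every run. `total = viable + apoptotic +
necrotic`.

## Agreement statistic

Manual-vs-automated validation uses the intraclass correlation in the
two-way random-effects, absolute-agreement, average-measures form:

```
ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)
```

with MSR/MSC/MSE the row (field), column (rater) and error mean squares of
the n×2 layout. Absolute agreement keeps rater variance in the denominator,
so a systematic counting bias lowers the coefficient. The p-value comes
from `F = MSR/MSE` with (n−1), (n−1)(k−1) degrees of freedom; 95% bounds
are the McGraw–Wong F-based single-measure bounds stepped up by
Spearman–Brown. A zero-variance table is defined as ICC 1.0 with a
degenerate [1, 1] interval. The packaged validation table contains the
paired counts for six HeLa fields (three untreated controls, three after
photodynamic treatment with a zinc-phthalocyanine photosensitiser); on it
the three coefficients are 0.993 (apoptotic), 0.998 (necrotic) and 1.000
(viable), all p < 0.0001, as recomputed by `scripts/acceptance.py` and the
test suite.

## Synthetic scenes

The generator renders what the staining logic implies, at 16-bit, fully
reproducible from a seed (per-cell spawned random streams, so adding a cell
never reshuffles the others):

* cells are flat-top disks with 2-px Gaussian edge feathering (radius
  9–13 px at the default calibration, ≈ twice the size gate at minimum);
* viable → green disk; apoptotic → green disk plus a co-localised red disk
  rendered slightly smaller (the annexin signal decorates the rounding
  cell and stays inside the cytoplasmic 6-CF footprint — the geometry the
  subtraction logic assumes); necrotic → seven overlapping punctate
  Gaussian foci in red only, dense enough to threshold into a single
  accumulation;
* background 300 counts with low-frequency shading (±7.5%) and Gaussian
  noise (σ 40); signal 3000 ± 15% per cell, i.e. signal-to-background 10;
* a negative `min_separation` forces touching: viable cells (by default)
  are laid down in pairs whose rims overlap by that amount, producing
  fused blobs for the watershed; non-negative values are a hard rim gap.

What the scenes do **not** emulate: optical blur matched to the PSF
(convolution with the generated PSF is available but off by default),
photon-statistics (Poisson) noise, irregular cell shapes, confluent
monolayers, debris, and bleed-through. Passing the recovery tests therefore
shows the pipeline's logic is correct under its stated assumptions
(separated or pairwise-touching round cells, nested apoptotic footprints,
adequate SNR) — it does not certify accuracy on arbitrary real micrographs,
which is what the manual-agreement validation is for.

Validated behaviour (recomputed by the test suite): on 20 seeded 512×512
scenes with non-touching cells the classifier recovers every per-class
count exactly, in both modes; with watershed-separable touching pairs
(2 px rim overlap) aggregate per-class counts stay within 5% over 20
scenes. Those problem sizes (10–13 cells per 512×512 field) keep the whole
suite fast while exercising every stage at the validated calibration.

## Numerical and design choices

* Connectivity: 8-connected foreground, 4-connected background, everywhere.
* Binary dilate/erode: 3×3 square, 1 iteration per application; erosion
  treats outside-the-image as foreground.
* Intensity planes stay in their native dtype through the stages; stage
  outputs round back to the input integer type.
* Thresholding happens at native depth via the 256-bin min–max scaling.
* The merge mask's intensity reference is the deconvolved green plane (a
  documented choice; the statistic is supplementary).
* Mode selection (C vs TR) is explicit and user-driven — red-dominant
  fields call for TR, green-dominant for C; no auto-detection.
* Determinism: identical stack + configuration give bit-identical masks
  and counts; run logs record mode, radii, chosen thresholds, gates and
  deconvolution iteration counts, enough to reproduce a run exactly.

## Limitations

* Auto-thresholding assumes the channel contains signal. A signal-free but
  noisy channel makes any histogram-shape method threshold inside the
  noise (the triangle method cuts at the noise peak's shoulder), producing
  spurious foreground; use the per-channel manual threshold override for
  such fields. With a truly empty (constant) channel the masks and counts
  degrade gracefully to zero.
* The perimeter/circularity convention is one of several defensible
  digitisation conventions; gates were validated under it and broad gate
  intervals make the pipeline robust to the choice, but gate values should
  not be transplanted to software using a different convention.
* Only the 10×/0.3 NA configuration is validated; higher magnifications
  change particle scales and gate meanings.
* Fused apoptotic (co-localised) cells are not re-split after the merge
  dilation closes the watershed line; heavily clumped dying cells will
  undercount.
* The two printed channel resolutions of the validated acquisition imply
  slightly inconsistent pixel spacings under `0.61·λ/NA`; pixel spacing is
  therefore treated strictly as user calibration and never inferred.
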