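# Methods

## The measurement problem

Quantifying tau pathology in immunofluorescently labeled brain sections by
hand is slow and rater-dependent. The alternative implemented here is a fixed
algorithmic pipeline: every section is processed with the same parameters, so
the output — percent of imaged area covered by marker-positive objects
("immunoreactive area", IR%) — is reproducible and free of rater bias. The
package covers three layers: a synthetic section generator with exact ground
truth, the measurement pipeline itself, and the factorial statistics of a
Braak-staged cohort design (4 stage groups x 5 brain regions x N cases).

## The measurement pipeline (`tauquant.quantify`)

Stage order is fixed:

1. **Maximum projection** of z-planes (`project_stack`). A handful of
   z-levels per field are collapsed to one 2-D image per channel.
2. **Background correction** (`correct_background`): subtract a Gaussian
   lowpass estimate of the image from itself, clip at zero. The scale
   (`background_sigma_um`, default 125 um for the tau marker) must sit well
   above the largest object diameter — roughly 5x — so the estimate tracks
   illumination gradients and diffuse background, not the objects. A constant
   image maps exactly to zero. For large sigmas the estimate is computed on a
   grid decimated by `sigma/8` and linearly resized back; the estimate is
   smooth by construction, so this changes nothing measurable (verified
   against full-resolution filtering in the tests) while cutting the cost by
   an order of magnitude.
3. **Autofluorescence masking** (`autofluorescence_mask` + `subtract_mask`).
   Lipofuscin granules and erythrocytes fluoresce in *every* emission channel;
   an unlabeled channel therefore images only them. That channel is
   thresholded, the mask dilated by one pixel (sub-threshold halo rims would
   otherwise survive as false marker signal), and the masked pixels are set
   to zero in the marker channel. Masked pixels stay in the denominator: IR%
   is reported per imaged area, not per unmasked area.
4. **Edge enhancement** (`edge_enhance`): high-boost (unsharp) filtering,
   `img + k*(img - lowpass(img, 1 um))`, clipped to the bit range. Strength 0
   is the identity. Sharpening object borders makes single-threshold
   detection robust to the soft shoulders of diffraction-blurred objects.
5. **Detection** (`detect_objects`): threshold (fixed value or Otsu), 8-connected
   components, then size (`min_area_um2`..`max_area_um2`) and shape
   (roundness `4*pi*A/P^2`, clipped to 1 on the pixel grid) restrictions.
   Object mean intensities are always measured on the raw, pre-enhancement
   image so reported brightness refers to the original signal.
6. **Measurement** (`measure_ir_area`): IR% = 100 * sum(object areas) / ROI
   area, with the full image as ROI.

**Plaque cores** (`detect_plaque_cores`) skip edge enhancement: the
ThioflavinS channel is thresholded directly and a minimum-size filter
(default 200 um^2) is applied. Plaque cores are large (>= 30 um across) and
intensely labeled; tangles are only weakly ThioS-positive, so only their
brightest interior crosses the threshold and the resulting fragments sit far
below the size cutoff. Brightness gap and size cutoff act together, and the
discrimination survives either one being marginal.

### Parameters that matter

| parameter | default | why |
|---|---|---|
| `background_sigma_um` | 125 (tau marker) | ~5x largest tangle diameter |
| `af_threshold` | fixed, 50% of nominal AF intensity | robust mid-gap value |
| `af_dilation_px` | 1 | swallows sub-threshold granule rims |
| `edge_strength` / `edge_sigma_um` | 1.0 / 1 um | identity at 0; 1 um is the scale of object borders |
| `signal_threshold` | fixed, 25% of nominal stain intensity | above noise floor and lowpass bias, below the dimmest object pixel (half-peak x gradient) |
| `min_area_um2`, `max_area_um2` | 5, 1e4 (tau marker) | drops noise specks; keeps threads and tangle clusters |
| `roundness_range` | [0, 1] for tau | threads are elongated — no lower bound |
| plaque `signal_threshold`, `min_area_um2` | 18% of stain intensity, 200 um^2 | threshold below weak tangle labeling so the size filter is exercised; cutoff between the largest tangle (~170 um^2) and the smallest plaque core (>= 350 um^2 even border-clipped) |

Every one of these is configuration (YAML per marker), never a constant: on
real data thresholds and size bounds must be re-calibrated per antibody and
microscope, and a snapshot of the values used is written next to every
output. The defaults above are calibrated on the synthetic generator, whose
stain intensities are known.

## The synthetic generator (`tauquant.synthetic`)

The generator emulates what the pipeline must cope with, not tissue optics:

- **tangles** — anisotropic Gaussian blobs cut at half maximum (rotated
  ellipses, 15-25 um long, elongation 0.28-0.35, interior profile in
  [0.5, 1] of peak), bright in the tau channel and weakly present (factor
  0.3) in the ThioS channel;
- **neuropil threads** — random-walk polylines dilated to 1-2 um width;
- **plaque cores** — 30-80 um discs with a bright plateau core and a dimmer
  skirt, in the ThioS channel only;
- **lipofuscin** — 2-6 um discs bright in *all four* channels (the defining
  property of autofluorescence), intense enough to cross the marker
  detection threshold, so autofluorescence subtraction is genuinely load-bearing;
- **nuclei** — 6-10 um discs in the counterstain channel;
- a low-order polynomial illumination gain (+/-15%), Poisson shot noise and
  Gaussian read noise (SD 10 counts on a background of 200, 16-bit range).

Object burden is a target area fraction per class. Objects are placed at
uniformly random positions until the realized pixel count approaches the
target; the last object of a class is sized to the remaining deficit where
the size range allows, so the per-section realized fraction tracks the
target to within half the smallest allowed object (typically a few percent
relative; coarser when the target is below one minimum-size object).
Overlaps are resolved by the fixed priority plaque > tangle > thread >
lipofuscin > nucleus, and ground-truth fractions are counted from the final
disjoint masks — exact by construction.

A whole study (`generate_study`) is 4 stage groups x 5 regions x N cases,
with monotone stage burdens (sparse threads in controls up to ~3-5% combined
tangle+thread burden at stage V/VI) modulated per region (strongest in the
transentorhinal region). Sections get sub-seeds from a counter scheme
(`master * 1000003 + index mod 2^31`), so regeneration is order-independent
and whole studies are reproducible from one integer.

Two mosaic fields per section are supported (`n_mosaics=2`) and averaged
downstream (`average_mosaics`); the default is one section per (case,
region), matching the study bookkeeping of one measurement row per case,
region and marker.

**What the simulator does not model** — optical PSF blur, mosaic stitching
seams, staining chemistry variability, tissue texture, white/grey-matter
structure, erythrocytes as a separate autofluorescence class, 3-D object
shape. Passing the recovery tests therefore shows the pipeline's logic is
correct under a faithful noise/gradient/confounder model, not that the
default thresholds transfer to any particular microscope.

## Statistics (`tauquant.stats`)

- `summarize_cases`: per-group demographic means at printed precision (one
  decimal, rounding half away from zero).
- `isocortex_mean`: per case and marker, the mean of the four isocortical
  regions (temporal, frontal, cingulate, occipital); the transentorhinal
  region never enters. Cases missing a region are excluded and logged.
- `apply_exclusions`: documented per-case rules, scoped to one marker or to
  all; the input table is never mutated and rules naming unknown cases raise.
- `two_way_anova`: stage group x region with interaction. Balanced designs
  use classical sums of squares; unbalanced ones (exclusions break balance)
  fall back to type II, recorded in the result. When the interaction is
  significant at alpha (default 0.05), two Bonferroni families of
  pooled-variance t comparisons follow: stage groups within each region, and
  regions within each stage group, each corrected by its own family size m
  (adjusted p = min(1, m*p), logged).
- `one_way_anova` with Tukey HSD (studentized range at the full number of
  means) or Newman-Keuls (critical value from the span of each comparison in
  the ordered means; a non-significant range seals all nested ranges). On the
  largest span the two coincide by construction. With zero residual variance
  F is reported as 0 (all groups identical) and nothing is significant.
- `fold_change`: group mean / control-group mean per (region, marker);
  control is exactly 1; zero-reference strata are flagged as undefined, not
  reported as infinite.
- `ks_normality`: Kolmogorov-Smirnov with estimated parameters
  (Lilliefors-corrected null, the appropriate choice when no population
  parameters exist). For n = 3 — below the tabulated range — the null is
  simulated with a fixed internal seed. Constant samples raise instead of
  producing a meaningless p. A `fitted` flavor with the naive KS null is
  available as a config switch.
- SEM is SD/sqrt(n) with n counted after exclusions.

## Problem sizes and numerical choices

Single-section fixtures use 512^2 px at 0.5 um/px (a 256 x 256 um field);
simulated studies use 256^2 px sections so a 20-study sweep stays cheap.
These sizes keep every validation surface dense (hundreds of objects per
section at high burden) while the full suite runs in minutes. Ties and edge
cases: degenerate single-pixel outlines get roundness 1; Otsu on a constant
image returns "nothing above threshold"; subtraction steps clip at 0
(unsigned images); components are 8-connected; coordinates are 0-based with
origin top-left, x rightward, y downward; areas are pixel counts times
pixel_size^2.

Known limitation: the background lowpass is biased near image borders
(nearest-neighbour padding), which can over-subtract next to a bright object
touching the border and occasionally split a border-straddling plaque into
two detected pieces. Border effects of this kind are inherent to local
background estimation; validation therefore scores plaque recovery by
object-level coverage rather than exact fragment counts.

## Reproducibility

Everything is deterministic given the master seed: simulation via the
counter scheme above, the pipeline itself seed-free, and study outputs
byte-identical across repeated runs. Each CLI output directory contains a
`run_config.yaml` snapshot (including the library version) sufficient to
replay the run.
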