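# Methods

`mitophen` quantifies four mitotic phenotypes of KIF22-variant chondrocytes
from fluorescence microscopy, and ships a synthetic-microscopy generator
whose condition presets encode the study's per-condition means so that every
stage can be validated by parameter recovery. This note documents the
models, the defaults and why they were chosen, and what the synthetic data
do and do not establish about real images.

## Quantification procedures

### Anaphase separation tracking (`anaphase_quant`)

Per frame of a two-channel movie (chromosome label + tubulin):

1. z maximum-intensity projection (movies carry 3 focal planes per
   timepoint; the projection is this package's choice — standard for thin
   mitotic cells and sufficient for 2-D algorithms).
2. Spindle poles: Gaussian smoothing (σ 0.5 µm) of the tubulin plane, the
   two brightest local maxima at least 2 µm apart, sub-pixel refinement by
   local intensity-weighted centroid, ordered along x. Pole identity across
   frames is kept by nearest-neighbour matching to the previous frame so the
   profile orientation cannot flip.
3. Chromosome-channel intensity is sampled along the infinite line through
   both poles at one-pixel spacing, bilinearly interpolated, averaged over a
   perpendicular band of ±0.55 µm (5 px at the default calibration; the
   original macro's line width is unstated — a narrow band suppresses noise
   without blurring the peaks).
4. The profile is split at the midpoint between the poles (position 0); the
   intensity maximum of each half is refined by 3-point parabolic
   interpolation, and the distance between the two refined maxima is the
   chromosome-mass separation. Ties within a half resolve toward the
   midpoint, and tied (flat-topped) maxima are reported at the tie-rule
   position without refinement.

The reported endpoints are the per-division maxima of the chromosome-mass
and pole separations. Frames failing pole detection are recorded as missing
and excluded; a movie with more than half its frames missing is rejected.
No background subtraction is applied to live movies.

### Polar-ejection-force assay (`pef_assay`)

On fixed monopolar cells, relative PEF is the distance from the collapsed
pole pair to the maximum of the DNA channel's radial intensity profile. The
center is the midpoint of the two brightest centrin foci (their blurred
merged spot's half-maximum-region centroid when they are unresolved), or the
Otsu-thresholded tubulin centroid when no centrin channel exists. Pixels
inside a 14 µm circular ROI are assigned to annular bins (default width one
pixel, 0.11 µm) by Euclidean distance; each bin reports its mean intensity.
The profile maximum is refined parabolically; ties break toward the smaller
radius (conservatively toward lower PEF). No background subtraction by
default (exposed as an option).

A known property of annulus-mean profiling: for chromosomes of radial width
σ_r placed on a ring of radius r, the profile peak sits inside the ring by
roughly σ_r²/2r. With the generator's 0.25 µm blobs this is ≈0.01 µm at
r = 3 µm and ≈0.05 µm at r = 1.2 µm — visible in the knockdown condition's
recovered mean (≈1.10–1.15 µm vs encoded 1.2 µm) and well inside the
acceptance band (3 × the reported SEM of 0.1 µm).

### Nuclear morphometry (`nuclear_morphometry`)

Segmentation: Gaussian smoothing (σ 0.5 µm), global Otsu threshold, hole
filling, removal of components smaller than 20 µm² or touching the border;
touching nuclei are not split (the generator guarantees non-overlap and
clump splitting is out of scope). Solidity is mask area divided by the area
of the filled convex hull, where a pixel belongs to the filled hull when its
center satisfies every hull half-plane (hull vertices from
`scipy.spatial.ConvexHull`; degenerate point/line masks are their own hull).
This pixel-center convention yields exactly 1.0 for digitized convex shapes,
matching the "solidity 1 = round nucleus" reading of the assay; corner-based
hulls (e.g. skimage's) give ≈0.98 for a digitized circle and would shift
every downstream threshold.

The abnormality threshold is the 5th percentile of control-population
solidity (linear interpolation between order statistics, ≥ 20 values);
classification is strict (`solidity < threshold` ⇒ abnormal, equality ⇒
normal). Thresholding is pooled across control images.

### Expression quantification (`intensity_quant`)

The spindle mask is the largest connected component of the Otsu-thresholded,
lightly smoothed (σ 0.3 µm) tubulin channel, computed per cell. Background
is the median intensity outside a 2 µm dilation of the mask (robust and
parameter-light); the background-subtracted mean KIF22 intensity within the
mask is floored at 0. Per-cell values are normalized to the mean of the
control condition; knockdown percentage is 100·(1 − normalized mean) and
fold change is the normalized mean itself. Cells are pooled across
replicates before normalization.

### Statistics (`stats_report`)

Condition summaries are mean ± SEM (sample SD/√n; a single-value group
reports SEM 0 and is flagged). Comparisons follow the study's figure
legends: classic equal-variance one-way ANOVA, then either Tukey's HSD
(studentized range, via statsmodels) or Šídák-adjusted pairwise t-tests
(p_adj = 1 − (1 − p)^m). Significance bands use the conventional
0.05/0.01/0.001/0.0001 thresholds. `run_pipeline` chains
simulate → quantify → summarize → compare deterministically (bitwise-equal
summary JSON under a fixed config).

## Synthetic data model

Objects are sums of Gaussian components (or radially parameterised polygons
for nuclei), blurred with a Gaussian PSF (σ 0.15 µm) and degraded with
Poisson shot noise on object-plus-background photons plus additive Gaussian
read noise — the standard sCMOS model. Defaults: 0.11 µm pixels, 1 min
frame interval, 300 expected photons per unit object intensity, background
0.3 units, read noise 2 counts. Pixel values are photon counts. Identical
(preset, acquisition, seed) triples are bitwise reproducible.

**Anaphase movies.** True separations follow a saturating exponential
d(t) = D(1 − e^(−t/τ)) with τ = 5 min for both chromosome masses and poles
(poles start from the 9 µm metaphase spindle length). The study reports
only mean ± SEM trajectories and analyzes the per-division maximum, so a
smooth monotone approach to a plateau is a modeling choice, not a fact of
the source data. Per-cell plateau variability is lognormal with CV 10%
(chosen so batch SEMs at study-scale n are of the right order), truncated so
the spindle stays inside the field. Chromosome masses are isotropic
Gaussians (σ 1.5 µm); poles are σ 0.5 µm points joined by a dim ridge.

**Monopoles.** 8–16 chromosome blobs (σ 0.25 µm) at uniform-random angles
on a ring of the preset radius, per-blob radial scatter SD 0.15 µm and
per-cell lognormal radius factor (CV 10%); two centrin points ≤ 1 µm apart
at the center; a diffuse GFP halo.

**Nucleus fields.** Nuclei are placed on a jittered 20 µm grid (no overlap,
no border contact), base radius 5.0–6.2 µm, mild ellipticity. Normal nuclei
carry a low-amplitude radial texture (harmonics k = 2…6 with a fixed 1/k
weight profile and random phases); the per-nucleus amplitude is drawn as
scale·√U so that the solidity deficit — roughly quadratic in amplitude — is
spread with near-uniform density down to its deepest value. That dense,
smooth lower tail is what makes the control 5th percentile a stable
quantile (n = 2000 estimator SD ≈ 0.001 across seeds); thin-tailed
amplitude laws were tried first and produced percentile estimates swinging
by ±0.005 or worse. Lobed nuclei carry 2–4 deep lobes cutting inward from
the ellipse boundary. The normal texture scale is calibrated by bisection
so that the 5th percentile of *measured* solidity over a large
control-preset batch (including its 4.4% lobed component) equals 0.966; the
packaged calibration is cached, versioned, and keyed to the acquisition
parameters (`calibrate_presets` re-runs the bisection for other
acquisitions).

**Expression images.** A bipolar metaphase spindle in the tubulin channel;
spindle- plus chromatin-plate-shaped KIF22 signal scaled by the preset's
expression fold with per-cell CV 10%.

**Presets.** Each named condition encodes the study's printed means as
ground truth: chromosome/pole separation plateaus (e.g. wt 14.8/21.3 µm,
e222q 5.0/14.4 µm, p144t 8.6/17.4 µm, r149q 4.7/15.8 µm, r49q 11.4/18.2 µm
with control KD and 8.9/18.9 µm with KIF22 KD, GFP-only 14.3/22.0 µm control
and 17.2/21.0 µm KIF22 KD), monopole ring radii (3.0 µm endogenous control,
1.2 µm knockdown, 3.1/2.8/3.1/2.6 µm for WT/P144T/E222Q/R49Q rescues),
abnormal-nucleus fractions (4.4%…67.9%), and expression folds (0.25 for the
75% knockdown; 2.0 for induced constructs, inside the reported 1.6–2.5×
range). The R149Q abnormal fraction was not reported and is set equal to
E222Q, the variant of comparable severity.

### What the synthetic data do not model

No chromosome-level substructure, lagging chromosomes, cytokinesis, spindle
drift or rotation during anaphase, uneven illumination, camera fixed-pattern
noise, or clumped/overlapping nuclei. Passing recovery tests therefore
demonstrates correctness of the measurement algorithms under the stated
imaging model — not robustness to every artifact of real microscopy; on
real data the segmentation and detection parameters are the knobs to
revisit.

## Numerical choices and degenerate inputs

- Peak refinement is 3-point parabolic with the offset clipped to ±half a
  sample; non-concave or flat neighbourhoods and tied maxima are left at
  the tie-rule sample.
- Pole detection requires two maxima ≥ 2 µm apart; monopoles therefore fail
  detection by design and are reported per-frame as missing.
- Radial bins are (0, R] half-open; the pixel exactly at the center (r = 0)
  belongs to no bin; empty bins propagate as missing values.
- Stack pixels are stored as float32; all measurement arithmetic is float64.
- Solidity of degenerate masks (single pixels, lines) is defined as 1.

## Problem sizes

Recovery checks use 20 movies (256×256, 30 one-minute frames) per anaphase
condition, 30 monopoles per PEF condition, 2000 control and 400 variant
nuclei, and 50 cells per expression condition — the per-condition scale of
the study itself (20–50 cells for imaging endpoints, hundreds of nuclei per
condition).
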