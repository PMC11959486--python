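# Methods

This note documents the measurement models implemented in `synaptoquant`,
the assumptions behind them, the parameters that matter, and what the
synthetic phantoms do and do not establish about real data.

## Membrane-shell intensity

The quantity of interest is the mean fluorescence of a postsynaptic
protein in the thin zone surrounding the presynaptic membrane of an NMJ
bouton. The procedure, per NMJ:

1. A square ROI (default 47×47 px; at 0.21 µm/px roughly a 10 µm square)
   is selected on the maximum-intensity projection — bouton selection is
   inherently manual, so the ROI centre is an input — and carried through
   all z slices of every channel.
2. Every channel is background-corrected by subtracting the mean of its
   sub-Otsu signal; negatives are clamped to zero (intensities are
   non-negative; the subtraction constant is reported alongside each
   measurement).
3. The membrane mask M is the Otsu foreground of the **uncorrected** HRP
   channel, cleaned by 3D morphological opening with a digital ball of
   radius 2 voxels (0.42 µm laterally). The measurement region is the
   shell `dilate(M, ball) AND NOT erode(M, ball)` — a band straddling the
   mask boundary roughly two voxels on either side.
4. The reported value per channel is the mean background-corrected
   intensity inside the shell, together with the shell voxel count.

Assumptions: the HRP channel has a bimodal histogram (Otsu separability);
the membrane is thick enough to survive opening with the radius-2 ball
(otherwise a "no membrane found" error is raised rather than measuring a
spurious region). Otsu is computed once on the full 3D cropped channel,
not per slice; the histogram always has 256 bins over the data range and
ties resolve to the lowest qualifying threshold, making results
deterministic and bit-depth independent. The ball is isotropic in voxel
units even though the z pitch (0.24 µm) is coarser than xy (0.21 µm) —
the radius is defined in pixels, and the slight physical anisotropy of
the shell is the same for every group being compared.

Two useful invariances follow from the construction and are enforced by
tests: adding a constant offset to a measured channel leaves the shell
mean unchanged (absorbed by background correction, as long as the offset
does not move Otsu class memberships), and scaling a channel by k scales
the shell mean by k.

## Receptor-field segmentation and sizing

Glutamate-receptor fields are segmented by combining a neuronal-membrane
gate with a local threshold of the receptor channel:

1. **Mask 1** — each slice of the HRP channel is binarized with the
   moment-preserving (Tsai) threshold: the threshold whose binary image
   preserves the first three gray-level moments of the slice, computed on
   a 256-bin histogram; the threshold lands on the lowest gray level
   whose cumulative histogram reaches the background fraction p₀ given by
   the moment equations.
2. **Mask 2** — each receptor-channel slice undergoes rolling-ball
   background subtraction (radius 2 px) and then Bernsen local
   thresholding (radius 10 px); the per-slice masks are stacked into a
   3D mask.
3. Mask 2 is gated by mask 1 (voxelwise AND); parts of the receptor
   signal outside the HRP-positive territory are excluded.
4. 3D connected components (26-neighbour connectivity, configurable) are
   counted; only objects with **strictly more than** `min_voxels`
   (default 10) voxels are kept. At 0.21/0.24 µm sampling the 10-voxel
   cut corresponds to 0.10584 µm³.
5. Each object's voxel count × voxel volume gives V, reported with the
   equivalent sphere radius r_eq = (3V/4π)^(1/3) and the centroid in µm.

**Rolling ball.** The background is the sliding-paraboloid construction:
the upper envelope of all paraboloids of curvature 1/radius that fit
under the intensity surface — equivalently a grayscale opening by the
quadratic structuring function −d²/(2r). We deliberately do not use a
flat disk (or finite-ball) opening: a flat element of radius 2 returns
any convex plateau wider than ~2 px unchanged, so the subtraction would
hollow out exactly the objects the pipeline is meant to measure. The
paraboloid instead removes arbitrarily wide *smooth* backgrounds while
preserving high-contrast structures of any width, because it cannot climb
an intensity cliff taller than its curvature allows; this matches the
behaviour practitioners expect from the classic background-subtraction
tool at small radii. The min-plus/max-plus passes are separable per axis
and exact (full-extent windows), and the implementation is verified
against a naive sup-over-translates oracle. One consequence worth noting:
the operation is not equivariant under intensity scaling (the quadratic
term has fixed units), so segmentation is only approximately invariant to
global gain changes — exact on high-contrast phantoms, and tested as such.

**Bernsen.** For each pixel, the local min/max over the radius-10 disk
define the midgray (min+max)/2 and local contrast (max−min). Pixels in
windows with contrast ≥ the contrast parameter are foreground iff their
value exceeds the midgray; low-contrast neighbourhoods are classified
wholesale by comparing their midgray to the slice's global Otsu
threshold. This keeps the *interior* of objects wider than the Bernsen
window (where local contrast collapses) foreground, and distant empty
background background. The contrast parameter defaults to 15 on an
8-bit-normalized scale and is rescaled by the composite pipeline to
15/255 of the background-subtracted channel's global range, making the
default meaningful for float data of any gain. Out-of-bounds pixels are
excluded from local windows (not padded). Slices without two distinct
values yield empty masks rather than errors inside the composite.

## Active-zone / receptor-field apposition

The ratio reported is **total BRP spots in the image divided by total
receptor fields in the image** — a division of two counts, not a
per-field assignment, so spots need not lie inside a field to count.

Spots are detected as blobs of stated physical size (xy diameter 0.2 µm,
z diameter 0.8 µm): the channel is filtered with a
Laplacian-of-Gaussian whose per-axis scales map the anisotropic diameters
onto the voxel grid (σ = radius/√3 per axis), strict local maxima of the
negated response are extracted with a neighbourhood matched to the spot
size, and plateaus of tied maxima (sub-voxel spots centred between voxel
centres) are merged into a single detection at their centroid. The
original procedure this stands in for used a manually adjusted "quality"
cut; since a manual step is not reproducible, the stand-in discards
maxima whose response does not exceed a configurable quantile of the
response volume (default 0.995). Spots closer than about one spot
diameter merge — a documented limitation shared by any single-scale
detector.

Receptor fields are segmented as surfaces: Gaussian smoothing at the
surface-detail scale (0.065 µm), background subtraction by grayscale
opening at the largest-inscribed-sphere diameter (0.244 µm — a no-op at
default sampling, where that sphere is smaller than one voxel), Otsu
thresholding, 3D hole filling (donut-shaped fields become solid objects),
and watershed splitting of touching objects seeded by smoothed
distance-transform maxima no closer than the seed-point diameter
(0.6 µm). Thresholding is automatic (Otsu) where the original workflow
was manual, for the same reproducibility reason.

## mEJP analysis

A recording passes QC only if its resting membrane potential is at or
below −60 mV (inclusive). The RMP is estimated as the 10th percentile of
the voltage trace — robust to depolarizing events and deterministic.

Event detection is a documented surrogate for interactive mini-analysis
software whose criteria are not public: a blockwise (0.25 s) 10th
percentile baseline is interpolated to the sample grid; the
baseline-subtracted trace is lightly smoothed (2 ms boxcar); peaks are
accepted if they rise at least `threshold` mV above baseline with a
prominence of 0.8×threshold (so noise wiggles riding on a decay are not
double-counted); peaks closer than a quarter of the decay-time hint are
merged. Consequences: events below threshold are never seen (any
threshold detector truncates the amplitude distribution from below), and
near-coincident events merge. At SNR ≥ 10 the detector's recall and
precision both exceed 0.95 on generator traces — the regime the summary
statistics are intended for.

Summaries: frequency = count/duration; mean amplitude = arithmetic mean;
amplitude histograms are reported as fractions per bin (summing to 1)
plus the fraction of events **strictly above** a cut, default 0.8 mV.

## Synthetic phantoms: what they emulate, and what they do not

All generators are pure functions of (parameters, seed), one
`numpy.random.default_rng` stream per call, so every fixture is exactly
reproducible.

* **NMJ stacks** (`make_nmj_stack`): hollow spherical bouton membranes
  (radius 2.0 µm, half-thickness 0.65 µm — thick enough to survive
  opening by the radius-2 ball) in the HRP channel; a perimembrane slab
  of uniform intensity `shell_intensity × group_effect` in the measured
  channel, wide enough to cover the entire morphological shell so that
  with zero noise the measured shell mean equals the stored truth
  exactly; donut-shaped receptor fields (radius 0.35 µm, bright rim, dim
  core) on the bouton equators; Gaussian BRP spots placed on fixed slots
  around field centres (centre + two rings, capacity 11), with fixed or
  Poisson-distributed counts per field. Noise is Poisson-gated signal
  plus background (level 20) with additive Gaussian read noise.
* **Field phantoms** (`make_field_phantom`): solid spheres (in µm space;
  ellipsoids in voxel space) of stated radii inside a box-shaped
  HRP-positive envelope; optional spheres outside the envelope exercise
  the gating step. The stored truth volume is the **post-rasterization
  voxel count** × voxel volume, because the pipeline measures voxels; a
  radius below 2 voxels on any axis raises rather than silently
  disappearing. The small-radius recovery checks therefore run at a
  finer sampling (0.105/0.12 µm) than the default confocal geometry.
* **Traces** (`make_mejp_trace`): homogeneous-Poisson event times over
  the recording; each event an instantaneous rise with exponential decay
  (τ = 40 ms default); amplitudes from a zero-truncated Gaussian with an
  optional second, heavier truncated-Gaussian mixture component for
  right-tailed histograms; Gaussian baseline noise on a resting potential
  of −68 mV; 2 kHz sampling; default duration 108 s (1.8 min, a typical
  control recording length). The default amplitude parameters
  (μ = 0.60 mV, σ = 0.29 mV) put ≈25% of the mass above 0.8 mV, the
  control-like condition; the "depleted" condition (rate 3 Hz, μ = 0.71,
  σ = 0.33) puts ≈40% above the same cut. The real amplitude distribution
  of mEJPs is not known in closed form; these are explicit stand-ins.

The phantoms contain no optical point-spread function, no spectral
bleed-through, no bleaching or drift, and their structures are geometric
idealizations. Passing recovery tests therefore demonstrates that the
pipelines measure what they claim on data satisfying their assumptions —
correct plumbing, thresholding, morphology and statistics — not that the
biological numbers from any particular microscope would be reproduced.

## Group statistics

Group comparisons use the unpaired t-test; since pooling of variances is
a free choice, the unequal-variance (Welch) form is the default and the
pooled Student form is available via a flag. Reported per group: n, mean,
s.e.m., percent change versus control (100×(control−group)/control, so a
reduction is positive), t, p and a significance marker (ns, *, **, ***
at 0.05/0.005/0.0001). One-tailed tests require an explicit direction.
No multiple-testing correction is applied, matching the reporting style
the pipeline reproduces; users running many comparisons should correct
downstream.

## Numerical choices and problem sizes

* Histograms for Otsu and Moments: 256 bins over [min, max]; ties to the
  lowest qualifying threshold; foreground strictly above the threshold.
  When a sparse valley separates two classes the between-class variance
  is numerically flat across it; any threshold in the flat region is an
  equally valid maximizer, which is how oracle equivalence is asserted.
* Morphology: digital ball/disk footprints defined by d² ≤ r²; binary
  operations treat out-of-bounds as background; local min/max filters
  ignore out-of-bounds pixels.
* Coordinates are voxel-centre based: physical position = (index+0.5) ×
  pitch; ROIs are half-open; even-sized ROIs centre toward the origin.
* Default test/recovery problem sizes (chosen to keep the whole suite
  comfortably interactive): 20 seed pairs for the intensity-reduction
  recovery, 100 seeds for the Poisson apposition and mEJP statistical
  recoveries, 10 × 30 s traces for detector quality, single stacks of
  order 40×50×200 voxels.

## Known limitations

* The 47 px ROI at the nominal 0.21 µm pixel pitch is 9.87 µm, slightly
  short of the ~10 µm square usually quoted for this ROI size; pixel
  pitch is an input and no attempt is made to reconcile rounded
  calibrations.
* The Bernsen contrast parameter and its low-contrast tie rule, the spot
  "quality" cut and the mEJP detector settings are stand-ins for manual
  or undocumented steps; all are explicit configuration with documented
  defaults, and absolute values measured from real data will depend on
  them.
* Single-scale spot detection merges spots closer than about one
  diameter; the detector merges events within a quarter decay constant.
* TIFF geometry comes from configuration, not from tags; a conflicting
  calibrated tag triggers a warning and the configured value wins.
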