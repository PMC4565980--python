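# Methods

## Scope and model

`telolamina` quantifies, in three-channel 3D-SIM-like volumes of single
nuclei (lamin A, LAP2α, TRF1), three spatial statistics that together
describe how the nucleoplasmic lamin-binding protein LAP2α relates to
telomeres and how telomeres relate to the nuclear lamina:

1. **Radial intensity profiles.** For each detected telomere (TRF1 focus)
   inside a projected optical section, LAP2α intensity is sampled along
   eight rays at 45° intervals out to 400 nm, bilinearly interpolated at a
   40 nm step, and averaged over rays. Profiles are normalized per nucleus
   to the LAP2α min/max over the nucleus section, which removes
   between-nucleus brightness differences before pooling. Condition-level
   curves are the pointwise mean ± SEM over telomeres (telomeres, not rays,
   are the unit of replication), and the profile peak is the grid distance
   of maximal mean normalized intensity. In wild-type-like geometry the
   peak sits at the telomere center; when the LAP2α partner focus is
   displaced by ~380 nm the peak moves to the 360–400 nm bin.

2. **Surface-colocalization coverage.** The LAP2α channel is binarized by
   an Otsu threshold computed from intensities inside the nucleus only.
   Per-nucleus coverage (`lap2c`, in percent) is the fraction of the
   projected nucleus section occupied by the binarized LAP2α mask.
   Per-telomere coverage is the fraction of the telomere's projected pixels
   overlapping that mask. Telomeres are classified *low* / *average* /
   *high* relative to `lap2c ± σ`, with both boundaries inclusive into
   *average* (a determinism choice; the convention only affects ties).

3. **Telomere-to-lamina distance.** The lamina surface is the inner
   morphological boundary (6-connectivity) of the nucleus mask. Distances
   are Euclidean in nanometres with per-axis voxel sizes, from the spot's
   intensity-weighted centroid to the nearest surface voxel, computed with
   a k-d tree over surface-voxel coordinates. This is mathematically the
   brute-force minimum — a grid-sampled distance transform was rejected
   because it is only exact at voxel centers, while centroids are
   continuous. A telomere is peripheral when its distance is ≤ 250 nm.

"Surface" quantities (1, 2) are measured in 2-D projected sections of
default thickness 544 nm (≈ 5 planes at the 125 nm axial pitch), mirroring
how such areas are quantified in practice; lamina distances (3) are
measured in full 3-D. Only telomeres whose centroid lies inside the
section window are profiled — telomeres away from the section otherwise
dilute the profiles with unrelated content.

## Segmentation and detection choices

* **Nucleus**: Otsu on the Gaussian-smoothed (σ = 100 nm) marker channel,
  per-slice hole filling (a lamina stain is hollow in mid-nucleus slices),
  then the largest 3-D connected component. Discarded components trigger a
  warning.
* **Spots**: multiscale Laplacian-of-Gaussian (4 log-spaced radii spanning
  100–400 nm, σ = r/√3 per axis in nm so anisotropy is respected). Local
  maxima inside the nucleus are kept when the smoothed intensity exceeds
  `median + k · 1.4826 · MAD` of the smoothed channel inside the nucleus.
  The robust statistics are taken on the *smoothed* channel because the raw
  background of a fluorescence stack is zero-inflated, which collapses both
  median and MAD; the default factor is `k = 10` because the expected
  maximum of ~10⁶ background voxels is itself ≈ 5σ, so any single-digit-σ
  cut admits noise maxima by construction while genuine SIM-resolved foci
  sit tens of σ above background. Candidates closer than the stronger
  candidate's detected blob radius (and never closer than the minimum
  radius) are merged; member voxels are assigned by watershed on the
  smoothed channel seeded at the kept maxima. Ties between equal-intensity
  maxima break on lexicographic (z, y, x) order.
* **Category σ**: the population behind "one standard deviation" is taken
  as the per-telomere coverage values within the same nucleus
  (`coverage_sigma`), matching the per-nucleus normalization philosophy
  used everywhere else. This is a genuine free choice and is exposed so a
  caller can substitute e.g. a patch-based σ.

## Synthetic volumes

The generator emulates the statistical structure the analysis assumes — it
is the test bed, not a physical simulation:

* ellipsoidal nucleus, default semi-axes (2000, 3000, 3000) nm. This is a
  deliberately scaled-down fibroblast nucleus: it preserves every length
  scale that matters to the method (PSF, spot size, shell thickness,
  section thickness, 250 nm proximity band) while keeping volumes around
  10⁶ voxels so whole-batch analyses run quickly;
* voxel size (125, 40, 40) nm — the axial pitch follows standard 3D-SIM
  acquisition (0.125 µm z-spacing); the 40 nm lateral pitch is a typical
  reconstructed 3D-SIM pixel, a free choice since reconstruction pitch is
  instrument-dependent;
* a lamina shell (100 nm thick) plus a dim nucleoplasmic lamin pool (25% of
  shell amplitude). Lamin A is not exclusively peripheral, and the interior
  signal is also what makes whole-nucleus thresholding behave as it does on
  real stacks — a pure hollow shell loses its polar caps under Otsu;
* telomere foci of radius 150 nm; a `lamina_fraction` of them is placed
  within 250 nm of the surface by rejection sampling (hard cap of 1000
  attempts per focus, then a generation error naming the constraint). The
  default 0.32 makes the *total* peripheral fraction ≈ 50% once the
  uniformly placed remainder's shell-volume share (~26% for this geometry)
  is added;
* LAP2α foci of radius 150 nm. A fraction (default 0.9) of telomeres gets
  an associated focus displaced by `lap2_offset_nm`; the displacement
  direction is uniform **within the section plane** by default. An
  isotropic 3-D mode exists, but out-of-plane displacement is invisible to
  a 2-D section measurement: it smears the projected offset toward zero
  and piles partner-focus tails onto the telomere center, so the in-plane
  mode is what "offset as seen by the measurement" means. Background foci
  are added until the *binarized* LAP2α mask (blur + within-nucleus Otsu,
  i.e. exactly what the analysis computes) covers the target fraction of
  the central section; the count is found by doubling plus bisection. The
  LAP2α texture (focus size, density) is otherwise a free parameter — no
  quantitative description of the real texture exists to match;
* anisotropic Gaussian PSF, default σ = (125, 50, 50) nm — consistent with
  ~120 nm lateral / ~300 nm axial SIM resolution; no optical-sectioning or
  reconstruction-artifact physics;
* Poisson shot noise (scale = photons per intensity unit) followed by
  additive Gaussian read noise, both optional; ground truth (telomere
  centers, analytic distances to the ellipsoid surface via the Lagrange
  root, LAP2α focus centers, assignment, achieved coverage) is recorded
  before blur and noise.

The 2-D intensity-field generator lays non-overlapping elliptical nuclei on
a cell grid (one nucleus per cell guarantees non-overlap; an explicitly
too-small canvas is a generation error) with per-nucleus mean stain
intensities drawn from a bivariate normal with the requested correlation.

What passing tests on these volumes does **not** show: robustness to SIM
reconstruction artifacts, chromatic shift, uneven illumination, clustered
or touching nuclei, or LAP2α textures unlike blurred granules. Results on
real data depend on those factors; the tests establish correctness of the
measurement machinery, not instrument-level validity.

## Numerical conventions

* Arrays are (channel, z, y, x); voxel *i* sits at coordinate
  `i · voxel_size`; all distances in nm.
* Section windows include planes with `|z − z_center| ≤ thickness/2`
  (inclusive); binary masks project by the any-voxel rule, intensities by
  the mean.
* Rays leaving the nucleus section are truncated and excluded from the
  per-distance mean (zero-filling would fabricate a decaying profile for
  peripheral telomeres).
* Normalized intensities are clipped to [0, 1]; normalization is undefined
  (an error) for a constant nucleus section.
* Welch's t is the default two-group comparison — the pooled-variance
  Student form is available by flag but is not robust to unequal
  variances; the χ² homogeneity test drops all-zero categories (they carry
  no information) and refuses tables with expected counts below 1.
* Pearson CIs use the Fisher-z transform with ±1.96/√(n−3).

## Problem sizes

Default acceptance-scale runs use 20 nuclei per condition (~100 telomere
profiles per condition, comparable to the replication such experiments
report), 10⁴ placement draws for the shell-fraction check, 100 random masks
for the distance oracle, 1000/2000 nuclei for the correlation stages, and
2000 replicates for test calibration. These sizes give standard errors
comfortably inside every tolerance asserted.

## Known limitations

* Nucleus boundaries from intensity thresholding carry a small systematic
  dilation when a bright shell overlays a dim interior; lamina distances
  inherit a bias of roughly half a lateral PSF width (~tens of nm).
* The LoG detector is tuned for SIM-resolved, roughly spherical foci
  (100–400 nm); densely packed or elongated foci will merge.
* Coverage calibration targets the central section; off-center sections of
  the same volume may deviate by a few percentage points.
* `read_volume` handles plain multi-page TIFF and OME-TIFF only; no
  proprietary microscope formats.
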