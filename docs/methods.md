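# Methods

This note documents the models implemented in `vesishape`, the defaults and
why they were chosen, the numerical decisions that matter for reproducing
its outputs, and what the synthetic-data generators do and do not emulate.

## Forward model: surface-labeled structures

Structures are ideal geometric surfaces decorated by label: a **vesicle** is
a sphere of diameter *d*; a **tubule** is a capsule (spherocylinder) of tube
diameter *d* and full end-to-end length *L*, *L* ≥ *d*, so that *L* = *d*
degenerates exactly to a sphere. The capsule's hemispherical caps are a
modeling choice — the end geometry of a membrane tubule has no sharp edges,
and the capsule makes the vesicle a smooth limit of the tubule family.
"Length" always includes the caps.

Rasterization is binary: a voxel carries label 1 when its center lies within
the shell half-width (default ±5 nm, emulating an antibody layer) of the
ideal surface, else 0. Voxel centers are tested exactly, with no
anti-aliasing or partial-volume weighting; this keeps the rendered shell
verifiable voxel-by-voxel against a brute-force distance computation, which
the test suite does on small grids.

Grid conventions: the default grid is 200³ cubic voxels of 5 nm. Voxel and
pixel centers sit at (i + 0.5)·size in absolute nm. Structures are centered
on the **center voxel** (index n//2 along each axis) rather than the grid's
geometric center: for even n the geometric center falls on a voxel corner,
and centering on a voxel makes the degenerate point source (diameter 0,
shell 0) occupy exactly one voxel. The resulting half-voxel (2.5 nm) offset
is immaterial for fits, which have sub-pixel centers.

Orientations are uniform over the rotation group, drawn as normalized
4-vectors of iid standard normals (uniform unit quaternions). The sampler is
seeded; its isotropy is property-tested (E|cos θ| = 1/2, octant uniformity).

Projection into the focal plane is an orthographic sum along the optical
axis. This is appropriate because the largest simulated object (300 nm) is
far smaller than the axial extent of the emulated microscope's focal volume
(~700 nm), so the whole structure is effectively in focus; total signal is
conserved exactly. There is no 3D PSF, refractive-index or aberration model.

## Optics

The lateral PSF is radially symmetric with FWHM Γ:

* STED (`lorentzian`): k(r) ∝ 1 / (1 + (2r/Γ)²), Γ = 80 nm by default.
  This is the unique radially symmetric Lorentzian with the stated FWHM.
* confocal (`gaussian`): k(r) ∝ exp(−4 ln2 · r²/Γ²).

Kernels are rendered on an odd-sized pixel grid covering ±`support_radius`
(default 4Γ; at least 3Γ) and renormalized to unit sum. The Lorentzian's
heavy tails make truncation a real modeling decision — about 20% of the
untruncated 2D mass lies beyond 4Γ — so the radius is explicit and
configurable rather than implicit in an array size. Convolution is
FFT-based with zero padding; simulated objects are centered and small
relative to the field, so boundary losses are below 1% (tested).

Detection noise is a single Poisson draw per pixel with mean
`signal_scale · (label ⊛ k) + background_rate`. The defaults
(`signal_scale` = 50 counts per unit projected label, `background_rate` = 5
counts/pixel) give a peak signal-to-background of order 20:1 for a 110 nm
vesicle, comparable to published STED images of labeled carriers. The
shape-discrimination conclusions are verified in the acceptance tests over a
4× range of these settings (scales 25/2.5 to 100/10). There is no read
noise, gain or drift model.

## Spot measurement

Each spot is fit by bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective; xtol = ftol = gtol = 1e-8) with the elliptical
profile

    f(x, y) = offset + amplitude · g(u² + v²)

where (u, v) is the displacement from the sub-pixel center rotated by θ and
divided by the major/minor FWHMs, and g(q) = 1/(1 + 4q) (Lorentzian, STED)
or exp(−4 ln2 q) (Gaussian, confocal); both profiles fall to half their
amplitude half a FWHM from the center along each principal axis.

Numerical choices:

* **Initialization is deterministic and seed-free**: center at the
  intensity-weighted centroid above the median, offset at the crop median,
  amplitude at max − median, both FWHMs at the PSF FWHM when known
  (otherwise a half-max-area estimate), θ = 0.
* **Fit window**: a 61×61 px (305 nm) crop around the detected center by
  default, which limits contamination from neighboring spots; the
  single-structure pipeline uses the same window.
* **Bounds**: FWHMs in [pixel size, full field extent] — the *full* field,
  not the crop, so a ~250 nm major axis can be recovered inside a 305 nm
  window; amplitude > 0; **offset ≥ 0**. The offset bound is physical
  (backgrounds are nonnegative count rates) and important in practice: left
  free, the offset of a Lorentzian fit to an extended object such as the
  projected vesicle shell drifts negative and inflates the fitted FWHM by
  tens of nm, with strong dependence on the fit-window size.
* Major/minor are ordered after the fit (θ rotated by π/2 when swapped and
  wrapped into [0, π)); θ is set to 0 for circular spots, where it is not
  identifiable. Optimizer failure is reported as `converged=False`, never an
  exception; downstream statistics refuse non-converged fits.

**Size statistic.** `spot_size` defaults to the **major-axis FWHM**, with
the geometric and arithmetic means of the two FWHMs available as
alternatives, and no PSF deconvolution. The default is the package's
position on a genuinely open definition question, fixed by a consistency
argument with the simulation itself: under the forward model above, an ideal
110 nm vesicle fits at ≈143 nm extent while a 30×150 nm tubule averages
≈136 nm extent but only ≈120 nm geometric-mean size (its ~90 nm minor axis
drags the mean down). Measured by extent, a sphere and a capsule of equal
physical span are — as expected at 80 nm resolution — statistically
inseparable; measured by geometric mean they separate by more than two
pooled SDs, an artifact of folding elongation into "size" while a separate
axis-ratio statistic already carries that information. The axis ratio
(major/minor, ≥ 1) is the elongation statistic throughout.

## Class comparison and the distinguishability rule

Per structure class the pipeline reports the fitted-size and axis-ratio
distributions (mean, SD, n, failures). Each tubule class is compared with
the vesicle class on both statistics. "Indistinguishable at this
resolution" is an inherently qualitative claim; the pipeline operationalizes
it: a pair is **distinguishable** on a statistic when

1. |Δ mean| ≥ pooled within-class SD, and
2. a two-sided Mann–Whitney U test, Holm-corrected across the tubule
   classes, rejects at α = 0.01;

anything else — including the mixed cases — is reported as
indistinguishable (the null label). The mean-vs-spread condition encodes
"the distributions substantially overlap"; the rank test guards against
calling noise a difference at small n. α and the rule thresholds are
config-exposed. With the default design (isotropic orientations, default
noise), the flags are stable from ~50 structures per class upward across
seeds and across the tested SNR range.

## Colocalization classification

Per channel, the intensity cutoff is the mean plus one sample SD of the
brightest pixels of `n_rois` = 100 randomly placed square background ROIs
(default 10×10 px), placed outside an exclusion mask (by default a dilation
of everything bright in any channel). Spots are detected on the reference
channel as local maxima with non-maximum suppression (minimum separation
2× PSF FWHM), fit as above on the raw reference image, and excluded when the
fit fails or the fitted size reaches 150 nm. Retained spots are scored
positive in a cargo channel when the channel's local peak exceeds the
channel cutoff; fractions are reported over spots positive in ≥ 1 channel.

Because the cutoff is calibrated on a *maximum* statistic, naive peak
lookup is badly miscalibrated, and two corrections are applied:

* **Shot noise.** Thresholding and peak lookup run on a lightly
  Gaussian-smoothed copy of each channel (σ = 1 px), and the peak is taken
  within a small registration radius (10 nm) of the fitted center. The ROI
  maximum then pools roughly ten independent noise-correlation cells while
  the presence statistic is a single one. A mean+1SD cutoff is exceeded by
  an *identically distributed* maximum ~15–35% of the time on pure
  background (the exceedance of a Gumbel-type statistic above its mean+1SD
  is scale-free), so the presence statistic must be stochastically smaller
  than the calibration statistic; this construction brings the empty-channel
  false-positive rate down to the percent level.
* **Structured background.** Lorentzian tails of neighboring spots form a
  slowly varying carpet. Detection therefore runs on a band-passed
  (difference-of-Gaussians, σ = 1 px minus σ = FWHM) reference image with a
  robust median + 6·MAD cutoff — the mean+1SD channel cutoff is far too low
  for a whole-field maximum search and is not used for detection — and the
  presence peak is corrected by the median of a local annulus
  (1.5–3 × FWHM) in aperture-photometry style before comparison with the
  cutoff.

Pearson correlation is computed over all pixels (optional mask) with the
standard estimator; constant channels are rejected.

## Kinetics utilities

ROI timecourses are per-frame means over a rectangle or boolean mask.
Fold increase is the raw ratio I(t)/I(t₀) with linear interpolation between
frames and no background subtraction. FRAP recovery percent is
100·(I(t) − I(t_bleach)) / (I(t_pre) − I(t_bleach)). Both are invariant to
positive rescaling of the intensities (property-tested).

The carrier-flux extrapolation multiplies dots observed per frame by the
number of frames over the duration and by the ratio of cell thickness to
focal-slab depth, with explicit unit conversions; it assumes non-overlapping
focal slabs and no re-counting of a dot across frames, and reports both the
raw product and a one-significant-figure rounding that matches how such
order-of-magnitude estimates are quoted. With the default observation
conditions (6 dots/frame, 1 frame/5 s, 30 min, 500 nm slab, 5 µm cell) the
product is 6 × 360 × 10 = 21,600, quoted as ~20,000.

## Synthetic data: what is and is not emulated

All generators are pure functions of their config including the seed
(bit-reproducible; per-frame child seeds are drawn from the master stream).

* **Shape frames** reproduce the stated simulation design exactly: classes
  {vesicle 110 nm; tubules 30 × 80/110/150/300 nm}, 150 frames per class by
  default, 200³ grid at 5 nm, Lorentzian 80 nm PSF, Poisson noise. Ground
  truth records geometry, orientation quaternion and seed.
* **Spot fields** are an invented test harness: real multi-channel fields
  cannot be reconstructed, so the generator only needs to exercise the
  classifier against known truth. Spots are placed uniformly with a 400 nm
  minimum separation in a 10.2 µm field (200 spots; carrier dots in cells
  are sparse, and only resolvably isolated objects are analyzable);
  categories are drawn per spot from configured (A-only, B-only, both)
  fractions — defaults (0.66, 0.20, 0.15), renormalized since the printed
  fractions sum to 1.01; intrinsic spot sizes and peak brightnesses are
  log-normal (60 ± 25 nm; reference 120, cargo 90 counts at the peak — the
  size spread intentionally sends a minority of spots over the 150 nm gate).
  The peak calibration inverts the exact kernel–blob inner product, not a
  Gaussian approximation, because Lorentzian tails carry a large fraction of
  the flux.
* **Timecourses** use a single-exponential approach to a plateau with
  conservation between donor and acceptor and optional bleach events; the
  simplest monotone model that supports the fold/recovery calculations, not
  a kinetic claim about real transport.

Passing tests on these generators show that the *measurement chain* is
correct and well calibrated under the stated forward model. They do not
show that real carriers are vesicles: real images add antibody-geometry
variability, heterogeneous coat coverage, cytoplasmic autofluorescence
texture, and motion — none of which are modeled.

## Problem sizes used by the test suite

Unit tests use small grids (48³–96³) where brute-force oracles are exact.
The end-to-end checks run the full 200³/5 nm design at 50 structures per
class (five seeds at default noise plus one seed at each SNR extreme), 40
frames per class for the noise-free monotonicity check, and 200-spot fields
for classifier recovery; these sizes are where the flag decisions and
binomial comparisons are already stable, and the full 150-per-class design
is a config change (`n_per_class=150`).

## Known limitations

* No 3D PSF or axial blur; projection is exact, so defocus-induced size
  broadening is absent.
* Least-squares (not Poisson maximum-likelihood) fitting; at very low
  counts the fitted amplitude and offset are mildly biased.
* The detector replacement for the original proprietary object finder is a
  deliberately simple maxima-plus-suppression scheme; crowded fields beyond
  the generator's separation regime will merge or drop spots.
* Per-cell masks for Pearson correlation are not modeled; the statistic is
  whole-image by default.
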