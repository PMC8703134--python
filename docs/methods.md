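# Methods

## The aberration model

`chromaxial` treats axial chromatic aberration as a per-channel, depth-linear
displacement: an object whose true (reference-channel) depth is *d* appears in
channel *c* at stage position

    z_c(d) = d + a_c·d + b_c .

The model assumes

* the displacement depends on depth only — not on lateral position in the
  field (valid for the objective/clearing combinations this workflow targets;
  verify per setup by inspecting the lateral residuals the fit reports);
* linearity in depth over the acquired range — adequate in practice, though a
  nonlinear profile would be fitted badly without warning beyond a poor r²;
* the calibration (bead slab or guide stars) was acquired under the same
  optics, immersion and clearing agent as the data to be corrected — the
  refractive index of the mounting medium enters *a* and *b* directly;
* stacks are acquired at uniform frame spacing `dz` with channels sharing
  stage positions.

Because the relation is linear in depth for every channel, any channel can
serve as the reference; slopes compose approximately as
`a(A→C) ≈ a(A→B) + a(B→C)` with error of order `a²`.

## Centroid measurement

Object positions are intensity-weighted centres of mass over a rectangular
ROI, computed per channel:

1. a length-3 median filter along z on each (y, x) column (nearest padding at
   the first/last frame) suppresses detector shot noise;
2. mean `m` and SD `s` are taken over the **filtered** ROI voxels and voxels
   with intensity `> m + k·s`, `k = 10`, are kept.  Filtering before the
   statistics is deliberate: a hot pixel must not inflate `s` and thereby the
   threshold.  `threshold_before_filter=True` restores the opposite order for
   comparison.
3. if nothing clears the threshold (dim guide stars), `k` is halved until at
   least one voxel passes; `k < 1` means "no object in ROI".  Every fallback
   is flagged on the sample and logged.

The ROI must contain exactly one object and, for elongated guide stars, span
its full z extent; a sample with more than 1% of its kept mass in the first
or last ROI frame is flagged `possibly_truncated`.  The depth covariate of a
sample is always the reference-channel centroid z, not the ROI's geometric
middle.

Accuracy: for a Gaussian-like object with axial σ ≳ 1 frame, the dominant
error is the discrete truncation of the thresholded voxel set, empirically
≤ ~0.1·dz per centroid at σ_z/dz ≈ 2.5 (sub-voxel phase sweeps in the test
suite).  The high default threshold buys robustness to background structure
at some cost in sub-voxel precision; centre-of-mass is used throughout — no
Gaussian PSF fitting.

## Bead detection

Calibration slabs are sparse bright blobs, so detection is a global
threshold at `mean + k_sigma·SD` of the whole stack (default `k_sigma = 10`)
followed by 26-connected 3D labeling.  Components outside
`[min_voxels, max_voxels]` are dropped; each survivor's bounding box, padded
by `margin_xy`/`margin_z` voxels, becomes an ROI.  Padded boxes that overlap
another component, overlap each other, or cross the volume border are
discarded (with logged counts) to preserve the one-object-per-ROI contract.
Detection runs on the reference channel and the boxes are shared across
channels, so `margin_z` must exceed the largest expected axial shift —
configure it accordingly for strongly aberrated deep stacks.

## Regression, effect size, power

`fit_axial` is plain OLS of Δz on depth (statsmodels under the hood), with
r², slope/intercept standard errors, and the residual SD retained so the
standard error of the fitted line at any depth can be propagated.  An
optional MAD-based outlier pass (`flag_outliers_mad=3.0`, off by default)
excludes gross outliers once and refits, recording the count.

Effect size is Cohen's `f² = r²/(1−r²)`.  Achieved power follows the
fixed-model "R² deviation from zero" convention used by standard power
software (G*Power): the F-test with df₁ = 1, df₂ = n−2 and noncentrality
λ = f²·n.  In the f²→0 limit the power equals α (default 0.05).
`required_n` inverts this by bisection on the (strictly increasing) power
curve.  For r² = 0.757 — the weakest fit quality worth planning around —
this gives power 0.957 at n = 7 and 0.998 at n = 10.

A noiseless fit (r² = 1, possible only on synthetic data) is reported as
infinite f² and power 1 with a `degenerate_fit` flag, not an error; a
constant response (reference fitted against itself) is reported as r² = 0.
A model whose power falls below `power_threshold` (default 0.7) is still
written, but the correction step refuses it unless forced.

Lateral shifts are summarised (mean and max |Δx|, |Δy| per channel) and a
warning is emitted when the mean exceeds one voxel pitch; they are never
regressed or corrected.

## Correction by frame reassignment

The fitted relation is inverted exactly: a target frame acquired at stage
position z holds content from reference depth

    z_c = (z − b) / (1 + a) ,

(|1 + a| < 1e-6 is rejected as degenerate).  Each reference frame n takes
the target frame whose corrected position is nearest to z_ref[n]; ties break
toward the smaller frame index, deterministically.  Depending on the sign of
the depth dependence, some target frames are used twice (duplicated) and
others never (deleted); reference frames beyond the corrected range are
clamped to the nearest existing frame and flagged "extrapolated" rather than
blanked.  Output stacks always keep the input dimensions; x–y content and
intensity statistics are untouched — no interpolation along z, so the
residual mismatch after correction is bounded by half a frame spacing plus
measurement error.  A first-order inverse `z − (a·z + b)` is available for
comparison; it differs by O(a²·z), negligible at realistic slopes
(|a| ≲ 0.01).

## Synthetic phantoms

The generator emulates the two calibration scenarios end to end, with exact
ground truth:

* **Bead slabs** — anisotropic 3D Gaussians (σ_xy = 1.7 μm, matching a 4 μm
  FWHM multi-fluorophore bead; axial σ multiplier 3 for confocal
  elongation) placed by rejection sampling so that every bead's ROI is
  disjoint and in-bounds in every channel.  Default grid: 96 × 96 × 1000
  voxels at 0.5 × 0.5 × 2 μm — a 48 × 48 × 2000 μm column, i.e. a lateral
  crop of a deep-stack acquisition with the full depth range kept, since
  depth is the covariate.  Default truth for the 559 nm channel:
  Δz(d) = 0.004·d − 18 μm plus per-bead jitter ε ~ N(0, 0.5² μm²) and a
  (0.3, −0.2) μm lateral offset; peak 10 000 counts over background 100 with
  Gaussian read noise σ = 50 on a 16-bit scale (optional Poisson).  The
  truth table records every ε realisation, so tests can separate fit error
  from model error.
* **Guide stars** — capsules (segments with Gaussian cross-section, same
  axial elongation, mostly-lateral orientation) whose depths are drawn only
  from the top and bottom thirds of the feasible range, the sampling scheme
  that anchors a linear regression at both ends; ROIs span each object's
  full z extent.

Same spec + same seed reproduces stacks, truth tables and ROIs
bit-identically.  The rendering is analytic, so the unthresholded centre of
mass of a rendered object matches the truth to well under 0.05·dz; the
*thresholded* measurement adds its own ~0.1·dz truncation error, which is
why correction-accuracy tests allow half a frame plus 0.1·dz per centroid.

What the phantoms deliberately do **not** model: diffraction PSFs,
refractive-index-mismatch physics, spherical aberration, depth-dependent
attenuation, tissue background, or field-position-dependent shifts.  Passing
tests therefore demonstrate that the *pipeline* recovers and removes a
depth-linear axial shift under realistic sampling and noise — not that any
particular microscope is depth-linear; that must be established per setup
from the bead or guide-star fit itself.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use a 50-bead slab (the default
spec) for parameter recovery — repeated over 20 seeds for confidence-interval
coverage — a 102-bead slab for the calibration demonstration, a clean
20-bead sample for correction round trips, 16 guide stars for the in-sample
calibration, and 100 000-replicate Monte-Carlo simulations to validate the
analytic power curve (agreement within 0.005).  Reduced grids
(96 × 96 × 300) back the fast unit tests.

Other numerics: physical voxel positions use the voxel-centre convention
(`index · pitch`, frames at `z0 + n·dz`); ROIs are half-open, 0-based;
whether "deeper" is +z or −z is metadata (`z_orientation`), never assumed;
stacks are held in memory (no out-of-core path; fine to a few hundred MB);
fitted models serialise to JSON with infinite f² stored as a string.

## Known limitations

* Axial correction only; lateral shifts are reported, not fixed.
* Linear depth model; strongly nonlinear aberration profiles need piecewise
  calibration over depth windows.
* Nearest-frame reassignment quantizes the correction to the frame spacing —
  residuals up to dz/2 are inherent; z-interpolation is deliberately not the
  default because it alters intensity statistics.
* The mean + 10·SD threshold assumes a dominant bright object per ROI;
  crowded fields need manual ROIs or the stricter detector settings.
* Proprietary formats (.oib, .lif) must be converted to TIFF first.
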