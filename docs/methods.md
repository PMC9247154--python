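# Methods

`bonetomo` quantifies image quality and specimen properties for neutron and
X-ray tomography of bone: edge sharpness, contrast-to-noise ratio (CNR),
grey-value phase histograms, bone volume fraction (BV/TV), compression
mechanics and hydration weight kinetics.  Every analysis stage is paired
with a synthetic phantom generator that produces inputs with known ground
truth, so the whole pipeline is verifiable without archived beamline data.

## Phantom model

Phantoms live in reconstructed-image space; no projection physics or
reconstruction is simulated.  A volume is built in four steps:

1. **Label painting.**  Geometric primitives (full-cover background,
   half-spaces, boxes, spheres, (hollow) cylinders, seeded sphere clouds,
   three-axis rod lattices) are painted in declaration order; a later phase
   overwrites an earlier one, so the label map is always a partition.  An
   `overlap="error"` mode instead rejects any overlap among non-base phases.
2. **Grey assignment.**  Each phase has a mean grey value.  Per-phase means
   are free parameters of the phantom: they are chosen so that the
   qualitative hydration-state orderings of neutron images are reproduced
   (cortex approaches background with hydration; dry plugs carry an air-void
   phase and near-coincident bone/marrow means; soaked plugs lack voids and
   separate bone from marrow), and so that every mean sits at least four
   noise SDs inside the representable range — otherwise clipping truncates
   the noise model and biases SD-based statistics.
3. **Point-spread blur.**  An isotropic Gaussian blur of σ given in
   micrometres (default 5 µm at 7.15 µm voxels) is applied with `reflect`
   boundary handling, which preserves the volume mean to well within 0.1%
   and avoids dark rims that would bias edge fits.
4. **Noise and quantization.**  Additive Gaussian noise (grey-value units)
   is applied after the blur, then values are clipped to the bit-depth range
   and rounded to the declared integer type.  The default noise SDs are the
   background grey-value SDs reported for the emulated scans: 2250.6
   (tibia-style volumes) and 1192.4 (plug-style volumes).

The rod-lattice trabecular model places rods along all three axes on a
regular grid with seeded per-rod radius jitter; the mean radius is
calibrated by bisection *on the actual voxel grid* until the volume fraction
inside the plug cylinder matches the target, and the achieved fraction is
recorded in the output metadata as ground truth.  Rod spacing controls
absolute rod thickness: the BV/TV analyses use spacing 40 voxels (rod
diameters ≈ 8–18 voxels), both because real trabeculae at 7.15 µm voxels are
tens of voxels thick and because much thinner rods are visibly eroded by the
radius-2 median filter, which would measure the filter rather than the
thresholding pipeline.  Anatomically realistic trabecular microarchitecture
is explicitly out of scope.

Sphere-cloud voids keep a 3-voxel clearance from the plug surface; a void
breaching the surface would merge with the exterior background during
masking (a dark channel open to the border is genuinely indistinguishable
from exterior).

All four generators (volumes, 1D edge profiles, compression curves, weight
series) are deterministic given their seed.

## Edge sharpness

The intensity profile across a boundary (edge-spread function) is modelled
as `low + (high − low)·Φ((x − µ)/σ)`, the integral of a Gaussian line-spread
function; fitting the CDF rather than the differentiated profile avoids
noise amplification.  Sharpness is reported as FWHM = 2·√(2 ln 2)·σ ≈
2.3548·σ, in the profile's abscissa units (pixels or µm, recorded on the
result).

Pipeline choices:

- Profiles are sampled with transverse averaging over an odd number of
  parallel lines (default 11) using bilinear interpolation.
- Conditioning is Savitzky-Golay smoothing (span 9, polynomial order 3 —
  the order is a package choice; a cubic preserves the sigmoid inflection)
  followed by cubic-spline resampling at 4× density for sub-pixel µ
  localization.  Fitting the raw profile instead is a flag away.
- Nonlinear least squares (trust-region, bounded) with initial guesses:
  µ at the max absolute first difference, σ = window span / 10, plateaus
  from the window-end means.  µ is constrained to the fit window; a σ at
  its upper bound is flagged.  Non-convergence yields `converged=False`
  with NaN parameters instead of an exception.
- Goodness of fit is NRMSE: RMSE divided by the observed grey range in the
  window, making fits comparable across grey scales.  It is undefined (an
  error) for a constant observed series.
- Automatic window proposals come from gradient-magnitude peaks but are
  suggestions only; fits always receive an explicit window.

Measured performance on generator edges (also enforced by tests): noiseless
σ recovery to 1e−4 relative; median relative error ≈ 3% at 5% contrast
noise over 50 seeded replicates per σ ∈ {0.5, 1, 2, 4} px.

## Contrast-to-noise ratio

CNR = |mean(S₁) − mean(S₂)| / √(sd(S₁)² + sd(S₂)²) with sample (n−1) SDs
throughout; it is symmetric, affine-invariant, and halves when both SDs
double.  Noise is estimated as the sample SD of a background-only ROI.
ROIs are rectangular boxes in named slices (auditable), with a 30-voxel
floor to stabilize SD estimates; on phantoms, ROIs can be taken from the
ground-truth label map after 3D erosion — the erosion must be 3D because
the point spread leaks across slices.  Degenerate inputs (both SDs zero)
return 0 for equal means and a flagged infinity otherwise.  Panels report
per-slice values and the mean ± SD over the (typically three) slices; both
granularities are exported because either may be wanted downstream.

## Phase histograms

Histograms use 250 bins over the specimen interior only.  The specimen mask
is computed as: lowest threshold of a 3-class multi-Otsu split → connected
components of below-threshold voxels touching the volume border form the
exterior → complement, reduced to its largest component and morphologically
closed (with edge padding so specimens touching the volume faces are not
eroded).  The 3-class split matters: with plain Otsu, a dark rim phase
(marrow in X-ray volumes) joins the background class and the mask collapses
onto bone.  Interior dark structure (voids, marrow) stays inside the mask.
A background-only volume is detected by the absence of a histogram valley
at the threshold (smoothed density there above 50% of the modal density)
and raises an error.  On phantoms the mask recovers ≥ 99% of the labelled
specimen voxels.

The bin range defaults to the masked min–max (shape comparison); a fixed
range is available for cross-specimen overlays, with out-of-range voxels
clamped into the end bins so count conservation (Σ counts = mask voxels)
holds in every mode.

Peak detection finds local maxima with prominence ≥ 5% of the modal count
on lightly box-smoothed counts (5 bins) — at 250-bin resolution single-bin
shot noise otherwise creates spurious peaks; reported locations remain bin
centers.  Labelling follows the dark-to-bright phase order
void < bone < marrow (configurable for X-ray volumes, where bone is
brightest).  When fewer (or more) peaks than expected labels are found, an
order-preserving minimum-distance assignment against expected phase
locations (generator means or nominal config levels) decides which labels
are present; an unmatched label whose expected location lies within 10% of
the histogram range of an assigned peak is reported as *merged* with that
peak (the dried bone/marrow case), otherwise as *absent* (the soaked void
case).  Peak-pair separation is scored as 1 − valley/smaller-peak, in
[0, 1].

## BV/TV morphometry

Radius-2 3D median filter (cube side 2r+1 by default, ball optional) →
inclusive grey-interval threshold → BV/TV = bone ∩ specimen / specimen.
The instrument presets `next` = (30375, 65535) and `4dlab` = (53500, 65535)
are stored by name; custom intervals are accepted.  Total volume is the
specimen mask from the histogram module, since plugs do not fill the field
of view.  On rod-lattice phantoms at 2% noise the pipeline recovers the
recorded achieved fraction within ±0.02 across f ∈ {0.1, 0.2, 0.3, 0.4}
(measured max error ≈ 0.012 at spacing 40).

## Compression mechanics

Records are normalized after a 15 N pre-load: samples before the force
first reaches the pre-load are discarded and displacement is re-zeroed at
the linearly interpolated crossing (no sampling-grid bias); stress = F/(π
d²/4) with the Ø6 mm × 10 mm plug geometry, strain = Δℓ/h.

- **Failure** is the first local maximum with prominence above 5% of the
  global maximum stress.  Candidates are located on a lightly
  Savitzky-Golay-smoothed curve and then refined on the raw samples —
  at 2% per-sample noise raw wiggles would otherwise satisfy the
  prominence rule and fire spurious early failures.  A curve with no such
  peak is a valid outcome (`clear_peak=False`) and is excluded from the
  analysis table with its reason, mirroring the experimental inclusion
  rule.
- **Modulus** is the maximum slope of least-squares line fits in sliding
  strain windows over the pre-failure data; the max-slope criterion skips
  the concave toe without locating it.  The default window width is 0.01
  strain with a quadratic Savitzky-Golay pre-smooth: a max over many noisy
  narrow windows is upward-biased (≈ +8% at width 0.005 and 1% noise at the
  generator's sampling density), while the quadratic smoother is exact on
  linear and parabolic segments, so noiseless results are unchanged.
  Measured bias at width 0.01: ≤ 4% at 1% noise.
- **Toughness** is the trapezoidal integral of stress dε up to failure;
  MPa × dimensionless strain ≡ MJ/m³ with no conversion factor.

The synthetic curve model is a linear ramp of slope E into a parabolic cap
peaking at σ_p (matched in value and slope), then linear softening; E and
σ_p scale as BV/TV² (defaults 8000·f² and 300·f² MPa, giving ~500 MPa and
~19 MPa at f = 0.25 — typical trabecular-bone magnitudes).  With zero
post-peak drop the curve has no interior peak, exercising the exclusion
rule.  On 30-curve seeded batches over f ∈ [0.1, 0.4] at 2% noise, the rank
correlation between recovered and generator modulus/peak/toughness
exceeds 0.99.

The analysis-table exporter only assembles response, log-response, BV/TV,
(BV/TV)², hydration group and campaign columns for external mixed-model
fitting; fitting itself is out of scope.

## Hydration kinetics

Percent weight change C = (w_after − w_initial)/w_initial × 100; the
regained fraction R(t) = (w(t) − w_dry)/(w_initial − w_dry) × 100 with
linear interpolation between weighings (weighings are 3-hourly; nothing
finer is knowable).  Cohorts report mean ± sample SD; specimens missing the
requested stage are listed as excluded, and fewer than two usable specimens
is an error.

The weight generator dries toward (1 − loss)·w₀ exponentially (default
loss 10%, rate 1.169/h so 97% of the loss occurs within 3 h) and rehydrates
with a two-component exponential: a single rate cannot produce both ≈ 49%
of lost weight regained at 3 h and ≈ 82% at 48 h, so the default is a fast
pool (fraction 0.452 at 3.0/h) plus a slow pool (0.0231/h) calibrated to
those two fractions.  Cohorts draw per-specimen loss fractions
(SD 0.029) and jitter the kinetic constants by 20% relative so regained
fractions scatter across specimens as real cohorts do.

## What the phantoms do and do not show

Passing tests demonstrate that each estimator recovers the truth of its
forward model under additive Gaussian noise, Gaussian blur and the stated
geometries.  They do not demonstrate robustness to reconstruction
artifacts (rings, beam hardening, scattered neutrons), misalignment between
sequential scans, anatomically realistic trabecular networks, non-Gaussian
or spatially correlated noise, or rate-dependent mechanics — none of which
the generators emulate.  Results on real volumes therefore depend on ROI
and window placement choices that the phantom tests cannot validate.

## Numerical conventions

- Volumes are (z, y, x) with strictly positive isotropic voxel size (µm).
- Sample (ddof = 1) SDs everywhere.
- All RNG flows through `numpy.random.default_rng` seeds carried in the
  spec objects; identical spec + seed ⇒ bit-identical outputs.
- Problem sizes in tests and in `scripts/acceptance.py` (volumes up to
  96×160×160, 30-curve batches, 10-specimen cohorts, 50-replicate edge
  sweeps) are chosen to give stable statistics at interactive runtimes.
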