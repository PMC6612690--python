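# Methods

## The forward model

The simulator accumulates entrance exposure on the unwrapped cylindrical
plate by integrating over gantry angle.  The source sits at the
focus–isocenter distance FID and moves on a helix: the gantry angle advances
uniformly (default step 0.5°) while the beam-center z advances by one table
feed (`pitch × nominal collimation`) per rotation.  A plate point at
cylinder angle φ and height z receives, from a source at angle θ and beam
center z_c, the contribution

```
w(Δφ) · A( (z − z_c) · FID / s(Δφ) )
```

where `s` is the in-plane focus-to-point distance,
`A` is the beam's z-aperture, and the weight `w` combines:

* **inverse-square** 1/s²;
* **incidence obliquity**: the cosine of the angle between the ray and the
  inward surface normal, floored at zero.  The visibility condition
  (cos Δφ > R/FID) and the obliquity zero coincide at the tangent rays, so
  each point is exposed only while it faces the source;
* **an in-plane fan fluence profile**: a Gaussian in the ray's isocenter
  impact parameter `p = FID·R·|sin Δφ|/s`, with half value at 80 mm
  (configurable; `None` disables it).  This term stands for the scanner's
  beam-shaping filter.  It is load-bearing: without any periphery
  suppression, near-tangent rays — whose aperture projection on the plate is
  up to √(FID²−R²)/FSD ≈ 1.6× wider than at the radial pass — fill the
  gaps between stripes to tens of percent of the stripe peak.  Real stripe
  images show dark gaps and cleanly separable stripes even at pitch < 1,
  which is the property the whole overbeaming measurement rests on.  With
  the 80-mm half value (a strong body filter, appropriate at 80 kVp) the
  simulated gaps stay below 10% of peak at all study conditions and the
  beam-width round trip closes within ±1.2%.

Exposure is **entrance-only**: the 500-mm acrylic phantom filling the
cylinder attenuates the exit beam to negligible levels, so only the first
intersection of a ray with the cylinder records dose.  No spectra, scatter,
detector blur or plate fading are modelled.

### Beam aperture

`A` is a symmetric trapezoid at the isocenter: flat umbra, linear penumbra
ramps of width `penumbra_iso` on each side.  Its FWHM equals the configured
actual beam width exactly, and its FWTM is `umbra + 1.8 × penumbra`.  The
default penumbra is 3 mm: a ~1-mm focal spot magnified by
(FID − FCD)/FCD ≈ 2 with the collimator at FCD = 200 mm, plus blur.  The
study beams put the umbra above the nominal collimation
(39 mm actual at 32 mm nominal, 88 mm at 80 mm), i.e. overbeaming is a
vendor margin plus the penumbra, matching area-detector scanners.

### Scan extent and overranging

The planned scan range [0, d] is defined at the isocenter.  Exposure starts
with the beam center at `−(base/2 + lead_rotations × feed)` and ends
symmetrically past d: the fully open beam base clears the range, plus the
extra rotations helical reconstruction needs at each end
(`lead_rotations = 0.5` per end by default).  The ground-truth exposure
length is therefore driven by both the beam base and the feed, which is why
overranging grows with pitch and with collimation, and it is measured — not
assumed — as the FWTM of the noiseless column-mean z-profile of the
simulated image itself.  `overranging_true = (exposure_length − d)/2`.

### Active collimator

The blade trajectory of real dynamic z-collimators is vendor firmware and
not public.  The model clamps the outside blade exactly at the range
boundary while the beam center is within `ramp_rotations × feed`
(default 0.5 rotations) of that boundary, and is fully open otherwise:

* when the beam center sits exactly on a boundary, the exposed width is
  exactly half the fully open width — the hallmark observation on real
  stripe images;
* stripes whose beam center fell inside a ramp are visibly tapered, and the
  simulator records those z-zones in the metadata so the analyzer excludes
  them from beam-width measurement.

The blade release at the end of the ramp is discontinuous.  This idealised
schedule removes nearly all exposure outside the range near the boundaries,
so the simulated reduction ratio (~85% at the study conditions) is much
larger than the ~17% a real scanner achieves with speed-limited blades; the
direction and the per-configuration pairing are what the model is used for,
not the magnitude of the reduction.

### Noise and encoding

Noise is multiplicative Gaussian on exposure (relative SD, seeded NumPy
generator) — additive on the log-encoded pixel value, which matches CR
response.  Encoding follows `PV = G log10(E)` with G = 1024, clipped to the
bit depth and quantised; exposures are normalised so the image peak maps to
PV = 3G (a mid-range CR operating point).  Non-positive exposures map to
PV 0 and are counted in the metadata.

## The analysis pipeline

All widths are measured on exposure-converted data (`E = 10^(PV/G)`), never
on raw PV, which would compress the upper profile and bias widths.

* **FWHM / FWTM**: background is the mean of the outer 10% of samples on
  each tail of the profile window; the level is
  `background + fraction × (peak − background)`; flank crossings are
  linearly interpolated between the bracketing samples (sub-sample
  resolution, no smoothing by default; an optional odd moving average is
  recorded in the result when used).
* **Stripe detection**: threshold at 50% of the 99.5th-percentile robust
  maximum, 8-connected labelling; components touching the first/last z-row,
  inside recorded taper zones, or smaller than 1% of the largest component
  (noise speckles) are discarded.  Tilt is fitted per component by
  intensity-weighted total least squares (principal axis of the weighted
  covariance); centroids are intensity-weighted.
* **Perpendicular profiles**: sampled through the stripe centroid
  perpendicular to the fitted axis with a step of half a pixel, bilinear
  interpolation, averaging 5 parallel lines offset ±2 pixels along the
  stripe axis.  The default window is **1.05× the measured stripe spacing**
  so that the outer-10% background tails straddle the inter-stripe gaps;
  a tighter window would put the tails on the stripe's own penumbra flank
  at marginal separation (32 mm at pitch 0.83 leaves a ~2-mm gap on the
  plate) and bias the width low by several percent.  If the background
  exceeds 40% of the profile peak the stripes overlap and the analysis
  refuses with advice to raise the pitch or plate radius.
* **Beam width**: the stripe FWHM is magnified to the rotation center with
  the printed linear relation `BW = FWHM × FID/FSD` (despite the phrase
  "inverse-square corrected" sometimes attached to it, the relation used
  and implemented is the linear magnification).  "Three arbitrary stripes"
  is made deterministic as the n stripes nearest mid-range; means and
  sample SDs (ddof = 1) are reported.
* **Overranging**: z-profile = per-row mean over an ROI containing the
  entire stripe image; FWTM = actual exposure length;
  `overranging = (FWTM − d)/2`.  A negative value is reported but flagged.
* **Flat-plate mode**: for a plate at the rotation center every ray crosses
  with its nominal z-offset, so the FWHM is the actual beam width with no
  magnification correction; with a scan range the FWTM gives overranging as
  above.  This is the internal cross-check of the stripe method.
* **DLP** is console-reported pass-through metadata only; it is echoed in
  reports and never computed.

## Problem sizes and validation scope

The round-trip validation sweep uses the study conditions — collimations
{32, 80} mm, pitches {0.83, 0.87, 0.99, 1.48}, 160-mm range, active
collimator off/on — on the full 250-mm-radius circumference at the default
0.2 mm/px grid and 0.5° gantry step (~1400–2100 × 7854 px per image,
10–30 s each).  Unit tests use the same geometry with a shortened scan
range and coarser pixels, which keeps them in the same stripe-separability
regime.

What passing round trips do **not** show about real data: the fan fluence
term is a one-parameter stand-in for a real bowtie; CR plate response,
scatter, plate-reader calibration and mechanical placement errors are
absent; and the active-collimator schedule is idealised, so measured
reduction ratios of real scanners are not reproduced quantitatively.  The
real-scanner reference measurements themselves (beam widths of ~39/88 mm,
overranging of 27–100 mm) are physical measurements of one scanner and are
reproduced only in their arithmetic (dose efficiency, overranging from
exposure length, reduction ratio) and their trends, not their absolute
values.

## Numerical choices and degenerate inputs

* Angles are degrees at interfaces, radians internally; all lengths mm.
* Pixel centers at (i + 0.5) × spacing, 0-based, rows = z, columns = u.
* Gantry integration: rectangle rule at 0.5° (configurable); halving the
  step or the pixel changes recovered widths by well under a pixel.
* A grid coarser than the plate-level penumbra records an under-resolution
  warning in the image metadata rather than failing.
* Zero-penumbra beams degenerate to a rectangular aperture; zero feed is
  rejected for acquisitions (pitch > 0) and treated as non-separable in the
  separability predicate.
* Stitching averages overlap regions; with zero overlap it is the exact
  inverse of plate splitting (bit-identical, integer dtypes preserved).
* Profile windows that exit the image, spans shorter than the stripe, flat
  images, and PV-unit images fed to exposure-domain operations all raise
  specific exceptions rather than returning numbers.
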