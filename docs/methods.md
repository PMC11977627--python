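# Methods

This package models the computational chain of a pre-clinical PET scanner
built on a single tetradecagonal (14-facet) annulus of LYSO: photon
transport, scintillation-light readout, trigger/coincidence logic, neural
event positioning, reconstruction onto virtual pseudo-detectors, and
NU4-2008 performance analysis.  Everything is synthetic and seeded; the
package is a desk-scale laboratory for the *methods*, not a re-measurement
of any physical scanner.

## Geometry

The scintillator is the solid between a 30 mm-radius bore and a regular
14-gon prism of apothem 39.7 mm, 72 mm long.  Derived quantities follow
from the polygon: facet width `2·a·tan(π/14)` = 18.12 mm, maximum outer
radius `a/cos(π/14)` = 40.72 mm — matching the as-built 18.2 mm facets and
8.2 cm outer diameter to printing precision.  World frame: origin at the
scanner centre, +z along the bore, facet 0's outward normal along +x;
facet-local coordinates are (u, v) with u transaxial (increasing azimuth)
and v = z.  Points are assigned to facet sectors by maximum dot product
with the facet normals, ties to the lower index.

Each facet carries 4 axially stacked 4×4 SiPM arrays (4 mm pixels, 4.4 mm
pitch): a 4 (transaxial) × 16 (axial) grid.  Virtual pseudo-detector
planes — one per facet, tangent to a 30 mm circle, 16×84 elements of
0.84 mm — are the LOR-projection targets for reconstruction.

Each facet is in coincidence with the seven opposing facets at index
offsets 4–10 (mod 14): the unique symmetric seven-set whose cross-facet
chords all traverse the bore, so the coincidence volume spans the whole
bore (49 unique facet pairs).

## Photon transport (`gamma_mc`)

Reduced physics, chosen so the statistical structure the downstream
pipeline depends on is present without a general-purpose transport code:

* back-to-back 511 keV pairs; acollinearity is an angular Gaussian of
  0.25° FWHM; positron range an isotropic Gaussian blur of the emission
  point (0.54 mm FWHM for F-18, 1.0 mm for Na-22) — both toggleable;
* object attenuation and single-to-triple Compton scatter in the phantom,
  using analytic chord lengths of the phantom body (cylinder/box) at its
  bulk 511 keV attenuation coefficient.  The voxelized μ-map is used on
  the correction side (recon), not during transport — transport needs only
  the interaction probability along a chord, and the analytic form is exact
  for these shapes and much faster;
* exponential free paths in LYSO from a small log-log-interpolated table
  anchored at μ_total(511 keV) = 0.087 /mm with photoelectric fraction
  0.33; photoelectric vs Compton branching by μ_PE/μ_total; Klein–Nishina
  scatter kinematics (rejection sampling in cos θ with the forward-scatter
  envelope); chains terminate at absorption, escape, or the 50 keV cutoff,
  below which the photon is absorbed at its next interaction site (its
  true mean free path is well under a millimetre), keeping per-chain
  energy accounting exact.  Rayleigh scattering, fluorescence escape and
  Doppler broadening are omitted as second order for positioning and
  reconstruction behaviour.

Each photon's chain is labelled PE, CSE, CS-PE, multi-CS or miss; CS-PE is
the two-site case whose light map has two peaks and whose *first*
interaction (the Compton vertex) is the correct LOR endpoint.

## Optics

Optical transport is replaced by a parametric model of the expected signal
per SiPM pixel from a point deposition of energy E at x:

```
S(x, pix) = Y·E·ε · [T(θ)·Ω(x, pix)·B(x, pix) + ρ·T(θ')·Ω(x', pix)] / 4π · e^(−r/λ)
```

* `Ω` — exact solid angle of the 4 mm active square (Van Oosterom–Strackee
  triangle formula; the 0.4 mm dead border at 4.4 mm pitch is outside the
  integration domain);
* `B` — bore occlusion: a chord whose transaxial closest approach dips
  inside the 30 mm bore would have to exit through the specular inner
  reflector, so its direct term is dropped;
* `T(θ)` — unpolarized Fresnel transmittance of the crystal→coupling
  interface (n 1.82 → 1.41), zero beyond the total-internal-reflection
  angle (~51°).  This is the term that confines detected light to a few
  facets despite the optically continuous annulus;
* `x'` — the point mirrored radially across the bore surface, weighted by
  the inner-surface reflectance ρ = 0.95.  The convex cylindrical mirror
  is treated as locally flat, so the image term is only applied to sensors
  within ±1 facet of the source azimuth.  The painted annulus ends are
  absorptive: no axial image term;
* defaults: light yield Y = 29 photons/keV, collection ε = 0.25 (folds
  coupling and PDE), bulk attenuation λ = 200 mm.  All parameters are
  config fields.

With these defaults, uniform photoelectric events keep ≈96.5 % (5th
percentile ≈94 %) of their expected light within the primary facet ±1,
consistent with the >90 % three-facet containment the hardware shows, and
CS-PE chains superpose into two-peak 12×16 maps.  Two monotonicities one
might guess do *not* hold in this model and are deliberately not asserted:
total collected light is not monotone in deposition depth (the Fresnel
acceptance admits more pixels for deeper events), and containment is not
monotone in depth either (shallow events have a relatively stronger,
wider mirror component).

Measured amplitudes are Poisson draws around the expectation, multiplied
by fixed per-pixel lognormal gains (σ = 2 %, set by a scanner seed) plus a
dark floor (mean 0.5 p.e. per pixel per event window), all in
photoelectron units.

## DAQ

Per-array sums below the threshold (default 5 p.e., the stand-in for the
hardware's 125 mV analog cut — far below a photopeak array sum, above the
dark floor; comparisons are inclusive) are excluded from the facet sums;
no facet-level energy threshold is applied.  The coincidence window
(default 2 ns) is the FULL width of the accepted time-difference range,
i.e. |Δt| ≤ 1 ns: under this convention the singles-product estimate
`R_ij = window·S_i·S_j` equals the accidental rate a delayed-window
measurement sees, and "1 ns apart coincides, 3 ns apart does not" holds.
Clusters of ≥3 in-window singles are discarded.  The primary facet is the
larger facet sum, the secondary the largest among the primary's partners;
each side's 12×16 distribution concatenates the 4×16 grids of
(facet−1, facet, facet+1) in increasing azimuth.  Dead time is not
modelled, so count-rate curves roll over only through randoms growth and
multiple-coincidence losses.

## Positioning

Harmonization subtracts `f·Σpixels` from every pixel (f = 0.0025), clamps
at zero, then divides by the maximum — subtract → clamp → normalize, so
any non-zero map has max exactly 1 and the transform is invariant to
positive rescaling.  All-zero maps are flagged, not positioned.

Two positioners operate in the primary facet's local frame
(u transaxial, d depth below the sensor plane, z axial):

* **centre of mass** — signal-weighted centroid over the unrolled 3-facet
  span for (u, z); depth from a monotone lookup mapping the distribution's
  radial second moment to mean depth, calibrated on simulated
  photoelectric events (the centroid itself carries no depth
  information);
* **residual network** — a seeded numpy implementation of a residual
  multilayer perceptron (input 192 harmonized pixels; default 96-wide with
  3 two-layer residual blocks; Adam on mean-squared error).  Training
  labels are the first interaction of the chain.  Working in facet-local
  coordinates makes the task rotation-invariant, so one network serves all
  fourteen facets.  Depth, width, epochs, batch size and learning rate are
  config fields; the default is a desk-scale stand-in for the scanner's
  much larger convolutional network, trained here on 2×10⁵ single-site
  photoelectric samples rather than 16 million full simulation events.

Estimates are clamped into the annulus solid (u to the facet width, z to
the annulus length, the radial coordinate to the bore-to-flat band) and
flagged when clamping acted.  Evaluation reports per-axis bias and RMSE
stratified by chain label; the CS-PE stratum isolates the two-peak
ambiguity, which shows up as an inflated RMSE exactly as expected.

## Reconstruction

The line through the two position estimates is intersected with each
endpoint's virtual plane (intersection, not radial projection, so the LOR
direction is preserved); in-plane bins by `floor((coord − min)/0.84)`;
lines missing either 16×84 grid are rejected with a reason code.
Corrections: per-LOR attenuation weight `exp(+∫μ dl)` along the chord of
element centres through the object μ-map (water 0.0096 /mm, polyethylene
0.0093 /mm, acrylic 0.0112 /mm at 511 keV); expected randoms per facet
pair `window·S_i·S_j` from singles rates.

* **SSRB-FBP** — slice = sum of the two axial element indices (167 slices
  at 0.42 mm pitch); transaxial bins: 128 angles over π, 0.42 mm radial
  bins; LORs beyond the maximum ring difference are rejected and counted.
  The 2-D filter is the band-limited Ram-Lak kernel built in the spatial
  domain (its DC term matters: naive |frequency| sampling loses a few
  percent of the count scale), with optional Hann apodization, linear
  interpolation in backprojection, count-preserving normalization.
* **list-mode MLEM** — exact voxel traversal (Amanatides–Woo) between
  element centres, attenuation survival in the forward model, randoms as
  additive ordinary-Poisson background (no pre-subtraction, preserving
  non-negativity).  The sensitivity image accumulates survival-weighted
  intersection lengths over a strided enumeration of all allowed element
  pairs (default stride 2 transaxial × 4 axial, ~5.5M rays); voxels with
  sensitivity below 5 % of the positive mean are masked — they are grazed
  by too few strided rays for a stable division.  The Poisson
  log-likelihood is tracked and is non-decreasing per iteration.

The hardware voxel size is 0.25 mm; desk-scale runs default to coarser
grids (0.5–1 mm) because synthetic counts are 10³–10⁵, not 10⁸.

## NU4-2008 analyses

* **Resolution**: response functions sum the orthogonal directions over
  ±2×FWHM around the peak (two passes from a 4 mm initial window); peak
  amplitude from a parabola through the three highest samples; FWHM/FWTM
  by linear interpolation at the crossings — no function fitting.
* **Sensitivity**: `S_i = (R_i − R_B)/A`, absolute sensitivity divides by
  the positron branching fraction (0.9060 for Na-22, 0.9686 for F-18);
  "integrated" sums the measured positions, the reading under which a
  0.751 cps/Bq integral converts to 82.9 % absolute.  Background comes
  from an equal-duration source-out acquisition.
* **Count rates**: per acquisition, sinogram bins more than 8 mm outside
  the 25 mm phantom are zeroed, each angular profile is aligned to its
  maximum, and counts outside the centred 14 mm strip plus the linear
  background interpolated beneath it are scatter+randoms; randoms come
  from the singles-product estimate or truth links; NECR = T²/(T+S+R);
  peak NECR by parabolic interpolation over the activity sweep; scatter
  fraction from acquisitions with R < 1 % of T.
* **Image quality**: uniformity over a 22.5 mm × 10 mm cylinder VOI;
  recovery coefficient per rod from the axial line profile at the hottest
  pixel of the 10 mm averaged slab inside a 2×-diameter ROI, with the NU4
  combined %STD; spillover ratio in 4 mm × 7.5 mm VOIs inside the water
  and air cold chambers.  Phantom internals not restated by the scanner
  description (rod layout, chamber bores) follow the NU4-2008 standard
  and are config-overridable.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the pipeline assumes —
interaction-chain mixtures, depth-dependent light spread across up to
three facets, Poisson photon statistics and sensor noise, Poisson event
timelines with decaying activity, accidental coincidences, object
attenuation, two-peak CS-PE maps.  They do not emulate: full optical
transport (wavelength spectra, surface micro-structure, multiple bounces),
Lu-176 decay spectroscopy (a flat intrinsic-singles rate stands in), ADC
quantization and electronics drift, dead time, or object-scatter
correction (deliberately absent in the reconstruction, matching the
scanner's current processing).  Passing tests therefore certify the
*algorithms* — trigger logic, harmonization, positioning, projection,
corrections, reconstruction, NU4 arithmetic — under controlled conditions,
not the absolute performance numbers of any hardware.

## Determinism and problem sizes

One master seed spawns per-stage children via
`SeedSequence(master, spawn_key=(stage_index,))`; per-scanner gains use a
separate scanner seed.  Every simulation is bit-reproducible at fixed
configuration, which the pipeline manifest (SHA-256 of every output file)
verifies end-to-end.

Default problem sizes were chosen as the smallest at which each behaviour
is unambiguous: 10⁴ events for optical containment, 10⁶ samples for the
Klein–Nishina check, 10⁶ singles for the randoms/delayed-window
comparison, 2×10⁵ training samples for the positioner comparison,
~10⁵ LORs on 48³-scale grids for the MLEM recovery studies.

## Known limitations

* The optical model is parametric; its containment was calibrated to the
  hardware's >90 % three-facet figure, and absolute p.e. scales are
  nominal.
* The centre-of-mass depth lookup gives the baseline a fair depth
  estimate, but both positioners inherit the light model's idealizations.
* NECR curves lack a dead-time roll-over mechanism.
* The delayed-window convention (full-width window) is an interpretation;
  the alternative (max-|Δt| = window) is one config field away but makes
  the singles-product formula undercount accidentals by 2×.
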