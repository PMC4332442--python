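# Methods

This note documents the models, estimators and numerical choices behind
`valveflow`, in the order the pipeline runs them.

## Scope and data model

The package quantifies left atrioventricular valve (LAVV) regurgitation
from whole-heart 4D-flow CMR: three velocity-component volumes over the
cardiac cycle, with voxel geometry in a NIfTI affine and timing given by
mid-phase trigger times and the RR interval. All velocities are cm/s
internally, geometry is world millimetres, volumes are reported in mL and
flow rates in mL/s. A dataset on disk is three one-component 4D NIfTI
files plus a JSON sidecar (`venc_cm_s`, `phase_times_ms`, `rr_ms`,
`wrapped`); NIfTI has no standard vector-component convention, so
separate files are unambiguous.

## Synthetic phantom

No public 4D-flow datasets with regurgitation ground truth exist at the
scale needed for testing, so the package ships a parametric phantom whose
defaults encode the acquisition and the cohort-scale magnitudes the
pipeline is designed for:

| parameter | default | meaning |
|---|---|---|
| voxel size | 2.3 × 2.3 × 3.0 mm | clinical whole-heart 4D-flow resolution |
| phases | 30 at 31 ms | retrospectively gated cycle (RR 930 ms) |
| Venc | 150 cm/s | three-directional velocity encoding limit |
| grid | 48 × 48 × 40 voxels | ~110 × 110 × 120 mm field of view |
| systole | 0–310 ms | regurgitant/aortic jets active 10–310 ms |
| regurgitant volume | 11 mL | canonical test magnitude |
| inflow volume | 70 mL | diastolic transvalvular filling (340–900 ms) |
| aortic volume | inflow − regurgitation | internal-validation difference is exactly 0 |
| jet semi-axes | 9 × 5.49 mm | circularity (axis ratio) 0.61 |
| jet sweep | 50°→86° in the 2-chamber view | angle difference 36° across systole |
| noise | 3 cm/s SD Gaussian | velocity noise of a well-tuned acquisition |
| rim width | 2 mm | cosine taper of the plug profile |

Each jet is an elliptical cylinder of plug flow with a cosine-tapered
rim. With normalised elliptical radius ρ (ρ = 1 on the ellipse with
semi-axes a ≥ b) the profile is 1 for ρ ≤ ρ₀, ½(1 + cos π(ρ−ρ₀)/w) for
ρ₀ < ρ < 1 (w = rim/b, ρ₀ = 1 − w), 0 outside. Level sets are similar
ellipses, so the programmed b/a is exactly the cross-sectional
circularity index. The flux through any orifice-normal cross-section is
s(t)·A_eff with the closed form

    A_eff = π a b (ρ₀² + wρ₀ + w²(1/2 − 2/π²)),

and the half-sine waveform amplitude is solved so that the
time-integrated flux equals the programmed volume exactly. Ground truth
(per-jet volumes, per-phase rates, per-phase directions and view angles,
peak phase, circularity) is computed analytically before noise,
baseline offset or aliasing are applied.

Voxel values are the profile averaged over a 2×2×2 sub-grid of each
voxel (partial-volume emulation). Point sampling of the sub-voxel rim
over-integrates the discrete flux by ~3%; volume averaging is what the
scanner does and brings the discrete flux within ~0.2% of the analytic
value.

What the phantom does *not* emulate: divergence-free flow outside the
jet cylinders (conservation checks are therefore restricted to parallel
planes cutting the same jet segment), chamber anatomy and moving
myocardium, turbulence and phase dispersion, k-space/SNR physics, eddy
currents beyond a constant baseline offset. Passing tests demonstrate
correct geometry, interpolation, tracking and integration under
realistic magnitudes and noise — not robustness to anatomy-specific
segmentation or acquisition artefacts.

## Venc aliasing and unwrapping

Aliasing maps a true velocity v to v − 2k·Venc into [−Venc, +Venc).
Unwrapping is **temporal**: each voxel's velocity-time series is
unwrapped with period 2·Venc (`numpy.unwrap`), treating any
consecutive-phase jump larger than Venc as a wrap. This exploits that
blood accelerates smoothly on the 31 ms timing, and is robust where
spatial unwrapping is not: a plug jet's edge is narrower than a voxel,
so spatial neighbour jumps at the rim exceed Venc and are
indistinguishable from wraps. Assumptions: the first reconstructed phase
is alias-free (early systole quiescent relative to Venc) and
|dv/dt| < Venc per 31 ms — both hold for physiological flow at
Venc 150. The correction is idempotent because it is derived from the
re-wrapped values. A jet whose *edge* sweeps across a voxel between two
phases at supra-Venc amplitude would produce a genuine full-amplitude
jump that no rule can disambiguate; the aliasing stress phantom
therefore uses a static-direction supra-Venc jet (peak 180 cm/s).

## Reformatting and ROIs

Measurement planes are 64 × 64 pixel rasters at 1.0 mm (finer than the
voxel grid; trilinear interpolation supplies sub-voxel sampling — both
choices ours, as clinical software leaves them unstated). Through-plane
velocity is the dot product with the plane normal. Polygon ROI
membership is pixel-centre containment under the even–odd rule;
out-of-bounds pixels (planes may overhang the volume, returning zero
velocity with a flag) are always excluded.

The automatic jet ROI thresholds |through-plane velocity| at 10% of the
**cycle-wide** peak of the tracked series, read within 3 mm of the plane
centre (the tracked plane passes through its jet's axis, so another jet
crossing the same plane cannot inflate the threshold), keeps the
8-connected component containing the plane centre, and dilates by one
pixel. A frame-relative threshold would flood the ROI with background at
weak early/late-systolic frames; frames whose jet falls below the cycle
threshold reuse the nearest detectable frame's ROI. Clinical use passes
explicit contour polygons instead.

## Retrospective valve tracking

Per phase, the jet direction is estimated as the speed-weighted mean
velocity in a 10 mm sphere around a seed (voxels at ≥ 50% of the local
peak). Directions across the tracked interval are regularised by a
weighted quadratic fit of each component against time, weighted by the
squared *coherent speed* (norm of the weighted mean vector over the
weight sum): valve-jet dynamics are smooth, while the raw estimate is
noise-limited at frames where the jet barely exceeds the noise floor,
and coherent speed is ≈ 0 for incoherent noise. Streamline tracing
(fixed-step RK4 on the normalised instantaneous field) is provided for
visualisation and as an independent direction reading
(`streamline_mean_direction`, averaging early tangents of a seed
bundle).

The measurement plane is perpendicular to the fitted jet direction,
offset 15 mm (middle of the 1–2 cm proximal convention, avoiding phase
dispersion at the orifice) from the annulus/orifice centre into the
receiving chamber; in-plane axes are the world x axis orthogonalised
against the normal (y fallback), v = n × u. Offsets outside 10–20 mm
warn but proceed.

Background (baseline phase offset) correction subtracts the mean
through-plane velocity of a tissue ROI — by default the first fully
in-bounds, jet-free 12 × 12 mm corner box of the plane in a fixed corner
order (choosing a corner by its velocity content would bias the estimate
under noise). Flow rate is Σ through-plane × pixel area over the ROI
(cm/s·mm² → mL/s), and volumes are trapezoidal integrals of the
per-phase rates over the tracked interval. Systolic series are extended
by the adjacent valve-closed frame on each side so the integral keeps
the down-ramp tail; without this the systolic volumes are biased low by
~1–2% relative to the naturally anchored diastolic inflow, which shows
up directly in the internal validation difference.

Derived quantities (identities asserted in code): total regurgitation =
Σ per-jet volumes; effective forward = forward − total; regurgitant
fraction = total/forward × 100 with the **total diastolic inflow** as
denominator (steady-state inflow = effective forward + regurgitation;
the conventional denominator); internal validation difference =
effective forward − aortic volume, with aortic flow measured by the same
tracking at the aortic valve.

## Jet characterization

Angles are measured per systolic phase by projecting the tracked jet
direction into the declared 2-/4-chamber view planes and taking the
angle to the annulus line in [0, 180) — the orientation is fixed so a
jet entering the atrium along the annulus normal reads 90°, and angles
are not folded to [0, 90] (laterally hugging jets read > 90°). Reported
dynamics are (min, max, max − min) per view.

Circularity is measured at the phase of maximum regurgitant flow rate on
the perpendicular tracked plane, reformatted at 0.5 mm to resolve the
cross-section: pixels at ≥ 50% of peak (half-max is conventional and
stable for near-plug profiles), largest 8-connected component, min/max
Feret diameter of its convex hull at 1° rotation granularity. One pixel
spacing is added to each diameter because centre-to-centre extents
understate the pixelated footprint by one pixel.

## Volumetry and agreement

Ventricular volumes use Simpson summation of traced contour areas
(shoelace formula on polygon vertices — contours are vector inputs) ×
slice thickness. EF = (LVEDV − LVESV)/LVEDV. The biplane area–length
atrial volume uses the constant 8/(3π) ≈ 0.8488 — the standard
prolate-ellipsoid factor; the alternative literal grouping 8π/3 would
overestimate ~10×. Du Bois BSA = 0.007184·weight^0.425·height^0.725.
The indirect regurgitant volume (planimetric stroke volume − aortic
flow) cross-checks the direct measurement; negative values are returned
with a warning. Agreement statistics are Pearson/Spearman correlation
(scipy, average ranks for ties) and Bland–Altman with an n−1 SD and
fixed 1.96 multiplier for the 95% limits (no small-sample t correction,
matching the method's standard form).

## Pipeline, determinism, problem sizes

`run_pipeline` composes simulate → unwrap (if wrapped) → track →
quantify → characterize and emits a `SubjectReport` that validates
against the JSON schema in `schemas/`; reports carry a provenance block
(SHA-256 of the config, seed, package version) and contain no
timestamps, so a fixed config and seed reproduce byte-identical output.
All randomness flows from the config seed through
`numpy.random.default_rng`.

Tests and the acceptance script run phantoms at the full acquisition
geometry (48 × 48 × 40 × 3 × 30 samples); the synthetic cohort for the
internal-validation agreement uses 20 phantoms with regurgitant volumes
drawn from a clipped N(11, 6²) mL and inflow from N(70, 10²) mL — the
cohort-scale spread the method is meant to span. A single phantom
generates in ~0.5 s and quantifies in ~1 s.

## Known limitations

- The fraction denominator (total inflow) is a convention; tools that
  use effective forward + regurgitation as denominator will differ for
  the same volumes. Forward volume is reported so either can be formed.
- Sub-detection frames contribute the nearest frame's ROI, not a model
  extrapolation; truly silent frames still measure ≈ 0.
- The temporal unwrapper requires an alias-free first frame per voxel.
- Trapezoidal cycle integration underestimates a half-sine by ~0.9% at
  10 samples; this is inherent to the sampling, shared by all series,
  and partially cancels in derived differences.
- 2-/4-chamber view orientations are configuration inputs, not estimated
  from anatomy.
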