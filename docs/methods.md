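# Methods

`octatlas` implements a spatio-temporal reference frame ("retinal
atlas") for en-face analysis of macular OCT: per-visit feature maps of
one eye are aligned to the eye's first visit, all eyes are normalized
into a common fovea-centred grid, and the resulting maps are analysed
cross-sectionally (pixelwise nonparametric maps, eccentricity profiles)
and longitudinally (a joint growth-curve / survival model of conversion
to advanced AMD). Because the clinical cohort this methodology targets
is not redistributable, the package ships a synthetic phantom generator
that serves as the test bed for every stage.

## Vessel maps (`enface`)

Retinal vessels absorb the OCT beam and darken the reflective RPE band
below them. The per-A-scan **0.7 quantile** (linear-interpolation
definition, oracle-tested against a sort-based reference) of the
intensities in the 30 µm window above the RPE border yields an en-face
image in which the vessel tree appears as dark ridges. The projection is
min-max rescaled to [0, 1], resampled to isotropic pixels at the finer
lateral spacing, denoised with non-local means (h = 0.025 of the unit
range, 5×5 patches, 11×11 search window) and contrast-normalized with
CLAHE on an 8×8 tile grid.

The CLAHE clip limit of 0.4 is interpreted in the OpenCV/Zuiderveld
convention — a multiple of the mean histogram bin count — and converted
to scikit-image's normalized parameter by dividing by the 256 histogram
bins. Measured on noise-free phantoms, reading 0.4 as scikit-image's
normalized fraction instead amplifies a flat background into full-range
structure (binary vessel Dice ≈ 0.3-0.5, ~30% foreground), whereas the
cv-style reading yields Dice ≈ 0.8 at the downstream threshold of 0.4
with the 80-pixel minimum component size; the cv-style reading is the
only one under which the published downstream constants are coherent.

Vesselness is a multi-scale Frangi filter (dark ridges, β = 0.5, γ set
per scale to half the maximum Hessian norm) with scales {15, 30, 45,
60} µm converted to Hessian sigmas of half the scale; the maximum over
scales is reported unnormalized so that responses are comparable across
images. Binarization thresholds at 0.4 and removes 8-connected
components below 80 px (implemented by component labelling + size
count, keeping the ≥ 80 px rule exact under scikit-image 0.26's changed
`remove_small_objects` semantics).

## Landmarks (`landmarks`)

The **fovea** is the centroid of the pixels whose 3×3-median-smoothed
ILM-to-GCL thickness lies within 2 µm of the global minimum — a region
centroid rather than a single argmin, which is fragile under noise. A
region covering more than half the field (no discernible pit) is
returned with a low-confidence flag instead of an error.

The **ONH** is detected in the SLO image: adaptive threshold (local mean
over a 31-px block minus a small offset, dark class), a morphological
opening with a 0.25-mm disc to erase thin vessel shadows while keeping
the disc, edge extraction, and a RANSAC circle fit (3-point minimal
samples, 2 px inlier tolerance, 1000 iterations, least-squares refit on
the inliers, radii constrained to the anatomical 0.5–1.3 mm range).
Insufficient inlier support yields an explicit "not found" result.

## Registration (`registration`)

Follow-up visits are aligned to the first acquisition of the same eye.
The rigid stage runs on the **binary** vessel maps with a mean-squares
metric (robust capture range); the affine refinement runs on the
**probability** maps with windowed normalized cross-correlation (window
9 px). Both optimize coarse-to-fine over a four-level Gaussian pyramid
(downsampling factor 2) with derivative-free coordinate descent whose
steps halve until 0.02° / 0.1 px — fully deterministic, no RNG. Search
bounds are ±10° and ±1 mm (same-eye follow-ups). A solution that does
not improve on its initialization is replaced by that initialization
with a failure flag; within `register_series` a final NCC below 0.2
additionally flags the visit (no real correspondence), mirroring the
exclusion of unusable acquisitions in practice.

Resampling uses bilinear interpolation; a target pixel is valid only
when all four source neighbours are valid, which prevents zero-filled
invalid values from bleeding across the field border (measured
round-trip error on smooth maps drops from ~25% to ~1% of the value
range with this rule).

A simple axial de-jitter precedes projection: each B-scan's mean depth
profile is shifted (bounded integer shifts) to maximize correlation
with its neighbour, and cumulative shifts are median-centred.

## Reference frame (`refframe`)

The atlas grid is **512×512 px at 15 µm** (7.68 × 7.68 mm), fovea at
pixel (255.5, 255.5), +x nasal, +y superior. The inter-patient
transform is rigid: right eyes are mirrored about the vertical axis so
nasal is +x for all eyes, the fovea maps exactly to the grid centre,
and the fovea→ONH direction is rotated to the population-mean 5.6°
above the horizontal. The sign convention (ONH above the horizon) and
mirror-before-rotation order are package conventions applied uniformly;
only the angle's magnitude is anatomically constrained. Intra- and
inter-patient transforms are composed and applied as a single
interpolation to avoid double smoothing.

## Features (`features`)

Layer thickness is the per-A-scan axial distance between two boundary
surfaces in µm (the two samples share an en-face position, so the
Euclidean distance reduces to the axial one). The seven boundaries
define six layers: RNFL, GCL-IPL, INL-OPL, ONL, ORB (RPE + outer
photoreceptor segments) and choroid.

Choroidal texture: per A-scan a 5-px-wide, 300-µm-deep patch starting
at Bruch's membrane is extracted (laterally clamped at borders; marked
invalid if less than half the nominal depth fits). GLCMs use 16 bins
over the intensity range 0–128 (values above 128 are clipped into the
top bin), are symmetrized (each pair counted both ways, so µx = µy) and
computed for four offsets — (1, 0), (0, 6), (1, 6), (1, −6) in
(lateral, axial) pixels, the 6:1 ratio compensating the ~30:3.9 µm
voxel anisotropy so all four probe comparable physical distances. The
six Haralick descriptors (energy, entropy with log₂ and 0·log 0 := 0,
inverse difference moment, inertia, cluster shade, cluster prominence —
the last two as third/fourth moments of i+j about µx+µy) are averaged
over the offsets for approximate rotation invariance. Both the GLCM and
the descriptors are oracle-tested against brute-force double-loop
implementations.

## Population statistics (`popstats`)

One scan per eye enters a cross-sectional analysis: converters the
visit closest to one month before conversion (restricted to strictly
pre-conversion visits), non-progressors their last visit. Group
mean/std/n maps are computed pixelwise over eyes. Group differences use
the two-sided Mann-Whitney U test — exact when the combined sample is
≤ 12 and tie-free, otherwise the tie-corrected normal approximation
with continuity correction — and Benjamini-Hochberg FDR at 5% over the
family of valid pixels (or bins). Topographic profiles average each
eye's map over 0.1-mm eccentricity annuli; group curves carry
normal-theory 95% CIs of the mean over eyes, and per-bin tests compare
**eye-level** annulus means (never pooled pixels, which would
pseudo-replicate) with BH-FDR across bins. Pixels/bins with fewer than
3 eyes per group are untested.

## Longitudinal model (`longitudinal`)

The central feature value of a visit is the mean of its atlas map over
the 3-mm-diameter foveal disc. Trajectories are described by a linear
growth-curve mixed model with dummy-coded groups (non-progressors as
reference) and per-eye random intercept and slope; right-censored
conversion is handled by a proportional-hazards submodel sharing those
random effects:

    y_ij = (β₀ + γ₀g + b₀ᵢ) + (β₁ + γ₁g + b₁ᵢ)·t + ε,   ε ~ N(0, σ²)
    hᵢ(t) = h₀g(t) · exp(α₀ b₀ᵢ + α₁ b₁ᵢ)

with a piecewise-constant baseline hazard over 6-month intervals,
**stratified by group**. Stratification resolves the label/event
circularity of the design (groups are defined by the conversion fate,
so non-progressors have no events by construction); without it the
shared baseline forces the association term to absorb the group
difference in event rates and biases the longitudinal intercepts by
several µm in simulation.

Inference is a model-specific MCMC: conjugate Gibbs updates for the
fixed effects (near-flat normal prior), residual variance (IG(0.01,
0.01)), random-effect covariance (inverse-Wishart, ν₀ = 4, Ψ₀ =
diag(1, 0.001)) and the baseline rates (Gamma(0.01, 0.01)); an
independence Metropolis step for the random effects that proposes from
their longitudinal full conditional and accepts on the survival
likelihood ratio; a random-walk step (warm-up-adapted scale, N(0, 5²)
prior) for the association; and an interweaving recentering move that
trades each group's mean random intercept/slope against the
corresponding fixed effect — exact for the longitudinal part,
MH-corrected for the survival part. Without recentering the intercept
R-hats stall near 1.3–1.8; with it all R-hats reach ≈ 1.00 within a few
hundred iterations. Convergence is gated on split R-hat < 1.1 across
chains for every reported parameter; the default budget is 4 chains ×
5000 iterations (2000 warm-up), and the test suite uses 2 × 1200 (400
warm-up), which the R-hat gate confirms is sufficient for the phantom
cohorts. Fixed seeds make chains bitwise reproducible.

`mixed_model_only` (statsmodels MixedLM, REML, random intercept +
slope, falling back to a random intercept with a warning when the
covariance is singular) provides initialization-free maximum-likelihood
estimates and an independent cross-check: under zero hazard the joint
posterior means match it closely, while under informative dropout the
naive mixed model visibly biases the converter slopes — the effect the
joint model exists to correct.

LOESS trajectories use a local-linear tricube smoother (span 0.75)
with pointwise standard errors from the linear-smoother weights and a
residual-variance estimate; statsmodels' lowess provides no standard
errors, hence the in-package implementation. The converter time axis is
months relative to conversion (grid ending at 0); non-progressors use
months in study.

## Synthetic phantoms (`synthetic`)

The generator defines the study conditions:

* **Geometry**: 200 A-scans × 128 B-scans × 320 depth samples at (30,
  60, 3.9) µm — desk-scale but anisotropic like a clinical macular
  cube. Bruch's membrane sits flat at 800 µm depth; inner-layer
  thickness fields (RNFL rising as r^1.5 from a 4 µm foveal minimum,
  ring-shaped GCL-IPL and INL-OPL) produce a foveal pit whose ILM-GCL
  minimum coincides with the configured fovea position. ONL, ORB and
  choroid are spatially flat at their configured central means, so the
  central-3-mm mean equals the generating linear trajectory exactly.
* **Trajectories**: defaults are the published growth-curve estimates —
  ONL 90.78 µm baseline, −0.11 µm/month reference slope, MNV/MA
  baseline offsets −3.1/−9.15 µm and slope offsets −0.080/−0.11; ORB
  60.68, −0.023, +0.31/−1.15, −0.094/−0.12; choroid 132.19, −0.47,
  +4.84/−3.31, −0.38/−0.20; cluster shade 69.06, −0.24, −7.82/−9.65,
  +0.086/+0.16. Random-effect and residual scales are not published;
  the defaults (e.g. ONL intercept sd 7.5 µm — consistent with the
  width of the published baseline CI at the study's sample size — slope
  sd 0.08 µm/month, residual 2 µm) were chosen once as clinically
  plausible magnitudes.
* **Vessels**: eight branches fan from the ONH (4.2 mm nasal of the
  fovea, at ≈ 5.6° elevation) as curved polylines with widths 70–140 µm;
  each attenuates intensities under its Gaussian lateral profile by
  40–70% from just below the ILM through the RPE — the shadow physics
  the projection exploits.
* **Acquisition**: per-visit rigid misalignments (rotation sd 1.5°
  clipped at ±4°, translation sd 120 µm clipped at ±280 µm; visit 0 is
  the identity and defines the eye's frame); multiplicative gamma
  speckle (shape 25, sd 20%) plus additive Gaussian noise, both
  disabled at `noise_sd = 0` for fully deterministic renders; an SLO
  with bright background, dark vessels and a dark ONH disc.
* **Conversion**: piecewise-constant baseline hazard (default
  0.08/month for the converter groups, 0 for non-progressors — the
  label means the eye never converts) scaled by exp(α·b) with the ONL
  random effects, inverse-transform sampled, administratively censored
  at month 24. Monthly visits run through month 24; converters
  contribute visits strictly before conversion.

What the phantoms do **not** emulate: realistic speckle statistics and
axial PSF, B-scan-level pathology (drusen substructure, fluid, SHRM —
optional hemispherical RPE elevations exist but default off), vessel
calibre hierarchy and branching realism, segmentation errors (surfaces
are returned noise-free), and treatment effects. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under known truth — not clinical performance on real OCT.

## Problem sizes in the test suite

The suite exercises registration recovery on 20 phantom pairs, landmark
accuracy over 50 noise seeds, GLCM/Haralick oracles on 100 random
patches, null calibration of the pixelwise test on 1000 pixels, FDR
control over 1000 replicates of 100 tests, joint-model coverage over 50
replicate cohorts of 300 eyes at a 2-chain × 1200-iteration budget, and
an end-to-end profile-specificity experiment with 65 eyes; these sizes
give Monte-Carlo error comfortably below the asserted margins while
keeping the suite desk-scale. `scripts/acceptance.py` re-runs the same
computations (20 replicates for the joint model) from scratch.
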