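# Methods

## Geometry model

All geometry lives in a right-handed physical frame in micrometres:
x en-face temporal→nasal, y inferior→superior, z axial anterior→posterior.
Left eyes are mirrored into this OD frame on ingest (x and the FoBMO angle
negated, exactly once — a `normalized` flag guards idempotence), so every
computation sees a single convention and "temporal = 0°" holds for both
lateralities.

**Plane fit.** The BMO and BMB planes are orthogonal-regression (total
least squares) fits: the normal is the smallest-eigenvalue eigenvector of
the centred scatter matrix. A functional z-on-(x,y) regression would make
the tilt depend on the device frame orientation; the orthogonal fit is
rigid-motion invariant. Normal signs are fixed to positive z (ties to +x,
then +y); the tilt uses |n·n'| so the sign convention is observationally
irrelevant. Collinear or <3-point configurations raise a degenerate-
geometry error (rank test at 1e-12 of the leading eigenvalue).

**In-plane basis.** Projection into a plane uses e1 = unit projection of
the temporal axis onto the plane and e2 = n × e1. This makes in-plane
angles comparable across eyes but means the rotation angle is defined in
the *tilted* plane: under a joint en-face rotation of the eye and its FoBMO
angle the rotation angle is equivariant only to O(tilt²) (≈0.03° at 3.4°
tilt). Ovality, tilt and area are rigid-motion invariant to numerical
precision; scaling coordinates by k leaves the angles and ovality fixed and
multiplies area by k².

**Ellipse fit.** Direct least-squares conic fitting with the
ellipse-specific constraint 4AC − B² = 1 (the numerically stable
Halir–Flusser block decomposition), after centring and scaling the points.
This is exact on noiseless ellipse samples. If the constrained eigenproblem
yields no valid ellipse (possible for adversarial inputs), a second-moment
fallback uses covariance axes (semi-axes √(2λ) for uniform parameter-angle
samples). Near-circular fits are flagged: above ovality 0.99 the major-axis
orientation is numerically meaningless, so the rotation angle reports 0°
with a `rotation_circular` flag instead of noise.

**Rotation fold.** The major axis is undirected, so the FoBMO-adjusted
angle is folded into [0°, 90°] via min(x mod 180, 180 − x mod 180). The
fold convention makes both typical group means (~36°) and strongly rotated
individual discs (~72°) representable.

**Cross-validation tilt.** The variant replaces the scan-edge BMB points
with Bruch's-membrane reference points at a fixed en-face distance
(default 1700 µm) from the BMO centre, linearly interpolated per half-scan
between the BMO point and the scan-edge BMB point (both lie on Bruch's
membrane). On synthetic eyes whose BMO plane is tilted against a flat
peripapillary BM, the ring points inherit part of the tilt, so the variant
is proportional to — not equal to — the primary tilt; its role is
concordance (observed Pearson r > 0.99 across noisy eyes), not equality.

## Thickness metrics

**BMO-MRW** is the minimum point-to-segment distance from each BMO point to
the ILM polyline within its scan plane (signed-radius × depth coordinates);
48 values per eye, sector-assigned by the BMO point's FoBMO-relative
en-face angle.

**RNFL thickness** is the per-A-scan axial separation rnfl_posterior − ilm
on the 3.5 mm circle scan.

**PCT** is measured perpendicular to the local BM boundary: axial
separation × cos φ, with φ the BM inclination in the unrolled B-scan plane
from central differences of depth against arc length (one-sided at the
endpoints). The BM boundary is Savitzky–Golay smoothed (quadratic, 31
A-scans ≈ 0.44 mm of arc) before differencing: raw per-A-scan segmentation
jitter of 3 µm over a 14 µm A-scan pitch otherwise inflates |φ| enough to
bias PCT low by ~1%. Smoothing preserves linear boundaries exactly, so the
constant-slope closed form d·cos φ still holds to machine precision. An
axial mode (φ ≡ 0) is selectable. The direction of "perpendicular" is not
uniquely determined by the measurement's verbal definition; the
local-normal reading is the default here, with the axial fallback for
sensitivity checks.

**Sectorization** uses the Garway-Heath limits in the FoBMO-relative frame:
T [315°, 45°), ST [45°, 85°), SN [85°, 125°), N [125°, 235°),
IN [235°, 275°), IT [275°, 315°) — the instrument-convention sector map for
BMO-MRW/RNFL reporting. Sector means are arithmetic means of member
A-scans (uniform weights); the global mean is the mean over all A-scans,
hence exactly the count-weighted mean of sector means. Quality filtering
excludes scans with quality score strictly below 15 dB (a score of exactly
15 is included).

## Synthetic generator

Per eye the BMO ellipse (semi-axes a, a·ovality) is laid out in its own
plane whose normal makes the configured tilt with the BMB plane (z = 0); the
in-plane major-axis angle is chosen so the *measured*, FoBMO-adjusted,
folded rotation equals the configured rotation — truth and measurement
conventions coincide by construction, which is what makes the ≤1e-6
noiseless closure possible. Each radial scan (24 scans at 7.5°) contributes
the two exact ellipse/scan-line intersections as BMO points and two ring
points at 2500 µm as BMB points ("furthest peripheral" BM positions). The
ILM polyline per scan has a flat rim shelf at exactly the configured rim
width anterior to each BMO point (shelf half-width 250 µm, capped at 45% of
the BMO radius), a 300 µm posterior cup dip between shelves, and flat
retina to the scan edges; the construction guarantees the true minimum
distance is the perpendicular onto the shelf. Circle-scan boundaries are
flat base curves plus the configured per-angle RNFL/choroid profiles
(constants, per-sector steps, or arbitrary callables).

Noise: isotropic Gaussian on BMO/BMB points (default SD 5 µm — plausible
device-scale segmentation error), axial-only on ILM vertices, independent
per-boundary Gaussian on circle-scan depths (default 3 µm). Default quality
score 25 dB so exclusion logic is exercised only by explicit override. All
randomness flows from a single `numpy` Generator seeded by the caller;
identical (params, seed) gives bit-identical geometry.

Cohorts: per myopia group, axial length is drawn from a Gaussian truncated
exactly to the group interval ((−∞,24], (24,26], (26,∞) mm), patients are
filled with two eyes until the eye budget forces one-eye patients (second
eyes are OS, exercising laterality handling), and outcomes combine a
group-level marginal distribution (or a global linear link to AL), a shared
patient-level Gaussian intercept, and eye-level residual noise. Positive
outcomes (tilt, area) use a gamma family so the configured mean is exact;
bounded outcomes use truncated normals, whose realized mean shifts slightly
off the configured location when the SD is large relative to the distance
to a bound (~+1.3° for rotation at SD 20 within [0°, 90°]) — mean-critical
recovery runs therefore fix the truth at the group mean and let measurement
noise alone vary, while cohort-level statistics use the dispersed families.

What the generator does *not* emulate: raster images and speckle, real ILM
topography (the shelf construction is an analytic idealization), BMO
segmentation failure modes, peripapillary atrophy or staphyloma, and any
AL-dependence of scan scaling. Passing recovery tests therefore demonstrate
the correctness of the measurement and inference chain on geometry with
known truth — not segmentation robustness on clinical images.

## Statistics

Eye-level models are linear mixed models with a single patient random
intercept, REML-estimated via statsmodels `MixedLM` (L-BFGS with Powell and
CG fallbacks). Inference is computed in-package from the estimated
variance components (τ², σ²):

- GLS fixed effects β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y with V = σ²I + τ²ZZ'.
- Satterthwaite df for a contrast c: ν = 2g²/Var(g) with g = c'(X'V⁻¹X)⁻¹c,
  Var(g) = ∇g' A ∇g, where ∇g is the gradient in (τ², σ²) and A is the
  inverse expected REML information (½ tr(PVᵢPVⱼ) entries,
  P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹). lmerTest uses the observed profiled
  Hessian instead; the two agree on estimates and SEs to ~1e-5 and on dfs
  to a few percent (cross-checked in the test suite against lmerTest).
- Multi-df F-tests use the eigendecomposition of the contrast covariance
  with per-eigenvector Satterthwaite dfs combined through
  E = Σ νᵢ/(νᵢ−2), denominator df 2E/(E−q).
- Boundary handling: if τ̂² is at (or within 1e-8 of) zero, or every
  patient contributes one eye, the τ component is dropped and inference
  reduces *exactly* to OLS (df = n − p). Negative variance estimates are
  clipped at zero with the boundary flag set.
- Edwards semi-partial R² = (ν₁F/ν₂)/(1 + ν₁F/ν₂) from the marginal
  (Type-III) F of the effect of interest; the marginal rather than
  sequential F is used since covariate-adjusted effect sizes are the use
  case.
- No multiplicity adjustment anywhere; pairwise group markers use raw
  p < 0.05. Missing data are dropped listwise per model and counted.
- Constant-outcome degenerate calls report NaN p-values rather than
  spurious significance.

Adjusted models ("age and VF MD adjusted") add the covariates as
untransformed linear fixed effects. Patient-level variables use one row
per patient with one-way ANOVA (continuous) or chi-squared (categorical).

## Problem sizes and tolerances

The Monte-Carlo suites use 200 eyes or replicates per configuration (1000
for the plane/ellipse primitive checks and the type-I calibration), chosen
so the Monte-Carlo standard error sits well inside each assertion band:
group-mean recoveries are asserted at ±2% (±0.1° for tilt), the
mixed-model slope at 3 Monte-Carlo SEs, the null rejection rate at 3
binomial SEs around 5%, and the cross-validation concordance at r ≥ 0.95.
Noiseless closures assert ≤1e-6 relative error; pure formula evaluations
assert at 1e-9–1e-12.

## Known limitations

- The Satterthwaite covariance of variance components uses expected rather
  than observed information; dfs can differ from lmerTest by a few percent
  (p-values agree to the precision that matters at these sample sizes).
- The rotation angle inherits an O(tilt²) frame effect from the in-plane
  basis convention (≤0.05° at clinically typical tilts).
- `crossval_tilt` on data with only two BM landmarks per half-scan
  interpolates linearly, so its scale differs from the primary tilt by
  design; only its concordance is meaningful.
- The generator's ILM is piecewise linear; MRW noise behaviour on smooth
  curved rims (slight downward bias of a minimum over a noisy curve) is
  not reproduced.
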