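# onhmorph

Optic-nerve-head (ONH) morphometrics on segmented OCT geometry, for
researchers studying how axial myopia reshapes the glaucomatous optic disc.

Fundus-photograph measures of disc shape depend on the subjective clinical
disc margin. An objective alternative anchors everything to the Bruch's
membrane opening (BMO): 24 radial OCT B-scans each contribute two BMO points
and two peripheral Bruch's-membrane boundary (BMB) points in physical 3D
coordinates, and a 3.5 mm circle scan provides boundary depths for
thickness profiles. From that geometry this package computes:

- **BMO ovality index** — fit a total-least-squares plane to the 48 BMO
  points, project them into it, fit an ellipse by direct constrained conic
  least squares; ovality = *b*/*a* (semi-minor over semi-major; 1 = circular).
- **BMO tilt angle** — angle between the unit normals of the BMO plane and
  the BMB plane, `arccos(|n_BMO · n_BMB|)` in [0°, 90°], plus an independent
  cross-validation variant using Bruch's-membrane reference points at a
  fixed 1700 µm from the BMO centre.
- **BMO rotation angle** — angle of the ellipse's semi-major axis against
  the temporal horizontal, adjusted by the eye's fovea–BMO-centre (FoBMO)
  angle and folded to [0°, 90°] (the axis is undirected).
- **BMO area** — π·*a*·*b* of the fitted ellipse, in mm².
- **BMO-MRW** — minimum rim width: shortest distance from each BMO point to
  the internal limiting membrane within its scan plane.
- **RNFL thickness and peripapillary choroidal thickness (PCT)** — per
  A-scan boundary separations on the 3.5 mm circle scan (PCT measured
  perpendicular to the local Bruch's membrane), summarized globally and in
  the six FoBMO-aligned Garway-Heath sectors (T 90°, ST/SN/IN/IT 40° each,
  N 110°).
- **Cohort statistics** — axial-length myopia grouping (≤24 / 24–26 /
  >26 mm), eye-level linear mixed models with a patient random intercept
  (REML), Satterthwaite degrees of freedom for every t- and F-test, Edwards
  semi-partial R² = (ν₁F/ν₂)/(1 + ν₁F/ν₂), pairwise group contrasts,
  Pearson correlations, and patient-level ANOVA/chi-squared tests.

Because clinical scan data cannot be redistributed, the package includes a
first-class synthetic generator: it builds the same segmented geometry from
explicit ground-truth morphometrics and sector thickness profiles, with
seeded measurement noise and two-eyes-per-patient cohort structure. With
zero noise every metric reproduces its configured truth to ≤1e-6, which is
the basis of the test suite.

## Worked example

```python
from onhmorph import (simulate_eye, compute_bmo_morphometrics,
                      compute_mrw, compute_pct, compute_rnfl_thickness)
from onhmorph.synthetic import SyntheticEyeParams

params = SyntheticEyeParams(
    true_tilt_deg=3.4, true_rotation_deg=36.7, true_ovality=0.85,
    mrw_profile={"T": 155.6, "ST": 170.9, "SN": 192.0,
                 "N": 211.1, "IN": 217.0, "IT": 178.5},
    rnfl_profile_um={"T": 58.8, "ST": 85.2, "SN": 71.4,
                     "N": 57.7, "IN": 70.3, "IT": 89.2},
    choroid_profile_um=109.8,
    point_noise_sd_um=5.0, boundary_noise_sd_um=3.0,
)
scans, profile, truth = simulate_eye(params, seed=7)
m = compute_bmo_morphometrics(scans)
print(f"ovality index : {m.ovality_index:.3f}")
print(f"tilt angle    : {m.tilt_deg:.2f} deg")
print(f"rotation angle: {m.rotation_deg:.1f} deg")
_, mrw = compute_mrw(scans)
print(f"MRW SN sector : {mrw['SN']:.1f} um")
print(f"PCT global    : {compute_pct(profile).global_um:.1f} um")
```

prints

```
ovality index : 0.848
tilt angle    : 3.40 deg
rotation angle: 37.9 deg
MRW SN sector : 191.6 um
PCT global    : 109.8 um
```

i.e. one eye simulated with a high-myopia-like truth (ovality 0.85, tilt
3.4°, rotation 36.7°, superonasal rim width 192 µm, global choroid
109.8 µm) and 5 µm point / 3 µm boundary noise is measured back within the
single-eye noise floor; averaging 200 such eyes recovers the configured
group means to well under 2%.

A CLI wraps the same functions:

```sh
onhmorph simulate --seed 3 --out sim/ --geometry   # cohort + geometry JSONs
onhmorph morph sim/P0001-OD.json --crossval-ring-um 1700
onhmorph thickness sim/P0001-OD.json
onhmorph stats sim/cohort.csv --outcome tilt_deg --by-group
onhmorph pipeline --config run.yaml                # end-to-end, CSV outputs
```

Exit codes: 0 success, 2 validation error, 3 statistical failure.

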