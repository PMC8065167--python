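"""Seeded synthetic ONH scan geometry and cohorts with known ground truth.

The generator builds, per eye, the same segmented geometry the measurement
pipeline consumes — 24 radial B-scans with 2 BMO + 2 BMB points each and an
ILM polyline, plus a 3.5 mm circle-scan boundary profile — from explicit
ground-truth morphometrics (ovality, tilt, rotation, area) and per-angle
thickness profiles. With all noise set to zero every downstream metric
reproduces its configured truth to numerical precision, which is what makes
the whole pipeline testable without clinical data.

Cohort simulation layers the study's sampling structure on top: three
axial-myopia groups with truncated-Gaussian axial length, up to two eyes
per patient sharing a patient-level random intercept, and optional linear
links of an outcome's truth to axial length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .containers import (
    DEFAULT_N_ASCANS,
    N_RADIAL_SCANS,
    RADIAL_STEP_DEG,
    SECTOR_LIMITS_DEG,
    BMOMorphometrics,
    CircleScanProfile,
    RadialScan,
    RadialScanSet,
    SectorSummary,
)
from .thickness import sector_of_angles, sectorize

__all__ = [
    "ParameterError",
    "SyntheticEyeParams",
    "EyeTruth",
    "simulate_eye",
    "Dist",
    "SlopeLink",
    "GroupSpec",
    "CohortSpec",
    "simulate_cohort",
    "simulate_cohort_geometry",
    "default_cohort_spec",
    "constant_profile",
    "sector_step_profile",
    "modulated_profile",
    "GROUP_AL_INTERVALS",
    "TABLE_GROUP_SIZES",
]

Profile = Callable[[np.ndarray], np.ndarray]


class ParameterError(ValueError):
    """A synthetic-data parameter violated its invariant."""


# ---------------------------------------------------------------------------
# thickness profile helpers (all map FoBMO-relative angle ψ in degrees → µm)

def constant_profile(value_um: float) -> Profile:
    def f(psi: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(psi, dtype=float), float(value_um))

    return f


def sector_step_profile(sector_values_um: dict[str, float]) -> Profile:
    """Piecewise-constant profile taking one value per Garway-Heath sector."""
    missing = set(SECTOR_LIMITS_DEG) - set(sector_values_um)
    if missing:
        raise ParameterError(f"sector_step_profile missing sectors: {sorted(missing)}")

    def f(psi: np.ndarray) -> np.ndarray:
        labels = sector_of_angles(np.asarray(psi, dtype=float))
        return np.array([sector_values_um[str(lab)] for lab in labels.ravel()]).reshape(
            np.shape(psi)
        )

    return f


def modulated_profile(global_um: float, amplitude_um: float, harmonic: int = 2) -> Profile:
    """Mean ``global_um`` with a zero-mean sinusoidal sectoral modulation."""

    def f(psi: np.ndarray) -> np.ndarray:
        p = np.radians(np.asarray(psi, dtype=float))
        return global_um + amplitude_um * np.sin(harmonic * p)

    return f


def _as_profile(spec: "float | dict[str, float] | Profile") -> Profile:
    if callable(spec):
        return spec
    if isinstance(spec, dict):
        return sector_step_profile(spec)
    return constant_profile(float(spec))


# ---------------------------------------------------------------------------
# single-eye simulation

@dataclass
class SyntheticEyeParams:
    """Ground-truth parameters of one synthetic eye.

    Angles are degrees, lengths µm. ``mrw_profile``, ``rnfl_profile_um`` and
    ``choroid_profile_um`` map the FoBMO-relative en-face angle ψ to a
    thickness; they accept a constant, a per-sector dict, or a callable.
    ``tilt_azimuth_deg`` sets the en-face direction of the tilt axis (the
    truth morphometrics do not depend on it).
    """

    true_tilt_deg: float = 2.0
    true_rotation_deg: float = 35.0
    true_ovality: float = 0.88
    bmo_semimajor_um: float = 860.0
    bmb_ring_radius_um: float = 2500.0
    mrw_profile: object = 200.0
    rnfl_profile_um: object = 67.0
    choroid_profile_um: object = 125.0
    fobmo_deg: float = -7.0
    laterality: Literal["OD", "OS"] = "OD"
    point_noise_sd_um: float = 5.0
    boundary_noise_sd_um: float = 3.0
    quality_score_db: float = 25.0
    tilt_azimuth_deg: float = 90.0
    n_ascans: int = DEFAULT_N_ASCANS
    ilm_shelf_halfwidth_um: float = 250.0
    cup_depth_um: float = 300.0
    eye_id: str = "synthetic"

    def validate(self) -> None:
        if not (0.0 < self.true_ovality <= 1.0):
            raise ParameterError(f"true_ovality must be in (0, 1]: {self.true_ovality}")
        if not (0.0 <= self.true_tilt_deg < 90.0):
            raise ParameterError(f"true_tilt_deg must be in [0, 90): {self.true_tilt_deg}")
        if not (0.0 <= self.true_rotation_deg <= 90.0):
            raise ParameterError(
                f"true_rotation_deg must be in [0, 90]: {self.true_rotation_deg}"
            )
        if not self.bmb_ring_radius_um > self.bmo_semimajor_um:
            raise ParameterError(
                "bmb_ring_radius_um must exceed bmo_semimajor_um: "
                f"{self.bmb_ring_radius_um} <= {self.bmo_semimajor_um}"
            )
        if self.point_noise_sd_um < 0:
            raise ParameterError(f"point_noise_sd_um must be >= 0: {self.point_noise_sd_um}")
        if self.boundary_noise_sd_um < 0:
            raise ParameterError(
                f"boundary_noise_sd_um must be >= 0: {self.boundary_noise_sd_um}"
            )
        if self.laterality not in ("OD", "OS"):
            raise ParameterError(f"laterality must be OD or OS: {self.laterality}")
        if self.n_ascans < 36:
            raise ParameterError(f"n_ascans too small for sectorization: {self.n_ascans}")
        psi = np.arange(0.0, 360.0, 1.0)
        for name in ("mrw_profile", "rnfl_profile_um", "choroid_profile_um"):
            vals = _as_profile(getattr(self, name))(psi)
            if np.any(np.asarray(vals) < 0):
                raise ParameterError(f"{name} must be non-negative everywhere")


@dataclass(frozen=True)
class EyeTruth:
    """Configured ground truth of a simulated eye, in measurement convention."""

    morphometrics: BMOMorphometrics
    mrw: SectorSummary
    rnfl: SectorSummary
    pct: SectorSummary


def _mirror_scanset_to_os(scans: RadialScanSet) -> RadialScanSet:
    """Re-express OD-frame geometry as an OS acquisition (en-face x mirrored)."""
    flip = np.array([-1.0, 1.0, 1.0])
    mirrored = tuple(
        RadialScan(
            scan_angle_deg=(180.0 - s.scan_angle_deg) % 180.0,
            bmo_points=s.bmo_points * flip,
            bmb_points=s.bmb_points * flip,
            ilm_curve=s.ilm_curve * flip,
        )
        for s in scans.scans
    )
    return RadialScanSet(
        eye_id=scans.eye_id,
        laterality="OS",
        fobmo_deg=-scans.fobmo_deg,
        scans=mirrored,
        quality_score_db=scans.quality_score_db,
        normalized=False,
    )


def _mirror_profile_to_os(p: CircleScanProfile) -> CircleScanProfile:
    ang = (180.0 - p.angle_deg) % 360.0
    order = np.argsort(ang)
    return CircleScanProfile(
        eye_id=p.eye_id,
        laterality="OS",
        fobmo_deg=-p.fobmo_deg,
        angle_deg=ang[order],
        ilm=p.ilm[order],
        rnfl_posterior=p.rnfl_posterior[order],
        bm_posterior=p.bm_posterior[order],
        choroid_posterior=p.choroid_posterior[order],
        quality_score_db=p.quality_score_db,
        diameter_mm=p.diameter_mm,
        normalized=False,
    )


def simulate_eye(
    params: SyntheticEyeParams, seed: int
) -> tuple[RadialScanSet, CircleScanProfile, EyeTruth]:
    """Simulate one eye's radial-scan set and circle-scan profile.

    The BMO ellipse (semi-axes a and a·ovality) is laid out in its own
    plane, whose normal makes ``true_tilt_deg`` with the BMB plane (z = 0);
    the major axis sits at the in-plane angle that makes the measured,
    FoBMO-adjusted rotation equal ``true_rotation_deg`` by construction.
    Each radial scan contributes the two exact ellipse/scan-line
    intersections as BMO points, the two ring points at
    ``bmb_ring_radius_um`` as BMB points, and an ILM polyline whose closest
    approach to each BMO point equals the configured rim width. Isotropic
    Gaussian noise of ``point_noise_sd_um`` perturbs the landmark points
    (axially for ILM vertices); ``boundary_noise_sd_um`` perturbs the
    circle-scan boundaries. Identical seeds give identical output.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    t = math.radians(params.true_tilt_deg)
    az = math.radians(params.tilt_azimuth_deg)
    n = np.array([math.sin(t) * math.cos(az), math.sin(t) * math.sin(az), math.cos(t)])
    # in-plane basis matching the measurement convention (e1 = projected +x)
    x_axis = np.array([1.0, 0.0, 0.0])
    e1 = x_axis - np.dot(x_axis, n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    a = params.bmo_semimajor_um
    b = a * params.true_ovality
    axis_angle = math.radians((params.fobmo_deg + params.true_rotation_deg) % 180.0)
    u = math.cos(axis_angle) * e1 + math.sin(axis_angle) * e2  # major direction
    v = -math.sin(axis_angle) * e1 + math.cos(axis_angle) * e2
    A3, B3 = a * u, b * v  # conjugate semi-diameters of the 3D ellipse
    center = np.zeros(3)

    mrw_prof = _as_profile(params.mrw_profile)
    rnfl_prof = _as_profile(params.rnfl_profile_um)
    pct_prof = _as_profile(params.choroid_profile_um)

    sigma = params.point_noise_sd_um
    R_edge = params.bmb_ring_radius_um
    scans = []
    truth_bmo_psi = []
    for k in range(N_RADIAL_SCANS):
        theta = math.radians(k * RADIAL_STEP_DEG)
        d = np.array([math.cos(theta), math.sin(theta)])
        # exact ellipse/scan-line intersection: solve (A×d)cosφ + (B×d)sinφ = 0
        cxA = A3[0] * d[1] - A3[1] * d[0]
        cxB = B3[0] * d[1] - B3[1] * d[0]
        phi0 = math.atan2(-cxA, cxB)
        bmo_clean = np.array(
            [
                center + math.cos(phi) * A3 + math.sin(phi) * B3
                for phi in (phi0, phi0 + math.pi)
            ]
        )
        # order so index 0 lies on the +d side of the scan
        if bmo_clean[0, :2] @ d < 0:
            bmo_clean = bmo_clean[::-1]
        bmb_clean = np.array(
            [
                np.array([R_edge * d[0], R_edge * d[1], 0.0]),
                np.array([-R_edge * d[0], -R_edge * d[1], 0.0]),
            ]
        )
        for pt in bmo_clean:
            truth_bmo_psi.append(
                (math.degrees(math.atan2(pt[1], pt[0])) - params.fobmo_deg) % 360.0
            )

        ilm2d = _ilm_vertices(bmo_clean, d, params, mrw_prof)
        ilm3d = np.column_stack(
            [ilm2d[:, 0] * d[0], ilm2d[:, 0] * d[1], ilm2d[:, 1]]
        )
        if sigma > 0:
            bmo_noisy = bmo_clean + rng.normal(0.0, sigma, size=(2, 3))
            bmb_noisy = bmb_clean + rng.normal(0.0, sigma, size=(2, 3))
            ilm3d = ilm3d + np.column_stack(
                [np.zeros((ilm3d.shape[0], 2)), rng.normal(0.0, sigma, size=ilm3d.shape[0])]
            )
        else:
            bmo_noisy, bmb_noisy = bmo_clean, bmb_clean
        scans.append(
            RadialScan(
                scan_angle_deg=k * RADIAL_STEP_DEG,
                bmo_points=bmo_noisy,
                bmb_points=bmb_noisy,
                ilm_curve=ilm3d,
            )
        )

    scanset = RadialScanSet(
        eye_id=params.eye_id,
        laterality="OD",
        fobmo_deg=params.fobmo_deg,
        scans=tuple(scans),
        quality_score_db=params.quality_score_db,
        normalized=False,
    )

    # circle scan
    angles = np.arange(params.n_ascans) * (360.0 / params.n_ascans)
    psi = (angles - params.fobmo_deg) % 360.0
    ilm_base = np.full(params.n_ascans, 150.0)
    rnfl_true = rnfl_prof(psi)
    pct_true = pct_prof(psi)
    bm_base = np.full(params.n_ascans, 470.0)
    bnoise = params.boundary_noise_sd_um

    def jitter(size: int) -> np.ndarray:
        return rng.normal(0.0, bnoise, size=size) if bnoise > 0 else np.zeros(size)

    profile = CircleScanProfile(
        eye_id=params.eye_id,
        laterality="OD",
        fobmo_deg=params.fobmo_deg,
        angle_deg=angles,
        ilm=ilm_base + jitter(params.n_ascans),
        rnfl_posterior=ilm_base + rnfl_true + jitter(params.n_ascans),
        bm_posterior=bm_base + jitter(params.n_ascans),
        choroid_posterior=bm_base + pct_true + jitter(params.n_ascans),
        quality_score_db=params.quality_score_db,
        normalized=False,
    )

    truth = EyeTruth(
        morphometrics=BMOMorphometrics(
            ovality_index=params.true_ovality,
            tilt_deg=params.true_tilt_deg,
            rotation_deg=params.true_rotation_deg if params.true_ovality <= 0.99 else 0.0,
            bmo_area_mm2=math.pi * a * b * 1e-6,
            rotation_circular=params.true_ovality > 0.99,
        ),
        mrw=sectorize(mrw_prof(np.asarray(truth_bmo_psi)), np.asarray(truth_bmo_psi), 0.0),
        rnfl=sectorize(rnfl_true, psi, 0.0),
        pct=sectorize(pct_true, psi, 0.0),
    )

    if params.laterality == "OS":
        scanset = _mirror_scanset_to_os(scanset)
        profile = _mirror_profile_to_os(profile)
    return scanset, profile, truth


def _ilm_vertices(
    bmo_clean: np.ndarray,
    d: np.ndarray,
    params: SyntheticEyeParams,
    mrw_prof: Profile,
) -> np.ndarray:
    """ILM polyline of one scan in (signed radius, depth) coordinates.

    A flat rim shelf sits anterior to each BMO point at exactly its
    configured rim width (so the true minimum distance is the perpendicular
    onto the shelf), the cup dips posteriorly between the shelves, and the
    retina continues flat out to the scan edges.
    """
    L = params.ilm_shelf_halfwidth_um
    R_edge = params.bmb_ring_radius_um
    rho = bmo_clean[:, :2] @ d  # signed radii; index 0 positive side
    z = bmo_clean[:, 2]
    psi = np.degrees(np.arctan2(bmo_clean[:, 1], bmo_clean[:, 0]))
    m = mrw_prof((psi - params.fobmo_deg) % 360.0)
    rho_pos, rho_neg = float(rho[0]), float(rho[1])
    z_pos, z_neg = float(z[0]), float(z[1])
    m_pos, m_neg = float(m[0]), float(m[1])
    z_cup = max(z_pos, z_neg) + params.cup_depth_um
    return np.array(
        [
            (-R_edge, z_neg - m_neg),
            (rho_neg - L, z_neg - m_neg),
            (rho_neg + L, z_neg - m_neg),
            (0.0, z_cup),
            (rho_pos - L, z_pos - m_pos),
            (rho_pos + L, z_pos - m_pos),
            (R_edge, z_pos - m_pos),
        ]
    )


# ---------------------------------------------------------------------------
# cohort simulation

GROUP_AL_INTERVALS = {
    "no": (-np.inf, 24.0),
    "mild": (24.0, 26.0),
    "high": (26.0, np.inf),
}

# study cohort sizes per myopia group: (patients, eyes)
TABLE_GROUP_SIZES = {"no": (81, 145), "mild": (128, 214), "high": (68, 93)}


class Dist(BaseModel):
    """Marginal distribution of an outcome or covariate.

    ``family='gamma'`` keeps positive-support outcomes (angles, thicknesses)
    unbiased at the configured mean; ``'truncnorm'`` clips to
    [lower, upper]; ``'normal'`` is unbounded. ``sd=0`` degenerates to the
    mean for any family.
    """

    mean: float
    sd: float = 0.0
    family: Literal["normal", "gamma", "truncnorm"] = "normal"
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Dist":
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.family == "gamma" and self.sd > 0 and self.mean <= 0:
            raise ValueError("gamma family requires a positive mean")
        return self

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        if self.family == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return rng.gamma(shape, scale, size=size)
        if self.family == "truncnorm":
            lo = -np.inf if self.lower is None else (self.lower - self.mean) / self.sd
            hi = np.inf if self.upper is None else (self.upper - self.mean) / self.sd
            u = rng.uniform(size=size)
            return sps.truncnorm.ppf(u, lo, hi, loc=self.mean, scale=self.sd)
        return rng.normal(self.mean, self.sd, size=size)


class SlopeLink(BaseModel):
    """Global linear link of an outcome's truth to axial length (per mm)."""

    intercept: float
    slope: float


class GroupSpec(BaseModel):
    """Sampling specification of one axial-myopia group."""

    n_patients: int = Field(gt=0)
    n_eyes: int = Field(gt=0)
    al_mm: Dist
    age_yr: Dist = Dist(mean=72.0, sd=10.0)
    vf_md_db: Dist = Dist(mean=-6.8, sd=6.0)
    outcomes: dict[str, Dist] = Field(default_factory=dict)
    mrw_sectors_um: Optional[dict[str, float]] = None
    rnfl_sectors_um: Optional[dict[str, float]] = None
    pct_sectors_um: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "GroupSpec":
        if self.n_eyes < self.n_patients:
            raise ValueError("n_eyes must be >= n_patients")
        if self.n_eyes > 2 * self.n_patients:
            raise ValueError("n_eyes must be <= 2 * n_patients")
        if self.al_mm.sd <= 0:
            raise ValueError("al_mm.sd must be > 0 (truncated Gaussian is degenerate)")
        return self


class CohortSpec(BaseModel):
    """Full cohort: the three AL-defined groups plus correlation structure.

    ``patient_intercept_sd`` adds a shared patient-level Gaussian intercept
    to an outcome (both eyes of a patient move together);
    ``residual_sd`` adds independent eye-level noise; ``slope_links``
    replaces an outcome's group means with a global linear function of AL.
    """

    groups: dict[Literal["no", "mild", "high"], GroupSpec]
    slope_links: dict[str, SlopeLink] = Field(default_factory=dict)
    patient_intercept_sd: dict[str, float] = Field(default_factory=dict)
    residual_sd: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not self.groups:
            raise ValueError("at least one myopia group is required")
        for name, sd in {**self.patient_intercept_sd, **self.residual_sd}.items():
            if sd < 0:
                raise ValueError(f"negative SD for outcome {name!r}")
        return self


def _group_al_dist(name: str, dist: Dist) -> Dist:
    lo, hi = GROUP_AL_INTERVALS[name]
    return Dist(
        mean=dist.mean,
        sd=dist.sd,
        family="truncnorm",
        lower=None if np.isneginf(lo) else lo,
        upper=None if np.isposinf(hi) else hi,
    )


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate an eye-level cohort table with the configured structure.

    Returns one row per eye: patient_id, eye_id, laterality, myopia_group,
    al_mm, age_yr, vf_md_db, plus one column per configured outcome.
    Patients are filled with two eyes until the eye budget forces one-eye
    patients, so the eye/patient ratios are reproduced exactly. The result
    is a pure function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    outcome_names = sorted(
        {o for g in spec.groups.values() for o in g.outcomes} | set(spec.slope_links)
    )
    pid_counter = 0
    for gname, g in spec.groups.items():
        al_dist = _group_al_dist(gname, g.al_mm)
        n_two = g.n_eyes - g.n_patients
        ages = g.age_yr.draw(rng, g.n_patients)
        for i in range(g.n_patients):
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            n_eyes = 2 if i < n_two else 1
            intercepts = {
                o: rng.normal(0.0, sd) if (sd := spec.patient_intercept_sd.get(o, 0.0)) > 0 else 0.0
                for o in outcome_names
            }
            for j in range(n_eyes):
                lat = "OD" if j == 0 else "OS"
                al = float(al_dist.draw(rng, 1)[0])
                row = {
                    "patient_id": pid,
                    "eye_id": f"{pid}-{lat}",
                    "laterality": lat,
                    "myopia_group": gname,
                    "al_mm": al,
                    "age_yr": float(ages[i]),
                    "vf_md_db": float(g.vf_md_db.draw(rng, 1)[0]),
                }
                for o in outcome_names:
                    if o in spec.slope_links:
                        link = spec.slope_links[o]
                        base = link.intercept + link.slope * al
                    elif o in g.outcomes:
                        base = float(g.outcomes[o].draw(rng, 1)[0])
                    else:
                        continue
                    res = spec.residual_sd.get(o, 0.0)
                    noise = rng.normal(0.0, res) if res > 0 else 0.0
                    row[o] = base + intercepts[o] + noise
                rows.append(row)
    return pd.DataFrame(rows)


def _eye_params_from_row(row: pd.Series, g: GroupSpec, eye_id: str) -> SyntheticEyeParams:
    ovality = float(np.clip(row.get("ovality_index", 0.88), 0.05, 1.0))
    area = float(max(row.get("bmo_area_mm2", 2.11), 0.2))
    semimajor = math.sqrt(area * 1e6 / (math.pi * ovality))
    return SyntheticEyeParams(
        true_tilt_deg=float(np.clip(row.get("tilt_deg", 2.0), 0.0, 89.0)),
        true_rotation_deg=float(np.clip(row.get("rotation_deg", 35.0), 0.0, 90.0)),
        true_ovality=ovality,
        bmo_semimajor_um=semimajor,
        mrw_profile=g.mrw_sectors_um or 200.0,
        rnfl_profile_um=g.rnfl_sectors_um or 67.0,
        choroid_profile_um=g.pct_sectors_um or 125.0,
        laterality=str(row["laterality"]),
        eye_id=eye_id,
    )


def simulate_cohort_geometry(
    spec: CohortSpec, seed: int | None = None
) -> Iterator[tuple[pd.Series, RadialScanSet, CircleScanProfile, EyeTruth]]:
    """Yield per-eye geometry for a simulated cohort.

    Each eye's morphometric truth comes from the same cohort table
    `simulate_cohort` would produce; the geometry is then simulated from
    that truth, so pipeline-measured metrics estimate the table's values.
    """
    base_seed = spec.seed if seed is None else seed
    table = simulate_cohort(spec, seed=base_seed)
    rng = np.random.default_rng(np.random.SeedSequence([base_seed % (2**31), 911]))
    for _, row in table.iterrows():
        g = spec.groups[row["myopia_group"]]
        params = _eye_params_from_row(row, g, str(row["eye_id"]))
        child_seed = int(rng.integers(0, 2**31 - 1))
        scanset, profile, truth = simulate_eye(params, child_seed)
        yield row, scanset, profile, truth


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study-conditions cohort: printed group sizes, AL/age/VF means,
    and group-level morphometric truths with CI-derived between-eye spread."""
    sizes = TABLE_GROUP_SIZES
    morph = {
        # mean, between-eye sd (sd backed out of the printed 95% CIs)
        "no": {"tilt_deg": (1.7, 1.8), "ovality_index": (0.88, 0.045), "rotation_deg": (36.1, 20.0), "bmo_area_mm2": (2.11, 0.55)},
        "mild": {"tilt_deg": (2.0, 1.4), "ovality_index": (0.89, 0.04), "rotation_deg": (35.0, 20.0), "bmo_area_mm2": (2.12, 0.6)},
        "high": {"tilt_deg": (3.4, 1.4), "ovality_index": (0.85, 0.045), "rotation_deg": (36.7, 20.0), "bmo_area_mm2": (2.18, 0.6)},
    }
    rnfl = {
        "no": {"T": 52.6, "ST": 85.9, "SN": 77.4, "N": 57.6, "IN": 73.4, "IT": 89.9},
        "mild": {"T": 54.6, "ST": 81.5, "SN": 72.2, "N": 58.0, "IN": 68.1, "IT": 82.8},
        "high": {"T": 58.8, "ST": 85.2, "SN": 71.4, "N": 57.7, "IN": 70.3, "IT": 89.2},
    }
    mrw = {
        "no": {"T": 148.9, "ST": 179.4, "SN": 226.9, "N": 226.2, "IN": 243.9, "IT": 182.4},
        "mild": {"T": 148.3, "ST": 162.6, "SN": 206.6, "N": 228.8, "IN": 224.2, "IT": 177.2},
        "high": {"T": 155.6, "ST": 170.9, "SN": 192.0, "N": 211.1, "IN": 217.0, "IT": 178.5},
    }
    pct = {
        "no": {"T": 140.8, "ST": 152.5, "SN": 152.8, "N": 142.7, "IN": 111.2, "IT": 106.5},
        "mild": {"T": 121.0, "ST": 136.6, "SN": 140.9, "N": 131.4, "IN": 100.7, "IT": 95.1},
        "high": {"T": 95.0, "ST": 114.1, "SN": 128.7, "N": 128.6, "IN": 100.0, "IT": 82.7},
    }
    al = {"no": (23.4, 0.5), "mild": (24.8, 0.55), "high": (26.7, 0.7)}
    age = {"no": (77.2, 11.2), "mild": (73.0, 11.0), "high": (65.6, 12.6)}
    vf = {"no": (-6.09, 8.0), "mild": (-6.9, 8.1), "high": (-7.34, 7.6)}
    groups = {}
    for name in ("no", "mild", "high"):
        outcomes = {
            "tilt_deg": Dist(mean=morph[name]["tilt_deg"][0], sd=morph[name]["tilt_deg"][1], family="gamma"),
            "ovality_index": Dist(
                mean=morph[name]["ovality_index"][0],
                sd=morph[name]["ovality_index"][1],
                family="truncnorm",
                lower=0.3,
                upper=1.0,
            ),
            "rotation_deg": Dist(
                mean=morph[name]["rotation_deg"][0],
                sd=morph[name]["rotation_deg"][1],
                family="truncnorm",
                lower=0.0,
                upper=90.0,
            ),
            "bmo_area_mm2": Dist(
                mean=morph[name]["bmo_area_mm2"][0],
                sd=morph[name]["bmo_area_mm2"][1],
                family="gamma",
            ),
        }
        groups[name] = GroupSpec(
            n_patients=sizes[name][0],
            n_eyes=sizes[name][1],
            al_mm=Dist(mean=al[name][0], sd=al[name][1]),
            age_yr=Dist(mean=age[name][0], sd=age[name][1]),
            vf_md_db=Dist(mean=vf[name][0], sd=vf[name][1]),
            outcomes=outcomes,
            mrw_sectors_um=mrw[name],
            rnfl_sectors_um=rnfl[name],
            pct_sectors_um=pct[name],
        )
    return CohortSpec(
        groups=groups,
        patient_intercept_sd={"tilt_deg": 0.5, "ovality_index": 0.01},
        residual_sd={},
        seed=seed,
    )
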