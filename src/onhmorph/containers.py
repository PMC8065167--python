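"""Typed in-memory containers for segmented ONH scan geometry and metrics.

These are the interchange objects between the synthetic generator, the
morphometry/thickness computations and file I/O. All lengths are µm and all
angles degrees unless a field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_RADIAL_SCANS = 24
RADIAL_STEP_DEG = 180.0 / N_RADIAL_SCANS  # 7.5° between successive B-scans
CIRCLE_DIAMETER_MM = 3.5
DEFAULT_N_ASCANS = 768

SECTOR_NAMES = ("T", "ST", "SN", "N", "IN", "IT")

# Garway-Heath sector limits in the FoBMO-relative, laterality-normalized
# en-face frame (temporal = 0°, superior = 90°): T 90°, ST/SN/IN/IT 40°, N 110°.
SECTOR_LIMITS_DEG = {
    "T": ((315.0, 360.0), (0.0, 45.0)),
    "ST": ((45.0, 85.0),),
    "SN": ((85.0, 125.0),),
    "N": ((125.0, 235.0),),
    "IN": ((235.0, 275.0),),
    "IT": ((275.0, 315.0),),
}


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


@dataclass(frozen=True)
class RadialScan:
    """One radial B-scan: its en-face angle and segmented 3D landmarks."""

    scan_angle_deg: float
    bmo_points: np.ndarray  # (2, 3) µm
    bmb_points: np.ndarray  # (2, 3) µm
    ilm_curve: np.ndarray  # (k, 3) ordered polyline, µm

    def __post_init__(self) -> None:
        bmo = np.asarray(self.bmo_points, dtype=float)
        bmb = np.asarray(self.bmb_points, dtype=float)
        ilm = np.asarray(self.ilm_curve, dtype=float)
        if bmo.shape != (2, 3):
            raise ValidationError("each radial scan must carry exactly 2 BMO points")
        if bmb.shape != (2, 3):
            raise ValidationError("each radial scan must carry exactly 2 BMB points")
        if ilm.ndim != 2 or ilm.shape[1] != 3 or ilm.shape[0] < 2:
            raise ValidationError("ilm_curve must be an (k>=2, 3) polyline")
        for arr, name in ((bmo, "bmo_points"), (bmb, "bmb_points"), (ilm, "ilm_curve")):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite coordinates")
        r_bmo = np.linalg.norm(bmo[:, :2], axis=1)
        r_bmb = np.linalg.norm(bmb[:, :2], axis=1)
        if not np.all(r_bmb.min() > r_bmo.max()):
            raise ValidationError(
                "BMB points must lie en-face peripheral to both BMO points of the scan"
            )
        object.__setattr__(self, "bmo_points", bmo)
        object.__setattr__(self, "bmb_points", bmb)
        object.__setattr__(self, "ilm_curve", ilm)


@dataclass(frozen=True)
class RadialScanSet:
    """One eye's 24 radial B-scans plus acquisition metadata.

    ``fobmo_deg`` is the angle of the fovea–BMO-center axis against the
    en-face horizontal; sector placement and the rotation angle are both
    referenced to it. ``normalized`` marks whether OS geometry has already
    been mirrored into the internal OD frame.
    """

    eye_id: str
    laterality: str  # "OD" | "OS"
    fobmo_deg: float
    scans: tuple[RadialScan, ...]
    quality_score_db: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValidationError("laterality must be 'OD' or 'OS'")
        if len(self.scans) != N_RADIAL_SCANS:
            raise ValidationError(
                f"scans: expected {N_RADIAL_SCANS}, got {len(self.scans)}"
            )
        angles = sorted(s.scan_angle_deg % 180.0 for s in self.scans)
        expected = [k * RADIAL_STEP_DEG for k in range(N_RADIAL_SCANS)]
        if not np.allclose(angles, expected, atol=1e-6):
            raise ValidationError(
                "scan angles must form {k * 7.5deg : k = 0..23}"
            )
        object.__setattr__(self, "scans", tuple(self.scans))

    def to_od_frame(self) -> "RadialScanSet":
        """Mirror an OS eye into the internal OD frame (idempotent).

        En-face x is negated and the FoBMO angle flips sign; OD eyes and
        already-normalized sets pass through unchanged.
        """
        if self.laterality == "OD" or self.normalized:
            return replace(self, normalized=True)
        flip = np.array([-1.0, 1.0, 1.0])
        scans = tuple(
            RadialScan(
                scan_angle_deg=(180.0 - s.scan_angle_deg) % 180.0,
                bmo_points=s.bmo_points * flip,
                bmb_points=s.bmb_points * flip,
                ilm_curve=s.ilm_curve * flip,
            )
            for s in self.scans
        )
        return replace(self, scans=scans, fobmo_deg=-self.fobmo_deg, normalized=True)

    def pooled_bmo_points(self) -> np.ndarray:
        return np.vstack([s.bmo_points for s in self.scans])

    def pooled_bmb_points(self) -> np.ndarray:
        return np.vstack([s.bmb_points for s in self.scans])


@dataclass(frozen=True)
class BMOMorphometrics:
    """The four BMO-plane morphometrics of one eye."""

    ovality_index: float
    tilt_deg: float
    rotation_deg: float
    bmo_area_mm2: float
    rotation_circular: bool = False  # near-circular BMO: orientation ill-defined

    def __post_init__(self) -> None:
        if not (0.0 < self.ovality_index <= 1.0 + 1e-9):
            raise ValidationError(f"ovality_index out of (0, 1]: {self.ovality_index}")
        if not (0.0 <= self.tilt_deg <= 90.0):
            raise ValidationError(f"tilt_deg out of [0, 90]: {self.tilt_deg}")
        if not (0.0 <= self.rotation_deg <= 90.0):
            raise ValidationError(f"rotation_deg out of [0, 90]: {self.rotation_deg}")
        if not self.bmo_area_mm2 > 0:
            raise ValidationError(f"bmo_area_mm2 must be positive: {self.bmo_area_mm2}")


@dataclass(frozen=True)
class CircleScanProfile:
    """Boundary depths along the 3.5 mm peripapillary circle scan.

    Depths are µm, anterior→posterior, one value per A-scan; angles are the
    en-face position of each A-scan on the circle.
    """

    eye_id: str
    laterality: str
    fobmo_deg: float
    angle_deg: np.ndarray  # (n,) strictly increasing, covering [0, 360)
    ilm: np.ndarray
    rnfl_posterior: np.ndarray
    bm_posterior: np.ndarray
    choroid_posterior: np.ndarray
    quality_score_db: float
    diameter_mm: float = CIRCLE_DIAMETER_MM
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValidationError("laterality must be 'OD' or 'OS'")
        arrays = {}
        for name in ("angle_deg", "ilm", "rnfl_posterior", "bm_posterior", "choroid_posterior"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"{name} must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            arrays[name] = arr
        n = arrays["angle_deg"].size
        if any(arrays[k].size != n for k in arrays):
            raise ValidationError("boundary arrays must share the A-scan count")
        ang = arrays["angle_deg"]
        if np.any(np.diff(ang) <= 0):
            raise ValidationError("angle_deg must be strictly increasing")
        if ang[0] < 0 or ang[-1] >= 360.0:
            raise ValidationError("angle_deg must cover [0, 360)")
        if np.any(arrays["ilm"] > arrays["rnfl_posterior"] + 1e-9):
            raise ValidationError("segmentation error: ilm posterior to rnfl_posterior")
        if np.any(arrays["rnfl_posterior"] > arrays["bm_posterior"] + 1e-9):
            raise ValidationError("segmentation error: rnfl_posterior posterior to bm_posterior")
        if np.any(arrays["bm_posterior"] > arrays["choroid_posterior"] + 1e-9):
            raise ValidationError("segmentation error: bm_posterior posterior to choroid_posterior")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def n_ascans(self) -> int:
        return int(self.angle_deg.size)

    def to_od_frame(self) -> "CircleScanProfile":
        """Mirror an OS circle scan into the OD frame (idempotent).

        En-face mirroring maps angle θ → (180° − θ) mod 360 and flips the
        FoBMO sign; arrays are re-sorted to keep angles increasing.
        """
        if self.laterality == "OD" or self.normalized:
            return replace(self, normalized=True)
        ang = (180.0 - self.angle_deg) % 360.0
        order = np.argsort(ang)
        return replace(
            self,
            angle_deg=ang[order],
            ilm=self.ilm[order],
            rnfl_posterior=self.rnfl_posterior[order],
            bm_posterior=self.bm_posterior[order],
            choroid_posterior=self.choroid_posterior[order],
            fobmo_deg=-self.fobmo_deg,
            normalized=True,
        )


@dataclass(frozen=True)
class SectorSummary:
    """Global + six Garway-Heath sector means of a thickness metric (µm)."""

    global_um: float
    sectors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(SECTOR_NAMES) - set(self.sectors)
        if missing:
            raise ValidationError(f"missing sector means: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.sectors[name]

    def as_dict(self) -> dict[str, float]:
        d = {"global": self.global_um}
        d.update({k: self.sectors[k] for k in SECTOR_NAMES})
        return d
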