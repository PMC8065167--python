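"""Sectoral thickness metrics: BMO-MRW, circumpapillary RNFL, and PCT.

BMO-MRW is the shortest distance, within each radial B-scan plane, from a
BMO point to the internal limiting membrane. RNFL thickness and
peripapillary choroidal thickness (PCT) are per-A-scan boundary separations
on the 3.5 mm circle scan. All three are summarized globally and in the six
Garway-Heath sectors placed relative to the eye's FoBMO axis.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .containers import (
    SECTOR_LIMITS_DEG,
    SECTOR_NAMES,
    CircleScanProfile,
    RadialScanSet,
    SectorSummary,
)

__all__ = [
    "point_to_polyline_distance",
    "compute_mrw",
    "compute_rnfl_thickness",
    "compute_pct",
    "sectorize",
    "sector_of_angles",
    "quality_filter",
    "QUALITY_THRESHOLD_DB",
]

QUALITY_THRESHOLD_DB = 15.0


class SegmentationError(ValueError):
    """Boundary data too degenerate to measure a thickness."""


def point_to_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Minimum Euclidean distance from ``point`` to a polyline (vectorized).

    Works in any dimension; each segment's closest point is the clamped
    orthogonal projection.
    """
    p = np.asarray(point, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise SegmentationError("polyline must have at least 2 vertices")
    a = poly[:-1]
    d = poly[1:] - a
    denom = np.einsum("ij,ij->i", d, d)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / denom, 0.0, 1.0)
    closest = a + t[:, None] * d
    return float(np.min(np.linalg.norm(closest - p, axis=1)))


def sector_of_angles(psi_deg: np.ndarray) -> np.ndarray:
    """Garway-Heath sector label for each FoBMO-relative angle (degrees)."""
    psi = np.asarray(psi_deg, dtype=float) % 360.0
    labels = np.empty(psi.shape, dtype=object)
    for name, spans in SECTOR_LIMITS_DEG.items():
        for lo, hi in spans:
            labels[(psi >= lo) & (psi < hi)] = name
    return labels


def sectorize(
    values: np.ndarray,
    angles_deg: np.ndarray,
    fobmo_deg: float,
    laterality: str = "OD",
) -> SectorSummary:
    """Summarize per-A-scan values globally and by Garway-Heath sector.

    Angles are first normalized to the OD frame (OS mirrors θ → 180° − θ and
    flips the FoBMO sign), then shifted by the FoBMO angle; each sample is
    assigned to the sector containing its FoBMO-relative angle ψ. Sector
    means are arithmetic means of member samples; the global value is the
    mean over all samples.
    """
    vals = np.asarray(values, dtype=float)
    ang = np.asarray(angles_deg, dtype=float)
    if vals.shape != ang.shape or vals.ndim != 1:
        raise ValueError("values and angles must be aligned 1-D arrays")
    if vals.size == 0:
        raise SegmentationError("no samples to sectorize")
    if laterality == "OS":
        ang = (180.0 - ang) % 360.0
        fobmo_deg = -fobmo_deg
    elif laterality != "OD":
        raise ValueError("laterality must be 'OD' or 'OS'")
    psi = (ang - fobmo_deg) % 360.0
    labels = sector_of_angles(psi)
    sectors: dict[str, float] = {}
    for name in SECTOR_NAMES:
        mask = labels == name
        if not np.any(mask):
            raise SegmentationError(f"sector {name} received no A-scans")
        sectors[name] = float(vals[mask].mean())
    return SectorSummary(global_um=float(vals.mean()), sectors=sectors)


def compute_mrw(scans: RadialScanSet) -> tuple[np.ndarray, SectorSummary]:
    """BMO minimum rim width per BMO point (48 values, µm) + sector summary.

    Each radial scan plane is parameterized by the signed en-face radial
    coordinate and axial depth; the MRW of a BMO point is the minimum
    point-to-segment distance to the scan's ILM polyline in that plane.
    Sector assignment uses the BMO point's FoBMO-relative en-face angle.
    """
    norm = scans.to_od_frame()
    mrw = []
    angles = []
    for scan in norm.scans:
        theta = np.radians(scan.scan_angle_deg)
        direction = np.array([np.cos(theta), np.sin(theta)])
        ilm = scan.ilm_curve
        if ilm.shape[0] < 2:
            raise SegmentationError(
                f"eye {scans.eye_id}: degenerate ILM curve on scan {scan.scan_angle_deg}°"
            )
        # in-plane coordinates (signed radius along scan direction, depth)
        ilm2d = np.column_stack([ilm[:, :2] @ direction, ilm[:, 2]])
        for pt in scan.bmo_points:
            p2d = np.array([pt[:2] @ direction, pt[2]])
            mrw.append(point_to_polyline_distance(p2d, ilm2d))
            angles.append(np.degrees(np.arctan2(pt[1], pt[0])) % 360.0)
    mrw_arr = np.asarray(mrw)
    summary = sectorize(mrw_arr, np.asarray(angles), norm.fobmo_deg, "OD")
    return mrw_arr, summary


def compute_rnfl_thickness(profile: CircleScanProfile) -> SectorSummary:
    """Circumpapillary RNFL thickness: rnfl_posterior − ilm per A-scan, µm."""
    p = profile.to_od_frame()
    thickness = p.rnfl_posterior - p.ilm
    return sectorize(thickness, p.angle_deg, p.fobmo_deg, "OD")


def compute_pct(
    profile: CircleScanProfile, mode: str = "normal", smooth_window: int = 31
) -> SectorSummary:
    """Peripapillary choroidal thickness per A-scan, µm.

    ``mode="normal"`` (default) measures perpendicular to the local Bruch's
    membrane boundary in the unrolled B-scan plane: the axial separation
    choroid_posterior − bm_posterior is multiplied by cos(φ), with φ the
    local BM inclination estimated by central differences of depth vs. arc
    length (one-sided at the endpoints). The BM boundary is
    Savitzky–Golay smoothed (quadratic, ``smooth_window`` A-scans;
    0 disables) before differencing — otherwise per-A-scan segmentation
    jitter inflates |φ| and biases the perpendicular distance low.
    ``mode="axial"`` uses the raw axial separation.
    """
    if mode not in ("normal", "axial"):
        raise ValueError("mode must be 'normal' or 'axial'")
    p = profile.to_od_frame()
    sep = p.choroid_posterior - p.bm_posterior
    if mode == "normal":
        if p.n_ascans < 3:
            raise SegmentationError("too few A-scans for slope estimation")
        radius_um = p.diameter_mm * 1000.0 / 2.0
        arc = np.radians(p.angle_deg) * radius_um
        bm = p.bm_posterior
        window = min(int(smooth_window), p.n_ascans)
        if window % 2 == 0:
            window -= 1
        if window > 3:
            bm = savgol_filter(bm, window, polyorder=2, mode="interp")
        slope = np.gradient(bm, arc)
        sep = sep * np.cos(np.arctan(slope))
    return sectorize(sep, p.angle_deg, p.fobmo_deg, "OD")


def quality_filter(
    quality_score_db: float, threshold_db: float = QUALITY_THRESHOLD_DB
) -> tuple[bool, str]:
    """Inclusion decision for a scan quality score.

    Scans strictly below the threshold (default 15 dB) are excluded; a
    score exactly at the threshold is included. Returns (include, reason).
    """
    if not np.isfinite(threshold_db):
        raise ValueError("threshold_db must be finite")
    if quality_score_db < threshold_db:
        return False, (
            f"quality score {quality_score_db:g} dB below threshold {threshold_db:g} dB"
        )
    return True, f"quality score {quality_score_db:g} dB meets threshold {threshold_db:g} dB"
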