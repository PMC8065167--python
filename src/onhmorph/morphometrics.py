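"""BMO morphometrics: ovality index, tilt angle, rotation angle, BMO area.

The measurement pipeline mirrors the 3D geometry of the radial-scan ONH
protocol: the 48 pooled BMO points and 48 pooled Bruch's-membrane-boundary
(BMB) points each get a total-least-squares plane; the tilt is the angle
between the plane normals; the BMO points are projected into the BMO plane
and an ellipse is fit there to yield ovality (minor/major axis ratio),
rotation (major axis vs FoBMO-adjusted temporal axis) and area.
"""

from __future__ import annotations

import numpy as np

from .containers import BMOMorphometrics, RadialScanSet
from .geometry import (
    DegenerateGeometryError,
    Ellipse2D,
    Plane,
    angle_between_planes,
    fit_ellipse_2d,
    fit_plane,
    project_to_plane,
)

__all__ = [
    "compute_ovality",
    "compute_rotation_angle",
    "compute_bmo_area",
    "compute_bmo_morphometrics",
    "crossval_tilt",
    "fold_to_quadrant",
    "CIRCULAR_OVALITY_THRESHOLD",
]

# above this ovality the major-axis orientation is numerically meaningless
CIRCULAR_OVALITY_THRESHOLD = 0.99

DEFAULT_CROSSVAL_RING_UM = 1700.0


def compute_ovality(e: Ellipse2D) -> float:
    """Ovality index: minor axis divided by major axis, in (0, 1]."""
    return float(e.semi_minor_um / e.semi_major_um)


def fold_to_quadrant(angle_deg: float) -> float:
    """Fold an undirected-axis angle into [0°, 90°]."""
    a = angle_deg % 180.0
    return float(min(a, 180.0 - a))


def compute_rotation_angle(
    e: Ellipse2D, fobmo_deg: float, laterality: str = "OD"
) -> tuple[float, bool]:
    """Rotation angle of the BMO major axis, FoBMO-adjusted, in [0°, 90°].

    The major axis is undirected, so the FoBMO-relative angle is folded into
    [0°, 90°]. Inputs must already be laterality-normalized (OS mirrored to
    the OD frame); ``laterality`` is accepted for interface symmetry and
    only sanity-checked. Near-circular ellipses (ovality above
    ``CIRCULAR_OVALITY_THRESHOLD``) have no meaningful orientation: 0° is
    returned with the circular flag set.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    if compute_ovality(e) > CIRCULAR_OVALITY_THRESHOLD:
        return 0.0, True
    return fold_to_quadrant(e.axis_angle_deg - fobmo_deg), False


def compute_bmo_area(e: Ellipse2D) -> float:
    """BMO area of the fitted ellipse, mm² (π·a·b with a, b in µm)."""
    return float(np.pi * e.semi_major_um * e.semi_minor_um * 1e-6)


def _fit_bmo_planes(scans: RadialScanSet) -> tuple[RadialScanSet, Plane, Plane]:
    norm = scans.to_od_frame()
    try:
        bmo_plane = fit_plane(norm.pooled_bmo_points())
        bmb_plane = fit_plane(norm.pooled_bmb_points())
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(
            f"eye {scans.eye_id}: degenerate BMO/BMB geometry ({err})"
        ) from err
    return norm, bmo_plane, bmb_plane


def compute_bmo_morphometrics(scans: RadialScanSet) -> BMOMorphometrics:
    """Full morphometric pipeline on one eye's radial scan set.

    Steps: normalize laterality → pool the 48 BMO and 48 BMB points → fit a
    plane to each set → tilt = inter-plane angle → project BMO points to the
    BMO plane → fit an ellipse → ovality, FoBMO-adjusted rotation, area.
    """
    norm, bmo_plane, bmb_plane = _fit_bmo_planes(scans)
    tilt = angle_between_planes(bmo_plane, bmb_plane)
    pts2d = project_to_plane(norm.pooled_bmo_points(), bmo_plane)
    ellipse = fit_ellipse_2d(pts2d)
    rotation, circular = compute_rotation_angle(ellipse, norm.fobmo_deg)
    return BMOMorphometrics(
        ovality_index=min(compute_ovality(ellipse), 1.0),
        tilt_deg=tilt,
        rotation_deg=rotation,
        bmo_area_mm2=compute_bmo_area(ellipse),
        rotation_circular=circular,
    )


def crossval_tilt(scans: RadialScanSet, ring_um: float = DEFAULT_CROSSVAL_RING_UM) -> float:
    """Independent tilt variant with reference points at a fixed BMO-center distance.

    Instead of the scan-edge BMB points, the Bruch's-membrane reference for
    the peripapillary plane is taken at ±``ring_um`` (default 1700 µm) from
    the en-face BMO center along each radial scan. The BM surface between
    the BMO point and the scan-edge BMB point is linearly interpolated per
    half-scan (both landmarks lie on Bruch's membrane). Returns the angle
    between the BMO plane and the ring-reference plane, degrees.
    """
    norm, bmo_plane, _ = _fit_bmo_planes(scans)
    center_xy = norm.pooled_bmo_points()[:, :2].mean(axis=0)
    ring_pts = []
    for scan in norm.scans:
        for bmo_pt in scan.bmo_points:
            # the BMB point on the same side of the disc center as this BMO point
            d_bmo = bmo_pt[:2] - center_xy
            sides = [float(np.dot(bmb[:2] - center_xy, d_bmo)) for bmb in scan.bmb_points]
            bmb_pt = scan.bmb_points[int(np.argmax(sides))]
            r0 = float(np.linalg.norm(d_bmo))
            r1 = float(np.linalg.norm(bmb_pt[:2] - center_xy))
            if not (r0 < ring_um <= r1):
                raise ValueError(
                    f"eye {scans.eye_id}: ring radius {ring_um} µm outside the BM extent "
                    f"({r0:.1f}, {r1:.1f}] µm on scan at {scan.scan_angle_deg}°"
                )
            t = (ring_um - r0) / (r1 - r0)
            ring_pts.append(bmo_pt + t * (bmb_pt - bmo_pt))
    ring_plane = fit_plane(np.asarray(ring_pts))
    return angle_between_planes(bmo_plane, ring_plane)
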