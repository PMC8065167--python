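"""Low-level 3D/2D geometry primitives for optic-nerve-head morphometry.

All coordinates are physical micrometres in a right-handed frame:
``x`` en-face temporal→nasal (after laterality normalization), ``y`` en-face
inferior→superior, ``z`` axial anterior→posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Plane",
    "Ellipse2D",
    "DegenerateGeometryError",
    "EllipseFitError",
    "fit_plane",
    "angle_between_planes",
    "plane_basis",
    "project_to_plane",
    "fit_ellipse_2d",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point configuration cannot support the requested fit."""


class EllipseFitError(ValueError):
    """Raised when no ellipse can be fit to the supplied points."""


@dataclass(frozen=True)
class Plane:
    """A plane through ``centroid`` with unit ``normal``.

    The normal is oriented with positive z-component (ties broken toward
    positive x, then positive y) so that two fits of the same surface always
    compare the same orientation.
    """

    centroid: np.ndarray  # shape (3,), µm
    normal: np.ndarray  # shape (3,), unit

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if c.shape != (3,) or n.shape != (3,):
            raise ValueError("Plane requires 3-vectors for centroid and normal")
        if not np.all(np.isfinite(c)) or not np.all(np.isfinite(n)):
            raise ValueError("Plane coordinates must be finite")
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("Plane normal must be unit length (|n| = 1 to 1e-9)")
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "normal", _orient_normal(n))


@dataclass(frozen=True)
class Ellipse2D:
    """In-plane ellipse: center (µm), semi-axes (µm), major-axis angle.

    ``axis_angle_deg`` is the orientation of the major axis in [0°, 180°),
    counterclockwise from the (laterality-normalized) temporal horizontal
    axis of the plane's 2D basis.
    """

    center: np.ndarray  # shape (2,), µm
    semi_major_um: float
    semi_minor_um: float
    axis_angle_deg: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (2,):
            raise ValueError("Ellipse2D center must be a 2-vector")
        if not (self.semi_major_um >= self.semi_minor_um > 0):
            raise ValueError(
                "Ellipse2D requires semi_major_um >= semi_minor_um > 0, got "
                f"({self.semi_major_um}, {self.semi_minor_um})"
            )
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axis_angle_deg", float(self.axis_angle_deg) % 180.0)


def _orient_normal(n: np.ndarray) -> np.ndarray:
    """Fix the sign of a unit normal: positive z, ties to +x then +y."""
    for k in (2, 0, 1):
        if abs(n[k]) > 1e-12:
            return n if n[k] > 0 else -n
    return n


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through ``points`` (n×3, n ≥ 3).

    Minimizes the sum of squared *orthogonal* distances (not z-residuals),
    so the fit is invariant to rigid motions of the coordinate frame. The
    normal is the eigenvector of the centered scatter matrix with the
    smallest eigenvalue.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit requires at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scatter = centered.T @ centered
    evals, evecs = np.linalg.eigh(scatter)
    # rank check: collinear points leave two near-zero eigenvalues
    scale = max(evals[-1], 1.0)
    if evals[1] <= scale * 1e-12:
        raise DegenerateGeometryError("points are collinear; plane is underdetermined")
    normal = evecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    return Plane(centroid=centroid, normal=_orient_normal(normal))


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Dihedral angle between two planes, degrees in [0, 90].

    Uses arccos(|n_a · n_b|) so antiparallel normals (one orientation,
    opposite sign conventions) give 0°.
    """
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def plane_basis(ref: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e1, e2) of ``ref``.

    e1 is the unit projection of the en-face temporal axis (+x) onto the
    plane and e2 = normal × e1, so 2D angles are measured from the temporal
    horizontal. Degenerate when the plane is vertical (tilt ≥ 90°).
    """
    n = ref.normal
    x = np.array([1.0, 0.0, 0.0])
    e1 = x - np.dot(x, n) * n
    norm = np.linalg.norm(e1)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "temporal axis is parallel to the plane normal; in-plane basis undefined"
        )
    e1 = e1 / norm
    e2 = np.cross(n, e1)
    return e1, e2


def project_to_plane(points: np.ndarray, ref: Plane) -> np.ndarray:
    """Orthogonally project ``points`` (n×3) into ``ref``'s 2D basis (n×2).

    Pairwise distances of points already lying in the plane are preserved
    exactly (the projection restricted to the plane is an isometry).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    e1, e2 = plane_basis(ref)
    rel = pts - ref.centroid
    return np.column_stack([rel @ e1, rel @ e2])


def _conic_to_ellipse(coef: np.ndarray) -> Ellipse2D:
    """Convert conic coefficients (A,B,C,D,E,F) of Ax²+Bxy+Cy²+Dx+Ey+F=0."""
    A, B, C, D, E, F = coef
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise EllipseFitError("conic is not an ellipse (non-negative discriminant)")
    # center
    x0 = (2 * C * D - B * E) / disc
    y0 = (2 * A * E - B * D) / disc
    # constant at center
    Fc = F + A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0
    if Fc == 0:
        raise EllipseFitError("degenerate conic (point ellipse)")
    M = np.array([[A, B / 2], [B / 2, C]]) / (-Fc)
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals <= 0):
        raise EllipseFitError("conic is not a real ellipse")
    axes = 1.0 / np.sqrt(evals)  # descending axis for ascending eigenvalue
    # evals ascending -> axes descending: axes[0] = semi-major
    major_vec = evecs[:, 0]
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0]))) % 180.0
    return Ellipse2D(
        center=np.array([x0, y0]),
        semi_major_um=float(axes[0]),
        semi_minor_um=float(axes[1]),
        axis_angle_deg=angle,
    )


def _moment_axes(pts: np.ndarray) -> Ellipse2D:
    """Second-moment (covariance) ellipse axes — fallback for failed conic fits.

    For points sampled uniformly in parameter angle on an ellipse the
    covariance eigenvalues are a²/2 and b²/2.
    """
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise EllipseFitError("collinear points; covariance fallback degenerate")
    a = float(np.sqrt(2 * evals[1]))
    b = float(np.sqrt(2 * evals[0]))
    major_vec = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0]))) % 180.0
    return Ellipse2D(center=center, semi_major_um=a, semi_minor_um=b, axis_angle_deg=angle)


def fit_ellipse_2d(points: np.ndarray) -> Ellipse2D:
    """Direct least-squares ellipse fit (Halir–Flusser) to ≥5 2D points.

    Solves the constrained conic least-squares problem with the
    ellipse-specific constraint 4AC − B² = 1, which is exact on noiseless
    ellipse samples and always returns an ellipse when one exists. Points
    are centred and scaled before fitting for numerical stability. If the
    constrained system is degenerate a second-moment (covariance-axes)
    fallback is used.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 5:
        raise EllipseFitError("ellipse fit requires at least 5 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    # collinearity check
    centered0 = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered0, compute_uv=False)
    if sv[1] <= max(sv[0], 1.0) * 1e-10:
        raise EllipseFitError("points are collinear; no ellipse exists")

    mean = pts.mean(axis=0)
    scale = float(np.abs(centered0).mean())
    if scale == 0:
        raise EllipseFitError("all points coincide")
    q = centered0 / scale
    x, y = q[:, 0], q[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        return _rescale(_moment_axes(q), mean, scale)
    M = S1 + S2 @ T
    # premultiply by inv(C1) where C1 encodes 4AC - B^2
    M = np.array([M[2] / 2, -M[1], M[0] / 2])
    evals, evecs = np.linalg.eig(M)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    good = np.where(np.isreal(evals) & (cond > 0))[0]
    if good.size == 0:
        return _rescale(_moment_axes(q), mean, scale)
    a1 = np.real(evecs[:, good[0]])
    coef = np.concatenate([a1, T @ a1])
    try:
        ell = _conic_to_ellipse(coef)
    except EllipseFitError:
        ell = _moment_axes(q)
    return _rescale(ell, mean, scale)


def _rescale(e: Ellipse2D, mean: np.ndarray, scale: float) -> Ellipse2D:
    return Ellipse2D(
        center=e.center * scale + mean,
        semi_major_um=e.semi_major_um * scale,
        semi_minor_um=e.semi_minor_um * scale,
        axis_angle_deg=e.axis_angle_deg,
    )
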