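"""Pure 3D geometric primitives and least-squares fitting routines.

Everything downstream of the mesh/landmark loaders is built on the objects in
this module: infinite lines and planes, planar ellipses embedded in 3D, circles
in 3D fitted by Gauss-Newton, and two mesh probes (plane sections and
line-surface intersections).

Coordinates are right-handed and in millimetres throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import (
    DegenerateInputError,
    DegenerateProjectionError,
    EmptyIntersectionError,
)

__all__ = [
    "Line3",
    "Plane3",
    "Ellipse3D",
    "Circle3D",
    "SectionContour",
    "as_point",
    "as_unit",
    "orthonormal_basis",
    "fit_line_tls",
    "fit_ellipse_planar",
    "fit_circle_3d",
    "project_direction",
    "angle_deg",
    "signed_angle_deg",
    "plane_mesh_section",
    "line_mesh_intersections",
]

_UNIT_TOL = 1e-9
# sin(0.1 deg): below this projected norm a direction counts as parallel to the
# plane normal and its in-plane projection is meaningless.
_PROJ_TOL = np.sin(np.radians(0.1))


def as_point(p) -> np.ndarray:
    """Validate and return a finite 3-vector as a float array."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point has non-finite components")
    return a


def as_unit(v) -> np.ndarray:
    """Normalize a 3-vector; raise on (near-)zero input."""
    a = as_point(v)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise DegenerateInputError("cannot normalize a zero vector")
    return a / n


@dataclass(frozen=True)
class Line3:
    """Infinite line ``anchor + k * direction`` with unit direction."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", as_point(self.anchor))
        d = as_point(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            d = as_unit(d)
        object.__setattr__(self, "direction", d)

    def point_at(self, k: float) -> np.ndarray:
        return self.anchor + k * self.direction

    def distance_to_point(self, p) -> float:
        w = as_point(p) - self.anchor
        return float(np.linalg.norm(w - (w @ self.direction) * self.direction))

    def translated(self, offset) -> "Line3":
        return Line3(self.anchor + as_point(offset), self.direction)


@dataclass(frozen=True)
class Plane3:
    """Plane through ``anchor`` with unit ``normal``."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", as_point(self.anchor))
        object.__setattr__(self, "normal", as_unit(self.normal))

    def signed_distance(self, p) -> float:
        return float((as_point(p) - self.anchor) @ self.normal)


@dataclass(frozen=True)
class Ellipse3D:
    """Planar ellipse in 3D: P(t) = a cos(t) u + b sin(t) (n x u) + C."""

    center: np.ndarray
    a: float
    b: float
    normal: np.ndarray
    major_dir: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        object.__setattr__(self, "normal", as_unit(self.normal))
        object.__setattr__(self, "major_dir", as_unit(self.major_dir))
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse radii must satisfy a >= b > 0, got a={self.a}, b={self.b}")
        if abs(self.normal @ self.major_dir) > 1e-6:
            raise ValueError("major_dir must be perpendicular to normal")

    def point_at(self, t: float) -> np.ndarray:
        u = self.major_dir
        v = np.cross(self.normal, u)
        return self.center + self.a * np.cos(t) * u + self.b * np.sin(t) * v


@dataclass(frozen=True)
class Circle3D:
    """Circle in 3D with per-point fit diagnostics.

    ``radial_residuals`` are signed in-plane residuals (in-plane distance to the
    center minus the radius; positive = outside the circle).  The out-of-plane
    components of the fitted points are kept separately in
    ``out_of_plane_residuals``; the fit objective is the full 3D point-to-circle
    distance, i.e. the root of the sum of the two squared components.
    """

    center: np.ndarray
    radius: float
    normal: np.ndarray
    radial_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    out_of_plane_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = True
    iterations: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        object.__setattr__(self, "normal", as_unit(self.normal))
        object.__setattr__(self, "radial_residuals", np.atleast_1d(np.asarray(self.radial_residuals, float)))
        object.__setattr__(self, "out_of_plane_residuals", np.atleast_1d(np.asarray(self.out_of_plane_residuals, float)))
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")

    @property
    def objective(self) -> float:
        """Sum of squared 3D point-to-circle distances of the fitted points."""
        return float(np.sum(self.radial_residuals**2) + np.sum(self.out_of_plane_residuals**2))

    def point_at(self, t: float) -> np.ndarray:
        u, v = orthonormal_basis(self.normal)
        return self.center + self.radius * (np.cos(t) * u + np.sin(t) * v)


@dataclass(frozen=True)
class SectionContour:
    """One closed polyline of a plane-mesh intersection."""

    points: np.ndarray  # (n, 3), first point not repeated at the end
    primary: bool = False

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def orthonormal_basis(n) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis (u, v) with u x v = n for unit n."""
    n = as_unit(n)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    u = as_unit(np.cross(helper, n))
    v = np.cross(n, u)
    return u, v


# ---------------------------------------------------------------------------
# line / direction operations
# ---------------------------------------------------------------------------

def fit_line_tls(points, orient_along=(0.0, 0.0, 1.0)) -> Line3:
    """Total-least-squares 3D line through ``points``.

    Minimizes the sum of squared perpendicular distances; the anchor is the
    centroid and the direction is the leading principal direction of the
    centered scatter.  The sign of the direction is chosen so its component
    along ``orient_along`` is >= 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need at least 2 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u_svd, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise DegenerateInputError("all points coincide; line direction undefined")
    direction = vt[0]
    ref = np.asarray(orient_along, dtype=float)
    if direction @ ref < 0:
        direction = -direction
    return Line3(centroid, direction)


def project_direction(d, plane: Plane3) -> np.ndarray:
    """Normalized component of direction ``d`` within ``plane``."""
    d = as_unit(d)
    n = plane.normal
    w = d - (d @ n) * n
    norm = np.linalg.norm(w)
    if norm < _PROJ_TOL:
        raise DegenerateProjectionError(
            f"direction is within 0.1 deg of the plane normal (|proj| = {norm:.2e})"
        )
    return w / norm


def angle_deg(d1, d2) -> float:
    """Unsigned angle between two directions, degrees in [0, 180]."""
    c = float(np.clip(as_unit(d1) @ as_unit(d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def signed_angle_deg(d_from, d_to, axis) -> float:
    """Signed angle from ``d_from`` to ``d_to`` about ``axis`` (right-hand rule)."""
    a = as_unit(d_from)
    b = as_unit(d_to)
    ax = as_unit(axis)
    return float(np.degrees(np.arctan2(ax @ np.cross(a, b), a @ b)))


# ---------------------------------------------------------------------------
# ellipse fitting (geometric, radial deviation)
# ---------------------------------------------------------------------------

def _ellipse_radius(theta, a, b, phi):
    """Boundary radius of an ellipse along the ray at polar angle theta."""
    t = theta - phi
    return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def fit_ellipse_planar(points, slicing_plane: Plane3, fit_orientation: bool = True) -> Ellipse3D:
    """Fit an ellipse to coplanar 3D points, minimizing squared radial deviation.

    The radial deviation of a point is measured along the ray from the ellipse
    center: ``|p - C| - R(theta)`` with R the boundary radius at the point's
    polar angle.  Points must lie on ``slicing_plane`` (within 1e-6 mm); the
    fitted normal is the plane normal.  With ``fit_orientation=False`` the
    ellipse axes are held parallel to the plane's deterministic in-plane basis.
    """
    from scipy.optimize import least_squares

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    n = slicing_plane.normal
    off = (pts - slicing_plane.anchor) @ n
    if np.max(np.abs(off)) > 1e-6:
        raise ValueError(
            f"points are not on the slicing plane (max offset {np.max(np.abs(off)):.2e} mm)"
        )
    u0, v0 = orthonormal_basis(n)
    xy = np.column_stack([(pts - slicing_plane.anchor) @ u0, (pts - slicing_plane.anchor) @ v0])

    # moment-based initialization
    c0 = xy.mean(axis=0)
    cov = np.cov((xy - c0).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-12 * max(evals[-1], 1.0):
        raise DegenerateInputError("points are (near-)collinear; ellipse fit is rank-deficient")
    # uniform samples on an ellipse have coordinate std a/sqrt(2) along each axis
    a0 = float(np.sqrt(2.0 * evals[1]))
    b0 = float(np.sqrt(2.0 * evals[0]))
    phi0 = float(np.arctan2(evecs[1, 1], evecs[0, 1]))

    def residual(params):
        if fit_orientation:
            cx, cy, a, b, phi = params
        else:
            cx, cy, a, b = params
            phi = 0.0
        dx = xy[:, 0] - cx
        dy = xy[:, 1] - cy
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        return r - _ellipse_radius(theta, a, b, phi)

    x0 = [c0[0], c0[1], a0, b0, phi0] if fit_orientation else [c0[0], c0[1], a0, b0]
    sol = least_squares(residual, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if fit_orientation:
        cx, cy, a, b, phi = sol.x
    else:
        cx, cy, a, b = sol.x
        phi = 0.0
    a, b = abs(a), abs(b)
    if b > a:
        a, b = b, a
        phi += np.pi / 2.0
    res = sol.fun
    center = slicing_plane.anchor + cx * u0 + cy * v0
    major = np.cos(phi) * u0 + np.sin(phi) * v0
    return Ellipse3D(center, float(a), float(b), n, major, rms_residual=float(np.sqrt(np.mean(res**2))))


# ---------------------------------------------------------------------------
# 3D circle fitting (Gauss-Newton)
# ---------------------------------------------------------------------------

def _circle_residual_parts(pts, c, n, r):
    """In-plane (q - r) and out-of-plane (w) residual components."""
    d = pts - c
    w = d @ n
    u = d - np.outer(w, n)
    q = np.linalg.norm(u, axis=1)
    return q, w, u


def _kasa_circle_2d(xy):
    """Algebraic (Kasa) circle fit in 2D: linear least squares."""
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    bvec = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    cx, cy, c0 = sol
    r = np.sqrt(max(c0 + cx**2 + cy**2, 1e-12))
    return np.array([cx, cy]), float(r)


def fit_circle_3d(points, init: Circle3D | None = None, orient_reference=(1.0, 0.0, 0.0),
                  max_iterations: int = 100) -> Circle3D:
    """Gauss-Newton fit of a circle in 3D minimizing squared radial deviations.

    The objective is the sum of squared 3D point-to-circle distances
    ``d_i^2 = (q_i - r)^2 + w_i^2`` with ``q_i`` the in-plane distance to the
    center and ``w_i`` the out-of-plane offset.  The radius is profiled out in
    closed form (``r = mean(q)``), so the Gauss-Newton step acts on the
    residual stack ``[q - mean(q); w]`` over center (3) and plane normal (2,
    updated in a local tangent basis each step); this keeps the normal
    equations well conditioned when the points lie nearly in a plane.
    Initialization uses the PCA plane of the points and a 2D Kasa fit unless an
    explicit ``init`` circle is given.  A Levenberg damping term is enabled
    whenever a plain Gauss-Newton step fails to decrease the objective.

    Non-convergence after ``max_iterations`` yields ``converged=False`` on the
    returned circle, not an exception.  The returned normal is flipped, if
    needed, to have a positive dot product with ``orient_reference``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 4:
        raise ValueError("circle fit needs at least 4 points")

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise DegenerateInputError("points are (near-)collinear; circle fit is degenerate")

    if init is not None:
        c = np.array(init.center, float)
        n = as_unit(init.normal)
    else:
        n = vt[2]  # PCA plane normal
        u0, v0 = orthonormal_basis(n)
        xy = np.column_stack([centered @ u0, centered @ v0])
        c2, _ = _kasa_circle_2d(xy)
        c = centroid + c2[0] * u0 + c2[1] * v0

    def objective(c, n):
        q, w, _ = _circle_residual_parts(pts, c, n, 0.0)
        return float(np.sum((q - q.mean()) ** 2 + w**2))

    obj = objective(c, n)
    lam = 0.0
    converged = False
    iterations = 0
    m = len(pts)
    for iterations in range(1, max_iterations + 1):
        q, w, u = _circle_residual_parts(pts, c, n, 0.0)
        t1, t2 = orthonormal_basis(n)
        d = pts - c
        qs = np.maximum(q, 1e-12)
        uhat = u / qs[:, None]
        # residuals: [q - mean(q); w]; columns: center (3), normal tangents (2)
        Jq = np.empty((m, 5))
        Jw = np.empty((m, 5))
        Jq[:, 0:3] = -uhat
        Jw[:, 0:3] = -n
        for j, tk in enumerate((t1, t2)):
            dt = d @ tk
            Jq[:, 3 + j] = -(w / qs) * dt
            Jw[:, 3 + j] = dt
        Jq -= Jq.mean(axis=0)  # chain rule through mean(q)
        J = np.vstack([Jq, Jw])
        resid = np.concatenate([q - q.mean(), w])

        JtJ = J.T @ J
        g = J.T @ resid
        gmax = float(np.max(np.abs(g)))
        if gmax < 1e-9 * max(1.0, obj):
            converged = True
            break
        diag = np.diag(JtJ)
        D = np.diag(np.maximum(diag, 1e-6 * max(float(diag.max()), 1e-12)))
        step_accepted = False
        for _ in range(50):
            try:
                delta = np.linalg.solve(JtJ + lam * D, -g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
                continue
            c_new = c + delta[0:3]
            n_new = as_unit(n + delta[3] * t1 + delta[4] * t2)
            obj_new = objective(c_new, n_new)
            if obj_new < obj or obj_new <= obj * (1.0 + 1e-15):
                step_accepted = True
                lam = lam / 3.0 if lam > 1e-12 else 0.0
                break
            lam = max(lam * 10.0, 1e-4)  # Levenberg fallback on a non-decreasing step
        if not step_accepted:
            break
        step_norm = float(np.linalg.norm(delta))
        rel_change = (obj - obj_new) / max(obj, 1e-300)
        c, n, obj = c_new, n_new, obj_new
        # the gradient guard keeps heavily damped micro-steps far from a
        # stationary point from masquerading as convergence
        if (rel_change < 1e-12 or step_norm < 1e-10) and gmax < 1e-6 * max(1.0, obj):
            converged = True
            break

    ref = np.asarray(orient_reference, dtype=float)
    if n @ ref < 0:
        n = -n
    q, w, _ = _circle_residual_parts(pts, c, n, 0.0)
    r = float(q.mean())
    return Circle3D(center=c, radius=r, normal=n,
                    radial_residuals=q - r, out_of_plane_residuals=w,
                    converged=converged, iterations=iterations)


# ---------------------------------------------------------------------------
# mesh probes
# ---------------------------------------------------------------------------

def _as_trimesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Trimesh):
        return mesh
    inner = getattr(mesh, "mesh", None)
    if isinstance(inner, trimesh.Trimesh):
        return inner
    raise TypeError(f"expected a trimesh.Trimesh or BoneMesh, got {type(mesh)}")


def plane_mesh_section(mesh, plane: Plane3) -> list[SectionContour]:
    """Ordered closed contours of the plane-surface intersection.

    The largest-perimeter loop is tagged ``primary``.  Raises
    EmptyIntersectionError (naming the plane offset) when the plane misses the
    mesh entirely.
    """
    tm = _as_trimesh(mesh)
    path = tm.section(plane_origin=plane.anchor, plane_normal=plane.normal)
    if path is None:
        raise EmptyIntersectionError(
            f"plane at anchor {np.round(plane.anchor, 3).tolist()} "
            f"(normal {np.round(plane.normal, 4).tolist()}) does not intersect the mesh"
        )
    loops = []
    for poly in path.discrete:
        pts = np.asarray(poly, dtype=float)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) >= 3:
            loops.append(pts)
    if not loops:
        raise EmptyIntersectionError("plane-mesh intersection contains no closed loop")
    contours = [SectionContour(points=p) for p in loops]
    perims = [c.perimeter for c in contours]
    order = np.argsort(perims)[::-1]
    return [dataclasses.replace(contours[i], primary=(rank == 0)) for rank, i in enumerate(order)]


def line_mesh_intersections(line: Line3, mesh) -> list[tuple[np.ndarray, float]]:
    """All intersections of an infinite line with the mesh surface, sorted by k.

    Vectorized Moller-Trumbore over every triangle; duplicate hits produced by
    rays crossing shared edges are merged.  An empty list is allowed.
    """
    tm = _as_trimesh(mesh)
    tri = tm.triangles  # (m, 3, 3)
    if len(tri) == 0:
        return []
    o = line.anchor
    d = line.direction
    eps = 1e-12
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = o[None, :] - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv_det
    bary_eps = 1e-10
    hit = ok & (u >= -bary_eps) & (v >= -bary_eps) & (u + v <= 1.0 + bary_eps)
    k = np.einsum("ij,ij->i", e2, qvec) * inv_det
    ks = np.sort(k[hit])
    merged: list[float] = []
    for kv in ks:
        if not merged or abs(kv - merged[-1]) > 1e-9 * max(1.0, abs(kv)):
            merged.append(float(kv))
    return [(line.point_at(kv), kv) for kv in merged]
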