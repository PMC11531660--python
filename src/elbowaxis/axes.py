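"""Construction of the three axes of one specimen from a mesh and landmarks.

The three axes are:

* the **epicondylar axis** through the averaged medial and lateral epicondyle
  picks (the surgeon-palpable surrogate for the hinge axis),
* the **long (intramedullary) axis** of the distal humeral shaft, a
  total-least-squares line through the centers of ellipses fitted to five
  evenly spaced shaft cross-sections, and
* the **true flexion-extension (F-E) axis**, the normal through the center of
  the circle fitted to points picked on the deepest part of the trochlear
  groove.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import geometry as geo
from .errors import DegenerateInputError, EmptyIntersectionError, LandmarkError
from .geometry import Circle3D, Ellipse3D, Line3, Plane3

log = logging.getLogger(__name__)

# fractions of the shaft window at which the five slicing planes sit;
# chosen away from the window ends to avoid end effects
SLICE_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class BoneMesh:
    """A triangulated distal-humerus surface model (units mm)."""

    mesh: trimesh.Trimesh
    specimen_id: str = "unknown"
    side: str = "right"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.mesh.faces) == 0:
            raise ValueError("mesh has no faces")
        if not self.mesh.is_watertight:
            log.warning("mesh %s is not watertight; sections/intersections may be unreliable",
                        self.specimen_id)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)


@dataclass
class LandmarkSet:
    """Manually picked landmarks for one specimen.

    ``shaft_zrange`` bounds the distal diaphysis/metaphysis window as scalar
    coordinates along the provisional shaft direction, measured from the mesh
    vertex centroid (see :func:`provisional_shaft_frame`).
    """

    medial_picks: np.ndarray   # (3, 3)
    lateral_picks: np.ndarray  # (3, 3)
    groove_points: np.ndarray  # (>=4, 3), canonically 20
    shaft_zrange: tuple[float, float]

    def __post_init__(self):
        self.medial_picks = np.atleast_2d(np.asarray(self.medial_picks, float))
        self.lateral_picks = np.atleast_2d(np.asarray(self.lateral_picks, float))
        self.groove_points = np.atleast_2d(np.asarray(self.groove_points, float))
        if self.medial_picks.shape != (3, 3) or self.lateral_picks.shape != (3, 3):
            raise LandmarkError("exactly 3 picks per epicondyle are required")
        if self.groove_points.shape[0] < 4:
            raise LandmarkError("at least 4 trochlear-groove points are required")
        self.shaft_zrange = (float(self.shaft_zrange[0]), float(self.shaft_zrange[1]))
        if not self.shaft_zrange[1] > self.shaft_zrange[0]:
            raise LandmarkError("shaft_zrange must be an increasing (k_min, k_max) pair")

    # -- serialization ------------------------------------------------------

    def to_json(self, path):
        Path(path).write_text(json.dumps({
            "medial_picks": self.medial_picks.tolist(),
            "lateral_picks": self.lateral_picks.tolist(),
            "groove_points": self.groove_points.tolist(),
            "shaft_zrange": list(self.shaft_zrange),
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise LandmarkError(f"cannot read landmark file {path}: {exc}") from exc
        missing = {"medial_picks", "lateral_picks", "groove_points", "shaft_zrange"} - set(data)
        if missing:
            raise LandmarkError(f"landmark file {path} is missing keys: {sorted(missing)}")
        return cls(data["medial_picks"], data["lateral_picks"],
                   data["groove_points"], tuple(data["shaft_zrange"]))

    def to_csv(self, path):
        rows = [("medial_pick", *p) for p in self.medial_picks]
        rows += [("lateral_pick", *p) for p in self.lateral_picks]
        rows += [("groove", *p) for p in self.groove_points]
        rows.append(("shaft_range", self.shaft_zrange[0], self.shaft_zrange[1], 0.0))
        pd.DataFrame(rows, columns=["point_role", "x", "y", "z"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        if "point_role" not in df.columns:
            raise LandmarkError(f"landmark CSV {path} lacks a point_role column")
        def pts(role):
            return df.loc[df.point_role == role, ["x", "y", "z"]].to_numpy(float)
        rng = pts("shaft_range")
        if len(rng) != 1:
            raise LandmarkError("landmark CSV needs exactly one shaft_range row")
        return cls(pts("medial_pick"), pts("lateral_pick"), pts("groove"),
                   (rng[0, 0], rng[0, 1]))

    # -- validation ---------------------------------------------------------

    def validate_against_mesh(self, bone: BoneMesh, tol: float = 2.0) -> float:
        """Warn if any landmark is farther than ``tol`` mm from the surface.

        Returns the maximum landmark-to-surface distance.  Uses a brute-force
        closest-point query over all triangles.
        """
        pts = np.vstack([self.medial_picks, self.lateral_picks, self.groove_points])
        tris = bone.mesh.triangles
        dmax = 0.0
        for p in pts:
            closest = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
            dist = np.linalg.norm(closest - p, axis=1)
            dmax = max(dmax, float(np.min(dist)))
        if dmax > tol:
            log.warning("specimen %s: landmark lies %.2f mm from the mesh surface (tol %.1f)",
                        bone.specimen_id, dmax, tol)
        return dmax


@dataclass
class SpecimenAxes:
    """The three fitted axes of one specimen plus their fit primitives."""

    epicondylar: Line3
    long_axis: Line3
    fe_axis: Line3
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    trochlear_circle: Circle3D
    shaft_ellipses: list[Ellipse3D] = field(default_factory=list)

    def __post_init__(self):
        if geo.angle_deg(self.fe_axis.direction, self.trochlear_circle.normal) > 1e-6:
            raise ValueError("F-E axis direction must equal the trochlear-circle normal")


# ---------------------------------------------------------------------------
# axis builders
# ---------------------------------------------------------------------------

def epicondylar_axis(landmarks: LandmarkSet) -> tuple[Line3, np.ndarray, np.ndarray]:
    """Average the three picks per epicondyle; line through the two means.

    Direction is lateral -> medial; the anchor is the lateral epicondyle.
    """
    medial = landmarks.medial_picks.mean(axis=0)
    lateral = landmarks.lateral_picks.mean(axis=0)
    if np.linalg.norm(medial - lateral) < 1e-9:
        raise DegenerateInputError("epicondyle means coincide; epicondylar axis undefined")
    direction = geo.as_unit(medial - lateral)
    return Line3(lateral, direction), medial, lateral


def provisional_shaft_frame(bone: BoneMesh, groove_hint) -> tuple[np.ndarray, np.ndarray]:
    """(origin, direction) of the provisional shaft coordinate.

    Ranks vertices along the principal axis of the vertex cloud, then uses the
    line through the centroids of the most distal and most proximal 10% of
    vertices.  The sign points away from the articular mass (``groove_hint``,
    e.g. the groove-point centroid), i.e. distal -> proximal.  The scalar
    coordinate k of a point p is ``(p - origin) . direction`` with origin the
    vertex centroid; shaft_zrange values in a landmark file use this scale.
    """
    v = bone.vertices
    centroid = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
    e0 = vt[0]
    k = (v - centroid) @ e0
    qlo, qhi = np.quantile(k, [0.1, 0.9])
    lo_c = v[k <= qlo].mean(axis=0)
    hi_c = v[k >= qhi].mean(axis=0)
    direction = geo.as_unit(hi_c - lo_c)
    if (centroid - np.asarray(groove_hint, float).reshape(-1, 3).mean(axis=0)) @ direction < 0:
        direction = -direction
    return centroid, direction


def _slice_centers(bone: BoneMesh, origin, direction, k_window,
                   fractions=SLICE_FRACTIONS) -> tuple[list[Ellipse3D], np.ndarray]:
    k0, k1 = k_window
    ellipses = []
    for f in fractions:
        k = k0 + f * (k1 - k0)
        plane = Plane3(origin + k * direction, direction)
        contours = geo.plane_mesh_section(bone, plane)
        primary = next(c for c in contours if c.primary)
        if len(primary.points) < 5:
            raise EmptyIntersectionError(f"slice at k={k:.2f} has fewer than 5 contour points")
        ellipses.append(geo.fit_ellipse_planar(primary.points, plane))
    centers = np.array([e.center for e in ellipses])
    return ellipses, centers


def distal_humeral_axis(bone: BoneMesh, landmarks: LandmarkSet,
                        fractions=SLICE_FRACTIONS,
                        reslice: bool = True) -> tuple[Line3, list[Ellipse3D]]:
    """Long axis of the distal humerus from five shaft cross-section ellipses.

    Five planes, evenly spaced at ``fractions`` of the landmark shaft window
    and normal to the provisional shaft direction, cut the shaft; an ellipse is
    fitted to each primary contour and the axis is the total-least-squares line
    through the five centers (direction distal -> proximal).  One re-slicing
    pass normal to the fitted axis (default on) removes most of the dependence
    on the provisional direction.
    """
    if landmarks.shaft_zrange[1] - landmarks.shaft_zrange[0] < 20.0:
        raise LandmarkError("shaft_zrange must span at least 20 mm of diaphysis/metaphysis")
    origin, pdir = provisional_shaft_frame(bone, landmarks.groove_points)
    ellipses, centers = _slice_centers(bone, origin, pdir, landmarks.shaft_zrange, fractions)
    line = geo.fit_line_tls(centers, orient_along=pdir)
    if reslice:
        # re-slice normal to the fitted axis through the same window endpoints
        w0 = origin + landmarks.shaft_zrange[0] * pdir
        w1 = origin + landmarks.shaft_zrange[1] * pdir
        kw = ((w0 - line.anchor) @ line.direction, (w1 - line.anchor) @ line.direction)
        ellipses, centers = _slice_centers(bone, line.anchor, line.direction, kw, fractions)
        line = geo.fit_line_tls(centers, orient_along=line.direction)
    return line, ellipses


def true_fe_axis(landmarks: LandmarkSet, lateral_to_medial) -> tuple[Line3, Circle3D]:
    """Circle fit of the groove points; F-E axis = normal through its center.

    The circle normal is canonically oriented lateral -> medial using the
    epicondylar direction, so signed angles downstream are reproducible.
    """
    circle = geo.fit_circle_3d(landmarks.groove_points, orient_reference=lateral_to_medial)
    if not circle.converged:
        log.warning("trochlear circle fit did not converge after %d iterations "
                    "(objective %.3g); axis flagged", circle.iterations, circle.objective)
    return Line3(circle.center, circle.normal), circle


def build_specimen_axes(bone: BoneMesh, landmarks: LandmarkSet,
                        reslice: bool = True) -> SpecimenAxes:
    """Run all three axis constructions for one specimen."""
    epi_line, medial, lateral = epicondylar_axis(landmarks)
    long_line, ellipses = distal_humeral_axis(bone, landmarks, reslice=reslice)
    fe_line, circle = true_fe_axis(landmarks, epi_line.direction)
    log.info("specimen %s: circle fit converged=%s iters=%d rms_inplane=%.4f mm; "
             "shaft ellipse rms %.4f mm",
             bone.specimen_id, circle.converged, circle.iterations,
             float(np.sqrt(np.mean(circle.radial_residuals**2))),
             float(np.mean([e.rms_residual for e in ellipses])))
    log.debug("specimen %s circle residuals: %s", bone.specimen_id,
              np.array2string(circle.radial_residuals, precision=4))
    return SpecimenAxes(epicondylar=epi_line, long_axis=long_line, fe_axis=fe_line,
                        medial_epicondyle=medial, lateral_epicondyle=lateral,
                        trochlear_circle=circle, shaft_ellipses=ellipses)
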