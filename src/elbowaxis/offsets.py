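"""Translational offsets of the true F-E axis relative to the epicondyles.

Three quantities are measured on the mesh surface:

* the **trochlear point** and **capitellum point**, where the F-E axis exits
  the humerus medially and laterally;
* the per-direction offsets of those points from the structurally paired
  epicondyle (trochlear <-> medial, capitellum <-> lateral);
* the **axis translational offset**: the F-E axis is translated so it passes
  through the lateral epicondyle, its most-medial surface intersection (the
  medial humerus intersection point) is found, and that point's offset from
  the medial epicondyle is resolved the same way.

Signs follow anterior(+)/posterior(-), medial(+)/lateral(-) and
distal(+)/proximal(-); the last component is labelled inferior-superior in
reports as well, with distal positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .errors import EmptyIntersectionError
from .frames import AnatomicalFrame
from .geometry import Line3

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffsetRecord:
    """Absolute plus per-direction components (mm) of one point offset."""

    absolute: float
    anterior_posterior: float
    medial_lateral: float
    inferior_superior: float  # distal positive

    def __post_init__(self):
        comp_sq = (self.anterior_posterior**2 + self.medial_lateral**2
                   + self.inferior_superior**2)
        if abs(self.absolute**2 - comp_sq) > 1e-6:
            raise ValueError("offset components are not Pythagorean-consistent "
                             f"(|v|^2={self.absolute**2:.9f}, sum={comp_sq:.9f})")

    def to_dict(self) -> dict:
        return {
            "absolute_mm": self.absolute,
            "anterior_posterior_mm": self.anterior_posterior,
            "medial_lateral_mm": self.medial_lateral,
            "inferior_superior_mm": self.inferior_superior,
            "sign_convention": "anterior+/medial+/distal+ (inferior-superior = distal-proximal)",
        }

    @classmethod
    def from_vector(cls, vec, frame: AnatomicalFrame) -> "OffsetRecord":
        comp = frame.components(vec)
        return cls(absolute=float(np.linalg.norm(np.asarray(vec, float))),
                   anterior_posterior=comp["anterior_posterior"],
                   medial_lateral=comp["medial_lateral"],
                   inferior_superior=comp["inferior_superior"])


@dataclass(frozen=True)
class OffsetReport:
    trochlear_point: np.ndarray
    capitellum_point: np.ndarray
    medial_intersection_point: np.ndarray
    medial_offset: OffsetRecord
    lateral_offset: OffsetRecord
    axis_offset: OffsetRecord

    def to_dict(self) -> dict:
        return {
            "trochlear_point": np.asarray(self.trochlear_point).tolist(),
            "capitellum_point": np.asarray(self.capitellum_point).tolist(),
            "medial_intersection_point": np.asarray(self.medial_intersection_point).tolist(),
            "medial_offset": self.medial_offset.to_dict(),
            "lateral_offset": self.lateral_offset.to_dict(),
            "axis_offset": self.axis_offset.to_dict(),
        }


def axis_exit_points(fe_axis: Line3, mesh, medial_dir) -> tuple[np.ndarray, np.ndarray]:
    """Most medial / most lateral surface intersections of the F-E axis.

    ``medial_dir`` (the frame's medial direction) ranks intersections; the
    most medial exit is the trochlear point, the most lateral the capitellum
    point.  Fewer than two intersections raise EmptyIntersectionError.
    """
    hits = geo.line_mesh_intersections(fe_axis, mesh)
    if len(hits) < 2:
        raise EmptyIntersectionError(
            f"F-E axis intersects the mesh at {len(hits)} point(s); need >= 2 "
            f"(anchor {np.round(fe_axis.anchor, 2).tolist()}, "
            f"direction {np.round(fe_axis.direction, 4).tolist()})")
    medial_dir = geo.as_unit(medial_dir)
    scores = [p @ medial_dir for p, _ in hits]
    trochlear = hits[int(np.argmax(scores))][0]
    capitellum = hits[int(np.argmin(scores))][0]
    return trochlear, capitellum


def point_offsets(trochlear_point, capitellum_point, medial_epi, lateral_epi,
                  frame: AnatomicalFrame) -> tuple[OffsetRecord, OffsetRecord]:
    """Offsets of the exit points from their structurally paired epicondyles.

    Pairing is structural (trochlear <-> medial epicondyle, capitellum <->
    lateral epicondyle); a warning is logged if plain distance would pair them
    the other way round.
    """
    trochlear_point = geo.as_point(trochlear_point)
    capitellum_point = geo.as_point(capitellum_point)
    medial_epi = geo.as_point(medial_epi)
    lateral_epi = geo.as_point(lateral_epi)
    if (np.linalg.norm(trochlear_point - lateral_epi)
            < np.linalg.norm(trochlear_point - medial_epi)):
        log.warning("distance-nearest epicondyle of the trochlear point is the lateral one; "
                    "structural pairing (medial) kept")
    if (np.linalg.norm(capitellum_point - medial_epi)
            < np.linalg.norm(capitellum_point - lateral_epi)):
        log.warning("distance-nearest epicondyle of the capitellum point is the medial one; "
                    "structural pairing (lateral) kept")
    medial = OffsetRecord.from_vector(trochlear_point - medial_epi, frame)
    lateral = OffsetRecord.from_vector(capitellum_point - lateral_epi, frame)
    return medial, lateral


def axis_translational_offset(fe_axis: Line3, lateral_epi, medial_epi, mesh,
                              frame: AnatomicalFrame,
                              capitellum_point=None) -> tuple[OffsetRecord, np.ndarray]:
    """Offset of the translated-axis medial intersection from the medial epicondyle.

    The F-E axis is translated by (lateral epicondyle - capitellum point) so it
    runs through the lateral epicondyle; its most-medial intersection with the
    humeral surface is the medial humerus intersection point.  Returns the
    offset record and that point.
    """
    if capitellum_point is None:
        _, capitellum_point = axis_exit_points(fe_axis, mesh, frame.medial)
    shift = geo.as_point(lateral_epi) - geo.as_point(capitellum_point)
    translated = fe_axis.translated(shift)
    hits = geo.line_mesh_intersections(translated, mesh)
    if not hits:
        raise EmptyIntersectionError(
            "translated F-E axis does not intersect the humerus "
            f"(anchor {np.round(translated.anchor, 2).tolist()}, "
            f"direction {np.round(translated.direction, 4).tolist()})")
    scores = [p @ frame.medial for p, _ in hits]
    medial_intersection = hits[int(np.argmax(scores))][0]
    record = OffsetRecord.from_vector(medial_intersection - geo.as_point(medial_epi), frame)
    return record, medial_intersection


def full_offset_report(fe_axis: Line3, medial_epi, lateral_epi, mesh,
                       frame: AnatomicalFrame) -> OffsetReport:
    """Exit points + all three offset records for one specimen."""
    trochlear, capitellum = axis_exit_points(fe_axis, mesh, frame.medial)
    medial_rec, lateral_rec = point_offsets(trochlear, capitellum, medial_epi,
                                            lateral_epi, frame)
    axis_rec, medial_int = axis_translational_offset(
        fe_axis, lateral_epi, medial_epi, mesh, frame, capitellum_point=capitellum)
    return OffsetReport(trochlear_point=trochlear, capitellum_point=capitellum,
                        medial_intersection_point=medial_int,
                        medial_offset=medial_rec, lateral_offset=lateral_rec,
                        axis_offset=axis_rec)
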