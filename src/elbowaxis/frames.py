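"""Anatomical coordinate frame of the elbow and per-plane rotational differences.

The frame is derived from the two fitted axes alone:

* **coronal** plane: parallel to both the long axis and the F-E axis
  (normal = long x F-E, oriented anterior);
* **sagittal** plane: perpendicular to the coronal plane and to the F-E axis
  (normal oriented lateral -> medial);
* **axial** plane: transecting the long axis (normal oriented
  proximal -> distal).

Rotational differences between the epicondylar and F-E axes are reported per
plane as the signed angle (right-hand rule about the oriented plane normal)
from the projected epicondylar axis to the projected F-E axis, which equals
the difference alpha - beta of the projected angles to the long axis wherever
the latter are defined.  Clinical labels follow the convention: coronal ->
external(+)/internal(-), sagittal -> flexion(+)/extension(-), axial ->
varus(+)/valgus(-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .errors import DegenerateInputError, DegenerateProjectionError
from .geometry import Line3, Plane3

# minimum angle between the long and F-E axes for a well-posed frame
_MIN_AXIS_ANGLE_DEG = 5.0


@dataclass(frozen=True)
class AnatomicalFrame:
    coronal: Plane3
    sagittal: Plane3
    axial: Plane3
    anterior: np.ndarray
    medial: np.ndarray
    distal: np.ndarray
    side: str = "right"

    def __post_init__(self):
        dots = [abs(self.anterior @ self.medial), abs(self.medial @ self.distal),
                abs(self.anterior @ self.distal)]
        if max(dots) > 1e-9:
            raise ValueError("frame signed directions are not mutually orthogonal")
        if np.cross(self.anterior, self.medial) @ self.distal < 0.999:
            raise ValueError("(anterior, medial, distal) must form a right-handed triad")

    def components(self, vec) -> dict[str, float]:
        """Resolve a displacement onto the signed anatomical directions."""
        v = np.asarray(vec, float)
        return {
            "anterior_posterior": float(v @ self.anterior),
            "medial_lateral": float(v @ self.medial),
            "inferior_superior": float(v @ self.distal),
        }


@dataclass(frozen=True)
class AxisComparison:
    """Raw angles vs the long axis and per-plane signed differences (degrees).

    ``flexion_extension`` / ``varus_valgus`` / ``external_internal`` may be NaN
    when the corresponding projection is degenerate (flagged in ``degenerate``).
    """

    alpha: float  # long vs F-E
    beta: float   # long vs epicondylar
    absolute_diff: float
    flexion_extension: float
    varus_valgus: float
    external_internal: float
    degenerate: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "alpha_deg": self.alpha,
            "beta_deg": self.beta,
            "absolute_diff_deg": self.absolute_diff,
            "flexion_extension_deg": self.flexion_extension,
            "varus_valgus_deg": self.varus_valgus,
            "external_internal_deg": self.external_internal,
            "degenerate_planes": list(self.degenerate),
        }


def _closest_point_between_lines(l1: Line3, l2: Line3) -> np.ndarray:
    """Point on l1 closest to l2 (midpoint rule not needed; anchor for planes)."""
    d1, d2 = l1.direction, l2.direction
    w = l1.anchor - l2.anchor
    a = 1.0
    b = float(d1 @ d2)
    denom = a - b * b
    if abs(denom) < 1e-12:
        return l1.anchor
    t1 = (b * (w @ d2) - (w @ d1)) / denom
    return l1.point_at(t1)


def build_frame(long_axis: Line3, fe_axis: Line3, side: str = "right") -> AnatomicalFrame:
    """Anatomical frame from the long and F-E axes.

    ``long_axis`` must be oriented distal -> proximal and ``fe_axis``
    lateral -> medial (the canonical orientations produced by the axis
    builders).  ``side`` fixes the chirality: for a left specimen analysed in
    its own (unmirrored) coordinates the anterior direction flips so that the
    triad stays anatomically labelled.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    ang = geo.angle_deg(long_axis.direction, fe_axis.direction)
    if ang < _MIN_AXIS_ANGLE_DEG or ang > 180.0 - _MIN_AXIS_ANGLE_DEG:
        raise DegenerateInputError(
            f"long and F-E axes are near-parallel ({ang:.2f} deg); frame undefined")
    proximal = long_axis.direction
    sign = 1.0 if side == "right" else -1.0
    anterior = geo.as_unit(sign * np.cross(proximal, fe_axis.direction))
    distal = -proximal
    medial = np.cross(distal, anterior)
    anchor = _closest_point_between_lines(long_axis, fe_axis)
    return AnatomicalFrame(
        coronal=Plane3(anchor, anterior),
        sagittal=Plane3(anchor, medial),
        axial=Plane3(anchor, distal),
        anterior=anterior, medial=medial, distal=distal, side=side,
    )


def _canonical(direction, medial) -> np.ndarray:
    """Orient an axis direction lateral -> medial to avoid 180-deg ambiguity."""
    d = geo.as_unit(direction)
    return d if d @ medial >= 0 else -d


def rotational_difference(frame: AnatomicalFrame, long_dir, fe_dir, epi_dir) -> AxisComparison:
    """Per-plane signed rotational differences between the two axes.

    Both axes are canonically oriented lateral -> medial first.  The absolute
    angles alpha (long vs F-E) and beta (long vs epicondylar) are unsigned.
    Each per-plane value is the signed angle from the projected epicondylar
    axis to the projected F-E axis about the plane's oriented normal; a
    degenerate projection flags that component NaN while the others are still
    reported.
    """
    fe = _canonical(fe_dir, frame.medial)
    epi = _canonical(epi_dir, frame.medial)
    long_d = geo.as_unit(long_dir)
    alpha = geo.angle_deg(long_d, fe)
    beta = geo.angle_deg(long_d, epi)

    # oriented measurement normals: anterior (coronal), medial (sagittal),
    # proximal (axial); chosen once so positive values carry the clinical
    # labels external/flexion/varus for a canonical right-side specimen
    planes = {
        "external_internal": (frame.coronal, frame.anterior),
        "flexion_extension": (frame.sagittal, frame.medial),
        "varus_valgus": (frame.axial, -frame.distal),
    }
    values: dict[str, float] = {}
    degenerate: list[str] = []
    for name, (plane, normal) in planes.items():
        try:
            p_fe = geo.project_direction(fe, plane)
            p_epi = geo.project_direction(epi, plane)
        except DegenerateProjectionError:
            values[name] = math.nan
            degenerate.append(name)
            continue
        values[name] = geo.signed_angle_deg(p_epi, p_fe, normal)

    return AxisComparison(
        alpha=alpha, beta=beta, absolute_diff=abs(alpha - beta),
        flexion_extension=values["flexion_extension"],
        varus_valgus=values["varus_valgus"],
        external_internal=values["external_internal"],
        degenerate=tuple(degenerate),
    )


def compare_axes(frame: AnatomicalFrame, axes) -> AxisComparison:
    """Convenience wrapper over :func:`rotational_difference` for SpecimenAxes."""
    return rotational_difference(frame, axes.long_axis.direction,
                                 axes.fe_axis.direction, axes.epicondylar.direction)
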