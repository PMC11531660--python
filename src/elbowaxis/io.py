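"""File formats, run configuration, and the per-specimen / cohort pipeline.

Meshes are STL or PLY (units mm, right-handed coordinates); landmarks are the
JSON/CSV dialect of :class:`~elbowaxis.axes.LandmarkSet`.  Left-side specimens
are mirrored internally to the canonical right-side frame before analysis (the
flag is recorded in the report).  Every output embeds the config hash and seed
so a synthetic run is bit-reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .axes import BoneMesh, LandmarkSet, build_specimen_axes
from .errors import ElbowAxisError, StageError
from .frames import AxisComparison, build_frame, compare_axes
from .offsets import OffsetReport, full_offset_report
from .stats import shapiro_wilk, summarize, t_test

log = logging.getLogger(__name__)

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # x is the medial-lateral axis


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    mesh_path: str = ""
    landmark_path: str = ""
    side: str = "right"
    slice_fractions: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    reslice: bool = True
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_mesh(path, side: str = "right", specimen_id: str | None = None) -> BoneMesh:
    """Load an STL/PLY surface model; specimen id defaults to the file stem."""
    path = Path(path)
    if not path.exists():
        raise ElbowAxisError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise ElbowAxisError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ElbowAxisError(f"mesh file {path} contains no triangles")
    return BoneMesh(mesh=mesh, specimen_id=specimen_id or path.stem, side=side)


def write_mesh(bone: BoneMesh, path):
    path = Path(path)
    bone.mesh.export(str(path))


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return LandmarkSet.from_csv(path)
    return LandmarkSet.from_json(path)


def _mirror_to_right(bone: BoneMesh, landmarks: LandmarkSet) -> tuple[BoneMesh, LandmarkSet]:
    """Reflect a left-side specimen across the sagittal midplane."""
    mesh = bone.mesh.copy()
    mesh.vertices = mesh.vertices @ _MIRROR
    mesh.invert()  # keep outward orientation after the reflection
    lm = LandmarkSet(
        medial_picks=landmarks.medial_picks @ _MIRROR,
        lateral_picks=landmarks.lateral_picks @ _MIRROR,
        groove_points=landmarks.groove_points @ _MIRROR,
        shaft_zrange=landmarks.shaft_zrange,
    )
    return BoneMesh(mesh=mesh, specimen_id=bone.specimen_id, side="right"), lm


@dataclass
class SpecimenResult:
    specimen_id: str
    comparison: AxisComparison
    offsets: OffsetReport
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "comparison": self.comparison.to_dict(),
            "offsets": self.offsets.to_dict(),
            "diagnostics": self.diagnostics,
        }

    def scalar_row(self) -> dict:
        c, o = self.comparison, self.offsets
        row = {"specimen_id": self.specimen_id,
               "alpha_deg": c.alpha, "beta_deg": c.beta,
               "absolute_diff_deg": c.absolute_diff,
               "flexion_extension_deg": c.flexion_extension,
               "varus_valgus_deg": c.varus_valgus,
               "external_internal_deg": c.external_internal}
        for name, rec in (("medial", o.medial_offset), ("lateral", o.lateral_offset),
                          ("axis", o.axis_offset)):
            row[f"{name}_abs_mm"] = rec.absolute
            row[f"{name}_ap_mm"] = rec.anterior_posterior
            row[f"{name}_ml_mm"] = rec.medial_lateral
            row[f"{name}_is_mm"] = rec.inferior_superior
        return row


def _check_invariants(result: SpecimenResult, frame):
    """Built-in consistency assertions run on every pipeline result."""
    for rec in (result.offsets.medial_offset, result.offsets.lateral_offset,
                result.offsets.axis_offset):
        comp_sq = rec.anterior_posterior**2 + rec.medial_lateral**2 + rec.inferior_superior**2
        assert abs(rec.absolute**2 - comp_sq) <= 1e-6, "offset components not Pythagorean"
    normals = np.stack([frame.coronal.normal, frame.sagittal.normal, frame.axial.normal])
    gram = normals @ normals.T - np.eye(3)
    assert np.max(np.abs(gram)) <= 1e-9, "anatomical plane normals not orthonormal"


def analyze_specimen(bone: BoneMesh, landmarks: LandmarkSet,
                     config: RunConfig | None = None) -> SpecimenResult:
    """Run the full measurement chain for one specimen.

    Stages: axis construction -> anatomical frame -> rotational comparison ->
    translational offsets.  Any stage failure is re-raised as a StageError
    naming the stage and specimen.
    """
    config = config or RunConfig(side=bone.side)
    mirrored = False
    if bone.side == "left":
        bone, landmarks = _mirror_to_right(bone, landmarks)
        mirrored = True
    try:
        axes = build_specimen_axes(bone, landmarks, reslice=config.reslice)
    except ElbowAxisError as exc:
        raise StageError("axis_construction", bone.specimen_id, exc) from exc
    try:
        frame = build_frame(axes.long_axis, axes.fe_axis, side="right")
        comparison = compare_axes(frame, axes)
    except ElbowAxisError as exc:
        raise StageError("anatomical_frame", bone.specimen_id, exc) from exc
    try:
        offsets = full_offset_report(axes.fe_axis, axes.medial_epicondyle,
                                     axes.lateral_epicondyle, bone, frame)
    except ElbowAxisError as exc:
        raise StageError("offset_analysis", bone.specimen_id, exc) from exc
    circ = axes.trochlear_circle
    result = SpecimenResult(
        specimen_id=bone.specimen_id, comparison=comparison, offsets=offsets,
        diagnostics={
            "mirrored_from_left": mirrored,
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
            "circle_fit": {
                "converged": circ.converged, "iterations": circ.iterations,
                "radius_mm": circ.radius,
                "signed_residual_range_mm": [float(circ.radial_residuals.min()),
                                             float(circ.radial_residuals.max())],
                "rms_out_of_plane_mm": float(np.sqrt(np.mean(circ.out_of_plane_residuals**2))),
            },
            "shaft_ellipse_rms_mm": [e.rms_residual for e in axes.shaft_ellipses],
        })
    _check_invariants(result, frame)
    return result


def run_specimen(config: RunConfig, out_dir=None) -> SpecimenResult:
    """File-level entry point: read inputs, analyze, write the JSON report."""
    bone = read_mesh(config.mesh_path, side=config.side)
    landmarks = read_landmarks(config.landmark_path)
    result = analyze_specimen(bone, landmarks, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{result.specimen_id}.json").write_text(
            json.dumps(result.to_dict(), indent=2))
    return result


def cohort_report(results: list[SpecimenResult], paired: bool = True) -> dict:
    """Cohort table + summary statistics mirroring the study's report layout.

    Includes Shapiro-Wilk normality checks per column and the medial-vs-lateral
    offset t-tests per direction (paired by default, since both offsets come
    from the same specimens; logged prominently in the report).
    """
    table = pd.DataFrame([r.scalar_row() for r in results]).set_index("specimen_id")
    report: dict = {"n": len(results), "columns": list(table.columns)}
    if len(results) < 2:
        report["statistics"] = "unavailable (n < 2)"
        return {"table": table, "report": report}
    summary = summarize(table)
    report["summary"] = {c: {"mean": float(summary.loc[c, "mean"]),
                             "sd": float(summary.loc[c, "sd"])}
                         for c in summary.index}
    normality = {}
    for c in table.columns:
        col = table[c].dropna()
        if 3 <= len(col) <= 5000 and np.ptp(col.to_numpy()) > 0:
            w, p = shapiro_wilk(col)
            normality[c] = {"W": w, "p": p}
    report["shapiro_wilk"] = normality
    report["t_test_kind"] = "paired" if paired else "two-sample"
    tests = {}
    for direction in ("abs", "ap", "ml", "is"):
        med = table[f"medial_{direction}_mm"].abs()
        lat = table[f"lateral_{direction}_mm"].abs()
        res = t_test(med, lat, paired=paired)
        tests[f"medial_vs_lateral_{direction}"] = {
            "t": res.t, "df": res.df, "p": res.p, "degenerate": res.degenerate}
    report["t_tests"] = tests
    return {"table": table, "report": report}


def write_cohort_report(cohort: dict, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort["table"].to_csv(out_dir / "cohort_table.csv")
    (out_dir / "cohort_report.json").write_text(json.dumps(cohort["report"], indent=2))
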