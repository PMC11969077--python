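"""Winston-Lutz test orchestration: plans, isocenter solves, subset study.

A WL test is a set of portal images at prescribed (gantry, collimator)
angles.  Each image yields the BB projection and the field center; the
field centers define beam central rays (BCRs) whose least-squares
intersection is the radiation isocenter, and the BB projections are
back-projected the same way to give the BB position, so the reported
quantity is the 3D offset (BB - Iso).

The collimator-subset study re-solves the isocenter from 31 prescribed
subsets of a 56-image test (8 gantry x 7 collimator angles), grouped by
collimator usage — single 0 degrees, single 90 or 270, the opposed pair
90 & 270, and mixed/oblique sets — and reports each subset's deviation
from a reference isocenter defined as the mean of the 21 mixed-group
solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    IsocenterSolution,
    MachineGeometry,
    PlaneCoord,
    Ray,
    bcr_from_field_center,
    imager_axes,
    beam_direction,
    solve_bb_position,
    solve_isocenter,
    wrap_angle,
)
from .image_analysis import AnalysisError, EpidImage, ImageAnalysisResult, analyze_image

__all__ = [
    "AcquisitionPlan",
    "SubsetSpec",
    "WLTestResult",
    "SubsetStudyResult",
    "GROUP_C0",
    "GROUP_C90_OR_270",
    "GROUP_C90_AND_270",
    "GROUP_MIXED",
    "long_plan",
    "short_plan",
    "subset_table",
    "analyze_wl_test",
    "solve_from_measurements",
    "subset_study",
    "isocenter_from_offsets",
]

GROUP_C0 = "C = 0"
GROUP_C90_OR_270 = "C = 90|270"
GROUP_C90_AND_270 = "C = 90&270"
GROUP_MIXED = "C = Mixed"

LONG_GANTRY_ANGLES = (225.0, 270.0, 315.0, 0.0, 45.0, 90.0, 135.0, 180.0)
LONG_COLLIMATOR_ANGLES = (225.0, 270.0, 315.0, 0.0, 45.0, 90.0, 135.0)
SHORT_GANTRY_ANGLES = (270.0, 0.0, 90.0, 180.0)
SHORT_COLLIMATOR_ANGLES = (225.0, 45.0)

G4_CARDINAL = [270, 0, 90, 180]
G4_OBLIQUE = [225, 315, 45, 135]
G8_ALL = [225, 270, 315, 0, 45, 90, 135, 180]


@dataclass(frozen=True)
class AcquisitionPlan:
    """Ordered list of (gantry_deg, collimator_deg, couch_deg) items."""

    items: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if any(item[2] != 0.0 for item in self.items):
            raise ValueError("couch rotation is out of scope; couch_deg must be 0")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def long_plan() -> AcquisitionPlan:
    """The 56-image plan: 8 gantry x 7 collimator angles, gantry-major."""
    return AcquisitionPlan(
        tuple(
            (g, c, 0.0)
            for g in LONG_GANTRY_ANGLES
            for c in LONG_COLLIMATOR_ANGLES
        )
    )


def short_plan() -> AcquisitionPlan:
    """The 8-image plan: 4 cardinal gantry angles x opposed collimators 225/45."""
    return AcquisitionPlan(
        tuple(
            (g, c, 0.0)
            for g in SHORT_GANTRY_ANGLES
            for c in SHORT_COLLIMATOR_ANGLES
        )
    )


@dataclass(frozen=True)
class SubsetSpec:
    """One row of the 31-subset sampling scheme of the long WL test."""

    index: int
    gantry_angles: tuple[float, ...]
    collimator_angles: tuple[float, ...]
    group: str
    n_bcr: int

    def __post_init__(self) -> None:
        if self.n_bcr != len(self.gantry_angles) * len(self.collimator_angles):
            raise ValueError(
                f"subset {self.index}: n_bcr must be "
                f"len(gantry) * len(collimator)"
            )


def _spec(idx, gantries, colls, group):
    g = tuple(float(x) for x in gantries)
    c = tuple(float(x) for x in (colls if isinstance(colls, (list, tuple)) else [colls]))
    return SubsetSpec(idx, g, c, group, len(g) * len(c))


def subset_table() -> list[SubsetSpec]:
    """The 31 gantry/collimator subsets of the long test, with group labels.

    Groups: 3 single-collimator-0 subsets, 4 single-90-or-270 subsets,
    3 opposed-90&270 subsets, and 21 mixed subsets whose mean defines the
    reference isocenter.
    """
    rows = [
        _spec(1, G4_CARDINAL, 0, GROUP_C0),
        _spec(2, G4_CARDINAL, 90, GROUP_C90_OR_270),
        _spec(3, G4_CARDINAL, 270, GROUP_C90_OR_270),
        _spec(4, G4_OBLIQUE, 0, GROUP_C0),
        _spec(5, G8_ALL, 0, GROUP_C0),
        _spec(6, G8_ALL, 90, GROUP_C90_OR_270),
        _spec(7, G8_ALL, 270, GROUP_C90_OR_270),
        _spec(8, G4_CARDINAL, [270, 90], GROUP_C90_AND_270),
        _spec(9, G4_CARDINAL, [225, 45], GROUP_MIXED),
        _spec(10, G4_CARDINAL, [315, 135], GROUP_MIXED),
        _spec(11, G4_OBLIQUE, [270, 90], GROUP_C90_AND_270),
        _spec(12, G4_OBLIQUE, [225, 45], GROUP_MIXED),
        _spec(13, G4_OBLIQUE, [315, 135], GROUP_MIXED),
        _spec(14, G4_CARDINAL, [270, 0, 90], GROUP_MIXED),
        _spec(15, G4_OBLIQUE, [270, 0, 90], GROUP_MIXED),
        _spec(16, G8_ALL, [270, 90], GROUP_C90_AND_270),
        _spec(17, G8_ALL, [225, 45], GROUP_MIXED),
        _spec(18, G8_ALL, [315, 135], GROUP_MIXED),
        _spec(19, G4_CARDINAL, [225, 315, 45, 135], GROUP_MIXED),
        _spec(20, G4_OBLIQUE, [225, 315, 45, 135], GROUP_MIXED),
        _spec(21, G4_CARDINAL, [225, 315, 0, 45, 135], GROUP_MIXED),
        _spec(22, G4_OBLIQUE, [225, 315, 0, 45, 135], GROUP_MIXED),
        _spec(23, G8_ALL, [270, 0, 90], GROUP_MIXED),
        _spec(24, G4_CARDINAL, [225, 270, 315, 45, 90, 135], GROUP_MIXED),
        _spec(25, G4_OBLIQUE, [225, 270, 315, 45, 90, 135], GROUP_MIXED),
        _spec(26, G4_CARDINAL, [225, 270, 315, 0, 45, 90, 135], GROUP_MIXED),
        _spec(27, G4_OBLIQUE, [225, 270, 315, 0, 45, 90, 135], GROUP_MIXED),
        _spec(28, G8_ALL, [225, 315, 45, 135], GROUP_MIXED),
        _spec(29, G8_ALL, [225, 315, 0, 45, 135], GROUP_MIXED),
        _spec(30, G8_ALL, [225, 270, 315, 45, 90, 135], GROUP_MIXED),
        _spec(31, G8_ALL, [225, 270, 315, 0, 45, 90, 135], GROUP_MIXED),
    ]
    return rows


@dataclass
class WLTestResult:
    """Outcome of one WL test: per-image offsets and the solved 3D vector."""

    per_image: list[ImageAnalysisResult]
    bb_minus_iso: np.ndarray
    solution: IsocenterSolution
    bb_solution: IsocenterSolution | None = None

    def offsets_frame(self) -> pd.DataFrame:
        """Per-image measurements as a table (mm, iso-plane scale)."""
        rows = []
        for r in self.per_image:
            meta = r.meta
            rows.append(
                {
                    "image_id": meta.image_id if meta else "",
                    "gantry_deg": meta.gantry_deg if meta else np.nan,
                    "collimator_deg": meta.collimator_deg if meta else np.nan,
                    "u_bb_mm": r.bb_center.u,
                    "v_bb_mm": r.bb_center.v,
                    "u_fc_mm": r.field_center.u,
                    "v_fc_mm": r.field_center.v,
                    "du_mm": r.bb_minus_bcr.u,
                    "dv_mm": r.bb_minus_bcr.v,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SubsetStudyResult:
    """31 subset isocenters, the mixed-group reference, and the deviations."""

    per_subset: dict[int, np.ndarray]
    reference: np.ndarray
    deviations: pd.DataFrame  # columns: subset, group, n_bcr, dx/dy/dz/d3d (mm)

    def to_frame(self) -> pd.DataFrame:
        return self.deviations.copy()


def deviation_3d(dx: float, dy: float, dz: float) -> float:
    """3D deviation magnitude sqrt(dx^2 + dy^2 + dz^2), mm."""
    return float(np.sqrt(dx * dx + dy * dy + dz * dz))


def analyze_wl_test(
    images: Iterable[EpidImage], bb_mode: str = "parallel"
) -> WLTestResult:
    """Analyze a full WL image set and solve for (BB - Iso).

    Images failing QC (BB not found, edge fit failure, contamination) are
    excluded with a warning; at least four analyzable images are required.
    ``bb_mode`` selects parallel or perspective back-projection of the BB.
    """
    results: list[ImageAnalysisResult] = []
    for img in images:
        try:
            results.append(analyze_image(img))
        except AnalysisError as exc:
            warnings.warn(
                f"image {img.meta.image_id!r} excluded from WL solve: {exc}",
                stacklevel=2,
            )
    if len(results) < 4:
        raise ValueError(
            f"only {len(results)} analyzable images; need at least 4"
        )
    return solve_from_measurements(results, bb_mode=bb_mode)


def solve_from_measurements(
    results: Sequence[ImageAnalysisResult], bb_mode: str = "parallel"
) -> WLTestResult:
    """Solve isocenter and BB position from per-image analysis results."""
    geom = results[0].meta.geometry if results[0].meta else MachineGeometry()
    bcrs = [
        bcr_from_field_center(r.field_center, r.meta.gantry_deg, geom)
        for r in results
    ]
    iso = solve_isocenter(bcrs)
    bb = solve_bb_position(
        [(r.bb_center, r.meta.gantry_deg) for r in results], geom, mode=bb_mode
    )
    return WLTestResult(
        per_image=list(results),
        bb_minus_iso=bb.position - iso.position,
        solution=iso,
        bb_solution=bb,
    )


def _angle_key(gantry: float, coll: float) -> tuple[float, float]:
    return (wrap_angle(gantry), wrap_angle(coll))


def subset_study(long_test: WLTestResult | Sequence[ImageAnalysisResult]) -> SubsetStudyResult:
    """Re-solve the isocenter from each of the 31 collimator subsets.

    Reuses the per-image measurements of an analyzed 56-image long test
    (retrospective sampling; no re-imaging).  The reference isocenter is
    the componentwise mean of the 21 mixed-group solutions, and each
    subset's deviation (dx, dy, dz, d3d) is reported relative to it.
    """
    results = long_test.per_image if isinstance(long_test, WLTestResult) else list(long_test)
    geom = results[0].meta.geometry if results[0].meta else MachineGeometry()
    by_angles: dict[tuple[float, float], ImageAnalysisResult] = {}
    for r in results:
        if r.meta is None:
            raise ValueError("subset study requires per-image metadata")
        by_angles[_angle_key(r.meta.gantry_deg, r.meta.collimator_deg)] = r

    per_subset: dict[int, np.ndarray] = {}
    specs = subset_table()
    for spec in specs:
        missing = [
            (g, c)
            for g in spec.gantry_angles
            for c in spec.collimator_angles
            if _angle_key(g, c) not in by_angles
        ]
        if missing:
            raise ValueError(
                f"subset {spec.index} missing (gantry, collimator) "
                f"combinations: {missing}"
            )
        rays = [
            bcr_from_field_center(
                by_angles[_angle_key(g, c)].field_center, g, geom
            )
            for g in spec.gantry_angles
            for c in spec.collimator_angles
        ]
        per_subset[spec.index] = solve_isocenter(rays).position

    mixed = np.array(
        [per_subset[s.index] for s in specs if s.group == GROUP_MIXED]
    )
    reference = mixed.mean(axis=0)

    rows = []
    for spec in specs:
        d = per_subset[spec.index] - reference
        rows.append(
            {
                "subset": spec.index,
                "group": spec.group,
                "n_bcr": spec.n_bcr,
                "dx_mm": d[0],
                "dy_mm": d[1],
                "dz_mm": d[2],
                "d3d_mm": deviation_3d(*d),
            }
        )
    return SubsetStudyResult(
        per_subset=per_subset,
        reference=reference,
        deviations=pd.DataFrame(rows),
    )


def isocenter_from_offsets(
    offset_table: pd.DataFrame | Iterable[tuple[float, float, float, float]],
    geom: MachineGeometry | None = None,
) -> WLTestResult:
    """Solve (BB - Iso) directly from per-image 2D offsets.

    Accepts rows of ``(gantry_deg, collimator_deg, du_mm, dv_mm)`` where
    (du, dv) = BB - field center at the isocenter plane — the export
    format of external WL analysis tools.  The BB is taken as the frame
    origin, so each BCR passes through ``-(du, dv)`` in image-plane
    coordinates, and the returned ``bb_minus_iso`` is the negative of the
    solved isocenter position.
    """
    geom = geom or MachineGeometry()
    if isinstance(offset_table, pd.DataFrame):
        required = {"gantry_deg", "collimator_deg", "du_mm", "dv_mm"}
        missing = required - set(offset_table.columns)
        if missing:
            raise ValueError(f"offset table missing columns: {sorted(missing)}")
        rows = list(
            offset_table[["gantry_deg", "collimator_deg", "du_mm", "dv_mm"]]
            .itertuples(index=False, name=None)
        )
    else:
        rows = [tuple(map(float, r)) for r in offset_table]
        if any(len(r) != 4 for r in rows):
            raise ValueError("offset rows must be (gantry, collimator, du, dv)")
    gantries = {wrap_angle(r[0]) for r in rows}
    if len(rows) < 2 or len(gantries) < 2:
        raise ValueError("need offsets at >= 2 distinct gantry angles")
    rays = [
        bcr_from_field_center(PlaneCoord(-du, -dv), g, geom)
        for (g, _c, du, dv) in rows
    ]
    iso = solve_isocenter(rays)
    return WLTestResult(
        per_image=[],
        bb_minus_iso=-iso.position,
        solution=iso,
        bb_solution=None,
    )
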