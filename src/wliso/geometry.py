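"""Room-frame geometry: beam central rays and the least-squares isocenter.

Conventions
-----------
All lengths are millimetres, all angles degrees on the Varian IEC 601-2-1
scale.  The static room frame has its origin at the ball-bearing (BB)
center; +x points to the right when facing the gantry, +y toward the
floor, +z toward the gantry.  The radiation source sits at

    source(G) = SAD * (sin G, -cos G, 0)

so at gantry 0 the source is above the isocenter and the beam points
toward the floor (+y).  The imager-plane basis is

    u_hat(G) = (cos G, sin G, 0)       (crossplane)
    v_hat    = (0, 0, 1)               (inplane, toward gantry)

which together with the beam direction form a right-handed orthonormal
triad at every gantry angle.

A beam's central ray (BCR) is the line perpendicular to the image plane
through the detected radiation-field center.  BCRs are modelled as
*parallel* rays along the beam axis (not diverging source rays); the
radiation isocenter is the point minimizing the summed squared
point-to-line distances over all BCRs of a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MachineGeometry",
    "PlaneCoord",
    "Ray",
    "IsocenterSolution",
    "room_vector",
    "wrap_angle",
    "source_position",
    "beam_direction",
    "imager_axes",
    "project_to_isoplane",
    "bcr_from_field_center",
    "solve_isocenter",
    "solve_bb_position",
]

# Relative eigenvalue threshold below which the normal-equation matrix is
# treated as rank deficient (all rays parallel).
RANK_DEFICIENCY_RTOL = 1e-9


def room_vector(x: float, y: float, z: float) -> np.ndarray:
    """Build a room-frame vector (mm) as a float ndarray of shape (3,)."""
    v = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"room vector components must be finite, got {v}")
    return v


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval [0, 360)."""
    return float(deg) % 360.0


@dataclass(frozen=True)
class MachineGeometry:
    """Projection geometry of the linac + EPID.

    Parameters
    ----------
    sad_mm : float
        Source-axis distance. Default 1000 mm (TrueBeam).
    sid_mm : float
        Source-imager distance. Default 1500 mm.
    pixel_pitch_imager_mm : float
        Physical EPID pixel pitch at the imager plane. Default 0.336 mm
        (aS1200 panel); scaled by SAD/SID this gives 0.224 mm per pixel
        at the isocenter plane.
    """

    sad_mm: float = 1000.0
    sid_mm: float = 1500.0
    pixel_pitch_imager_mm: float = 0.336

    def __post_init__(self) -> None:
        if not self.sad_mm > 0:
            raise ValueError("sad_mm must be positive")
        if not self.sid_mm > self.sad_mm:
            raise ValueError("sid_mm must exceed sad_mm")
        if not self.pixel_pitch_imager_mm > 0:
            raise ValueError("pixel_pitch_imager_mm must be positive")

    @property
    def magnification(self) -> float:
        """Imager-plane magnification SID/SAD."""
        return self.sid_mm / self.sad_mm

    @property
    def pixel_pitch_iso_mm(self) -> float:
        """Pixel pitch rescaled to the isocenter plane (mm/px)."""
        return self.pixel_pitch_imager_mm * self.sad_mm / self.sid_mm


class PlaneCoord(NamedTuple):
    """2D coordinate in the image plane at the isocenter-plane scale (mm).

    ``u`` is the crossplane axis, ``v`` the inplane axis.
    """

    u: float
    v: float

    def __add__(self, other):  # type: ignore[override]
        return PlaneCoord(self.u + other[0], self.v + other[1])

    def __sub__(self, other):
        return PlaneCoord(self.u - other[0], self.v - other[1])

    @property
    def norm(self) -> float:
        return math.hypot(self.u, self.v)


@dataclass(frozen=True)
class Ray:
    """A line in room coordinates: point ``origin`` plus unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.isfinite(n):
            raise ValueError("ray direction must be a nonzero finite vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def distance_to(self, point: np.ndarray) -> float:
        """Perpendicular distance from ``point`` to this line."""
        r = np.asarray(point, dtype=float) - self.origin
        return float(np.linalg.norm(r - (r @ self.direction) * self.direction))


@dataclass
class IsocenterSolution:
    """Result of a least-squares point-to-lines solve.

    Attributes
    ----------
    position : ndarray
        Solved point in room coordinates (mm), relative to the BB.
    per_ray_distance_mm : ndarray
        Perpendicular distance from the solution to each input ray.
    rms_mm : float
        Root-mean-square of the per-ray distances (the BCR "wobble" or
        isocenter-size statistic).
    condition_flag : bool
        True when the geometry was degenerate (all rays parallel) and the
        minimum-norm pseudoinverse solution was returned.
    """

    position: np.ndarray
    per_ray_distance_mm: np.ndarray = field(repr=False)
    rms_mm: float = 0.0
    condition_flag: bool = False


def source_position(gantry_deg: float, geom: MachineGeometry) -> np.ndarray:
    """Radiation source position in room coordinates at a gantry angle."""
    g = math.radians(wrap_angle(gantry_deg))
    return geom.sad_mm * np.array([math.sin(g), -math.cos(g), 0.0])


def beam_direction(gantry_deg: float) -> np.ndarray:
    """Unit beam-axis direction (source toward imager)."""
    g = math.radians(wrap_angle(gantry_deg))
    return np.array([-math.sin(g), math.cos(g), 0.0])


def imager_axes(gantry_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Image-plane basis ``(u_hat, v_hat)`` in room coordinates.

    ``v_hat`` is fixed to +z (toward the gantry) for every gantry angle;
    EPID flips/rotations are normalized away at image load.
    """
    g = math.radians(wrap_angle(gantry_deg))
    u_hat = np.array([math.cos(g), math.sin(g), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    return u_hat, v_hat


def project_to_isoplane(
    p: np.ndarray, gantry_deg: float, geom: MachineGeometry
) -> PlaneCoord:
    """Perspective-project a room point onto the isocenter-scale image plane.

    With zeta the coordinate of ``p`` along the beam axis, the projection
    is ``(p.u, p.v) * SAD / (SAD + zeta)``: a point in the plane through
    the origin (zeta = 0) projects with unit magnification.
    """
    p = np.asarray(p, dtype=float)
    u_hat, v_hat = imager_axes(gantry_deg)
    zeta = float(p @ beam_direction(gantry_deg))
    denom = geom.sad_mm + zeta
    if denom <= 0:
        raise ValueError(
            f"point at zeta={zeta:.1f} mm lies at or behind the source "
            f"(SAD={geom.sad_mm} mm)"
        )
    s = geom.sad_mm / denom
    return PlaneCoord(float(p @ u_hat) * s, float(p @ v_hat) * s)


def bcr_from_field_center(
    fc: PlaneCoord, gantry_deg: float, geom: MachineGeometry | None = None
) -> Ray:
    """Construct the beam's central ray through a measured field center.

    The BCR is perpendicular to the image plane (i.e. parallel to the beam
    axis) and passes through the field center expressed at the isocenter
    plane.  The diverging source ray is deliberately not used; see
    :func:`solve_bb_position` for the perspective variant.
    """
    u_hat, v_hat = imager_axes(gantry_deg)
    origin = fc.u * u_hat + fc.v * v_hat
    return Ray(origin=origin, direction=beam_direction(gantry_deg))


def solve_isocenter(rays: Sequence[Ray]) -> IsocenterSolution:
    """Find the point minimizing the sum of squared distances to the rays.

    Solves the normal equations ``A x = b`` with ``A = sum(I - d d^T)``
    and ``b = sum((I - d d^T) p)`` over rays ``(p, d)``.  If ``A`` is rank
    deficient (all rays parallel) the minimum-norm solution is returned
    with ``condition_flag`` set.
    """
    rays = list(rays)
    if len(rays) < 2:
        raise ValueError(f"need at least 2 rays to solve, got {len(rays)}")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in rays:
        P = np.eye(3) - np.outer(ray.direction, ray.direction)
        A += P
        b += P @ ray.origin
    w = np.linalg.eigvalsh(A)
    degenerate = w[0] < RANK_DEFICIENCY_RTOL * max(w[-1], np.finfo(float).tiny)
    if degenerate:
        x = np.linalg.pinv(A, rcond=RANK_DEFICIENCY_RTOL) @ b
    else:
        x = np.linalg.solve(A, b)
    dists = np.array([ray.distance_to(x) for ray in rays])
    return IsocenterSolution(
        position=x,
        per_ray_distance_mm=dists,
        rms_mm=float(np.sqrt(np.mean(dists**2))),
        condition_flag=bool(degenerate),
    )


def solve_bb_position(
    bb_projections: Iterable[tuple[PlaneCoord, float]],
    geom: MachineGeometry,
    mode: str = "parallel",
) -> IsocenterSolution:
    """Back-project BB image positions and solve for the 3D BB position.

    Parameters
    ----------
    bb_projections : iterable of (PlaneCoord, gantry_deg)
        Measured BB centers at the isocenter-plane scale, one per image.
    mode : {"parallel", "perspective"}
        "parallel" builds a ray through the back-projected point along the
        beam axis, mirroring the BCR construction; "perspective" builds
        the true diverging source->projection ray.  For a BB within
        ~2 mm of the origin the two differ by less than |b|^2/SAD
        (second order, < 0.01 mm).
    """
    projections = list(bb_projections)
    if len(projections) < 2:
        raise ValueError("need at least 2 BB projections")
    if mode not in ("parallel", "perspective"):
        raise ValueError(f"unknown mode {mode!r}")
    rays = []
    for pc, gantry in projections:
        u_hat, v_hat = imager_axes(gantry)
        p0 = pc.u * u_hat + pc.v * v_hat
        if mode == "parallel":
            rays.append(Ray(origin=p0, direction=beam_direction(gantry)))
        else:
            src = source_position(gantry, geom)
            rays.append(Ray(origin=src, direction=p0 - src))
    return solve_isocenter(rays)
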