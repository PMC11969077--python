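"""Subpixel localization of the BB and the MLC field center in EPID images.

The per-image measurement of a Winston-Lutz test is the 2D offset
(BB - BCR): the BB projection center minus the radiation-field center,
expressed in mm at the isocenter plane.  The BB is found with a circular
Hough transform followed by intensity-weighted centroid refinement of
the attenuation deficit; the field center comes from 50%-of-net-intensity
edge crossings on profiles perpendicular to each of the four MLC field
edges, robust line fits per edge, and intersection of the bisectors of
the two opposing-edge pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .geometry import MachineGeometry, PlaneCoord

__all__ = [
    "EpidImage",
    "ImageMeta",
    "EdgeFit",
    "ImageAnalysisResult",
    "AnalysisError",
    "BBNotFoundError",
    "FieldFitError",
    "ContaminationError",
    "px_to_isoplane_mm",
    "isoplane_mm_to_px",
    "detect_bb",
    "detect_field",
    "analyze_image",
]

BB_DIAMETER_MM = 6.5  # tungsten sphere of the phantom


class AnalysisError(RuntimeError):
    """Base class for image-analysis failures."""


class BBNotFoundError(AnalysisError):
    """No circular Hough peak consistent with the BB was found."""


class FieldFitError(AnalysisError):
    """Too many edge profiles failed to yield a 50% crossing."""


class ContaminationError(AnalysisError):
    """BB too close to a field edge for uncontaminated localization."""


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition metadata attached to an EPID image."""

    gantry_deg: float
    collimator_deg: float
    couch_deg: float = 0.0
    geometry: MachineGeometry = dc_field(default_factory=MachineGeometry)
    field_size_cm: float | None = None
    image_id: str = ""
    # Sign mapping of the pixel row axis onto the inplane (v) axis.
    # +1: row-increasing = +v (default machine orientation).
    row_to_v_sign: int = 1


@dataclass
class EpidImage:
    """A 2D megavoltage portal image plus its acquisition metadata."""

    pixels: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if px.size and px.min() < 0:
            raise ValueError("pixel values must be non-negative")
        self.pixels = px


@dataclass
class EdgeFit:
    """Robust line fit of one field edge in the collimator frame.

    The edge is the locus ``s = offset + slope * t`` where ``s`` is the
    coordinate perpendicular to the edge and ``t`` runs along it, both in
    iso-plane mm.
    """

    name: str
    offset_mm: float
    slope: float
    rms_mm: float
    n_profiles: int
    n_used: int


@dataclass
class ImageAnalysisResult:
    """Per-image outcome: BB center, field center, and their difference."""

    bb_center: PlaneCoord
    field_center: PlaneCoord
    bb_minus_bcr: PlaneCoord
    edges: dict[str, EdgeFit]
    qc: dict[str, Any]

    @property
    def meta(self) -> ImageMeta | None:
        return self.qc.get("meta")


def _center_rc(shape: tuple[int, int]) -> tuple[float, float]:
    return (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0


def px_to_isoplane_mm(row: float, col: float, image: EpidImage) -> PlaneCoord:
    """Map pixel indices to iso-plane mm; the image center maps to (0, 0).

    Pixel centers sit at integer indices; one pixel step equals the imager
    pitch scaled by SAD/SID (0.336 * 1000/1500 = 0.224 mm by default).
    """
    geom = image.meta.geometry
    k = geom.pixel_pitch_iso_mm
    rc, cc = _center_rc(image.pixels.shape)
    u = (col - cc) * k
    v = (row - rc) * k * image.meta.row_to_v_sign
    return PlaneCoord(u, v)


def isoplane_mm_to_px(coord: PlaneCoord, image: EpidImage) -> tuple[float, float]:
    """Inverse of :func:`px_to_isoplane_mm` (returns fractional row, col)."""
    geom = image.meta.geometry
    k = geom.pixel_pitch_iso_mm
    rc, cc = _center_rc(image.pixels.shape)
    row = rc + coord.v / k * image.meta.row_to_v_sign
    col = cc + coord.u / k
    return row, col


def _normalized(image: EpidImage) -> np.ndarray:
    px = image.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        raise AnalysisError("image has no contrast")
    return (px - lo) / (hi - lo)


def expected_bb_radius_px(image: EpidImage, bb_diameter_mm: float = BB_DIAMETER_MM) -> float:
    """BB projected radius at the imager, in pixels (~14.5 px by default)."""
    geom = image.meta.geometry
    return (bb_diameter_mm / 2.0) * geom.magnification / geom.pixel_pitch_imager_mm


def detect_bb(
    image: EpidImage,
    bb_diameter_mm: float = BB_DIAMETER_MM,
    accumulator_threshold: float = 0.3,
    refine_window_factor: float = 1.5,
    polarity: str = "deficit",
) -> PlaneCoord:
    """Locate the BB projection center with subpixel precision.

    Stage 1 is a circular Hough transform on Canny edges of the
    normalized image over radii 0.8-1.2x the expected projected BB
    radius.  Stage 2 refines by the intensity-weighted centroid of the
    background-flattened attenuation deficit within
    ``refine_window_factor`` x radius of the coarse center; because the
    deficit vanishes outside the BB disc the centroid has no truncation
    bias.  Returns the center in iso-plane mm.

    ``polarity="deficit"`` (default) expects the BB darker than the open
    field; ``"excess"`` inverts for opposite-polarity exports.
    """
    img = _normalized(image)
    if polarity == "excess":
        img = 1.0 - img
    elif polarity != "deficit":
        raise ValueError(f"unknown polarity {polarity!r}")

    r_exp = expected_bb_radius_px(image, bb_diameter_mm)
    radii = np.arange(max(2.0, 0.8 * r_exp), 1.2 * r_exp + 0.5, 0.5)
    edges = canny(img, sigma=2.0)
    accs = hough_circle(edges, radii)
    _, cols, rows, fitted_radii = hough_circle_peaks(accs, radii, total_num_peaks=1)
    peak = float(accs.max()) if accs.size else 0.0
    if len(rows) == 0 or peak < accumulator_threshold:
        raise BBNotFoundError(
            f"no circular feature near radius {r_exp:.1f} px "
            f"(best accumulator {peak:.2f} < {accumulator_threshold})"
        )
    r0, c0 = float(rows[0]), float(cols[0])
    r_bb = float(fitted_radii[0])

    # Centroid refinement of the attenuation deficit, iterated so the
    # window re-centers onto the subpixel solution.
    win = refine_window_factor * r_bb
    nrow, ncol = img.shape
    for _ in range(3):
        rlo, rhi = int(max(0, math.floor(r0 - win - 2))), int(min(nrow, math.ceil(r0 + win + 3)))
        clo, chi = int(max(0, math.floor(c0 - win - 2))), int(min(ncol, math.ceil(c0 + win + 3)))
        patch = img[rlo:rhi, clo:chi]
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dist = np.hypot(rr - r0, cc - c0)
        annulus = (dist > win + 0.1 * r_bb) & (dist < win + 0.7 * r_bb)
        if not annulus.any():
            raise BBNotFoundError("BB refinement window extends outside the image")
        background = float(np.median(patch[annulus]))
        deficit = np.clip(background - patch, 0.0, None)
        deficit[dist > win] = 0.0
        total = deficit.sum()
        if total <= 0:
            raise BBNotFoundError("no attenuation deficit at the Hough location")
        r0 = float((deficit * rr).sum() / total)
        c0 = float((deficit * cc).sum() / total)
    return px_to_isoplane_mm(r0, c0, image)


def _rotation(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _sample_uv(img: np.ndarray, image: EpidImage, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear sample of the image at iso-plane (u, v) mm coordinates."""
    geom = image.meta.geometry
    k = geom.pixel_pitch_iso_mm
    rc, cc = _center_rc(img.shape)
    rows = rc + v / k * image.meta.row_to_v_sign
    cols = cc + u / k
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _estimate_collimator_blind(img: np.ndarray) -> float:
    """Estimate the field-edge orientation (mod 90 deg) from gradients."""
    gr = ndimage.sobel(img, axis=0)
    gc = ndimage.sobel(img, axis=1)
    mag = np.hypot(gr, gc)
    strong = mag > 0.5 * mag.max()
    ang = np.degrees(np.arctan2(gr[strong], gc[strong])) % 90.0
    hist, edges = np.histogram(ang, bins=90, range=(0, 90), weights=mag[strong])
    return float(edges[np.argmax(hist)] + 0.5) % 90.0


def detect_field(
    image: EpidImage,
    profiles_per_edge: int = 48,
    mad_k: float = 2.0,
    blind: bool = False,
) -> tuple[PlaneCoord, dict[str, EdgeFit]]:
    """Locate the MLC field center from 50% edge crossings.

    The baseline is the median of out-of-field pixels and the plateau the
    median of a central in-field patch (robust against the BB deficit).
    For each of the four edges, ``profiles_per_edge`` profiles are sampled
    perpendicular to the expected edge orientation (seeded from the
    collimator angle in the metadata, or estimated from the gradient
    histogram when ``blind=True``); the 50%-of-(plateau-baseline) crossing
    is located by linear interpolation, and a line is fit per edge with
    ``mad_k``-MAD outlier rejection.  The field center is the intersection
    of the bisectors of the two opposing-edge pairs, returned in
    iso-plane mm together with the four edge fits.
    """
    img = _normalized(image)
    geom = image.meta.geometry
    k = geom.pixel_pitch_iso_mm

    # -- rough extent from a mid-level threshold mask -------------------
    lo, hi = np.percentile(img, [2, 98])
    mask = ndimage.binary_fill_holes(img > 0.5 * (lo + hi))
    if mask.sum() < 16:
        raise FieldFitError("no in-field region found")
    out = ~ndimage.binary_dilation(mask, iterations=3)
    baseline = float(np.median(img[out])) if out.any() else 0.0

    rr, cc = np.nonzero(mask)
    r_ctr, c_ctr = float(rr.mean()), float(cc.mean())
    rough_center = px_to_isoplane_mm(r_ctr, c_ctr, image)

    if image.meta.field_size_cm is not None:
        half_mm = image.meta.field_size_cm * 10.0 / 2.0
    else:
        half_mm = 0.5 * math.sqrt(mask.sum()) * k

    coll = _estimate_collimator_blind(img) if blind else image.meta.collimator_deg
    R = _rotation(coll)       # collimator frame -> image uv
    Rinv = _rotation(-coll)   # image uv -> collimator frame

    # plateau: central patch in the collimator frame, two-pass median to
    # exclude the BB attenuation deficit
    t = np.linspace(-0.25 * half_mm, 0.25 * half_mm, 21)
    pp, qq = np.meshgrid(t, t)
    uv = R @ np.vstack([pp.ravel(), qq.ravel()])
    patch = _sample_uv(img, image, uv[0] + rough_center.u, uv[1] + rough_center.v)
    m1 = float(np.median(patch))
    inlier = patch > 0.8 * m1
    plateau = float(np.median(patch[inlier])) if inlier.any() else m1
    net = plateau - baseline
    if net <= 0:
        raise FieldFitError("field plateau not above baseline")

    # -- per-edge 50% crossings -----------------------------------------
    # Collimator-frame coordinates (p, q) centered on the rough center.
    # Edges: p = +/-half (names u+/u-), q = +/-half (names v+/v-).
    w = min(max(6.0 * k, 3.0), 0.45 * half_mm)  # search half-width, mm
    s_step = 0.25 * k
    ts = np.linspace(-0.35 * half_mm * 2, 0.35 * half_mm * 2, profiles_per_edge) / 2.0
    ss = np.arange(-w, w + s_step, s_step)

    def crossings_for(axis: int, sign: int) -> tuple[np.ndarray, np.ndarray]:
        s0 = sign * half_mm
        good_t, good_s = [], []
        for t_i in ts:
            frame = np.zeros((2, ss.size))
            frame[axis] = s0 + ss
            frame[1 - axis] = t_i
            uv_i = R @ frame
            prof = _sample_uv(img, image, uv_i[0] + rough_center.u, uv_i[1] + rough_center.v)
            y = (prof - baseline) / net - 0.5
            # walking outward: signal falls through 0.5 at the edge
            flips = np.nonzero(np.diff(np.signbit(y)))[0]
            if flips.size == 0:
                continue
            mid = np.abs(ss[flips]).argmin()
            j = flips[mid]
            frac = y[j] / (y[j] - y[j + 1])
            good_t.append(t_i)
            good_s.append(s0 + ss[j] + frac * s_step)
        return np.array(good_t), np.array(good_s)

    names = {(0, +1): "u+", (0, -1): "u-", (1, +1): "v+", (1, -1): "v-"}
    fits: dict[str, EdgeFit] = {}
    for (axis, sign), name in names.items():
        t_ok, s_ok = crossings_for(axis, sign)
        if t_ok.size < 0.75 * profiles_per_edge:
            raise FieldFitError(
                f"edge {name}: 50% crossing found in only {t_ok.size}/"
                f"{profiles_per_edge} profiles"
            )
        # robust straight-line fit s(t) with MAD rejection
        use = np.ones(t_ok.size, dtype=bool)
        for _ in range(2):
            coef = np.polyfit(t_ok[use], s_ok[use], 1)
            resid = s_ok - np.polyval(coef, t_ok)
            mad = np.median(np.abs(resid[use] - np.median(resid[use])))
            if mad <= 0:
                break
            use = np.abs(resid) <= mad_k * mad / 0.6745
            if use.sum() < 3:
                use = np.ones(t_ok.size, dtype=bool)
                break
        coef = np.polyfit(t_ok[use], s_ok[use], 1)
        resid = (s_ok - np.polyval(coef, t_ok))[use]
        fits[name] = EdgeFit(
            name=name,
            offset_mm=float(coef[1]),
            slope=float(coef[0]),
            rms_mm=float(np.sqrt(np.mean(resid**2))),
            n_profiles=int(t_ok.size),
            n_used=int(use.sum()),
        )

    # orthogonality warning between the two edge-pair directions
    ang_u = math.degrees(math.atan((fits["u+"].slope + fits["u-"].slope) / 2.0))
    ang_v = math.degrees(math.atan((fits["v+"].slope + fits["v-"].slope) / 2.0))
    if abs(ang_u + ang_v) > 2.0:  # slopes of orthogonal pairs should be opposite
        warnings.warn(
            f"fitted edge pairs deviate from orthogonality by "
            f"{abs(ang_u + ang_v):.2f} deg",
            stacklevel=2,
        )

    # -- center: intersection of the opposing-pair bisectors -------------
    # bisector of u-pair: p = P0 + P1*q ; bisector of v-pair: q = Q0 + Q1*p
    P0 = 0.5 * (fits["u+"].offset_mm + fits["u-"].offset_mm)
    P1 = 0.5 * (fits["u+"].slope + fits["u-"].slope)
    Q0 = 0.5 * (fits["v+"].offset_mm + fits["v-"].offset_mm)
    Q1 = 0.5 * (fits["v+"].slope + fits["v-"].slope)
    A = np.array([[1.0, -P1], [-Q1, 1.0]])
    pq = np.linalg.solve(A, np.array([P0, Q0]))
    uv_c = R @ pq
    center = PlaneCoord(rough_center.u + float(uv_c[0]), rough_center.v + float(uv_c[1]))

    # re-express edge offsets relative to the refined center so that
    # (u+) - (u-) spans the fitted field size
    for f in fits.values():
        axis = 0 if f.name.startswith("u") else 1
        f.offset_mm -= float(pq[axis])
    return center, fits


def analyze_image(image: EpidImage, bb_mode: str = "deficit") -> ImageAnalysisResult:
    """Full per-image analysis: field center, BB center, (BB - BCR) offset.

    Raises :class:`ContaminationError` when the BB sits within 2 pixels of
    a 50% field edge (its deficit would bias both detectors there).
    """
    field_center, edges = detect_field(image)
    bb_center = detect_bb(image, polarity=bb_mode)

    geom = image.meta.geometry
    k = geom.pixel_pitch_iso_mm
    bb_r_mm = BB_DIAMETER_MM / 2.0
    margin = bb_r_mm + 2.0 * k
    # BB position in the collimator frame relative to the field center
    rel = np.array([bb_center.u - field_center.u, bb_center.v - field_center.v])
    pq = _rotation(-image.meta.collimator_deg) @ rel
    for f in edges.values():
        axis = 0 if f.name.startswith("u") else 1
        s_bb, t_bb = pq[axis], pq[1 - axis]
        dist = abs(s_bb - (f.offset_mm + f.slope * t_bb)) / math.hypot(1.0, f.slope)
        if dist < margin:
            raise ContaminationError(
                f"BB center {dist:.2f} mm from edge {f.name}; "
                f"needs >= {margin:.2f} mm for uncontaminated localization"
            )

    offset = PlaneCoord(bb_center.u - field_center.u, bb_center.v - field_center.v)
    qc = {
        "bb_found": True,
        "edge_fit_rms_px": max(f.rms_mm for f in edges.values()) / k,
        "meta": image.meta,
    }
    return ImageAnalysisResult(
        bb_center=bb_center,
        field_center=field_center,
        bb_minus_bcr=offset,
        edges=edges,
        qc=qc,
    )
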