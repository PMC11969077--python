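"""Synthetic Winston-Lutz image generation with known ground truth.

The simulator renders megavoltage portal images of a tungsten BB seen
through a square MLC field: an open-field plateau bounded by error-function
penumbras at the four field edges (rotated by the collimator angle),
multiplied by the transmission of the perspective-projected sphere, plus
Gaussian noise and 16-bit quantization.

Field-center misalignment follows three mechanisms discussed for C-arm
linacs:

* a constant collimator-axis offset ``c`` that rotates with the collimator
  (cancels exactly between opposed collimator angles),
* gravitational sag of the MLC leaf bank, modelled as an in-plane shift of
  amplitude ``a_g * (g_hat . leaf_axis)`` along the leaf-travel direction —
  maximal at lateral gantry angles with collimator 0 and zero with
  collimator 90/270, and *not* cancelled by opposing collimators,
* isotropic per-image Gaussian wobble (the linac's random field-placement
  jitter, i.e. the "isocenter size").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import (
    MachineGeometry,
    PlaneCoord,
    beam_direction,
    imager_axes,
    project_to_isoplane,
)
from .image_analysis import EpidImage, ImageMeta

__all__ = ["SimConfig", "GroundTruth", "field_center_model", "render_image",
           "generate_wl_dataset", "simulate_offset_table"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated WL acquisition.

    Parameters
    ----------
    bb_position : tuple of float
        BB center in room coordinates (mm); laser setup places it within
        about +/-2 mm of the isocenter.
    bb_diameter_mm : float
        Tungsten sphere diameter, 6.5 mm for the phantom emulated here.
    collimator_offset_mm : tuple of float
        Field-center offset ``c`` expressed in the collimator frame.
    sag_amplitude_mm : float
        Amplitude ``a_g`` of the gravitational MLC sag term.
    wobble_sigma_mm : float
        Per-image isotropic field-placement jitter (1-sigma per axis).
        Default 0.1 mm, consistent with sub-0.05 mm isocenter scatter at
        N_BCR = 8-56 on a well-tuned machine.
    penumbra_sigma_px : float
        Gaussian penumbra width of the MLC edges in imager pixels.
    noise_sigma_rel : float
        Additive Gaussian noise sigma relative to the open-field plateau.
    field_size_cm : float
        MLC square field side length at the isocenter plane.
    image_shape_px : tuple or None
        Rendered image shape; None picks the smallest even size covering
        the field plus a 12 mm iso-plane margin.
    mu_per_mm : float
        Effective attenuation coefficient of the BB; the default gives a
        ~60% central transmission deficit (contrast only matters for
        detector SNR, not geometry).
    jaw_size_cm : float
        Secondary-jaw aperture; rendered (with a wider penumbra) only when
        it fits inside the image, otherwise omitted.
    """

    bb_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bb_diameter_mm: float = 6.5
    collimator_offset_mm: tuple[float, float] = (0.0, 0.0)
    sag_amplitude_mm: float = 0.0
    wobble_sigma_mm: float = 0.1
    penumbra_sigma_px: float = 3.0
    noise_sigma_rel: float = 0.01
    field_size_cm: float = 10.0
    image_shape_px: tuple[int, int] | None = None
    seed: int = 0
    geometry: MachineGeometry = field(default_factory=MachineGeometry)
    mu_per_mm: float = 0.141
    jaw_size_cm: float = 15.0
    plateau_counts: float = 40000.0
    noise_model: str = "gaussian"  # or "poisson"

    def __post_init__(self) -> None:
        if self.bb_diameter_mm <= 0:
            raise ValueError("bb_diameter_mm must be positive")
        for name in ("sag_amplitude_mm", "wobble_sigma_mm", "penumbra_sigma_px",
                     "noise_sigma_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.field_size_cm <= 0:
            raise ValueError("field_size_cm must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """True per-image field-center and BB-projection positions (iso-plane mm)."""

    image_id: str
    gantry_deg: float
    collimator_deg: float
    field_center: PlaneCoord
    bb_projection: PlaneCoord
    config: SimConfig


def _rot2(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def image_rng(config: SimConfig, gantry_deg: float, collimator_deg: float) -> np.random.Generator:
    """Deterministic per-image random stream derived from the config seed."""
    return np.random.default_rng(
        [int(config.seed), int(round(gantry_deg * 100)) % (1 << 20),
         int(round(collimator_deg * 100)) % (1 << 20)]
    )


def field_center_model(
    gantry_deg: float,
    collimator_deg: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PlaneCoord:
    """True field-center position in iso-plane (u, v) mm for one image.

    fc = R(C) c  +  a_g (g_hat . leaf_axis(G, C)) leaf_axis_img(C)  +  wobble

    where R(C) rotates the collimator-frame offset into the image plane,
    ``leaf_axis`` is the MLC leaf-travel direction (the collimator-frame u
    axis) expressed in room coordinates, and ``g_hat = +y`` is gravity.
    The gravity projection ``g_hat . leaf_axis`` equals ``sin G * cos C``:
    largest at gantry 90/270 with collimator 0, zero with collimator
    90/270, and identical for collimators C and C+180 (sag does not cancel
    between opposed collimator angles, unlike the ``c`` term).
    """
    fc = _rot2(collimator_deg) @ np.asarray(config.collimator_offset_mm, dtype=float)
    if config.sag_amplitude_mm:
        u_hat, v_hat = imager_axes(gantry_deg)
        leaf_img = np.array([math.cos(math.radians(collimator_deg)),
                             math.sin(math.radians(collimator_deg))])
        leaf_room = leaf_img[0] * u_hat + leaf_img[1] * v_hat
        g_dot = leaf_room[1]  # gravity is +y
        fc = fc + config.sag_amplitude_mm * g_dot * leaf_img
    if config.wobble_sigma_mm:
        if rng is None:
            rng = image_rng(config, gantry_deg, collimator_deg)
        fc = fc + rng.normal(0.0, config.wobble_sigma_mm, size=2)
    return PlaneCoord(float(fc[0]), float(fc[1]))


def _auto_shape(config: SimConfig, margin_mm: float = 12.0) -> tuple[int, int]:
    geom = config.geometry
    extent_mm = (config.field_size_cm * 10.0 + 2 * margin_mm) * geom.magnification
    n = int(math.ceil(extent_mm / geom.pixel_pitch_imager_mm))
    n += n % 2  # even
    return (n, n)


def _aperture(pp: np.ndarray, qq: np.ndarray, half_mm: float, sigma_mm: float) -> np.ndarray:
    """Separable erf aperture: 1 inside |p|,|q| < half, 50% at the edges."""
    s = math.sqrt(2.0) * sigma_mm
    fp = 0.5 * (erf((pp + half_mm) / s) - erf((pp - half_mm) / s))
    fq = 0.5 * (erf((qq + half_mm) / s) - erf((qq - half_mm) / s))
    return fp * fq


def render_image(
    gantry_deg: float,
    collimator_deg: float,
    config: SimConfig,
    image_id: str = "",
) -> tuple[EpidImage, GroundTruth]:
    """Render one synthetic EPID image and its ground truth.

    The same (seed, gantry, collimator) triple always produces a bitwise
    identical image.
    """
    geom = config.geometry
    shape = config.image_shape_px or _auto_shape(config)
    rng = image_rng(config, gantry_deg, collimator_deg)
    fc = field_center_model(gantry_deg, collimator_deg, config, rng=rng)

    # iso-plane mm coordinates of every pixel
    k = geom.pixel_pitch_iso_mm
    rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * k
    cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * k
    vv, uu = np.meshgrid(rows, cols, indexing="ij")

    # MLC aperture in the collimator frame, centered on the field center
    Rinv = _rot2(-collimator_deg)
    du, dv = uu - fc.u, vv - fc.v
    pp = Rinv[0, 0] * du + Rinv[0, 1] * dv
    qq = Rinv[1, 0] * du + Rinv[1, 1] * dv
    sigma_mm = config.penumbra_sigma_px * k
    half = config.field_size_cm * 10.0 / 2.0
    intensity = _aperture(pp, qq, half, sigma_mm)

    # secondary jaws, only when they fit inside the rendered image
    jaw_half = config.jaw_size_cm * 10.0 / 2.0
    img_half = min(shape) / 2.0 * k
    if jaw_half + 4 * sigma_mm < img_half:
        jp = Rinv[0, 0] * uu + Rinv[0, 1] * vv
        jq = Rinv[1, 0] * uu + Rinv[1, 1] * vv
        intensity = intensity * _aperture(jp, jq, jaw_half, 2.0 * sigma_mm)

    # BB transmission at its perspective projection
    bb = np.asarray(config.bb_position, dtype=float)
    proj = project_to_isoplane(bb, gantry_deg, geom)
    zeta = float(bb @ beam_direction(gantry_deg))
    scale = (geom.sad_mm + zeta) / geom.sad_mm  # iso-plane mm -> physical mm at BB depth
    r_phys = np.hypot(uu - proj.u, vv - proj.v) * scale
    R_bb = config.bb_diameter_mm / 2.0
    chord = 2.0 * np.sqrt(np.clip(R_bb**2 - r_phys**2, 0.0, None))
    intensity = intensity * np.exp(-config.mu_per_mm * chord)

    signal = config.plateau_counts * intensity
    if config.noise_model == "poisson" and config.noise_sigma_rel > 0:
        # map the relative plateau sigma onto an equivalent photon count
        n_eq = 1.0 / config.noise_sigma_rel**2
        signal = rng.poisson(np.clip(signal, 0, None) / config.plateau_counts * n_eq)
        signal = signal.astype(float) * config.plateau_counts / n_eq
    elif config.noise_sigma_rel > 0:
        signal = signal + rng.normal(
            0.0, config.noise_sigma_rel * config.plateau_counts, size=shape
        )
    pixels = np.clip(np.rint(signal), 0, 65535).astype(np.uint16)

    meta = ImageMeta(
        gantry_deg=float(gantry_deg),
        collimator_deg=float(collimator_deg),
        couch_deg=0.0,
        geometry=geom,
        field_size_cm=config.field_size_cm,
        image_id=image_id or f"G{gantry_deg:g}_C{collimator_deg:g}",
    )
    truth = GroundTruth(
        image_id=meta.image_id,
        gantry_deg=float(gantry_deg),
        collimator_deg=float(collimator_deg),
        field_center=fc,
        bb_projection=proj,
        config=config,
    )
    return EpidImage(pixels=pixels, meta=meta), truth


def generate_wl_dataset(
    plan: Iterable[tuple[float, float, float]] | "AcquisitionPlan",
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[EpidImage], pd.DataFrame]:
    """Render one image per acquisition-plan item.

    Each image draws its wobble independently from a stream derived from
    the config seed and its (gantry, collimator) pair.  When ``out_dir``
    is given, 16-bit TIFFs with JSON sidecars and a ground-truth CSV are
    written there.

    Returns the images and a ground-truth table with columns
    ``image_id, gantry_deg, collimator_deg, fc_u_mm, fc_v_mm, bb_u_mm,
    bb_v_mm``.
    """
    items = list(getattr(plan, "items", plan))
    if not items:
        raise ValueError("acquisition plan is empty")
    images: list[EpidImage] = []
    records = []
    for i, item in enumerate(items):
        gantry, coll = item[0], item[1]
        img, truth = render_image(gantry, coll, config, image_id=f"wl_{i:03d}")
        images.append(img)
        records.append(
            {
                "image_id": truth.image_id,
                "gantry_deg": truth.gantry_deg,
                "collimator_deg": truth.collimator_deg,
                "fc_u_mm": truth.field_center.u,
                "fc_v_mm": truth.field_center.v,
                "bb_u_mm": truth.bb_projection.u,
                "bb_v_mm": truth.bb_projection.v,
            }
        )
    truth_df = pd.DataFrame.from_records(records)
    if out_dir is not None:
        from .io import write_image  # local import to avoid a cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            write_image(img, out / f"{img.meta.image_id}.tif")
        truth_df.to_csv(out / "ground_truth.csv", index=False)
    return images, truth_df


def simulate_offset_table(
    plan: Iterable[tuple[float, float, float]] | "AcquisitionPlan",
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Measurement-level simulation: per-image (BB - BCR) offsets, no pixels.

    The BB projection is the exact perspective projection of the BB
    position and the field center follows :func:`field_center_model`
    (with per-image wobble); the returned table has columns
    ``gantry_deg, collimator_deg, du_mm, dv_mm`` and plugs directly into
    the offset-table isocenter solver.  Detector noise is not modelled —
    this mode isolates the geometry and the field-placement statistics
    from pixel-level localization error.
    """
    items = list(getattr(plan, "items", plan))
    if not items:
        raise ValueError("acquisition plan is empty")
    rows = []
    for item in items:
        gantry, coll = item[0], item[1]
        item_rng = rng if rng is not None else image_rng(config, gantry, coll)
        fc = field_center_model(gantry, coll, config, rng=item_rng)
        bb = project_to_isoplane(np.asarray(config.bb_position, float), gantry,
                                 config.geometry)
        rows.append(
            {
                "gantry_deg": float(gantry),
                "collimator_deg": float(coll),
                "du_mm": bb.u - fc.u,
                "dv_mm": bb.v - fc.v,
            }
        )
    return pd.DataFrame(rows)
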