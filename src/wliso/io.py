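"""Image and configuration IO.

Canonical on-disk format: 16-bit grayscale TIFF plus a JSON sidecar
(`<name>.json`) carrying the acquisition metadata::

    {"gantry_deg": 90.0, "collimator_deg": 45.0, "couch_deg": 0.0,
     "sad_mm": 1000.0, "sid_mm": 1500.0, "pixel_pitch_imager_mm": 0.336,
     "field_size_cm": 10.0, "image_id": "wl_003"}

DICOM RT images are readable too (tag mapping below); angles are stored
in degrees on the Varian IEC 601-2-1 scale throughout.

DICOM tag mapping
-----------------
==========================  =========================
sidecar field               DICOM attribute
==========================  =========================
gantry_deg                  GantryAngle (300A,011E)
collimator_deg              BeamLimitingDeviceAngle (300A,0120)
couch_deg                   PatientSupportAngle (300A,0122)
sad_mm                      RadiationMachineSAD (3002,0022)
sid_mm                      RTImageSID (3002,0026)
pixel_pitch_imager_mm       ImagePlanePixelSpacing (3002,0011)
==========================  =========================
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .geometry import MachineGeometry
from .image_analysis import EpidImage, ImageMeta

__all__ = ["MetadataError", "read_image", "write_image", "RunConfig"]

REQUIRED_SIDECAR_FIELDS = (
    "gantry_deg",
    "collimator_deg",
    "sad_mm",
    "sid_mm",
    "pixel_pitch_imager_mm",
)


class MetadataError(ValueError):
    """Required acquisition metadata is missing or malformed."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(image: EpidImage, path: str | Path) -> Path:
    """Write a 16-bit TIFF and its JSON metadata sidecar."""
    path = Path(path)
    pixels = np.asarray(image.pixels)
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels)
    m = image.meta
    sidecar = {
        "gantry_deg": m.gantry_deg,
        "collimator_deg": m.collimator_deg,
        "couch_deg": m.couch_deg,
        "sad_mm": m.geometry.sad_mm,
        "sid_mm": m.geometry.sid_mm,
        "pixel_pitch_imager_mm": m.geometry.pixel_pitch_imager_mm,
        "field_size_cm": m.field_size_cm,
        "image_id": m.image_id,
        "row_to_v_sign": m.row_to_v_sign,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_tiff(path: Path) -> EpidImage:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"no metadata sidecar {sidecar.name} next to {path.name}")
    raw = json.loads(sidecar.read_text())
    missing = [f for f in REQUIRED_SIDECAR_FIELDS if f not in raw]
    if missing:
        raise MetadataError(f"sidecar {sidecar.name} missing fields: {missing}")
    geom = MachineGeometry(
        sad_mm=float(raw["sad_mm"]),
        sid_mm=float(raw["sid_mm"]),
        pixel_pitch_imager_mm=float(raw["pixel_pitch_imager_mm"]),
    )
    meta = ImageMeta(
        gantry_deg=float(raw["gantry_deg"]),
        collimator_deg=float(raw["collimator_deg"]),
        couch_deg=float(raw.get("couch_deg", 0.0)),
        geometry=geom,
        field_size_cm=(
            float(raw["field_size_cm"]) if raw.get("field_size_cm") is not None else None
        ),
        image_id=str(raw.get("image_id", path.stem)),
        row_to_v_sign=int(raw.get("row_to_v_sign", 1)),
    )
    return EpidImage(pixels=tifffile.imread(path), meta=meta)


def _read_dicom(path: Path) -> EpidImage:
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    required = {
        "gantry_deg": "GantryAngle",
        "collimator_deg": "BeamLimitingDeviceAngle",
        "sad_mm": "RadiationMachineSAD",
        "sid_mm": "RTImageSID",
    }
    missing = [f for f, attr in required.items() if getattr(ds, attr, None) is None]
    if missing:
        raise MetadataError(f"DICOM {path.name} missing fields: {missing}")
    spacing = getattr(ds, "ImagePlanePixelSpacing", None)
    if spacing is None:
        raise MetadataError(f"DICOM {path.name} missing fields: ['pixel_pitch_imager_mm']")
    geom = MachineGeometry(
        sad_mm=float(ds.RadiationMachineSAD),
        sid_mm=float(ds.RTImageSID),
        pixel_pitch_imager_mm=float(spacing[0]),
    )
    meta = ImageMeta(
        gantry_deg=float(ds.GantryAngle),
        collimator_deg=float(ds.BeamLimitingDeviceAngle),
        couch_deg=float(getattr(ds, "PatientSupportAngle", 0.0)),
        geometry=geom,
        field_size_cm=None,
        image_id=str(getattr(ds, "SOPInstanceUID", path.stem)),
    )
    return EpidImage(pixels=ds.pixel_array.astype(np.uint16), meta=meta)


def read_image(path: str | Path) -> EpidImage:
    """Read a TIFF+sidecar or DICOM RT image into an :class:`EpidImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    return _read_tiff(path)


# --------------------------------------------------------------------------
# Run configuration

_GEOMETRY_KEYS = {"sad_mm", "sid_mm", "pixel_pitch_imager_mm"}
_SIM_KEYS = {
    "bb_position", "bb_diameter_mm", "collimator_offset_mm", "sag_amplitude_mm",
    "wobble_sigma_mm", "penumbra_sigma_px", "noise_sigma_rel", "field_size_cm",
    "image_shape_px", "seed", "mu_per_mm", "jaw_size_cm", "plateau_counts",
    "noise_model",
}
_ANALYSIS_KEYS = {"profiles_per_edge", "mad_k", "accumulator_threshold", "bb_polarity"}
_EXPERIMENT_KEYS = {
    "plan", "seed", "n_repeats", "n_random_positions", "shift_range_mm",
    "sizes_cm", "mode",
}


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of a reproducible run.

    Four blocks (geometry, simulator, analysis, experiment) plus the
    output directory; unknown keys in any block are rejected so that a
    typo cannot silently fall back to a default.
    """

    geometry: dict[str, Any] = dataclasses.field(default_factory=dict)
    simulator: dict[str, Any] = dataclasses.field(default_factory=dict)
    analysis: dict[str, Any] = dataclasses.field(default_factory=dict)
    experiment: dict[str, Any] = dataclasses.field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name, block, allowed in (
            ("geometry", self.geometry, _GEOMETRY_KEYS),
            ("simulator", self.simulator, _SIM_KEYS),
            ("analysis", self.analysis, _ANALYSIS_KEYS),
            ("experiment", self.experiment, _EXPERIMENT_KEYS),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        allowed_top = {"geometry", "simulator", "analysis", "experiment", "output_dir"}
        unknown = set(raw) - allowed_top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def machine_geometry(self) -> MachineGeometry:
        return MachineGeometry(**self.geometry)

    def sim_config(self, **overrides: Any):
        from .simulator import SimConfig

        kw = dict(self.simulator)
        for seq_key in ("bb_position", "collimator_offset_mm", "image_shape_px"):
            if isinstance(kw.get(seq_key), list):
                kw[seq_key] = tuple(kw[seq_key])
        kw.update(overrides)
        return SimConfig(geometry=self.machine_geometry(), **kw)
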