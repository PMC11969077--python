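"""Parameter studies: BB-shift recovery and field-size dependence.

Both studies run the short WL test (4 cardinal gantry angles x opposed
collimators 225/45) repeatedly under controlled perturbations of the
simulated machine:

* the shift study moves the BB (via the couch) by known random amounts
  within +/-2.5 mm per axis and checks that the WL-derived BB shifts
  Delta(BB-Iso) track the known shifts Delta(T) with unit slope — the BB
  acts as a static reference point, so its position must not matter;
* the field-size study repeats the test at MLC field sizes 2-20 cm and
  tests with a one-way ANOVA per axis whether field size shifts the
  solved isocenter.

Each study supports two modes.  ``mode="image"`` renders every portal
image and runs the full Hough/edge analysis; ``mode="analytic"`` works at
measurement level (exact projections plus field-placement wobble),
isolating the geometry and statistics from pixel-level localization
error — this is the mode for large replicate counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    MachineGeometry,
    bcr_from_field_center,
    project_to_isoplane,
    solve_bb_position,
    solve_isocenter,
)
from .image_analysis import BB_DIAMETER_MM
from .simulator import SimConfig, field_center_model, generate_wl_dataset
from .wl_pipeline import analyze_wl_test, short_plan

__all__ = [
    "AxisFit",
    "ShiftStudyResult",
    "FieldSizeStudyResult",
    "linear_fit",
    "one_way_anova",
    "shift_study",
    "fieldsize_study",
]

AXES = ("x", "y", "z")


class AxisFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def linear_fit(x: Sequence[float], y: Sequence[float]) -> AxisFit:
    """Ordinary least-squares line fit with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; slope undefined")
    res = stats.linregress(x, y)
    return AxisFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Between/within mean-square F test with (k-1, N-k) df.

    Raises on degenerate input (fewer than 2 groups, a group with fewer
    than 2 values, or zero variance everywhere, where F is undefined).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; F statistic undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not math.isfinite(f):
        raise ValueError("degenerate groups (zero within-group variance)")
    return float(f), float(p)


@dataclass
class ShiftStudyResult:
    """Known couch shifts vs WL-derived BB shifts plus the per-axis fits."""

    table: pd.DataFrame          # position, dT_{x,y,z}_mm, dBB_{x,y,z}_mm
    fits: dict[str, AxisFit]
    mode: str
    seed: int

    def fit_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": ax, "slope_k": f.slope, "intercept_a_mm": f.intercept,
             "r_squared": f.r_squared}
            for ax, f in self.fits.items()
        ]
        return pd.DataFrame(rows)

    def max_abs_error_mm(self) -> float:
        """Largest |Delta(BB-Iso) - Delta(T)| over positions and axes."""
        d = np.abs(
            self.table[[f"dBB_{a}_mm" for a in AXES]].to_numpy()
            - self.table[[f"dT_{a}_mm" for a in AXES]].to_numpy()
        )
        return float(d.max())


@dataclass
class FieldSizeStudyResult:
    """Per-size repeated isocenters and the per-axis one-way ANOVA."""

    sizes_cm: tuple[float, ...]
    isocenters: pd.DataFrame     # field_size_cm, repeat, x/y/z_mm
    anova: dict[str, tuple[float, float]]   # axis -> (F, p)
    mode: str
    seed: int

    def mean_by_size(self) -> pd.DataFrame:
        return (
            self.isocenters.groupby("field_size_cm")[["x_mm", "y_mm", "z_mm"]]
            .mean()
            .reset_index()
        )


def _derived_seed(seed: int, *keys: int) -> int:
    """Deterministic 31-bit child seed from a base seed and integer keys."""
    return int(np.random.default_rng([int(seed), *map(int, keys)]).integers(2**31))


def _analytic_short_wl(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Measurement-level short WL test: returns the 3D (BB - Iso) vector.

    BCRs are parallel rays through the (wobbled) field centers; the BB is
    back-projected in perspective mode so that noiseless mechanics are
    exact.
    """
    geom = config.geometry
    bb = np.asarray(config.bb_position, dtype=float)
    rays, projections = [], []
    for g, c, _ in short_plan():
        fc = field_center_model(g, c, config, rng=rng)
        rays.append(bcr_from_field_center(fc, g, geom))
        projections.append((project_to_isoplane(bb, g, geom), g))
    iso = solve_isocenter(rays)
    bb_sol = solve_bb_position(projections, geom, mode="perspective")
    return bb_sol.position - iso.position


def _image_short_wl(config: SimConfig) -> np.ndarray:
    images, _ = generate_wl_dataset(short_plan(), config)
    return analyze_wl_test(images).bb_minus_iso


def shift_study(
    config: SimConfig,
    n_random_positions: int = 11,
    shift_range_mm: float = 2.5,
    seed: int = 0,
    mode: str = "analytic",
    couch_error_sigma_mm: float = 0.0,
) -> ShiftStudyResult:
    """Move the BB by known random couch shifts and recover them by WL.

    Protocol: a short WL test at the initial position T0, one at each of
    ``n_random_positions`` positions obtained by adding fresh uniform
    draws in +/-``shift_range_mm`` per axis to T0, and a final test back
    at T0.  Shifts Delta(T)_i and WL-derived shifts Delta(BB-Iso)_i are
    taken relative to position 0 and fit per axis with
    Delta(BB-Iso) = a + k Delta(T).

    ``couch_error_sigma_mm`` adds Gaussian error to the executed couch
    motion (default 0: exact translation, so couch precision is not
    conflated with what the study tests).
    """
    if mode not in ("analytic", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    base = np.asarray(config.bb_position, dtype=float)

    shifts = [np.zeros(3)]
    shifts += [
        rng.uniform(-shift_range_mm, shift_range_mm, size=3)
        for _ in range(n_random_positions)
    ]
    shifts.append(np.zeros(3))  # return to start

    rows = []
    bbiso = []
    for i, dT in enumerate(shifts):
        executed = dT if couch_error_sigma_mm == 0 else dT + rng.normal(
            0.0, couch_error_sigma_mm, size=3
        )
        cfg_i = replace(
            config,
            bb_position=tuple(base + executed),
            seed=_derived_seed(seed, 101, i),
        )
        try:
            if mode == "analytic":
                vec = _analytic_short_wl(cfg_i, rng)
            else:
                vec = _image_short_wl(cfg_i)
        except Exception as exc:
            raise RuntimeError(f"WL test failed at position {i}: {exc}") from exc
        bbiso.append(vec)
        rows.append({"position": i, **{f"dT_{a}_mm": dT[j] for j, a in enumerate(AXES)}})

    bbiso = np.array(bbiso)
    dbb = bbiso - bbiso[0]
    for i, row in enumerate(rows):
        for j, a in enumerate(AXES):
            row[f"dBB_{a}_mm"] = dbb[i, j]
    table = pd.DataFrame(rows)

    fits = {
        a: linear_fit(table[f"dT_{a}_mm"], table[f"dBB_{a}_mm"]) for a in AXES
    }
    return ShiftStudyResult(table=table, fits=fits, mode=mode, seed=seed)


def fieldsize_study(
    config: SimConfig,
    sizes_cm: Sequence[float] = (2, 3, 5, 6, 10, 15, 20),
    n_repeats: int = 5,
    seed: int = 0,
    mode: str = "analytic",
) -> FieldSizeStudyResult:
    """Repeat short WL tests across MLC field sizes and ANOVA the isocenters.

    The secondary jaws are opened to 25 x 25 cm so the MLC defines every
    field.  Raises if the BB projection would encroach on the edge of the
    smallest field (BB radius + 2 pixels of clearance required).
    """
    if mode not in ("analytic", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    sizes = tuple(float(s) for s in sizes_cm)
    if len(sizes) < 2:
        raise ValueError("need at least 2 field sizes")

    geom = config.geometry
    half_min = min(sizes) * 10.0 / 2.0
    bb = np.asarray(config.bb_position, dtype=float)
    clearance = BB_DIAMETER_MM / 2.0 + 2.0 * geom.pixel_pitch_iso_mm
    max_proj = float(np.max(np.abs(bb))) + 3.0 * config.wobble_sigma_mm
    if max_proj + clearance > half_min:
        raise ValueError(
            f"BB within {half_min - max_proj:.2f} mm of the "
            f"{min(sizes):g} cm field edge; needs {clearance:.2f} mm"
        )

    rng = np.random.default_rng(seed)
    rows = []
    for s_idx, size in enumerate(sizes):
        for rep in range(n_repeats):
            cfg = replace(
                config,
                field_size_cm=size,
                jaw_size_cm=25.0,
                seed=_derived_seed(seed, s_idx, rep),
            )
            vec = (
                _analytic_short_wl(cfg, rng)
                if mode == "analytic"
                else _image_short_wl(cfg)
            )
            rows.append(
                {
                    "field_size_cm": size,
                    "repeat": rep,
                    "x_mm": vec[0],
                    "y_mm": vec[1],
                    "z_mm": vec[2],
                }
            )
    iso = pd.DataFrame(rows)
    anova = {
        a: one_way_anova(
            [iso.loc[iso.field_size_cm == s, f"{a}_mm"].to_numpy() for s in sizes]
        )
        for a in AXES
    }
    return FieldSizeStudyResult(
        sizes_cm=sizes, isocenters=iso, anova=anova, mode=mode, seed=seed
    )
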