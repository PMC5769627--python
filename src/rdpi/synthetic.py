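"""Synthetic single-cell tables and intensity fields with known ground truth.

Emulates the study's imaging-derived data so every downstream stage is
testable without microscopy: disk-shaped micropatterned colonies (single or
gridded), radial nuclear-intensity gradients with configurable noise,
periodic interior "spot" fields, and fate-labeled datasets generated by the
positional-information rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .rd import FieldSnapshot
from .fates import FateThresholds, assign_fate, exposure_at

__all__ = [
    "ColonySpec",
    "GradientSpec",
    "PeriodicFieldSpec",
    "generate_colony_layout",
    "apply_gradient",
    "generate_periodic_field",
    "generate_fate_dataset",
]

#: canonical cell-table columns preceding the intensity channels
CELL_TABLE_COLUMNS = ["well", "field", "cell_id", "x_um", "y_um"]


@dataclass(frozen=True)
class ColonySpec:
    """Layout of one or a grid of disk colonies on a micropatterned well."""

    diameter: float  # um
    n_cells: int  # cells per colony
    layout: Literal["single", "grid"] = "single"
    grid_shape: tuple[int, int] = (1, 1)
    grid_pitch: float = 0.0  # um, center-to-center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.layout == "grid" and self.grid_pitch <= self.diameter:
            raise ValueError("grid_pitch must exceed diameter (colonies would overlap)")


@dataclass(frozen=True)
class GradientSpec:
    """Radial mean-intensity profile plus a per-cell noise model."""

    profile: Callable[[np.ndarray], np.ndarray]  # radius fraction in [0,1] -> mean a.u.
    noise_sd: float = 0.0
    noise_model: Literal["additive_gaussian", "lognormal_multiplicative"] = "additive_gaussian"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PeriodicFieldSpec:
    """Disk field with a radially periodic intensity, ground truth for the
    periodicity pipeline."""

    grid_px: int = 256
    colony_radius_px: float = 110.0
    n_cycles: int = 4
    amplitude: float = 1.0
    baseline: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.colony_radius_px > self.grid_px / 2:
            raise ValueError("colony_radius_px must be <= grid_px/2")


def generate_colony_layout(spec: ColonySpec) -> pd.DataFrame:
    """Place cells uniformly (by area) inside each disk colony.

    Radius is drawn proportional to sqrt(u), matching the area-uniform
    density of a confluent monolayer.  The returned table carries the true
    colony id and true centroid of every cell; fixed seed gives a
    bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.diameter / 2.0
    if spec.layout == "single":
        centers = [(0.0, 0.0)]
    else:
        rows, cols = spec.grid_shape
        centers = [
            (j * spec.grid_pitch, i * spec.grid_pitch)
            for i in range(rows)
            for j in range(cols)
        ]
    frames = []
    for cid, (cx, cy) in enumerate(centers):
        u = rng.random(spec.n_cells)
        theta = rng.random(spec.n_cells) * 2.0 * np.pi
        r = R * np.sqrt(u)
        frames.append(
            pd.DataFrame(
                {
                    "well": "A1",
                    "field": 1,
                    "cell_id": np.arange(spec.n_cells) + cid * spec.n_cells,
                    "x_um": cx + r * np.cos(theta),
                    "y_um": cy + r * np.sin(theta),
                    "true_colony_id": cid,
                    "true_cx_um": cx,
                    "true_cy_um": cy,
                    "true_radius_um": R,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def apply_gradient(
    cells: pd.DataFrame,
    g: GradientSpec,
    seed: int = 0,
    channel: str = "ch1",
) -> pd.DataFrame:
    """Add one intensity channel whose mean at radius fraction r is g.profile(r).

    Additive Gaussian noise is truncated at zero so intensities stay
    non-negative; the lognormal model multiplies by a unit-median factor.
    """
    required = {"true_cx_um", "true_cy_um", "true_radius_um"}
    if not required <= set(cells.columns):
        raise ValueError("cells must carry colony centroids (generate_colony_layout)")
    rng = np.random.default_rng(seed)
    r_frac = np.hypot(
        cells["x_um"] - cells["true_cx_um"], cells["y_um"] - cells["true_cy_um"]
    ) / cells["true_radius_um"]
    if np.any(r_frac > 1.0 + 1e-9):
        raise ValueError("cells found outside their declared colony disk")
    mean = np.asarray(g.profile(np.clip(r_frac.to_numpy(), 0.0, 1.0)), dtype=float)
    if g.noise_sd == 0:
        vals = mean
    elif g.noise_model == "additive_gaussian":
        vals = np.clip(mean + rng.normal(0.0, g.noise_sd, mean.shape), 0.0, None)
    else:
        # unit-median multiplicative lognormal with sd parameterized on log scale
        vals = mean * rng.lognormal(0.0, g.noise_sd, mean.shape)
    out = cells.copy()
    out[channel] = vals
    return out


def generate_periodic_field(spec: PeriodicFieldSpec) -> FieldSnapshot:
    """Disk field ``baseline + amplitude*sin(2 pi n_cycles r / R)`` plus noise.

    Intensity is zero outside the disk; truncated-Gaussian noise (per seed)
    is added inside.  The snapshot stores the intensity in the activator slot.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_px
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(x - c, y - c)
    mask = r <= spec.colony_radius_px
    field = spec.baseline + spec.amplitude * np.sin(
        2.0 * np.pi * spec.n_cycles * r / spec.colony_radius_px
    )
    if spec.noise_sd > 0:
        field = field + rng.normal(0.0, spec.noise_sd, field.shape)
    field = np.clip(field, 0.0, None)
    a = np.where(mask, field, np.nan)
    return FieldSnapshot(a=a, i=np.where(mask, 0.0, np.nan), t=0.0, um_per_px=1.0, mask=mask)


def generate_fate_dataset(
    field_history: Sequence[FieldSnapshot],
    thresholds: FateThresholds,
    cells: pd.DataFrame,
    label_noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Label each cell with the fate the positional-information rule assigns.

    Samples every snapshot at each cell position (bilinear), applies
    :func:`rdpi.fates.assign_fate` to the resulting exposure trajectory and
    optionally flips a fraction ``label_noise`` of labels uniformly at
    random.  Returns ``(table, times, levels)`` where ``levels`` has shape
    (n_cells, n_times) so threshold fitting can be tested against the raw
    exposures.
    """
    if not field_history:
        raise ValueError("field_history must be non-empty")
    times = np.array([s.t for s in field_history])
    xy = cells[["x_um", "y_um"]].to_numpy()
    levels = np.stack([exposure_at(s, xy) for s in field_history], axis=1)
    if np.any(~np.isfinite(levels)):
        raise ValueError("cell position outside the field domain")
    labels = np.array(
        [assign_fate(times, lv, thresholds) for lv in levels], dtype=object
    )
    if label_noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(labels)) < label_noise
        choices = np.array(["ectoderm_like", "primitive_streak_like", "trophoblast_like"])
        labels[flip] = rng.choice(choices, flip.sum())
    out = cells.copy()
    out["fate"] = labels
    out["mean_exposure"] = levels.mean(axis=1)
    return out, times, levels
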