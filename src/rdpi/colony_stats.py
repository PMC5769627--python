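"""Single-cell colony spatial statistics.

Mirrors the image-analysis workflow used for micropatterned colonies:
DBSCAN colony identification from nuclear positions, centroid-relative
coordinates, radial trend lines with dispersion across colonies,
Savitzky-Golay smoothing, hexagonal-bin expression overlays pooled across
colonies, and percent-positive quantification per colony.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import t as t_dist
from skimage.filters import threshold_otsu
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .rd import RadialProfile

__all__ = [
    "identify_colonies",
    "default_eps",
    "radial_trend",
    "smooth_profile",
    "HexOverlay",
    "hex_overlay",
    "percent_positive",
    "read_cell_table",
]

log = logging.getLogger(__name__)


def read_cell_table(path, channels: list[str] | None = None) -> pd.DataFrame:
    """Read a delimited cell table, tolerating Cellomics-style extra columns.

    Requires columns well, field, cell_id, x_um, y_um; any unrecognized
    columns beyond the requested channels are kept but logged.
    """
    df = pd.read_csv(path)
    required = ["well", "field", "cell_id", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    extra = [c for c in df.columns if c not in required and (channels is None or c not in channels)]
    if extra:
        log.info("ignoring extra cell-table columns: %s", extra)
    return df


def default_eps(xy: np.ndarray) -> float:
    """Data-adaptive DBSCAN eps: 3x the median nearest-neighbor distance."""
    nn = NearestNeighbors(n_neighbors=2).fit(xy)
    d, _ = nn.kneighbors(xy)
    return 3.0 * float(np.median(d[:, 1]))


def identify_colonies(
    cells: pd.DataFrame,
    eps_um: float | None = None,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Label colonies by DBSCAN on (x, y); assign centroid-relative coordinates.

    Noise cells get colony_id = -1 and NaN relative coordinates; they are
    excluded from all downstream statistics.  Adds columns colony_id,
    cx_um, cy_um (colony centroid), rel_x_um, rel_y_um, r_um and r_frac
    (radius normalized by the colony's maximal cell radius).
    """
    xy = cells[["x_um", "y_um"]].to_numpy()
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite cell positions")
    if eps_um is None:
        eps_um = default_eps(xy)
    if eps_um <= 0:
        raise ValueError("eps must be > 0")
    labels = DBSCAN(eps=eps_um, min_samples=min_samples).fit_predict(xy)
    out = cells.copy()
    out["colony_id"] = labels
    out["cx_um"] = np.nan
    out["cy_um"] = np.nan
    for cid in np.unique(labels):
        if cid < 0:
            continue
        sel = labels == cid
        out.loc[sel, "cx_um"] = xy[sel, 0].mean()
        out.loc[sel, "cy_um"] = xy[sel, 1].mean()
    out["rel_x_um"] = out["x_um"] - out["cx_um"]
    out["rel_y_um"] = out["y_um"] - out["cy_um"]
    out["r_um"] = np.hypot(out["rel_x_um"], out["rel_y_um"])
    out["r_frac"] = np.nan
    for cid in np.unique(labels):
        if cid < 0:
            continue
        sel = out["colony_id"] == cid
        rmax = out.loc[sel, "r_um"].max()
        out.loc[sel, "r_frac"] = out.loc[sel, "r_um"] / max(rmax, 1e-12)
    return out


def radial_trend(
    cells: pd.DataFrame,
    channel: str,
    n_bins: int = 15,
    normalize: bool = True,
) -> RadialProfile:
    """Mean/SD/95% CI of a channel vs radius, dispersion across colonies.

    Cells are binned by r_frac (normalize=True) or r_um in half-open
    equal-width bins; the per-bin statistic is the mean over colony-level
    means, with the 95% CI a t-interval across colonies, matching
    replicate-colony error bars.
    """
    if channel not in cells.columns:
        raise ValueError(f"channel {channel!r} not in table")
    df = cells[cells["colony_id"] >= 0]
    if df.empty:
        raise ValueError("no non-noise cells")
    rcol = "r_frac" if normalize else "r_um"
    rmax = 1.0 if normalize else float(df[rcol].max())
    edges = np.linspace(0.0, rmax * (1 + 1e-9), n_bins + 1)
    which = np.clip(np.digitize(df[rcol], edges) - 1, 0, n_bins - 1)
    per_colony = (
        pd.DataFrame({"bin": which, "colony": df["colony_id"].to_numpy(),
                      "v": df[channel].to_numpy()})
        .groupby(["bin", "colony"])["v"].mean().reset_index()
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean, sd, ci, n, used = [], [], [], [], []
    for b, grp in per_colony.groupby("bin"):
        v = grp["v"].to_numpy()
        mean.append(v.mean())
        sd.append(v.std(ddof=1) if len(v) > 1 else 0.0)
        if len(v) > 1:
            ci.append(float(t_dist.ppf(0.975, len(v) - 1)) * v.std(ddof=1) / np.sqrt(len(v)))
        else:
            ci.append(0.0)
        n.append(len(v))
        used.append(int(b))
    used = np.asarray(used)
    return RadialProfile(
        r_um=centers[used] if not normalize else centers[used] * np.nan,
        r_frac=centers[used] if normalize else centers[used] * np.nan,
        mean=np.asarray(mean),
        sd=np.asarray(sd),
        ci95=np.asarray(ci),
        n=np.asarray(n),
    )


def smooth_profile(profile: RadialProfile, window: int = 7, polyorder: int = 3) -> RadialProfile:
    """Savitzky-Golay smoothing of the mean series; dispersion untouched."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > len(profile.mean):
        raise ValueError("window larger than the profile")
    sm = savgol_filter(profile.mean, window_length=window, polyorder=polyorder)
    return RadialProfile(
        r_um=profile.r_um,
        r_frac=profile.r_frac,
        mean=sm,
        sd=profile.sd,
        ci95=profile.ci95,
        n=profile.n,
    )


@dataclass
class HexOverlay:
    """Pooled multi-colony expression map on hexagonal spatial bins."""

    centers: np.ndarray  # (n_bins, 2) hex centers in centroid-relative um
    mean: np.ndarray
    n: np.ndarray
    bounds: tuple[float, float]  # color normalization (min mean, max mean)
    hex_size_um: float


def hex_bin_index(xy: np.ndarray, size: float) -> np.ndarray:
    """Axial (q, r) index of the nearest pointy-top hex center for each point.

    Uses the standard fractional axial transform followed by cube rounding,
    which is exactly nearest-center assignment.
    """
    x, y = xy[:, 0], xy[:, 1]
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return np.stack([q, r], axis=1).astype(np.int64)


def hex_center(qr: np.ndarray, size: float) -> np.ndarray:
    """Cartesian center of pointy-top hexes given axial indices."""
    q, r = qr[:, 0].astype(float), qr[:, 1].astype(float)
    x = size * np.sqrt(3.0) * (q + r / 2.0)
    y = size * 1.5 * r
    return np.stack([x, y], axis=1)


def hex_overlay(cells: pd.DataFrame, channel: str, hex_size_um: float = 25.0) -> HexOverlay:
    """Per-hex mean expression pooled across colonies in relative coordinates."""
    if channel not in cells.columns:
        raise ValueError(f"channel {channel!r} not in table")
    df = cells[cells["colony_id"] >= 0]
    if df.empty:
        raise ValueError("no assigned cells to overlay")
    xy = df[["rel_x_um", "rel_y_um"]].to_numpy()
    qr = hex_bin_index(xy, hex_size_um)
    key = pd.DataFrame({"q": qr[:, 0], "r": qr[:, 1], "v": df[channel].to_numpy()})
    agg = key.groupby(["q", "r"])["v"].agg(["mean", "size"]).reset_index()
    centers = hex_center(agg[["q", "r"]].to_numpy(), hex_size_um)
    means = agg["mean"].to_numpy()
    return HexOverlay(
        centers=centers,
        mean=means,
        n=agg["size"].to_numpy(),
        bounds=(float(means.min()), float(means.max())),
        hex_size_um=hex_size_um,
    )


def percent_positive(
    cells: pd.DataFrame, channel: str, gate: float | None = None
) -> pd.DataFrame:
    """Fraction of cells at/above the gate per colony.

    Default gate: Otsu threshold on the pooled log-intensity distribution
    (the positivity cutoff between the low- and high-expressing modes).
    Returns one row per colony with columns colony_id, n_cells, fraction,
    plus the gate used (same for all rows).
    """
    if channel not in cells.columns:
        raise ValueError(f"channel {channel!r} not in table")
    df = cells[cells["colony_id"] >= 0]
    if gate is None:
        v = df[channel].to_numpy()
        v = v[v > 0]
        gate = float(np.exp(threshold_otsu(np.log(v))))
    if gate < 0:
        raise ValueError("gate must be >= 0")
    rows = []
    for cid, grp in df.groupby("colony_id"):
        frac = float(np.mean(grp[channel] >= gate))
        rows.append({"colony_id": cid, "n_cells": len(grp), "fraction": frac, "gate": gate})
    return pd.DataFrame(rows)
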