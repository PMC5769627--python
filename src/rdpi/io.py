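"""Serialization: cell tables as CSV, field snapshots and runs as NPZ."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rd import (
    BoundaryCondition,
    Domain,
    FieldSnapshot,
    InitialCondition,
    RadialProfile,
    RDParams,
    SimulationResult,
)

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "save_snapshot",
    "load_snapshot",
    "save_result",
    "load_result",
    "profile_frame",
    "write_profile",
]


def write_cell_table(cells: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    from .colony_stats import read_cell_table as _read

    return _read(path)


def save_snapshot(snapshot: FieldSnapshot, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        a=snapshot.a,
        i=snapshot.i,
        mask=snapshot.mask,
        t=snapshot.t,
        um_per_px=snapshot.um_per_px,
    )
    return path


def load_snapshot(path) -> FieldSnapshot:
    z = np.load(path)
    return FieldSnapshot(
        a=z["a"], i=z["i"], t=float(z["t"]), um_per_px=float(z["um_per_px"]),
        mask=z["mask"],
    )


def save_result(result: SimulationResult, path) -> Path:
    """NPZ container with stacked snapshots and full provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": vars(result.params).copy(),
        "domain": {"colony_diameter": result.domain.colony_diameter,
                   "grid_spacing": result.domain.grid_spacing},
        "bc": {"bmpi": result.bc.bmpi, "inhibitor_bc": result.bc.inhibitor_bc,
               "activator_bc": result.bc.activator_bc},
        "ic": {"a0": result.ic.a0, "i0_peak": result.ic.i0_peak,
               "i0_length": result.ic.i0_length, "noise_rel": result.ic.noise_rel,
               "seed": result.ic.seed},
    }
    np.savez_compressed(
        path,
        a=np.stack([s.a for s in result.snapshots]),
        i=np.stack([s.i for s in result.snapshots]),
        t=result.times,
        mask=result.terminal.mask,
        um_per_px=result.terminal.um_per_px,
        meta=json.dumps(meta),
    )
    return path


def load_result(path) -> SimulationResult:
    z = np.load(path)
    meta = json.loads(str(z["meta"]))
    params = RDParams(**meta["params"])
    domain = Domain(**meta["domain"])
    bc = BoundaryCondition(**meta["bc"])
    ic = InitialCondition(**meta["ic"])
    mask = z["mask"]
    upp = float(z["um_per_px"])
    snaps = [
        FieldSnapshot(a=z["a"][k], i=z["i"][k], t=float(z["t"][k]),
                      um_per_px=upp, mask=mask)
        for k in range(len(z["t"]))
    ]
    return SimulationResult(snaps, params, domain, bc, ic)


def profile_frame(profile: RadialProfile) -> pd.DataFrame:
    df = pd.DataFrame({
        "radius_um": profile.r_um,
        "radius_frac": profile.r_frac,
        "mean_activator": profile.mean,
    })
    if profile.sd is not None:
        df["sd"] = profile.sd
    if profile.ci95 is not None:
        df["ci95"] = profile.ci95
    if profile.n is not None:
        df["n"] = profile.n
    return df


def write_profile(profile: RadialProfile, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile_frame(profile).to_csv(path, index=False, float_format="%.10g")
    return path
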