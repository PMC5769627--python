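import numpy as np
import pytest

from rdpi.rd import BoundaryCondition, Domain, FieldSnapshot, InitialCondition, RDParams, SimulationResult


@pytest.fixture
def classic_params() -> RDParams:
    """Unsaturated activator-inhibitor kinetics, diffusionless-stable."""
    return RDParams(D_a=1.0, D_i=50.0, rho_a=1.0, rho_i=1.0, mu_a=1.0, mu_i=2.0)


def disk_snapshot(fn, grid=101, radius_px=45.0, um_per_px=1.0, t=0.0):
    """FieldSnapshot from an analytic function fn(r_px, theta) on a disk."""
    c = (grid - 1) / 2.0
    y, x = np.mgrid[0:grid, 0:grid]
    r = np.hypot(x - c, y - c)
    theta = np.arctan2(y - c, x - c)
    mask = r <= radius_px
    vals = np.clip(fn(r, theta), 0.0, None)
    return FieldSnapshot(
        a=np.where(mask, vals, np.nan),
        i=np.where(mask, 0.0, np.nan),
        t=t,
        um_per_px=um_per_px,
        mask=mask,
    )


def analytic_result(level_fn, times, diameter=200.0, spacing=4.0):
    """SimulationResult whose activator follows level_fn(r_frac, t) exactly."""
    domain = Domain(diameter, spacing)
    mask = domain.mask()
    r_frac = domain.radii() / domain.radius
    snaps = []
    for t in times:
        a = np.where(mask, np.clip(level_fn(r_frac, t), 0.0, None), np.nan)
        snaps.append(FieldSnapshot(a=a, i=np.where(mask, 0.0, np.nan), t=float(t),
                                   um_per_px=spacing, mask=mask))
    return SimulationResult(
        snaps,
        RDParams(D_a=1.0, D_i=10.0),
        domain,
        BoundaryCondition(bmpi=50.0),
        InitialCondition(),
    )
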