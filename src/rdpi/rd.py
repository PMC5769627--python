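"""Activator-inhibitor reaction-diffusion solver on disk-shaped colony domains.

The model describes the self-organization of free BMP4 ligand (the activator,
read out as pSMAD1 activity) under negative feedback from a diffusible
inhibitor (NOG) in a geometrically confined, disk-shaped stem-cell colony.
Kinetics follow the saturating Gierer-Meinhardt form, which encodes the
implicated feedback network directly: BMP4 upregulates both its own
production and that of NOG, while NOG suppresses BMP4 signaling::

    da/dt = D_a lap(a) + rho_a * a^2 / (i * (1 + kappa * a^2)) - mu_a * a + basal_a
    di/dt = D_i lap(i) + rho_i * a^2 - mu_i * i + basal_i

The basal inhibitor production term represents the constitutive secretion of
BMP antagonists by pluripotent cells; it gives the system a stable
low-signaling state (a = 0, i = basal_i/mu_i), so that sub-threshold BMP4
levels decay instead of reigniting, and makes interior pattern ignition
dose-gated.

The activator is held at the bulk-medium concentration on the colony rim
(Dirichlet), reflecting a colony bathed in induction medium with a fixed
BMP4 dose; the inhibitor satisfies zero-flux by default.  Space is in um,
time in hours; concentrations are dimensionless with the conventional
50 ng/ml dose mapped to 1.0.

Discretization: method of lines on a square grid with a disk mask, 5-point
Laplacian, IMEX time stepping (implicit diffusion via sparse LU, explicit
reaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import i0, jnp_zeros


__all__ = [
    "RDParams",
    "Domain",
    "BoundaryCondition",
    "InitialCondition",
    "FieldSnapshot",
    "SimulationResult",
    "RadialProfile",
    "DEFAULT_PARAMS",
    "DOSE_SCALE_NG_ML",
    "homogeneous_steady_state",
    "turing_instability",
    "disk_modes_in_band",
    "simulate",
    "sweep",
    "radialize",
]

#: bulk dose (ng/ml) that maps to activator boundary value 1.0
DOSE_SCALE_NG_ML = 50.0

# numerical floor for the inhibitor in the activation term denominator
_I_FLOOR = 1e-9


@dataclass(frozen=True)
class RDParams:
    """Kinetic and transport parameters of the activator-inhibitor system.

    Rates are per hour, diffusivities in um^2/h, kappa in 1/concentration^2.
    """

    D_a: float  # activator diffusivity
    D_i: float  # inhibitor diffusivity
    rho_a: float = 1.0  # activator autocatalysis rate
    rho_i: float = 1.0  # inhibitor production rate
    mu_a: float = 1.0  # activator decay
    mu_i: float = 2.0  # inhibitor decay
    kappa: float = 0.0  # activator saturation constant
    basal_a: float = 0.0  # basal activator production
    basal_i: float = 0.0  # basal (constitutive) inhibitor production

    def __post_init__(self) -> None:
        for name in ("D_a", "D_i", "rho_a", "rho_i", "mu_a", "mu_i", "kappa",
                     "basal_a", "basal_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def reaction(self, a: np.ndarray, i: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reaction terms (da/dt, di/dt) without diffusion."""
        i_safe = np.maximum(i, _I_FLOOR)
        act = self.rho_a * a * a / (i_safe * (1.0 + self.kappa * a * a))
        f = act - self.mu_a * a + self.basal_a
        g = self.rho_i * a * a - self.mu_i * i + self.basal_i
        return f, g


#: Calibrated default parameter set.  One fixed set reproduces the four
#: qualitative dose/size regimes (dose-dependent peripheral peak, size-
#: dependent center level, dose-gated interior periodicity at 3 mm, and
#: dose-dependent rescue of a low-signal center at 250 um).  Found by the
#: coarse search in analysis/01_calibrate_rd.py.
DEFAULT_PARAMS = RDParams(
    D_a=2000.0,
    D_i=60000.0,
    rho_a=1.0,
    rho_i=0.2,
    mu_a=1.0,
    mu_i=2.0,
    kappa=0.005,
    basal_a=0.0,
    basal_i=3.0,
)


@dataclass(frozen=True)
class Domain:
    """Square grid with a centered disk mask representing one colony."""

    colony_diameter: float  # um
    grid_spacing: float  # um

    def __post_init__(self) -> None:
        if self.colony_diameter <= 0 or self.grid_spacing <= 0:
            raise ValueError("diameter and spacing must be positive")
        if self.grid_spacing > self.colony_diameter / 50.0 + 1e-12:
            raise ValueError(
                f"grid_spacing {self.grid_spacing} exceeds colony_diameter/50 "
                f"= {self.colony_diameter / 50.0}"
            )

    @property
    def radius(self) -> float:
        return self.colony_diameter / 2.0

    @property
    def n(self) -> int:
        # grid points per side; cell centers span the full diameter
        return int(round(self.colony_diameter / self.grid_spacing)) + 1

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates (x, y) in um, origin at the disk center."""
        c = (np.arange(self.n) - (self.n - 1) / 2.0) * self.grid_spacing
        return np.meshgrid(c, c)

    def mask(self) -> np.ndarray:
        # include cells whose center is within half a spacing of the disk:
        # the rim-node set then straddles the true circle, canceling most of
        # the first-order boundary-position bias of a staircase rim
        x, y = self.coords()
        return np.hypot(x, y) <= self.radius + 0.5 * self.grid_spacing + 1e-9

    def rim(self) -> np.ndarray:
        """Mask cells with at least one 4-neighbor outside the mask."""
        m = self.mask()
        inner = np.zeros_like(m)
        inner[1:-1, 1:-1] = (
            m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
        )
        return m & ~inner

    def radii(self) -> np.ndarray:
        x, y = self.coords()
        return np.hypot(x, y)


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary treatment: activator clamped to the bulk dose at the rim."""

    bmpi: float = 50.0  # bulk BMP4 dose, ng/ml
    inhibitor_bc: Literal["zero_flux", "zero_dirichlet"] = "zero_flux"
    activator_bc: Literal["dirichlet_bulk", "zero_flux"] = "dirichlet_bulk"

    def __post_init__(self) -> None:
        if self.bmpi < 0:
            raise ValueError("bmpi must be >= 0")

    @property
    def a_rim(self) -> float:
        """Dimensionless activator value at the rim."""
        return self.bmpi / DOSE_SCALE_NG_ML


@dataclass(frozen=True)
class InitialCondition:
    """Initial fields: uniform activator at the bulk dose; center-high inhibitor.

    The inhibitor pre-pattern is the steady secretion-diffusion profile of a
    uniformly secreting disk that loses inhibitor at the rim,
    ``i0(r) = peak * (1 - I0(r/l) / I0(R/l)) / (1 - 1/I0(R/l))``,
    which is maximal at the colony center.  It stands for the BMP
    antagonists accumulated in the pluripotent colony before induction.
    """

    a0: float | None = None  # uniform activator; default = rim value
    i0_peak: float = 1.0  # inhibitor pre-pattern at the center
    i0_length: float | None = None  # decay length l (um); default sqrt(D_i/mu_i)
    i0_uniform: float | None = None  # overrides the pre-pattern with a flat field
    noise_rel: float = 0.0  # relative sd of multiplicative activator noise
    seed: int = 0

    def activator(self, domain: Domain, bc: BoundaryCondition) -> np.ndarray:
        a0 = bc.a_rim if self.a0 is None else self.a0
        a = np.full((domain.n, domain.n), float(a0))
        if self.noise_rel > 0:
            rng = np.random.default_rng(self.seed)
            a *= 1.0 + self.noise_rel * rng.standard_normal(a.shape)
            np.clip(a, 0.0, None, out=a)
        return a

    def inhibitor(self, domain: Domain, params: RDParams) -> np.ndarray:
        """Baseline basal_i/mu_i plus the center-high secretion pre-pattern."""
        if self.i0_uniform is not None:
            return np.full((domain.n, domain.n), float(self.i0_uniform))
        base = params.basal_i / params.mu_i if params.mu_i > 0 else 0.0
        out = np.full((domain.n, domain.n), base)
        if self.i0_peak == 0:
            return out
        ell = self.i0_length
        if ell is None:
            ell = float(np.sqrt(params.D_i / max(params.mu_i, 1e-12)))
        if ell <= 0:
            raise ValueError("inhibitor pre-pattern length scale must be positive")
        r = domain.radii()
        R = domain.radius
        denom = i0(R / ell)
        prof = (1.0 - i0(np.minimum(r, R) / ell) / denom) / (1.0 - 1.0 / denom)
        return out + self.i0_peak * np.clip(prof, 0.0, None)


@dataclass(frozen=True)
class FieldSnapshot:
    """Activator/inhibitor grids at one time point (NaN outside the mask)."""

    a: np.ndarray
    i: np.ndarray
    t: float  # hours
    um_per_px: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside_a = self.a[self.mask]
        inside_i = self.i[self.mask]
        if np.any(inside_a < 0) or np.any(inside_i < 0):
            raise ValueError("negative concentration inside mask")


@dataclass
class SimulationResult:
    """Time-ordered snapshots plus full provenance of the run."""

    snapshots: list[FieldSnapshot]
    params: RDParams
    domain: Domain
    bc: BoundaryCondition
    ic: InitialCondition

    def __post_init__(self) -> None:
        ts = [s.t for s in self.snapshots]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def terminal(self) -> FieldSnapshot:
        return self.snapshots[-1]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])


@dataclass
class RadialProfile:
    """Azimuthally binned statistic vs radius."""

    r_um: np.ndarray  # bin centers, um
    r_frac: np.ndarray  # bin centers as fraction of colony radius
    mean: np.ndarray
    sd: np.ndarray | None = None
    ci95: np.ndarray | None = None
    n: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Linear (Turing) analysis
# ---------------------------------------------------------------------------

def homogeneous_steady_state(params: RDParams) -> tuple[float, float]:
    """Positive fixed point of the reaction terms without diffusion.

    On the inhibitor nullcline ``i(a) = (rho_i a^2 + basal_i) / mu_i`` the
    activator equation reduces to a polynomial in ``a`` (degree <= 5); the
    largest positive real root with non-negative net decay is returned (the
    ignited branch relevant for pattern analysis), polished by Newton steps
    to residual < 1e-10.  Raises when no positive fixed point exists.
    """
    if params.mu_a <= 0 or params.mu_i <= 0:
        raise ValueError("mu_a and mu_i must be positive")
    if params.rho_a <= 0:
        raise ValueError("no positive fixed point: rho_a must be > 0 "
                         "(the a* = 0 branch is non-positive)")
    if params.rho_i <= 0 and params.basal_i <= 0:
        raise ValueError("no positive fixed point: inhibitor never produced")
    mu_a, mu_i = params.mu_a, params.mu_i
    rho_a, rho_i = params.rho_a, params.rho_i
    k, c, b = params.kappa, params.basal_a, params.basal_i
    # (mu_a a - c)(rho_i a^2 + b)(1 + k a^2) = rho_a mu_i a^2
    coeffs = [
        mu_a * rho_i * k,                    # a^5
        -c * rho_i * k,                      # a^4
        mu_a * (rho_i + b * k),              # a^3
        -c * (rho_i + b * k) - rho_a * mu_i,  # a^2
        mu_a * b,                            # a^1
        -c * b,                              # a^0
    ]
    coeffs = np.array(coeffs, dtype=float)
    nz = np.nonzero(coeffs)[0]
    if nz.size == 0:
        raise ValueError("degenerate kinetics: zero polynomial")
    roots = np.roots(coeffs[nz[0]:])
    cands = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and r.real > 1e-12 and mu_a * r.real - c >= -1e-12
    ]
    cands = sorted(set(cands))
    if not cands:
        raise ValueError("no positive fixed point for these parameters")
    a_star = cands[-1]
    i_star = (rho_i * a_star * a_star + b) / mu_i
    # Newton polish on the activator equation along the inhibitor nullcline
    for _ in range(50):
        f, _ = params.reaction(np.array([a_star]), np.array([i_star]))
        if abs(f[0]) < 1e-12:
            break
        eps = max(abs(a_star), 1.0) * 1e-7
        i_eps = (rho_i * (a_star + eps) ** 2 + b) / mu_i
        f2, _ = params.reaction(np.array([a_star + eps]), np.array([i_eps]))
        d = (f2[0] - f[0]) / eps
        if d == 0:
            break
        a_star -= f[0] / d
        i_star = (rho_i * a_star * a_star + b) / mu_i
    if a_star <= 0 or i_star <= 0:
        raise ValueError("no positive fixed point found")
    f, g = params.reaction(np.array([a_star]), np.array([i_star]))
    if abs(f[0]) > 1e-10 or abs(g[0]) > 1e-10:  # pragma: no cover - safety net
        raise RuntimeError(f"steady-state residual too large: f={f[0]}, g={g[0]}")
    return float(a_star), float(i_star)


def _jacobian(params: RDParams, a: float, i: float) -> np.ndarray:
    k = params.kappa
    denom = 1.0 + k * a * a
    f_a = params.rho_a * 2.0 * a / (i * denom * denom) - params.mu_a
    f_i = -params.rho_a * a * a / (i * i * denom)
    g_a = 2.0 * params.rho_i * a
    g_i = -params.mu_i
    return np.array([[f_a, f_i], [g_a, g_i]])


def turing_instability(
    params: RDParams, domain: Domain | None = None
) -> tuple[float, float] | None:
    """Band of wavenumbers (1/um) with positive linear growth rate, or None.

    Standard two-component dispersion analysis: the homogeneous steady state
    must be stable without diffusion (trace < 0, det > 0); diffusion-driven
    instability occurs for wavenumbers q where
    ``h(q^2) = D_a D_i q^4 - (D_i f_a + D_a g_i) q^2 + det J < 0``.

    Raises if the homogeneous state is unstable without diffusion (not a
    Turing regime).  ``domain`` is accepted for interface symmetry; use
    :func:`disk_modes_in_band` to test whether the disk admits a mode.
    """
    a_star, i_star = homogeneous_steady_state(params)
    J = _jacobian(params, a_star, i_star)
    tr = J[0, 0] + J[1, 1]
    det = float(np.linalg.det(J))
    if tr >= 0 or det <= 0:
        raise ValueError(
            f"homogeneous state unstable without diffusion (tr={tr:.3g}, det={det:.3g})"
        )
    # h(z) = D_a D_i z^2 - (D_i f_a + D_a g_i) z + det, z = q^2
    b = params.D_i * J[0, 0] + params.D_a * J[1, 1]
    c2 = params.D_a * params.D_i
    if b <= 0:
        return None
    disc = b * b - 4.0 * c2 * det
    if disc <= 0:
        return None
    sq = float(np.sqrt(disc))
    z_lo = (b - sq) / (2.0 * c2)
    z_hi = (b + sq) / (2.0 * c2)
    if z_hi <= 0:
        return None
    z_lo = max(z_lo, 0.0)
    return float(np.sqrt(z_lo)), float(np.sqrt(z_hi))


def max_growth_rate(params: RDParams, q: float) -> float:
    """Largest real part of the dispersion-relation eigenvalues at wavenumber q."""
    a_star, i_star = homogeneous_steady_state(params)
    J = _jacobian(params, a_star, i_star)
    M = J - np.diag([params.D_a, params.D_i]) * q * q
    return float(np.max(np.linalg.eigvals(M).real))


def disk_modes_in_band(
    band: tuple[float, float] | None, radius: float, n_orders: int = 8, n_roots: int = 8
) -> list[float]:
    """Zero-flux disk wavenumbers j'_{n,m}/R that fall inside the band."""
    if band is None:
        return []
    q_lo, q_hi = band
    modes: list[float] = []
    for order in range(n_orders):
        roots = jnp_zeros(order, n_roots)
        if order == 0:
            # j'_{0,1}=0 is the uniform mode; jnp_zeros already skips it
            pass
        for r in roots:
            q = r / radius
            if q_lo <= q <= q_hi:
                modes.append(float(q))
    return sorted(modes)


# ---------------------------------------------------------------------------
# PDE integration
# ---------------------------------------------------------------------------

class _DiskOperators:
    """Sparse Laplacians on the masked disk for the two boundary treatments."""

    def __init__(self, domain: Domain):
        self.domain = domain
        self.mask = domain.mask()
        self.rim = domain.rim()
        self.interior = self.mask & ~self.rim
        n = domain.n
        h2 = domain.grid_spacing**2

        idx_mask = -np.ones((n, n), dtype=np.int64)
        idx_mask[self.mask] = np.arange(self.mask.sum())
        self.idx_mask = idx_mask
        idx_int = -np.ones((n, n), dtype=np.int64)
        idx_int[self.interior] = np.arange(self.interior.sum())
        self.idx_int = idx_int

        self.L_neumann = self._neumann_laplacian(h2)
        self.L_int, self.B_rim = self._dirichlet_laplacian(h2)

    def _neighbors(self, ii: np.ndarray, jj: np.ndarray):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yield ii + di, jj + dj

    def _neumann_laplacian(self, h2: float) -> sparse.csc_matrix:
        """Zero-flux Laplacian over all mask nodes (missing neighbors dropped)."""
        n = self.domain.n
        ii, jj = np.nonzero(self.mask)
        rows, cols, vals = [], [], []
        diag = np.zeros(self.mask.sum())
        for ni, nj in self._neighbors(ii, jj):
            ok = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
            ok_idx = ok.copy()
            ok_idx[ok] &= self.mask[ni[ok], nj[ok]]
            src = self.idx_mask[ii[ok_idx], jj[ok_idx]]
            dst = self.idx_mask[ni[ok_idx], nj[ok_idx]]
            rows.append(src)
            cols.append(dst)
            vals.append(np.full(src.size, 1.0 / h2))
            np.add.at(diag, src, -1.0 / h2)
        rows.append(np.arange(diag.size))
        cols.append(np.arange(diag.size))
        vals.append(diag)
        return sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(diag.size, diag.size),
        )

    def _dirichlet_laplacian(self, h2: float):
        """Laplacian over interior nodes; rim values enter via B_rim."""
        n = self.domain.n
        n_int = int(self.interior.sum())
        n_rim = int(self.rim.sum())
        idx_rim = -np.ones((n, n), dtype=np.int64)
        idx_rim[self.rim] = np.arange(n_rim)
        self.idx_rim = idx_rim
        ii, jj = np.nonzero(self.interior)
        rows, cols, vals = [], [], []
        brow, bcol, bval = [], [], []
        diag = np.full(n_int, -4.0 / h2)
        for ni, nj in self._neighbors(ii, jj):
            # interior nodes never touch outside-mask cells
            is_int = self.interior[ni, nj]
            is_rim = self.rim[ni, nj]
            src = self.idx_int[ii[is_int], jj[is_int]]
            dst = self.idx_int[ni[is_int], nj[is_int]]
            rows.append(src)
            cols.append(dst)
            vals.append(np.full(src.size, 1.0 / h2))
            srcr = self.idx_int[ii[is_rim], jj[is_rim]]
            dstr = idx_rim[ni[is_rim], nj[is_rim]]
            brow.append(srcr)
            bcol.append(dstr)
            bval.append(np.full(srcr.size, 1.0 / h2))
        rows.append(np.arange(n_int))
        cols.append(np.arange(n_int))
        vals.append(diag)
        L = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_int, n_int),
        )
        B = sparse.csc_matrix(
            (np.concatenate(bval), (np.concatenate(brow), np.concatenate(bcol))),
            shape=(n_int, n_rim),
        )
        return L, B


def simulate(
    params: RDParams,
    domain: Domain,
    bc: BoundaryCondition,
    ic: InitialCondition,
    duration_h: float,
    dt_h: float,
    save_every_h: float | None = None,
) -> SimulationResult:
    """Integrate the coupled PDEs on the masked disk.

    IMEX stepping: diffusion implicit (backward Euler, sparse LU factorized
    once), reaction explicit.  The explicit reaction imposes the stability
    requirement ``dt < 1/max(mu_a, mu_i)``, checked before integration.
    The first snapshot is the initial condition; the last is at ``duration_h``.
    """
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    mu_max = max(params.mu_a, params.mu_i)
    if mu_max > 0 and dt_h >= 1.0 / mu_max:
        raise ValueError(
            f"dt={dt_h} h exceeds the explicit-reaction stability limit "
            f"1/max(mu) = {1.0 / mu_max:.4g} h"
        )

    ops = _DiskOperators(domain)
    mask, rim, interior = ops.mask, ops.rim, ops.interior

    a_grid = ic.activator(domain, bc)
    i_grid = ic.inhibitor(domain, params)
    dirichlet = bc.activator_bc == "dirichlet_bulk"
    if dirichlet:
        a_grid[rim] = bc.a_rim

    n_steps = int(round(duration_h / dt_h)) if duration_h > 0 else 0
    if n_steps > 0 and abs(n_steps * dt_h - duration_h) > 1e-9 * max(duration_h, 1.0):
        n_steps = int(np.ceil(duration_h / dt_h))
        dt_h = duration_h / n_steps

    ident_int = sparse.identity(ops.L_int.shape[0], format="csc")
    ident_all = sparse.identity(ops.L_neumann.shape[0], format="csc")
    if dirichlet:
        lu_a = splu((ident_int - dt_h * params.D_a * ops.L_int).tocsc())
    else:
        lu_a = splu((ident_all - dt_h * params.D_a * ops.L_neumann).tocsc())
    lu_i_op = ops.L_neumann  # inhibitor zero-flux; zero_dirichlet handled below
    if bc.inhibitor_bc == "zero_dirichlet":
        lu_i = splu((ident_int - dt_h * params.D_i * ops.L_int).tocsc())
    else:
        lu_i = splu((ident_all - dt_h * params.D_i * lu_i_op).tocsc())

    if save_every_h is None:
        save_every = max(n_steps, 1)
    else:
        save_every = max(int(round(save_every_h / dt_h)), 1)

    def snap(t: float) -> FieldSnapshot:
        a_out = np.where(mask, a_grid, np.nan)
        i_out = np.where(mask, i_grid, np.nan)
        return FieldSnapshot(a_out, i_out, t, domain.grid_spacing, mask)

    snapshots = [snap(0.0)]
    a_rim_vec = np.full(int(rim.sum()), bc.a_rim)

    for step in range(1, n_steps + 1):
        f, g = params.reaction(a_grid, i_grid)
        # activator
        if dirichlet:
            rhs = (a_grid[interior] + dt_h * f[interior]
                   + dt_h * params.D_a * (ops.B_rim @ a_rim_vec))
            a_grid[interior] = lu_a.solve(rhs)
            a_grid[rim] = bc.a_rim
        else:
            a_grid[mask] = lu_a.solve(a_grid[mask] + dt_h * f[mask])
        # inhibitor
        if bc.inhibitor_bc == "zero_dirichlet":
            i_grid[interior] = lu_i.solve(i_grid[interior] + dt_h * g[interior])
            i_grid[rim] = 0.0
        else:
            i_grid[mask] = lu_i.solve(i_grid[mask] + dt_h * g[mask])

        if step % 25 == 0 or step == n_steps:
            am, im = a_grid[mask], i_grid[mask]
            if not (np.all(np.isfinite(am)) and np.all(np.isfinite(im))):
                raise RuntimeError(f"non-finite concentration at t={step * dt_h:.3g} h")
            if am.min() < -1e-9 or im.min() < -1e-9:
                raise RuntimeError(
                    f"negative concentration at t={step * dt_h:.3g} h "
                    f"(min a={am.min():.3g}, min i={im.min():.3g})"
                )
        # clip tiny negative round-off
        np.clip(a_grid, 0.0, None, out=a_grid)
        np.clip(i_grid, 0.0, None, out=i_grid)

        if step % save_every == 0 or step == n_steps:
            snapshots.append(snap(step * dt_h))

    return SimulationResult(snapshots, params, domain, bc, ic)


def radialize(snapshot: FieldSnapshot, n_bins: int = 50) -> RadialProfile:
    """Azimuthal mean of the activator per radial bin.

    Bins are half-open equal-width intervals in radius over [0, R]; empty
    bins are merged with their inner neighbor.
    """
    mask = snapshot.mask
    n = mask.shape[0]
    h = snapshot.um_per_px
    c = (np.arange(n) - (n - 1) / 2.0) * h
    x, y = np.meshgrid(c, c)
    r = np.hypot(x, y)[mask]
    vals = snapshot.a[mask]
    R = float(r.max())  # disk radius as realized on the grid
    edges = np.linspace(0.0, R * (1 + 1e-9), n_bins + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=vals, minlength=n_bins)
    cnts = np.bincount(which, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = cnts > 0
    # merge empty bins into the inner neighbor (weighted)
    mean = sums[keep] / cnts[keep]
    centers = centers[keep]
    cnts = cnts[keep]
    return RadialProfile(
        r_um=centers,
        r_frac=centers / R,
        mean=mean,
        sd=None,
        ci95=None,
        n=cnts,
    )


def sweep(
    params: RDParams,
    diameters: Sequence[float],
    bmpi_doses: Sequence[float],
    duration_h: float,
    *,
    grid_spacing: float | None = None,
    dt_h: float = 0.02,
    ic: InitialCondition | None = None,
    n_bins: int = 50,
    save_every_h: float | None = None,
) -> dict[tuple[float, float], "SweepCell"]:
    """Terminal radial profile for each (diameter, dose) pair.

    Errors in individual cells are caught and recorded so the rest of the
    sweep continues.
    """
    out: dict[tuple[float, float], SweepCell] = {}
    for d in diameters:
        for dose in bmpi_doses:
            gs = grid_spacing if grid_spacing is not None else min(d / 50.0, 20.0)
            try:
                dom = Domain(colony_diameter=d, grid_spacing=gs)
                bc = BoundaryCondition(bmpi=dose)
                this_ic = ic if ic is not None else InitialCondition()
                res = simulate(params, dom, bc, this_ic, duration_h, dt_h,
                               save_every_h=save_every_h)
                out[(d, dose)] = SweepCell(
                    profile=radialize(res.terminal, n_bins), result=res, error=None
                )
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                out[(d, dose)] = SweepCell(profile=None, result=None, error=str(exc))
    return out


@dataclass
class SweepCell:
    profile: RadialProfile | None
    result: SimulationResult | None
    error: str | None


def diffusion_decay_profile(r: np.ndarray, R: float, c_b: float, k: float, D: float) -> np.ndarray:
    """Closed-form steady state of pure diffusion + linear decay on a disk.

    ``c(r) = c_b * I0(r sqrt(k/D)) / I0(R sqrt(k/D))`` with the rim held at
    c_b; the standard modified-Bessel solution used as a verification oracle.
    """
    q = np.sqrt(k / D)
    return c_b * i0(r * q) / i0(R * q)
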