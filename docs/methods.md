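# Methods

This note records the model, the choices behind its implementation, and what
the validation experiments do and do not establish.

## The stepwise model

Peri-gastrulation-like patterning in BMP4-treated, geometrically confined
hPSC colonies is modeled in two decoupled stages:

1. **Reaction-diffusion (RD).** Free BMP4 ligand (the activator `a`, read
   out as pSMAD1 activity) and a diffusible inhibitor standing for NOG
   (`i`) evolve on a disk-shaped colony domain:

   ```
   da/dt = D_a lap(a) + rho_a a^2 / (i (1 + kappa a^2)) - mu_a a + basal_a
   di/dt = D_i lap(i) + rho_i a^2 - mu_i i + basal_i
   ```

   This is the saturating Gierer-Meinhardt form: BMP4 upregulates both its
   own production and NOG's (the measured positive and negative feedback),
   NOG suppresses BMP4 signaling, and `kappa` caps the autocatalysis at
   high ligand levels. Pattern formation requires the inhibitor to spread
   faster than the activator (`D_i >> D_a`).

2. **Positional information (PI).** Each location reads its activator
   history against two level thresholds and two duration requirements:
   trophoblast-like if cumulative time at/above `T2` exceeds `tau_cdx2`,
   else primitive-streak-like if cumulative time at/above `T1` exceeds
   `tau_bra`, else ectoderm-like. Cumulative time is counted
   non-contiguously, equality at a threshold counts as above, and exposure
   between stored snapshots is treated as piecewise-constant (the level at
   `t_k` holds on `[t_k, t_{k+1})`). Fate labels are phenomenological
   classes, not a gene-regulatory model.

### Boundary, initial conditions, and units

- The activator is clamped at the colony rim to the bulk-medium BMP4
  concentration (Dirichlet): a colony bathed in induction medium with a
  fixed dose. Doses map linearly to dimensionless units with 50 ng/ml = 1.0.
- The inhibitor satisfies zero-flux at the rim by default; a zero-Dirichlet
  option represents NOG dilution into the bulk.
- Initially the activator is uniform at the bulk dose. The inhibitor starts
  at its basal level `basal_i/mu_i` plus a center-high pre-pattern — the
  steady secretion-diffusion profile of a uniformly secreting disk that
  loses inhibitor at the rim, `i0(r) ∝ 1 - I0(r/l)/I0(R/l)` — representing
  the BMP antagonists a pluripotent colony accumulates before induction.
  This is why the earliest pSMAD1 readout dips slightly at colony centers.
- Optional multiplicative seeded noise on the initial activator breaks the
  radial symmetry; it is required for the periodic (spot-forming) regime
  and set to zero for plain gradient runs.

### Why the inhibitor has a basal production term

With inhibitor production `rho_i a^2` alone, the low state decays along
`a ~ e^{-mu_a t}`, `i ~ e^{-2 mu_a t}`, so the ratio `a/i` — which controls
reignition of the autocatalysis — grows without bound: every sub-threshold
interior eventually reignites, and no colony can hold a low-signaling
center. A constitutive inhibitor source `basal_i` gives the system a
genuinely stable dark state `(a, i) = (0, basal_i/mu_i)`. It is also the
biologically sensible reading: pluripotent colonies constitutively secrete
BMP antagonists. With `basal_i > 0` the kinetics are bistable — ignition
requires the activator to exceed a saddle threshold (about 1.9 in
dimensionless units for the defaults, i.e. between the 50 ng/ml and
200 ng/ml doses) — which is exactly what makes interior periodic patterning
dose-gated.

## Default parameters

All rates per hour, diffusivities in um^2/h, concentrations in dimensionless
dose units (50 ng/ml = 1):

| parameter | value | role |
|---|---|---|
| `D_a` | 2000 | activator penetration length `sqrt(D_a/mu_a)` ~ 45 um, setting the rim boundary-layer width |
| `D_i` | 60000 | 30x activator diffusivity; inhibitor range ~ 170 um |
| `rho_a`, `mu_a` | 1, 1 | fix the time scale; gradients form within hours, well inside the 24 h readout |
| `rho_i`, `mu_i` | 0.2, 2 | weak induction / fast turnover of the inhibitor keeps the ignited branch in existence |
| `kappa` | 0.005 | saturation; caps spot amplitude near a* ~ 6 |
| `basal_a` | 0 | the dark state sits at a = 0 |
| `basal_i` | 3.0 | dark-state inhibitor 1.5; ignition saddle ~ 1.9 |
| `i0_peak` | 1.0 | center-high pre-pattern amplitude |

The set was found by the coarse search shipped as
`analysis/01_calibrate_rd.py`: a nullcline scan for bistability with a
Turing-unstable ignited branch (wavelength 380-950 um, several wavelengths
across a 3 mm colony), followed by PDE verification of the four regime
requirements with one fixed set. The defaults are a self-consistent
illustration of the mechanism, not a claim about measured rate constants.

Fate thresholds paired with these parameters: `T1 = 0.15`, `T2 = 0.20`,
`tau_bra = 16 h`, `tau_cdx2 = 24 h` over a 48 h induction. They sit inside
the window the calibrated gradients span: at 250 um the 50 ng/ml field stays
above `T1` everywhere (no ectoderm-like center) while 12.5 ng/ml spans all
three regimes.

## Numerics

- **Discretization.** Method of lines on a square grid with a disk mask;
  5-point Laplacian. The mask includes cells whose center is within half a
  grid spacing of the disk, so the rim-node set straddles the true circle —
  this cancels most of the first-order boundary-position bias of a
  staircase rim (verified against the modified-Bessel closed form for
  diffusion + decay: max relative error 0.07% at 2.5 um spacing, and < 1%
  change under grid/time-step halving).
- **Time stepping.** IMEX backward-Euler: diffusion implicit (one sparse LU
  per species, factorized once), reaction explicit. Explicit reaction
  requires `dt < 1/max(mu_a, mu_i)`, checked before integration. The
  implicit diffusion operator is an M-matrix, so the scheme preserves
  non-negativity; concentrations are checked for NaN/negativity during the
  run and clipped only for round-off. Because backward Euler's fixed point
  is the exact discrete steady state, steady-state benchmarks can use large
  steps.
- **Degenerate inputs.** The inhibitor in the activation denominator is
  floored at 1e-9 to avoid 0/0 at the dark state; `rho_a = 0` (no
  autocatalysis) makes the positive fixed point vanish and is reported as
  an error by the steady-state solver.
- **Linear analysis.** The homogeneous steady state is the largest positive
  root of the nullcline polynomial (degree <= 5), Newton-polished to
  residual < 1e-10. The Turing band solves the standard 2x2 dispersion
  relation `det(J - q^2 D) = 0`; a disk "admits a mode" when some zero-flux
  disk wavenumber `j'_{n,m}/R` falls inside the band with positive growth.
  Parameter draws whose fastest in-band growth rate is below 0.03/h are
  redrawn in the consistency experiment: dynamically marginal cases cannot
  be classified by a finite-time simulation in either direction.

## Single-cell colony statistics

Colonies are identified by DBSCAN on cell positions (default
`eps = 3 x median nearest-neighbor distance`, `min_samples = 10`; the
upstream software's settings are unpublished, so both are exposed). Radial
trends use 15 half-open equal-width bins in normalized radius, with the SD
and 95% t-interval computed across colony-level means — dispersion between
replicate colonies, not between cells. Savitzky-Golay smoothing defaults to
window 7, polyorder 3, applied to the binned mean only. Hex overlays pool
centroid-relative coordinates across colonies on a pointy-top hexagonal
lattice (nearest-center assignment via cube rounding). Percent-positive
gating defaults to an Otsu threshold on pooled log-intensities, overridable
by a fixed gate, since no published gate value exists.

## Periodicity quantification

Pipeline per field: zero pixels strictly below mean + 1 SD (statistics over
in-mask pixels, single pass); sample 12 radii (30-degree steps, 256 bilinear
samples per ray, rays inset half a pixel from the staircase rim and
renormalized by the interpolated mask weight); subtract the mean and smooth
with a reflected-boundary Gaussian (sigma 3 samples for experimental-source
images, 20 for model fields, following the different spatial resolutions;
the mean is re-subtracted after smoothing, and smooth-then-detrend is
available as a config option since the printed order is ambiguous); take
the dominant period as the inverse of the maximal-magnitude FFT frequency,
DC excluded, ties broken toward the lower frequency. Signals are
zero-padded 4x before the FFT so the frequency grid resolves periods longer
than one radius; a period > 1 (or the all-zero sentinel) classifies the
radius as aperiodic. The outer fraction of each radius can be excluded for
fate-marker stains (default 10%) where rim cell accumulation is an
artifact; model/pSMAD1 fields use no exclusion.

**Null behavior — an important caveat.** The per-radius rule "period > 1 =
aperiodic" has a high chance rate of *periodic* calls on structureless
white-noise fields: a Gaussian-smoothed noise spectrum is argmax-dominated
by its lowest few frequency cells, and the maximum falls below 1 cycle per
radius only ~30% of the time at sigma = 20 (~4% at sigma = 3). Suppressing
this would need sigma ~ 0.27 x the ray length, which destroys recovery of
genuine patterns up to 6 cycles (attenuation e^-53). The rule separates
smooth monotone gradients (trend-dominated, period >= 1) from genuinely
periodic fields — the contrast that matters for the 3 mm dose-gate result —
but it is not a calibrated white-noise test per radius. The package
therefore ships `null_aperiodic_fraction`, a simulation of the detector's
own null, and the workflow makes its "RD-like" call by comparing a field's
periodic fraction against that null rather than trusting single radii.

## Synthetic data: what it emulates, what it does not

The generator produces disk colonies (single or gridded) with area-uniform
cell placement (radius ~ sqrt(u); confluent monolayer), radial mean-
intensity profiles with truncated-additive-Gaussian (default) or
unit-median lognormal noise, radially periodic "spot" fields with pixel
white noise, and fate labels assigned by the package's own PI rule to
analytic exposure histories. Intensities are arbitrary units with the
pluripotent baseline near 1. No per-cell noise statistics are published for
the real assay, so noise defaults are placeholders exposed in the specs.
The generator does not emulate raw microscopy (no PSF, illumination or
segmentation errors), cell migration, division, or the rim cell-crowding
artifact; green tests therefore validate the statistical machinery, not
robustness to those effects.

The threshold-recovery experiment uses an exposure field mixing sustained,
ramped and pulsed trajectories across the colony. This is deliberate: under
any single global time course, a level threshold and a duration requirement
trade off exactly and the pair `(T, tau)` is unidentifiable; sustained
exposures pin the levels and variable-duration pulses pin the durations.

## Problem sizes used in the shipped analyses

Grid spacing 20 um (5 um for 250 um colonies, 2.5 um for the Bessel
benchmark), dt 0.02 h, 24 h gradient / 48 h fate runs; 20 random parameter
sets in the Turing-consistency experiment; 100 noise fields x 12 radii in
the null; 20 seeds x 600 cells in threshold recovery. These sizes make the
full validation suite run in a few minutes on one CPU while leaving every
qualitative conclusion insensitive to a 2x refinement (checked by the
convergence test).

## Known limitations

- One collapsed inhibitor species; no NODAL/SMAD2 arm (the Nodal
  requirement for the primitive-streak fate is a post-hoc mask, not a PDE).
- 2D disk only; no apical/basolateral receptor geometry, no growth or
  motility.
- The pSMAD1 readout is taken as identical to free-BMP4 concentration; a
  monotone readout map can be supplied but defaults to identity.
- Default kinetic constants are calibrated to qualitative regimes, not
  fitted to measurements; all are config-exposed.
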