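# Methods

## Physical model

A cell (an oocyte with its zona pellucida excluded from the contour) is
modelled as an incompressible tensile elastic shell. The surface stress is

    tau = tau0 + E * th * (A / A0 - 1)

with `tau0` the resting cortical tension (nN/um), `E` the elastic modulus of
the shell (kPa), `th` its mean thickness (um), and `A/A0 - 1` the areal
strain relative to the undeformed sphere of diameter `D0`
(`V0 = pi D0^3 / 6`, `A0 = pi D0^2`). The channel is a straight constriction
of minimal width `d` preceded by a ramp of inclination `alpha`; the axis
coordinate `x` grows in the flow direction with the constriction entry at
`x = 0`. Two cross-section idealizations are supported: axisymmetric
(`conical`, the default) and square (`pyramidal`), the spherical caps being
identical in both.

Every equilibrium shape is assembled from closed-form primitives: a rear
spherical cap tangent to the ramp wall (`hr = (Dr/2)(tan a + sec a)`, cap
radius `Dr/(2 cos a)`), a frustum of the wall cone between the two cap
bases, optionally a cylinder (or prism) of length `L` inside the
constriction, and a front spherical cap. The frustum's lateral area uses
the slant factor `1/sin a` (standard frustum geometry). At each imposed
front position the rear cap base position is the root of the
incompressibility condition `V = V0`, and the driving pressure across the
cell follows from Laplace's law applied to the two caps:

    dP = P_rear - P_front = 2 tau (1/Rf - 1/Rr)

`dP` is reported as the driving pressure (upstream minus downstream), which
is non-negative along the stable branch. Internally lengths are um,
tensions nN/um and moduli/pressures kPa (`tau/R` is then a kPa with no
conversion factor); applied pressures at I/O boundaries are mbar,
1 kPa = 10 mbar.

## Passage sweep

The passage is parameterized by position, not pressure, so the sweep never
meets the fold instability of pressure-controlled loading:

1. **Ramp stage.** Both caps tangent to the wall; the front cap base sweeps
   from the inscribed-sphere start (base diameter `D0 cos a`, where `dP = 0`
   by symmetry) to the entry.
2. **Entry stage.** Front cap base pinned at the entry with base diameter
   `d`; the cap height `hf` sweeps up to `d/2`, at which point the front cap
   is a hemisphere of radius `d/2` (the classical Laplace threshold
   configuration).
3. **Constriction stage.** The front remains a hemisphere of radius `d/2`
   while a cylinder (conical mode) or square prism (pyramidal mode) of
   length `L` grows between the entry and the front cap; the sweep ends when
   the rear cap base reaches the entry. The cylinder's lateral surface
   (`pi d L`, or `4 d L` for the prism) is included in the area entering the
   stress law.

The third stage is a reconstruction: the quasi-static description of the
first two stages is standard, while the continuation past the hemispherical
front admits several parameterizations. The one used here is the minimal
four-section shape consistent with volume conservation; it reduces to the
pure Laplace behaviour when `E = 0` (monotonically decreasing `dP`, so it
adds nothing to the threshold) and produces the elastic excess
`Pmax > P(Xf = d/2)` when `E > 0`, which is the experimentally relevant
signature.

Defaults: 500 uniform steps per stage (tests and cohort generation use
120-400 for speed; the marker pressures are insensitive to this because
they interpolate a smooth curve). The rear-position root is found with
Brent's method, bracket grown geometrically from the previous step's
solution, position tolerance 1e-12; the volume closure of every emitted
point is better than 1e-10 relative. Marker pressures `P(Xf=0)` and
`P(Xf=d/2)` are linear interpolations of `dP` in front-tip position;
`Pmax` is the maximum of `dP` over the whole sweep. Degenerate inputs:
`d >= D0` yields a trivial zero-pressure trajectory with a warning;
`D0 cos a <= d` (ramp too steep for the cell to rest tangent to both walls)
raises a no-solution error.

A computational note: the whole geometric backbone of the sweep
(positions, areas, cap radii, aspect ratios) is independent of `tau0` and
`E`; the pressure curve is affine in both. The backbone is therefore cached
per `(D0, d, alpha, mode, n_steps)` and re-evaluated vectorially for
parameter sweeps and inverse fits.

## Closed-form threshold and sensitivities

At the end of the entry stage (`hf = d/2`, front base `d`), volume closure
is cubic in the rear cap base diameter and solves in closed form:

    Dr_cr^3 = [V0 - pi d^3/12 + k_mid d^3] / (k_mid + k_rear)

with `k_mid = pi/(24 tan a)` (conical) or `1/(6 tan a)` (pyramidal) and
`k_rear` the rear tangent-cap volume coefficient. In the conical case this
simplifies to
`Dr_cr = [sin a cos^3 a (4 D0^3 - (2 - cot a) d^3) / (1 + sin a)^2]^(1/3)`.
With the critical area `A_cr` assembled from the same primitives, the
threshold is

    Pc = 4 [tau0 + E th (A_cr/A0 - 1)] (1/d - cos a / Dr_cr)
       = m_tau0 * tau0 + m_E * E,

so `m_tau0 = 4 (1/d - cos a / Dr_cr)` and
`m_E = th (A_cr/A0 - 1) m_tau0` are exact parameter sensitivities: the
threshold is affine in tension and elasticity, and linear regressions of
`Pc` on either parameter recover these slopes identically. A critical
configuration exists only while `Dr_cr > d` (the rear cap base still in the
ramp); steep ramps or small cells raise a no-critical-point error, and
design maps flag such cells rather than dropping them.

The analytic `Pc` serves as an independent oracle for the numerical sweep:
the last entry-stage equilibrium matches it to ~1e-14 relative at default
parameters, and to better than 1e-6 across the tested grid.

**Droplet-limit subtlety.** For `E = 0` the trajectory maximum is *not*
exactly `Pc`: with the front cap base pinned at the entry, `d(1/Rf)/dhf`
vanishes quadratically as `hf -> d/2` while volume conservation keeps
shrinking the rear cap (so `1/Rr` keeps growing), making `dP` peak slightly
*before* the hemispherical front. At the default geometry (`D0 = 74.4`,
`d = 50`, `alpha = 9 deg`) the excess is ~0.4% of `Pc`, vanishing as
`alpha -> 0`. The classical statement "the droplet threshold is the
pressure at `Xf = d/2`" is thus an approximation within this model, albeit
an excellent one; with `E = 1.5 kPa` the elastic excess is ~14%, about 40x
larger.

## Geometry design maps

`design_map` scans `(alpha, d, D0)` and reports `m_tau0`, `m_E` and their
ratio. When `D0` varies, the shell thickness is scaled proportionally
(`th/D0` fixed): the cortex is treated as a constant fraction of the cell
radius, so cells of different sizes are mechanically self-similar. Under
this convention, scaling the whole geometry up at fixed `D0/d` leaves
`m_E` unchanged (areal strain is scale-invariant and `th m_tau0` is
scale-free) while `m_tau0` falls as `1/D0` — larger cells lose tension
sensitivity but not elasticity sensitivity. With `th` held fixed instead,
`m_E` would fall as `1/D0` too; the self-similar convention is the one that
matches how sensitivity behaves across species of different oocyte sizes.

## Inverse fit

`ConstrictionCurveFit` recovers `(tau0, E)` from an observed (driving
pressure, aspect ratio) curve; `th` and `D0` are fixed inputs (not jointly
identifiable with `E` from one curve). The loss is the sum of squared
*pressure* residuals — pressure is the controlled variable — with the model
pressure linearly interpolated at the observed aspect ratios. Minimization
is a 20x20 coarse grid over the bounds (defaults `tau0 in [0.05, 10]`,
`E in [0, 20]`) followed by Nelder-Mead with a 1e-6 relative loss
tolerance; estimates within 1e-6 of a bound are flagged non-converged.
Because the model pressure is affine in the parameters, the least-squares
surface is quadratic, the optimum is unique, and the reported standard
errors (`bse`, residual variance times the inverse Gram matrix) are exact
rather than a local approximation.

Identifiability: the two regressor profiles (the geometric Laplace factor
and its strain-weighted version) are strongly correlated along the curve
(r ~ 0.7-0.95 depending on the sampled range), so noiseless curves invert
essentially exactly (errors ~0.01%) but pressure noise inflates the
parameter variance well beyond the naive per-point estimate. With 0.02 kPa
Gaussian pressure noise on 50 points spanning the default curve, the exact
covariance gives a standard deviation of ~0.35 kPa on `E` (about 23% of
1.5 kPa) — an information limit of the curve itself, not of the optimizer.
Noise studies should therefore expect median elasticity errors of ~15-20%
under these conditions; discriminating *groups* of cells is much easier
than fitting individual cells, which is why the cohort comparison uses
rank statistics rather than per-cell fits.

## Trace analysis conventions

- **Phases.** Approach: front tip upstream of the entry. Entry: front
  inside while the rear stays within a threshold (default 1 um, exposed as
  a flag) of its position at the first entry frame. Transit: from the first
  clear rear displacement, or from full deformation, whichever comes first.
  Labels are contiguous by construction.
- **Event pressures.** The crossing times of `x_front = 0`, `x_front = d/2`
  and `x_rear = 0` are linearly interpolated between bracketing frames, and
  the pressure is read from the recorded series at that time (same
  interpolation). Interpolating in time rather than snapping to the plateau
  makes extraction robust to frame decimation, and because the position
  jump happens across a step boundary it also recovers sub-step pressure
  resolution. `d/2` uses each trace's metadata `d_um` (the effective
  constriction width for that cell). The half-width event is read as the
  front *tip* crossing `x = d/2`. Events never reached are flagged invalid,
  not errors. The maximum aspect ratio is taken over frames before full
  deformation (`x_rear <= 0`).
- **Normalization.** Robust z-like scores per experiment:
  `(P - median) / IQR` of the *control group's* front-entry pressure, the
  same location/scale applied to all three pressures of every cell in the
  experiment. Quartiles use linear interpolation between order statistics
  (numpy's default, the common "type 7" rule). At least 3 valid control
  values are required; a zero control IQR is a hard error.
- **Spindle.** Baseline length is the approach-phase mean ("before
  deformation" is otherwise ambiguous); both the elongation at full
  deformation and the maximum over entry+transit are reported, since either
  may be the quantity of interest. Angles are folded to [0, 90] degrees via
  `|((theta + 90) mod 180) - 90|` (axis orientation has period 180).
- **Group comparison.** Two-sided Mann-Whitney U; exact permutation
  enumeration when both groups have n <= 8 (correct with ties via
  midranks), tie-corrected normal approximation otherwise.

## Synthetic cohorts

The generator emulates the stepwise assay: pressure staircase of 0.1 mbar
every 2.5 s (the experimental protocol), frames every 250 ms by default
(a decimation of the experimental 50 ms chosen to keep traces small; the
extraction is interpolation-based and insensitive to it, and 50 ms remains
available), cell diameters normal with median 73.09 um and 10th-90th range
7.5 um (sigma = range / 2.5631, truncated at 3 sigma), mechanical
parameters lognormal with 10% CV around group centres (positivity-
preserving; the within-group spread of tension and elasticity is not an
experimentally reported quantity, so 10% is a generator choice), reference
mechanics `tau0 = 1 nN/um`, `E = 1.5 kPa`, `th = 24.4 um`, and a softened
group at half both values. Below threshold, frames sit on the first stable
equilibrium at the applied driving pressure (the increasing envelope of the
model curve, emulating pressure-controlled loading with sticking at local
maxima); once the applied pressure first exceeds `Pmax`, the rear relaxes
exponentially (time constant 2 s) toward one constriction width past the
entry, which guarantees the full-deformation event within the first
supra-threshold plateau. Gaussian noise (defaults 0.15 um on positions,
0.005 on aspect ratio) is added per frame; the pressure series is exact.
All randomness flows from one seed through named substreams (diameters,
mechanics, noise; per group, per cell).

What the generator does *not* emulate: bulk viscosity and rate dependence
(the model is quasi-static), zona pellucida mechanics and perivitelline
space, fluid flow and shear stress, out-of-plane motion, segmentation
artifacts, and the true post-threshold dynamics (the relaxation tail is
synthetic scaffolding — the quasi-static model itself never reaches the
full-deformation configuration). Pipeline tests on these cohorts therefore
validate the measurement and statistics machinery, and the model's own
self-consistency, not the biological fidelity of any particular trace.

## Known limitations

- The entry-stage/constriction-stage continuation is one reconstruction of
  the unstable branch; other parameterizations would change `Pmax` slightly
  (not `Pc`, which is closed-form).
- The droplet-limit threshold exceeds the closed form by the small
  rear-curvature correction described above.
- `(tau0, E, th)` are not jointly identifiable from a single curve; `th`
  is held fixed during fitting.
- The model has no time scale: entry durations and strain rates in
  synthetic traces are protocol artifacts, not predictions.
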