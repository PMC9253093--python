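# Methods

This note documents the models, conventions, and numerical choices behind
`ectoswim`, and what the synthetic study conditions do and do not show
about real pool experiments or living animals.

## Units and frames

Geometry and mass work in cm / g / s (densities in g/cm³), matching the
constants the field prints; forces are newtons at module interfaces, and
the trial simulator integrates in SI internally. The frame is
right-handed with *z* vertical and the planispiral coiling axis along
*y*, so the spiral lives in the x–z plane. Trial CSVs give positions in
metres, the convention of videogrammetry toolchains.

## Conch generation

A conch is a closed whorl section (superellipse of exponent 2.5 by
default, or an imported outline normalised to unit height) swept along a
logarithmic spiral: venter radius `r_v(θ) = W^(θ/360)`, piecewise in θ if
ontogenetic overrides are given. With umbilical exposure `u` the section
height follows `h = r_v (W−1)/(W−(1−u))`, which makes whorl geometry
self-similar: `u → 1` gives barely touching whorls (serpenticones),
`u → 0` a closed umbilicus.

**Impression zone instead of booleans.** Involute sections would cut into
the previous whorl. Rather than mesh booleans (fragile, and they would
destroy exact volume arithmetic), any dorsal vertex falling inside the
previous whorl is clamped radially onto the previous venter — the
impression zone of real shells. Every surface is then watertight and free
of self-intersection, so the shell wall, septa, chambers, and soft body
partition the displaced-water envelope *exactly*: the conservation
identity holds to ≈1e−16 relative on all bundled morphotypes, and is a
regression test.

**Shell and septa.** The inner shell surface is the section offset inward
along vertex normals by 3.1% of the inner whorl height (venter to
previous venter); septa are thin lofted slices of the internal tube, 2.1%
of inner whorl height thick, every 23° of spiral. Real septa are domed,
sutured surfaces; here each septal face carries a parametric spherical-cap
concavity (default 0.3 of the half-height, bulging adapically, clamped so
it never punches through the adjacent chamber). Hydrostatic quantities
depend on septal volume and position, not suture shape, which is why this
stand-in is acceptable; it is *not* suitable for suture morphology work.
Both faces of a septum are built from bit-identical cap surfaces shared
with the neighbouring chamber meshes, which is what makes the volume
partition exact.

**Morphospace placement.** The Westermann ternary coordinates are
computed from four classical measurements (diameter D, umbilical diameter
U, apertural height a_h and breadth b) as the normalisation of the raw
indices `(2·a_h/D, U/D, b/D)`. This is this package's documented
operationalisation — chosen so the three classical end-members each
maximise their own corner — not a transcription of any published
normalisation; treat cross-study comparisons accordingly.

**Problem sizes.** `ConchSpec` defaults to 1° steps and 64-point
sections; the bundled demo morphotypes use 2° and 48 points, building a
full multi-component model in ~1–3 s, which the test suite and examples
use throughout. Venter-radius spiral predictions, chamber counts, and
conservation are resolution-independent checks.

## Hydrostatics

Neutral buoyancy fixes the cameral liquid/gas split in closed form. The
fill formula as printed evaluates to the **gas** fraction of total
chamber volume (`Φ = 0` when the chambers must be all liquid, `Φ = 1`
when all gas); the API therefore exposes both `phi` (the formula's value)
and `liquid_fraction = 1 − phi`, and every report states which reading it
quotes. Default densities: soft body 1.049, shell 2.54, cameral liquid
1.025, cameral gas 0.001, ambient water 1.025 g/cm³ (configurable for
fresher pool water).

Chamber contents share a single centre — the centre of volume of all
chambers — a deliberate simplification relative to capillary retention of
liquid around septal margins.

Equilibrium orientation is the smallest rotation bringing the buoyancy
centre vertically above the mass centre (ties broken by the identity).
Apertural angle: 0° = soft body facing horizontally, +90° = upward.
Thrust angle: elevation of the hyponome relative to the midpoint of the
hydrostatic centres, so +90° means jet energy transmits most efficiently
into *downward* motion. The body-chamber solver bisects on a fast
cumulative-volume integral (Pappus slices of the internal tube, with an
analytic correction for the final septum's dome bulge), then polishes
with secant steps on exact mesh volumes until the liquid fraction is
within ±0.005 of target (default 0.12, the Nautilus-like retention).

## Robot mass budgets

The printable thermoplastic (PETG) is the budget's free variable: its
mass is displaced mass minus everything else, and its centre comes from
the centre-of-mass identity with the *total* (PETG-inclusive) mass in the
first term — the only non-circular reading, enforced by a round-trip
property (re-evaluating the weighted mean over all components returns the
target centre to 1e−9 cm on randomized budgets). The counterweight moves
only vertically, which leaves horizontal mass-centre components untouched
by construction; its height is solved so the stability index reaches the
requested target, with a hull-floor constraint that reports the maximum
attainable index when violated. PETG is treated as a point-mass placement
target; generating the printable solid is out of scope. Electronics,
motor, and battery masses in the demo budget are synthetic placeholders,
not measured values.

## Trial simulator

The simulator replaces the pool: it is the ground-truth generator every
downstream estimator is validated against, not a fluid-dynamics model.

- **Thrust**: exponential rise to a plateau (τ = 50 ms) and exponential
  decay after switch-off; `from_mean_thrust` picks the plateau so the
  pulse-averaged thrust equals a configured mean (0.3 N default,
  Nautilus-like). Zero time constants give ideal rectangular pulses for
  closed-form tests.
- **Linear dynamics**: `(m + m_a)·dv/dt = T(t) − ½ρC_dA·v|v|` along the
  jet axis; added mass as a fixed coefficient of body mass (0.5 for
  sphere-like, 0.2 for compressed bodies — a conventional potential-flow
  scale, configurable; velocity dependence of added mass is not
  modelled). Optional buoyancy-imbalance vertical drift, constant lateral
  drift, and pitch rocking of the tracking points.
- **Yaw dynamics**: `I_zz·dω/dt = T(t)·L − c_rot·ω|ω|`, counter-clockwise
  positive from above. The quadratic rotational-resistance law is this
  package's stand-in — no such law is measured for these bodies — and
  wake re-encounter oscillations are deliberately absent.
- **Integration**: explicit RK4 with 1 ms substeps that land exactly on
  frame times (23.975 fps) and on thrust breakpoints, so there is no
  resampling interpolation; step-halving changes positions by < 1e−8 m.
- **Observation model**: two body-fixed tracking points, i.i.d. Gaussian
  position noise (default 3 mm/axis, keeping the reconstructed
  inter-point distance SD under the 8.5 mm calibration gate).

**Morphotype parameter sets.** The four bundled bodies encode the study
conditions: drag coefficients 0.14 (oxycone), 0.5 (serpenticone and
centre), 0.61 (sphaerocone); frontal areas scaled by section compression
(30%, 45%, 75%, 100% of the 15 cm sphere); strong rotational drag for the
broad-flanked compressed bodies and weak for the sphere-like ones. Under
the quadratic rotational-drag law a single parameter set cannot both spin
>3 revolutions and hold its 1-s yaw rate an order of magnitude below the
vacuum value — strong in-pulse damping kills the coasting angle — so the
two behaviours live where the physics puts them: the compressed sets
realise the ~10× vacuum gap, the sphaerocone realises the >3-revolution
spins. Synthetic trials share none of the pool's messiness (currents,
wake interactions, tracking dropouts), so passing recovery tests shows
estimator correctness under the stated forward model, not robustness to
unmodelled flow phenomena.

## Kinematics and statistics

Velocities difference the midpoint of the two tracking points; the
horizontal-only (2D) variant nullifies imperfect buoyancy. Acceleration
is an OLS slope of 2D speed over the motor-on window(s). Peak velocity is
taken on a centred 5-frame moving average (raw series retained), and
"rest" is smoothed speed < 1 cm/s sustained for 0.5 s — both
operationalisations are configurable since no canonical choice exists.
Yaw uses the unwrapped horizontal bearing of the inter-point axis;
angular velocity is frame-differenced (so it estimates ω at the
mid-interval time — closed-form comparisons account for the half-frame
offset). The rocking angle is `arccos((z₂−z₁)/|p₂−p₁|) − θ_tp`; with a
vertical static axis this yields |pitch| (one-sided), with a tilted axis
the full signed oscillation.

Group comparison uses Welch's heteroscedastic one-way ANOVA and a
Games-Howell post hoc implemented from their definitions (pairwise Welch
t, Welch–Satterthwaite df, p from the studentized-range distribution with
q = |t|·√2); an installed reference implementation (pingouin) is the
independent cross-check in the test suite, and a 1000-draw Monte-Carlo
confirms the ~5% size under the null. Welch's variant is used ahead of
the classic ANOVA because Games-Howell already assumes unequal variances.

## Drag estimation

Pure quadratic-drag coasting has the closed form `v(t) = v0/(1+k·v0·t)`
with `k = ρC_dA/(2(m+m_a))`; nonlinear least squares on the horizontal
speed series over the coasting window recovers `k`, hence `C_d`. The
window opens strictly after motor-off plus a 0.25 s settle period (the
pump's thrust tail and wake), and closes at rest, track end, or where the
smoothed heading has yawed beyond 60° from the initial coast direction —
frames whose headings no longer face the motion direction carry no
usable drag signal. Conventions recorded in every fit: reference area =
frontal projected area of the displaced-water body (computed as the
polygon union of projected front-facing triangles); effective mass = body
mass + constant added mass. The fit is on speeds, not log-speeds, with an
optional soft-L1 robust loss; noise-free recovery is unbiased to < 2%
across the (C_d, v0) grid, and the late-coast overprediction caveat of
this rough estimator applies whenever yaw truncates the window.

## Known limitations

- No computational fluid dynamics: drag laws are imposed, not derived;
  Reynolds-number dependence of C_d is out of scope.
- Septum geometry is parametric, not specimen-derived; ornamentation,
  keels, and heteromorph coiling are not generated.
- The morphospace normalisation is package-specific (see above).
- The demo morphotype conch specs are qualitative stand-ins placed in the
  correct morphospace regions, not reconstructions of figured specimens.
- Camera projection, wand calibration, and pixel tracking are upstream of
  this package; trials arrive as calibrated world coordinates, with the
  inter-point distance SD as the only data-quality gate.
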