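# ectoswim

Hydrostatics and jet-propulsion biomechanics of planispiral, externally
shelled cephalopods (ammonoids and nautiloids) and of the neutrally
buoyant biomimetic robots used to study them.

Externally shelled cephalopods were dominant marine animals for hundreds of
millions of years, and their coiled conchs span a wide morphospace — from
evolute, many-whorled **serpenticones**, through streamlined, involute
**oxycones**, to globular **sphaerocones**. The conch shape fixes the
animal's buoyancy apparatus, resting orientation, drag, and turning
resistance, so it encodes a physical tradeoff between *hydrodynamic
stability* (coasting efficiency, course holding) and *yaw maneuverability*
(ease of spinning about the vertical axis). `ectoswim` implements the full
computational chain needed to quantify that tradeoff:

1. **Theoretical conch generation** — a whorl section swept along a
   logarithmic spiral (expansion rate `W` per revolution, umbilical
   exposure, section inflation) builds watertight meshes of the shell,
   septa (23° spacing; wall = 3.1% and septa = 2.1% of the inner whorl
   height), soft body, cameral chambers, and displaced-water envelope, and
   places each shape in the Westermann ternary morphospace.
2. **Hydrostatics** — the cameral liquid/gas split `Φ` that balances
   organismal mass against displaced mass
   (`Φ = ((V_wd ρ_wd − V_sb ρ_sb − V_sh ρ_sh)/V_ct − ρ_cl)/(ρ_cg − ρ_cl)`),
   the centres of buoyancy `B` and mass `M`, the scale-free stability index
   `St = |B − M| / V^{1/3}`, and the apertural and thrust angles at
   equilibrium.
3. **Robot design** — the 3D-printed thermoplastic mass that closes the
   buoyancy budget, its centre placement
   `D_PETG = (M·m_total − Σ D_i m_i)/m_PETG` reproducing the virtual
   model's centre of mass, counterweight stabilisation, and composite
   moments of inertia with vacuum-yaw comparisons.
4. **Trial simulation** — a rigid-body forward model of the pool
   experiments: 1-s, ~0.3 N Nautilus-like jet pulses, quadratic drag
   `(m+m_a) dv/dt = T − ½ρC_dAv²`, yaw dynamics
   `I_zz dω/dt = T·L − c_rot ω|ω|`, rocking, buoyancy drift, and tracking
   noise, sampled at 23.975 frames/s as two tracked points.
5. **Kinematics & statistics** — velocities (3D and horizontal-only),
   acceleration fits over the pulse window, rocking and unwrapped yaw
   series, trial summaries, and Welch ANOVA with a Games-Howell post hoc.
6. **Drag estimation** — the quadratic-drag coasting solution
   `v(t) = v0/(1 + k v0 t)` fitted to the post-jet deceleration to recover
   drag coefficients, with frontal projected areas as reference.

## Worked example

```python
from ectoswim.simulate import MORPHOTYPE_BODIES, JetProfile, \
    simulate_linear_trial, simulate_yaw_trial
from ectoswim.kinematics import summarize_trial, yaw_series
from ectoswim.drag import fit_drag_coefficient

jet = JetProfile()  # one 1-s pulse, 0.3 N plateau
for name in ("oxycone", "sphaerocone"):
    body = MORPHOTYPE_BODIES[name]
    trial = simulate_linear_trial(body, jet)
    s = summarize_trial(trial)
    fit = fit_drag_coefficient(trial, body.frontal_area_cm2,
                               body.mass_g * (1 + body.added_mass_coefficient))
    spin = yaw_series(simulate_yaw_trial(body, jet))
    print(f"{name:12s} accel={s.accel.slope_cms2:5.1f} cm/s^2  "
          f"peak={s.peak_velocity_mps*100:5.1f} cm/s  "
          f"coast={s.coasting_distance_m:4.2f} m  "
          f"Cd={fit.cd:.2f}  yaw={spin.revolutions:.2f} rev")
```

prints

```
oxycone      accel= 24.6 cm/s^2  peak= 24.5 cm/s  coast=1.39 m  Cd=0.14  yaw=0.24 rev
sphaerocone  accel= 17.1 cm/s^2  peak= 15.8 cm/s  coast=0.46 m  Cd=0.61  yaw=3.33 rev
```

The streamlined oxycone accelerates harder, reaches a higher peak speed,
and coasts three times farther on the same jet, while the globular
sphaerocone — whose coasting fit returns its high drag coefficient —
spins more than three full revolutions in the yaw trial against the
oxycone's quarter turn: the stability–maneuverability tradeoff in two
lines of output. The fitted `Cd` values recover each body's ground-truth
coefficient because the trials are synthetic with known physics; on real
tracks the same estimator carries its R² and windowing conventions in the
`DragFit` report.

A command-line pipeline wraps the same functionality
(`ectoswim generate-conch | hydrostatics | design-robot | simulate |
analyze-trial | fit-drag | stats | make-fixtures | run`); see
`ectoswim --help`.

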