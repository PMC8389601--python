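# eggmech

Eggshell contact-incubation mechanics for extant and extinct giant birds.

A bird incubating by contact rests its body on the clutch, so every egg
must carry an apex load of order the parent's weight without buckling —
while staying thin enough for the chick to hatch. `eggmech` quantifies
that trade-off for ratites (ostrich, rheas, emu, cassowaries, kiwi, the
extinct moa and elephant birds) and for fossil eggshell of debated
parentage, using nothing but egg length, width, shell thickness, egg
mass, and adult body mass.

## The model

An egg is idealized as a prolate ellipsoid of revolution with uniform
shell thickness *t*, linear-elastic shell material (*E* = 30 GPa,
*ν* = 0.307 by default). A bespoke axisymmetric thin-shell finite-element
solver (conical frustum elements, membrane + bending, Kirchhoff–Love
kinematics) computes:

* **Apex-load stiffness** *K* = *F*/*δ* of the equator-clamped half
  shell under a polar point force, halved for the full egg (two caps in
  series). Verified against the classical closed-form point-load
  stiffness of a spherical shell, 4*E t*²/(*R*√(3(1−*ν*²))) per cap, and
  against an independent axisymmetric *solid* (continuum) finite-element
  model of the same shell.
* **The dimensionless stiffness number** *C* = *A*²*K*/(*B W*), with
  *A* the equatorial width, *B* the polar length, and *W* the egg's own
  weight — a scale-free measure of shell stiffness that is comparable
  from hummingbirds to elephant birds.
* **The critical thickness** *t*<sub>cr</sub>: the thinnest shell whose
  buckling load equals the incubating parent's weight. The default
  buckling definition is the onset of dimple inversion (apex deflection
  reaching one shell thickness on the nonlinear von-Kármán path);
  linearized eigenvalue buckling and nonlinear harmonic-bifurcation
  analyses are also available.
* **The factor of safety** F.S. = *C*/*C*<sub>cr</sub>, with
  *C*<sub>cr</sub> re-solved at *t*<sub>cr</sub>. F.S. < 1 means the
  parent cannot sit on the egg without buckling it; F.S. > 2 is the
  adopted comfortably-safe criterion.

On top of the mechanics sit log-log allometric fits (egg mass, shell
thickness, *C*, *C*<sub>cr</sub> versus body mass) and the crossing mass
of the *C* and *C*<sub>cr</sub> trends — the body mass at which the
predicted F.S. falls to one, i.e. the theoretical upper limit for
contact incubation. A synthetic-assemblage generator stands in for a
large multi-species background dataset so the trend analyses are fully
testable.

## Worked example

Assess the elephant-bird egg (*Aepyornis maximus*, the largest egg
known: 303 × 224 mm, 3.7 mm shell, 9120 g) under a 440-kg incubator:

```bash
eggmech compute --length 303 --width 224 --thickness 3.7 \
    --egg-mass 9120 --parent-mass 440
```

```json
{
  "length_mm": 303.0,
  "width_mm": 224.0,
  "thickness_mm": 3.7,
  "egg_mass_g": 9120.0,
  "egg_weight_N": 89.46719999999999,
  "K_full_N_per_mm": 5640.356849678102,
  "C": 10439.895316668091,
  "incubator_mass_kg": 440.0,
  "t_cr_mm": 2.0194801909454374,
  "C_cr": 3189.1144270156883,
  "FS": 3.2736032386387413,
  "classification": "safe"
}
```

Reading: the full egg deflects 1 mm per 5.6 kN of apex load; its
stiffness number *C* ≈ 10,400 sits near the interspecific norm (~15,000
across birds, roughly 12,000 for this species depending on the stiffness
model); a 440-kg parent would need at least a 2.02-mm shell, so the
actual 3.7-mm shell carries a factor of safety of 3.3 — elephant birds,
which lacked sexual size dimorphism, could be contact-incubated by
either parent.

Other entry points:

```bash
eggmech reproduce --out report/        # all 18 ratite species, per sex
eggmech pgom --out pgom/               # fossil-egg attribution analysis
eggmech upper-limit --n-species 463 --seed 1
eggmech simulate --n-species 463 --seed 1 --out background.csv
```

`eggmech reproduce` flags the moa species whose eggs stay below
F.S. = 2 even for the lighter male sex (*Dinornis robustus*, *Dinornis
novaezealandiae*, *Emeus crassus*); `eggmech pgom` finds the Williams
egg unsafe for a 192-kg *Genyornis newtoni* but comfortably safe for the
extinct giant megapodes, supporting the megapode attribution of that
fossil material.

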