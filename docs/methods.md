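# Methods

## Problem and idealization

Contact incubation loads an egg at its pole with a force of order the
parent's weight. The package models the egg as a prolate ellipsoid of
revolution (polar diameter *B*, equatorial diameter *A*, *B* ≥ *A*) with
uniform shell thickness *t* and a linear-elastic, homogeneous, isotropic
shell material. Defaults: *E* = 30 GPa and *ν* = 0.307 (calcite-like
eggshell), *g* = 9.81 m s⁻², Hoyt weight coefficient
*k*<sub>w</sub> = 0.548 g cm⁻³ (this value reproduces the published
fossil-egg masses of 1327 g and 650 g exactly from their dimensions).
Egg contents are neglected — the shell is an empty structure. Shell
thickness below one tenth of the egg width is treated as the thin-shell
regime; outside it the package warns but proceeds.

A note on symbols: the interspecific literature tabulates the egg
*width* column as "A" and the *length* column as "B", opposite to what
prose like "major and minor axis" suggests. The package uses explicit
field names (`length_polar`, `width_equatorial`) everywhere and maps to
A/B only inside the C-number formula, where the assignment A = width,
B = length is the one that reproduces published C values from published
stiffnesses.

## Shell solver

**Discretization.** The load case (axial point force at the pole of a
clamped shell of revolution) is axisymmetric, so the half egg is reduced
to its meridian: two-node conical-frustum elements with linear membrane
displacement and Hermite-cubic normal deflection; three degrees of
freedom per node (radial, axial, meridional rotation). Strain measures
are Kirchhoff–Love (shear-rigid): membrane stretches
(ε<sub>s</sub> = u′, ε<sub>θ</sub> = δr/r) and curvature changes
(χ<sub>s</sub> = −w″, χ<sub>θ</sub> = −(cos φ/r)w′). The faceted
meridian recovers the curved shell under refinement exactly as straight
beam segments recover an arch. Nodes are placed exactly on the ellipse
with element arc lengths geometrically graded toward the pole (default
ratio 20), because the point load produces a bending boundary layer of
width ~√(*R t*) there. All internal mechanics are SI; millimetres and
grams are converted once at the mesh/record boundary.

**Linear stiffness.** Equator ring fully fixed; unit axial force at the
pole (0.1 N by default — the result is load-independent in the linear
regime, which is asserted to 10⁻⁹ in the tests); *K*<sub>half</sub> =
*F*/*δ*<sub>apex</sub>, *K*<sub>full</sub> = *K*<sub>half</sub>/2 (the
lower half adds an equal compliance in series). The mesh is doubled
(starting from 400 elements) until *K* changes by ≤ 0.5%; in practice
the 400-element solution is already converged to ~0.1%.

**Verification.** Three independent routes: (i) for a sphere the solver
matches the classical point-load stiffness
*K*<sub>cap</sub> = 4*E t*²/(*R*√(3(1−*ν*²))) within 2.5%; (ii) an
axisymmetric *solid* continuum model (8-node quadratic quadrilaterals
through the shell volume, no shell kinematics) loaded by an identical
small surface patch agrees with the shell solver within 1–6% for both a
thick (elephant-bird) and a thin (rhea) egg, the gap being the expected
transverse-shear effect; (iii) *K* scales as *t*^p with p ∈ [1.8, 2.2]
and isometrically as the linear size, as thin-shell theory requires.
The solid cross-check ships as a test (`tests/test_solid_oracle.py`).

**Known systematic offsets against previously published stiffness
values.** Published apex stiffnesses and C numbers for the same eggs
were produced with 3-D commercial shell FEA, partly on digitized real
egg profiles rather than perfect ellipses. Against those anchors this
solver's converged ellipse values differ by −15% (elephant bird, where
the published 6605 N/mm exceeds every converged thin-shell and solid
value we can produce for the stated inputs) to +8…+65% (eggs whose
published values derive from real, generally blunter profiles). These
offsets are properties of the reference values' provenance, not of this
solver — the package reports its own converged numbers and does not
rescale toward published ones. Factors of safety are insensitive to any
multiplicative stiffness bias because they are stiffness *ratios* at
fixed geometry.

## Buckling and the critical thickness

Three buckling definitions are implemented; `critical_thickness`
selects among them.

* **Dimple-onset (default).** The apex of the half model is pushed
  inward on the geometrically nonlinear (von Kármán moderate-rotation)
  path under displacement control; the buckling load is the reaction at
  an apex deflection of one shell thickness — the onset of local dimple
  inversion. This serviceability-type criterion is the calibration
  choice: evaluated across thirteen eggs of known geometry with
  published safety factors it is centered (geometric-mean ratio 1.12,
  and 2.82 vs 2.80 for the greater rhea anchor), whereas both
  alternatives below sit 2–3× high because they tolerate a deep, fully
  developed dimple before declaring failure.
* **Nonlinear bifurcation.** Along the same nonlinear path, the
  deformed, prestressed state is tested for stability against
  non-axisymmetric perturbations cos(*n*θ) for each circumferential
  harmonic *n* (classical shell-of-revolution bifurcation machinery on
  the deformed meridian; the harmonic stiffness is validated against the
  classical external-pressure buckling load of a sphere to 0.7%). The
  first bifurcation — circumferential lobes at the dimple rim, typically
  *n* = 2–4 — or an axisymmetric limit point defines the buckling load.
* **Linearized eigenvalue.** Geometric stiffness from the linear
  membrane-force state; smallest positive load multiplier, axisymmetric
  modes (for an apex load the hoop prestress near the pole is tensile,
  so the harmonic-zero mode governs the linear problem).

The critical thickness is found by bracketing and Brent root-finding on
log *t* (relative tolerance 10⁻³) of buckling-load = parent-weight; the
buckling path uses 200 meridian elements (the buckling load changes by
~0.1% on doubling). *C*<sub>cr</sub> is then obtained by re-running the
*linear* stiffness solve at *t*<sub>cr</sub>, not by analytic rescaling,
and F.S. = *C*/*C*<sub>cr</sub> ≈ (*t*/*t*<sub>cr</sub>)² follows from
the *t*² stiffness law. Classification: safe (F.S. > 2, the threshold
all surveyed extant species exceed), marginal (1 ≤ F.S. ≤ 2), unsafe
(F.S. < 1).

**Per-sex safety.** For dimorphic species the chain runs at all four
recorded body-mass endpoints. In reversed sexual size dimorphism (RSSD)
the lighter male incubates; a moa species is flagged as marginal when
even the male at his *maximum* recorded mass falls below F.S. = 2 —
i.e. when incubation by the lighter sex cannot guarantee the safe margin
across its size range. Under this rule exactly three of the eight moa
(D. robustus 1.07, D. novaezealandiae 1.99, E. crassus 1.46) are
flagged, while both Euryapteryx taxa clear the threshold. The
D. novaezealandiae margin (1.99 vs 2.0) is razor-thin; that is the
honest output of the calibrated criterion, not a tuned boundary.

## C number and its scaling

*C* = *A*²*K*/(*B W*) is *not* invariant under uniform (isometric)
scaling: since *K* ∝ *E t*²/*R*, scaling all lengths by *s* (and mass by
*s*³) gives *C* ∝ 1/*s*. The C-preserving similarity scales the outline
by *s*, the thickness by *s*^1.5, and the mass by *s*³ — verified to 2%
(the residual is the genuine t/R boundary-layer correction). Real
eggshells follow almost exactly that thickness allometry, which is why
C is empirically near-constant across five orders of magnitude in body
mass.

## Allometry

Trend lines are ordinary least squares of log₁₀(trait) on log₁₀(body
mass) — the convention behind published trend plots — with parametric
95% intervals; reduced-major-axis fitting is deliberately not used but
the fit object exposes everything needed to add it. Kiwis are excluded
from trend fits by default (egg ≈ ¼ of body mass, an extreme outlier
strategy); a flag re-includes them. The contact-incubation mass limit is
the crossing of the C and C_cr lines,
log₁₀ *M*\* = (b₂−b₁)/(a₁−a₂), with a first-order (delta-method) CI
treating the two fits as independent.

## Synthetic data

The assemblage generator samples body masses log-uniformly over a
configurable range (default 10^0.5–10^5.8 g, ~five orders of magnitude;
log-uniform rather than log-normal so the extremes that determine the
intersection are always populated) and draws log₁₀ C and log₁₀ C_cr
from linear trends plus independent Gaussian residuals. Defaults:
C slope −0.05 with C = 15,000 at the geometric-mean mass; C_cr slope
+0.15 anchored so the true trends cross at 2,000 kg; residual SD 0.15
dex for both — typical interspecific scatter. With n = 463 species the
recovered crossing mass has a median within a few percent of the
configured 2,000 kg over 100 seeded replicates (per-replicate scatter is
a factor ~1.3, dominated by the extrapolation beyond the sampled mass
range — matching the visibly wide published confidence band on the same
construct).

Synthetic single eggs use egg-mass ∝ (body mass)^0.77 and shell
thickness ∝ (egg mass)^0.456 with coefficients 0.277 and 0.0513 (g, mm
conventions), elongation 1.4, and 0.05 dex log-normal noise; dimensions
are back-computed through Hoyt's equation so every generated egg is
Hoyt-consistent by construction. These are conventional interspecific
values chosen once as realistic defaults; they are package choices, not
fitted or published constants. What the generator does *not* emulate:
phylogenetic correlation, measurement error correlated across traits,
asymmetric (non-ellipsoidal) egg profiles, and within-species variance —
so green tests on synthetic data demonstrate statistical recovery under
the stated model, not fidelity to any particular clade.

## Numerical choices and degenerate inputs

Gauss 3-point integration per element (the first element touches r = 0
only at its end node, so hoop terms stay finite); pole regularity
u_r = β = 0 plus clamped equator; sparse LU for linear solves; shifted
Lanczos with a dense fallback for the buckling eigenproblem; banded
Cholesky positive-definiteness tests for the harmonic stability scan;
Newton iteration with step-halving for the nonlinear path (tolerance
10⁻⁹ relative). Zero or negative dimensions, masses, or loads raise
`ValueError`; singular or non-finite solves raise `SolverError`;
pipeline runs record row-level failures and continue. Problem sizes in
the shipped tests and the acceptance script (400-element stiffness
meshes, 200-element buckling paths, 100-replicate calibrations) were
chosen as the sizes at which every reported quantity is converged to
well inside its stated tolerance.

## Known limitations

* Perfect prolate ellipse and uniform thickness only; real eggs are
  asymmetric and blunter at one pole, which measurably softens the
  apex response (see the systematic-offset note above).
* Kirchhoff–Love kinematics: no transverse shear; for the thickest
  shell in the data (t/R ≈ 4.5%) this overestimates patch-load
  stiffness by ~5% against the solid model.
* The dimple-onset buckling criterion is a calibrated engineering
  definition, not a first-principles instability load; the
  first-principles alternatives are provided and sit systematically
  higher.
* No fracture mechanics (buckling generally precedes fracture in
  compression only for thin shells; the safety factors here concern
  buckling alone), no distributed brood-patch loading, no egg turning,
  no clutch load sharing.
* Allometric fits are ordinary regressions without phylogenetic
  correction.
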