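"""Dimensionless stiffness number C, critical thickness, and factor of safety.

The dimensionless number

    C = A^2 K / (B W)

compares the full-egg apex stiffness K (N/m) with the egg's own weight
W (N), normalized by the egg proportions: A is the equatorial width and
B the polar length (m).  C is invariant when the egg outline scales by s
with shell thickness scaling by s^1.5 — almost exactly the thickness
allometry real eggs follow — which is what makes eggshell stiffness
comparable from hummingbirds to elephant birds.

A note on symbols: published tables label the width column "A" and the
length column "B", and only that assignment reproduces the published C
values; the package uses explicit names everywhere and maps to A/B only
inside :func:`c_number`.

The factor of safety for contact incubation is F.S. = C / C_cr, where
C_cr is C re-evaluated at the critical thickness t_cr — the thinnest
shell that can carry the incubating parent's weight as an apex point
load without buckling.  F.S. < 1 means the parent would break the egg
by sitting on it; F.S. > 2 is the adopted comfortably-safe criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .egg_models import (
    EggGeometry,
    EggRecord,
    Material,
    SpeciesRecord,
    ThinShellWarning,
)
from . import shell_solver
from .shell_solver import SolverError

__all__ = [
    "IncubationAssessment",
    "SexSpecificFS",
    "c_number",
    "critical_thickness",
    "factor_of_safety",
    "classify_fs",
    "assess_egg",
    "assess_species",
    "SAFE_FS",
    "UNSAFE_FS",
]

#: F.S. above which contact incubation is considered comfortably safe
SAFE_FS = 2.0
#: F.S. below which the egg cannot support the incubating parent
UNSAFE_FS = 1.0

#: default meridian elements for the nonlinear critical-thickness search
#: (convergence of the buckling load is ~0.1% against a doubled mesh)
_BUCKLING_ELEMENTS = 200


@dataclass(frozen=True)
class IncubationAssessment:
    """Full mechanical assessment of one egg under one incubator mass."""

    C: float
    t_cr: float  # mm
    C_cr: float
    FS: float
    incubator_mass: float  # kg
    classification: str  # "safe" | "marginal" | "unsafe"
    K_full: float  # N/m, at nominal thickness
    K_full_critical: float  # N/m, at t_cr

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "t_cr_mm": self.t_cr,
            "C_cr": self.C_cr,
            "FS": self.FS,
            "incubator_mass_kg": self.incubator_mass,
            "classification": self.classification,
            "K_full_N_per_m": self.K_full,
            "K_full_critical_N_per_m": self.K_full_critical,
        }


@dataclass(frozen=True)
class SexSpecificFS:
    """Factor-of-safety ranges per incubating sex.

    For each sex the F.S. is evaluated at both body-mass endpoints; the
    minimum mass gives the larger (more favorable) F.S.  Monomorphic
    species carry only the female entries, which stand for the species
    range.
    """

    species: str
    dimorphism_class: str
    female_fs_at_max_mass: float
    female_fs_at_min_mass: float
    male_fs_at_max_mass: Optional[float] = None
    male_fs_at_min_mass: Optional[float] = None

    @property
    def _lighter_is_male(self) -> bool:
        # reversed dimorphism: females larger, so the male is the lighter
        # sex; under conventional dimorphism or monomorphism the female
        # entries are the lighter (or only) range
        return self.dimorphism_class == "RSSD" and self.male_fs_at_max_mass is not None

    @property
    def lighter_sex_best_fs(self) -> float:
        """F.S. in the most favorable case: the lighter sex at its
        minimum recorded mass."""
        if self._lighter_is_male:
            return self.male_fs_at_min_mass
        return self.female_fs_at_min_mass

    @property
    def lighter_sex_worst_fs(self) -> float:
        """F.S. for the lighter sex at its maximum recorded mass — below
        the safe threshold, not even the lighter sex can incubate with a
        comfortable margin across its whole size range."""
        if self._lighter_is_male:
            return self.male_fs_at_max_mass
        return self.female_fs_at_max_mass

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "dimorphism_class": self.dimorphism_class,
            "female_fs_at_max_mass": self.female_fs_at_max_mass,
            "female_fs_at_min_mass": self.female_fs_at_min_mass,
            "male_fs_at_max_mass": self.male_fs_at_max_mass,
            "male_fs_at_min_mass": self.male_fs_at_min_mass,
        }


def c_number(geometry: EggGeometry, K_full: float, egg_weight_N: float) -> float:
    """Dimensionless stiffness number C = A^2 K / (B W).

    Parameters
    ----------
    geometry : EggGeometry
        Egg dimensions (mm); A = equatorial width, B = polar length.
    K_full : float
        Full-egg apex-load stiffness, N/m.
    egg_weight_N : float
        Weight of the egg, N.
    """
    if K_full <= 0:
        raise ValueError("stiffness must be positive")
    if egg_weight_N <= 0:
        raise ValueError("egg weight must be positive")
    A = geometry.width_equatorial / 1000.0
    B = geometry.length_polar / 1000.0
    return A * A * K_full / (B * egg_weight_N)


def classify_fs(fs: float) -> str:
    """Safety classification: safe (>2), marginal ([1, 2]), unsafe (<1)."""
    if fs > SAFE_FS:
        return "safe"
    if fs >= UNSAFE_FS:
        return "marginal"
    return "unsafe"


def factor_of_safety(C: float, C_cr: float) -> tuple[float, str]:
    """F.S. = C / C_cr with its safety classification."""
    if C_cr <= 0:
        raise ValueError("critical C must be positive")
    fs = C / C_cr
    return fs, classify_fs(fs)


def _buckling_load(geometry: EggGeometry, material: Material,
                   thickness_mm: float, criterion: str,
                   incubator_weight: float, n_elements: int) -> float:
    """Buckling load (N) of the egg at the given shell thickness."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ThinShellWarning)
        geo = geometry.with_thickness(thickness_mm)
    mesh = shell_solver.mesh_half_egg(geo, n_elements)
    if criterion == "deflection":
        return shell_solver.apex_reaction_at_deflection(
            mesh, material, thickness_mm / 1000.0
        )
    if criterion == "bifurcation":
        res = shell_solver.nonlinear_buckling_load(
            mesh, material, target_load=incubator_weight
        )
        # if the target was carried, report a value above the target
        return res.buckling_load if not res.reached_target \
            else max(res.buckling_load, incubator_weight)
    if criterion == "eigen":
        res = shell_solver.buckling_load_factor(mesh, material,
                                                incubator_weight)
        return res.buckling_load
    raise ValueError(f"unknown buckling criterion {criterion!r}")


def critical_thickness(
    geometry: EggGeometry,
    material: Material,
    incubator_mass: float,
    criterion: str = "deflection",
    rtol: float = 1e-3,
    n_elements: int = _BUCKLING_ELEMENTS,
) -> float:
    """Minimum shell thickness (mm) that carries the parent's weight.

    The incubating parent of mass ``incubator_mass`` (kg) presses on the
    egg pole with its full weight; the critical thickness is the smallest
    uniform shell thickness whose buckling load equals that weight, found
    by root bracketing and bisection on the thickness.

    ``criterion`` selects the buckling definition:

    * ``"deflection"`` (default) — load at which the apex of the half
      model has deflected inward by one shell thickness (onset of dimple
      inversion).  This is the criterion consistent with published
      factor-of-safety values for eggs of known geometry.
    * ``"bifurcation"`` — first non-axisymmetric bifurcation (or
      axisymmetric limit point) along the nonlinear dimple path.
    * ``"eigen"`` — classical linearized eigenvalue buckling.  Both
      alternatives sit systematically higher (they tolerate a deep,
      fully developed dimple), yielding ~2-3x larger safety factors.
    """
    if incubator_mass <= 0:
        raise ValueError("incubator mass must be positive")
    W = incubator_mass * material.gravity

    def excess(log_t: float) -> float:
        t_mm = math.exp(log_t)
        return math.log(_buckling_load(geometry, material, t_mm, criterion,
                                       W, n_elements) / W)

    # bracket the root starting from the nominal thickness, using the
    # t^2-ish scaling of the buckling load to take the first guess
    t0 = geometry.thickness
    f0 = excess(math.log(t0))
    step = math.log(1.6)
    lo = hi = math.log(t0)
    flo = fhi = f0
    for _ in range(40):
        if flo > 0 and fhi > 0:  # shell too strong; search thinner
            lo -= step
            flo = excess(lo)
        elif flo < 0 and fhi < 0:  # too weak; search thicker
            hi += step
            fhi = excess(hi)
        else:
            break
    else:  # pragma: no cover
        raise SolverError("failed to bracket the critical thickness")
    if flo == 0:
        return math.exp(lo)
    if fhi == 0:
        return math.exp(hi)
    log_t_cr = brentq(excess, lo, hi, rtol=rtol / 2)
    return float(math.exp(log_t_cr))


def assess_egg(
    egg: EggRecord,
    material: Material,
    incubator_mass: float,
    criterion: str = "deflection",
    stiffness: Optional[float] = None,
    n_elements: int = 400,
) -> IncubationAssessment:
    """Full assessment chain for one egg under one incubator mass.

    Solves the apex-load stiffness at the nominal thickness (unless a
    precomputed ``stiffness`` in N/m is supplied), forms C, finds the
    critical thickness for the incubator's weight, re-solves the
    stiffness at that thickness to obtain C_cr, and returns the factor
    of safety F.S. = C / C_cr with its classification.
    """
    geo = egg.geometry
    W_egg = egg.egg_weight
    if stiffness is None:
        mesh = shell_solver.mesh_half_egg(geo, n_elements)
        stiffness = shell_solver.linear_stiffness(mesh, material).K_full
    C = c_number(geo, stiffness, W_egg)

    t_cr = critical_thickness(geo, material, incubator_mass,
                              criterion=criterion)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ThinShellWarning)
        geo_cr = geo.with_thickness(t_cr)
    mesh_cr = shell_solver.mesh_half_egg(geo_cr, n_elements)
    K_cr = shell_solver.linear_stiffness(mesh_cr, material).K_full
    C_cr = c_number(geo, K_cr, W_egg)
    fs, label = factor_of_safety(C, C_cr)
    return IncubationAssessment(
        C=C,
        t_cr=t_cr,
        C_cr=C_cr,
        FS=fs,
        incubator_mass=incubator_mass,
        classification=label,
        K_full=stiffness,
        K_full_critical=K_cr,
    )


def assess_species(
    record: SpeciesRecord,
    material: Material,
    criterion: str = "deflection",
) -> SexSpecificFS:
    """Sex-resolved factor-of-safety ranges for one species.

    Runs the full chain at every recorded body-mass endpoint (female
    max/min and, for dimorphic species, male max/min) against the
    species' own egg.  Incubation safety is then judged per sex: in
    reversed size dimorphism (RSSD) the lighter male typically incubates.
    """
    mesh = shell_solver.mesh_half_egg(record.egg.geometry, 400)
    K = shell_solver.linear_stiffness(mesh, material).K_full

    def fs_at(mass: float) -> float:
        return assess_egg(record.egg, material, mass, criterion=criterion,
                          stiffness=K).FS

    female_max = fs_at(record.female_mass_max)
    female_min = fs_at(record.female_mass_min)
    male_max = male_min = None
    if record.male_mass_max is not None:
        male_max = fs_at(record.male_mass_max)
        male_min = fs_at(record.male_mass_min)
    return SexSpecificFS(
        species=record.species,
        dimorphism_class=record.dimorphism_class,
        female_fs_at_max_mass=female_max,
        female_fs_at_min_mass=female_min,
        male_fs_at_max_mass=male_max,
        male_fs_at_min_mass=male_min,
    )
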