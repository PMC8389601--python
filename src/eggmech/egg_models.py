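"""Domain types for eggs, species and shell material, plus basic egg arithmetic.

Geometry follows the prolate-ellipsoid idealization of an avian egg: a
surface of revolution about the long (polar) axis with uniform shell
thickness.  Dimensions are carried in the field's customary units
(millimetres for shell geometry, grams for egg mass, kilograms for body
mass); the mechanics modules convert to SI at their boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "STANDARD_GRAVITY",
    "EggGeometry",
    "EggRecord",
    "SpeciesRecord",
    "Material",
    "ThinShellWarning",
    "hoyt_egg_mass",
    "egg_weight",
    "egg_size_ratio",
    "pole_curvature_radius",
]

#: standard acceleration of free fall, m s^-2
STANDARD_GRAVITY = 9.81

#: Hoyt weight coefficient k_w, g cm^-3 (mass = k_w * L * B^2 in cm)
HOYT_COEFFICIENT = 0.548


class ThinShellWarning(UserWarning):
    """Shell thickness outside the thin-shell regime (t >= width/10)."""


@dataclass(frozen=True)
class EggGeometry:
    """Prolate-ellipsoidal egg with uniform shell thickness.

    Parameters
    ----------
    length_polar : float
        Polar (major-axis) diameter, mm.
    width_equatorial : float
        Equatorial (minor-axis) diameter, mm.
    thickness : float
        Uniform shell thickness, mm.
    """

    length_polar: float
    width_equatorial: float
    thickness: float

    def __post_init__(self) -> None:
        if self.length_polar <= 0 or self.width_equatorial <= 0 or self.thickness <= 0:
            raise ValueError("egg dimensions and thickness must be positive")
        if self.length_polar < self.width_equatorial:
            raise ValueError(
                "length_polar must be >= width_equatorial (prolate or spherical egg)"
            )
        if self.thickness >= self.width_equatorial / 10.0:
            warnings.warn(
                f"thickness {self.thickness} mm is not small against the "
                f"equatorial width {self.width_equatorial} mm; thin-shell "
                "assumptions degrade",
                ThinShellWarning,
                stacklevel=2,
            )

    @property
    def elongation(self) -> float:
        """Aspect ratio length/width (1 for a sphere)."""
        return self.length_polar / self.width_equatorial

    @property
    def semi_axis_polar(self) -> float:
        """Semi-major axis a, mm."""
        return self.length_polar / 2.0

    @property
    def semi_axis_equatorial(self) -> float:
        """Semi-minor axis b, mm."""
        return self.width_equatorial / 2.0

    def with_thickness(self, thickness: float) -> "EggGeometry":
        """Same outer dimensions with a different shell thickness."""
        return EggGeometry(self.length_polar, self.width_equatorial, thickness)


@dataclass(frozen=True)
class Material:
    """Linear-elastic, isotropic shell material plus physical constants.

    Defaults are calcite-like eggshell values: E = 30 GPa, nu = 0.307.
    ``hoyt_coefficient`` is the empirical weight coefficient k_w of
    Hoyt's egg-mass equation, g cm^-3.
    """

    elastic_modulus: float = 30e9
    poisson_ratio: float = 0.307
    gravity: float = STANDARD_GRAVITY
    hoyt_coefficient: float = HOYT_COEFFICIENT

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")


@dataclass(frozen=True)
class EggRecord:
    """An egg: geometry plus mass.  Weight (N) is derived from the mass."""

    geometry: EggGeometry
    egg_mass: float  # g
    label: str = ""
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.egg_mass <= 0:
            raise ValueError("egg mass must be positive")

    @property
    def egg_weight(self) -> float:
        """Weight of the egg, N."""
        return egg_weight(self.egg_mass, self.gravity)


@dataclass(frozen=True)
class SpeciesRecord:
    """A species with its egg and sex-specific adult body masses.

    ``dimorphism_class`` is one of ``"none"`` (monomorphic), ``"RSSD"``
    (reversed sexual size dimorphism: females larger, males typically
    incubate) or ``"SSD"`` (males larger).  Monomorphic species carry only
    the female columns, which then stand for the species-level range.
    """

    species: str
    egg: EggRecord
    dimorphism_class: str
    female_mass_max: float
    female_mass_min: float
    male_mass_max: Optional[float] = None
    male_mass_min: Optional[float] = None
    extinct: bool = False
    group: str = ""

    def __post_init__(self) -> None:
        if self.dimorphism_class not in ("none", "RSSD", "SSD"):
            raise ValueError(f"unknown dimorphism class {self.dimorphism_class!r}")
        masses = [self.female_mass_max, self.female_mass_min]
        if self.male_mass_max is not None:
            masses += [self.male_mass_max, self.male_mass_min]
        if not masses or any(m is None or m <= 0 for m in masses):
            raise ValueError("all provided body masses must be positive")
        if self.dimorphism_class == "none" and self.male_mass_max is not None:
            raise ValueError("monomorphic species must not carry male masses")

    @property
    def body_masses(self) -> list[float]:
        """All recorded adult body-mass endpoints, kg."""
        out = [self.female_mass_max, self.female_mass_min]
        if self.male_mass_max is not None:
            out += [self.male_mass_max, self.male_mass_min]
        return out

    @property
    def mean_body_mass(self) -> float:
        """Average of the recorded body-mass endpoints, kg."""
        masses = self.body_masses
        return sum(masses) / len(masses)


def hoyt_egg_mass(
    length_polar: float,
    width_equatorial: float,
    hoyt_coefficient: float = HOYT_COEFFICIENT,
) -> float:
    """Estimate fresh egg mass (g) from length and width via Hoyt's equation.

    mass = k_w * L * B**2 with L, B in cm and k_w in g cm^-3.

    Parameters
    ----------
    length_polar, width_equatorial : float
        Egg length and width, mm.
    hoyt_coefficient : float
        Weight coefficient k_w, g cm^-3 (default 0.548).
    """
    if length_polar <= 0 or width_equatorial <= 0:
        raise ValueError("egg dimensions must be positive")
    return hoyt_coefficient * (length_polar / 10.0) * (width_equatorial / 10.0) ** 2


def egg_weight(egg_mass: float, gravity: float = STANDARD_GRAVITY) -> float:
    """Weight (N) of an egg of mass ``egg_mass`` grams."""
    if egg_mass < 0:
        raise ValueError("egg mass must be non-negative")
    return egg_mass / 1000.0 * gravity


def egg_size_ratio(egg_mass: float, body_masses: Sequence[float]) -> float:
    """Egg size ratio: egg mass divided by the average adult body mass.

    Parameters
    ----------
    egg_mass : float
        Egg mass, g.
    body_masses : sequence of float
        Adult body-mass endpoints, kg; the average is used.

    Returns
    -------
    float
        Dimensionless fraction (0.02 for an egg 2% of body mass).
    """
    if len(body_masses) == 0:
        raise ValueError("body_masses must be non-empty")
    if any(m <= 0 for m in body_masses):
        raise ValueError("body masses must be positive")
    mean_mass = sum(body_masses) / len(body_masses)
    return (egg_mass / 1000.0) / mean_mass


def pole_curvature_radius(geometry: EggGeometry) -> float:
    """Principal radius of curvature (mm) at the pole of the ellipsoid.

    Both principal curvatures coincide at the pole of a surface of
    revolution; for semi-axes a (polar) and b (equatorial) the common
    radius is R = b**2 / a.  Equals the radius exactly for a sphere.
    """
    a = geometry.semi_axis_polar
    b = geometry.semi_axis_equatorial
    return b * b / a
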