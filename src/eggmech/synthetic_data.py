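"""Synthetic eggs and multi-species assemblages for pipeline testing.

The allometric analyses were designed for a background dataset of
hundreds of bird species spanning roughly five orders of magnitude in
body mass, which is not packaged here.  This module generates synthetic
stand-ins with the statistical structure those analyses assume:

* :func:`generate_assemblage` — species-level values of the stiffness
  number C and its critical value C_cr scattered log-normally about
  configurable power-law trends of body mass, with body masses sampled
  log-uniformly (guaranteeing coverage of the extremes that drive the
  trend-intersection estimate).
* :func:`generate_synthetic_egg` — a single egg whose mass and shell
  thickness follow configurable power laws of body mass with log-normal
  noise, dimensions consistent with Hoyt's equation at a fixed
  elongation.

Default trend levels mirror the empirical picture for birds: C near
15,000 at the geometric-mean mass with a slightly negative slope, and a
C_cr trend rising to cross C at 2,000 kg (the contact-incubation limit).
The egg scaling defaults (mass exponent 0.77, thickness exponent 0.456
against egg mass) are conventional interspecific values; they are
package choices, configurable, not measurements.

All sampling is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .egg_models import EggGeometry, EggRecord, hoyt_egg_mass

__all__ = [
    "AssemblageConfig",
    "EggScalingConfig",
    "generate_assemblage",
    "generate_synthetic_egg",
]


@dataclass(frozen=True)
class AssemblageConfig:
    """Configuration of a synthetic multi-species assemblage.

    Trends are straight lines in log10(C) versus log10(body mass in kg).
    The C line is set by its slope and its level at the geometric-mean
    mass of the sampled range; the C_cr line is set by its slope and the
    mass at which it crosses the C line (where the predicted factor of
    safety reaches one).
    """

    n_species: int = 463
    log10_mass_min_g: float = 0.5  # ~3 g
    log10_mass_max_g: float = 5.8  # ~630 kg
    c_slope: float = -0.05
    c_at_geometric_mean: float = 15000.0
    ccr_slope: float = 0.15
    crossing_mass_kg: float = 2000.0
    sigma_log10_c: float = 0.15
    sigma_log10_ccr: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 10:
            raise ValueError("assemblage needs at least 10 species")
        if self.sigma_log10_c < 0 or self.sigma_log10_ccr < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.log10_mass_max_g <= self.log10_mass_min_g:
            raise ValueError("empty body-mass range")
        if self.c_slope == self.ccr_slope:
            raise ValueError("equal trend slopes never cross")
        if self.crossing_mass_kg <= 0 or self.c_at_geometric_mean <= 0:
            raise ValueError("crossing mass and C level must be positive")

    @property
    def mean_log10_mass_kg(self) -> float:
        return (self.log10_mass_min_g + self.log10_mass_max_g) / 2.0 - 3.0

    @property
    def c_intercept(self) -> float:
        """log10 C at 1 kg."""
        return math.log10(self.c_at_geometric_mean) - self.c_slope * self.mean_log10_mass_kg

    @property
    def ccr_intercept(self) -> float:
        """log10 C_cr at 1 kg, anchored so the trends cross as configured."""
        xc = math.log10(self.crossing_mass_kg)
        log_c_at_crossing = self.c_intercept + self.c_slope * xc
        return log_c_at_crossing - self.ccr_slope * xc


def generate_assemblage(config: AssemblageConfig = AssemblageConfig()) -> pd.DataFrame:
    """Sample a synthetic assemblage of (body mass, C, C_cr) triples.

    Returns a DataFrame with columns ``species``, ``body_mass_g``, ``C``
    and ``C_cr`` — the schema accepted by the background-dataset import
    of the upper-limit analysis — deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    log_mass_g = rng.uniform(config.log10_mass_min_g, config.log10_mass_max_g, n)
    x = log_mass_g - 3.0  # log10 kg
    log_c = (config.c_intercept + config.c_slope * x
             + rng.normal(0.0, config.sigma_log10_c, n))
    log_ccr = (config.ccr_intercept + config.ccr_slope * x
               + rng.normal(0.0, config.sigma_log10_ccr, n))
    return pd.DataFrame(
        {
            "species": [f"synthetic_{i:04d}" for i in range(n)],
            "body_mass_g": 10.0**log_mass_g,
            "C": 10.0**log_c,
            "C_cr": 10.0**log_ccr,
        }
    )


@dataclass(frozen=True)
class EggScalingConfig:
    """Power-law scaling of egg properties with body mass.

    ``egg_mass = egg_mass_coeff * (body_mass_g) ** egg_mass_exponent`` (g)
    and ``thickness = thickness_coeff * (egg_mass_g) ** thickness_exponent``
    (mm), each with independent log-normal scatter; egg length and width
    follow from the egg mass through Hoyt's equation at the configured
    elongation, so generated eggs are Hoyt-consistent by construction.
    """

    egg_mass_coeff: float = 0.277
    egg_mass_exponent: float = 0.77
    thickness_coeff: float = 0.0513
    thickness_exponent: float = 0.456
    elongation: float = 1.4
    sigma_log10_egg_mass: float = 0.05
    sigma_log10_thickness: float = 0.05
    hoyt_coefficient: float = 0.548

    def __post_init__(self) -> None:
        if self.egg_mass_coeff <= 0 or self.thickness_coeff <= 0:
            raise ValueError("scaling coefficients must be positive")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1 (prolate egg)")
        if self.sigma_log10_egg_mass < 0 or self.sigma_log10_thickness < 0:
            raise ValueError("noise SDs must be non-negative")


def generate_synthetic_egg(
    body_mass: float,
    config: EggScalingConfig = EggScalingConfig(),
    seed: int | np.random.Generator = 0,
) -> EggRecord:
    """One synthetic egg for a bird of ``body_mass`` kg.

    Deterministic for a fixed integer seed; pass a Generator to draw
    several distinct eggs reproducibly.
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mass_g = body_mass * 1000.0
    egg_mass = config.egg_mass_coeff * mass_g**config.egg_mass_exponent
    egg_mass *= 10.0 ** rng.normal(0.0, config.sigma_log10_egg_mass)
    thickness = config.thickness_coeff * egg_mass**config.thickness_exponent
    thickness *= 10.0 ** rng.normal(0.0, config.sigma_log10_thickness)

    # invert Hoyt's equation at fixed elongation: m = k_w * e * B^3 (cm)
    width_cm = (egg_mass / (config.hoyt_coefficient * config.elongation)) ** (1 / 3)
    width = width_cm * 10.0
    length = config.elongation * width
    geometry = EggGeometry(length, width, thickness)
    # restate the mass through Hoyt so the record is exactly consistent
    egg_mass = hoyt_egg_mass(length, width, config.hoyt_coefficient)
    return EggRecord(geometry, egg_mass, label=f"synthetic egg ({body_mass} kg)")
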