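"""Log-log allometric fits and the contact-incubation body-mass limit.

Traits that scale as power laws of body mass, y = c * M^a, are fitted as
straight lines on double-logarithmic axes by ordinary least squares of
log10(y) on log10(M), the convention used for interspecific trend lines.
The mass at which the fitted trends of the stiffness number C and its
critical value C_cr cross is where the predicted factor of safety drops
to one — the theoretical upper body-mass limit for contact incubation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .egg_models import SpeciesRecord

__all__ = [
    "AllometricFit",
    "IntersectionResult",
    "ReproductionTrends",
    "fit_loglog",
    "intersection_mass",
    "fit_reproduction_trends",
]


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of log10(response) on log10(body mass).

    ``slope`` and ``intercept`` are on the log10 scale (the power-law
    exponent and log10 of the prefactor).  Confidence half-widths are
    parametric 95% intervals from the t distribution.
    """

    slope: float
    intercept: float
    residual_sd: float
    n: int
    slope_ci_halfwidth: float
    intercept_ci_halfwidth: float
    slope_var: float
    intercept_var: float
    slope_intercept_cov: float

    def predict_log10(self, log10_mass: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_mass)

    def predict(self, mass: float | np.ndarray) -> np.ndarray:
        return 10.0 ** self.predict_log10(np.log10(mass))

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept_log10": self.intercept,
            "residual_sd_log10": self.residual_sd,
            "n": self.n,
            "slope_ci95_halfwidth": self.slope_ci_halfwidth,
            "intercept_ci95_halfwidth": self.intercept_ci_halfwidth,
        }


@dataclass(frozen=True)
class IntersectionResult:
    """Crossing mass of two allometric lines with a delta-method CI."""

    mass: float  # kg (units of the fitted masses)
    log10_mass: float
    log10_sd: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "mass": self.mass,
            "log10_mass": self.log10_mass,
            "log10_sd": self.log10_sd,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
        }


@dataclass(frozen=True)
class ReproductionTrends:
    """Egg-mass and shell-thickness allometries with per-species residuals."""

    egg_mass_fit: AllometricFit
    thickness_fit: AllometricFit
    egg_mass_residuals: dict[str, float]  # log10 residual per species
    thickness_residuals: dict[str, float]


def fit_loglog(
    body_masses: Sequence[float],
    responses: Sequence[float],
) -> AllometricFit:
    """Fit log10(response) = intercept + slope * log10(mass) by OLS.

    Parameters
    ----------
    body_masses, responses : sequences of positive floats
        Equal length, at least 3 points (2 points leave no residual
        degrees of freedom for the confidence intervals).
    """
    x = np.asarray(body_masses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("body_masses and responses must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 points for a log-log fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("all masses and responses must be positive")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("degenerate fit: all body masses identical")

    res = stats.linregress(lx, ly)
    n = x.size
    dof = n - 2
    resid = ly - (res.intercept + res.slope * lx)
    ssr = float(resid @ resid)
    sigma2 = ssr / dof
    sxx = float(np.sum((lx - lx.mean()) ** 2))
    slope_var = sigma2 / sxx
    intercept_var = sigma2 * (1.0 / n + lx.mean() ** 2 / sxx)
    cov = -lx.mean() * slope_var
    tcrit = stats.t.ppf(0.975, dof)
    return AllometricFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=math.sqrt(sigma2),
        n=n,
        slope_ci_halfwidth=float(tcrit * math.sqrt(slope_var)),
        intercept_ci_halfwidth=float(tcrit * math.sqrt(intercept_var)),
        slope_var=slope_var,
        intercept_var=intercept_var,
        slope_intercept_cov=cov,
    )


def intersection_mass(
    fit_C: AllometricFit,
    fit_Ccr: AllometricFit,
) -> IntersectionResult:
    """Mass where two fitted log-log lines cross.

    log10(M*) = (b2 - b1) / (a1 - a2) for lines y = a_i x + b_i; this is
    the mass at which the predicted F.S. = C/C_cr equals one.  The
    uncertainty of log10(M*) comes from first-order (delta-method) error
    propagation treating the two fits as independent.
    """
    da = fit_C.slope - fit_Ccr.slope
    db = fit_Ccr.intercept - fit_C.intercept
    if abs(da) < 1e-12 * max(1.0, abs(fit_C.slope), abs(fit_Ccr.slope)):
        raise ValueError("fitted lines are parallel: no intersection")
    log_m = db / da

    var_db = fit_C.intercept_var + fit_Ccr.intercept_var
    var_da = fit_C.slope_var + fit_Ccr.slope_var
    # cov(da, db) = cov(a1 - a2, b2 - b1) = -cov(a1,b1) - cov(a2,b2)
    cov_ab = -fit_C.slope_intercept_cov - fit_Ccr.slope_intercept_cov
    var_log_m = (var_db + log_m**2 * var_da + 2 * log_m * cov_ab) / da**2
    sd = math.sqrt(max(var_log_m, 0.0))
    return IntersectionResult(
        mass=10.0**log_m,
        log10_mass=log_m,
        log10_sd=sd,
        ci_low=10.0 ** (log_m - 1.96 * sd),
        ci_high=10.0 ** (log_m + 1.96 * sd),
    )


def fit_reproduction_trends(
    records: Sequence[SpeciesRecord],
    include_kiwis: bool = False,
) -> ReproductionTrends:
    """Egg mass and shell thickness versus body mass across species.

    Kiwis are excluded by default: their egg is roughly a quarter of
    their body mass (versus <5% for most birds), an extreme reproductive
    strategy that would otherwise lever the interspecific trend.
    Residuals are returned per species so that anomalously thin shells
    (negative thickness residuals) can be flagged.
    """
    used = [
        r for r in records
        if include_kiwis or r.group != "kiwi"
    ]
    if len(used) < 3:
        raise ValueError("need at least 3 species for trend fits")
    masses = [r.mean_body_mass for r in used]
    egg_masses = [r.egg.egg_mass for r in used]
    thicknesses = [r.egg.geometry.thickness for r in used]

    fit_m = fit_loglog(masses, egg_masses)
    fit_t = fit_loglog(masses, thicknesses)

    def residuals(fit: AllometricFit, values) -> dict[str, float]:
        out = {}
        for r, v in zip(used, values):
            out[r.species] = float(
                math.log10(v) - fit.predict_log10(math.log10(r.mean_body_mass))
            )
        return out

    return ReproductionTrends(
        egg_mass_fit=fit_m,
        thickness_fit=fit_t,
        egg_mass_residuals=residuals(fit_m, egg_masses),
        thickness_residuals=residuals(fit_t, thicknesses),
    )
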