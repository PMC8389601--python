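"""Orchestration of the full incubation-mechanics analysis.

Three entry points mirror the headline analyses:

* :func:`run_ratite_analysis` — the full stiffness / C / critical
  thickness / factor-of-safety chain for the 18 packaged ratite species,
  resolved by sex and body-mass endpoint, flagging moa whose eggs are
  marginal even for the lighter sex.
* :func:`run_pgom_analysis` — the nine fossil-egg x candidate-parent
  combinations for the putative *Genyornis* oological material.
* :func:`run_upper_limit_analysis` — C and C_cr trends over a
  background assemblage (real or synthetic) and their crossing mass, the
  theoretical upper body-mass limit for contact incubation.

Each run returns an :class:`AnalysisReport` carrying tidy tables plus a
provenance block (package version, material constants, solver settings)
and can serialize itself to CSV + JSON.  Row-level solver failures are
recorded in the table and do not abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .allometry import IntersectionResult, fit_loglog, intersection_mass
from .egg_models import EggRecord, Material, SpeciesRecord
from .metrics import SAFE_FS, assess_egg, classify_fs
from .shell_solver import SolverError, linear_stiffness, mesh_half_egg
from .species_data import load_table1, pgom_combinations
from .synthetic_data import AssemblageConfig, generate_assemblage

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_ratite_analysis",
    "run_pgom_analysis",
    "run_upper_limit_analysis",
]

logger = logging.getLogger("eggmech")


@dataclass(frozen=True)
class PipelineConfig:
    """Material constants and solver settings for a pipeline run."""

    elastic_modulus: float = 30e9  # Pa
    poisson_ratio: float = 0.307
    gravity: float = 9.81  # m s^-2
    criterion: str = "deflection"  # buckling criterion for t_cr
    n_elements: int = 400  # meridian elements for stiffness solves
    stiffness_tol: float = 0.005  # mesh-doubling convergence tolerance
    safe_fs: float = SAFE_FS

    @property
    def material(self) -> Material:
        return Material(
            elastic_modulus=self.elastic_modulus,
            poisson_ratio=self.poisson_ratio,
            gravity=self.gravity,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML 1.1 reads "2.0e10" (no sign) as a string; coerce numerics
        coerced = {
            k: (float(v) if fields[k] == "float" and v is not None else v)
            for k, v in raw.items()
        }
        return cls(**coerced)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    """Results of one pipeline run: tidy tables plus provenance."""

    species_table: Optional[pd.DataFrame] = None
    pgom_table: Optional[pd.DataFrame] = None
    fit_summaries: dict = field(default_factory=dict)
    intersection: Optional[IntersectionResult] = None
    flagged_marginal_moa: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        """Write CSV tables and a JSON summary into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.species_table is not None:
            self.species_table.to_csv(out / "species_assessments.csv", index=False)
        if self.pgom_table is not None:
            self.pgom_table.to_csv(out / "pgom_assessments.csv", index=False)
        summary = {
            "fits": self.fit_summaries,
            "intersection": (self.intersection.to_dict()
                             if self.intersection else None),
            "flagged_marginal_moa": self.flagged_marginal_moa,
            "provenance": self.provenance,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def _provenance(config: PipelineConfig, **extra) -> dict:
    return {"package_version": _pkg_version, "config": config.to_dict(), **extra}


def _assess_rows(egg: EggRecord, material, incubator_masses, criterion,
                 stiffness: float, base: dict) -> list[dict]:
    """One tidy row per incubator-mass entry; failures become error rows."""
    rows = []
    for sex, endpoint, mass in incubator_masses:
        row = dict(base, sex=sex, mass_endpoint=endpoint,
                   incubator_mass_kg=mass)
        try:
            a = assess_egg(egg, material, mass, criterion=criterion,
                           stiffness=stiffness)
            row.update(
                K_full_N_per_mm=a.K_full / 1000.0,
                K_half_N_per_mm=a.K_full * 2.0 / 1000.0,
                C=a.C,
                t_cr_mm=a.t_cr,
                C_cr=a.C_cr,
                FS=a.FS,
                classification=a.classification,
                error="",
            )
        except (SolverError, ValueError) as exc:
            logger.warning("assessment failed for %s (%s %s): %s",
                           base.get("species", "?"), sex, endpoint, exc)
            row.update(K_full_N_per_mm=np.nan, K_half_N_per_mm=np.nan,
                       C=np.nan, t_cr_mm=np.nan, C_cr=np.nan, FS=np.nan,
                       classification="error", error=str(exc))
        rows.append(row)
    return rows


def run_ratite_analysis(
    config: PipelineConfig = PipelineConfig(),
    records: Optional[Sequence[SpeciesRecord]] = None,
) -> AnalysisReport:
    """Full chain for the packaged ratite table (or supplied records).

    Produces one row per species x sex x body-mass endpoint and flags
    the RSSD moa species whose factor of safety falls below the safe
    threshold even for the lighter (male) sex across its recorded mass
    range.
    """
    if records is None:
        records = load_table1()
    material = config.material
    rows: list[dict] = []
    for rec in records:
        logger.info("assessing %s", rec.species)
        base = dict(species=rec.species, group=rec.group,
                    dimorphism=rec.dimorphism_class, extinct=rec.extinct)
        try:
            mesh = mesh_half_egg(rec.egg.geometry, config.n_elements)
            K = linear_stiffness(mesh, material,
                                 tol=config.stiffness_tol).K_full
        except (SolverError, ValueError) as exc:
            logger.warning("stiffness solve failed for %s: %s",
                           rec.species, exc)
            rows.append(dict(base, sex="", mass_endpoint="", C=np.nan,
                             FS=np.nan, classification="error",
                             error=str(exc)))
            continue
        masses = [("female", "max", rec.female_mass_max),
                  ("female", "min", rec.female_mass_min)]
        if rec.male_mass_max is not None:
            masses += [("male", "max", rec.male_mass_max),
                       ("male", "min", rec.male_mass_min)]
        rows.extend(_assess_rows(rec.egg, material, masses,
                                 config.criterion, K, base))
    table = pd.DataFrame(rows)

    # Flag RSSD moa for which even incubation by the lighter sex (the male)
    # cannot guarantee the safe margin across its recorded mass range,
    # i.e. the male F.S. at the maximum male mass falls below the threshold.
    flagged: list[str] = []
    if len(table):
        for rec in records:
            if rec.group != "moa" or rec.male_mass_max is None:
                continue
            sub = table[(table.species == rec.species)
                        & (table.sex == "male")
                        & (table.mass_endpoint == "max")
                        & (table.classification != "error")]
            if len(sub) and float(sub.FS.iloc[0]) < config.safe_fs:
                flagged.append(rec.species)

    return AnalysisReport(
        species_table=table,
        flagged_marginal_moa=flagged,
        provenance=_provenance(config, analysis="ratite"),
    )


def run_pgom_analysis(config: PipelineConfig = PipelineConfig()) -> AnalysisReport:
    """Factor of safety for all nine PGOM egg x candidate combinations."""
    material = config.material
    rows = []
    stiffness_cache: dict[str, float] = {}
    for combo in pgom_combinations():
        if combo.egg_label not in stiffness_cache:
            mesh = mesh_half_egg(combo.geometry, config.n_elements)
            stiffness_cache[combo.egg_label] = linear_stiffness(
                mesh, material, tol=config.stiffness_tol
            ).K_full
        K = stiffness_cache[combo.egg_label]
        base = dict(egg=combo.egg_label, candidate=combo.candidate,
                    egg_mass_g=combo.egg_mass,
                    esr_percent=100 * combo.egg_size_ratio)
        rows.extend(_assess_rows(
            combo.egg, material,
            [("", "point", combo.candidate_mass)],
            config.criterion, K, base,
        ))
    table = pd.DataFrame(rows).drop(columns=["sex", "mass_endpoint"])
    table["verdict"] = [
        classify_fs(fs) if np.isfinite(fs) else "error" for fs in table.FS
    ]
    return AnalysisReport(
        pgom_table=table,
        provenance=_provenance(config, analysis="pgom"),
    )


def run_upper_limit_analysis(
    background: Optional[pd.DataFrame] = None,
    synthetic_config: Optional[AssemblageConfig] = None,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Crossing mass of the C and C_cr allometric trends.

    ``background`` must have columns ``body_mass_g``, ``C`` and ``C_cr``
    (the schema produced by :func:`eggmech.synthetic_data.generate_assemblage`
    and by the background-CSV import); if omitted, a synthetic assemblage
    is generated from ``synthetic_config``.
    """
    if background is None:
        synthetic_config = synthetic_config or AssemblageConfig()
        background = generate_assemblage(synthetic_config)
    required = {"body_mass_g", "C", "C_cr"}
    if not required.issubset(background.columns):
        raise ValueError(f"background data needs columns {sorted(required)}")
    if len(background) < 10:
        raise ValueError("need at least 10 background species")
    mass_kg = background["body_mass_g"].to_numpy() / 1000.0
    fit_c = fit_loglog(mass_kg, background["C"].to_numpy())
    fit_ccr = fit_loglog(mass_kg, background["C_cr"].to_numpy())
    inter = intersection_mass(fit_c, fit_ccr)
    return AnalysisReport(
        fit_summaries={"C": fit_c.to_dict(), "C_cr": fit_ccr.to_dict()},
        intersection=inter,
        provenance=_provenance(
            config,
            analysis="upper_limit",
            n_background=int(len(background)),
            synthetic=(synthetic_config.to_dict()
                       if hasattr(synthetic_config, "to_dict")
                       else dataclasses.asdict(synthetic_config)
                       if synthetic_config else None),
        ),
    )
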