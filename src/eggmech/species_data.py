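"""Packaged reference data: ratite egg tables and the PGOM combinations.

Two validated CSV fixtures ship with the package:

* ``table1.csv`` — 18 ratite species (9 extant, 9 extinct) with egg
  geometry, egg mass, and sex-resolved adult body-mass ranges.  "RSSD"
  marks reversed sexual size dimorphism (females larger; males
  incubate), "SSD" conventional dimorphism, "none" monomorphic species
  (no male columns).
* ``table3.csv`` — 13 extant species whose eggs are geometrically close
  to the Spooner egg, with published reference values of the
  dimensionless number C and the factor of safety retained for
  comparison.

The PGOM (putative *Genyornis* oological material) combinations pair the
two fossil egg morphotypes — the Williams egg (155 x 125 mm, shell
1.15 mm) and the Spooner egg (126 x 97 mm, shell 1.3 mm) — plus a third
"additional" specimen (Spooner dimensions with the Williams shell
thickness, in case the Williams egg size was overestimated) with three
candidate parent birds: the giant galloansere *Genyornis newtoni*
(192 kg) and the extinct giant megapodes *Latagallina naracoortensis*
(6.1 kg) and *Progura gallinacea* (7.7 kg).  Egg masses follow Hoyt's
equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import pandas as pd

from .egg_models import (
    EggGeometry,
    EggRecord,
    SpeciesRecord,
    hoyt_egg_mass,
)

__all__ = [
    "PGOMCombination",
    "load_table1",
    "load_table3",
    "pgom_combinations",
    "species_to_frame",
    "frame_to_species",
    "write_species_csv",
    "read_species_csv",
    "DataIntegrityError",
]

TABLE1_COLUMNS = [
    "species", "group", "length_mm", "width_mm", "thickness_mm",
    "egg_mass_g", "fbm_max_kg", "fbm_min_kg", "mbm_max_kg", "mbm_min_kg",
    "dimorphism", "extinct", "esr_percent_printed",
]

#: the three PGOM egg morphotypes: (length, width, thickness), mm
PGOM_EGGS = {
    "Williams": (155.0, 125.0, 1.15),
    "Spooner": (126.0, 97.0, 1.3),
    "additional": (126.0, 97.0, 1.15),
}

#: candidate parent species and their body masses, kg
PGOM_CANDIDATES = {
    "Genyornis newtoni": 192.0,
    "Latagallina naracoortensis": 6.1,
    "Progura gallinacea": 7.7,
}


class DataIntegrityError(RuntimeError):
    """A packaged fixture failed its validation checks."""


@dataclass(frozen=True)
class PGOMCombination:
    """One fossil egg paired with one candidate parent species."""

    egg_label: str
    candidate: str
    geometry: EggGeometry
    egg_mass: float  # g, via Hoyt's equation
    candidate_mass: float  # kg

    @property
    def egg(self) -> EggRecord:
        return EggRecord(self.geometry, self.egg_mass,
                         label=f"{self.egg_label} egg")

    @property
    def egg_size_ratio(self) -> float:
        return (self.egg_mass / 1000.0) / self.candidate_mass


def _data_path(name: str) -> Path:
    return Path(str(resources.files("eggmech").joinpath("data", name)))


def _row_to_species(row: pd.Series) -> SpeciesRecord:
    geo = EggGeometry(row["length_mm"], row["width_mm"], row["thickness_mm"])
    egg = EggRecord(geo, row["egg_mass_g"], label=row["species"])
    male_max = row.get("mbm_max_kg")
    male_min = row.get("mbm_min_kg")
    if pd.isna(male_max):
        male_max = male_min = None
    return SpeciesRecord(
        species=row["species"],
        egg=egg,
        dimorphism_class=row["dimorphism"],
        female_mass_max=row["fbm_max_kg"],
        female_mass_min=row["fbm_min_kg"],
        male_mass_max=male_max,
        male_mass_min=male_min,
        extinct=bool(row["extinct"]),
        group=row.get("group", "") or "",
    )


def load_table1() -> list[SpeciesRecord]:
    """The 18 ratite species records (validated on load)."""
    df = pd.read_csv(_data_path("table1.csv"))
    if list(df.columns) != TABLE1_COLUMNS:
        raise DataIntegrityError("table1.csv columns do not match the schema")
    if len(df) != 18:
        raise DataIntegrityError(f"table1.csv must have 18 rows, found {len(df)}")
    records = [_row_to_species(row) for _, row in df.iterrows()]
    # audit: recomputed egg-size ratio must match the printed column
    # (0.05 pp absorbs one rounding slip in the published little-kiwi row)
    for rec, (_, row) in zip(records, df.iterrows()):
        esr = (rec.egg.egg_mass / 1000.0) / rec.mean_body_mass * 100.0
        if abs(esr - row["esr_percent_printed"]) > 0.05:
            raise DataIntegrityError(
                f"ESR audit failed for {rec.species}: "
                f"recomputed {esr:.2f}% vs printed {row['esr_percent_printed']}%"
            )
    return records


def load_table3() -> pd.DataFrame:
    """The 13 comparison species with published reference C and F.S."""
    df = pd.read_csv(_data_path("table3.csv"))
    if len(df) != 13:
        raise DataIntegrityError(f"table3.csv must have 13 rows, found {len(df)}")
    required = {"species", "length_mm", "width_mm", "thickness_mm",
                "egg_mass_g", "body_mass_g", "C_printed", "FS_printed"}
    if not required.issubset(df.columns):
        raise DataIntegrityError("table3.csv is missing required columns")
    return df


def pgom_combinations() -> list[PGOMCombination]:
    """All 9 egg-by-candidate PGOM combinations (3 eggs x 3 candidates)."""
    out = []
    for egg_label, (length, width, t) in PGOM_EGGS.items():
        mass = hoyt_egg_mass(length, width)
        for candidate, body_mass in PGOM_CANDIDATES.items():
            out.append(
                PGOMCombination(
                    egg_label=egg_label,
                    candidate=candidate,
                    geometry=EggGeometry(length, width, t),
                    egg_mass=mass,
                    candidate_mass=body_mass,
                )
            )
    return out


def species_to_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    """Species records as a tidy DataFrame in the fixture CSV schema."""
    rows = []
    for r in records:
        rows.append({
            "species": r.species,
            "group": r.group,
            "length_mm": r.egg.geometry.length_polar,
            "width_mm": r.egg.geometry.width_equatorial,
            "thickness_mm": r.egg.geometry.thickness,
            "egg_mass_g": r.egg.egg_mass,
            "fbm_max_kg": r.female_mass_max,
            "fbm_min_kg": r.female_mass_min,
            "mbm_max_kg": r.male_mass_max,
            "mbm_min_kg": r.male_mass_min,
            "dimorphism": r.dimorphism_class,
            "extinct": r.extinct,
        })
    return pd.DataFrame(rows)


def frame_to_species(df: pd.DataFrame) -> list[SpeciesRecord]:
    """Inverse of :func:`species_to_frame`."""
    return [_row_to_species(row) for _, row in df.iterrows()]


def write_species_csv(records: list[SpeciesRecord], path) -> None:
    species_to_frame(records).to_csv(path, index=False)


def read_species_csv(path) -> list[SpeciesRecord]:
    return frame_to_species(pd.read_csv(path))
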