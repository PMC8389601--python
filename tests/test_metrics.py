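"""Tests for the C number, critical thickness and factor of safety."""

import math

import numpy as np
import pytest

from eggmech import (
    EggGeometry,
    EggRecord,
    Material,
    assess_egg,
    assess_species,
    c_number,
    classify_fs,
    critical_thickness,
    factor_of_safety,
    SpeciesRecord,
)
from eggmech.metrics import _buckling_load


class TestCNumber:
    def test_reproduces_elephant_bird_from_published_stiffness(
        self, elephant_bird_geometry
    ):
        """With the published K = 6605 N/mm and W from the 9120-g egg, the
        A/B assignment must land near the published C ~ 12,000 — this pins
        down which symbol is the width."""
        C = c_number(elephant_bird_geometry, 6.605e6, 9.12 * 9.81)
        assert C == pytest.approx(12000, rel=0.05)

    def test_linear_in_stiffness(self, rhea_geometry):
        c1 = c_number(rhea_geometry, 1e6, 5.0)
        c2 = c_number(rhea_geometry, 2e6, 5.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_zero_weight_rejected(self, rhea_geometry):
        with pytest.raises(ValueError):
            c_number(rhea_geometry, 1e6, 0.0)

    def test_scaling_invariance_under_elastic_similarity(
        self, material, rhea_geometry
    ):
        """C is unchanged within 2% when the egg outline scales by s, the
        shell thickness by s^1.5, and the egg mass by s^3.  (Point-load
        stiffness goes as t^2/R, so this — not uniform scaling — is the
        C-preserving similarity; it also matches how real shell thickness
        scales with egg size, which is why C is comparable across birds
        of vastly different mass.)"""
        from eggmech import linear_stiffness, mesh_half_egg

        def C_of(geo, mass_g):
            K = linear_stiffness(mesh_half_egg(geo, 200), material,
                                 max_refinements=0).K_full
            return c_number(geo, K, mass_g / 1000 * 9.81)

        s = 2.0
        c1 = C_of(rhea_geometry, 525.0)
        scaled = EggGeometry(s * 128.0, s * 86.0, s**1.5 * 0.9)
        c2 = C_of(scaled, s**3 * 525.0)
        # the residual ~1.7% is the genuine t/R boundary-layer correction
        assert c2 == pytest.approx(c1, rel=0.02)


class TestClassification:
    @pytest.mark.parametrize(
        "fs,expected",
        [(2.5, "safe"), (2.0, "marginal"), (1.0, "marginal"),
         (1.5, "marginal"), (0.99, "unsafe")],
    )
    def test_thresholds(self, fs, expected):
        assert classify_fs(fs) == expected

    def test_factor_of_safety_ratio(self):
        fs, label = factor_of_safety(10000.0, 5000.0)
        assert fs == pytest.approx(2.0)
        assert label == "marginal"
        with pytest.raises(ValueError):
            factor_of_safety(1.0, 0.0)


class TestCriticalThickness:
    def test_rhea_value(self, rhea_geometry, material):
        """t_cr for a 23-kg incubator on the rhea egg is near 0.54 mm (the
        value implied by the published F.S. through the t^2 stiffness
        scaling)."""
        t_cr = critical_thickness(rhea_geometry, material, 23.0)
        assert t_cr == pytest.approx(0.54, rel=0.20)

    def test_monotone_in_incubator_mass(self, rhea_geometry, material):
        tcrs = [critical_thickness(rhea_geometry, material, m)
                for m in (10.0, 23.0, 60.0)]
        assert tcrs[0] < tcrs[1] < tcrs[2]

    def test_fixed_point(self, rhea_geometry, material):
        """At t = t_cr the buckling load equals the parent weight."""
        mass = 23.0
        t_cr = critical_thickness(rhea_geometry, material, mass)
        load = _buckling_load(rhea_geometry, material, t_cr, "deflection",
                              mass * 9.81, 200)
        assert load == pytest.approx(mass * 9.81, rel=5e-3)

    def test_invalid_mass(self, rhea_geometry, material):
        with pytest.raises(ValueError):
            critical_thickness(rhea_geometry, material, -5.0)


class TestAssessEgg:
    def test_fs_follows_thickness_squared(self, material):
        """F.S. ~ (t/t_cr)^p with p in [1.8, 2.2]: a consequence of the
        t^2 scaling of shell stiffness at fixed geometry."""
        egg = EggRecord(EggGeometry(128.0, 86.0, 0.9), 525.0)
        a = assess_egg(egg, material, 23.0)
        p = math.log(a.FS) / math.log(0.9 / a.t_cr)
        assert 1.8 <= p <= 2.2

    def test_fs_decreases_with_incubator_mass(self, material):
        egg = EggRecord(EggGeometry(128.0, 86.0, 0.9), 525.0)
        fs = [assess_egg(egg, material, m).FS for m in (15.0, 23.0, 40.0)]
        assert fs[0] > fs[1] > fs[2]

    def test_consistency_of_fs_and_classification(self, material):
        egg = EggRecord(EggGeometry(128.0, 86.0, 0.9), 525.0)
        a = assess_egg(egg, material, 23.0)
        assert a.FS == pytest.approx(a.C / a.C_cr, rel=1e-9)
        assert a.classification == classify_fs(a.FS)


class TestAssessSpecies:
    def test_equal_sex_masses_give_identical_ranges(self, material):
        egg = EggRecord(EggGeometry(128.0, 86.0, 0.9), 525.0)
        rec = SpeciesRecord(
            species="test", egg=egg, dimorphism_class="RSSD",
            female_mass_max=30.0, female_mass_min=20.0,
            male_mass_max=30.0, male_mass_min=20.0,
        )
        fs = assess_species(rec, material)
        assert fs.male_fs_at_max_mass == pytest.approx(
            fs.female_fs_at_max_mass, rel=1e-6
        )
        assert fs.male_fs_at_min_mass == pytest.approx(
            fs.female_fs_at_min_mass, rel=1e-6
        )
        # min mass always gives the larger safety factor
        assert fs.female_fs_at_min_mass >= fs.female_fs_at_max_mass
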