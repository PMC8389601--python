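"""Verification of the axisymmetric shell solver.

The linear solver is checked against the classical closed-form point-load
stiffness of a spherical shell, its own mesh convergence, and physical
scaling laws (stiffness ~ t^2, isometric scaling ~ s).  The harmonic
stability machinery is checked against the classical external-pressure
buckling load of a sphere.
"""

import math

import numpy as np
import pytest

from eggmech import (
    EggGeometry,
    Material,
    apex_reaction_at_deflection,
    buckling_load_factor,
    linear_stiffness,
    mesh_half_egg,
    reissner_stiffness,
)
from eggmech._harmonic import HarmonicModel
from eggmech.shell_solver import _ElementData, _solve_linear


def quick_K(geometry, material, n=200):
    """Single-mesh half-model stiffness (no refinement loop), N/m."""
    data = _ElementData(mesh_half_egg(geometry, n), material)
    K_half, _, _ = _solve_linear(data, 0.1)
    return K_half


class TestMeshHalfEgg:
    def test_nodes_on_circle_for_sphere(self, sphere_geometry):
        mesh = mesh_half_egg(sphere_geometry, 100)
        radius = np.hypot(mesh.r, mesh.z)
        assert np.allclose(radius, 0.05, rtol=1e-12)

    def test_meridian_length_matches_quadrature(self, elephant_bird_geometry):
        mesh = mesh_half_egg(elephant_bird_geometry, 400)
        # independent quarter-perimeter of the ellipse by dense quadrature
        a, b = 0.1515, 0.112
        psi = np.linspace(0.0, math.pi / 2, 200001)
        integrand = np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
        quarter = np.trapezoid(integrand, psi)
        assert mesh.arc[-1] == pytest.approx(quarter, rel=1e-3)

    def test_pole_refinement_ratio(self, rhea_geometry):
        mesh = mesh_half_egg(rhea_geometry, 400, pole_refinement=20.0)
        sizes = np.diff(mesh.arc)
        assert sizes[0] <= sizes[-1] / 20.0 * (1 + 1e-9)

    def test_too_few_elements_rejected(self, rhea_geometry):
        with pytest.raises(ValueError):
            mesh_half_egg(rhea_geometry, 10)


class TestLinearStiffness:
    def test_sphere_matches_closed_form(self, sphere_geometry, material):
        res = linear_stiffness(mesh_half_egg(sphere_geometry, 200), material)
        expected = reissner_stiffness(sphere_geometry, material)
        assert res.K_full == pytest.approx(expected, rel=0.10)
        assert res.converged

    def test_full_is_half_over_two(self, rhea_geometry, material):
        res = linear_stiffness(mesh_half_egg(rhea_geometry, 200), material)
        assert res.K_full == pytest.approx(res.K_half / 2.0, rel=1e-12)

    def test_mesh_convergence_below_half_percent(
        self, elephant_bird_geometry, material
    ):
        res = linear_stiffness(
            mesh_half_egg(elephant_bird_geometry, 400), material, tol=0.005
        )
        assert res.converged
        assert res.relative_change <= 0.005

    def test_load_magnitude_independence(self, rhea_geometry, material):
        mesh = mesh_half_egg(rhea_geometry, 200)
        k1 = linear_stiffness(mesh, material, apex_load=0.1, max_refinements=0)
        k2 = linear_stiffness(mesh, material, apex_load=1.0, max_refinements=0)
        assert k1.K_full == pytest.approx(k2.K_full, rel=1e-9)

    def test_thickness_squared_scaling(self, rhea_geometry, material):
        """log K vs log t slope within [1.8, 2.2] over 0.5-2x nominal."""
        thicknesses = np.array([0.45, 0.9, 1.8])
        ks = [
            quick_K(rhea_geometry.with_thickness(t), material)
            for t in thicknesses
        ]
        slope = np.polyfit(np.log(thicknesses), np.log(ks), 1)[0]
        assert 1.8 <= slope <= 2.2

    def test_isometric_scaling_multiplies_K_by_s(self, rhea_geometry, material):
        s = 2.0
        k1 = quick_K(rhea_geometry, material)
        scaled = EggGeometry(
            s * rhea_geometry.length_polar,
            s * rhea_geometry.width_equatorial,
            s * rhea_geometry.thickness,
        )
        k2 = quick_K(scaled, material)
        assert k2 == pytest.approx(s * k1, rel=1e-3)

    @pytest.mark.parametrize(
        "geometry_mm",
        [(303.0, 224.0, 3.7), (128.0, 86.0, 0.9), (158.0, 131.0, 1.92),
         (110.2, 66.7, 0.92)],
        ids=["elephant-bird", "rhea", "ostrich", "condor"],
    )
    def test_within_30_percent_of_shell_theory(self, geometry_mm, material):
        geo = EggGeometry(*geometry_mm)
        k_fem = quick_K(geo, material) / 2.0
        k_ref = reissner_stiffness(geo, material)
        assert k_fem == pytest.approx(k_ref, rel=0.30)


class TestEigenBuckling:
    def test_load_factor_scales_inversely_with_reference(
        self, rhea_geometry, material
    ):
        mesh = mesh_half_egg(rhea_geometry, 200)
        r1 = buckling_load_factor(mesh, material, 10.0)
        r2 = buckling_load_factor(mesh, material, 20.0)
        assert r2.load_factor == pytest.approx(r1.load_factor / 2.0, rel=1e-6)
        assert r1.buckling_load == pytest.approx(r2.buckling_load, rel=1e-6)

    def test_monotone_in_thickness(self, rhea_geometry, material):
        loads = []
        for t in (0.6, 0.9, 1.3):
            mesh = mesh_half_egg(rhea_geometry.with_thickness(t), 200)
            loads.append(buckling_load_factor(mesh, material, 100.0).buckling_load)
        assert loads[0] < loads[1] < loads[2]

    def test_mesh_convergence(self, rhea_geometry, material):
        l1 = buckling_load_factor(
            mesh_half_egg(rhea_geometry, 400), material, 100.0
        ).buckling_load
        l2 = buckling_load_factor(
            mesh_half_egg(rhea_geometry, 800), material, 100.0
        ).buckling_load
        assert abs(l1 - l2) / l2 <= 0.01


class TestHarmonicStability:
    def test_sphere_pressure_buckling_matches_classical(self, material):
        """Minimum over harmonics of the eigen pressure equals the classical
        2 E t^2 / (R^2 sqrt(3 (1 - nu^2))) within 2%."""
        R, t = 0.05, 0.0005
        mesh = mesh_half_egg(EggGeometry(100.0, 100.0, 0.5), 300,
                             pole_refinement=1.0)
        hm = HarmonicModel(mesh.r, mesh.z, mesh.thickness, material)
        membrane = np.full(hm.jac.shape, -0.5 * R)  # unit pressure state
        p_cr = min(hm.buckling_factor(n, membrane, membrane)
                   for n in range(2, 26, 2))
        classical = (
            2 * material.elastic_modulus * t**2
            / (R**2 * math.sqrt(3 * (1 - material.poisson_ratio**2)))
        )
        assert p_cr == pytest.approx(classical, rel=0.02)


class TestNonlinearBuckling:
    def test_thick_shell_carries_modest_target(self, rhea_geometry, material):
        from eggmech import nonlinear_buckling_load

        mesh = mesh_half_egg(rhea_geometry.with_thickness(1.5), 200)
        res = nonlinear_buckling_load(mesh, material, target_load=200.0)
        assert res.reached_target and res.mode == "carried"
        assert res.buckling_load >= 200.0

    def test_path_traversal_finds_no_spurious_instability(
        self, rhea_geometry, material
    ):
        """The axisymmetric dimple of an apex-loaded egg grows stably well
        past first contact loads: sweeping the path under a very large
        target must report a lower bound far above the parent weight."""
        from eggmech import limit_point_load

        mesh = mesh_half_egg(rhea_geometry, 200)
        curve = limit_point_load(mesh, material, target_load=500.0)
        assert curve.reached_target
        assert np.all(np.diff(curve.load) > 0)


class TestNonlinearResponse:
    def test_reaction_softens_below_linear(self, rhea_geometry, material):
        """At one thickness of deflection the nonlinear reaction must fall
        below the linear extrapolation (the dimple is a softening mode)."""
        mesh = mesh_half_egg(rhea_geometry, 200)
        t = 0.9e-3
        reaction = apex_reaction_at_deflection(mesh, material, t)
        k_half = quick_K(rhea_geometry, material)
        assert reaction < k_half * t
        assert reaction > 0.3 * k_half * t

    def test_small_deflection_recovers_linear_stiffness(
        self, rhea_geometry, material
    ):
        mesh = mesh_half_egg(rhea_geometry, 200)
        delta = 1e-6  # 1/900 of the thickness: effectively linear
        reaction = apex_reaction_at_deflection(mesh, material, delta, n_steps=1)
        k_half = quick_K(rhea_geometry, material)
        assert reaction == pytest.approx(k_half * delta, rel=1e-3)
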