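"""Axisymmetric thin-shell finite elements for apex-loaded eggshells.

The load case of interest — an axial point force at the pole of a shell of
revolution clamped at its equator — is axisymmetric, so the half-egg is
discretized along its meridian only.  Elements are two-node conical
frusta (straight meridian segments) carrying coupled membrane and bending
action with Kirchhoff-Love (shear-rigid) kinematics: the membrane
displacement is interpolated linearly and the normal deflection with
Hermite cubics, giving three degrees of freedom per meridian node
(radial displacement, axial displacement, meridional rotation).  The
curved meridian is recovered in the limit of refinement, exactly as an
arch is recovered from straight beam segments.

Two instability analyses are provided:

* :func:`buckling_load_factor` — classical linearized eigenvalue
  buckling: geometric stiffness from the membrane-force state of the
  linear solve, smallest positive load multiplier.
* :func:`limit_point_load` — geometrically nonlinear (von Karman
  moderate-rotation) displacement-controlled compression of the pole,
  returning the first limit point of the load-deflection curve.  An apex
  point load forms an inward dimple whose response softens strongly well
  below the linearized eigenvalue, so the limit point is the physically
  meaningful buckling load for contact incubation.

All internal mechanics are in SI units (m, N, Pa); egg geometry enters
in mm through :class:`~eggmech.egg_models.EggGeometry` and is converted
once at meshing time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .egg_models import EggGeometry, Material, pole_curvature_radius

__all__ = [
    "ShellMesh",
    "StiffnessResult",
    "BucklingResult",
    "LoadDeflectionCurve",
    "NonlinearBucklingResult",
    "SolverError",
    "mesh_half_egg",
    "linear_stiffness",
    "reissner_stiffness",
    "buckling_load_factor",
    "limit_point_load",
    "nonlinear_buckling_load",
]

MIN_ELEMENTS = 50

# 3-point Gauss rule on [0, 1]
_GAUSS_XI = np.array([0.5 - math.sqrt(0.15), 0.5, 0.5 + math.sqrt(0.15)])
_GAUSS_W = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])


class SolverError(RuntimeError):
    """Raised when the shell solver cannot produce a valid solution."""


@dataclass(frozen=True)
class ShellMesh:
    """Meridian discretization of the upper half of an ellipsoidal shell.

    Nodes run from the pole (r = 0, z = a) to the equator (r = b, z = 0),
    placed exactly on the ellipse, with element arc lengths graded
    geometrically so the pole-adjacent element is ``1/pole_refinement``
    times the equator-adjacent one (the apex-load solution has a boundary
    layer at the pole).  Coordinates are stored in metres.
    """

    geometry: EggGeometry
    arc: np.ndarray  # nodal arc-length coordinate from the pole, m
    r: np.ndarray  # nodal radial coordinate, m
    z: np.ndarray  # nodal axial coordinate, m
    tangent_angle: np.ndarray  # angle of the meridian tangent to the r axis, rad
    thickness: np.ndarray  # per-element thickness, m
    pole_refinement: float

    def __post_init__(self) -> None:
        n = self.n_elements
        if n < MIN_ELEMENTS:
            raise ValueError(f"mesh needs at least {MIN_ELEMENTS} elements, got {n}")
        if self.r[0] != 0.0:
            raise ValueError("first node must sit on the pole (r = 0)")
        if abs(self.z[-1]) > 1e-12 * self.arc[-1]:
            raise ValueError("last node must sit on the equator (z = 0)")
        if np.any(np.diff(self.arc) <= 0):
            raise ValueError("nodes must be strictly ordered in arc length")
        if np.any(self.thickness <= 0):
            raise ValueError("element thickness must be positive")

    @property
    def n_nodes(self) -> int:
        return self.r.size

    @property
    def n_elements(self) -> int:
        return self.r.size - 1

    def refined(self, factor: int = 2) -> "ShellMesh":
        """Re-mesh the same geometry with ``factor`` times more elements."""
        return mesh_half_egg(
            self.geometry, self.n_elements * factor, self.pole_refinement
        )


@dataclass(frozen=True)
class StiffnessResult:
    """Apex-load stiffness of the half model and the derived full-egg value."""

    K_half: float  # N/m
    K_full: float  # N/m, = K_half / 2 (two half-shells in series)
    apex_displacement: float  # m, under the applied reference load
    apex_load: float  # N
    n_elements: int
    converged: bool
    relative_change: float

    def to_dict(self) -> dict:
        return {
            "K_half_N_per_m": self.K_half,
            "K_full_N_per_m": self.K_full,
            "apex_displacement_m": self.apex_displacement,
            "apex_load_N": self.apex_load,
            "n_elements": self.n_elements,
            "converged": self.converged,
            "relative_change": self.relative_change,
        }


@dataclass(frozen=True)
class BucklingResult:
    """Lowest positive buckling multiplier of a reference apex load."""

    load_factor: float  # dimensionless multiplier of reference_load
    reference_load: float  # N
    mode_peak_arc_fraction: float  # arc position of max mode amplitude / length
    n_elements: int

    @property
    def buckling_load(self) -> float:
        """Predicted instability load, N."""
        return self.load_factor * self.reference_load

    def to_dict(self) -> dict:
        return {
            "load_factor": self.load_factor,
            "reference_load_N": self.reference_load,
            "buckling_load_N": self.buckling_load,
            "mode_peak_arc_fraction": self.mode_peak_arc_fraction,
            "n_elements": self.n_elements,
        }


@dataclass(frozen=True)
class LoadDeflectionCurve:
    """Displacement-controlled apex response from the nonlinear solve."""

    deflection: np.ndarray  # apex deflection, m (positive inward)
    load: np.ndarray  # apex reaction, N
    limit_load: float | None  # first limit-point load, N (None if none found)
    reached_target: bool  # load target reached before any limit point
    n_elements: int

    @property
    def peak_load(self) -> float:
        return float(self.load.max(initial=0.0))


def mesh_half_egg(
    geometry: EggGeometry,
    n_elements: int = 400,
    pole_refinement: float = 20.0,
) -> ShellMesh:
    """Mesh the upper half of an ellipsoidal egg along its meridian.

    Parameters
    ----------
    geometry : EggGeometry
        Outer egg dimensions (mm) and uniform shell thickness.
    n_elements : int
        Number of meridian elements (>= 50).
    pole_refinement : float
        Ratio of the equator-adjacent to the pole-adjacent element length;
        element sizes are graded geometrically between the two.
    """
    if n_elements < MIN_ELEMENTS:
        raise ValueError(f"n_elements must be >= {MIN_ELEMENTS}, got {n_elements}")
    if pole_refinement < 1.0:
        raise ValueError("pole_refinement must be >= 1")

    a = geometry.semi_axis_polar / 1000.0  # m
    b = geometry.semi_axis_equatorial / 1000.0
    t = geometry.thickness / 1000.0

    # arc length along r = b sin(psi), z = a cos(psi), psi in [0, pi/2]
    psi_dense = np.linspace(0.0, math.pi / 2.0, 20 * n_elements + 1)
    ds_dpsi = np.sqrt((b * np.cos(psi_dense)) ** 2 + (a * np.sin(psi_dense)) ** 2)
    s_dense = scipy.integrate.cumulative_trapezoid(ds_dpsi, psi_dense, initial=0.0)
    total = s_dense[-1]

    # geometric grading: h_i = h0 * g**i, pole element smallest
    if pole_refinement == 1.0:
        targets = np.linspace(0.0, total, n_elements + 1)
    else:
        g = pole_refinement ** (1.0 / (n_elements - 1))
        h0 = total * (g - 1.0) / (g**n_elements - 1.0)
        sizes = h0 * g ** np.arange(n_elements)
        targets = np.concatenate(([0.0], np.cumsum(sizes)))
        targets[-1] = total

    psi_nodes = np.interp(targets, s_dense, psi_dense)
    psi_nodes[0] = 0.0
    psi_nodes[-1] = math.pi / 2.0
    r = b * np.sin(psi_nodes)
    z = a * np.cos(psi_nodes)
    r[0], z[0] = 0.0, a
    r[-1], z[-1] = b, 0.0

    # meridian tangent angle to the r axis (z decreases pole -> equator)
    dr = b * np.cos(psi_nodes)
    dz = -a * np.sin(psi_nodes)
    angle = np.arctan2(dz, dr)

    return ShellMesh(
        geometry=geometry,
        arc=targets,
        r=r,
        z=z,
        tangent_angle=angle,
        thickness=np.full(n_elements, t),
        pole_refinement=pole_refinement,
    )


class _ElementData:
    """Precomputed, vectorized element quantities for one mesh + material.

    Local element DOF order: [u1, w1, beta1, u2, w2, beta2] with u the
    meridian tangential displacement, w the normal deflection and
    beta = -dw/ds the meridional rotation.  ``B`` maps local DOFs to the
    strain vector [eps_s, eps_theta, chi_s, chi_theta]; ``g`` maps local
    DOFs to dw/ds (the rotation entering both the geometric stiffness and
    the von Karman membrane strain).
    """

    def __init__(self, mesh: ShellMesh, material: Material):
        self.mesh = mesh
        dr = np.diff(mesh.r)
        dz = np.diff(mesh.z)
        L = np.hypot(dr, dz)  # (e,)
        c = dr / L
        ell = dz / L
        n_el = mesh.n_elements
        self.n_dof = 3 * mesh.n_nodes
        self.L, self.c, self.ell = L, c, ell

        xi = _GAUSS_XI[None, :]  # (1, g)
        r_gp = mesh.r[:-1, None] + xi * dr[:, None]  # (e, g)
        self.jac = 2.0 * math.pi * r_gp * L[:, None] * _GAUSS_W[None, :]  # (e, g)

        # Hermite shape values/derivatives at Gauss points, scaled per element
        Lc = L[:, None]
        h = np.stack(
            [
                1 - 3 * xi**2 + 2 * xi**3 + 0 * Lc,
                Lc * (xi - 2 * xi**2 + xi**3),
                3 * xi**2 - 2 * xi**3 + 0 * Lc,
                Lc * (-(xi**2) + xi**3),
            ],
            axis=-1,
        )  # (e, g, 4)
        dh = (
            np.stack(
                [
                    -6 * xi + 6 * xi**2 + 0 * Lc,
                    Lc * (1 - 4 * xi + 3 * xi**2),
                    6 * xi - 6 * xi**2 + 0 * Lc,
                    Lc * (-2 * xi + 3 * xi**2),
                ],
                axis=-1,
            )
            / Lc[..., None]
        )
        d2h = (
            np.stack(
                [
                    -6 + 12 * xi + 0 * Lc,
                    Lc * (-4 + 6 * xi),
                    6 - 12 * xi + 0 * Lc,
                    Lc * (-2 + 6 * xi),
                ],
                axis=-1,
            )
            / Lc[..., None] ** 2
        )

        ng = _GAUSS_XI.size
        B = np.zeros((n_el, ng, 4, 6))
        cc = c[:, None]
        el = ell[:, None]
        # membrane meridional strain du/ds
        B[:, :, 0, 0] = -1.0 / Lc
        B[:, :, 0, 3] = 1.0 / Lc
        # hoop strain (u*c - w*ell)/r; w = h0*w1 - h1*b1 + h2*w2 - h3*b3
        B[:, :, 1, 0] = (1 - xi) * cc / r_gp
        B[:, :, 1, 3] = xi * cc / r_gp
        B[:, :, 1, 1] = -el * h[..., 0] / r_gp
        B[:, :, 1, 2] = el * h[..., 1] / r_gp
        B[:, :, 1, 4] = -el * h[..., 2] / r_gp
        B[:, :, 1, 5] = el * h[..., 3] / r_gp
        # meridional curvature change -w''
        B[:, :, 2, 1] = -d2h[..., 0]
        B[:, :, 2, 2] = d2h[..., 1]
        B[:, :, 2, 4] = -d2h[..., 2]
        B[:, :, 2, 5] = d2h[..., 3]
        # hoop curvature change -(c/r) w'
        B[:, :, 3, 1] = -cc / r_gp * dh[..., 0]
        B[:, :, 3, 2] = cc / r_gp * dh[..., 1]
        B[:, :, 3, 4] = -cc / r_gp * dh[..., 2]
        B[:, :, 3, 5] = cc / r_gp * dh[..., 3]
        self.B = B

        # dw/ds rows (e, g, 6)
        g_row = np.zeros((n_el, ng, 6))
        g_row[:, :, 1] = dh[..., 0]
        g_row[:, :, 2] = -dh[..., 1]
        g_row[:, :, 4] = dh[..., 2]
        g_row[:, :, 5] = -dh[..., 3]
        self.g = g_row

        # constitutive matrix per element
        E, nu = material.elastic_modulus, material.poisson_ratio
        t = mesh.thickness
        Am = E * t / (1 - nu * nu)
        Db = E * t**3 / (12 * (1 - nu * nu))
        D = np.zeros((n_el, 4, 4))
        D[:, 0, 0] = D[:, 1, 1] = Am
        D[:, 0, 1] = D[:, 1, 0] = nu * Am
        D[:, 2, 2] = D[:, 3, 3] = Db
        D[:, 2, 3] = D[:, 3, 2] = nu * Db
        self.D = D
        self.nu = nu

        # local->global transformation, block diag of per-node rotations
        T = np.zeros((n_el, 6, 6))
        for off in (0, 3):
            T[:, off, off] = c
            T[:, off, off + 1] = ell
            T[:, off + 1, off] = -ell
            T[:, off + 1, off + 1] = c
            T[:, off + 2, off + 2] = 1.0
        self.T = T

        base = 3 * np.arange(n_el)[:, None]
        self.dofs = base + np.arange(6)[None, :]  # (e, 6)
        self._rows = np.repeat(self.dofs, 6, axis=1).ravel()
        self._cols = np.tile(self.dofs, (1, 6)).ravel()

        # fixed DOFs: pole regularity (u_r = 0, beta = 0), clamped equator
        last = 3 * (mesh.n_nodes - 1)
        self.fixed = np.array([0, 2, last, last + 1, last + 2])
        self.free = np.setdiff1d(np.arange(self.n_dof), self.fixed)

    # -- assembly helpers -------------------------------------------------
    def _to_sparse(self, ke_global: np.ndarray) -> sp.csc_matrix:
        return sp.coo_matrix(
            (ke_global.ravel(), (self._rows, self._cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsc()

    def stiffness_matrix(self) -> sp.csc_matrix:
        ke = np.einsum(
            "egai,eab,egbj,eg->eij", self.B, self.D, self.B, self.jac, optimize=True
        )
        ke_g = np.einsum("eki,ekl,elj->eij", self.T, ke, self.T, optimize=True)
        return self._to_sparse(ke_g)

    def local_dofs(self, u: np.ndarray) -> np.ndarray:
        """Gather global solution into local element DOFs, (e, 6)."""
        return np.einsum("eij,ej->ei", self.T, u[self.dofs])

    def strains(self, u_loc: np.ndarray, nonlinear: bool = False):
        eps = np.einsum("egai,ei->ega", self.B, u_loc)
        dwds = np.einsum("egi,ei->eg", self.g, u_loc)
        if nonlinear:
            eps = eps.copy()
            eps[:, :, 0] += 0.5 * dwds**2
        return eps, dwds

    def stress_resultants(self, eps: np.ndarray) -> np.ndarray:
        return np.einsum("eab,egb->ega", self.D, eps)

    def geometric_matrix(self, N_s: np.ndarray) -> sp.csc_matrix:
        """Geometric stiffness from meridional membrane force N_s, (e, g)."""
        kg = np.einsum("eg,egi,egj->eij", N_s * self.jac, self.g, self.g)
        kg_g = np.einsum("eki,ekl,elj->eij", self.T, kg, self.T, optimize=True)
        return self._to_sparse(kg_g)

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        """Internal nodal forces for the von Karman nonlinear strain state."""
        u_loc = self.local_dofs(u)
        eps, dwds = self.strains(u_loc, nonlinear=True)
        S = self.stress_resultants(eps)
        f_loc = np.einsum("egai,ega,eg->ei", self.B, S, self.jac)
        f_loc += np.einsum("egi,eg->ei", self.g, S[:, :, 0] * dwds * self.jac)
        f_glob_e = np.einsum("eij,ei->ej", self.T, f_loc)
        f = np.zeros(self.n_dof)
        np.add.at(f, self.dofs.ravel(), f_glob_e.ravel())
        return f

    def tangent_matrix(self, u: np.ndarray) -> sp.csc_matrix:
        """Consistent tangent stiffness for the von Karman state ``u``."""
        u_loc = self.local_dofs(u)
        eps, dwds = self.strains(u_loc, nonlinear=True)
        S = self.stress_resultants(eps)
        # B_eff = B + dwds * g in the eps_s row
        B_eff = self.B.copy()
        B_eff[:, :, 0, :] += dwds[..., None] * self.g
        ke = np.einsum(
            "egai,eab,egbj,eg->eij", B_eff, self.D, B_eff, self.jac, optimize=True
        )
        ke += np.einsum("eg,egi,egj->eij", S[:, :, 0] * self.jac, self.g, self.g)
        ke_g = np.einsum("eki,ekl,elj->eij", self.T, ke, self.T, optimize=True)
        return self._to_sparse(ke_g)


def _solve_linear(data: _ElementData, apex_load: float):
    """Linear solve under an apex point load; returns (K_half, u, K)."""
    K = data.stiffness_matrix()
    f = np.zeros(data.n_dof)
    f[1] = -apex_load  # axial load pressing the pole toward the equator
    free = data.free
    try:
        u_free = spla.spsolve(K[np.ix_(free, free)], f[free])
    except Exception as exc:  # pragma: no cover - singular systems
        raise SolverError(f"linear solve failed: {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise SolverError("linear solve produced non-finite displacements")
    u = np.zeros(data.n_dof)
    u[free] = u_free
    delta = abs(u[1])
    if delta <= 0:
        raise SolverError("zero apex displacement; system is singular")
    return apex_load / delta, u, K


def linear_stiffness(
    mesh: ShellMesh,
    material: Material,
    apex_load: float = 0.1,
    tol: float = 0.005,
    max_refinements: int = 4,
) -> StiffnessResult:
    """Apex-load stiffness of the clamped half shell, with mesh refinement.

    Solves the axisymmetric membrane-bending problem with the equator ring
    fully fixed and an axial point force at the pole, returning
    ``K_half = F / delta_apex`` and the full-egg stiffness
    ``K_full = K_half / 2`` (the lower half adds an equal compliance in
    series).  The mesh is doubled until the stiffness changes by no more
    than ``tol`` relative; non-convergence is flagged on the result, not
    silently ignored.

    In the linear regime the stiffness is independent of ``apex_load``.
    """
    if apex_load <= 0:
        raise ValueError("apex_load must be positive")
    current = mesh
    K_prev, _, _ = _solve_linear(_ElementData(current, material), apex_load)
    rel = math.inf
    converged = False
    for _ in range(max_refinements):
        finer = current.refined(2)
        K_new, _, _ = _solve_linear(_ElementData(finer, material), apex_load)
        rel = abs(K_new - K_prev) / abs(K_new)
        current, K_prev = finer, K_new
        if rel <= tol:
            converged = True
            break
    delta = apex_load / K_prev
    return StiffnessResult(
        K_half=K_prev,
        K_full=K_prev / 2.0,
        apex_displacement=delta,
        apex_load=apex_load,
        n_elements=current.n_elements,
        converged=converged,
        relative_change=rel,
    )


def reissner_stiffness(geometry: EggGeometry, material: Material) -> float:
    """Closed-form full-egg apex stiffness estimate, N/m.

    Classical shallow-shell result for a point load on a spherical cap of
    curvature radius R: K_cap = 4 E t^2 / (R sqrt(3 (1 - nu^2))).  Applied
    with the pole curvature radius of the ellipsoid and halved because the
    full egg presents two caps in series:

        K_full ~= 2 E t^2 / (R sqrt(3 (1 - nu^2)))

    Exact only for shallow spherical caps; used as an independent sanity
    check on the finite-element stiffness (it overestimates increasingly
    with egg elongation, since the tight pole curvature of a prolate egg
    relaxes quickly away from the pole).
    """
    E, nu = material.elastic_modulus, material.poisson_ratio
    t = geometry.thickness / 1000.0
    R = pole_curvature_radius(geometry) / 1000.0
    return 2.0 * E * t * t / (R * math.sqrt(3.0 * (1.0 - nu * nu)))


def buckling_load_factor(
    mesh: ShellMesh,
    material: Material,
    reference_load: float,
) -> BucklingResult:
    """Smallest positive multiplier of the reference apex load at buckling.

    Assembles the geometric stiffness from the membrane-force state of the
    linear solve under ``reference_load`` and solves the linearized
    eigenproblem (K + lambda K_g) v = 0 for the smallest positive lambda;
    the predicted instability load is ``lambda * reference_load``.  By
    linearity of the prestress, lambda scales inversely with
    ``reference_load``.

    Linearized eigen-buckling ignores the pre-buckling dimple growth under
    a point load and therefore sits well above the nonlinear limit point
    computed by :func:`limit_point_load`; it is retained as the classical
    upper-bound surrogate.
    """
    if reference_load <= 0:
        raise ValueError("reference_load must be positive")
    data = _ElementData(mesh, material)
    _, u, K = _solve_linear(data, reference_load)
    eps, _ = data.strains(data.local_dofs(u))
    S = data.stress_resultants(eps)
    KG = data.geometric_matrix(S[:, :, 0])

    free = data.free
    Kff = K[np.ix_(free, free)].tocsc()
    Gff = (-KG)[np.ix_(free, free)].tocsc()

    # (K + lambda K_g) v = 0  <=>  G v = mu K v with G = -K_g, mu = 1/lambda
    mu, vec = _largest_generalized_eig(Gff, Kff)
    if mu <= 0:
        raise SolverError("no positive buckling eigenvalue found")
    lam = 1.0 / mu

    mode = np.zeros(data.n_dof)
    mode[free] = vec
    trans = np.hypot(mode[0::3], mode[1::3])
    peak = int(np.argmax(trans))
    return BucklingResult(
        load_factor=lam,
        reference_load=reference_load,
        mode_peak_arc_fraction=float(mesh.arc[peak] / mesh.arc[-1]),
        n_elements=mesh.n_elements,
    )


def _largest_generalized_eig(G: sp.csc_matrix, K: sp.csc_matrix):
    """Largest algebraic eigenpair of G v = mu K v (K positive definite)."""
    try:
        mu, vecs = spla.eigsh(G, k=1, M=K, which="LA", maxiter=5000)
        return float(mu[0]), vecs[:, 0]
    except Exception:
        mu_all, vecs = scipy.linalg.eigh(G.toarray(), K.toarray())
        idx = int(np.argmax(mu_all))
        return float(mu_all[idx]), vecs[:, idx]


def limit_point_load(
    mesh: ShellMesh,
    material: Material,
    target_load: float,
    max_deflection_thicknesses: float = 8.0,
    n_steps: int = 80,
    drop_tolerance: float = 0.01,
) -> LoadDeflectionCurve:
    """Displacement-controlled nonlinear apex compression of the half shell.

    The pole is pushed inward in increments while Newton iteration
    restores equilibrium of the von Karman (moderate-rotation) shell
    equations; the apex reaction is recorded at each step.  The run stops
    as soon as the reaction reaches ``target_load`` (the shell can carry
    the load without snapping) or the reaction falls ``drop_tolerance``
    below its running maximum (a limit point — the inward dimple has gone
    unstable), whichever happens first.

    Parameters
    ----------
    target_load : float
        Load the shell must sustain, N (e.g. the incubating parent's
        weight applied to one egg).
    max_deflection_thicknesses : float
        Deflection sweep range in units of shell thickness; apex-load
        dimple instability happens at deflections of order the thickness.
    n_steps : int
        Number of displacement increments over the sweep range.
    """
    if target_load <= 0:
        raise ValueError("target_load must be positive")
    data = _ElementData(mesh, material)
    t = float(np.min(mesh.thickness))
    delta_max = max_deflection_thicknesses * t
    steps = np.linspace(0.0, delta_max, n_steps + 1)[1:]

    u = np.zeros(data.n_dof)
    # free DOFs excluding the driven apex axial DOF
    drive = 1
    free = data.free[data.free != drive]

    deflections = [0.0]
    loads = [0.0]
    peak = 0.0
    limit = None
    reached = False
    for delta in steps:
        u[drive] = -delta
        ok = _newton(data, u, free)
        if not ok:
            # halve the increment once; if still failing, stop the sweep here
            u[drive] = -(deflections[-1] + (delta - deflections[-1]) / 2)
            if not _newton(data, u, free):
                break
        reaction = -data.internal_force(u)[drive]
        deflections.append(-u[drive])
        loads.append(reaction)
        if reaction > peak:
            peak = reaction
        if reaction >= target_load:
            reached = True
            break
        if peak > 0 and reaction < (1.0 - drop_tolerance) * peak:
            limit = peak
            break

    return LoadDeflectionCurve(
        deflection=np.array(deflections),
        load=np.array(loads),
        limit_load=limit,
        reached_target=reached,
        n_elements=mesh.n_elements,
    )


def apex_reaction_at_deflection(
    mesh: ShellMesh,
    material: Material,
    deflection: float,
    n_steps: int = 8,
) -> float:
    """Apex reaction (N) when the pole is pushed inward by ``deflection``.

    Solves the geometrically nonlinear (von Karman) axisymmetric problem
    under displacement control.  The reaction at an apex deflection equal
    to the shell thickness marks the onset of dimple inversion — the
    working definition of the buckling load for contact incubation (see
    :func:`eggmech.metrics.critical_thickness`).
    """
    if deflection <= 0:
        raise ValueError("deflection must be positive")
    data = _ElementData(mesh, material)
    u = np.zeros(data.n_dof)
    drive = 1
    free = data.free[data.free != drive]
    prev = 0.0
    for delta in np.linspace(0.0, deflection, n_steps + 1)[1:]:
        u[drive] = -delta
        if not _newton(data, u, free):
            # retry with a halved increment from the last good state
            mid = prev + (delta - prev) / 2
            u[drive] = -mid
            if not _newton(data, u, free):
                raise SolverError(
                    f"nonlinear solve failed at deflection {delta:.3e} m"
                )
            u[drive] = -delta
            if not _newton(data, u, free):
                raise SolverError(
                    f"nonlinear solve failed at deflection {delta:.3e} m"
                )
        prev = delta
    return float(-data.internal_force(u)[drive])


@dataclass(frozen=True)
class NonlinearBucklingResult:
    """Outcome of the nonlinear buckling assessment under an apex load.

    ``mode`` is one of:

    * ``"carried"`` — the shell reached ``target_load`` with no
      instability; ``buckling_load`` is then a lower bound (the last
      computed reaction).
    * ``"bifurcation"`` — a non-axisymmetric harmonic went unstable on
      the axisymmetric dimple path; ``critical_harmonic`` is its
      circumferential wave number.
    * ``"limit"`` — an axisymmetric limit point (reaction maximum) was
      met first.
    """

    buckling_load: float  # N (first instability, or last reaction if carried)
    mode: str
    critical_harmonic: int | None
    deflection: float  # apex deflection at the reported load, m
    reached_target: bool
    target_load: float
    n_elements: int

    @property
    def carries_target(self) -> bool:
        return self.reached_target

    def to_dict(self) -> dict:
        return {
            "buckling_load_N": self.buckling_load,
            "mode": self.mode,
            "critical_harmonic": self.critical_harmonic,
            "deflection_m": self.deflection,
            "reached_target": self.reached_target,
            "target_load_N": self.target_load,
            "n_elements": self.n_elements,
        }


def nonlinear_buckling_load(
    mesh: ShellMesh,
    material: Material,
    target_load: float,
    harmonics: range = range(2, 11),
    max_deflection_thicknesses: float = 10.0,
    n_steps: int = 60,
    drop_tolerance: float = 0.01,
) -> NonlinearBucklingResult:
    """Buckling load of the apex-compressed shell from nonlinear analysis.

    Traces the displacement-controlled axisymmetric dimple path (von
    Karman kinematics) and, at every converged step, tests the stability
    of the deformed, prestressed state against non-axisymmetric
    perturbations ``cos(n theta)`` for each harmonic in ``harmonics``
    (classical shell-of-revolution bifurcation analysis on the deformed
    meridian).  The buckling load is the apex reaction at the first
    instability — either a harmonic bifurcation (circumferential lobes at
    the dimple rim, the physical failure mode of a point-loaded shell) or
    an axisymmetric limit point, whichever comes first.

    The sweep stops early once the reaction reaches ``target_load``
    (the shell then carries the target without buckling), which makes
    this predicate cheap for safely thick shells.
    """
    from ._harmonic import HarmonicModel

    if target_load <= 0:
        raise ValueError("target_load must be positive")
    data = _ElementData(mesh, material)
    t = float(np.min(mesh.thickness))
    delta_max = max_deflection_thicknesses * t
    steps = np.linspace(0.0, delta_max, n_steps + 1)[1:]

    u = np.zeros(data.n_dof)
    drive = 1
    free = data.free[data.free != drive]

    prev_delta = 0.0
    prev_reaction = 0.0
    peak = 0.0
    for delta in steps:
        u[drive] = -delta
        if not _newton(data, u, free):
            u[drive] = -(prev_delta + (delta - prev_delta) / 2)
            if not _newton(data, u, free):
                # path cannot be continued; treat the peak so far as a limit
                return NonlinearBucklingResult(
                    buckling_load=peak,
                    mode="limit",
                    critical_harmonic=None,
                    deflection=prev_delta,
                    reached_target=False,
                    target_load=target_load,
                    n_elements=mesh.n_elements,
                )
        reaction = -data.internal_force(u)[drive]

        # harmonic bifurcation check on the deformed meridian
        u_loc = data.local_dofs(u)
        eps, _ = data.strains(u_loc, nonlinear=True)
        S = data.stress_resultants(eps)
        r_def = mesh.r + u[0::3]
        z_def = mesh.z + u[1::3]
        r_def[0] = 0.0
        hm = HarmonicModel(r_def, z_def, mesh.thickness, material)
        for n in harmonics:
            if not hm.is_stable(n, S[:, :, 0], S[:, :, 1]):
                return NonlinearBucklingResult(
                    buckling_load=max(reaction, prev_reaction),
                    mode="bifurcation",
                    critical_harmonic=n,
                    deflection=-u[drive],
                    reached_target=False,
                    target_load=target_load,
                    n_elements=mesh.n_elements,
                )

        peak = max(peak, reaction)
        if reaction >= target_load:
            return NonlinearBucklingResult(
                buckling_load=reaction,
                mode="carried",
                critical_harmonic=None,
                deflection=-u[drive],
                reached_target=True,
                target_load=target_load,
                n_elements=mesh.n_elements,
            )
        if peak > 0 and reaction < (1.0 - drop_tolerance) * peak:
            return NonlinearBucklingResult(
                buckling_load=peak,
                mode="limit",
                critical_harmonic=None,
                deflection=-u[drive],
                reached_target=False,
                target_load=target_load,
                n_elements=mesh.n_elements,
            )
        prev_delta = delta
        prev_reaction = reaction

    # swept the whole range without instability or reaching the target
    return NonlinearBucklingResult(
        buckling_load=peak,
        mode="limit",
        critical_harmonic=None,
        deflection=delta_max,
        reached_target=False,
        target_load=target_load,
        n_elements=mesh.n_elements,
    )


def _newton(data: _ElementData, u: np.ndarray, free: np.ndarray,
            tol: float = 1e-9, max_iter: int = 30) -> bool:
    """Newton equilibrium iteration at fixed driven DOFs; updates ``u``."""
    scale = None
    for _ in range(max_iter):
        r = data.internal_force(u)[free]
        if scale is None:
            scale = max(float(np.abs(data.internal_force(u)).max()), 1e-12)
        if np.linalg.norm(r) <= tol * scale + 1e-14:
            return True
        Kt = data.tangent_matrix(u)[np.ix_(free, free)]
        try:
            du = spla.spsolve(Kt, -r)
        except Exception:
            return False
        if not np.all(np.isfinite(du)):
            return False
        u[free] += du
    return False
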