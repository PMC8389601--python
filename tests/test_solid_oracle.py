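"""Cross-check of the shell solver against an axisymmetric solid model.

The thin-shell solver reduces the egg to its mid-surface; this test
rebuilds the same problem as a plain 2-D axisymmetric *continuum* model
(8-node quadratic quadrilaterals through the actual shell volume) with
no shell kinematics at all, loads it with a small vertical surface patch
at the pole, and compares apex stiffnesses.  Agreement validates the
shell strain measures, the meridian meshing and the boundary conditions
against an independent discretization of the full elasticity equations.

A true point load is singular in 3-D elasticity, so both models carry
the same finite patch; the patch is kept small against the bending
boundary layer sqrt(R t) so the comparison probes the same physics as
the apex point load.
"""

import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from eggmech import EggGeometry, Material, mesh_half_egg
from eggmech.shell_solver import _ElementData, _GAUSS_XI, _GAUSS_W


def solid_half_stiffness(L_mm, W_mm, t_mm, material, n_s=300, n_t=3,
                         r0_mm=2.0, pole_refine=15.0):
    """Apex stiffness (N/m) of the half egg from Q8 axisymmetric solids."""
    a, b, t = L_mm / 2000.0, W_mm / 2000.0, t_mm / 1000.0
    E, nu = material.elastic_modulus, material.poisson_ratio

    psid = np.linspace(0, math.pi / 2, 40 * n_s)
    Jd = np.sqrt((b * np.cos(psid)) ** 2 + (a * np.sin(psid)) ** 2)
    sd = np.concatenate(([0], np.cumsum(0.5 * (Jd[1:] + Jd[:-1]) * np.diff(psid))))
    g = pole_refine ** (1.0 / (n_s - 1))
    h0 = sd[-1] * (g - 1) / (g ** n_s - 1)
    starc = np.concatenate(([0], np.cumsum(h0 * g ** np.arange(n_s))))
    starc[-1] = sd[-1]
    s_nodes = np.interp(np.linspace(0, n_s, 2 * n_s + 1),
                        np.arange(n_s + 1), starc)
    psi = np.interp(s_nodes, sd, psid)
    eta = np.linspace(-1.0, 1.0, 2 * n_t + 1)

    r_mid, z_mid = b * np.sin(psi), a * np.cos(psi)
    J = np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
    nr, nz = a * np.sin(psi) / J, b * np.cos(psi) / J
    R = r_mid[:, None] + 0.5 * t * eta[None, :] * nr[:, None]
    Z = z_mid[:, None] + 0.5 * t * eta[None, :] * nz[:, None]
    R[0, :] = 0.0

    npsi, neta = len(psi), len(eta)
    nid = -np.ones((npsi, neta), dtype=int)
    count = 0
    for i in range(npsi):
        for j in range(neta):
            if i % 2 == 1 and j % 2 == 1:
                continue  # serendipity elements have no interior node
            nid[i, j] = count
            count += 1
    coords = np.zeros((count, 2))
    for i in range(npsi):
        for j in range(neta):
            if nid[i, j] >= 0:
                coords[nid[i, j]] = (R[i, j], Z[i, j])

    def shape(xi, et):
        N = np.array([
            0.25 * (1 - xi) * (1 - et) * (-xi - et - 1),
            0.25 * (1 + xi) * (1 - et) * (xi - et - 1),
            0.25 * (1 + xi) * (1 + et) * (xi + et - 1),
            0.25 * (1 - xi) * (1 + et) * (-xi + et - 1),
            0.5 * (1 - xi * xi) * (1 - et),
            0.5 * (1 + xi) * (1 - et * et),
            0.5 * (1 - xi * xi) * (1 + et),
            0.5 * (1 - xi) * (1 - et * et),
        ])
        dNdxi = np.array([
            0.25 * (1 - et) * (2 * xi + et),
            0.25 * (1 - et) * (2 * xi - et),
            0.25 * (1 + et) * (2 * xi + et),
            0.25 * (1 + et) * (2 * xi - et),
            -xi * (1 - et), 0.5 * (1 - et * et),
            -xi * (1 + et), -0.5 * (1 - et * et),
        ])
        dNdet = np.array([
            0.25 * (1 - xi) * (xi + 2 * et),
            0.25 * (1 + xi) * (-xi + 2 * et),
            0.25 * (1 + xi) * (xi + 2 * et),
            0.25 * (1 - xi) * (-xi + 2 * et),
            -0.5 * (1 - xi * xi), -et * (1 + xi),
            0.5 * (1 - xi * xi), -et * (1 - xi),
        ])
        return N, dNdxi, dNdet

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.array([
        [lam + 2 * mu, lam, lam, 0],
        [lam, lam + 2 * mu, lam, 0],
        [lam, lam, lam + 2 * mu, 0],
        [0, 0, 0, mu],
    ])
    gp = np.array([-1 / math.sqrt(3), 1 / math.sqrt(3)])
    rows, cols, vals = [], [], []
    ndof = 2 * count
    for ei in range(n_s):
        for ej in range(n_t):
            ii, jj = 2 * ei, 2 * ej
            loc = [(ii, jj), (ii + 2, jj), (ii + 2, jj + 2), (ii, jj + 2),
                   (ii + 1, jj), (ii + 2, jj + 1), (ii + 1, jj + 2),
                   (ii, jj + 1)]
            nodes = np.array([nid[i, j] for (i, j) in loc])
            xy = coords[nodes]
            ke = np.zeros((16, 16))
            for xi in gp:
                for et in gp:
                    N, dxi, det_ = shape(xi, et)
                    Jm = np.array([[dxi @ xy[:, 0], dxi @ xy[:, 1]],
                                   [det_ @ xy[:, 0], det_ @ xy[:, 1]]])
                    dN = np.linalg.solve(Jm, np.vstack([dxi, det_]))
                    rr = N @ xy[:, 0]
                    B = np.zeros((4, 16))
                    B[0, 0::2] = dN[0]
                    B[1, 1::2] = dN[1]
                    B[2, 0::2] = N / rr
                    B[3, 0::2] = dN[1]
                    B[3, 1::2] = dN[0]
                    ke += (B.T @ D @ B) * np.linalg.det(Jm) * 2 * math.pi * rr
            dofs = np.empty(16, dtype=int)
            dofs[0::2], dofs[1::2] = 2 * nodes, 2 * nodes + 1
            rows.append(np.repeat(dofs, 16))
            cols.append(np.tile(dofs, 16))
            vals.append(ke.ravel())
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(ndof, ndof)).tocsc()

    # vertical traction over the outer-surface polar cap, total force F
    F, r0 = 0.1, r0_mm / 1000.0
    f = np.zeros(ndof)
    jtop = neta - 1
    for ei in range(n_s):
        ii = 2 * ei
        enodes = [nid[ii, jtop], nid[ii + 1, jtop], nid[ii + 2, jtop]]
        xy = coords[enodes]
        for xi, w in zip([-math.sqrt(0.6), 0, math.sqrt(0.6)],
                         [5 / 9, 8 / 9, 5 / 9]):
            N = np.array([0.5 * xi * (xi - 1), 1 - xi * xi,
                          0.5 * xi * (xi + 1)])
            dN = np.array([xi - 0.5, -2 * xi, xi + 0.5])
            dl = math.hypot(dN @ xy[:, 0], dN @ xy[:, 1])
            rr = N @ xy[:, 0]
            if rr < r0:
                for k in range(3):
                    f[2 * enodes[k] + 1] -= N[k] * rr * dl * w * 2 * math.pi
    f *= F / (-f.sum())

    fixed = set()
    for j in range(neta):
        if nid[npsi - 1, j] >= 0:  # equator cross-section clamped
            fixed.update((2 * nid[npsi - 1, j], 2 * nid[npsi - 1, j] + 1))
        if nid[0, j] >= 0:  # axis: radial displacement zero
            fixed.add(2 * nid[0, j])
    free = np.setdiff1d(np.arange(ndof), np.array(sorted(fixed)))
    u = np.zeros(ndof)
    u[free] = spla.spsolve(K[np.ix_(free, free)], f[free])
    apex = [nid[0, j] for j in range(neta) if nid[0, j] >= 0]
    return F / abs(np.mean([u[2 * n + 1] for n in apex]))


def shell_half_stiffness_patch(geometry, material, r0_mm, n=400):
    """Shell solver under the same vertical patch traction, N/m."""
    mesh = mesh_half_egg(geometry, n)
    data = _ElementData(mesh, material)
    r0 = r0_mm / 1000.0
    f = np.zeros(data.n_dof)
    L = np.diff(mesh.arc)
    for e in range(mesh.n_elements):
        c, ell = data.c[e], data.ell[e]
        for xi, wq in zip(_GAUSS_XI, _GAUSS_W):
            r_gp = mesh.r[e] + xi * (mesh.r[e + 1] - mesh.r[e])
            if r_gp >= r0:
                continue
            jac = 2 * math.pi * r_gp * L[e] * wq
            h = np.array([
                1 - 3 * xi**2 + 2 * xi**3,
                L[e] * (xi - 2 * xi**2 + xi**3),
                3 * xi**2 - 2 * xi**3,
                L[e] * (-(xi**2) + xi**3),
            ])
            Nu = np.array([1 - xi, 0, 0, xi, 0, 0])
            Nw = np.array([0, h[0], -h[1], 0, h[2], -h[3]])
            f_loc = -jac * (ell * Nu + c * Nw)  # vertical direction
            f[data.dofs[e]] += data.T[e].T @ f_loc
    f *= 0.1 / (-f[1::3].sum())
    free = data.free
    u = np.zeros(data.n_dof)
    u[free] = spla.spsolve(
        data.stiffness_matrix()[np.ix_(free, free)], f[free]
    )
    return 0.1 / abs(u[1])


@pytest.mark.parametrize(
    "geometry_mm,r0_mm,tol",
    [
        ((303.0, 224.0, 3.7), 5.0, 0.06),  # thick shell: shear effects
        ((128.0, 86.0, 0.9), 1.0, 0.04),  # thin shell
    ],
    ids=["elephant-bird", "rhea"],
)
def test_shell_matches_solid_continuum(material, geometry_mm, r0_mm, tol):
    geo = EggGeometry(*geometry_mm)
    k_solid = solid_half_stiffness(*geometry_mm, material, r0_mm=r0_mm)
    k_shell = shell_half_stiffness_patch(geo, material, r0_mm)
    assert k_shell == pytest.approx(k_solid, rel=tol)
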