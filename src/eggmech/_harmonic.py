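"""Fourier-harmonic stability analysis for shells of revolution.

Non-axisymmetric displacement fields on an axisymmetric shell separate
into circumferential harmonics

    u = U(s) cos nθ,   v = V(s) sin nθ,   w = W(s) cos nθ,

so each harmonic ``n`` reduces to a one-dimensional problem along the
meridian.  This module builds the harmonic elastic stiffness and the
geometric (initial-stress) stiffness on a given meridian polyline — which
may be the *deformed* meridian of a nonlinear axisymmetric state — and
tests whether the prestressed shell is stable against that harmonic.
This is the classical shell-of-revolution bifurcation machinery (the
BOSOR approach) specialized to conical-facet elements matching
:mod:`eggmech.shell_solver`.

Kinematics per node: [U, V, W, beta] with beta = -dW/ds; U and V linear,
W Hermite-cubic.  Strain vector: membrane [eps_s, eps_theta, gamma] and
bending [chi_s, chi_theta, omega] with omega the full twist (plate limit
omega = -2 w_{,xy}).  The geometric stiffness uses the meridional and
hoop membrane forces acting on the squared normal rotations — the
standard rotation-based form.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg

from .egg_models import Material

# 3-point Gauss rule on [0, 1] (matches shell_solver)
_GAUSS_XI = np.array([0.5 - math.sqrt(0.15), 0.5, 0.5 + math.sqrt(0.15)])
_GAUSS_W = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])

_HALF_BANDWIDTH = 7  # 4 DOF/node, 2-node elements


class HarmonicModel:
    """Harmonic stiffness machinery on a meridian polyline.

    Parameters
    ----------
    r, z : arrays
        Nodal coordinates of the meridian polyline, pole (r=0) first, m.
    thickness : array
        Per-element shell thickness, m.
    material : Material
    """

    def __init__(self, r: np.ndarray, z: np.ndarray, thickness: np.ndarray,
                 material: Material):
        self.r, self.z = r, z
        dr, dz = np.diff(r), np.diff(z)
        L = np.hypot(dr, dz)
        c, ell = dr / L, dz / L
        nr = -ell  # radial component of the facet normal (-ell, c)
        n_el = L.size
        self.n_nodes = r.size
        self.n_dof = 4 * self.n_nodes

        xi = _GAUSS_XI[None, :]
        r_gp = r[:-1, None] + xi * dr[:, None]
        self.jac = math.pi * r_gp * L[:, None] * _GAUSS_W[None, :]

        Lc = L[:, None]
        h = np.stack(
            [
                1 - 3 * xi**2 + 2 * xi**3 + 0 * Lc,
                Lc * (xi - 2 * xi**2 + xi**3),
                3 * xi**2 - 2 * xi**3 + 0 * Lc,
                Lc * (-(xi**2) + xi**3),
            ],
            axis=-1,
        )
        dh = np.stack(
            [
                -6 * xi + 6 * xi**2 + 0 * Lc,
                Lc * (1 - 4 * xi + 3 * xi**2),
                6 * xi - 6 * xi**2 + 0 * Lc,
                Lc * (-2 * xi + 3 * xi**2),
            ],
            axis=-1,
        ) / Lc[..., None]
        d2h = np.stack(
            [
                -6 + 12 * xi + 0 * Lc,
                Lc * (-4 + 6 * xi),
                6 - 12 * xi + 0 * Lc,
                Lc * (-2 + 6 * xi),
            ],
            axis=-1,
        ) / Lc[..., None] ** 2

        ng = _GAUSS_XI.size
        cc, el, nrr = c[:, None], ell[:, None], nr[:, None]

        # local DOFs [U1, V1, W1, b1, U2, V2, W2, b2]
        # interpolation rows at Gauss points
        U = np.zeros((n_el, ng, 8))
        U[:, :, 0] = 1 - xi
        U[:, :, 4] = xi
        dU = np.zeros((n_el, ng, 8))
        dU[:, :, 0] = -1.0 / Lc
        dU[:, :, 4] = 1.0 / Lc
        V = np.zeros((n_el, ng, 8))
        V[:, :, 1] = 1 - xi
        V[:, :, 5] = xi
        dV = np.zeros((n_el, ng, 8))
        dV[:, :, 1] = -1.0 / Lc
        dV[:, :, 5] = 1.0 / Lc
        W = np.zeros((n_el, ng, 8))
        W[:, :, 2] = h[..., 0]
        W[:, :, 3] = -h[..., 1]
        W[:, :, 6] = h[..., 2]
        W[:, :, 7] = -h[..., 3]
        dW = np.zeros((n_el, ng, 8))
        dW[:, :, 2] = dh[..., 0]
        dW[:, :, 3] = -dh[..., 1]
        dW[:, :, 6] = dh[..., 2]
        dW[:, :, 7] = -dh[..., 3]
        d2W = np.zeros((n_el, ng, 8))
        d2W[:, :, 2] = d2h[..., 0]
        d2W[:, :, 3] = -d2h[..., 1]
        d2W[:, :, 6] = d2h[..., 2]
        d2W[:, :, 7] = -d2h[..., 3]

        rg = r_gp[..., None]
        # strain rows decomposed by power of the harmonic number:
        # B(n) = B0 + n B1 + n^2 B2, rows [eps_s, eps_th, gam, chi_s, chi_th, omg]
        B0 = np.zeros((n_el, ng, 6, 8))
        B1 = np.zeros((n_el, ng, 6, 8))
        B2 = np.zeros((n_el, ng, 6, 8))
        B0[:, :, 0] = dU
        B0[:, :, 1] = (cc[..., None] * U + nrr[..., None] * W) / rg
        B1[:, :, 1] = V / rg
        B0[:, :, 2] = dV - cc[..., None] * V / rg
        B1[:, :, 2] = -U / rg
        B0[:, :, 3] = -d2W
        B0[:, :, 4] = -cc[..., None] * dW / rg
        B1[:, :, 4] = nrr[..., None] * V / rg**2
        B2[:, :, 4] = W / rg**2
        # omega = (n W' + nr V')/r + (n/r) W' - 2 c (n W + nr V)/r^2
        B0[:, :, 5] = nrr[..., None] * dV / rg - 2 * cc[..., None] * nrr[..., None] * V / rg**2
        B1[:, :, 5] = 2 * dW / rg - 2 * cc[..., None] * W / rg**2
        self._B = (B0, B1, B2)

        # rotation rows for the geometric stiffness:
        # beta_s -> dW/ds ; beta_theta -> (n W + nr V)/r
        self._rot_s = dW
        self._rot_t0 = nrr[..., None] * V / rg
        self._rot_t1 = W / rg

        E, nu = material.elastic_modulus, material.poisson_ratio
        t = thickness
        Am = E * t / (1 - nu * nu)
        Db = E * t**3 / (12 * (1 - nu * nu))
        D = np.zeros((n_el, 6, 6))
        D[:, 0, 0] = D[:, 1, 1] = Am
        D[:, 0, 1] = D[:, 1, 0] = nu * Am
        D[:, 2, 2] = 0.5 * (1 - nu) * Am
        D[:, 3, 3] = D[:, 4, 4] = Db
        D[:, 3, 4] = D[:, 4, 3] = nu * Db
        D[:, 5, 5] = 0.5 * (1 - nu) * Db
        self._D = D

        # local (U, W) <-> global (u_r, u_z) rotation; V, beta invariant
        T = np.zeros((n_el, 8, 8))
        for off in (0, 4):
            T[:, off, off] = c
            T[:, off, off + 2] = ell
            T[:, off + 2, off] = -ell
            T[:, off + 2, off + 2] = c
            T[:, off + 1, off + 1] = 1.0
            T[:, off + 3, off + 3] = 1.0
        self._T = T

        base = 4 * np.arange(n_el)[:, None]
        self.dofs = base + np.arange(8)[None, :]

    def _combine_B(self, n: int) -> np.ndarray:
        B0, B1, B2 = self._B
        return B0 + n * B1 + n * n * B2

    def elastic_blocks(self, n: int) -> np.ndarray:
        """Per-element 8x8 global-frame elastic stiffness blocks."""
        B = self._combine_B(n)
        ke = np.einsum("egai,eab,egbj,eg->eij", B, self._D, B, self.jac,
                       optimize=True)
        return np.einsum("eki,ekl,elj->eij", self._T, ke, self._T,
                         optimize=True)

    def geometric_blocks(self, n: int, N_s: np.ndarray,
                         N_theta: np.ndarray) -> np.ndarray:
        """Per-element geometric stiffness blocks from membrane prestress.

        ``N_s`` and ``N_theta`` are membrane forces (N/m) at the Gauss
        points, shape (n_elements, n_gauss); compression negative.
        """
        rot_t = self._rot_t0 + n * self._rot_t1
        kg = np.einsum("eg,egi,egj->eij", N_s * self.jac, self._rot_s,
                       self._rot_s)
        kg += np.einsum("eg,egi,egj->eij", N_theta * self.jac, rot_t, rot_t)
        return np.einsum("eki,ekl,elj->eij", self._T, kg, self._T,
                         optimize=True)

    def _fixed_dofs(self) -> np.ndarray:
        # harmonic n >= 2: all field amplitudes vanish on the axis; equator
        # ring clamped
        last = 4 * (self.n_nodes - 1)
        return np.concatenate([np.arange(4), last + np.arange(4)])

    def _assemble_banded(self, blocks: np.ndarray) -> np.ndarray:
        """Assemble element blocks into LAPACK lower-banded storage and
        apply constraints by dropping to an identity row/column."""
        nd = self.n_dof
        ab = np.zeros((_HALF_BANDWIDTH + 1, nd))
        dofs = self.dofs
        for ii in range(8):
            for jj in range(8):
                gi = dofs[:, ii]
                gj = dofs[:, jj]
                d = gi - gj
                m = (d >= 0) & (d <= _HALF_BANDWIDTH)
                np.add.at(ab, (d[m], gj[m]), blocks[m, ii, jj])
        fixed = self._fixed_dofs()
        scale = max(np.abs(ab).max(), 1.0)
        for k in fixed:
            lo = max(0, k - _HALF_BANDWIDTH)
            ab[k - np.arange(lo, k + 1), np.arange(lo, k + 1)] = 0.0
            hi = min(nd - 1, k + _HALF_BANDWIDTH)
            ab[np.arange(k, hi + 1) - k, k] = 0.0
            ab[0, k] = scale
        return ab

    def is_stable(self, n: int, N_s: np.ndarray, N_theta: np.ndarray) -> bool:
        """Positive definiteness of K_n + K_g(n) under the given prestress."""
        blocks = self.elastic_blocks(n) + self.geometric_blocks(n, N_s, N_theta)
        ab = self._assemble_banded(blocks)
        try:
            scipy.linalg.cholesky_banded(ab, lower=True, check_finite=False)
            return True
        except scipy.linalg.LinAlgError:
            return False

    def buckling_factor(self, n: int, N_s: np.ndarray,
                        N_theta: np.ndarray) -> float:
        """Smallest positive lambda with K_n + lambda K_g(n) singular.

        Used for validation against classical closed-form buckling loads;
        the prestress is scaled by lambda.
        """
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        ke = self.elastic_blocks(n)
        kg = self.geometric_blocks(n, N_s, N_theta)
        nd = self.n_dof
        rows = np.repeat(self.dofs, 8, axis=1).ravel()
        cols = np.tile(self.dofs, (1, 8)).ravel()
        K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(nd, nd)).tocsc()
        G = sp.coo_matrix((-kg.ravel(), (rows, cols)), shape=(nd, nd)).tocsc()
        free = np.setdiff1d(np.arange(nd), self._fixed_dofs())
        Kff = K[np.ix_(free, free)]
        Gff = G[np.ix_(free, free)]
        try:
            mu, _ = spla.eigsh(Gff, k=1, M=Kff, which="LA", maxiter=5000)
            mu = float(mu[0])
        except Exception:
            mu_all = scipy.linalg.eigh(Gff.toarray(), Kff.toarray(),
                                       eigvals_only=True)
            mu = float(mu_all.max())
        if mu <= 0:
            return math.inf
        return 1.0 / mu
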