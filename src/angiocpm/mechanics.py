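"""Substrate mechanics: stationary linear elasticity under cell traction, and durotaxis.

The substrate is a clamped square sheet discretized with four-noded square
elements (one per CPM pixel), plane stress.  Cells pull their nodes toward
their node centroid; solving ``K u = f`` yields nodal displacements, from
which a per-pixel strain tensor and its principal decomposition are derived.
The durotaxis energy term rewards cell extensions along directions where the
strain-stiffened substrate exceeds a threshold stiffness.

Everything is computed in SI units (metres, pascals, N/m of force per unit
substrate thickness); strains are dimensionless.  The stiffness matrix is
constant for a run, so its sparse factorization is cached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .config import DurotaxisParameters, ElasticityParameters, LatticeConfig

_GAUSS = 1.0 / math.sqrt(3.0)


def d_matrix(E_pa: float, nu: float) -> np.ndarray:
    """Plane-stress constitutive matrix (Pa)."""
    c = E_pa / (1.0 - nu * nu)
    return c * np.array([[1.0, nu, 0.0],
                         [nu, 1.0, 0.0],
                         [0.0, 0.0, 0.5 * (1.0 - nu)]])


def _b_matrix(xi: float, eta: float, h_m: float) -> np.ndarray:
    """Strain-displacement matrix of the square bilinear element at (xi, eta).

    Local node order: (0,0), (h,0), (h,h), (0,h) on the reference square
    [-1,1]^2; rows are (eps11, eps22, gamma12).
    """
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    dN_dx = dN_dxi * 2.0 / h_m
    dN_dy = dN_deta * 2.0 / h_m
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def element_stiffness(h_m: float, D: np.ndarray) -> np.ndarray:
    """8x8 element stiffness from 2x2 Gauss integration of B^T D B."""
    Ke = np.zeros((8, 8))
    det_j = (h_m / 2.0) ** 2
    for xi in (-_GAUSS, _GAUSS):
        for eta in (-_GAUSS, _GAUSS):
            B = _b_matrix(xi, eta, h_m)
            Ke += B.T @ D @ B * det_j
    return Ke


class FemSystem:
    """Assembled global stiffness with clamped boundary and cached factorization.

    Nodes live on the ``M x M`` grid; dofs are interleaved ``(ux, uy)`` with
    node id ``ix * M + iy``.
    """

    def __init__(self, lattice: LatticeConfig, elasticity: ElasticityParameters):
        self.M = lattice.M
        self.h_m = lattice.h_um * 1e-6
        self.elasticity = elasticity
        D = d_matrix(elasticity.E_kpa * 1e3, elasticity.nu)
        Ke = element_stiffness(self.h_m, D)
        M = self.M
        # element -> global dof map, identical Ke for every element
        ii, jj = np.meshgrid(np.arange(M - 1), np.arange(M - 1), indexing="ij")
        n00 = (ii * M + jj).ravel()
        elem_nodes = np.stack([n00, n00 + M, n00 + M + 1, n00 + 1], axis=1)
        dofs = np.empty((elem_nodes.shape[0], 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * elem_nodes
        dofs[:, 1::2] = 2 * elem_nodes + 1
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()
        vals = np.tile(Ke.ravel(), elem_nodes.shape[0])
        ndof = 2 * M * M
        self.K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
        # clamped boundary: u = 0 on all edge nodes
        gx, gy = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
        interior_nodes = ((gx > 0) & (gx < M - 1) & (gy > 0) & (gy < M - 1)).ravel()
        self.interior = np.repeat(interior_nodes, 2)
        self._int_idx = np.flatnonzero(self.interior)
        K_int = self.K[self._int_idx][:, self._int_idx].tocsc()
        self._lu = splu(K_int)

    def solve(self, f: np.ndarray) -> np.ndarray:
        """Solve ``K u = f`` with the clamped boundary; returns the full dof vector."""
        u = np.zeros_like(f)
        u[self._int_idx] = self._lu.solve(f[self._int_idx])
        return u

    def residual(self, u: np.ndarray, f: np.ndarray) -> float:
        """Relative residual of the interior equations."""
        r = (self.K @ u - f)[self._int_idx]
        norm_f = np.linalg.norm(f[self._int_idx])
        return float(np.linalg.norm(r) / norm_f) if norm_f > 0 else float(np.linalg.norm(r))


def assemble_stiffness(lattice: LatticeConfig,
                       elasticity: ElasticityParameters) -> FemSystem:
    """Build (and factorize) the global plane-stress stiffness for the grid."""
    return FemSystem(lattice, elasticity)


def solve_displacements(system: FemSystem, f: np.ndarray,
                        tol: float = 1e-10) -> np.ndarray:
    """Nodal displacements under ``f``; raises if the relative residual exceeds ``tol``."""
    u = system.solve(f)
    res = system.residual(u, f)
    if res > tol:
        raise RuntimeError(f"elasticity solve did not converge: residual {res:.3e}")
    return u


def traction_forces(state, mu_force: float, M: int,
                    pixel_map=None) -> np.ndarray:
    """Nodal traction forces per unit substrate thickness (N/m).

    Every node incident to a pixel of a cell receives the contractile pull
    ``f_k = mu_force * sum_j (X_j - X_k)`` over the nodes ``j`` of the same
    cell (signed component-wise distances, in metres): a net-zero force field
    pointing toward the cell's node centroid.  Nodes outside every cell carry
    zero force; nodes shared between cells accumulate each cell's pull.
    """
    h_m = state.h * 1e-6
    f = np.zeros(2 * M * M)
    if pixel_map is None:
        pixel_map = state.pixel_map()
    for cid in state.cells:
        pts = pixel_map.get(cid)
        if pts is None or len(pts) == 0:
            continue
        corners = np.concatenate([pts, pts + [1, 0], pts + [0, 1], pts + [1, 1]])
        nodes = np.unique(corners[:, 0] * M + corners[:, 1])
        X = np.stack([nodes // M, nodes % M], axis=1) * h_m
        centroid = X.mean(axis=0)
        pull = mu_force * len(nodes) * (centroid - X)
        f[2 * nodes] += pull[:, 0]
        f[2 * nodes + 1] += pull[:, 1]
    return f


@dataclass
class StrainField:
    """Per-pixel strain tensor with cached principal values and directions.

    ``eps1 >= eps2`` are the principal strains; ``(v1x, v1y)`` and
    ``(v2x, v2y)`` the corresponding orthonormal eigenvector components.
    """

    eps11: np.ndarray
    eps22: np.ndarray
    eps12: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    v1x: np.ndarray
    v1y: np.ndarray
    v2x: np.ndarray
    v2y: np.ndarray


def pixel_strain(u: np.ndarray, M: int, h_m: float) -> StrainField:
    """Strain tensor at each pixel centroid from the nodal displacement vector.

    The bilinear element's ``B`` matrix is evaluated once at the element
    center, which for the square element reduces to centered differences of
    the edge-averaged displacements.
    """
    ux = u[0::2].reshape(M, M)
    uy = u[1::2].reshape(M, M)
    # averages over the two nodes of each vertical/horizontal element edge
    def ddx(w):
        return (w[1:, :-1] + w[1:, 1:] - w[:-1, :-1] - w[:-1, 1:]) / (2.0 * h_m)

    def ddy(w):
        return (w[:-1, 1:] + w[1:, 1:] - w[:-1, :-1] - w[1:, :-1]) / (2.0 * h_m)

    e11 = ddx(ux)
    e22 = ddy(uy)
    e12 = 0.5 * (ddy(ux) + ddx(uy))
    mean = 0.5 * (e11 + e22)
    half_diff = 0.5 * (e11 - e22)
    r = np.sqrt(half_diff ** 2 + e12 ** 2)
    phi = 0.5 * np.arctan2(2.0 * e12, e11 - e22)
    v1x = np.cos(phi)
    v1y = np.sin(phi)
    return StrainField(e11, e22, e12, mean + r, mean - r,
                       v1x, v1y, -v1y, v1x)


def stiffened_modulus(eps: np.ndarray | float,
                      duro: DurotaxisParameters) -> np.ndarray | float:
    """Strain-stiffened substrate modulus ``E(eps) = E0 (1 + eps/eps_st)`` for
    tensile strain; compression neither stiffens nor softens (kPa)."""
    return duro.E0_kpa * (1.0 + np.maximum(eps, 0.0) / duro.eps_st)


def stiffness_sigmoid(E_kpa: np.ndarray | float,
                      duro: DurotaxisParameters) -> np.ndarray | float:
    """Perception sigmoid ``h(E) = 1 / (1 + exp(-omega (E - E_theta)))``."""
    return 1.0 / (1.0 + np.exp(-duro.omega * (np.asarray(E_kpa, dtype=float)
                                              - duro.E_theta_kpa)))


def durotaxis_weights(strain: StrainField,
                      duro: DurotaxisParameters) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel sigmoid weights ``h(E(eps1))`` and ``h(E(eps2))``."""
    h1 = stiffness_sigmoid(stiffened_modulus(strain.eps1, duro), duro)
    h2 = stiffness_sigmoid(stiffened_modulus(strain.eps2, duro), duro)
    return np.asarray(h1), np.asarray(h2)


def durotaxis_delta(strain: StrainField, source: tuple[int, int],
                    target: tuple[int, int], extension: bool,
                    duro: DurotaxisParameters, rho_durot: float) -> float:
    """Durotaxis energy variation of one copy attempt.

    Uses the strain in the target pixel for extensions (``g = +1``) and in the
    source pixel for retractions (``g = -1``); the unit step direction runs
    from source to target.  Invariant under the sign flip of either
    eigenvector (projections enter squared).
    """
    dx = float(target[0] - source[0])
    dy = float(target[1] - source[1])
    norm = math.hypot(dx, dy)
    dx, dy = dx / norm, dy / norm
    px = target if extension else source
    g = 1.0 if extension else -1.0
    h1 = stiffness_sigmoid(stiffened_modulus(float(strain.eps1[px]), duro), duro)
    h2 = stiffness_sigmoid(stiffened_modulus(float(strain.eps2[px]), duro), duro)
    pr1 = strain.v1x[px] * dx + strain.v1y[px] * dy
    pr2 = strain.v2x[px] * dx + strain.v2y[px] * dy
    return -rho_durot * g * (h1 * pr1 * pr1 + h2 * pr2 * pr2)
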