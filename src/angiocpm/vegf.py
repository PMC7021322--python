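"""VEGF reaction-diffusion field with cellular consumption and fixed boundary profile.

The concentration obeys ``dC/dt = D_f Laplacian(C) - nu C - G`` on the node
grid, with Dirichlet data ``C = 0`` on the left edge, ``C = S`` on the right
(hypoxic) edge and a linear ramp ``S x / L`` on top and bottom.  The field is
stored nondimensionally, ``c = C/S`` (see :class:`~angiocpm.config.VegfParameters`
for the molecule-count conversion used by signaling).

The default time scheme is backward Euler (unconditionally stable; the
diffusive CFL limit at h = 2.5 um is ~4e-5 h, far below one MCTS); the
operator factorization is cached per time-step size.  An explicit FTCS scheme
with automatic sub-stepping is available via the config.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .config import ConfigError, LatticeConfig, VegfParameters


def consumption(c_value: float | np.ndarray, in_ec: bool | np.ndarray,
                params: VegfParameters) -> float | np.ndarray:
    """Cellular VEGF uptake rate ``G`` in c-units per hour.

    ``G = Gamma`` where uptake saturates (``Gamma <= upsilon C``), ``upsilon C``
    below saturation, and 0 outside endothelial cells.  Negative concentrations
    are clamped to zero before evaluation.
    """
    c = np.maximum(np.asarray(c_value, dtype=float), 0.0)
    g = np.minimum(params.upsilon * c, params.Gamma_c_units)
    out = np.where(in_ec, g, 0.0)
    return float(out) if np.isscalar(c_value) else out


def boundary_profile(M: int, boundary_value: float = 1.0) -> dict[str, np.ndarray]:
    """Dirichlet data per edge: left 0, right ``boundary_value``, ramp on top/bottom."""
    ramp = boundary_value * np.arange(M) / (M - 1)
    return {"left": np.zeros(M), "right": np.full(M, boundary_value),
            "bottom": ramp.copy(), "top": ramp.copy()}


def apply_boundary(c: np.ndarray, boundary_value: float = 1.0) -> np.ndarray:
    """Pin the Dirichlet boundary values on a ``(M, M)`` node field ``c[ix, iy]``."""
    M = c.shape[0]
    bp = boundary_profile(M, boundary_value)
    c[0, :] = bp["left"]
    c[-1, :] = bp["right"]
    c[:, 0] = bp["bottom"]
    c[:, -1] = bp["top"]
    return c


def ec_node_mask(spin: np.ndarray) -> np.ndarray:
    """Nodes lying on or adjacent to an endothelial-cell pixel.

    A node is "in an EC" if any of its (up to four) incident pixels carries an
    EC label; consumption is evaluated on nodes although cells are pixel sets.
    """
    nx, ny = spin.shape
    M = nx + 1
    pix = spin > 0
    mask = np.zeros((M, M), dtype=bool)
    mask[:-1, :-1] |= pix
    mask[1:, :-1] |= pix
    mask[:-1, 1:] |= pix
    mask[1:, 1:] |= pix
    return mask


class VegfModel:
    """Concentration field plus cached implicit operators.

    ``c[ix, iy]`` holds the nondimensional concentration at node (ix, iy).
    """

    def __init__(self, lattice: LatticeConfig, params: VegfParameters,
                 boundary_value: float = 1.0, initial: str = "zero",
                 boundary: dict[str, np.ndarray] | None = None):
        self.M = lattice.M
        self.h_um = lattice.h_um
        self.params = params
        self.boundary_value = float(boundary_value)
        #: Dirichlet data per edge; override for verification fixtures
        self.boundary = boundary if boundary is not None \
            else boundary_profile(self.M, self.boundary_value)
        self.c = np.zeros((self.M, self.M))
        if initial == "ramp":
            self.c[:] = boundary_value * (np.arange(self.M) / (self.M - 1))[:, None]
        elif initial != "zero":
            raise ConfigError("initial must be 'zero' or 'ramp'")
        self._apply_boundary()
        self._lu_cache: dict[float, tuple] = {}

    def _apply_boundary(self) -> None:
        self.c[0, :] = self.boundary["left"]
        self.c[-1, :] = self.boundary["right"]
        self.c[:, 0] = self.boundary["bottom"]
        self.c[:, -1] = self.boundary["top"]

    # -- implicit operator -------------------------------------------------
    def _operator(self, dt: float):
        key = round(dt, 12)
        if key not in self._lu_cache:
            M = self.M
            m = M - 2
            alpha = dt * self.params.D_um2_h / self.h_um ** 2
            lap = sp.diags([np.ones(m - 1), -2.0 * np.ones(m), np.ones(m - 1)],
                           [-1, 0, 1], format="csr")
            eye = sp.identity(m, format="csr")
            L2 = sp.kron(lap, eye) + sp.kron(eye, lap)
            A = (1.0 + dt * self.params.nu_decay) * sp.identity(m * m) - alpha * L2
            # boundary contributions (constant in time)
            bp = self.boundary
            bvec = np.zeros((m, m))
            bvec[0, :] += bp["left"][1:-1]
            bvec[-1, :] += bp["right"][1:-1]
            bvec[:, 0] += bp["bottom"][1:-1]
            bvec[:, -1] += bp["top"][1:-1]
            self._lu_cache[key] = (splu(A.tocsc()), alpha * bvec.ravel())
        return self._lu_cache[key]

    def step(self, dt_hours: float, ec_nodes: np.ndarray | None = None) -> np.ndarray:
        """Advance one time step of diffusion - decay - consumption."""
        if self.params.scheme == "explicit":
            return self._step_explicit(dt_hours, ec_nodes)
        lu, bvec = self._operator(dt_hours)
        interior = self.c[1:-1, 1:-1]
        g = 0.0
        if ec_nodes is not None:
            g = consumption(interior, ec_nodes[1:-1, 1:-1], self.params)
        rhs = interior.ravel() - dt_hours * np.ravel(g) + bvec
        m = self.M - 2
        self.c[1:-1, 1:-1] = np.maximum(lu.solve(rhs).reshape(m, m), 0.0)
        self._apply_boundary()
        return self.c

    def _step_explicit(self, dt_hours: float, ec_nodes: np.ndarray | None) -> np.ndarray:
        dt_max = self.h_um ** 2 / (4.0 * self.params.D_um2_h)
        nsub = int(np.ceil(dt_hours / dt_max))
        dt = dt_hours / nsub
        D = self.params.D_um2_h / self.h_um ** 2
        for _ in range(nsub):
            c = self.c
            lap = (c[:-2, 1:-1] + c[2:, 1:-1] + c[1:-1, :-2] + c[1:-1, 2:]
                   - 4.0 * c[1:-1, 1:-1])
            g = 0.0
            if ec_nodes is not None:
                g = consumption(c[1:-1, 1:-1], ec_nodes[1:-1, 1:-1], self.params)
            c[1:-1, 1:-1] += dt * (D * lap - self.params.nu_decay * c[1:-1, 1:-1]
                                   - np.asarray(g))
            np.maximum(c, 0.0, out=c)
            self._apply_boundary()
        return self.c

    def iterate_to_steady(self, dt_hours: float = 5.0, max_iter: int = 500,
                          tol: float = 1e-12,
                          ec_nodes: np.ndarray | None = None) -> np.ndarray:
        """Iterate implicit steps until the max change per step drops below ``tol``."""
        for _ in range(max_iter):
            prev = self.c.copy()
            self.step(dt_hours, ec_nodes)
            if np.max(np.abs(self.c - prev)) < tol:
                break
        return self.c

    # -- sampling ----------------------------------------------------------
    def pixel_values(self) -> np.ndarray:
        """Concentration per pixel, read at the pixel's bottom-left node."""
        return self.c[:-1, :-1]

    def gradient_at(self, ix: int, iy: int) -> tuple[float, float]:
        """Central-difference gradient (per um) at node (ix, iy)."""
        M = self.M
        ix = min(max(ix, 1), M - 2)
        iy = min(max(iy, 1), M - 2)
        gx = (self.c[ix + 1, iy] - self.c[ix - 1, iy]) / (2.0 * self.h_um)
        gy = (self.c[ix, iy + 1] - self.c[ix, iy - 1]) / (2.0 * self.h_um)
        return float(gx), float(gy)


def step_vegf(model: VegfModel, spin: np.ndarray | None, dt_hours: float) -> np.ndarray:
    """One VEGF time step given the current CPM spin field (or None for no cells)."""
    mask = ec_node_mask(spin) if spin is not None else None
    return model.step(dt_hours, mask)
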