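"""Per-cell Notch / Delta-4 / Jagged-1 / NICD / VEGFR2 / VEGF signaling dynamics.

Each cell carries six molecule counts (N, D, J, I, VR, V).  Production is
gated by shifted Hill functions of NICD (and of internal VEGF for Delta);
receptors and ligands interact by cis-inhibition within a cell and
trans-activation with the perimeter-weighted ligand content of the contacting
neighbors; trans-interactions release NICD; VEGFR2 internalizes external VEGF
sampled from the continuum field at the cell's hypoxia-facing pixel.

Lateral inhibition (a high-Delta cell suppressing the tip phenotype in its
neighbors) and lateral induction (Jagged propagating the stalk phenotype)
both emerge from these equations depending on the production rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import HillParameters, SignalingRates, VegfParameters
from .lattice import InvalidCellError, LatticeState

SPECIES = ("N", "D", "J", "I", "VR", "V")


def hill_shifted(xi: np.ndarray | float, xi0: float, n: float,
                 lam: float) -> np.ndarray | float:
    """Shifted Hill function ``H^S = H^- + lam * H^+``.

    ``H^-(xi) = 1/(1 + (xi/xi0)^n)`` is inhibitory and ``H^+ = 1 - H^-``
    excitatory; the fold change ``lam`` interpolates between pure inhibition
    (``lam = 0``), no regulation (``lam = 1``) and excitation (``lam > 1``).
    """
    ratio = (np.maximum(np.asarray(xi, dtype=float), 0.0) / xi0) ** n
    h_minus = 1.0 / (1.0 + ratio)
    out = h_minus + lam * (1.0 - h_minus)
    return float(out) if np.isscalar(xi) else out


# ---------------------------------------------------------------------------
# contact graph
# ---------------------------------------------------------------------------

@dataclass
class ContactGraph:
    """Shared-boundary lengths between cells.

    ``shared[(i, j)]`` (i < j) is the boundary length P_ij (um); ``perimeter``
    maps each cell to its total perimeter P_i (um), which includes boundary
    shared with the ECM, so ``sum_j P_ij <= P_i``.
    """

    shared: dict[tuple[int, int], float] = field(default_factory=dict)
    perimeter: dict[int, float] = field(default_factory=dict)

    def neighbors(self, cid: int):
        for (a, b), length in self.shared.items():
            if a == cid:
                yield b, length
            elif b == cid:
                yield a, length

    def weight_matrix(self, order: list[int]) -> np.ndarray:
        """``W[i, j] = P_ij / P_i`` for the given cell ordering."""
        pos = {cid: k for k, cid in enumerate(order)}
        W = np.zeros((len(order), len(order)))
        for (a, b), length in self.shared.items():
            if a in pos and b in pos:
                W[pos[a], pos[b]] = length / self.perimeter[a]
                W[pos[b], pos[a]] = length / self.perimeter[b]
        return W


def build_contact_graph(state: LatticeState) -> ContactGraph:
    """Cell-cell shared boundary lengths from the spin field (von Neumann edges)."""
    spin = state.spin
    h = state.h
    shared: dict[tuple[int, int], float] = {}
    for a, b in ((spin[:-1, :], spin[1:, :]), (spin[:, :-1], spin[:, 1:])):
        m = (a != b) & (a != 0) & (b != 0)
        if not m.any():
            continue
        lo = np.minimum(a[m], b[m]).astype(np.int64)
        hi = np.maximum(a[m], b[m]).astype(np.int64)
        pairs, counts = np.unique(lo << 32 | hi, return_counts=True)
        for code, cnt in zip(pairs, counts):
            key = (int(code >> 32), int(code & 0xFFFFFFFF))
            shared[key] = shared.get(key, 0.0) + cnt * h
    perim = {cid: cell.perim_edges * h for cid, cell in state.cells.items()}
    return ContactGraph(shared=shared, perimeter=perim)


def external_ligand(cid: int, graph: ContactGraph,
                    values: Mapping[int, float]) -> float:
    """Perimeter-weighted external ligand count ``(1/P_i) sum_j P_ij X_j``."""
    P_i = graph.perimeter.get(cid, 0.0)
    if P_i <= 0:
        raise InvalidCellError(f"cell {cid} has zero perimeter")
    return sum(length * values[j] for j, length in graph.neighbors(cid)) / P_i


def hypoxia_facing_pixel(state: LatticeState, cid: int) -> tuple[int, int]:
    """The cell pixel closest to the hypoxic boundary: maximal x, then minimal y."""
    pts = state.pixels_of(cid)
    if len(pts) == 0:
        raise InvalidCellError(f"cell {cid} has no pixels")
    xmax = pts[:, 0].max()
    ys = pts[pts[:, 0] == xmax, 1]
    return int(xmax), int(ys.min())


def external_vegf(state: LatticeState, cid: int, c_nodes: np.ndarray,
                  hill: HillParameters, vegf: VegfParameters) -> float:
    """External VEGF molecule count seen by a cell.

    Reads the continuum field at the bottom-left grid node of the cell's
    hypoxia-facing pixel and converts c-units to molecules via
    ``chi_V * S_molec``.
    """
    ix, iy = hypoxia_facing_pixel(state, cid)
    return hill.chi_V * vegf.S_molec * float(c_nodes[ix, iy])


# ---------------------------------------------------------------------------
# ODE right-hand side and integrator
# ---------------------------------------------------------------------------

def signaling_rhs(y: np.ndarray, n_ext: np.ndarray, d_ext: np.ndarray,
                  j_ext: np.ndarray, v_ext: np.ndarray, rates: SignalingRates,
                  hill: HillParameters) -> np.ndarray:
    """Time derivatives of ``y = (N, D, J, I, VR, V)`` stacked as ``(6, n_cells)``."""
    N, D, J, I, VR, V = y
    h_I_N = hill_shifted(I, hill.I_0, hill.n_N, hill.lambda_I_N)
    h_I_D = hill_shifted(I, hill.I_0, hill.n_D, hill.lambda_I_D)
    h_V_D = hill_shifted(V, hill.V_0, hill.n_V, hill.lambda_V_D)
    h_I_J = hill_shifted(I, hill.I_0, hill.n_J, hill.lambda_I_J)
    h_I_VR = hill_shifted(I, hill.I_0, hill.n_VR, hill.lambda_I_VR)
    h_D_F = hill_shifted(I, hill.I_0, hill.n_F, hill.lambda_D_F)
    h_J_F = hill_shifted(I, hill.I_0, hill.n_F, hill.lambda_J_F)
    kC, kT, g, gS = rates.k_C, rates.k_T, rates.gamma, rates.gamma_S
    dN = rates.r_N * h_I_N - ((kC * D + kT * d_ext) * h_D_F
                              + (kC * J + kT * j_ext) * h_J_F + g) * N
    dD = rates.r_D * h_I_D * h_V_D - (kC * N * h_D_F + kT * n_ext + g) * D
    dJ = rates.r_J * h_I_J - (kC * N * h_J_F + kT * n_ext + g) * J
    dI = kT * N * (h_D_F * d_ext + h_J_F * j_ext) - gS * I
    dVR = rates.r_VR * h_I_VR - kT * VR * v_ext - g * VR
    dV = kT * VR * v_ext - gS * V
    return np.stack([dN, dD, dJ, dI, dVR, dV])


def integrate_signaling(y: np.ndarray, W: np.ndarray, v_ext: np.ndarray,
                        rates: SignalingRates, hill: HillParameters,
                        dt_hours: float, substeps: int = 20) -> np.ndarray:
    """Advance all cells' signaling states by ``dt_hours``.

    ``y`` is ``(6, n_cells)``; ``W`` the perimeter-weight matrix so that
    ``X_ext = W @ X``; ``v_ext`` the external VEGF molecule counts.  Explicit
    Euler with sub-stepping; any numerical undershoot below zero is clamped.
    """
    dt = dt_hours / substeps
    for _ in range(substeps):
        n_ext = W @ y[0]
        d_ext = W @ y[1]
        j_ext = W @ y[2]
        y = y + dt * signaling_rhs(y, n_ext, d_ext, j_ext, v_ext, rates, hill)
        np.maximum(y, 0.0, out=y)
    return y


def isolated_fixed_point(rates: SignalingRates, hill: HillParameters,
                         v_ext: float = 0.0) -> np.ndarray:
    """Steady state of an isolated cell (no EC neighbors) by root finding.

    Independent of the time-stepping path: solves ``rhs = 0`` with
    ``N_ext = D_ext = J_ext = 0`` using a damped Newton iteration from
    scipy.  Used as the cross-check oracle for the integrator.
    """
    from scipy.optimize import fsolve

    zeros = np.zeros(1)

    def fun(y):
        return signaling_rhs(y.reshape(6, 1), zeros, zeros, zeros,
                             np.full(1, v_ext), rates, hill).ravel()

    g = rates.gamma
    y0 = np.array([rates.r_N / g, rates.r_D / g, rates.r_J / g, 1.0,
                   rates.r_VR / g, 1.0])
    sol = fsolve(fun, y0, full_output=False, xtol=1e-12)
    return np.asarray(sol)


def nondimensional_scales(rates: SignalingRates,
                          hill: HillParameters) -> dict[str, float]:
    """Characteristic scales implied by the rate constants.

    ``N/D/J``-type ligands scale with ``r_D/k_C``; NICD with
    ``k_T r_D / (k_C gamma_S)``; VEGFR2 with ``r_VR/gamma``; internal and
    external VEGF with ``V_0`` and ``6 V_0``; time with ``1/(k_C r_D)``.
    """
    return {
        "ligand": rates.r_D / rates.k_C,
        "NICD": rates.k_T * rates.r_D / (rates.k_C * rates.gamma_S),
        "VR": rates.r_VR / rates.gamma,
        "V": hill.V_0,
        "V_ext": 6.0 * hill.V_0,
        "time_h": 1.0 / (rates.k_C * rates.r_D),
    }
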