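"""Square-lattice Cellular Potts model: state, Hamiltonian terms and Metropolis kinetics.

Cells are sets of lattice pixels carrying an integer spin label (label 0 is the
extracellular matrix).  The configuration energy penalizes deviations of each
cell's area, perimeter and inertia-tensor length from its targets, plus an
adhesion cost per heterotypic neighbor-pixel pair; chemotaxis and durotaxis
enter as per-flip energy variations.  One Monte Carlo time step (MCTS) is a
full sweep of ``(M-1)^2`` pixel-copy attempts accepted by the Metropolis rule.

Per-cell geometry (pixel count, raw coordinate moments, exposed-edge count) is
cached incrementally so a copy attempt costs O(1); the cached increments are
cross-checked against full recomputation in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import CellShapeTargets, ConfigError, PottsParameters

# phenotypes (integer-coded for the hot loop)
STALK, HYBRID, TIP = 0, 1, 2
PHENOTYPE_NAMES = {STALK: "stalk", HYBRID: "hybrid", TIP: "tip"}

ECM = 0

_VN4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_MOORE8 = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1))


class InvalidCellError(ValueError):
    """Raised for operations on an empty or unknown cell."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def cell_geometry(pixels: Iterable[tuple[int, int]], h: float) -> tuple[float, float, float]:
    """Area, perimeter and inertia-tensor length of a pixel set.

    Parameters
    ----------
    pixels : iterable of (ix, iy)
        Integer pixel coordinates occupied by the cell.
    h : float
        Pixel side length (um).

    Returns
    -------
    (area, perimeter, length)
        Area ``n h^2`` (um^2); perimeter as the number of pixel edges facing a
        different label (here: any coordinate not in the set) times ``h`` (um);
        length ``2a`` where ``a`` is twice the square root of the largest
        eigenvalue of the per-unit-area inertia tensor of the pixel centers
        about the centroid (um).  A single pixel has length 0.
    """
    pts = {(int(x), int(y)) for x, y in pixels}
    if not pts:
        raise InvalidCellError("empty pixel set")
    n = len(pts)
    edges = sum((x + dx, y + dy) not in pts for x, y in pts for dx, dy in _VN4)
    xs = np.fromiter((p[0] for p in pts), float, n) + 0.5
    ys = np.fromiter((p[1] for p in pts), float, n) + 0.5
    lam = _lambda_max(n, xs.sum(), ys.sum(), (xs * xs).sum(), (ys * ys).sum(),
                      (xs * ys).sum())
    return n * h * h, edges * h, 4.0 * math.sqrt(max(lam, 0.0)) * h


def _lambda_max(n: float, sx: float, sy: float, sxx: float, syy: float,
                sxy: float) -> float:
    """Largest eigenvalue of the per-unit-area inertia tensor from raw moments.

    The tensor is I = [[var_y, -cov], [-cov, var_x]] of the pixel centers
    (coordinates in pixel units unless the moments already carry um).
    """
    var_x = sxx / n - (sx / n) ** 2
    var_y = syy / n - (sy / n) ** 2
    cov = sxy / n - (sx / n) * (sy / n)
    half_tr = 0.5 * (var_x + var_y)
    disc = math.sqrt((0.5 * (var_x - var_y)) ** 2 + cov * cov)
    return half_tr + disc


# ---------------------------------------------------------------------------
# per-cell record
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """One endothelial cell: geometry caches, CPM targets, motility and signaling state.

    Coordinate moments (``sx`` ... ``sxy``) are raw sums over pixel centers in
    pixel units; ``perim_edges`` counts exposed von Neumann edges (lattice
    border counts as exposed).
    """

    id: int
    vessel: int = 0
    # geometry caches
    n: int = 0
    sx: float = 0.0
    sy: float = 0.0
    sxx: float = 0.0
    syy: float = 0.0
    sxy: float = 0.0
    perim_edges: int = 0
    # CPM targets (um^2, um, um)
    A_target: float = 78.50
    P_target: float = 31.4
    L_target: float = 49.5
    # effective per-cell motility coefficients (refreshed every MCTS)
    rho_length: float = 7200.0
    rho_chem: float = 0.0
    rho_durot: float = 0.0
    rho_persist: float = 0.0
    persist_cx: float = 0.0
    persist_cy: float = 0.0
    # bookkeeping
    phenotype: int = STALK
    proliferating: bool = False
    tip_prolif_allowed: bool = False
    # signaling state (molecule counts)
    N: float = 0.0
    D: float = 0.0
    J: float = 0.0
    I: float = 0.0
    VR: float = 0.0
    V: float = 0.0

    def geometry(self, h: float) -> tuple[float, float, float]:
        """(area, perimeter, length) in um units from the cached moments."""
        if self.n == 0:
            raise InvalidCellError(f"cell {self.id} has no pixels")
        lam = _lambda_max(self.n, self.sx, self.sy, self.sxx, self.syy, self.sxy)
        return (self.n * h * h, self.perim_edges * h,
                4.0 * math.sqrt(max(lam, 0.0)) * h)

    def centroid(self, h: float) -> tuple[float, float]:
        """Centroid in um."""
        return self.sx / self.n * h, self.sy / self.n * h

    def signaling_vector(self) -> np.ndarray:
        return np.array([self.N, self.D, self.J, self.I, self.VR, self.V])


# ---------------------------------------------------------------------------
# lattice state
# ---------------------------------------------------------------------------

class LatticeState:
    """Spin field plus per-cell registry.

    ``spin[ix, iy]`` holds the label of pixel (ix, iy); label 0 is ECM.  The
    per-cell caches are kept consistent with the spin field by all mutating
    methods and by :func:`mcts_sweep`.
    """

    def __init__(self, n_pixels_side: int, h: float):
        self.nx = self.ny = int(n_pixels_side)
        self.h = float(h)
        self.spin = np.zeros((self.nx, self.ny), dtype=np.int32)
        self.cells: dict[int, Cell] = {}
        self._next_id = 1

    # -- construction ------------------------------------------------------
    def new_cell_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    def add_cell(self, pixels: Iterable[tuple[int, int]], cell_id: Optional[int] = None,
                 **attrs) -> Cell:
        """Create a cell occupying ``pixels`` (must currently be ECM)."""
        pts = [(int(x), int(y)) for x, y in pixels]
        if not pts:
            raise InvalidCellError("cannot create a cell with no pixels")
        cid = self.new_cell_id() if cell_id is None else int(cell_id)
        if cell_id is not None:
            self._next_id = max(self._next_id, cid + 1)
        if cid in self.cells:
            raise InvalidCellError(f"cell id {cid} already exists")
        for x, y in pts:
            if self.spin[x, y] != ECM:
                raise InvalidCellError(f"pixel {(x, y)} is already occupied")
            self.spin[x, y] = cid
        cell = Cell(id=cid, **attrs)
        self.cells[cid] = cell
        self.recompute_cache(cid)
        return cell

    def remove_cell(self, cid: int) -> None:
        self.spin[self.spin == cid] = ECM
        del self.cells[cid]

    def pixels_of(self, cid: int) -> np.ndarray:
        """(n, 2) integer array of pixel coordinates of cell ``cid``."""
        return np.argwhere(self.spin == cid)

    def pixel_map(self) -> dict[int, np.ndarray]:
        """Pixel coordinates of every cell in one pass over the lattice."""
        xs, ys = np.nonzero(self.spin)
        labels = self.spin[xs, ys]
        order = np.argsort(labels, kind="stable")
        xs, ys, labels = xs[order], ys[order], labels[order]
        pts = np.stack([xs, ys], axis=1)
        out: dict[int, np.ndarray] = {}
        if len(labels):
            bounds = np.flatnonzero(np.diff(labels)) + 1
            for chunk, lab in zip(np.split(pts, bounds),
                                  labels[np.concatenate(([0], bounds))]):
                out[int(lab)] = chunk
        return out

    def recompute_cache(self, cid: int) -> None:
        """Rebuild the geometry caches of ``cid`` from the spin field."""
        cell = self.cells[cid]
        pts = self.pixels_of(cid)
        if len(pts) == 0:
            raise InvalidCellError(f"cell {cid} has no pixels")
        xs = pts[:, 0] + 0.5
        ys = pts[:, 1] + 0.5
        cell.n = len(pts)
        cell.sx = float(xs.sum())
        cell.sy = float(ys.sum())
        cell.sxx = float((xs * xs).sum())
        cell.syy = float((ys * ys).sum())
        cell.sxy = float((xs * ys).sum())
        edges = 0
        pset = {(int(x), int(y)) for x, y in pts}
        for x, y in pset:
            for dx, dy in _VN4:
                q = (x + dx, y + dy)
                if not (0 <= q[0] < self.nx and 0 <= q[1] < self.ny) or q not in pset:
                    edges += 1
        cell.perim_edges = edges

    # -- invariants --------------------------------------------------------
    def check_partition(self) -> None:
        """Assert the label partition and geometry caches are consistent."""
        counts = np.bincount(self.spin.ravel(), minlength=self._next_id)
        for cid, cell in self.cells.items():
            assert counts[cid] == cell.n, f"cell {cid}: cache n={cell.n}, field {counts[cid]}"
        labels = set(np.unique(self.spin)) - {ECM}
        assert labels == set(self.cells), "spin labels and registry differ"


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def shape_energy(geometry: tuple[float, float, float], targets: CellShapeTargets,
                 potts: PottsParameters,
                 rho_length: Optional[float] = None) -> tuple[float, float, float, float]:
    """Quadratic shape penalty of one cell.

    Returns ``(total, area_term, perimeter_term, length_term)`` with
    ``total = rho_area ((a-A)/A)^2 + rho_perimeter ((p-P)/P)^2 +
    rho_length ((l-L)/L)^2``.  ``rho_length`` may be overridden per cell
    (stalk cells drop the elongation constraint in case A).
    """
    a, p, l = geometry
    A, P, L = targets.area, targets.perimeter, targets.length
    if min(A, P, L) <= 0:
        raise ConfigError("shape targets must be positive")
    rl = potts.rho_length if rho_length is None else rho_length
    ta = potts.rho_area * ((a - A) / A) ** 2
    tp = potts.rho_perimeter * ((p - P) / P) ** 2
    tl = rl * ((l - L) / L) ** 2
    return ta + tp + tl, ta, tp, tl


def _shape_energy_from_moments(cell: Cell, n: int, sx: float, sy: float, sxx: float,
                               syy: float, sxy: float, perim_edges: int, h: float,
                               potts: PottsParameters) -> float:
    """Shape energy of a cell with hypothetical moments (hot-loop helper)."""
    a = n * h * h
    p = perim_edges * h
    lam = _lambda_max(n, sx, sy, sxx, syy, sxy)
    l = 4.0 * math.sqrt(max(lam, 0.0)) * h
    ta = potts.rho_area * ((a - cell.A_target) / cell.A_target) ** 2
    tp = potts.rho_perimeter * ((p - cell.P_target) / cell.P_target) ** 2
    tl = cell.rho_length * ((l - cell.L_target) / cell.L_target) ** 2
    return ta + tp + tl


def _adh_coeff(lbl1: int, lbl2: int, potts: PottsParameters) -> float:
    """Adhesion cost for a heterotypic neighbor pair (0 for same label)."""
    if lbl1 == lbl2:
        return 0.0
    if lbl1 != ECM and lbl2 != ECM:
        return potts.rho_adh_cell_cell
    return potts.rho_adh_cell_ecm


def adhesion_energy(state: LatticeState, potts: PottsParameters) -> float:
    """Total adhesion energy: sum over heterotypic neighbor-pixel pairs."""
    spin = state.spin
    shifts = ((1, 0), (0, 1)) if potts.adhesion_neighborhood == 1 else \
        ((1, 0), (0, 1), (1, 1), (1, -1))
    total = 0.0
    for dx, dy in shifts:
        a = spin[max(0, -dx):spin.shape[0] - max(0, dx),
                 max(0, -dy):spin.shape[1] - max(0, dy)]
        b = spin[max(0, dx):spin.shape[0] + min(0, dx),
                 max(0, dy):spin.shape[1] + min(0, dy)]
        diff = a != b
        cc = diff & (a != ECM) & (b != ECM)
        ce = diff & ~cc
        total += potts.rho_adh_cell_cell * cc.sum() + potts.rho_adh_cell_ecm * ce.sum()
    return float(total)


def adhesion_energy_delta(state: LatticeState, source: tuple[int, int],
                          target: tuple[int, int], potts: PottsParameters) -> float:
    """Adhesion-energy change of copying the source pixel's label into the target pixel."""
    s = int(state.spin[source])
    t = int(state.spin[target])
    if s == t:
        return 0.0
    return _adhesion_delta(state.spin, target[0], target[1], s, t, potts)


def _adhesion_delta(spin: np.ndarray, jx: int, jy: int, s: int, t: int,
                    potts: PottsParameters) -> float:
    offs = _VN4 if potts.adhesion_neighborhood == 1 else _MOORE8
    nx, ny = spin.shape
    delta = 0.0
    for dx, dy in offs:
        qx, qy = jx + dx, jy + dy
        if 0 <= qx < nx and 0 <= qy < ny:
            u = spin[qx, qy]
            delta += _adh_coeff(s, u, potts) - _adh_coeff(t, u, potts)
    return delta


def total_energy(state: LatticeState, potts: PottsParameters) -> float:
    """Full configuration energy (shape + adhesion terms; the taxis terms are
    defined only as per-flip variations)."""
    h = state.h
    total = adhesion_energy(state, potts)
    for cell in state.cells.values():
        targets = CellShapeTargets(cell.A_target, cell.P_target, cell.L_target)
        total += shape_energy(cell.geometry(h), targets, potts,
                              rho_length=cell.rho_length)[0]
    return total


def chemotaxis_delta(c_source: float, c_target: float, rho_chem: float,
                     alpha_chem: float) -> float:
    """Chemotaxis energy variation: ``-rho_chem (C(x') - C(x)) / (1 + alpha C(x))``."""
    return -rho_chem * (c_target - c_source) / (1.0 + alpha_chem * c_source)


def metropolis_accept(delta_H: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability 1 if ``delta_H <= 0``, else ``exp(-delta_H/T)``."""
    if T <= 0:
        raise ConfigError("Potts temperature must be positive")
    if delta_H <= 0:
        return True
    return rng.random() < math.exp(-delta_H / T)


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepFields:
    """Per-pixel external fields consumed by the sweep.

    ``c_pix`` is the VEGF concentration at each pixel (c-units); the durotaxis
    arrays hold the precomputed sigmoid weights ``h(E(eps_1))``, ``h(E(eps_2))``
    and the principal strain directions.  ``max_D`` feeds the case (B)
    Delta-weighted chemotaxis coefficient.
    """

    c_pix: Optional[np.ndarray] = None
    dur_h1: Optional[np.ndarray] = None
    dur_h2: Optional[np.ndarray] = None
    v1x: Optional[np.ndarray] = None
    v1y: Optional[np.ndarray] = None
    v2x: Optional[np.ndarray] = None
    v2y: Optional[np.ndarray] = None
    case: str = "A"
    max_D: float = 0.0


def _locally_connected_without(spin: np.ndarray, jx: int, jy: int, t: int) -> bool:
    """True if cell ``t``'s pixels in the Moore ring of (jx, jy) form one
    8-connected component, i.e. removing (jx, jy) does not locally split ``t``."""
    nx, ny = spin.shape
    ring = []
    for dx, dy in _MOORE8:
        qx, qy = jx + dx, jy + dy
        if 0 <= qx < nx and 0 <= qy < ny and spin[qx, qy] == t:
            ring.append((dx, dy))
    m = len(ring)
    if m <= 1:
        return True
    # flood fill over ring members (adjacent if offsets differ by <= 1)
    seen = [False] * m
    stack = [0]
    seen[0] = True
    count = 1
    while stack:
        i = stack.pop()
        xi, yi = ring[i]
        for k in range(m):
            if not seen[k]:
                xk, yk = ring[k]
                if abs(xi - xk) <= 1 and abs(yi - yk) <= 1:
                    seen[k] = True
                    count += 1
                    stack.append(k)
    return count == m


def flip_delta(state: LatticeState, potts: PottsParameters, ix: int, iy: int,
               jx: int, jy: int, fields: Optional[SweepFields] = None) -> float:
    """Total energy variation of copying pixel (ix, iy)'s label onto (jx, jy).

    Includes shape, adhesion, durotaxis, chemotaxis and the persistent-motion
    bonus of incubating tip cells.  Exposed for testing; :func:`mcts_sweep`
    evaluates the same expression inline.
    """
    spin = state.spin
    s = int(spin[ix, iy])
    t = int(spin[jx, jy])
    if s == t:
        return 0.0
    h = state.h
    px, py = jx + 0.5, jy + 0.5
    dH = _adhesion_delta(spin, jx, jy, s, t, potts)
    dH += _shape_delta(state, potts, s, t, jx, jy, px, py, h)
    if fields is not None:
        dH += _field_delta(state, potts, fields, s, t, ix, iy, jx, jy)
    return dH


def _shape_delta(state, potts, s, t, jx, jy, px, py, h):
    spin = state.spin
    nx, ny = spin.shape
    dH = 0.0
    # perimeter-edge changes for s (gaining) and t (losing)
    dps = dpt = 0
    for dx, dy in _VN4:
        qx, qy = jx + dx, jy + dy
        if 0 <= qx < nx and 0 <= qy < ny:
            u = spin[qx, qy]
        else:
            u = -1  # domain border: always an exposed edge
        dpt += 1 if u == t else -1
        dps += -1 if u == s else 1
    if s != ECM:
        cs = state.cells[s]
        dH += _shape_energy_from_moments(
            cs, cs.n + 1, cs.sx + px, cs.sy + py, cs.sxx + px * px,
            cs.syy + py * py, cs.sxy + px * py, cs.perim_edges + dps, h, potts)
        dH -= _shape_energy_from_moments(
            cs, cs.n, cs.sx, cs.sy, cs.sxx, cs.syy, cs.sxy, cs.perim_edges, h, potts)
    if t != ECM:
        ct = state.cells[t]
        dH += _shape_energy_from_moments(
            ct, ct.n - 1, ct.sx - px, ct.sy - py, ct.sxx - px * px,
            ct.syy - py * py, ct.sxy - px * py, ct.perim_edges + dpt, h, potts)
        dH -= _shape_energy_from_moments(
            ct, ct.n, ct.sx, ct.sy, ct.sxx, ct.syy, ct.sxy, ct.perim_edges, h, potts)
    return dH


def _field_delta(state, potts, fields, s, t, ix, iy, jx, jy):
    """Durotaxis + chemotaxis + persistence contribution of one flip."""
    dH = 0.0
    dx = float(jx - ix)
    dy = float(jy - iy)
    cells = state.cells
    if fields.dur_h1 is not None:
        # extension of the source cell: strain in the target pixel, g = +1
        if s != ECM:
            rho = cells[s].rho_durot
            if rho != 0.0:
                pr1 = fields.v1x[jx, jy] * dx + fields.v1y[jx, jy] * dy
                pr2 = fields.v2x[jx, jy] * dx + fields.v2y[jx, jy] * dy
                dH -= rho * (fields.dur_h1[jx, jy] * pr1 * pr1 +
                             fields.dur_h2[jx, jy] * pr2 * pr2)
        # retraction of the target-pixel cell: strain in the source pixel, g = -1
        if t != ECM:
            rho = cells[t].rho_durot
            if rho != 0.0:
                pr1 = fields.v1x[ix, iy] * dx + fields.v1y[ix, iy] * dy
                pr2 = fields.v2x[ix, iy] * dx + fields.v2y[ix, iy] * dy
                dH += rho * (fields.dur_h1[ix, iy] * pr1 * pr1 +
                             fields.dur_h2[ix, iy] * pr2 * pr2)
    if fields.c_pix is not None:
        c_src = fields.c_pix[ix, iy]
        c_tgt = fields.c_pix[jx, jy]
        if fields.case == "B":
            if fields.max_D > 0.0:
                if s != ECM and t != ECM:
                    dlev = 0.5 * (cells[s].D + cells[t].D)
                else:
                    dlev = cells[s].D if s != ECM else cells[t].D
                rho_c = potts.rho_chem0 * dlev / fields.max_D
            else:
                rho_c = 0.0
        else:
            rho_c = cells[s].rho_chem if s != ECM else cells[t].rho_chem
        if rho_c != 0.0:
            dH -= rho_c * (c_tgt - c_src) / (1.0 + potts.alpha_chem * c_src)
    # persistent motion of an incubating tip cell (extensions only)
    if s != ECM:
        cs = cells[s]
        if cs.rho_persist != 0.0:
            dH -= cs.rho_persist * (cs.persist_cx * dx + cs.persist_cy * dy)
    return dH


def mcts_sweep(state: LatticeState, potts: PottsParameters, T: float,
               rng: np.random.Generator, fields: Optional[SweepFields] = None,
               n_attempts: Optional[int] = None,
               use_kernel: bool = True) -> tuple[int, int]:
    """One Monte Carlo time step: ``n_attempts`` pixel-copy attempts.

    Each attempt picks a random pixel and a random von Neumann neighbor; if the
    labels differ, the total energy variation (shape + adhesion + durotaxis +
    chemotaxis + persistence) is evaluated and the copy accepted by the
    Metropolis rule.  Flips that would annihilate a cell's last pixel are
    rejected, as are flips failing the local-connectivity check (if enabled).

    The attempt loop runs in the compiled kernel when numba is available
    (``use_kernel=True``); the Python loop below is the reference
    implementation and consumes the identical random stream.

    Returns ``(n_evaluated, n_accepted)``.
    """
    if use_kernel:
        from ._kernel import HAVE_NUMBA
        if HAVE_NUMBA:
            return _sweep_via_kernel(state, potts, T, rng, fields, n_attempts)
    spin = state.spin
    nx, ny = spin.shape
    npix = nx * ny
    if n_attempts is None:
        n_attempts = npix
    # pre-draw the whole sweep's randomness, then visit only heterotypic pairs
    idx = rng.integers(0, npix, n_attempts)
    dirs = rng.integers(0, 4, n_attempts)
    unif = rng.random(n_attempts)
    ix_all = idx // ny
    iy_all = idx % ny
    dxy = np.array(_VN4)
    jx_all = ix_all + dxy[dirs, 0]
    jy_all = iy_all + dxy[dirs, 1]
    valid = (jx_all >= 0) & (jx_all < nx) & (jy_all >= 0) & (jy_all < ny)
    cand = np.flatnonzero(valid & (spin[ix_all % nx, iy_all] !=
                                   spin[jx_all % nx, jy_all % ny]))
    cells = state.cells
    check_conn = potts.connectivity_check
    n_eval = n_acc = 0
    for k in cand:
        ix = int(ix_all[k]); iy = int(iy_all[k])
        jx = int(jx_all[k]); jy = int(jy_all[k])
        s = int(spin[ix, iy])
        t = int(spin[jx, jy])
        if s == t:  # may have changed since the pre-filter
            continue
        if t != ECM:
            ct = cells[t]
            if ct.n <= 1:
                continue  # never annihilate a cell
            if check_conn and not _locally_connected_without(spin, jx, jy, t):
                continue
        n_eval += 1
        h = state.h
        px, py = jx + 0.5, jy + 0.5
        dH = _adhesion_delta(spin, jx, jy, s, t, potts)
        dH += _shape_delta(state, potts, s, t, jx, jy, px, py, h)
        if fields is not None:
            dH += _field_delta(state, potts, fields, s, t, ix, iy, jx, jy)
        if dH > 0.0 and unif[k] >= math.exp(-dH / T):
            continue
        # accept: apply the flip and update caches
        n_acc += 1
        spin[jx, jy] = s
        dps = dpt = 0
        for dx, dy in _VN4:
            qx, qy = jx + dx, jy + dy
            if 0 <= qx < nx and 0 <= qy < ny:
                u = spin[qx, qy]
                u = int(u)
            else:
                u = -1
            if u == s:  # note: (jx,jy) itself is now s but is not its own neighbor
                dps -= 1
            else:
                dps += 1
            if u == t:
                dpt += 1
            else:
                dpt -= 1
        # the neighbor scan above counts edges around (jx, jy) after the flip;
        # correct t's loss: edges formerly interior to t are now exposed for t
        if s != ECM:
            cs = cells[s]
            cs.n += 1
            cs.sx += px; cs.sy += py
            cs.sxx += px * px; cs.syy += py * py; cs.sxy += px * py
            cs.perim_edges += dps
        if t != ECM:
            ct = cells[t]
            ct.n -= 1
            ct.sx -= px; ct.sy -= py
            ct.sxx -= px * px; ct.syy -= py * py; ct.sxy -= px * py
            ct.perim_edges += dpt
    return n_eval, n_acc


def _sweep_via_kernel(state: LatticeState, potts: PottsParameters, T: float,
                      rng: np.random.Generator, fields: Optional[SweepFields],
                      n_attempts: Optional[int]) -> tuple[int, int]:
    """Gather per-cell caches into label-indexed arrays and run the compiled loop."""
    from ._kernel import sweep_kernel

    spin = state.spin
    nx, ny = spin.shape
    npix = nx * ny
    if n_attempts is None:
        n_attempts = npix
    idx = rng.integers(0, npix, n_attempts)
    dirs = rng.integers(0, 4, n_attempts)
    unif = rng.random(n_attempts)
    cells = state.cells
    cap = (max(cells) if cells else 0) + 1
    arrs = {name: np.zeros(cap) for name in
            ("nn", "sx", "sy", "sxx", "syy", "sxy", "perim", "A", "P", "L",
             "rlen", "rchem", "rdur", "rpers", "pcx", "pcy", "dlev")}
    for cid, c in cells.items():
        arrs["nn"][cid] = c.n
        arrs["sx"][cid] = c.sx
        arrs["sy"][cid] = c.sy
        arrs["sxx"][cid] = c.sxx
        arrs["syy"][cid] = c.syy
        arrs["sxy"][cid] = c.sxy
        arrs["perim"][cid] = c.perim_edges
        arrs["A"][cid] = c.A_target
        arrs["P"][cid] = c.P_target
        arrs["L"][cid] = c.L_target
        arrs["rlen"][cid] = c.rho_length
        arrs["rchem"][cid] = c.rho_chem
        arrs["rdur"][cid] = c.rho_durot
        arrs["rpers"][cid] = c.rho_persist
        arrs["pcx"][cid] = c.persist_cx
        arrs["pcy"][cid] = c.persist_cy
        arrs["dlev"][cid] = c.D
    empty = np.zeros((1, 1))
    if fields is not None and fields.c_pix is not None:
        c_pix = np.ascontiguousarray(fields.c_pix, dtype=np.float64)
    else:
        c_pix = empty
    if fields is not None and fields.dur_h1 is not None:
        h1f = np.ascontiguousarray(fields.dur_h1)
        h2f = np.ascontiguousarray(fields.dur_h2)
        v1x = np.ascontiguousarray(fields.v1x)
        v1y = np.ascontiguousarray(fields.v1y)
        v2x = np.ascontiguousarray(fields.v2x)
        v2y = np.ascontiguousarray(fields.v2y)
    else:
        h1f = h2f = v1x = v1y = v2x = v2y = empty
    has_fields = fields is not None and (c_pix is not empty or h1f is not empty)
    if has_fields and c_pix is empty:
        c_pix = np.zeros((nx, ny))
    if has_fields and h1f is empty:
        h1f = h2f = v1x = v1y = v2x = v2y = np.zeros((nx, ny))
    n_eval, n_acc = sweep_kernel(
        spin, idx, dirs, unif,
        arrs["nn"], arrs["sx"], arrs["sy"], arrs["sxx"], arrs["syy"],
        arrs["sxy"], arrs["perim"], arrs["A"], arrs["P"], arrs["L"],
        arrs["rlen"], arrs["rchem"], arrs["rdur"], arrs["rpers"],
        arrs["pcx"], arrs["pcy"], arrs["dlev"],
        state.h, T, potts.rho_area, potts.rho_perimeter,
        potts.rho_adh_cell_cell, potts.rho_adh_cell_ecm,
        potts.adhesion_neighborhood == 2, potts.connectivity_check,
        has_fields, c_pix, h1f, h2f, v1x, v1y, v2x, v2y,
        fields is not None and fields.case == "B", potts.rho_chem0,
        fields.max_D if fields is not None else 0.0, potts.alpha_chem)
    for cid, c in cells.items():
        c.n = int(arrs["nn"][cid])
        c.sx = arrs["sx"][cid]
        c.sy = arrs["sy"][cid]
        c.sxx = arrs["sxx"][cid]
        c.syy = arrs["syy"][cid]
        c.sxy = arrs["sxy"][cid]
        c.perim_edges = int(arrs["perim"][cid])
    return int(n_eval), int(n_acc)
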