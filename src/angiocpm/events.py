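"""Cellular events: phenotype selection, branching, proliferation, anastomosis, gap filling.

Phenotypes are assigned from each cell's internal VEGF relative to the
population maximum (tip > 0.5 max, hybrid in (0.2, 0.5) max); tip and hybrid
cells lead sprouts and may seed new vessels along the average principal-strain
direction of the surrounding matrix, provided that direction roughly aligns
with the VEGF gradient.  One stalk cell per active sprout proliferates by
growing to double area and splitting with 2-means clustering; sprouts that
collide anastomose by inactivating one vessel; sprouts that detach from their
parent vessel by more than a cell diameter are reconnected with a fresh stalk
cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.ndimage import label as cc_label

from .config import EventParameters, PottsParameters, TARGETS_PROLIFERATING
from .lattice import Cell, ECM, HYBRID, LatticeState, STALK, TIP
from .mechanics import StrainField
from .signaling import ContactGraph

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Vessel:
    """One (primary or sprouting) vessel: ordered member record and status."""

    id: int
    members: list[int] = dc_field(default_factory=list)
    active: bool = True
    parent: Optional[int] = None
    incubation: int = 0            #: remaining incubation MCTS (0 = none)
    theta: Optional[float] = None  #: persistent branching direction (rad)
    separated: bool = False        #: has been observed out of contact with parent
    created_mcts: int = 0
    inactivated_mcts: Optional[int] = None
    divisions: int = 0
    proliferating_cell: Optional[int] = None

    @property
    def incubating(self) -> bool:
        return self.incubation > 0


@dataclass
class BranchDirection:
    """Average strain vector at a branching cell and the local VEGF gradient angle."""

    Lambda: float  #: mean principal-strain modulus over ECM boundary pixels
    theta: float   #: mean strain-vector argument (rad, in (-pi, pi])
    Theta: float   #: VEGF gradient angle (rad)
    n_pixels: int  #: number of ECM pixels bordering the cell


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def classify_phenotypes(cells: dict[int, Cell], graph: ContactGraph,
                        events: EventParameters) -> dict[int, int]:
    """Assign tip / hybrid / stalk phenotypes from internal VEGF levels.

    A cell is a tip if its V exceeds every contacting neighbor's V and
    ``tip_fraction`` of the population maximum; cells with V between
    ``hybrid_fraction`` and ``tip_fraction`` of the maximum are hybrid
    tip/stalk; everything else (including all cells when V vanishes
    everywhere) is stalk.  Updates ``cell.phenotype`` and returns the map.
    """
    if not cells:
        return {}
    vmax = max(c.V for c in cells.values())
    out: dict[int, int] = {}
    neigh_v: dict[int, float] = {}
    for (a, b) in graph.shared:
        if a in cells and b in cells:
            neigh_v[a] = max(neigh_v.get(a, 0.0), cells[b].V)
            neigh_v[b] = max(neigh_v.get(b, 0.0), cells[a].V)
    for cid, cell in cells.items():
        if vmax <= 0.0:
            ph = STALK
        elif cell.V > neigh_v.get(cid, 0.0) and cell.V > events.tip_fraction * vmax:
            ph = TIP
        elif events.hybrid_fraction * vmax < cell.V < events.tip_fraction * vmax:
            ph = HYBRID
        else:
            ph = STALK
        cell.phenotype = ph
        out[cid] = ph
    return out


# ---------------------------------------------------------------------------
# branching
# ---------------------------------------------------------------------------

def ecm_boundary_pixels(state: LatticeState, cid: int) -> np.ndarray:
    """ECM pixels sharing a von Neumann edge with cell ``cid`` ((k, 2) array)."""
    pts = state.pixels_of(cid)
    spin = state.spin
    nx, ny = spin.shape
    out = set()
    for x, y in pts:
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            qx, qy = int(x) + dx, int(y) + dy
            if 0 <= qx < nx and 0 <= qy < ny and spin[qx, qy] == ECM:
                out.add((qx, qy))
    return np.array(sorted(out), dtype=int).reshape(-1, 2)


def branch_direction(state: LatticeState, cid: int, strain: StrainField,
                     grad: tuple[float, float]) -> Optional[BranchDirection]:
    """Average strain vector over the ECM pixels bordering a cell.

    The strain vector at each pixel is the largest principal strain times its
    unit eigenvector; eigenvectors are sign-ambiguous, so each is canonicalized
    into the half-plane of the VEGF gradient before the arguments are averaged
    (relative to the gradient angle, preventing +/-pi cancellation).  Returns
    None when the cell does not touch the ECM (branching impossible).
    """
    pix = ecm_boundary_pixels(state, cid)
    if len(pix) == 0:
        return None
    Theta = math.atan2(grad[1], grad[0])
    gx, gy = math.cos(Theta), math.sin(Theta)
    moduli = []
    rel_args = []
    for qx, qy in pix:
        e1 = float(strain.eps1[qx, qy])
        vx = float(strain.v1x[qx, qy])
        vy = float(strain.v1y[qx, qy])
        wx, wy = e1 * vx, e1 * vy
        if wx * gx + wy * gy < 0.0:
            wx, wy = -wx, -wy
        moduli.append(math.hypot(wx, wy))
        if wx == 0.0 and wy == 0.0:
            rel_args.append(0.0)
        else:
            rel_args.append(wrap_angle(math.atan2(wy, wx) - Theta))
    theta = wrap_angle(Theta + sum(rel_args) / len(rel_args))
    return BranchDirection(Lambda=float(np.mean(moduli)), theta=theta,
                           Theta=Theta, n_pixels=len(pix))


def _step_toward(theta: float) -> tuple[int, int]:
    """Quantize a direction onto the 8-neighborhood."""
    dx = int(round(math.cos(theta)))
    dy = int(round(math.sin(theta)))
    if dx == 0 and dy == 0:  # cannot happen for unit direction, kept defensive
        dx = 1
    return dx, dy


def pointing_pixel(state: LatticeState, cid: int, theta: float) -> Optional[tuple[int, int]]:
    """The lattice pixel just beyond the cell in direction ``theta``.

    Takes the cell pixel with maximal projection onto ``theta`` and steps one
    pixel further; returns None if that leaves the domain.
    """
    pts = state.pixels_of(cid)
    proj = pts[:, 0] * math.cos(theta) + pts[:, 1] * math.sin(theta)
    x, y = pts[int(np.argmax(proj))]
    dx, dy = _step_toward(theta)
    qx, qy = int(x) + dx, int(y) + dy
    if not (0 <= qx < state.nx and 0 <= qy < state.ny):
        return None
    return qx, qy


def exchange_cells(state: LatticeState, cid_a: int, cid_b: int) -> None:
    """Positionally swap two cells (their pixel sets trade labels).

    Mimics, in 2D, a new tip cell climbing over the parent vessel: the cells
    exchange locations while keeping their identities, signaling states and
    vessel memberships.
    """
    pts_a = state.pixels_of(cid_a)
    pts_b = state.pixels_of(cid_b)
    state.spin[pts_a[:, 0], pts_a[:, 1]] = cid_b
    state.spin[pts_b[:, 0], pts_b[:, 1]] = cid_a
    ca, cb = state.cells[cid_a], state.cells[cid_b]
    for attr in ("n", "sx", "sy", "sxx", "syy", "sxy", "perim_edges"):
        va, vb = getattr(ca, attr), getattr(cb, attr)
        setattr(ca, attr, vb)
        setattr(cb, attr, va)


def attempt_branch(state: LatticeState, vessels: dict[int, Vessel], cid: int,
                   direction: BranchDirection, potts: PottsParameters,
                   events: EventParameters, mcts: int,
                   next_vessel_id: int) -> tuple[str, Optional[Vessel]]:
    """Try to branch a newly tip-like cell out of its vessel.

    Returns ``("branch", vessel)`` when a new vessel is created, ``("exchange",
    None)`` when the cell was swapped with the neighbor its strain direction
    points to (to be retried in later MCTS), and ``("none", None)`` otherwise.
    """
    cell = state.cells[cid]
    target = pointing_pixel(state, cid, direction.theta)
    if target is None:
        return "none", None
    lbl = int(state.spin[target])
    if lbl == ECM:
        if not (-math.pi / 2.0 < wrap_angle(direction.theta - direction.Theta)
                < math.pi / 2.0):
            return "none", None  # chemotaxis opposes branching
        old = vessels[cell.vessel]
        if cid in old.members:
            old.members.remove(cid)
        vessel = Vessel(id=next_vessel_id, members=[cid], active=True,
                        parent=old.id, incubation=events.incubation_mcts,
                        theta=direction.theta, created_mcts=mcts)
        cell.vessel = vessel.id
        cell.tip_prolif_allowed = True
        cell.rho_persist = potts.rho_persist_frac * potts.rho_chem0
        cell.persist_cx = math.cos(direction.theta)
        cell.persist_cy = math.sin(direction.theta)
        vessels[vessel.id] = vessel
        return "branch", vessel
    if lbl != cid:
        exchange_cells(state, cid, lbl)
        return "exchange", None
    return "none", None


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------

def select_proliferating_cell(state: LatticeState, vessel: Vessel,
                              graph: ContactGraph,
                              rng: np.random.Generator) -> Optional[int]:
    """Pick one stalk cell of an active vessel that touches one of its tip-like cells.

    The chosen cell's CPM targets switch to the proliferating set (double
    area, triple perimeter).  Returns None when the vessel is inactive or has
    no eligible stalk cell; tip cells themselves are never selected.
    """
    if not vessel.active:
        return None
    members = set(vessel.members)
    tips = {c for c in members if state.cells[c].phenotype in (TIP, HYBRID)}
    if not tips:
        return None
    candidates = sorted(
        c for c in members
        if state.cells[c].phenotype == STALK
        and any((min(c, t), max(c, t)) in graph.shared for t in tips))
    if not candidates:
        return None
    cid = int(candidates[int(rng.integers(len(candidates)))])
    _mark_proliferating(state.cells[cid])
    vessel.proliferating_cell = cid
    return cid


def _mark_proliferating(cell: Cell) -> None:
    cell.proliferating = True
    cell.A_target = TARGETS_PROLIFERATING.area
    cell.P_target = TARGETS_PROLIFERATING.perimeter
    cell.L_target = TARGETS_PROLIFERATING.length


def has_ecm_contact(state: LatticeState, cid: int) -> bool:
    """True unless the cell is completely surrounded by other cells."""
    return len(ecm_boundary_pixels(state, cid)) > 0


def kmeans_split(pixels: np.ndarray, rng: np.random.Generator,
                 max_tries: int = 12) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Split a pixel set into two connected, balanced groups by 2-means.

    Starts from an unconstrained 2-means solution (scikit-learn) and then
    alternates balanced assignment with centroid correction: pixels are ranked
    by the difference of squared distances to the two centroids and the groups
    forced to equal size (+-1 pixel), after which the centroids are updated.
    Re-runs with a fresh initialization if a daughter comes out disconnected
    (4-connectivity); returns None if no valid split is found.
    """
    from sklearn.cluster import KMeans

    pts = np.asarray(pixels, dtype=float)
    n = len(pts)
    if n < 2:
        return None
    for attempt in range(max_tries):
        if attempt == 0:
            km = KMeans(n_clusters=2, n_init=4,
                        random_state=int(rng.integers(2 ** 31 - 1)))
            km.fit(pts)
            centers = km.cluster_centers_
        else:
            pick = rng.choice(n, size=2, replace=False)
            centers = pts[pick].copy()
        lab = None
        for _ in range(50):
            d = (((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
            order = np.argsort(d[:, 0] - d[:, 1], kind="stable")
            new_lab = np.ones(n, dtype=int)
            new_lab[order[: n // 2]] = 0  # the half closer to centroid 0
            if lab is not None and np.array_equal(new_lab, lab):
                break
            lab = new_lab
            centers = np.stack([pts[lab == 0].mean(axis=0),
                                pts[lab == 1].mean(axis=0)])
        g0 = pixels[lab == 0]
        g1 = pixels[lab == 1]
        if _connected(g0) and _connected(g1):
            return g0, g1
    return None


def _connected(pts: np.ndarray) -> bool:
    x0, y0 = pts.min(axis=0)
    grid = np.zeros(pts.max(axis=0) - (x0, y0) + 1, dtype=bool)
    grid[pts[:, 0] - x0, pts[:, 1] - y0] = True
    return cc_label(grid, structure=_FOUR_CONN)[1] == 1


def maybe_divide(state: LatticeState, cid: int, c_at_cell: float,
                 vessel_active: bool, psi_p: float,
                 rng: np.random.Generator) -> Optional[int]:
    """Divide a grown proliferating cell if the gating conditions hold.

    Gates: (i) external VEGF at the cell's hypoxia-facing pixel exceeds
    ``psi_p``; (ii) the cell's vessel is active (with proliferation); (iii)
    the cell is not completely surrounded by other cells.  The split is a
    2-means clustering of the pixel coordinates into two connected groups.
    Returns the new daughter cell id, or None if no division occurred.  The
    daughter inherits half of the parent's molecule counts, the parent keeps
    the other half; both daughters keep the parent's vessel.
    """
    cell = state.cells[cid]
    h2 = state.h * state.h
    if cell.n * h2 < cell.A_target:
        return None
    if c_at_cell <= psi_p or not vessel_active or not has_ecm_contact(state, cid):
        return None
    pts = state.pixels_of(cid)
    split = kmeans_split(pts, rng)
    if split is None:
        return None
    keep, give = split
    new_id = state.new_cell_id()
    state.spin[give[:, 0], give[:, 1]] = new_id
    daughter = Cell(id=new_id, vessel=cell.vessel)
    for sp in ("N", "D", "J", "I", "VR", "V"):
        half = getattr(cell, sp) * 0.5
        setattr(cell, sp, half)
        setattr(daughter, sp, half)
    daughter.phenotype = STALK
    daughter.rho_length = cell.rho_length
    state.cells[new_id] = daughter
    state.recompute_cache(new_id)
    state.recompute_cache(cid)
    return new_id


# ---------------------------------------------------------------------------
# anastomosis and gap filling
# ---------------------------------------------------------------------------

def resolve_anastomosis(state: LatticeState, vessels: dict[int, Vessel],
                        graph: ContactGraph, rng: np.random.Generator,
                        primary_id: int, mcts: int) -> list[dict]:
    """Inactivate one vessel per inter-sprout collision detected this MCTS.

    Tip-tip contact inactivates one of the two vessels at random; tip-stalk
    contact inactivates the tip's vessel.  Contacts within one vessel, with
    the primary vessel, between stalk cells only, or between a sprout and its
    not-yet-separated parent are ignored, as are vessels still in their
    incubation period (a branching vessel only follows the rules of an
    ordinary sprout once incubation ends).  Inactive vessels keep their cells
    and their signaling dynamics but no longer proliferate or branch.
    """
    events = []
    cells = state.cells
    for (a, b) in sorted(graph.shared):
        if a not in cells or b not in cells:
            continue
        va_id, vb_id = cells[a].vessel, cells[b].vessel
        if va_id == vb_id or primary_id in (va_id, vb_id):
            continue
        va, vb = vessels[va_id], vessels[vb_id]
        if not (va.active and vb.active) or va.incubating or vb.incubating:
            continue
        if (va.parent == vb_id and not va.separated) or \
           (vb.parent == va_id and not vb.separated):
            continue
        a_tip = cells[a].phenotype in (TIP, HYBRID)
        b_tip = cells[b].phenotype in (TIP, HYBRID)
        if a_tip and b_tip:
            loser = va if rng.random() < 0.5 else vb
        elif a_tip:
            loser = va
        elif b_tip:
            loser = vb
        else:
            continue
        loser.active = False
        loser.inactivated_mcts = mcts
        events.append({"event": "anastomosis", "mcts": mcts,
                       "cells": (int(a), int(b)),
                       "inactivated_vessel": loser.id})
    return events


def vessel_gap_um(state: LatticeState, members_a: list[int],
                  members_b: list[int],
                  pixel_map: Optional[dict] = None) -> float:
    """Minimal pixel-center distance (um) between two groups of cells."""
    pts_a, pts_b = (_group_pixels(state, m, pixel_map)
                    for m in (members_a, members_b))
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
    return float(math.sqrt(d2.min()) * state.h)


def _group_pixels(state: LatticeState, members: list[int],
                  pixel_map: Optional[dict]) -> np.ndarray:
    if pixel_map is not None:
        arrs = [pixel_map[c] for c in members if c in pixel_map]
    else:
        arrs = [state.pixels_of(c) for c in members]
    return np.concatenate(arrs) if arrs else np.empty((0, 2), dtype=int)


def fill_gap(state: LatticeState, vessel: Vessel, parent_members: list[int],
             events: EventParameters,
             pixel_map: Optional[dict] = None) -> Optional[int]:
    """Bridge a sprout that has detached from its parent vessel.

    When the closest approach between the sprout and its parent exceeds one
    cell diameter, a new stalk cell (zero signaling state, normal targets) is
    carved out of the ECM around the midpoint of the closest pixel pair and
    assigned to the sprout's vessel.  Returns the new cell id or None.
    """
    if not vessel.members or not parent_members:
        return None
    pts_s = _group_pixels(state, vessel.members, pixel_map)
    pts_p = _group_pixels(state, parent_members, pixel_map)
    if len(pts_s) == 0 or len(pts_p) == 0:
        return None
    d2 = ((pts_s[:, None, :] - pts_p[None, :, :]) ** 2).sum(axis=2)
    if math.sqrt(d2.min()) * state.h <= events.gap_distance_um:
        return None
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    mid = np.round((pts_s[i] + pts_p[j]) / 2.0).astype(int)
    pixels = _ecm_blob_near(state, tuple(mid), n_target=12)
    if len(pixels) < 3:
        return None
    cell = state.add_cell(pixels, vessel=vessel.id)
    cell.phenotype = STALK
    vessel.members.append(cell.id)
    return cell.id


def _ecm_blob_near(state: LatticeState, center: tuple[int, int],
                   n_target: int) -> list[tuple[int, int]]:
    """Grow a connected blob of ECM pixels near ``center`` (BFS order)."""
    from collections import deque

    nx, ny = state.spin.shape
    cx, cy = center
    # locate the nearest ECM pixel to start from
    start = None
    for radius in range(0, 6):
        best = None
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                qx, qy = cx + dx, cy + dy
                if 0 <= qx < nx and 0 <= qy < ny and state.spin[qx, qy] == ECM:
                    d = dx * dx + dy * dy
                    if best is None or d < best[0]:
                        best = (d, (qx, qy))
        if best is not None:
            start = best[1]
            break
    if start is None:
        return []
    out = [start]
    seen = {start}
    queue = deque([start])
    while queue and len(out) < n_target:
        x, y = queue.popleft()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            q = (x + dx, y + dy)
            if q not in seen and 0 <= q[0] < nx and 0 <= q[1] < ny \
                    and state.spin[q] == ECM:
                seen.add(q)
                out.append(q)
                queue.append(q)
                if len(out) >= n_target:
                    break
    return out


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------

def motility_parameters(cell: Cell, case: str, potts: PottsParameters,
                        max_D: float, tip_like: bool) -> tuple[float, float, float]:
    """Effective (rho_chem, rho_durot, rho_length) for one cell.

    Case (A): tip-like cells carry the full chemotaxis/durotaxis couplings and
    the elongation constraint; stalk cells are non-motile (all three zero).
    Case (B): every cell feels durotaxis and the elongation constraint, and
    chemotaxis scales with the cell's Delta level relative to the population
    maximum (``rho_chem0 * D_i / max_k D_k`` at cell-ECM interfaces; the sweep
    averages the two Delta levels at cell-cell interfaces).
    """
    if case == "A":
        if tip_like:
            return potts.rho_chem0, potts.rho_durot, potts.rho_length
        return 0.0, 0.0, 0.0
    rho_chem = potts.rho_chem0 * cell.D / max_D if max_D > 0 else 0.0
    return rho_chem, potts.rho_durot, potts.rho_length
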