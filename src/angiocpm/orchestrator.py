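"""Simulation orchestrator: per-MCTS schedule, metrics, calibration and I/O.

Each Monte Carlo time step executes, in order: phenotype classification,
branching attempts, proliferation selection/division, one VEGF step, Notch
signaling integration, the elasticity refresh, the CPM sweep, anastomosis
resolution, gap filling and metrics collection.  A single seeded generator
drives every stochastic choice, so one (config, seed) pair reproduces its
outputs bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import events as ev
from . import lattice as lat
from . import mechanics as mech
from . import signaling as sig
from . import vegf as veg
from .config import SimulationConfig, TARGETS_NORMAL
from .lattice import HYBRID, STALK, TIP, LatticeState, SweepFields


def mcts_calibration(sim_elongation_um: float, sim_mcts: float,
                     exp_elongation_um: float, exp_hours: float) -> float:
    """Physical hours per MCTS from matching simulated to observed sprout speed.

    The simulation covers ``sim_elongation_um`` in ``sim_mcts`` steps while the
    experiment advances at ``exp_elongation_um / exp_hours``; equating the two
    speeds gives ``hours/MCTS = (sim_elongation / exp_speed) / sim_mcts``.
    """
    if min(sim_elongation_um, sim_mcts, exp_elongation_um, exp_hours) <= 0:
        raise ValueError("calibration inputs must be positive")
    exp_speed = exp_elongation_um / exp_hours
    return (sim_elongation_um / exp_speed) / sim_mcts


def estimate_proliferation_time(sprouts: Iterable[tuple[float, int]]) -> float:
    """Mean MCTS per division over sprouts that proliferated at least once.

    ``sprouts`` yields ``(active_mcts, n_divisions)`` per sprout; sprouts with
    zero divisions are discarded.  Returns NaN when no sprout qualifies.
    """
    ratios = [active / n for active, n in sprouts if n >= 1]
    return float(np.mean(ratios)) if ratios else float("nan")


@dataclass
class SimulationResult:
    """Outputs of one run: per-MCTS metrics, the event log and final state."""

    config: SimulationConfig
    metrics: pd.DataFrame
    events: list[dict]
    state: LatticeState
    vessels: dict[int, ev.Vessel]
    vegf: veg.VegfModel

    def proliferation_time_mcts(self) -> float:
        end = self.config.n_mcts
        sprouts = [((v.inactivated_mcts if v.inactivated_mcts is not None else end)
                    - v.created_mcts, v.divisions)
                   for v in self.vessels.values() if v.parent is not None]
        return estimate_proliferation_time(sprouts)


class Simulation:
    """One configured run of the hybrid angiogenesis model."""

    PRIMARY = 0

    def __init__(self, config: SimulationConfig, seed: Optional[int] = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.t = 0
        self.metrics_rows: list[dict] = []
        self.event_log: list[dict] = []
        self.initialize()

    # ------------------------------------------------------------------
    def initialize(self) -> None:
        """Primary vessel along x = 0, linear VEGF ramp, zero signaling."""
        cfg = self.config
        npx = cfg.lattice.n_pixels_side
        self.state = LatticeState(npx, cfg.lattice.h_um)
        w = cfg.initial_column_width_px
        r = cfg.initial_cell_rows_px
        vessel = ev.Vessel(id=self.PRIMARY, active=True)
        y = 0
        while y < npx:
            y_hi = y + r
            if npx - y_hi < r:  # absorb the remainder into the last cell
                y_hi = npx
            pix = [(x, yy) for x in range(w) for yy in range(y, y_hi)]
            cell = self.state.add_cell(pix, vessel=self.PRIMARY)
            vessel.members.append(cell.id)
            y = y_hi
        self.vessels: dict[int, ev.Vessel] = {self.PRIMARY: vessel}
        self._next_vessel_id = 1
        self.vegf = veg.VegfModel(cfg.lattice, cfg.vegf, initial="ramp")
        self.fem = mech.assemble_stiffness(cfg.lattice, cfg.elasticity)
        self.strain: Optional[mech.StrainField] = None
        self._sweep_fields = SweepFields(case=cfg.case)
        self.graph = sig.build_contact_graph(self.state)
        self.pending_branchers: set[int] = set()
        self._divide_cooldown: dict[int, int] = {}
        self._prev_phenotype: dict[int, int] = {c: STALK for c in self.state.cells}
        self.initial_front_um = self._front_um()
        self._refresh_mechanics()
        self._append_metrics()

    # ------------------------------------------------------------------
    def run(self, n_mcts: Optional[int] = None,
            snapshot_dir: Optional[str | Path] = None) -> SimulationResult:
        n = self.config.n_mcts if n_mcts is None else n_mcts
        for _ in range(n):
            self.step()
            if snapshot_dir is not None and \
                    self.t % self.config.snapshot_every == 0:
                self.write_snapshot(snapshot_dir)
        return SimulationResult(self.config, self.metrics(), self.event_log,
                                self.state, self.vessels, self.vegf)

    def step(self) -> None:
        """One MCTS of the full schedule."""
        cfg = self.config
        self.t += 1
        # 1. phenotypes (from the signaling state of the previous MCTS)
        phenos = ev.classify_phenotypes(self.state.cells, self.graph, cfg.events)
        self._update_pending_branchers(phenos)
        # 2. branching
        self._branching()
        # 3. proliferation selection and division
        self._proliferation()
        # 4. VEGF
        veg.step_vegf(self.vegf, self.state.spin, cfg.mcts_hours)
        # 5. signaling
        self._signaling()
        # 6. mechanics
        if self.t % cfg.fem_every == 0 or self.strain is None:
            self._refresh_mechanics()
        # 7. CPM sweep
        self._refresh_motility()
        lat.mcts_sweep(self.state, cfg.potts, cfg.lattice.T, self.rng,
                       fields=self._sweep_fields)
        # 8-9. anastomosis, separation bookkeeping, gap filling
        self.graph = sig.build_contact_graph(self.state)
        self._update_separation()
        self.event_log.extend(ev.resolve_anastomosis(
            self.state, self.vessels, self.graph, self.rng, self.PRIMARY, self.t))
        self._gap_fill()
        self._tick_incubation()
        # 10. metrics
        self._append_metrics()

    # ------------------------------------------------------------------
    # sub-schedules
    # ------------------------------------------------------------------
    def _update_pending_branchers(self, phenos: dict[int, int]) -> None:
        allowed = (TIP, HYBRID) if self.config.events.hybrids_branch else (TIP,)
        for cid, ph in phenos.items():
            prev = self._prev_phenotype.get(cid, STALK)
            if prev == STALK and ph in allowed:
                self.pending_branchers.add(cid)
            elif ph == STALK:
                self.pending_branchers.discard(cid)
        self._prev_phenotype = dict(phenos)

    def _branching(self) -> None:
        # One branching decision per phenotype acquisition: a candidate stays
        # pending only while it is being exchanged outward through the vessel;
        # an ECM-facing decision (branch or chemotaxis veto) consumes it.
        for cid in sorted(self.pending_branchers):
            cell = self.state.cells.get(cid)
            if cell is None:
                self.pending_branchers.discard(cid)
                continue
            vessel = self.vessels[cell.vessel]
            if not vessel.active or vessel.incubating or self.strain is None:
                self.pending_branchers.discard(cid)
                continue
            cx, cy = cell.centroid(self.state.h)
            ix = int(round(cx / self.state.h))
            iy = int(round(cy / self.state.h))
            grad = self.vegf.gradient_at(ix, iy)
            direction = ev.branch_direction(self.state, cid, self.strain, grad)
            if direction is None:
                self.pending_branchers.discard(cid)  # enclosed: cannot branch
                continue
            kind, new_vessel = ev.attempt_branch(
                self.state, self.vessels, cid, direction, self.config.potts,
                self.config.events, self.t, self._next_vessel_id)
            if kind != "exchange":
                self.pending_branchers.discard(cid)
            if kind == "branch":
                self._next_vessel_id += 1
                ev._mark_proliferating(cell)  # one-time tip proliferation
                new_vessel.proliferating_cell = cid
                self.event_log.append({"mcts": self.t, "event": "branch",
                                       "cell": cid, "vessel": new_vessel.id,
                                       "theta": direction.theta,
                                       "Theta": direction.Theta,
                                       "Lambda": direction.Lambda})
            elif kind == "exchange":
                self.event_log.append({"mcts": self.t, "event": "exchange",
                                       "cell": cid, "vessel": vessel.id})

    def _proliferation(self) -> None:
        cfg = self.config
        for vid in sorted(self.vessels):
            vessel = self.vessels[vid]
            if vid == self.PRIMARY or not vessel.active:
                continue
            pcid = vessel.proliferating_cell
            if pcid is not None and pcid not in self.state.cells:
                vessel.proliferating_cell = pcid = None
            if pcid is None and not vessel.incubating:
                pcid = ev.select_proliferating_cell(self.state, vessel,
                                                   self.graph, self.rng)
            if pcid is None:
                continue
            cell = self.state.cells[pcid]
            if self._divide_cooldown.get(pcid, 0) > self.t:
                continue
            ix, iy = sig.hypoxia_facing_pixel(self.state, pcid)
            c_here = float(self.vegf.c[ix, iy])
            new_id = ev.maybe_divide(self.state, pcid, c_here, vessel.active,
                                     cfg.events.psi_p, self.rng)
            if new_id is None:
                if cell.n * self.state.h ** 2 >= cell.A_target:
                    # grown but split/gates failed; retry after a short pause
                    self._divide_cooldown[pcid] = self.t + 5
                continue
            vessel.members.append(new_id)
            vessel.divisions += 1
            self.event_log.append({"mcts": self.t, "event": "divide",
                                   "cell": pcid, "daughter": new_id,
                                   "vessel": vid})
            self._prev_phenotype[new_id] = STALK
            daughter = self.state.cells[new_id]
            if cell.tip_prolif_allowed:
                # the one-time division of an incubating branch's tip cell
                cell.tip_prolif_allowed = False
                self._revert_targets(cell)
                self._revert_targets(daughter)
                vessel.proliferating_cell = None
                continue
            touching = [c for c in (pcid, new_id)
                        if self._touches_tip(c, vessel)]
            if touching:
                keeper = pcid if self.rng.random() < 0.5 else new_id
                other = new_id if keeper == pcid else pcid
                ev._mark_proliferating(self.state.cells[keeper])
                self._revert_targets(self.state.cells[other])
                vessel.proliferating_cell = keeper
            else:
                self._revert_targets(cell)
                self._revert_targets(daughter)
                vessel.proliferating_cell = None

    @staticmethod
    def _revert_targets(cell: lat.Cell) -> None:
        cell.proliferating = False
        cell.A_target = TARGETS_NORMAL.area
        cell.P_target = TARGETS_NORMAL.perimeter
        cell.L_target = TARGETS_NORMAL.length

    def _touches_tip(self, cid: int, vessel: ev.Vessel) -> bool:
        tips = [c for c in vessel.members
                if c != cid and c in self.state.cells
                and self.state.cells[c].phenotype in (TIP, HYBRID)]
        if not tips:
            return False
        pts = self.state.pixels_of(cid)
        spin = self.state.spin
        nx, ny = spin.shape
        tipset = set(tips)
        for x, y in pts:
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                qx, qy = int(x) + dx, int(y) + dy
                if 0 <= qx < nx and 0 <= qy < ny and int(spin[qx, qy]) in tipset:
                    return True
        return False

    def _signaling(self) -> None:
        cfg = self.config
        cells = self.state.cells
        order = sorted(cells)
        W = self.graph.weight_matrix(order)
        hyp = self._hypoxia_pixels()
        scale = cfg.hill.chi_V * cfg.vegf.S_molec
        v_ext = np.array([scale * self.vegf.c[hyp[c]] for c in order])
        y = np.stack([np.array([getattr(cells[c], sp) for c in order])
                      for sp in sig.SPECIES])
        y = sig.integrate_signaling(y, W, v_ext, cfg.rates, cfg.hill,
                                    cfg.mcts_hours, cfg.signaling_substeps)
        for k, cid in enumerate(order):
            cell = cells[cid]
            cell.N, cell.D, cell.J = y[0, k], y[1, k], y[2, k]
            cell.I, cell.VR, cell.V = y[3, k], y[4, k], y[5, k]

    def _hypoxia_pixels(self) -> dict[int, tuple[int, int]]:
        """Per cell, the pixel with maximal x (ties: minimal y), in one pass."""
        xs, ys = np.nonzero(self.state.spin)
        labels = self.state.spin[xs, ys]
        order = np.lexsort((-ys, xs, labels))
        out: dict[int, tuple[int, int]] = {}
        for k in order:  # the last hit per label wins: max x, then min y
            out[int(labels[k])] = (int(xs[k]), int(ys[k]))
        return out

    def _refresh_mechanics(self) -> None:
        cfg = self.config
        f = mech.traction_forces(self.state, cfg.elasticity.mu_force,
                                 cfg.lattice.M)
        u = self.fem.solve(f)
        self.strain = mech.pixel_strain(u, cfg.lattice.M, self.fem.h_m)
        h1, h2 = mech.durotaxis_weights(self.strain, cfg.durotaxis)
        sf = self._sweep_fields
        sf.dur_h1, sf.dur_h2 = h1, h2
        sf.v1x, sf.v1y = self.strain.v1x, self.strain.v1y
        sf.v2x, sf.v2y = self.strain.v2x, self.strain.v2y
        sf.c_pix = self.vegf.pixel_values()

    def _refresh_motility(self) -> None:
        cfg = self.config
        sf = self._sweep_fields
        sf.case = cfg.case
        sf.c_pix = self.vegf.pixel_values()
        max_D = max((c.D for c in self.state.cells.values()), default=0.0)
        sf.max_D = max_D
        incubating_tips = {v.members[0] for v in self.vessels.values()
                           if v.incubating and v.members}
        for cid, cell in self.state.cells.items():
            tip_like = cell.phenotype in (TIP, HYBRID) or cid in incubating_tips
            rho_chem, rho_durot, rho_length = ev.motility_parameters(
                cell, cfg.case, cfg.potts, max_D, tip_like)
            cell.rho_chem = rho_chem
            cell.rho_durot = rho_durot
            cell.rho_length = rho_length
            if cid not in incubating_tips:
                cell.rho_persist = 0.0

    def _update_separation(self) -> None:
        for vessel in self.vessels.values():
            if vessel.parent is None or vessel.separated:
                continue
            parent = self.vessels.get(vessel.parent)
            if parent is None:
                vessel.separated = True
                continue
            touching = any(
                (min(a, b), max(a, b)) in self.graph.shared
                for a in vessel.members for b in parent.members)
            if not touching:
                vessel.separated = True

    def _gap_fill(self) -> None:
        pmap = self.state.pixel_map()
        for vid in sorted(self.vessels):
            vessel = self.vessels[vid]
            if vessel.parent is None or not vessel.active or not vessel.separated:
                continue
            parent = self.vessels.get(vessel.parent, self.vessels[self.PRIMARY])
            new_id = ev.fill_gap(self.state, vessel, parent.members,
                                 self.config.events, pixel_map=pmap)
            if new_id is not None:
                self._prev_phenotype[new_id] = STALK
                self.event_log.append({"mcts": self.t, "event": "gap_fill",
                                       "cell": new_id, "vessel": vid})

    def _tick_incubation(self) -> None:
        for vessel in self.vessels.values():
            if vessel.incubating:
                vessel.incubation -= 1
                if vessel.incubation == 0 and vessel.members:
                    tip = self.state.cells.get(vessel.members[0])
                    if tip is not None:
                        tip.rho_persist = 0.0

    # ------------------------------------------------------------------
    # metrics and I/O
    # ------------------------------------------------------------------
    def _front_um(self) -> float:
        xs = np.nonzero(self.state.spin)[0]
        return float((xs.max() + 0.5) * self.state.h) if len(xs) else 0.0

    def compute_metrics(self) -> dict:
        cells = self.state.cells
        counts = {TIP: 0, HYBRID: 0, STALK: 0}
        tip_x = []
        for cell in cells.values():
            counts[cell.phenotype] += 1
            if cell.phenotype == TIP:
                tip_x.append(cell.centroid(self.state.h)[0])
        col = self.state.spin[-1, :]
        phi = 100.0 * float((col > 0).sum()) / col.size
        return {
            "t": self.t,
            "n_cells": len(cells),
            "tip_count": counts[TIP],
            "hybrid_count": counts[HYBRID],
            "stalk_count": counts[STALK],
            "sprout_count": sum(1 for v in self.vessels.values()
                                if v.active and v.parent is not None),
            "phi": phi,
            "mean_tip_x": float(np.mean(tip_x)) if tip_x else math.nan,
            "mean_elongation": self._front_um() - self.initial_front_um,
        }

    def _append_metrics(self) -> None:
        self.metrics_rows.append(self.compute_metrics())

    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics_rows)

    def write_snapshot(self, out_dir: str | Path) -> Path:
        """Array container (.npz) plus a per-cell CSV table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        base = out / f"snapshot_{self.t:06d}"
        arrays = {"spin": self.state.spin, "c": self.vegf.c}
        if self.strain is not None:
            arrays.update(eps11=self.strain.eps11, eps22=self.strain.eps22,
                          eps12=self.strain.eps12, eps1=self.strain.eps1,
                          eps2=self.strain.eps2)
        np.savez_compressed(base.with_suffix(".npz"), **arrays)
        rows = []
        for cid, cell in sorted(self.state.cells.items()):
            cx, cy = cell.centroid(self.state.h)
            rows.append({"cell": cid,
                         "type": lat.PHENOTYPE_NAMES[cell.phenotype],
                         "vessel": cell.vessel,
                         "area_um2": cell.n * self.state.h ** 2,
                         "x_um": cx, "y_um": cy,
                         "N": cell.N, "D": cell.D, "J": cell.J,
                         "I": cell.I, "VR": cell.VR, "V": cell.V})
        pd.DataFrame(rows).to_csv(base.with_suffix(".csv"), index=False)
        return base


def run(config: SimulationConfig, seed: Optional[int] = None,
        snapshot_dir: Optional[str | Path] = None) -> SimulationResult:
    """Run a full simulation for ``config.n_mcts`` steps."""
    return Simulation(config, seed=seed).run(snapshot_dir=snapshot_dir)
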