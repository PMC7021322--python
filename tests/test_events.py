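"""Cell events: phenotypes, branch direction, division, anastomosis, gaps, motility."""

import math

import numpy as np
import pytest

from angiocpm.config import EventParameters, PottsParameters, TARGETS_PROLIFERATING
from angiocpm.events import (BranchDirection, Vessel, attempt_branch,
                             branch_direction, classify_phenotypes,
                             exchange_cells, fill_gap, kmeans_split,
                             maybe_divide, motility_parameters,
                             resolve_anastomosis, select_proliferating_cell,
                             vessel_gap_um, wrap_angle)
from angiocpm.lattice import Cell, HYBRID, LatticeState, STALK, TIP
from angiocpm.mechanics import StrainField
from angiocpm.signaling import ContactGraph, build_contact_graph
from conftest import random_blob


def _uniform_strain(shape, eps1, v1=(1.0, 0.0)):
    one = np.ones(shape)
    return StrainField(one * 0, one * 0, one * 0, one * eps1, one * 0,
                       one * v1[0], one * v1[1], -one * v1[1], one * v1[0])


class TestClassification:
    def _graph(self, pairs):
        return ContactGraph(shared={p: 10.0 for p in pairs},
                            perimeter={i: 40.0 for i in range(1, 10)})

    def test_tip_above_half_max_and_neighbors(self):
        cells = {1: Cell(id=1, V=40.0), 2: Cell(id=2, V=100.0), 3: Cell(id=3, V=15.0)}
        graph = self._graph([(1, 2), (2, 3)])
        ev = EventParameters()
        out = classify_phenotypes(cells, graph, ev)
        assert out[2] == TIP      # V = max, above neighbors and 0.5 max
        assert out[1] == HYBRID   # 0.2 max < 40 < 0.5 max
        assert out[3] == STALK    # below the hybrid band

    def test_hybrid_band(self):
        cells = {1: Cell(id=1, V=30.0), 2: Cell(id=2, V=100.0)}
        out = classify_phenotypes(cells, self._graph([(1, 2)]), EventParameters())
        assert out[1] == HYBRID and out[2] == TIP

    def test_all_zero_vegf_all_stalk(self):
        cells = {i: Cell(id=i, V=0.0) for i in (1, 2, 3)}
        out = classify_phenotypes(cells, self._graph([]), EventParameters())
        assert set(out.values()) == {STALK}

    def test_local_maximum_required_for_tip(self):
        # a cell above 0.5 max but below a touching neighbor is not a tip
        cells = {1: Cell(id=1, V=90.0), 2: Cell(id=2, V=100.0)}
        out = classify_phenotypes(cells, self._graph([(1, 2)]), EventParameters())
        assert out[1] == STALK  # 90 > 0.5*100 but neighbor higher; not in hybrid band
        assert out[2] == TIP


class TestBranchDirection:
    def test_uniform_strain_field(self):
        st = LatticeState(12, 1.0)
        st.add_cell([(x, y) for x in range(5, 7) for y in range(5, 7)])
        sf = _uniform_strain((12, 12), 0.2)
        out = branch_direction(st, 1, sf, grad=(1.0, 0.0))
        assert out.Lambda == pytest.approx(0.2)
        assert out.theta == pytest.approx(0.0, abs=1e-12)
        assert out.Theta == 0.0

    def test_two_pixel_average_cancels_symmetric_angles(self):
        # equal moduli at +pi/4 and -pi/4 average to 0 with modulus preserved
        st = LatticeState(12, 1.0)
        st.add_cell([(5, 5), (5, 6)])
        sf = _uniform_strain((12, 12), 0.3)
        m = 0.3
        for (qx, qy), ang in (((4, 5), math.pi / 4), ((4, 6), -math.pi / 4)):
            sf.v1x[qx, qy] = math.cos(ang)
            sf.v1y[qx, qy] = math.sin(ang)
        # restrict the boundary to two pixels by boxing the cell with another
        out = branch_direction(st, 1, sf, grad=(1.0, 0.0))
        assert out.n_pixels > 2  # full ECM ring; angles still average toward 0
        assert abs(out.theta) < 0.2

    def test_no_ecm_contact_vetoes_branching(self):
        st = LatticeState(6, 1.0)
        inner = st.add_cell([(2, 2), (2, 3), (3, 2), (3, 3)])
        ring = [(x, y) for x in range(6) for y in range(6)
                if (x, y) not in {(2, 2), (2, 3), (3, 2), (3, 3)}]
        st.add_cell(ring)
        sf = _uniform_strain((6, 6), 0.2)
        assert branch_direction(st, inner.id, sf, grad=(1.0, 0.0)) is None

    def test_sign_canonicalization_prevents_pi_cancellation(self):
        # eigenvectors given with opposite signs still average coherently
        st = LatticeState(12, 1.0)
        st.add_cell([(5, 5)])
        sf = _uniform_strain((12, 12), 0.2, v1=(-1.0, 0.0))
        out = branch_direction(st, 1, sf, grad=(1.0, 0.0))
        assert out.theta == pytest.approx(0.0, abs=1e-12)


class TestAttemptBranch:
    def _setup(self):
        st = LatticeState(16, 1.0)
        vessels = {0: Vessel(id=0)}
        cells = []
        for k in range(3):
            c = st.add_cell([(x, y) for x in range(2) for y in range(4 * k, 4 * k + 4)],
                            vessel=0)
            vessels[0].members.append(c.id)
            cells.append(c)
        return st, vessels, cells

    def test_ecm_facing_aligned_branch_creates_vessel(self):
        st, vessels, cells = self._setup()
        d = BranchDirection(Lambda=0.2, theta=0.0, Theta=0.0, n_pixels=4)
        kind, vessel = attempt_branch(st, vessels, cells[1].id, d,
                                      PottsParameters(), EventParameters(),
                                      mcts=10, next_vessel_id=1)
        assert kind == "branch"
        assert vessel.incubation == 400
        assert vessel.parent == 0
        assert cells[1].vessel == vessel.id
        assert cells[1].id not in vessels[0].members
        assert cells[1].rho_persist > 0

    def test_opposed_direction_vetoed_by_chemotaxis(self):
        st, vessels, cells = self._setup()
        # theta points into the ECM (up-right) but more than pi/2 away from
        # the VEGF gradient angle: chemotaxis opposes branching
        d = BranchDirection(Lambda=0.2, theta=0.3 * math.pi, Theta=-0.9 * math.pi,
                            n_pixels=4)
        kind, vessel = attempt_branch(st, vessels, cells[1].id, d,
                                      PottsParameters(), EventParameters(),
                                      mcts=10, next_vessel_id=1)
        assert kind == "none" and vessel is None
        assert cells[1].vessel == 0

    def test_pointing_into_neighbor_exchanges_cells(self):
        st, vessels, cells = self._setup()
        # aim cell 0 upward into cell 1
        d = BranchDirection(Lambda=0.2, theta=math.pi / 2, Theta=0.0, n_pixels=4)
        pts_before = {tuple(p) for p in st.pixels_of(cells[0].id)}
        other_before = {tuple(p) for p in st.pixels_of(cells[1].id)}
        kind, _ = attempt_branch(st, vessels, cells[0].id, d, PottsParameters(),
                                 EventParameters(), mcts=10, next_vessel_id=1)
        assert kind == "exchange"
        assert {tuple(p) for p in st.pixels_of(cells[0].id)} == other_before
        assert {tuple(p) for p in st.pixels_of(cells[1].id)} == pts_before
        st.check_partition()


class TestProliferationSelection:
    def _vessel_state(self):
        st = LatticeState(12, 1.0)
        tip = st.add_cell([(x, y) for x in range(4, 6) for y in range(4, 6)],
                          vessel=1)
        stalk = st.add_cell([(x, y) for x in range(4, 6) for y in range(6, 8)],
                            vessel=1)
        tip.phenotype = TIP
        stalk.phenotype = STALK
        vessel = Vessel(id=1, members=[tip.id, stalk.id], parent=0)
        return st, vessel, tip, stalk

    def test_single_candidate_selected(self, rng):
        st, vessel, tip, stalk = self._vessel_state()
        graph = build_contact_graph(st)
        chosen = select_proliferating_cell(st, vessel, graph, rng)
        assert chosen == stalk.id
        assert stalk.proliferating
        assert stalk.A_target == TARGETS_PROLIFERATING.area

    def test_tip_cells_never_selected(self, rng):
        st, vessel, tip, stalk = self._vessel_state()
        stalk.phenotype = HYBRID  # no stalk candidate left
        graph = build_contact_graph(st)
        assert select_proliferating_cell(st, vessel, graph, rng) is None
        assert not tip.proliferating

    def test_inactive_vessel_never_proliferates(self, rng):
        st, vessel, *_ = self._vessel_state()
        vessel.active = False
        graph = build_contact_graph(st)
        assert select_proliferating_cell(st, vessel, graph, rng) is None


class TestDivision:
    def test_symmetric_rectangle_splits_into_equal_halves(self, rng):
        st = LatticeState(20, 2.5)
        cell = st.add_cell([(x, y) for x in range(4, 12) for y in range(8, 12)])
        cell.A_target = 32 * 2.5 ** 2  # grown to target
        new_id = maybe_divide(st, cell.id, c_at_cell=0.5, vessel_active=True,
                              psi_p=1e-3, rng=rng)
        assert new_id is not None
        assert st.cells[new_id].n == cell.n == 16
        st.check_partition()

    def test_division_conserves_pixels(self, rng):
        st = LatticeState(30, 2.5)
        blob = random_blob(rng, 26, start=(15, 15))
        cell = st.add_cell(map(tuple, blob))
        cell.A_target = 26 * 2.5 ** 2
        before = {tuple(p) for p in st.pixels_of(cell.id)}
        new_id = maybe_divide(st, cell.id, 0.5, True, 1e-3, rng)
        after = {tuple(p) for p in st.pixels_of(cell.id)} | \
            {tuple(p) for p in st.pixels_of(new_id)}
        assert after == before

    def test_low_vegf_blocks_division(self, rng):
        st = LatticeState(20, 2.5)
        cell = st.add_cell([(x, y) for x in range(4, 12) for y in range(8, 12)])
        cell.A_target = 32 * 2.5 ** 2
        assert maybe_divide(st, cell.id, c_at_cell=1e-6, vessel_active=True,
                            psi_p=1e-3, rng=rng) is None

    def test_enclosed_cell_cannot_divide(self, rng):
        st = LatticeState(12, 2.5)
        inner = [(x, y) for x in range(4, 8) for y in range(4, 8)]
        cell = st.add_cell(inner)
        cell.A_target = 16 * 2.5 ** 2
        ring = [(x, y) for x in range(3, 9) for y in range(3, 9)
                if (x, y) not in set(inner)]
        st.add_cell(ring)
        assert maybe_divide(st, cell.id, 0.5, True, 1e-3, rng) is None

    def test_inactive_vessel_blocks_division(self, rng):
        st = LatticeState(20, 2.5)
        cell = st.add_cell([(x, y) for x in range(4, 12) for y in range(8, 12)])
        cell.A_target = 32 * 2.5 ** 2
        assert maybe_divide(st, cell.id, 0.5, vessel_active=False,
                            psi_p=1e-3, rng=rng) is None

    def test_daughters_split_molecule_counts(self, rng):
        st = LatticeState(20, 2.5)
        cell = st.add_cell([(x, y) for x in range(4, 12) for y in range(8, 12)])
        cell.A_target = 32 * 2.5 ** 2
        cell.N = 800.0
        cell.D = 400.0
        new_id = maybe_divide(st, cell.id, 0.5, True, 1e-3, rng)
        assert cell.N == st.cells[new_id].N == 400.0
        assert cell.D == st.cells[new_id].D == 200.0

    def test_random_blobs_split_balanced(self, rng):
        """2-means splits of irregular blobs stay connected and balanced."""
        ok = 0
        n_fixtures = 100
        for _ in range(n_fixtures):
            blob = random_blob(rng, int(rng.integers(20, 40)))
            split = kmeans_split(blob, rng)
            if split is None:
                continue
            g0, g1 = split
            imbalance = abs(len(g0) - len(g1)) / len(blob)
            if imbalance <= 0.10:
                ok += 1
        assert ok >= 95


class TestAnastomosis:
    def _two_sprouts(self):
        st = LatticeState(14, 1.0)
        a_tip = st.add_cell([(x, y) for x in range(4, 6) for y in range(4, 6)],
                            vessel=1)
        b_cell = st.add_cell([(x, y) for x in range(6, 8) for y in range(4, 6)],
                             vessel=2)
        vessels = {0: Vessel(id=0),
                   1: Vessel(id=1, members=[a_tip.id], parent=0, separated=True),
                   2: Vessel(id=2, members=[b_cell.id], parent=0, separated=True)}
        return st, vessels, a_tip, b_cell

    def test_tip_stalk_contact_inactivates_tip_vessel(self, rng):
        st, vessels, a_tip, b_cell = self._two_sprouts()
        a_tip.phenotype = TIP
        b_cell.phenotype = STALK
        graph = build_contact_graph(st)
        events = resolve_anastomosis(st, vessels, graph, rng, primary_id=0, mcts=5)
        assert len(events) == 1
        assert not vessels[1].active and vessels[2].active
        assert vessels[1].inactivated_mcts == 5

    def test_tip_tip_contact_inactivates_one_at_random(self):
        losers = []
        for seed in range(40):
            st, vessels, a_tip, b_cell = self._two_sprouts()
            a_tip.phenotype = TIP
            b_cell.phenotype = TIP
            graph = build_contact_graph(st)
            resolve_anastomosis(st, vessels, graph,
                                np.random.default_rng(seed), 0, 1)
            assert vessels[1].active != vessels[2].active
            losers.append(1 if not vessels[1].active else 2)
        assert 10 <= losers.count(1) <= 30  # both outcomes, roughly balanced

    def test_contacts_within_one_vessel_ignored(self, rng):
        st, vessels, a_tip, b_cell = self._two_sprouts()
        b_cell.vessel = 1
        vessels[1].members.append(b_cell.id)
        vessels[2].members = []
        a_tip.phenotype = TIP
        graph = build_contact_graph(st)
        assert resolve_anastomosis(st, vessels, graph, rng, 0, 1) == []

    def test_unseparated_child_ignores_parent_contact(self, rng):
        st, vessels, a_tip, b_cell = self._two_sprouts()
        vessels[1].parent = 2
        vessels[1].separated = False
        a_tip.phenotype = TIP
        b_cell.phenotype = TIP
        graph = build_contact_graph(st)
        assert resolve_anastomosis(st, vessels, graph, rng, 0, 1) == []
        assert vessels[1].active and vessels[2].active

    def test_stalk_stalk_contact_no_event(self, rng):
        st, vessels, a_tip, b_cell = self._two_sprouts()
        a_tip.phenotype = STALK
        b_cell.phenotype = STALK
        graph = build_contact_graph(st)
        assert resolve_anastomosis(st, vessels, graph, rng, 0, 1) == []


class TestGapFill:
    def _detached_sprout(self, gap_px):
        st = LatticeState(30, 2.5)
        primary = st.add_cell([(0, y) for y in range(30)] +
                              [(1, y) for y in range(30)], vessel=0)
        x0 = 2 + gap_px
        sprout_cell = st.add_cell(
            [(x, y) for x in range(x0, x0 + 2) for y in range(14, 16)], vessel=1)
        vessel = Vessel(id=1, members=[sprout_cell.id], parent=0, separated=True)
        return st, vessel, primary, sprout_cell

    def test_wide_gap_filled_with_new_stalk_cell(self):
        st, vessel, primary, _ = self._detached_sprout(gap_px=5)  # ~12.5 um
        assert vessel_gap_um(st, vessel.members, [primary.id]) > 10.0
        new_id = fill_gap(st, vessel, [primary.id], EventParameters())
        assert new_id is not None
        new = st.cells[new_id]
        assert new.phenotype == STALK
        assert new.vessel == 1
        assert (new.N, new.D, new.J, new.I, new.VR, new.V) == (0,) * 6
        st.check_partition()

    def test_small_gap_untouched(self):
        st, vessel, primary, _ = self._detached_sprout(gap_px=2)  # 5 um
        assert fill_gap(st, vessel, [primary.id], EventParameters()) is None


class TestMotility:
    potts = PottsParameters()

    def test_case_a_stalk_nonmotile(self):
        cell = Cell(id=1, D=500.0)
        assert motility_parameters(cell, "A", self.potts, 1000.0,
                                   tip_like=False) == (0.0, 0.0, 0.0)

    def test_case_a_tip_full_coupling(self):
        cell = Cell(id=1, D=500.0)
        rho_chem, rho_durot, rho_len = motility_parameters(
            cell, "A", self.potts, 1000.0, tip_like=True)
        assert (rho_chem, rho_durot, rho_len) == (60000.0, 25.0, 7200.0)

    def test_case_b_delta_weighted_chemotaxis(self):
        cell = Cell(id=1, D=1000.0)
        rho_chem, rho_durot, _ = motility_parameters(cell, "B", self.potts,
                                                     1000.0, tip_like=True)
        assert rho_chem == pytest.approx(60000.0)  # D_i = max D
        assert rho_durot == 25.0
        half = Cell(id=2, D=500.0)
        assert motility_parameters(half, "B", self.potts, 1000.0,
                                   tip_like=False)[0] == pytest.approx(30000.0)

    def test_case_b_zero_delta_population(self):
        cell = Cell(id=1, D=0.0)
        assert motility_parameters(cell, "B", self.potts, 0.0,
                                   tip_like=True)[0] == 0.0

    def test_case_b_pair_average_in_sweep(self):
        # the sweep's cell-cell interface coefficient is the Delta average
        from angiocpm.lattice import LatticeState, SweepFields, _field_delta
        st = LatticeState(6, 1.0)
        c1 = st.add_cell([(2, 2)], D=1000.0)
        c2 = st.add_cell([(3, 2)], D=500.0)
        c = np.zeros((6, 6))
        c[3, 2] = 0.1  # gradient between the two pixels
        fields = SweepFields(c_pix=c, case="B", max_D=1000.0)
        dH = _field_delta(st, self.potts, fields, c1.id, c2.id, 2, 2, 3, 2)
        rho_eff = self.potts.rho_chem0 * 750.0 / 1000.0
        assert dH == pytest.approx(-rho_eff * 0.1)


def test_wrap_angle_range():
    for a in np.linspace(-10, 10, 101):
        w = wrap_angle(a)
        assert -math.pi < w <= math.pi
        assert math.cos(w) == pytest.approx(math.cos(a), abs=1e-12)


def test_exchange_preserves_identity_and_geometry(rng):
    st = LatticeState(12, 1.0)
    a = st.add_cell([(2, 2), (2, 3), (3, 2)])
    b = st.add_cell([(6, 6), (6, 7)])
    a.N = 111.0
    b.N = 222.0
    exchange_cells(st, a.id, b.id)
    assert a.n == 2 and b.n == 3  # swapped footprints
    assert a.N == 111.0 and b.N == 222.0  # identities kept
    st.check_partition()
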