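"""Cellular scale: division, quiescence, polarization, phagocytosis,
migration, recruitment, death, and the one-cell-per-site contract."""

import numpy as np
import pytest

from gliomarl.agents import (AgentGrid, CellParams, age_and_die,
                             attempt_division, migrate, phagocytose, polarize,
                             recruit_and_differentiate, update_quiescence)
from gliomarl.kinds import (DC, EMPTY, M0, M1, M2, TC_ACTIVE, TC_QUIESCENT,
                            VESSEL)
from gliomarl.lattice import VascularMap


def make_grid(n=9, seed=0):
    return AgentGrid(n, n, np.random.default_rng(seed))


def place_tc(grid, y, x, params, ready=True, kind=TC_ACTIVE):
    flat = y * grid.nx + x
    grid.place(np.array([flat]), kind,
               lifespan=params.tc_lifespan, cycle_len=params.div,
               cycle_phase=params.div if ready else 0.0)
    return flat


class TestDivision:
    def test_enclosed_cell_becomes_quiescent(self):
        p = CellParams()
        g = make_grid()
        center = place_tc(g, 4, 4, p)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0):
                    place_tc(g, 4 + dy, 4 + dx, p, ready=False)
        attempt_division(g, 1.0, p)
        assert g.kind[4, 4] == TC_QUIESCENT

    def test_certain_division_fills_the_single_empty_neighbor(self):
        p = CellParams(pTC=1.0)
        g = make_grid()
        place_tc(g, 4, 4, p)
        empties = [(3, 3)]
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) not in ((0, 0), (-1, -1)):
                    place_tc(g, 4 + dy, 4 + dx, p, ready=False)
        n = attempt_division(g, 1.0, p)
        assert n == 1
        assert g.kind[3, 3] == TC_ACTIVE

    def test_division_frequency_matches_probability(self):
        """Isolated cells divide once per cycle with empirical frequency
        pTC*mult, within a binomial confidence band."""
        prob = 0.3
        p = CellParams(pTC=prob)
        n_trials = 4000
        hits = 0
        g = AgentGrid(200, 200, np.random.default_rng(1))
        flats = []
        for i in range(40):
            for j in range(40):
                flats.append(place_tc(g, 5 * i + 2, 5 * j + 2, p))
        attempt_division(g, 1.0, p)
        n_div = g.events["division"]
        n_cells = len(flats)
        se = np.sqrt(prob * (1 - prob) / n_cells)
        assert abs(n_div / n_cells - prob) < 4 * se

    def test_stem_lineage_halves_lifespan_and_doubles_cycle(self):
        p = CellParams(pTC=1.0)
        g = make_grid()
        flat = 4 * g.nx + 4
        g.place(np.array([flat]), TC_ACTIVE,
                lifespan=p.tc_lifespan * p.stem_lifespan_mult,
                cycle_len=p.div * p.stem_cycle_mult,
                cycle_phase=p.div * p.stem_cycle_mult)
        attempt_division(g, 1.0, p)
        daughters = np.flatnonzero((g.kind.ravel() == TC_ACTIVE)
                                   & (np.arange(g.kind.size) != flat))
        assert daughters.size == 1
        d = daughters[0]
        assert g.lifespan.ravel()[d] == p.tc_lifespan     # halved to regular
        assert g.cycle_len.ravel()[d] == p.div            # doubled to regular

    def test_non_tc_sites_never_divide(self):
        p = CellParams(pTC=1.0)
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=100.0)
        assert attempt_division(g, 1.0, p) == 0


class TestQuiescence:
    def _enclosed(self, p):
        g = make_grid()
        place_tc(g, 4, 4, p, kind=TC_QUIESCENT)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0):
                    place_tc(g, 4 + dy, 4 + dx, p, ready=False)
        return g

    def test_fully_enclosed_stays_quiescent_with_frozen_age(self):
        p = CellParams()
        g = self._enclosed(p)
        age0 = g.age[4, 4]
        update_quiescence(g, p)
        age_and_die(g, p, dt=1.0)
        assert g.kind[4, 4] == TC_QUIESCENT
        assert g.age[4, 4] == age0

    def test_freed_neighbor_triggers_reversion_and_immediate_division(self):
        """A site vacated (e.g. by phagocytosis) lets the quiescent cell
        revert and place a daughter in the same scheduler step."""
        p = CellParams(pTC=1.0)
        g = self._enclosed(p)
        g.clear_sites(np.array([3 * g.nx + 3]))   # free one Moore neighbor
        update_quiescence(g, p)
        assert g.kind[4, 4] == TC_ACTIVE
        attempt_division(g, 1.0, p)
        assert g.kind[3, 3] == TC_ACTIVE          # immediate daughter

    def test_nonquiescent_mode_keeps_cell_active_and_aging(self):
        p = CellParams(quiescence=False)
        g = self._enclosed(p)
        g.kind[4, 4] = TC_ACTIVE
        g.cycle_phase[4, 4] = p.div
        attempt_division(g, 1.0, p)
        assert g.kind[4, 4] == TC_ACTIVE          # no quiescent transition
        assert g.cycle_phase[4, 4] == 0.0         # proceeds to the next cycle
        age0 = g.age[4, 4]
        age_and_die(g, p, dt=1.0)
        assert g.age[4, 4] == age0 + 1.0


class TestPolarization:
    def test_no_csf1_no_drug_no_history_means_no_m1_to_m2(self):
        p = CellParams()
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=1e9)
        zeros = np.zeros((g.ny, g.nx))
        for _ in range(200):
            polarize(g, zeros, zeros, p, dt=0.5)
        assert g.kind.ravel()[40] == M1

    def test_m2_to_m1_probability_increases_with_csf1ri(self):
        p = CellParams()
        base = p.pM21
        probs = [min(1.0, base * (1.0 + p.KM12d * u)) for u in (0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(probs) > 0)

    def test_two_state_chain_reaches_analytic_stationary_fraction(self):
        """At fixed local concentrations the M1/M2 ensemble is a two-state
        Markov chain; the stationary M1 fraction is p21/(p12+p21)."""
        p = CellParams()
        n = 60
        g = AgentGrid(n, n, np.random.default_rng(3))
        idx = np.arange(n * n)[:: 2]
        g.place(idx, M2, lifespan=1e9)
        csf1 = np.full((n, n), 1.0)
        csf1ri = np.zeros((n, n))
        for _ in range(4000):
            polarize(g, csf1, csf1ri, p, dt=0.5)
        p12 = p.kM12 * 1.0 / (p.K_csf1 / p.alpha_C + 1.0)
        p21 = p.pM21
        expected = p21 / (p12 + p21)
        frac = (g.kind == M1).sum() / idx.size
        se = np.sqrt(expected * (1 - expected) / idx.size)
        assert abs(frac - expected) < 5 * se

    def test_polarize_ignores_m0(self):
        p = CellParams()
        g = make_grid()
        g.place(np.array([40]), M0, lifespan=1e9, mature=24.0)
        polarize(g, np.ones((g.ny, g.nx)), np.zeros((g.ny, g.nx)), p, 0.5)
        assert g.kind.ravel()[40] == M0


class TestPhagocytosis:
    def test_no_adjacent_target_no_event(self):
        p = CellParams(pha=1.0)
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=1e9)
        assert phagocytose(g, p, dt=0.5) == 0

    def test_certain_phagocytosis_moves_m1_into_victim_site(self):
        p = CellParams(pha=1.0)
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=1e9)
        place_tc(g, 4, 5, p)
        n = phagocytose(g, p, dt=0.5)
        assert n == 1
        assert g.kind.ravel()[41] == M1           # moved into the TC's site
        assert g.kind.ravel()[40] == EMPTY

    def test_tc_preferred_over_dc(self):
        p = CellParams(pha=1.0)
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=1e9)
        g.place(np.array([39]), DC)
        place_tc(g, 4, 5, p)
        phagocytose(g, p, dt=0.5)
        assert g.events["phago_tc"] == 1
        assert g.events["phago_dc"] == 0

    def test_event_frequency_matches_pha(self):
        """Isolated M1-TC pairs fire with per-step probability pha."""
        prob = 0.25
        p = CellParams(pha=prob)
        g = AgentGrid(200, 200, np.random.default_rng(4))
        n_pairs = 1600
        k = 0
        for i in range(40):
            for j in range(40):
                y, x = 5 * i + 1, 5 * j + 1
                g.place(np.array([y * 200 + x]), M1, lifespan=1e9)
                place_tc(g, y, x + 1, p)
                k += 1
        phagocytose(g, p, dt=0.5)
        freq = g.events["phago_tc"] / n_pairs
        se = np.sqrt(prob * (1 - prob) / n_pairs)
        assert abs(freq - prob) < 4 * se


class TestMigration:
    def test_zero_migration_rate_never_moves(self):
        p = CellParams(DM=0.0, p_tc_move=0.0)
        g = make_grid()
        g.place(np.array([40]), M1, lifespan=1e9)
        for _ in range(100):
            migrate(g, np.zeros((g.ny, g.nx)), p, dt=0.5)
        assert g.kind.ravel()[40] == M1

    def test_flat_field_moves_uniformly(self):
        """Destination counts over many independent single-step draws are
        uniform over the four Von Neumann neighbors (chi-square test)."""
        p = CellParams(DM=1.0)
        counts = np.zeros(4)
        offsets = {(-1, 0): 0, (1, 0): 1, (0, -1): 2, (0, 1): 3}
        n_draws = 4000
        for s in range(n_draws):
            g = AgentGrid(5, 5, np.random.default_rng(s))
            g.place(np.array([2 * 5 + 2]), M1, lifespan=1e9)
            migrate(g, np.zeros((5, 5)), p, dt=0.5)
            pos = np.flatnonzero(g.kind.ravel() == M1)[0]
            dy, dx = pos // 5 - 2, pos % 5 - 2
            counts[offsets[(dy, dx)]] += 1
        chi2 = np.sum((counts - n_draws / 4) ** 2 / (n_draws / 4))
        assert chi2 < 16.27      # chi2(3) at p=0.001

    def test_steep_gradient_biases_up_gradient(self):
        p = CellParams(DM=1.0, beta_chemo=30.0)
        up = 0
        n_draws = 300
        for s in range(n_draws):
            g = AgentGrid(5, 5, np.random.default_rng(s))
            g.place(np.array([2 * 5 + 2]), M1, lifespan=1e9)
            csf1 = np.tile(np.linspace(0, 0.4, 5), (5, 1))   # increases with x
            migrate(g, csf1, p, dt=0.5)
            pos = np.flatnonzero(g.kind.ravel() == M1)[0]
            if pos % 5 > 2:
                up += 1
        assert up / n_draws > 0.8


class TestRecruitmentAndDeath:
    def _vasc(self, n=9):
        mask = np.zeros((n, n), bool)
        mask[0, :] = True
        return VascularMap(mask, np.where(mask, 1.0, 0.0))

    def test_capacity_reached_blocks_recruitment(self):
        p = CellParams(prec=1.0)
        g = make_grid()
        g.place(np.arange(30, 33), M1, lifespan=1e9)
        n = recruit_and_differentiate(g, self._vasc(), np.ones((9, 9)), p,
                                      dt=0.5, capacity=3)
        assert n == 0

    def test_zero_recruitment_probability(self):
        p = CellParams(prec=0.0)
        g = make_grid()
        n = recruit_and_differentiate(g, self._vasc(), np.ones((9, 9)), p,
                                      dt=0.5, capacity=100)
        assert n == 0

    def test_m0_matures_into_m1_or_m2(self):
        p = CellParams(m0_maturation=1.0)
        g = make_grid()
        g.place(np.array([40]), M0, lifespan=1e9, mature=1.0)
        recruit_and_differentiate(g, self._vasc(), np.zeros((9, 9)), p,
                                  dt=1.0, capacity=100)
        assert g.kind.ravel()[40] in (M1, M2)

    def test_under_lifespan_cell_survives(self):
        p = CellParams()
        g = make_grid()
        place_tc(g, 4, 4, p)
        age_and_die(g, p, dt=1.0)
        assert g.kind[4, 4] == TC_ACTIVE

    def test_lifespan_reached_becomes_dead_cell(self):
        p = CellParams()
        g = make_grid()
        flat = place_tc(g, 4, 4, p)
        g.age.ravel()[flat] = p.tc_lifespan
        age_and_die(g, p, dt=1.0)
        assert g.kind[4, 4] == DC

    def test_dc_clearance_times_are_geometric(self):
        """A cohort of dead cells clears with geometric waiting times whose
        mean is 1/q steps."""
        q = 0.1
        p = CellParams(dc_removal=q)
        n = 50
        g = AgentGrid(n, n, np.random.default_rng(9))
        g.kind[:, :] = DC
        total = n * n
        waits = np.zeros(total)
        remaining = np.ones((n, n), bool)
        for step in range(1, 400):
            age_and_die(g, p, dt=0.5)
            cleared = remaining & (g.kind == EMPTY)
            waits[np.flatnonzero(cleared.ravel())] = step
            remaining &= g.kind == DC
            if not remaining.any():
                break
        waits = waits[waits > 0]
        mean = waits.mean()
        se = (1 / q) / np.sqrt(len(waits))    # geometric sd ~ 1/q
        assert abs(mean - 1 / q) < 5 * se


class TestSchedulerInvariants:
    def test_one_cell_per_site_and_ledger_reconciliation(self, scaled_params,
                                                         burnin_tme):
        """Over a fuzzed stretch of full scheduler steps, occupancy stays
        consistent and TC-count changes reconcile exactly with the event
        ledger (division - phagocytosis - death)."""
        from gliomarl.engine import _step
        from gliomarl.kinds import TC_KINDS, VESSEL
        import copy
        params = scaled_params
        state = burnin_tme.copy()
        state.grid.rng = np.random.default_rng(77)
        vessels0 = int((state.grid.kind == VESSEL).sum())
        for _ in range(60):
            tc_before = state.grid.count(*TC_KINDS)
            state.grid.reset_events()
            _step(state, params, None, params.tam_capacity)
            ev = state.grid.events
            tc_after = state.grid.count(*TC_KINDS)
            assert tc_after - tc_before == (ev["division"] - ev["phago_tc"]
                                            - ev["death_tc"])
            # occupancy sanity: vessels immobile, kind codes valid
            assert int((state.grid.kind == VESSEL).sum()) == vessels0
            assert state.grid.kind.max() <= VESSEL
            assert state.grid.kind.min() >= EMPTY
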