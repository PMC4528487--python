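"""Behavioural tests of the pure-Python reference engine (step/ctl_update)."""

import numpy as np
import pytest
from scipy import stats

import ctlsim.geometry as geo
from ctlsim import (CTLAgent, SimulationConfig, TissueWorld, choose_direction,
                    step)
from ctlsim.geometry import site_centre
from ctlsim.world import CONJUGATED, SCANNING, SEARCHING


def make_ctl(position, heading=0.0, persistence=25.0):
    pos = np.asarray(position, dtype=float)
    ctl = CTLAgent(position=pos.copy(), heading=heading,
                   distance_remaining=persistence)
    ctl.prev_position = pos.copy()
    return ctl


class TestStep:
    def test_null_dynamics(self, small_config, small_world, rng):
        before = small_world.cell_state.copy()
        step(small_world, small_config, rng)
        assert np.array_equal(small_world.cell_state, before)
        assert small_world.clock == pytest.approx(1.0 / 60.0)

    def test_site_and_ctl_conservation(self, rng):
        cfg = SimulationConfig(n_rows=16, n_cols=16, timestep=10.0,
                               ctl_velocity=7.5)
        world = TissueWorld.from_config(cfg)
        rows, cols = np.nonzero(world.cell_state == geo.SUSCEPTIBLE)
        for i in rng.choice(len(rows), 10, replace=False):
            world.infect(int(rows[i]), int(cols[i]))
        world.place_ctl(5, rng)
        for _ in range(50):
            step(world, cfg, rng)
            c = world.counts()
            assert (c["susceptible"] + c["infected"] + c["dead"]
                    == world.n_sites)
            assert c["ctl_free"] + c["ctl_conjugated"] == 5

    def test_cytopathic_halflife(self, rng):
        """With only cytopathic death acting, about half of 1000 infected
        cells survive one half-life (1.4 days)."""
        cfg = SimulationConfig(n_rows=40, n_cols=40, timestep=600.0,
                               infection_mode="clustered",
                               virion_production_rate=1e-9)
        world = TissueWorld.from_config(cfg)
        flat = rng.choice(1600, 1000, replace=False)
        for s in flat:
            world.infect(int(s) // 40, int(s) % 40)
        n_steps = int(1.4 * 86400 / 600)
        for _ in range(n_steps):
            step(world, cfg, rng)
        survivors = int(np.count_nonzero(world.cell_state == geo.INFECTED))
        # binomial(1000, 0.5): 4 sigma ~ 63
        assert abs(survivors - 500) < 65


class TestCTLStateMachine:
    def test_velocity_zero_never_moves_or_scans(self, nonsus_world, rng):
        cfg = SimulationConfig(n_rows=16, n_cols=16, ctl_velocity=0.0)
        ctl = make_ctl([33.0, 47.0])
        nonsus_world.ctl_agents.append(ctl)
        for _ in range(500):
            step(nonsus_world, cfg, rng)
        np.testing.assert_allclose(ctl.position, [33.0, 47.0])
        assert ctl.scan_count == 0

    def test_handling_time_is_exact(self, rng):
        """A CTL headed at the sole infected cell kills it exactly the
        handling time after first contact."""
        cfg = SimulationConfig(n_rows=16, n_cols=16, handling_time=30.0)
        world = TissueWorld.from_config(cfg)
        world.infect(4, 4)
        target_centre = site_centre(4, 4, 10.0)
        ctl = make_ctl(target_centre - [cfg.contact_radius + 4.0, 0.0])
        world.ctl_agents.append(ctl)
        t_contact = None
        for _ in range(5 * 3600):
            step(world, cfg, rng)
            if t_contact is None and ctl.state == CONJUGATED:
                t_contact = world.clock
            if world.cell_state[4, 4] == geo.DEAD:
                break
        assert t_contact is not None
        assert world.clock - t_contact == pytest.approx(30.0, abs=1e-6)
        assert ctl.kill_count == 1

    def test_multiple_binding_leaves_lysis_time_unchanged(self, rng):
        """A second CTL binding the same target neither delays nor advances
        the kill; both are released when the first-attached CTL finishes."""
        cfg = SimulationConfig(n_rows=16, n_cols=16, handling_time=30.0)
        world = TissueWorld.from_config(cfg)
        world.infect(4, 4)
        centre = site_centre(4, 4, 10.0)
        first = make_ctl(centre - [cfg.contact_radius + 2.0, 0.0])
        second = make_ctl(centre + [cfg.contact_radius + 6.0, 0.0],
                          heading=np.pi)
        world.ctl_agents += [first, second]
        t_first_contact = None
        for _ in range(5 * 3600):
            step(world, cfg, rng)
            if t_first_contact is None and first.state == CONJUGATED:
                t_first_contact = world.clock
            if world.cell_state[4, 4] == geo.DEAD:
                break
        assert world.cell_state[4, 4] == geo.DEAD
        assert world.clock - t_first_contact == pytest.approx(30.0, abs=1e-6)
        assert first.kill_count + second.kill_count == 1
        assert first.state == SEARCHING and second.state == SEARCHING

    def test_time_in_state_accounting_is_exact(self, rng):
        cfg = SimulationConfig(n_rows=16, n_cols=16)
        world = TissueWorld.from_config(cfg)
        world.infect(8, 8)
        world.place_ctl(3, rng)
        n_steps = 2000
        for _ in range(n_steps):
            step(world, cfg, rng)
        for ctl in world.ctl_agents:
            total = ctl.time_searching + ctl.time_scanning + ctl.time_conjugated
            assert total == pytest.approx(n_steps * cfg.timestep)


class TestChooseDirection:
    def test_full_chemotaxis_points_at_sole_infected(self, small_world, rng):
        small_world.infect(10, 3)
        ctl = make_ctl([15.0, 15.0])
        heading = choose_direction(ctl, small_world, 1.0, rng)
        delta = geo.toroidal_delta([15.0, 15.0], site_centre(10, 3, 10.0),
                                   small_world.extent)
        assert heading == pytest.approx(np.arctan2(delta[1], delta[0]))
        assert ctl.distance_remaining == 25.0

    def test_no_infected_falls_back_to_random_turn(self, small_world, rng):
        ctl = make_ctl([15.0, 15.0], heading=0.3)
        choose_direction(ctl, small_world, 1.0, rng)
        assert abs(ctl.heading - 0.3) <= np.pi / 4 + 1e-12

    def test_random_turns_uniform_on_45_degrees(self, small_world, rng):
        """KS test of the turn-angle distribution against U(-45, +45)."""
        ctl = make_ctl([15.0, 15.0], heading=0.0)
        deltas = []
        for _ in range(10_000):
            h0 = ctl.heading
            choose_direction(ctl, small_world, 0.0, rng)
            deltas.append(ctl.heading - h0)
        deltas = np.array(deltas)
        assert np.all(np.abs(deltas) <= np.pi / 4 + 1e-12)
        pval = stats.kstest(deltas, stats.uniform(-np.pi / 4,
                                                  np.pi / 2).cdf).pvalue
        assert pval > 1e-3

    def test_directed_turn_fraction_matches_probability(self, small_world,
                                                        rng):
        small_world.infect(0, 0)
        ctl = make_ctl([155.0, 155.0])
        target_bearing = None
        directed = 0
        n = 10_000
        for _ in range(n):
            ctl.heading = 1.234
            choose_direction(ctl, small_world, 0.2, rng)
            delta = geo.toroidal_delta(ctl.position,
                                       site_centre(0, 0, 10.0),
                                       small_world.extent)
            target_bearing = np.arctan2(delta[1], delta[0])
            if ctl.heading == pytest.approx(target_bearing, abs=1e-12):
                directed += 1
        # binomial(10^4, 0.2): 4 sigma ~ 160
        assert abs(directed - 0.2 * n) < 170

    def test_discrete_turn_option(self, small_world, rng):
        ctl = make_ctl([15.0, 15.0], heading=0.0)
        seen = set()
        for _ in range(100):
            ctl.heading = 0.0
            choose_direction(ctl, small_world, 0.0, rng, discrete_turns=True)
            seen.add(round(ctl.heading, 9))
        assert seen == {round(np.pi / 4, 9), round(-np.pi / 4, 9)}
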