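import numpy as np
import pytest
from scipy.spatial import cKDTree

import ctlsim.geometry as geo
from ctlsim import (SimulationConfig, TissueWorld, calibrate_virion_production,
                    diffuse_infect_step, estimate_growth_rate, run_growth)
from ctlsim.world import TimeCourse


def _timecourse(t_min, infected):
    n = len(t_min)
    z = np.zeros(n)
    return TimeCourse.from_arrays(
        time_min=np.asarray(t_min, float), susceptible=z, infected=infected,
        dead=z, ctl_free=z, ctl_conjugated=z, virions=z)


class TestDiffuseInfectStep:
    def test_zero_rate_no_infections(self, small_world, rng):
        small_world.infect(3, 3)
        assert diffuse_infect_step(small_world, 0.0, 1.0, rng) == 0

    def test_saturated_tissue_noop(self, rng):
        world = TissueWorld.uniform(4, 4)
        for r in range(4):
            for c in range(4):
                world.infect(r, c)
        assert diffuse_infect_step(world, 1.0, 1.0, rng) == 0

    def test_expected_infections_per_step(self, rng):
        """1000 infected cells at rate r = 1/day: the mean number of new
        infections per step matches the closed-form n p (Monte Carlo)."""
        r_per_min = 1.0 / 1440.0
        dt = 60.0
        p = 1 - np.exp(-r_per_min * dt / 60.0)
        total = 0
        n_steps = 400
        for _ in range(n_steps):
            world = TissueWorld.uniform(40, 40)
            flat = rng.choice(1600, 1000, replace=False)
            for s in flat:
                world.infect(int(s) // 40, int(s) % 40)
            total += diffuse_infect_step(world, r_per_min, dt, rng)
        expected = 1000 * p * n_steps
        assert abs(total - expected) < 4 * np.sqrt(expected)


class TestEstimateGrowthRate:
    def test_noiseless_exponential_recovery(self):
        t = np.linspace(0, 3 * 1440, 80)
        tc = _timecourse(t, 60 * np.exp(t / 1440.0))
        assert estimate_growth_rate(tc) == pytest.approx(1.0, rel=1e-9)

    def test_constant_counts_give_zero(self):
        t = np.linspace(0, 1440, 30)
        tc = _timecourse(t, np.full(30, 200.0))
        assert estimate_growth_rate(tc) == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_noise_recovery_within_5pc(self, rng):
        t = np.linspace(0, 3 * 1440, 50)
        counts = 60 * np.exp(t / 1440.0) * rng.lognormal(0.0, 0.05, 50)
        assert estimate_growth_rate(_timecourse(t, counts)) == pytest.approx(
            1.0, rel=0.05)

    def test_too_few_points_rejected(self):
        t = np.array([0.0, 30.0, 60.0])
        with pytest.raises(ValueError):
            estimate_growth_rate(_timecourse(t, np.array([60.0, 62, 64])))

    def test_zero_counts_truncated(self):
        t = np.linspace(0, 2 * 1440, 40)
        counts = 60 * np.exp(t / 1440.0)
        counts[-5:] = 0.0
        est = estimate_growth_rate(_timecourse(t, counts))
        assert est == pytest.approx(1.0, rel=1e-6)


class TestSpatialPattern:
    """Diffuse infections are complete-spatial-random; clustered are not.

    Clark-Evans statistic: observed mean nearest-neighbour distance over the
    CSR expectation 0.5/sqrt(density); ~1 under CSR, << 1 when aggregated.
    """

    def _ce_from_sites(self, sites_rc, n_rows, n_cols, d):
        pts = np.stack([(sites_rc[1] + 0.5) * d, (sites_rc[0] + 0.5) * d],
                       axis=1)
        box = [n_cols * d, n_rows * d]
        tree = cKDTree(pts, boxsize=box)
        nn, _ = tree.query(pts, k=2)
        density = len(pts) / (box[0] * box[1])
        return nn[:, 1].mean() / (0.5 / np.sqrt(density))

    def test_diffuse_csr_clustered_aggregated(self):
        ce = {"diffuse": [], "clustered": []}
        for mode in ce:
            cfg = SimulationConfig(n_rows=64, n_cols=64, timestep=10.0,
                                   t_max=12.0, infection_mode=mode)
            for seed in range(4):
                res = run_growth(cfg, seed, stop_at=200)
                sites = np.nonzero(res.final_state == geo.INFECTED)
                ce[mode].append(self._ce_from_sites(sites, 64, 64, 10.0))
        assert 0.85 < np.mean(ce["diffuse"]) < 1.15
        assert np.mean(ce["clustered"]) < 0.6


class TestCalibrateVirionProduction:
    def test_sweep_solves_target_and_closes_loop(self):
        cfg = SimulationConfig(n_rows=48, n_cols=48, timestep=10.0,
                               t_max=10.0, infection_mode="clustered")
        cal = calibrate_virion_production(cfg, target_r=1.0,
                                          sweep_fraction=0.3, n_points=5,
                                          reps=8, seed=4, stop_at=200)
        # response is increasing (production drives growth)
        slope = cal.slope
        assert slope > 0
        assert cal.production_rates.min() <= cal.solved_rate \
            <= cal.production_rates.max()
        # closed loop: re-simulating at the solved rate recovers the target
        cfg2 = cfg.replace(virion_production_rate=cal.solved_rate)
        rates = [estimate_growth_rate(
            run_growth(cfg2, 100 + s, stop_at=200).timecourse)
            for s in range(8)]
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert np.mean(rates) == pytest.approx(1.0, abs=max(4 * se, 0.15))

    def test_unreachable_target_reports_bracketing_failure(self):
        cfg = SimulationConfig(n_rows=48, n_cols=48, timestep=10.0,
                               t_max=10.0, infection_mode="clustered")
        with pytest.raises(ValueError, match="outside the swept response"):
            calibrate_virion_production(cfg, target_r=10.0,
                                        sweep_fraction=0.05, n_points=3,
                                        reps=4, seed=1, stop_at=150)

    def test_requires_clustered_mode(self):
        with pytest.raises(ValueError):
            calibrate_virion_production(SimulationConfig(), seed=0)
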