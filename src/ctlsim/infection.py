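"""Diffuse vs clustered spread mechanics and the growth-rate calibration.

The uncontrolled net growth rate r (default 1 /day) is the reference point
for everything downstream: critical CTL densities are expressed in units of
r/k. Diffuse infections implement mass-action-like spread directly (each
infected cell seeds a uniformly random susceptible cell, no virions);
clustered infections spread through straight-flying virions, and the virion
production rate is pinned to the target r by a regression sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import geometry as geo
from .config import SimulationConfig, rate_to_prob


def diffuse_infect_step(world, rate_per_min: float, dt: float,
                        rng: np.random.Generator,
                        rows: Optional[np.ndarray] = None,
                        cols: Optional[np.ndarray] = None) -> int:
    """One diffuse-spread substep: each (active) infected cell converts one
    uniformly chosen susceptible cell with probability ``rate * dt``,
    regardless of distance. Returns the number of new infections.

    ``rows``/``cols`` restrict the acting infected cells (used by
    :func:`ctlsim.abm.step` to exclude cells that die in the same step).
    """
    if rows is None:
        rows, cols = np.nonzero(world.cell_state == geo.INFECTED)
    n_active = len(rows)
    if n_active == 0:
        return 0
    sus_flat = np.flatnonzero(world.cell_state.ravel() == geo.SUSCEPTIBLE)
    if sus_flat.size == 0:
        return 0
    p = rate_to_prob(rate_per_min, dt)
    # sequential uniform choices without collisions == sampling w/o replacement
    n_new = min(int(rng.binomial(n_active, p)), sus_flat.size)
    if n_new == 0:
        return 0
    for s in rng.choice(sus_flat, size=n_new, replace=False):
        world.infect(int(s) // world.n_cols, int(s) % world.n_cols)
    return n_new


def estimate_growth_rate(timecourse, window: Optional[Tuple[float, float]] = None,
                         min_count: int = 50, min_samples: int = 5) -> float:
    """Exponential growth rate (per day) of the infected-cell count.

    Ordinary least squares of ln(infected) against time. By default the fit
    window starts when the count first reaches ``min_count`` cells (avoiding
    founder stochasticity) and runs to the end of the course; an explicit
    ``(t0, t1)`` window (minutes) overrides this. Zero counts inside the
    window are truncated away.
    """
    t = timecourse.time_min
    counts = timecourse.infected.astype(float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
    else:
        above = np.nonzero(counts >= min_count)[0]
        if above.size == 0:
            raise ValueError(
                f"infected count never reached min_count={min_count}")
        m = np.arange(len(t)) >= above[0]
    m &= counts > 0
    if m.sum() < min_samples:
        raise ValueError(f"need >= {min_samples} positive samples in the fit "
                         f"window, got {int(m.sum())}")
    slope_per_min = np.polyfit(t[m], np.log(counts[m]), 1)[0]
    return float(slope_per_min * 1440.0)


@dataclass
class GrowthCalibration:
    """Result of the virion-production sweep pinning the growth rate."""

    production_rates: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_reps: int
    slope: float
    intercept: float
    target_r: float
    solved_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "production_rate": self.production_rates,
            "mean_r": self.mean_r, "sd_r": self.sd_r,
            "n": np.full(len(self.production_rates), self.n_reps),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "target_r": self.target_r, "solved_rate": self.solved_rate,
                "n_reps": self.n_reps}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def calibrate_virion_production(config: SimulationConfig,
                                target_r: float = 1.0,
                                sweep_fraction: float = 0.05,
                                n_points: int = 21,
                                reps: int = 50,
                                seed: int = 0,
                                stop_at: int = 400,
                                centre: Optional[float] = None
                                ) -> GrowthCalibration:
    """Pin the virion production rate to a target uncontrolled growth rate.

    Simulates CTL-free clustered infections over a sweep of production rates
    (``centre * (1 +/- sweep_fraction)`` in ``n_points`` even steps, ``reps``
    replicates each), estimates the growth rate of each run, regresses the
    mean growth rate on the production rate, and solves the regression for
    ``target_r``. Raises if the target falls outside the swept response.
    """
    from .abm import run_growth  # local import to avoid a cycle

    if config.infection_mode != "clustered":
        raise ValueError("growth calibration applies to clustered infections")
    if centre is None:
        centre = config.virion_production_rate
    rates = centre * np.linspace(1 - sweep_fraction, 1 + sweep_fraction,
                                 n_points)
    mean_r = np.empty(n_points)
    sd_r = np.empty(n_points)
    for i, rate in enumerate(rates):
        cfg = config.replace(virion_production_rate=float(rate), n_ctl=0)
        sub = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        child_seeds = sub.generate_state(reps) % 2**31
        ests = []
        for s in child_seeds:
            res = run_growth(cfg, int(s), stop_at=stop_at)
            try:
                ests.append(estimate_growth_rate(res.timecourse))
            except ValueError:
                continue  # run died out / too short: drop from this point
        if len(ests) < max(3, reps // 4):
            raise RuntimeError(
                f"too few usable growth runs at production rate {rate:.3g}")
        mean_r[i] = np.mean(ests)
        sd_r[i] = np.std(ests, ddof=1)
    slope, intercept = np.polyfit(rates, mean_r, 1)
    if not (mean_r.min() <= target_r <= mean_r.max()):
        raise ValueError(
            f"target growth rate {target_r} /day is outside the swept "
            f"response [{mean_r.min():.3f}, {mean_r.max():.3f}]; "
            f"widen the sweep or move its centre")
    solved = (target_r - intercept) / slope
    return GrowthCalibration(
        production_rates=rates, mean_r=mean_r, sd_r=sd_r, n_reps=reps,
        slope=float(slope), intercept=float(intercept), target_r=target_r,
        solved_rate=float(solved))
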