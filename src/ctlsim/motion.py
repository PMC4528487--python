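"""CTL behavioural state machine and the surveillance-rate calibration.

A searching CTL performs a persistent random walk (straight segments of the
persistence length, joined by turns through a uniform deviate on +/-45
degrees), optionally biased by chemotaxis: with a fixed per-turn probability
the new heading points exactly at the nearest living infected cell. Contact
with a new cell interrupts the walk: uninfected cells are scanned for the
scan time, infected cells trigger conjugation for the (fixed) handling time,
after which the target is lysed. Chemotaxis never alters the speed, so the
surveillance rate k is a property of velocity, scan time and the contact
geometry alone.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import geometry as geo
from .config import SimulationConfig
from .world import CONJUGATED, SCANNING, SEARCHING, CTLAgent, TissueWorld


def choose_direction(ctl: CTLAgent, world: TissueWorld,
                     chemotaxis_prob: float, rng: np.random.Generator,
                     persistence_length: float = 25.0,
                     discrete_turns: bool = False) -> float:
    """Turn event: re-orient a CTL and reset its persistent segment.

    With probability ``chemotaxis_prob`` the new heading points exactly at
    the nearest living infected cell (toroidal bearing; falls back to a
    random turn when no infected cell exists); otherwise the heading deviates
    from the previous one by a uniform draw on [-45, +45] degrees (or exactly
    +/-45 degrees with ``discrete_turns``).
    """
    deg45 = math.pi / 4
    directed = (chemotaxis_prob > 0.0 and rng.random() < chemotaxis_prob)
    if directed:
        hit = geo.nearest_infected(ctl.position, world)
        if hit is not None:
            (r, c), _ = hit
            delta = geo.toroidal_delta(
                ctl.position, geo.site_centre(r, c, world.cell_diameter),
                world.extent)
            ctl.heading = math.atan2(delta[1], delta[0])
            ctl.distance_remaining = persistence_length
            return ctl.heading
    if discrete_turns:
        ctl.heading += deg45 if rng.random() < 0.5 else -deg45
    else:
        ctl.heading += (rng.random() * 2.0 - 1.0) * deg45
    ctl.distance_remaining = persistence_length
    return ctl.heading


def release_attached(world: TissueWorld, site: Tuple[int, int],
                     config: SimulationConfig, rng: np.random.Generator
                     ) -> None:
    """Release every CTL conjugated to a (now dead) target, with turn
    events."""
    for ctl in world.ctl_agents:
        if ctl.state == CONJUGATED and ctl.engaged_site == site:
            ctl.state = SEARCHING
            ctl.engaged_site = None
            ctl.state_elapsed = 0.0
            choose_direction(ctl, world, config.chemotaxis_prob, rng,
                             persistence_length=config.persistence_length,
                             discrete_turns=config.chemotaxis_discrete_turns)


def _entering_contact(ctl: CTLAgent, world: TissueWorld, contact_radius: float
                      ) -> Optional[Tuple[int, int]]:
    """The best lattice site whose contact disc the CTL entered this step.

    A contact fires only when the coarse-grained position crosses from
    outside to inside a site's contact radius; sites already in contact, dead
    sites and the last-scanned site never fire. Preference: smallest current
    distance, then infected over uninfected, then smallest (row, col).
    """
    d = world.cell_diameter
    ext = world.extent
    now = geo.coarse_grain(ctl.position)
    prev = geo.coarse_grain(ctl.prev_position)
    if now[0] == prev[0] and now[1] == prev[1]:
        return None
    m = int(math.ceil(contact_radius / d)) + 1
    row0 = int(now[1] // d) % world.n_rows
    col0 = int(now[0] // d) % world.n_cols
    best = None
    for dr in range(-m, m + 1):
        for dc in range(-m, m + 1):
            r = (row0 + dr) % world.n_rows
            c = (col0 + dc) % world.n_cols
            st = world.cell_state[r, c]
            if st == geo.DEAD or (r, c) == ctl.last_scanned_site:
                continue
            centre = geo.site_centre(r, c, d)
            dn = geo.toroidal_distance(now, centre, ext)
            if dn > contact_radius:
                continue
            if geo.toroidal_distance(prev, centre, ext) <= contact_radius:
                continue  # was already inside: not an entering contact
            key = (dn, 0 if st == geo.INFECTED else 1, r, c)
            if best is None or key < best:
                best = key
    return None if best is None else (best[2], best[3])


def ctl_update(ctl: CTLAgent, world: TissueWorld, config: SimulationConfig,
               dt: float, rng: np.random.Generator) -> CTLAgent:
    """Advance one CTL by one time step (reference implementation).

    Searching: move ``v * dt`` along the heading (wrapped), then entering-
    contact detection; a new uninfected living cell starts a scan, an
    infected cell starts a conjugation. Scanning completes after the scan
    time with a turn event. Conjugation kills the target after the fixed
    handling time if this CTL was the first to attach; all CTL attached to a
    dying target are released immediately.
    """
    state_at_entry = ctl.state
    scan_thresh = max(1, math.ceil(config.scan_time / dt))
    handle_thresh = max(1, math.ceil(config.handling_time * 60.0 / dt))
    my_index = next(i for i, c in enumerate(world.ctl_agents) if c is ctl)

    if ctl.state == SEARCHING:
        ctl.prev_position = ctl.position.copy()
        step_um = config.ctl_velocity * dt / 60.0
        if step_um > 0:
            ctl.position = geo.wrap_position(
                ctl.position + step_um * np.array([math.cos(ctl.heading),
                                                   math.sin(ctl.heading)]),
                world.extent)
            ctl.distance_remaining -= step_um
        hit = _entering_contact(ctl, world, config.contact_radius)
        if hit is not None:
            r, c = hit
            if world.cell_state[r, c] == geo.INFECTED:
                ctl.state = CONJUGATED
                ctl.state_elapsed = 0.0
                ctl.engaged_site = (r, c)
                if world.first_attached[r, c] < 0:
                    world.first_attached[r, c] = my_index
            else:
                ctl.state = SCANNING
                ctl.state_elapsed = 0.0
                ctl.engaged_site = (r, c)
                ctl.last_scanned_site = (r, c)
        elif ctl.distance_remaining <= 0:
            choose_direction(ctl, world, config.chemotaxis_prob, rng,
                             persistence_length=config.persistence_length,
                             discrete_turns=config.chemotaxis_discrete_turns)
    elif ctl.state == SCANNING:
        ctl.state_elapsed += dt
        if round(ctl.state_elapsed / dt) >= scan_thresh:
            ctl.scan_count += 1
            ctl.state = SEARCHING
            ctl.engaged_site = None
            ctl.state_elapsed = 0.0
            choose_direction(ctl, world, config.chemotaxis_prob, rng,
                             persistence_length=config.persistence_length,
                             discrete_turns=config.chemotaxis_discrete_turns)
    else:  # conjugated
        site = ctl.engaged_site
        if world.cell_state[site] != geo.INFECTED:
            # target died under us (cytopathic or another CTL's kill)
            ctl.state = SEARCHING
            ctl.engaged_site = None
            ctl.state_elapsed = 0.0
            choose_direction(ctl, world, config.chemotaxis_prob, rng,
                             persistence_length=config.persistence_length,
                             discrete_turns=config.chemotaxis_discrete_turns)
        else:
            ctl.state_elapsed += dt
            if (round(ctl.state_elapsed / dt) >= handle_thresh
                    and world.first_attached[site] == my_index):
                ctl.kill_count += 1
                ctl.last_scanned_site = site
                world.kill(*site)
                release_attached(world, site, config, rng)

    if state_at_entry == SEARCHING:
        ctl.time_searching += dt
    elif state_at_entry == SCANNING:
        ctl.time_scanning += dt
    else:
        ctl.time_conjugated += dt
    return ctl


# ---------------------------------------------------------------------------
# surveillance-rate calibration
# ---------------------------------------------------------------------------

@dataclass
class SurveillanceMeasurement:
    """Measured surveillance rate: completed scans per CTL per minute."""

    rate: float  # cells per CTL per minute
    per_ctl_rates: np.ndarray
    duration_min: float
    n_ctl: int

    @property
    def sd(self) -> float:
        return float(np.std(self.per_ctl_rates, ddof=1))

    def to_dict(self) -> dict:
        return {"rate": self.rate, "sd": self.sd,
                "duration_min": self.duration_min, "n_ctl": self.n_ctl}


def measure_surveillance_rate(config: SimulationConfig,
                              duration_min: float = 240.0,
                              n_ctl: int = 100,
                              seed: int = 0) -> SurveillanceMeasurement:
    """Measure the surveillance rate k on uninfected, non-susceptible tissue.

    ``n_ctl`` CTL patrol a tissue of non-susceptible cells (no infection, no
    killing) for ``duration_min``; the rate is the mean number of completed
    cell scans per CTL per minute.
    """
    from . import engine
    from .abm import _kernel_args

    dt = config.timestep
    kw = _kernel_args(config)
    ss = np.random.SeedSequence(entropy=seed)
    pyrng = np.random.Generator(np.random.PCG64(ss))
    kernel_seed = int(ss.generate_state(1)[0] % 2**31)
    state = np.full(config.n_sites, geo.NON_SUSCEPTIBLE, dtype=np.int8)
    n_steps = int(round(duration_min * 60.0 / dt))
    samples, status, _, kills, scans, _, _ = engine.run_abm(
        kernel_seed, state=state,
        init_inf_sites=np.empty(0, dtype=np.int32),
        n_ctl=n_ctl,
        ctl_x0=pyrng.random(n_ctl) * config.extent_x,
        ctl_y0=pyrng.random(n_ctl) * config.extent_y,
        ctl_h0=pyrng.random(n_ctl) * 2 * math.pi,
        i_c=0, max_growth_steps=0, max_steps_after=n_steps,
        sample_every=max(1, n_steps // 8), stop_at_inf=0, **kw)
    per_ctl = scans / duration_min
    rate = float(per_ctl.mean())
    if rate * duration_min < 1:
        warnings.warn("duration too short: fewer than one expected scan "
                      "per CTL")
    return SurveillanceMeasurement(rate=rate, per_ctl_rates=per_ctl,
                                   duration_min=duration_min, n_ctl=n_ctl)


@dataclass
class ContactCalibration:
    contact_radius: float
    measured_k: float
    target_k: float
    velocity: float
    scan_time: float
    ci: Tuple[float, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"velocity": self.velocity, "scan_time": self.scan_time,
                       "contact_radius": self.contact_radius,
                       "measured_k": self.measured_k,
                       "target_k": self.target_k,
                       "ci": list(self.ci)}, fh, indent=2)


def calibrate_contact_radius(config: SimulationConfig, target_k: float,
                             seed: int = 0, rel_tol: float = 0.05,
                             bracket: Tuple[float, float] = (0.5, 15.0),
                             duration_min: float = 240.0,
                             n_ctl: int = 100,
                             max_iter: int = 30) -> ContactCalibration:
    """Bisect the contact radius so the measured surveillance rate matches a
    target. The measured rate is monotone non-decreasing in the radius (a
    wider contact disc can only add contacts along a path), so bisection on a
    bracketing interval converges; a common seed per evaluation keeps the
    response smooth."""
    def f(radius):
        return measure_surveillance_rate(
            config.replace(contact_radius=radius), duration_min=duration_min,
            n_ctl=n_ctl, seed=seed).rate

    lo, hi = bracket
    k_lo, k_hi = f(lo), f(hi)
    if not (k_lo <= target_k <= k_hi):
        raise ValueError(
            f"target rate {target_k} not bracketed: k({lo})={k_lo:.4f}, "
            f"k({hi})={k_hi:.4f}")
    mid, k_mid = lo, k_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k_mid = f(mid)
        if abs(k_mid - target_k) <= rel_tol * target_k:
            break
        if k_mid < target_k:
            lo = mid
        else:
            hi = mid
    # MC error of the final measurement, per-CTL spread
    meas = measure_surveillance_rate(config.replace(contact_radius=mid),
                                     duration_min=duration_min, n_ctl=n_ctl,
                                     seed=seed + 1)
    sem = meas.sd / math.sqrt(n_ctl)
    return ContactCalibration(
        contact_radius=float(mid), measured_k=float(meas.rate),
        target_k=target_k, velocity=config.ctl_velocity,
        scan_time=config.scan_time,
        ci=(meas.rate - 1.96 * sem, meas.rate + 1.96 * sem))
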