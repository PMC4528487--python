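"""Discrete-time stochastic engine: single-step reference updates and the
whole-run driver.

Two routes exist through the model. :func:`step` advances a
:class:`~ctlsim.world.TissueWorld` by one time step in pure Python/numpy and
is the readable reference implementation; :func:`run_simulation` executes the
same rules through the compiled kernel in :mod:`ctlsim.engine` and is the
production path for replicate-heavy work. Equivalence of the two routes is
exercised in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import engine
from . import geometry as geo
from .config import SimulationConfig, rate_to_prob
from .infection import diffuse_infect_step
from .motion import ctl_update, release_attached
from .world import TimeCourse, TissueWorld, Virion


# ---------------------------------------------------------------------------
# reference single-step engine
# ---------------------------------------------------------------------------

def step(world: TissueWorld, config: SimulationConfig,
         rng: np.random.Generator) -> TissueWorld:
    """Advance the world by one time step ``config.timestep`` (in place).

    Update order: virions move/clear/infect; infected cells produce virions
    (clustered) or seed remote infections (diffuse) and may die
    cytopathically; CTL update in shuffled order. Site and CTL counts are
    conserved.
    """
    dt = config.timestep
    d = world.cell_diameter
    ext = world.extent

    # ---- virions ----------------------------------------------------------
    if config.infection_mode == "clustered" and world.virions:
        p_clear = rate_to_prob(config.virion_clearance_rate, dt)
        step_um = config.virion_speed * dt / 60.0
        survivors: List[Virion] = []
        for v in world.virions:
            v.position = geo.wrap_position(
                v.position + step_um * np.array([math.cos(v.heading),
                                                 math.sin(v.heading)]), ext)
            target = _nearest_susceptible_contact(v.position, world,
                                                  config.contact_radius)
            if target is not None:
                world.infect(*target)
                continue  # virion absorbed
            if rng.random() < p_clear:
                continue  # cleared
            survivors.append(v)
        world.virions = survivors

    # ---- infected cells ---------------------------------------------------
    rows, cols = np.nonzero(world.cell_state == geo.INFECTED)
    n_inf = rows.size
    p_cyto = (0.0 if config.diffuse_literal and
              config.infection_mode == "diffuse"
              else rate_to_prob(config.cytopathic_rate, dt))
    dying = rng.random(n_inf) < p_cyto if n_inf else np.zeros(0, bool)
    active = ~dying
    if not config.conjugated_cells_produce:
        conj = world.first_attached[rows, cols] >= 0
        active &= ~conj
    if config.infection_mode == "diffuse":
        diffuse_infect_step(world, config.diffuse_infection_rate, dt, rng,
                            rows[active], cols[active])
    else:
        p_prod = rate_to_prob(config.virion_production_rate / 1440.0, dt)
        producing = np.flatnonzero(active & (rng.random(n_inf) < p_prod))
        for i in producing:
            h = rng.random() * 2 * math.pi
            centre = geo.site_centre(rows[i], cols[i], d)
            pos = geo.wrap_position(
                centre + 0.5 * d * np.array([math.cos(h), math.sin(h)]), ext)
            world.virions.append(Virion(position=pos, heading=h,
                                        parent_site=(int(rows[i]),
                                                     int(cols[i]))))
    for i in np.flatnonzero(dying):
        world.kill(int(rows[i]), int(cols[i]))
        release_attached(world, (int(rows[i]), int(cols[i])), config, rng)

    # ---- CTL ---------------------------------------------------------------
    if world.ctl_agents:
        for k in rng.permutation(len(world.ctl_agents)):
            ctl_update(world.ctl_agents[k], world, config, dt, rng)

    world.clock += dt / 60.0
    return world


def _nearest_susceptible_contact(position, world, contact_radius):
    """Nearest susceptible site centre within the contact radius of a
    (continuous) position, ties broken by (row, col); None if none."""
    d = world.cell_diameter
    ext = world.extent
    m = int(math.ceil(contact_radius / d)) + 1
    row0 = int(position[1] // d) % world.n_rows
    col0 = int(position[0] // d) % world.n_cols
    best = None
    for dr in range(-m, m + 1):
        for dc in range(-m, m + 1):
            r = (row0 + dr) % world.n_rows
            c = (col0 + dc) % world.n_cols
            if world.cell_state[r, c] != geo.SUSCEPTIBLE:
                continue
            dist = geo.toroidal_distance(position,
                                         geo.site_centre(r, c, d), ext)
            if dist <= contact_radius and (best is None
                                           or (dist, r, c) < best):
                best = (dist, r, c)
    return None if best is None else (best[1], best[2])


# ---------------------------------------------------------------------------
# whole-run driver (compiled kernel)
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """One ABM realisation: sampled time course plus run metadata."""

    timecourse: TimeCourse
    status: str
    config: SimulationConfig
    seed: int
    t_intro_min: float
    kills_per_ctl: np.ndarray
    scans_per_ctl: np.ndarray
    final_infected: int
    n_growth_retries: int = 0
    final_state: Optional[np.ndarray] = None  # lattice states at termination

    @property
    def outcome(self) -> str:
        """'extinct' or 'established' (see cstar_estimation rules)."""
        from .estimation import classify_outcome

        return classify_outcome(self.timecourse, t_intro_min=self.t_intro_min)

    def post_intro(self) -> TimeCourse:
        """The time course from CTL introduction onwards, re-zeroed."""
        frame = self.timecourse.frame
        sub = frame[frame["time_min"] >= self.t_intro_min].copy()
        sub["time_min"] -= self.t_intro_min
        return TimeCourse(sub)

    def metadata(self) -> dict:
        return {
            "seed": int(self.seed),
            "status": self.status,
            "outcome": self.outcome,
            "t_intro_min": float(self.t_intro_min),
            "final_infected": int(self.final_infected),
            "n_growth_retries": int(self.n_growth_retries),
            "config": self.config.to_dict(),
        }


def _kernel_args(config: SimulationConfig):
    dt = config.timestep
    return dict(
        n_rows=config.n_rows, n_cols=config.n_cols,
        d=config.cell_diameter, dt=dt,
        mode_diffuse=config.infection_mode == "diffuse",
        p_inf=rate_to_prob(config.diffuse_infection_rate, dt),
        p_cyto=(0.0 if config.diffuse_literal
                and config.infection_mode == "diffuse"
                else rate_to_prob(config.cytopathic_rate, dt)),
        p_prod=rate_to_prob(config.virion_production_rate / 1440.0, dt),
        p_vclear=rate_to_prob(config.virion_clearance_rate, dt),
        virion_step=config.virion_speed * dt / 60.0,
        conj_produce=config.conjugated_cells_produce,
        ctl_step=config.ctl_velocity * dt / 60.0,
        scan_steps=max(1, math.ceil(config.scan_time / dt)),
        handling_steps=max(1, math.ceil(config.handling_time * 60.0 / dt)),
        persistence=config.persistence_length,
        chemo_prob=config.chemotaxis_prob,
        contact_radius=config.contact_radius,
        discrete_turns=config.chemotaxis_discrete_turns,
    )


def run_simulation(config: SimulationConfig, seed: Optional[int] = None,
                   initial_state: Optional[np.ndarray] = None,
                   n_seed_infected: int = 1,
                   max_retries: int = 200) -> SimulationResult:
    """Run one full realisation of the protocol.

    The tissue is seeded with ``n_seed_infected`` infected cells (default 1),
    the infection grows without CTL to ``config.i_c`` cells, then
    ``config.n_ctl`` CTL are placed uniformly at random and the run continues
    to extinction, saturation or ``config.t_max`` days post introduction.
    Fully reproducible from ``seed`` (falls back to ``config.seed``).

    If the infection dies out before reaching ``i_c``, the run is repeated
    with a fresh random substream; the retry count is reported.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    dt = config.timestep
    kw = _kernel_args(config)
    max_growth_steps = int(config.max_growth_days * 86400 / dt)
    max_steps_after = int(config.t_max * 86400 / dt)
    sample_every = max(1, round(config.sample_interval * 60.0 / dt))

    for attempt in range(max_retries):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
        pyrng = np.random.Generator(np.random.PCG64(ss))
        kernel_seed = int(ss.generate_state(1)[0] % 2**31)

        if initial_state is None:
            state = np.full(config.n_sites, geo.SUSCEPTIBLE, dtype=np.int8)
        else:
            state = np.asarray(initial_state, dtype=np.int8).ravel().copy()
        sus_sites = np.flatnonzero(state == geo.SUSCEPTIBLE)
        init_inf = pyrng.choice(sus_sites, size=min(n_seed_infected,
                                                    sus_sites.size),
                                replace=False).astype(np.int32)
        ctl_x0 = pyrng.random(config.n_ctl) * config.extent_x
        ctl_y0 = pyrng.random(config.n_ctl) * config.extent_y
        ctl_h0 = pyrng.random(config.n_ctl) * 2 * math.pi

        samples, status, t_intro_step, kills, scans, final_inf, _ = (
            engine.run_abm(
                kernel_seed, state=state, init_inf_sites=init_inf,
                n_ctl=config.n_ctl, ctl_x0=ctl_x0, ctl_y0=ctl_y0,
                ctl_h0=ctl_h0, i_c=config.i_c,
                max_growth_steps=max_growth_steps,
                max_steps_after=max_steps_after, sample_every=sample_every,
                stop_at_inf=0, **kw))
        if status != engine.STATUS_DIED_BEFORE_IC:
            if status == engine.STATUS_GROWTH_CAP:
                warnings.warn("infection failed to reach i_c within "
                              "max_growth_days")
            return SimulationResult(
                timecourse=TimeCourse.from_arrays(
                    time_min=samples[:, 0], susceptible=samples[:, 1],
                    infected=samples[:, 2], dead=samples[:, 3],
                    ctl_free=samples[:, 4], ctl_conjugated=samples[:, 5],
                    virions=samples[:, 6]),
                status=engine.STATUS_NAMES[status], config=config, seed=seed,
                t_intro_min=(t_intro_step * dt / 60.0
                             if t_intro_step >= 0 else 0.0),
                kills_per_ctl=kills, scans_per_ctl=scans,
                final_infected=int(final_inf), n_growth_retries=attempt,
                final_state=state.reshape(config.n_rows, config.n_cols))
    raise RuntimeError(f"infection died out before reaching i_c={config.i_c} "
                       f"in {max_retries} attempts")


def run_growth(config: SimulationConfig, seed: int, stop_at: int,
               n_seed_infected: int = 1,
               max_retries: int = 200) -> SimulationResult:
    """CTL-free growth run, terminating when the infected count reaches
    ``stop_at`` (or at the time cap). Used by the calibration pipelines.

    Runs in which the founder infection dies out before reaching the target
    are repeated with a fresh random substream (retry count reported), so
    the returned course always reflects an established infection.
    """
    dt = config.timestep
    kw = _kernel_args(config)
    empty = np.empty(0)
    for attempt in range(max_retries):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
        pyrng = np.random.Generator(np.random.PCG64(ss))
        kernel_seed = int(ss.generate_state(1)[0] % 2**31)
        state = np.full(config.n_sites, geo.SUSCEPTIBLE, dtype=np.int8)
        init_inf = pyrng.choice(config.n_sites, size=n_seed_infected,
                                replace=False).astype(np.int32)
        samples, status, _, kills, scans, final_inf, _ = engine.run_abm(
            kernel_seed, state=state, init_inf_sites=init_inf,
            n_ctl=0, ctl_x0=empty, ctl_y0=empty, ctl_h0=empty, i_c=0,
            max_growth_steps=0,
            max_steps_after=int(config.t_max * 86400 / dt),
            sample_every=max(1, round(config.sample_interval * 60.0 / dt)),
            stop_at_inf=stop_at, **kw)
        if status != engine.STATUS_EXTINCT:
            return SimulationResult(
                timecourse=TimeCourse.from_arrays(
                    time_min=samples[:, 0], susceptible=samples[:, 1],
                    infected=samples[:, 2], dead=samples[:, 3],
                    ctl_free=samples[:, 4], ctl_conjugated=samples[:, 5],
                    virions=samples[:, 6]),
                status=engine.STATUS_NAMES[status], config=config, seed=seed,
                t_intro_min=0.0, kills_per_ctl=kills, scans_per_ctl=scans,
                final_infected=int(final_inf), n_growth_retries=attempt,
                final_state=state.reshape(config.n_rows, config.n_cols))
    raise RuntimeError(f"founder infection died out in all {max_retries} "
                       f"attempts")
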