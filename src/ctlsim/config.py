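"""Run configuration: one object holding every rate, length and protocol knob.

All parameters carry explicit units (documented per field). Internally the
engines work in seconds and micrometres; the configuration keeps the units
most natural to each quantity (growth rates per day, velocities um/min,
handling time minutes) and converts on demand.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

LN2 = math.log(2.0)

#: Contact radius (um) calibrated so that a CTL moving at 7.5 um/min with a 5 s
#: scan time surveys ~1.1 cells/min (see ctlsim.motion.calibrate_contact_radius).
#: Fixed once by calibration and frozen here.
DEFAULT_CONTACT_RADIUS = 7.211

#: Virion production rate (virions per infected cell per day) calibrated so a
#: clustered infection without CTL grows at r = 1 /day
#: (see ctlsim.infection.calibrate_virion_production). Frozen after calibration.
DEFAULT_VIRION_PRODUCTION = 1.527


def rate_to_prob(rate: float, dt: float) -> float:
    """Per-step event probability for a Poisson process.

    Parameters
    ----------
    rate : float
        Event rate in events per **minute** (>= 0).
    dt : float
        Time step in **seconds** (> 0).

    Returns
    -------
    float
        ``1 - exp(-rate * dt / 60)``, the exact probability of at least one
        event in a window of length ``dt``.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return -math.expm1(-rate * dt / 60.0)


@dataclass
class SimulationConfig:
    """All parameters of a single agent-based run.

    Geometry
    --------
    n_rows, n_cols : lattice dimensions (default 320 x 320 = 102 400 cells).
    cell_diameter : um, lattice pitch (default 10), so the default tissue is a
        3.2 mm x 3.2 mm toroidal patch.

    Dynamics
    --------
    timestep : s, update interval for all agents (default 1).
    r_target : /day, net growth rate of the uncontrolled infection (default 1).
    infection_mode : "diffuse" (new infections appear at uniformly random
        susceptible cells) or "clustered" (spread via straight-flying virions).
    infected_cell_halflife : days, cytopathic death half-life (default 1.4).
    virion_halflife : h, free-virion clearance half-life (default 4).
    virion_speed : um/min, straight-line virion speed.
    virion_production_rate : virions per infected cell per day (calibrated).
    diffuse_literal : if True, diffuse mode uses the literal per-cell infection
        probability r*dt with cytopathic death disabled; by default the
        infection rate is r + ln2/halflife with death retained, so the realised
        net growth rate is r either way.
    conjugated_cells_produce : whether infected cells held in conjugates keep
        producing virions / infecting (default True: they are living targets
        until lysed).

    CTL behaviour
    -------------
    ctl_velocity : um/min (7.5 fast preset, 0.18 slow preset).
    scan_time : s spent stationary scanning an uninfected cell (default 5).
    handling_time : min spent conjugated before lysis (default 30, fixed).
    persistence_length : um of straight motion between spontaneous turns (25).
    chemotaxis_prob : probability that a turn points at the nearest infected
        cell instead of a random +/-45 degree deviation (0, 0.01, 0.05, 0.20).
    chemotaxis_discrete_turns : if True, random turns pick from {-45, +45}
        degrees exactly instead of a uniform deviate on [-45, +45].
    contact_radius : um within which a lattice-site centre counts as contacted
        (calibrated; see DEFAULT_CONTACT_RADIUS).

    Protocol
    --------
    i_c : infected-cell count at which CTL are introduced.
    n_ctl : number of CTL placed uniformly at random at introduction.
    t_max : days of simulated time after CTL introduction.
    max_growth_days : cap on the initial CTL-free growth phase.
    sample_interval : min between time-course samples.
    seed : root seed for the run (optional; run_simulation can supply one).
    """

    n_rows: int = 320
    n_cols: int = 320
    cell_diameter: float = 10.0
    timestep: float = 1.0
    r_target: float = 1.0
    infection_mode: str = "diffuse"
    infected_cell_halflife: float = 1.4
    virion_halflife: float = 4.0
    virion_speed: float = 10.0
    virion_production_rate: float = DEFAULT_VIRION_PRODUCTION
    diffuse_literal: bool = False
    conjugated_cells_produce: bool = True
    ctl_velocity: float = 7.5
    scan_time: float = 5.0
    handling_time: float = 30.0
    persistence_length: float = 25.0
    chemotaxis_prob: float = 0.0
    chemotaxis_discrete_turns: bool = False
    contact_radius: float = DEFAULT_CONTACT_RADIUS
    i_c: int = 1000
    n_ctl: int = 0
    t_max: float = 20.0
    max_growth_days: float = 40.0
    sample_interval: float = 30.0
    seed: Optional[int] = None

    # -- derived quantities ------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent_x(self) -> float:
        """Tissue extent (um) along the column axis."""
        return self.n_cols * self.cell_diameter

    @property
    def extent_y(self) -> float:
        """Tissue extent (um) along the row axis."""
        return self.n_rows * self.cell_diameter

    @property
    def cytopathic_rate(self) -> float:
        """Cytopathic death rate of infected cells, per minute."""
        return LN2 / (self.infected_cell_halflife * 1440.0)

    @property
    def virion_clearance_rate(self) -> float:
        """Free-virion clearance rate, per minute."""
        return LN2 / (self.virion_halflife * 60.0)

    @property
    def diffuse_infection_rate(self) -> float:
        """Per infected cell rate (per minute) of seeding a new infection in
        diffuse mode. The default compensates cytopathic death so that the net
        growth rate equals ``r_target``."""
        r_per_min = self.r_target / 1440.0
        if self.diffuse_literal:
            return r_per_min
        return r_per_min + self.cytopathic_rate

    def ctl_fraction(self) -> float:
        """CTL density as a fraction of all surveyable cells."""
        return self.n_ctl / self.n_sites

    # -- construction helpers ---------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.infection_mode not in ("diffuse", "clustered"):
            raise ValueError(f"unknown infection_mode {self.infection_mode!r}")
        for name in ("n_rows", "n_cols"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        positive = (
            "cell_diameter", "timestep", "r_target", "infected_cell_halflife",
            "virion_halflife", "virion_speed", "virion_production_rate",
            "scan_time", "handling_time", "persistence_length",
            "contact_radius", "t_max", "sample_interval",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.chemotaxis_prob <= 1.0:
            raise ValueError("chemotaxis_prob must lie in [0, 1]")
        if self.ctl_velocity < 0:
            raise ValueError("ctl_velocity must be non-negative")
        if self.n_ctl < 0 or self.i_c < 0:
            raise ValueError("n_ctl and i_c must be non-negative")
        # every per-step event probability must stay in the small-probability
        # regime so the discrete-time chain approximates the continuous process
        probs = {
            "cytopathic death": rate_to_prob(self.cytopathic_rate, self.timestep),
            "virion clearance": rate_to_prob(self.virion_clearance_rate, self.timestep),
            "diffuse infection": rate_to_prob(self.diffuse_infection_rate, self.timestep),
            "virion production": rate_to_prob(
                self.virion_production_rate / 1440.0, self.timestep),
        }
        for name, p in probs.items():
            if p >= 0.1:
                raise ValueError(
                    f"per-step probability of {name} is {p:.3f} >= 0.1; "
                    f"reduce timestep")

    # -- presets -----------------------------------------------------------
    @classmethod
    def full_scale(cls, **kw) -> "SimulationConfig":
        """The 320x320, 1 s preset."""
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "SimulationConfig":
        """Reduced preset for interactive use: 128x128 grid, 10 s steps, with
        the CTL-introduction threshold scaled to the same infected fraction as
        the full tissue (1000/102400)."""
        defaults = dict(n_rows=128, n_cols=128, timestep=10.0, i_c=160)
        defaults.update(kw)
        return cls(**defaults)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from JSON (or YAML when PyYAML is installed)."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # optional dependency

            data = yaml.safe_load(text)
        return cls.from_dict(data)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)
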