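"""In-memory containers: the tissue lattice, agents, and sampled time courses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import geometry as geo
from .config import SimulationConfig

SEARCHING = "searching"
SCANNING = "scanning"
CONJUGATED = "conjugated"


@dataclass
class CTLAgent:
    """A single cytotoxic T lymphocyte.

    The agent is a small state machine: ``searching`` (persistent random walk,
    possibly chemotactic), ``scanning`` (stationary on an uninfected cell for
    the scan time) or ``conjugated`` (attached to an infected cell for the
    handling time). ``kill_count`` is non-decreasing: one CTL can kill many
    times.
    """

    position: np.ndarray
    heading: float
    distance_remaining: float
    state: str = SEARCHING
    state_elapsed: float = 0.0  # seconds in current state
    engaged_site: Optional[Tuple[int, int]] = None
    last_scanned_site: Optional[Tuple[int, int]] = None
    kill_count: int = 0
    scan_count: int = 0
    prev_position: Optional[np.ndarray] = None
    # cumulative seconds per state, for time-in-state accounting
    time_searching: float = 0.0
    time_scanning: float = 0.0
    time_conjugated: float = 0.0


@dataclass
class Virion:
    """A free virion travelling in a straight line from its parent cell."""

    position: np.ndarray
    heading: float  # fixed for the virion's lifetime
    parent_site: Tuple[int, int]


@dataclass
class TissueWorld:
    """Lattice of cell states plus continuous-position agents and the clock.

    Sites are never created or destroyed, only relabelled among
    {non_susceptible, susceptible, infected, dead}.
    """

    n_rows: int
    n_cols: int
    cell_diameter: float
    cell_state: np.ndarray
    infected_since: np.ndarray  # min; NaN where not infected
    clock: float = 0.0  # minutes
    ctl_agents: List[CTLAgent] = field(default_factory=list)
    virions: List[Virion] = field(default_factory=list)
    # first-attached CTL index per site (-1: none); governs lysis timing
    first_attached: np.ndarray = None

    def __post_init__(self):
        if self.first_attached is None:
            self.first_attached = np.full((self.n_rows, self.n_cols), -1,
                                          dtype=np.int32)

    # -- construction ------------------------------------------------------
    @classmethod
    def uniform(cls, n_rows: int, n_cols: int, cell_diameter: float = 10.0,
                state: int = geo.SUSCEPTIBLE) -> "TissueWorld":
        return cls(
            n_rows=n_rows, n_cols=n_cols, cell_diameter=cell_diameter,
            cell_state=np.full((n_rows, n_cols), state, dtype=np.int8),
            infected_since=np.full((n_rows, n_cols), np.nan),
        )

    @classmethod
    def from_config(cls, config: SimulationConfig,
                    state: int = geo.SUSCEPTIBLE) -> "TissueWorld":
        return cls.uniform(config.n_rows, config.n_cols, config.cell_diameter,
                           state)

    # -- geometry ----------------------------------------------------------
    @property
    def extent_x(self) -> float:
        return self.n_cols * self.cell_diameter

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.cell_diameter

    @property
    def extent(self) -> np.ndarray:
        return np.array([self.extent_x, self.extent_y])

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    # -- mutation helpers ---------------------------------------------------
    def infect(self, row: int, col: int) -> None:
        if self.cell_state[row, col] != geo.SUSCEPTIBLE:
            raise ValueError(f"site ({row}, {col}) is not susceptible")
        self.cell_state[row, col] = geo.INFECTED
        self.infected_since[row, col] = self.clock

    def kill(self, row: int, col: int) -> None:
        if self.cell_state[row, col] != geo.INFECTED:
            raise ValueError(f"site ({row}, {col}) is not infected")
        self.cell_state[row, col] = geo.DEAD
        self.infected_since[row, col] = np.nan
        self.first_attached[row, col] = -1

    def place_ctl(self, n: int, rng: np.random.Generator,
                  persistence_length: float = 25.0) -> None:
        """Scatter ``n`` CTL uniformly at random with random headings."""
        for _ in range(n):
            pos = rng.random(2) * self.extent
            self.ctl_agents.append(CTLAgent(
                position=pos, heading=rng.random() * 2 * np.pi,
                distance_remaining=persistence_length,
                prev_position=pos.copy()))

    # -- observation --------------------------------------------------------
    def counts(self) -> dict:
        flat = self.cell_state.ravel()
        n_conj = sum(1 for c in self.ctl_agents if c.state == CONJUGATED)
        return {
            "time_min": self.clock,
            "susceptible": int(np.count_nonzero(flat == geo.SUSCEPTIBLE)),
            "infected": int(np.count_nonzero(flat == geo.INFECTED)),
            "dead": int(np.count_nonzero(flat == geo.DEAD)),
            "ctl_free": len(self.ctl_agents) - n_conj,
            "ctl_conjugated": n_conj,
            "virions": len(self.virions),
        }


COLUMNS = ["time_min", "susceptible", "infected", "dead", "ctl_free",
           "ctl_conjugated", "virions"]


class TimeCourse:
    """Sampled population counts over simulated time."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"time course missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "TimeCourse":
        return cls(pd.DataFrame.from_records(records, columns=COLUMNS))

    @classmethod
    def from_arrays(cls, **arrays) -> "TimeCourse":
        return cls(pd.DataFrame({c: arrays[c] for c in COLUMNS}))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def time_min(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    @property
    def infected(self) -> np.ndarray:
        return self.frame["infected"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def window(self, t0: float, t1: float) -> "TimeCourse":
        m = (self.time_min >= t0) & (self.time_min <= t1)
        return TimeCourse(self.frame[m])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        return cls(pd.read_csv(path))

    def __eq__(self, other) -> bool:
        return isinstance(other, TimeCourse) and self.frame.equals(other.frame)
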