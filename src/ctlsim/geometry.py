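"""Toroidal 2-D geometry, the static cell lattice, and spatial queries.

Conventions: lattice sites are indexed ``(row, col)``, 0-based; the centre of
site ``(row, col)`` sits at ``((col + 0.5) * d, (row + 0.5) * d)`` where ``d``
is the cell diameter. Positions are continuous ``(x, y)`` coordinates in um;
agent positions are coarse-grained to a 1 um grid before contact tests.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Optional, Set, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .world import TissueWorld

# lattice-site states
NON_SUSCEPTIBLE = 0
SUSCEPTIBLE = 1
INFECTED = 2
DEAD = 3

STATE_NAMES = {
    NON_SUSCEPTIBLE: "non_susceptible",
    SUSCEPTIBLE: "susceptible",
    INFECTED: "infected",
    DEAD: "dead",
}


def wrap_position(position, extent):
    """Wrap a position onto the torus: each coordinate into ``[0, extent)``.

    ``extent`` may be a scalar (square tissue) or a per-axis pair.
    """
    pos = np.asarray(position, dtype=float)
    ext = np.asarray(extent, dtype=float)
    if np.any(ext <= 0):
        raise ValueError("extent must be strictly positive")
    if not np.all(np.isfinite(pos)):
        raise ValueError("position coordinates must be finite")
    out = np.mod(pos, ext)
    # np.mod(-eps, L) can round up to exactly L; fold it back to 0
    return np.where(out >= ext, 0.0, out)


def toroidal_delta(a, b, extent):
    """Minimum-image displacement ``b - a`` on the torus."""
    ext = np.asarray(extent, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - ext * np.round(d / ext)


def toroidal_distance(a, b, extent) -> float:
    """Euclidean distance under the minimum-image convention."""
    d = toroidal_delta(a, b, extent)
    out = np.hypot(d[..., 0], d[..., 1])
    return float(out) if np.ndim(out) == 0 else out


def site_centre(row: int, col: int, cell_diameter: float) -> np.ndarray:
    """Continuous (x, y) coordinates of a lattice-site centre."""
    return np.array([(col + 0.5) * cell_diameter, (row + 0.5) * cell_diameter])


def coarse_grain(position) -> np.ndarray:
    """Round a continuous position to the 1 um contact-detection grid."""
    return np.rint(np.asarray(position, dtype=float))


def cells_in_contact(position, contact_radius: float,
                     world: "TissueWorld") -> Set[Tuple[int, int]]:
    """Lattice sites whose centre lies within ``contact_radius`` of a position.

    The position is coarse-grained to 1 um before the distance tests; distances
    use the toroidal metric. Deterministic given inputs.
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be positive")
    d = world.cell_diameter
    ext = np.array([world.extent_x, world.extent_y])
    pos = coarse_grain(wrap_position(position, ext))
    # candidate band of rows/cols around the containing site
    m = int(np.ceil(contact_radius / d)) + 1
    row0 = int(pos[1] // d) % world.n_rows
    col0 = int(pos[0] // d) % world.n_cols
    out = set()
    for dr in range(-m, m + 1):
        for dc in range(-m, m + 1):
            r = (row0 + dr) % world.n_rows
            c = (col0 + dc) % world.n_cols
            if toroidal_distance(pos, site_centre(r, c, d), ext) <= contact_radius:
                out.add((r, c))
    if contact_radius >= max(ext) * np.sqrt(2) / 2:
        # saturation: every site is within reach
        return {(r, c) for r in range(world.n_rows) for c in range(world.n_cols)}
    return out


def nearest_infected(position, world: "TissueWorld"
                     ) -> Optional[Tuple[Tuple[int, int], float]]:
    """The living infected site closest (toroidal metric) to a position.

    Conjugated targets count (they are living until lysed); dead cells never.
    Ties are broken by the smallest ``(row, col)`` index. Returns ``None`` when
    no infected site exists.
    """
    rows, cols = np.nonzero(world.cell_state == INFECTED)
    if rows.size == 0:
        return None
    d = world.cell_diameter
    ext = np.array([world.extent_x, world.extent_y])
    pos = wrap_position(position, ext)
    centres = np.stack([(cols + 0.5) * d, (rows + 0.5) * d], axis=1)
    delta = centres - pos
    delta -= ext * np.round(delta / ext)
    dist = np.hypot(delta[:, 0], delta[:, 1])
    # np.nonzero scans row-major, so the first minimal entry is the
    # lexicographically smallest (row, col)
    idx = int(np.flatnonzero(dist == dist.min())[0])
    return (int(rows[idx]), int(cols[idx])), float(dist[idx])
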