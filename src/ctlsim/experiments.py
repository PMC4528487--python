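"""Scripted computational experiments at configurable scale.

These drivers reproduce the study designs behind the headline results:
ABM-vs-ODE trajectory comparisons across effector:target (E:T) and
search:handling (S:H) regimes, critical-density surfaces for diffuse vs
clustered infections at slow and fast surveillance, chemotaxis sweeps, and
the lattice return-probability plausibility computation for three
dimensions. Scale (grid, time step, replicates) comes entirely from the
supplied configuration, so the same code runs desk-scale sketches and
full-scale reproductions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import __version__
from .abm import run_simulation
from .config import SimulationConfig
from .estimation import (ExtinctionCurve, adaptive_cstar_search,
                         extinction_probability, fit_sigmoid)
from .motion import measure_surveillance_rate
from .ode import ODEParams, simple_mass_action, solve_extended_model


@dataclass
class ControlRegime:
    """Summary of one experimental cell: who wins, search or handling."""

    E_T: float       # effectors per target at CTL introduction
    S_H: float       # search time over handling time
    k: float         # surveillance rate, cells/min
    I_C: int         # infected count at CTL introduction

    @classmethod
    def build(cls, n_ctl: int, i_c: int, k: float, h_min: float, n_sites: int,
              clustered: bool = False) -> "ControlRegime":
        # diffuse: S = N/(k I0); packed cluster: S = 1/k (lower bound)
        search = 1.0 / k if clustered else n_sites / (k * i_c)
        return cls(E_T=n_ctl / i_c, S_H=search / h_min, k=k, I_C=i_c)


# ---------------------------------------------------------------------------
# trajectory comparison (ABM vs the two deterministic models)
# ---------------------------------------------------------------------------

def _mean_log_trajectory(config: SimulationConfig, n_reps: int, seed: int,
                         horizon_min: float):
    """Mean log10 infected trajectory over replicates, aligned at CTL
    introduction and truncated to the common horizon."""
    grids = []
    t_ref = None
    for i, s in enumerate(np.random.SeedSequence(seed).generate_state(n_reps)
                          % 2**31):
        res = run_simulation(config, seed=int(s))
        tc = res.post_intro()
        t = tc.time_min
        counts = tc.infected.astype(float)
        m = t <= horizon_min
        if t_ref is None:
            t_ref = t[m]
        counts = np.interp(t_ref, t, counts)
        grids.append(counts)
    arr = np.vstack(grids)
    mean_counts = arr.mean(axis=0)
    return t_ref, mean_counts


def rms_log_discrepancy(t, abm_counts, model_fraction, n_sites) -> float:
    """RMS difference of log10 counts between an ABM mean trajectory and a
    deterministic model, over samples where both are positive."""
    model_counts = np.asarray(model_fraction) * n_sites
    m = (abm_counts > 0) & (model_counts > 0)
    return float(np.sqrt(np.mean(
        (np.log10(abm_counts[m]) - np.log10(model_counts[m])) ** 2)))


def run_fig1_experiment(base_config: SimulationConfig,
                        cells: Sequence[dict],
                        n_reps: int = 10,
                        horizon_days: float = 4.0,
                        seed: int = 0) -> pd.DataFrame:
    """Compare ABM mean trajectories of diffuse infections with the simple
    and extended mass-action models over a grid of (E:T, S:H) cells.

    Each cell is a dict with keys ``label``, ``n_ctl``, and optionally
    overrides (``ctl_velocity``, ``i_c``, ...). The measured surveillance
    rate of each cell's motility parameters (same time step) parameterises
    the ODEs. Returns one row per cell with the RMS log discrepancies of both
    models against the ABM mean.
    """
    horizon = horizon_days * 1440.0
    rows = []
    k_cache: Dict[tuple, float] = {}
    for i, cell in enumerate(cells):
        cell = dict(cell)
        label = cell.pop("label", f"cell{i}")
        n_ctl = cell.pop("n_ctl")
        cfg = base_config.replace(n_ctl=n_ctl, **cell)
        key = (cfg.ctl_velocity, cfg.scan_time, cfg.timestep,
               cfg.contact_radius)
        if key not in k_cache:
            k_cache[key] = measure_surveillance_rate(
                cfg, duration_min=max(240.0, 40.0 / (cfg.ctl_velocity / 7.5)),
                n_ctl=100, seed=seed + 1000 + i).rate
        k = k_cache[key]
        t, abm_mean = _mean_log_trajectory(cfg, n_reps, seed + i, horizon)
        params = ODEParams(r=cfg.r_target, k=k, h=cfg.handling_time,
                           C0=n_ctl / cfg.n_sites, T0=cfg.i_c / cfg.n_sites,
                           N=cfg.n_sites)
        simple = simple_mass_action(params, t)
        ext = solve_extended_model(params, horizon,
                                   dtau=cfg.handling_time / 30.0)
        ext_total = np.interp(t, ext.t, ext.T_total)
        regime = ControlRegime.build(n_ctl, cfg.i_c, k, cfg.handling_time,
                                     cfg.n_sites)
        rows.append({
            "label": label, "E_T": regime.E_T, "S_H": regime.S_H, "k": k,
            "I_C": cfg.i_c, "n_ctl": n_ctl,
            "rms_simple": rms_log_discrepancy(t, abm_mean, simple,
                                              cfg.n_sites),
            "rms_extended": rms_log_discrepancy(t, abm_mean, ext_total,
                                                cfg.n_sites),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# critical-density surfaces
# ---------------------------------------------------------------------------

def estimate_relative_cstar(config: SimulationConfig, k: float,
                            n_reps: int = 50, seed: int = 0,
                            tolerance: float = 0.1,
                            fit: bool = True) -> dict:
    """Estimate C* at one configuration and express it in units of r/k.

    Runs the adaptive search seeded around the mass-action estimate, then
    (optionally) fits the sigmoid to all evaluated points. Returns a dict
    with the curve, the fit and the relative C*.
    """
    from .ode import cstar_simple

    base = cstar_simple(config.r_target, k)
    guesses = [base * f for f in (0.5, 1.0, 2.0)]
    curve = adaptive_cstar_search(config, initial_guesses=guesses,
                                  n_reps=n_reps, tolerance=tolerance,
                                  seed=seed)
    out = {"curve": curve, "cstar_massaction": base}
    if fit:
        try:
            sf = fit_sigmoid(curve)
            out["fit"] = sf
            out["cstar"] = sf.C_star
        except ValueError:
            out["fit"] = None
            props = curve.proportion
            i = int(np.argmin(np.abs(props - 0.5)))
            out["cstar"] = float(curve.C[i])
    out["relative_cstar"] = out.get("cstar", np.nan) / base
    return out


def run_extinction_experiment(base_config: SimulationConfig,
                              i_c_list: Sequence[int],
                              mode_list: Sequence[str] = ("diffuse",
                                                          "clustered"),
                              n_reps: int = 50,
                              seed: int = 0,
                              k: Optional[float] = None) -> pd.DataFrame:
    """Relative C* per (infection mode, I_C): the Fig 2-style surface.

    ``k`` defaults to the measured surveillance rate of the configuration's
    motility parameters.
    """
    if k is None:
        k = measure_surveillance_rate(base_config, seed=seed + 999).rate
    rows = []
    for mode in mode_list:
        for j, i_c in enumerate(i_c_list):
            cfg = base_config.replace(infection_mode=mode, i_c=int(i_c))
            est = estimate_relative_cstar(cfg, k, n_reps=n_reps,
                                          seed=seed + 100 * j)
            regime = ControlRegime.build(
                max(1, int(round(est["cstar"] * cfg.n_sites))), int(i_c), k,
                cfg.handling_time, cfg.n_sites, clustered=mode == "clustered")
            rows.append({"mode": mode, "I_C": int(i_c), "k": k,
                         "S_H": regime.S_H,
                         "cstar": est["cstar"],
                         "relative_cstar": est["relative_cstar"],
                         "alpha": (est["fit"].alpha if est.get("fit")
                                   else np.nan)})
    return pd.DataFrame(rows)


def run_chemotaxis_experiment(base_config: SimulationConfig,
                              chemotaxis_levels: Sequence[float] = (
                                  0.0, 0.01, 0.05, 0.20),
                              i_c_list: Sequence[int] = (1000,),
                              mode_list: Sequence[str] = ("diffuse",
                                                          "clustered"),
                              n_reps: int = 50,
                              seed: int = 0,
                              k: Optional[float] = None) -> pd.DataFrame:
    """Relative C* per (chemotaxis level, mode, I_C): the Fig 3-style
    surface. Chemotaxis leaves the surveillance rate k unchanged (it only
    redirects turns), so the r/k normalisation is shared across levels."""
    if k is None:
        k = measure_surveillance_rate(base_config, seed=seed + 999).rate
    frames = []
    for lvl in chemotaxis_levels:
        cfg = base_config.replace(chemotaxis_prob=float(lvl))
        df = run_extinction_experiment(cfg, i_c_list, mode_list,
                                       n_reps=n_reps, seed=seed, k=k)
        df.insert(0, "chemotaxis", float(lvl))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# lattice return probability (drunkard's walk plausibility check)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _polya_kernel(seed, dim, n_walks, max_steps):
    np.random.seed(seed)
    returned = 0
    for _ in range(n_walks):
        x = 0
        y = 0
        z = 0
        for _s in range(max_steps):
            move = np.random.randint(0, 2 * dim)
            axis = move >> 1
            delta = 1 if (move & 1) == 1 else -1
            if axis == 0:
                x += delta
            elif axis == 1:
                y += delta
            else:
                z += delta
            if x == 0 and y == 0 and z == 0:
                returned += 1
                break
    return returned


def lattice_return_probability(dimension: int, n_walks: int = 100_000,
                               max_steps: int = 10_000,
                               seed: int = 0) -> float:
    """Fraction of simple symmetric lattice walks returning to the origin
    within ``max_steps`` — a lower bound on the eventual-return (Polya)
    probability, which is 1 in two dimensions and ~0.34 in three.
    """
    if dimension not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    if n_walks < 1_000 or max_steps < 1:
        raise ValueError("need n_walks >= 1000 and max_steps >= 1")
    returned = _polya_kernel(seed % 2**31, dimension, n_walks, max_steps)
    return returned / n_walks


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_bundle(config: SimulationConfig, seed: int,
                      extra: Optional[dict] = None) -> dict:
    """Everything needed to regenerate an experiment bit-identically."""
    out = {
        "ctlsim_version": __version__,
        "python": platform.python_version(),
        "seed": int(seed),
        "config": config.to_dict(),
    }
    if extra:
        out.update(extra)
    return out


def write_provenance(path, config: SimulationConfig, seed: int,
                     extra: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        json.dump(provenance_bundle(config, seed, extra), fh, indent=2)
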