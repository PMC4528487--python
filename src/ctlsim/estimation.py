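"""Stochastic critical-density estimation.

The critical CTL density C* is defined stochastically as the density (a
fraction of all scannable cells) at which half of simulated infections go
extinct. Runs are classified extinct/established, extinction probabilities
estimated from replicate proportions, the 50% crossing located by an
adaptive bisection on the density, and the full (density, proportion) curve
summarised by a two-parameter sigmoid fitted with Nelder-Mead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.stats.proportion import proportion_confint

from .config import SimulationConfig

EXTINCT = "extinct"
ESTABLISHED = "established"


def classify_outcome(timecourse, t_intro_min: float = 0.0,
                     window_h: float = 12.0) -> str:
    """Classify a finished run as 'extinct' or 'established'.

    An infected count of zero at the end means extinction. Otherwise the
    outcome is read off the OLS gradient of the infected count over the final
    ``window_h`` hours: negative implies eventual extinction, positive (or
    flat) a successful infection. Courses shorter than the window are
    classified on the full course, with a warning.
    """
    t = timecourse.time_min
    counts = timecourse.infected
    if len(t) == 0:
        raise ValueError("empty time course")
    if counts[-1] == 0:
        return EXTINCT
    t_end = t[-1]
    window = window_h * 60.0
    if t_end - max(t_intro_min, t[0]) < window:
        warnings.warn("time course shorter than the classification window; "
                      "classifying on the full course")
        m = np.ones(len(t), dtype=bool)
    else:
        m = t >= t_end - window
    if m.sum() < 2:
        m = np.ones(len(t), dtype=bool)
    slope = np.polyfit(t[m], counts[m].astype(float), 1)[0]
    return EXTINCT if slope < 0 else ESTABLISHED


# ---------------------------------------------------------------------------
# extinction curves
# ---------------------------------------------------------------------------

@dataclass
class ExtinctionCurve:
    """(CTL density, extinction proportion) samples with replicate counts."""

    C: np.ndarray
    n_reps: np.ndarray
    n_extinct: np.ndarray
    seeds: List[int] = field(default_factory=list)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        self.n_extinct = np.asarray(self.n_extinct, dtype=int)
        if np.any(self.n_extinct > self.n_reps) or np.any(self.n_extinct < 0):
            raise ValueError("need 0 <= n_extinct <= n_reps")
        order = np.argsort(self.C)
        self.C = self.C[order]
        self.n_reps = self.n_reps[order]
        self.n_extinct = self.n_extinct[order]
        if np.any(np.diff(self.C) <= 0):
            raise ValueError("C values must be distinct")

    @property
    def proportion(self) -> np.ndarray:
        return self.n_extinct / self.n_reps

    def wilson_ci(self, alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
        lo, hi = proportion_confint(self.n_extinct, self.n_reps, alpha=alpha,
                                    method="wilson")
        return np.asarray(lo), np.asarray(hi)

    @classmethod
    def from_points(cls, points: Sequence[Tuple[float, int, int]],
                    seeds: Optional[List[int]] = None) -> "ExtinctionCurve":
        """Build from (C, n_reps, n_extinct) tuples, merging duplicate C."""
        agg = {}
        for c, n, x in points:
            n0, x0 = agg.get(c, (0, 0))
            agg[c] = (n0 + n, x0 + x)
        cs = sorted(agg)
        return cls(C=np.array(cs),
                   n_reps=np.array([agg[c][0] for c in cs]),
                   n_extinct=np.array([agg[c][1] for c in cs]),
                   seeds=seeds or [])

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.wilson_ci()
        return pd.DataFrame({
            "C": self.C, "n_reps": self.n_reps, "n_extinct": self.n_extinct,
            "proportion": self.proportion, "ci_lo": lo, "ci_hi": hi})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extinction_probability(config: SimulationConfig, C: float, n_reps: int,
                           seed: int = 0
                           ) -> Tuple[float, Tuple[float, float]]:
    """Proportion of ``n_reps`` independent runs at CTL density ``C``
    (fraction of all cells) that go extinct, with a Wilson 95% interval."""
    from .abm import run_simulation

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_ctl = max(0, int(round(C * config.n_sites)))
    cfg = config.replace(n_ctl=n_ctl)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % 2**31
    n_ext = sum(run_simulation(cfg, seed=int(s)).outcome == EXTINCT
                for s in seeds)
    lo, hi = proportion_confint(n_ext, n_reps, method="wilson")
    return n_ext / n_reps, (float(lo), float(hi))


def adaptive_cstar_search(config: Optional[SimulationConfig] = None,
                          initial_guesses: Sequence[float] = (),
                          n_reps: int = 200,
                          tolerance: float = 0.05,
                          seed: int = 0,
                          prob_fn: Optional[Callable[[float],
                                                     Tuple[int, int]]] = None,
                          max_iter: int = 40) -> ExtinctionCurve:
    """Bracket C* by adaptive bisection on the extinction proportion.

    Starting from broadly spaced guesses, the bracketing interval around the
    50% crossing is bisected on the proportion point estimate until its width
    falls below ``tolerance`` times its midpoint; every evaluated
    (C, proportion) point is retained for the subsequent sigmoid fit. Ties at
    exactly 0.5 continue toward the smaller C. Guesses that do not bracket
    are widened geometrically, up to the [0, 1] density range.

    ``prob_fn(C) -> (n_reps, n_extinct)`` substitutes a synthetic oracle for
    the simulator (used in tests and by the experiment drivers for caching).
    """
    if prob_fn is None:
        if config is None:
            raise ValueError("need a config when no prob_fn is given")

        eval_counter = [0]

        def prob_fn(C):
            eval_counter[0] += 1
            p, _ = extinction_probability(config, C, n_reps,
                                          seed=seed + 7919 * eval_counter[0])
            return n_reps, int(round(p * n_reps))

    guesses = sorted(set(float(g) for g in initial_guesses))
    if not guesses:
        raise ValueError("need at least one initial guess")
    points: List[Tuple[float, int, int]] = []

    def evaluate(C):
        n, x = prob_fn(C)
        points.append((C, n, x))
        return x / n

    props = {g: evaluate(g) for g in guesses}
    lo = max((c for c, p in props.items() if p < 0.5), default=None)
    hi = min((c for c, p in props.items() if p >= 0.5), default=None)
    # widen until the interval brackets the 50% crossing
    width_iter = 0
    while lo is None or hi is None:
        width_iter += 1
        if width_iter > 20:
            raise RuntimeError("could not bracket the 50% crossing in [0, 1]")
        if lo is None:
            c = min(props) / 2.0
            if c < 1e-9:
                raise RuntimeError("extinction proportion >= 0.5 even as "
                                   "C -> 0")
            props[c] = evaluate(c)
            if props[c] < 0.5:
                lo = c
        else:
            c = min(1.0, max(props) * 2.0)
            props[c] = evaluate(c)
            if props[c] >= 0.5:
                hi = c
            elif c >= 1.0:
                raise RuntimeError("extinction proportion < 0.5 even at C=1")
    for _ in range(max_iter):
        if hi - lo < tolerance * 0.5 * (hi + lo):
            break
        mid = 0.5 * (lo + hi)
        p = evaluate(mid)
        if p >= 0.5:
            hi = mid
        else:
            lo = mid
    return ExtinctionCurve.from_points(points)


# ---------------------------------------------------------------------------
# sigmoid fit
# ---------------------------------------------------------------------------

def sigmoid(C, C_star: float, alpha: float):
    """Hill-type extinction-probability curve
    ``p(C) = C^alpha / (C^alpha + C*^alpha)``: zero at C=0, 1/2 at C=C*,
    saturating at one, strictly increasing, steepness alpha."""
    if C_star <= 0 or alpha <= 0:
        raise ValueError("C_star and alpha must be positive")
    C = np.asarray(C, dtype=float)
    with np.errstate(divide="ignore"):
        logratio = alpha * (np.log(np.maximum(C, 1e-300)) - np.log(C_star))
    out = 1.0 / (1.0 + np.exp(-logratio))
    out = np.where(C <= 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class SigmoidFit:
    """Fitted sigmoid: C* (50% extinction density) and steepness alpha."""

    C_star: float
    alpha: float
    objective: float
    converged: bool
    n_starts: int = 3

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"C_star": self.C_star, "alpha": self.alpha,
                       "objective": self.objective,
                       "converged": self.converged}, fh, indent=2)


def fit_sigmoid(curve: ExtinctionCurve, n_starts: int = 3,
                loss: str = "wls") -> SigmoidFit:
    """Fit (C*, alpha) to an extinction curve by Nelder-Mead.

    Default loss is least squares on the proportions weighted by the
    replicate counts; ``loss='binomial'`` uses the negative binomial
    log-likelihood instead. Optimisation runs in log-parameter space from
    ``n_starts`` starting points (steepness 2, 8 and 32 around the
    interpolated 50% crossing); the best objective wins.
    """
    C = curve.C
    p_obs = curve.proportion
    w = curve.n_reps.astype(float)
    if len(C) < 3:
        raise ValueError("need at least 3 distinct densities")
    if p_obs.max() < 0.5 or p_obs.min() > 0.5:
        warnings.warn("extinction proportions do not span 0.5; C* is an "
                      "extrapolation")

    def objective(theta):
        c_star, alpha = np.exp(theta)
        p = sigmoid(C, c_star, alpha)
        if loss == "binomial":
            eps = 1e-9
            p = np.clip(p, eps, 1 - eps)
            return -np.sum(w * (p_obs * np.log(p)
                                + (1 - p_obs) * np.log(1 - p)))
        return np.sum(w * (p_obs - p) ** 2)

    # initial C*: interpolated 50% crossing, else the median density
    cross = np.nonzero(np.diff(p_obs >= 0.5))[0]
    if cross.size:
        i = cross[0]
        f = (0.5 - p_obs[i]) / max(p_obs[i + 1] - p_obs[i], 1e-9)
        c0 = C[i] + f * (C[i + 1] - C[i])
    else:
        c0 = float(np.median(C))
    c0 = max(c0, 1e-12)

    best = None
    any_converged = False
    for alpha0 in (2.0, 8.0, 32.0)[:n_starts]:
        res = minimize(objective, x0=np.log([c0, alpha0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        any_converged |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn("Nelder-Mead did not converge from any start; "
                      "returning the best point found")
    c_star, alpha = np.exp(best.x)
    return SigmoidFit(C_star=float(c_star), alpha=float(alpha),
                      objective=float(best.fun), converged=any_converged,
                      n_starts=n_starts)
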