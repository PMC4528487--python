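"""Extinction probability vs CTL density, and the fitted C*.

Sweeps CTL density around the mass-action estimate r/k for a diffuse,
slow-CTL infection, estimates the extinction proportion at each density
(20 replicates here; use more for smooth curves), and fits the
two-parameter sigmoid whose midpoint is the critical density C*.
"""

from ctlsim import (ExtinctionCurve, SimulationConfig, cstar_simple,
                    extinction_probability, fit_sigmoid)

k_measured = 0.0298  # cells/min for this preset (see example 03)
base = cstar_simple(1.0, k_measured)
cfg = SimulationConfig(n_rows=64, n_cols=64, timestep=10.0,
                       ctl_velocity=0.18, i_c=41, t_max=15.0)

points = []
for i, f in enumerate((0.8, 1.0, 1.2, 1.5)):
    prop, ci = extinction_probability(cfg, f * base, n_reps=20, seed=50 + i)
    points.append((f * base, 20, round(prop * 20)))
    print(f"C = {f:.1f} r/k ({round(f * base * cfg.n_sites):3d} CTL): "
          f"extinct {prop:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f})")

fit = fit_sigmoid(ExtinctionCurve.from_points(points))
print(f"\nfitted C* = {fit.C_star:.4f} = {fit.C_star / base:.2f} r/k, "
      f"steepness alpha = {fit.alpha:.1f}")
print("A relative C* near 1 reproduces the key result: with slow CTL "
      "(search-limited killing) mass action predicts the critical density "
      "even for a fully stochastic, spatial infection.")
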