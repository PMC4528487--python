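"""Search time vs handling time: when does mass action break down?

Computes expected CTL search times 1/(k I) across infected-cell densities
and compares the critical CTL density C* of the simple mass-action model
(r/k) with the age-structured conjugate model that accounts for the 30 min
handling time.
"""

from ctlsim import ODEParams, cstar_extended, cstar_simple, expected_search_time

K_FAST = 0.7   # cells/min, in line with in vivo killing assays
K_SLOW = 0.02  # cells/min, inefficient or exhausted CTL
H = 30.0       # min handling time
N = 100_000

print("Expected search times 1/(k I) at k = 0.7 cells/min:")
for count in (1000, 2000, 4000):
    s = expected_search_time(K_FAST, count / N)
    print(f"  {count:5d} infected of {N}: {s:6.1f} min "
          f"(S:H = {s / H:.1f})")
print(f"Within a packed cluster at k = {K_SLOW}: "
      f"{expected_search_time(K_SLOW, 1.0):.0f} min vs {H:.0f} min handling")

print("\nCritical CTL density (fraction of surveyable cells):")
for k in (K_SLOW, K_FAST):
    for t0 in (0.01, 0.04):
        simple = cstar_simple(1.0, k)
        ext = cstar_extended(ODEParams(r=1.0, k=k, h=H, T0=t0))
        print(f"  k={k:5.2f}, I0={t0:.2f}: r/k = {simple:.3e}, "
              f"with handling = {ext:.3e} ({ext / simple:.2f}x)")

print("\nHandling time inflates C* only once k I h approaches 1: slow CTL "
      "never notice it; fast CTL against dense infections need "
      "substantially more than r/k.")
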