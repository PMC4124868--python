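"""Brownian-dynamics rupture ensemble versus the analytic distribution.

Simulates 2000 pull-to-rupture trajectories at 1e6 pN/s with the
Euler--Maruyama integrator (Brownian-bridge crossing detection) and compares
the empirical force histogram with the truncated closed-form density via
moments and a Kolmogorov--Smirnov distance.
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid

from rapidfs import (
    BondModel,
    LoadingProtocol,
    SimulationConfig,
    evaluate_theory,
    simulate_ruptures,
    summarize,
    truncate,
)

model = BondModel.from_kT(10.0, 1.0, 1000.0)
rate = 1e6
protocol = LoadingProtocol.field(rate)

dataset = simulate_ruptures(
    model, protocol, SimulationConfig(n=2000, seed=1)
)
stats = summarize(dataset).iloc[0]
print(f"simulated {stats['n']} ruptures at {rate:.0e} pN/s "
      f"(dt = {dataset.provenance['dt_s']:.2e} s)")
print(f"empirical mean {stats['mean_force_pN']:.2f} "
      f"+/- {stats['sem_force_pN']:.2f} pN, "
      f"std {stats['std_force_pN']:.2f} pN")

ev = truncate(evaluate_theory(model, protocol, n_grid=3000))
cdf = cumulative_trapezoid(ev.pdf, ev.force, initial=0.0)
cdf /= cdf[-1]
theory_mean = np.trapezoid(ev.force * ev.pdf, ev.force)
forces = np.sort(dataset.forces)
emp = np.searchsorted(forces, ev.force, side="right") / len(forces)
ks = np.max(np.abs(cdf - emp))
print(f"theory mean {theory_mean:.2f} pN, KS distance {ks:.3f}")
print("\nA KS distance of a few percent at n = 2000 means the analytic")
print("distribution tracks the exact bond dynamics closely at this rate.")
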