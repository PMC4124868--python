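"""Evaluate the closed-form rupture-force distribution across loading regimes.

Builds the reference bond (10 k_B T barrier, x_b = 1 nm, D = 1000 nm^2/s at
300 K) and tabulates the truncated rupture-force density at a slow, an
intermediate and a fast loading rate, printing the mode, mean and, where it
exists, the truncation point that removes the spurious tail of the
first-order theory.
"""

import numpy as np

from rapidfs import (
    BondModel,
    LoadingProtocol,
    evaluate_theory,
    mean_force_numeric,
    truncate,
)

model = BondModel.from_kT(10.0, 1.0, 1000.0)
print(f"bond: barrier {model.barrier_kT:.0f} kT, critical force "
      f"{model.critical_force:.1f} pN, relaxation time {model.tau_r:.2e} s\n")

for rate in (1e3, 1e5, 1e9):
    protocol = LoadingProtocol.field(rate)
    ev = truncate(evaluate_theory(model, protocol, n_grid=2000))
    mode = ev.force[np.argmax(ev.pdf)]
    mean = mean_force_numeric(model, protocol).mean
    line = (f"rate {rate:8.0e} pN/s: mode {mode:8.2f} pN, "
            f"mean {mean:8.2f} pN")
    if ev.truncated:
        line += (f", truncated at {ev.f_trunc:.1f} pN "
                 f"(removed mass {1 - ev.norm_const:.1%})")
    print(line)

print("\nThe mode and mean grow ~ sqrt(rate) once loading outruns the")
print("barrier (ballistic regime); the finite truncation point near")
print("1e5 pN/s marks the narrow window where the first-order theory")
print("develops an unphysical zero crossing.")
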