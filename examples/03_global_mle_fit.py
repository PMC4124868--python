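"""Recover bond parameters from multi-rate rupture data by global MLE.

Simulates 300 ruptures per decade of loading rate over 1e3..1e8 pN/s at a
known ground truth, then fits (barrier height, barrier position,
diffusivity) with a single likelihood across all rates — the protocol that
makes the three parameters jointly identifiable.  Takes about a minute.
"""

from rapidfs import (
    BondModel,
    LoadingProtocol,
    SimulationConfig,
    fit_mle,
    simulate_ruptures,
)

truth = BondModel.from_kT(10.0, 1.0, 1000.0)
print("ground truth: 10.000 kT, 1.0000 nm, 1000.0 nm^2/s")

dataset = None
for i, exponent in enumerate(range(3, 9)):
    part = simulate_ruptures(
        truth,
        LoadingProtocol.field(10.0 ** exponent),
        SimulationConfig(n=300, seed=700 + i),
    )
    dataset = part if dataset is None else dataset.merged(part)

result = fit_mle(dataset, n_restarts=4, seed=9)
print(f"global MLE fit of {result.n_events} events:")
print(f"  barrier height  {result.barrier_kT:7.3f} kT")
print(f"  barrier position {result.barrier_position:6.4f} nm")
print(f"  diffusivity     {result.diffusivity:7.1f} nm^2/s")
print(f"  log-likelihood  {result.log_likelihood:.1f}")
if result.breakdown_rates:
    print(f"  rates inside the theory's breakdown window: "
          f"{[f'{r:.0e}' for r in result.breakdown_rates]}")
print("\nEstimates within a few percent of truth are typical at this")
print("sample size; low rates pin the energetics (barrier, x_b), high")
print("rates pin the diffusivity.")
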