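"""Physical constants and the package-wide unit system.

All quantities are expressed in piconewtons (pN), nanometres (nm), seconds
(s) and kelvin (K).  Energies therefore carry units of pN nm
(1 pN nm = 1e-21 J), which matches the numbers typically printed in
single-molecule force-spectroscopy work.
"""

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM: float = 0.0138065


def thermal_energy(temperature: float) -> float:
    """Thermal energy k_B T in pN nm at ``temperature`` (K)."""
    return BOLTZMANN_PN_NM * temperature
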