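"""Dudko--Hummer--Szabo (nu = 1/2) reference rate and distribution.

The established cusp-potential force-spectroscopy result for quasi-adiabatic
loading, kept as an independent low-rate comparator for the unified theory:

    k(F) = k0 (1 - F/F_c) exp{ (beta dG / chi) [1 - (1 - F/F_c)^2] },

valid for F < F_c and with k0 the chi-dependent Kramers rate.  For a linear
ramp the survival integrates in closed form, giving the reference density

    p(F) = k(F)/Edot * exp{ -chi k0/(beta x_b Edot) [e^{(beta dG/chi)(1-w^2)} - 1] },

w = 1 - F/F_c.  chi = 1 covers the external-field case; chi < 1 is the
spring variant.  The rate diverges from reality above the critical force,
where the quasi-adiabatic assumption collapses; evaluation there is a
domain error.
"""

from __future__ import annotations

import math

import numpy as np

from .model import BondModel, kramers_rate_k0

__all__ = ["dhs_rate", "dhs_pdf"]


def _check_domain(force, fc):
    if np.any(np.asarray(force) >= fc):
        raise ValueError(
            f"DHS rate undefined at or above the critical force {fc:.6g} pN"
        )
    if np.any(np.asarray(force) < 0):
        raise ValueError("force must be non-negative")


def dhs_rate(force, model: BondModel, chi: float = 1.0):
    """Quasi-adiabatic escape rate (1/s) for F < F_c."""
    fc = model.critical_force
    _check_domain(force, fc)
    force = np.asarray(force, dtype=float)
    w = 1.0 - force / fc
    a = model.barrier_kT / chi
    k0 = kramers_rate_k0(model, chi)
    out = k0 * w * np.exp(a * (1.0 - w * w))
    return float(out) if out.ndim == 0 else out


def dhs_pdf(force, model: BondModel, rate: float, chi: float = 1.0):
    """Reference rupture-force density (1/pN) for a linear ramp, F < F_c.

    Sub-normalized over [0, F_c): the small probability of surviving to the
    critical force is unassigned, as in the original quasi-adiabatic theory.
    """
    if rate <= 0:
        raise ValueError("loading rate must be positive")
    fc = model.critical_force
    _check_domain(force, fc)
    force = np.asarray(force, dtype=float)
    w = 1.0 - force / fc
    a = model.barrier_kT / chi
    k0 = kramers_rate_k0(model, chi)
    coeff = chi * k0 / (model.beta * model.barrier_position * rate)
    surv = np.exp(-coeff * (np.exp(a * (1.0 - w * w)) - 1.0))
    out = dhs_rate(force, model, chi) / rate * surv
    return float(out) if np.ndim(out) == 0 else out
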