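"""Rupture-force distributions, truncation, mean forces and transducer mapping.

For a monotone loading protocol the measured rupture-force density is

    p(F) = k(F) / Fdot(F) * S(F),      S(F) = exp(-int_0^F k / Fdot dF'),

with k the unified escape rate of :mod:`rapidfs.model`.  For linear ramps
(external field or constant-speed spring) the survival integral admits a
closed form: writing u(F) = (x_b - xbar(F)) / s(F) for the scaled distance
of the Gaussian mean to the barrier,

    S(F) = Phi(u) / Phi(u0) * exp(-c_J [phi(u) - phi(u0)]),
    c_J  = kappa_m sigma0 / (chi**(3/2) tau_r Edot),

where Phi/phi are the standard normal CDF/PDF.  The Phi factor is the exact
survival of the boundary-free Gaussian (dominant in the ballistic
high-rate regime); the exponential factor integrates the doubled diffusive
flux in the quasi-adiabatic low-rate regime, where it reproduces the
Dudko--Hummer--Szabo (nu = 1/2) result exactly.  At intermediate rates the
rate k changes sign beyond the point where the Gaussian mean overtakes the
barrier; the spurious tail is removed by truncating p at its first zero
crossing and renormalizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy import special
from scipy.integrate import cumulative_trapezoid, quad
from scipy.optimize import brentq
from scipy.stats import norm

from .model import (
    BondModel,
    InitialCondition,
    InvalidProtocolError,
    LoadingProtocol,
    chi_factor,
    escape_rate,
    kramers_rate_k0,
    mean_path,
    gaussian_variance,
)

__all__ = [
    "TheoryEvaluation",
    "MeanForceResult",
    "pdf_linear_field",
    "pdf_general",
    "survival_linear",
    "evaluate_theory",
    "truncate",
    "truncation_force",
    "mean_force_numeric",
    "mean_force_asymptotic",
    "transducer_force_map",
    "transducer_force_slow",
    "transducer_mean_position",
]

#: Residual survival below which a formal zero crossing of p(F) lies beyond
#: the support of the distribution and is not treated as a real truncation.
TRUNCATION_SURVIVAL_FLOOR = 1e-12

#: Truncated probability mass above which a fit at this loading rate is
#: flagged as lying in the breakdown window of the first-order theory.
BREAKDOWN_MASS = 0.01


def _require_linear(protocol: LoadingProtocol) -> None:
    if not protocol.is_linear:
        raise InvalidProtocolError("closed form requires a linear force ramp")
    if protocol.nominal_rate <= 0:
        raise InvalidProtocolError("closed form requires a positive loading rate")


def survival_linear(
    force,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
):
    """Closed-form survival S(F) for a linear ramp (field or spring)."""
    _require_linear(protocol)
    force = np.asarray(force, dtype=float)
    t = force / protocol.nominal_rate
    chi = chi_factor(model, protocol)
    m = mean_path(t, model, protocol, init)
    s = np.sqrt(gaussian_variance(t, model, protocol, init))
    m0, v0 = init.moments(model)
    s_init = math.sqrt(v0) if v0 > 0 else 0.0
    xb = model.barrier_position
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(s > 0, (xb - m) / s, np.inf)
    cdf0 = norm.cdf((xb - m0) / s_init) if s_init > 0 else 1.0
    # The diffusive-leakage integral is a quasi-adiabatic object: it is
    # referenced to the stationary width, so that initial-state memory
    # (which the Phi factor handles exactly) does not enter it twice.
    s_inf = math.sqrt(chi) * model.sigma0
    phi_ref = norm.pdf((xb - m0) / s_inf)
    c_j = model.kappa_m * model.sigma0 / (
        chi ** 1.5 * model.tau_r * protocol.nominal_rate
    )
    leak = np.maximum(c_j * (norm.pdf(u) - phi_ref), 0.0)
    out = norm.cdf(u) / cdf0 * np.exp(-leak)
    return float(out) if out.ndim == 0 else out


def pdf_linear_field(
    force,
    model: BondModel,
    rate: float,
    mu: float = 1.0,
):
    """Closed-form rupture-force density (1/pN) for a linear external field.

    This is the chi = 1 branch of the theory: F(t) = rate * t applied
    directly to the bond (external field or soft spring).  ``mu`` rescales
    the initial Boltzmann variance relative to the cusp-well equilibrium
    value.  The density is consistent with the unified escape rate through
    p(F) = k(F) S(F) / rate and may turn negative beyond its first zero
    crossing; see :func:`truncate`.
    """
    if rate <= 0:
        raise InvalidProtocolError("rate must be positive")
    protocol = LoadingProtocol.field(rate)
    init = InitialCondition.boltzmann(mu=mu)
    force = np.asarray(force, dtype=float)
    k = escape_rate(model, protocol, force=force, init=init)
    s = survival_linear(force, model, protocol, init)
    with np.errstate(invalid="ignore"):
        out = k * s / rate
    return float(out) if np.ndim(out) == 0 else out


def pdf_general(
    force,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
):
    """Rupture-force density for a general monotone protocol.

    Linear ramps (field and spring mode) use the closed-form survival and
    are bit-identical to :func:`pdf_linear_field` in field mode with a
    Boltzmann start.  Arbitrary schedules integrate the unified rate
    numerically, S(t) = exp(-int_0^t k dt').
    """
    force = np.asarray(force, dtype=float)
    if protocol.is_linear:
        _require_linear(protocol)
        k = escape_rate(model, protocol, force=force, init=init)
        s = survival_linear(force, model, protocol, init)
        with np.errstate(invalid="ignore"):
            out = k * s / protocol.nominal_rate
        return float(out) if np.ndim(out) == 0 else out

    def _one(f):
        if f <= 0:
            f = 0.0
        t_f = float(protocol.time_of_force(f))
        k_f = escape_rate(model, protocol, t=t_f, init=init)
        integral, _ = quad(
            lambda s_: escape_rate(model, protocol, t=s_, init=init),
            0.0,
            t_f,
            limit=400,
        )
        fdot = float(protocol.rate_of_time(t_f))
        if fdot <= 0:
            raise InvalidProtocolError("force schedule must be strictly increasing")
        return k_f / fdot * math.exp(-integral)

    out = np.vectorize(_one)(force)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def truncation_force(
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
    survival_floor: float = TRUNCATION_SURVIVAL_FLOOR,
) -> float:
    """First zero crossing of p(F) beyond its mode, or +inf.

    For linear ramps the sign of p equals the sign of the rate factor
    f(t) + kappa_s x_b - 2 kappa_s xbar(t), whose root is bracketed and
    bisected directly.  A formal crossing at which the closed-form survival
    has already decayed below ``survival_floor`` lies outside the support
    of the distribution and is reported as +inf.
    """
    _require_linear(protocol)
    ks = protocol.total_stiffness(model)
    xb = model.barrier_position
    rate = protocol.nominal_rate

    def bracket(force):
        # sign of j*: drift A(x_b,t) plus doubled diffusive term
        t = force / rate
        m = mean_path(t, model, protocol, init)
        v = gaussian_variance(t, model, protocol, init)
        a = (protocol.drive(t) - ks * xb) / model.gamma
        return a + 2.0 * model.diffusivity * (xb - m) / v

    f_hi = max(10.0 * model.critical_force, 1e4 * rate * model.tau_r, 1.0)
    while bracket(f_hi) > 0:
        f_hi *= 4.0
        if f_hi > 1e300:
            return math.inf
    f_zero = brentq(bracket, 1e-300, f_hi, xtol=1e-10)
    if survival_linear(f_zero, model, protocol, init) <= survival_floor:
        return math.inf
    return float(f_zero)


@dataclass
class TheoryEvaluation:
    """Theory curves p(F), S(F), k(F) on a force grid, with truncation state."""

    force: np.ndarray          # pN, strictly increasing
    pdf: np.ndarray            # 1/pN (renormalized if truncated)
    survival: np.ndarray
    rate: np.ndarray           # 1/s
    f_trunc: float = math.inf  # pN
    norm_const: float = 1.0    # integral of the raw pdf up to f_trunc
    truncated: bool = False
    breakdown: bool = False    # truncated mass exceeds BREAKDOWN_MASS
    model: Optional[BondModel] = None
    protocol: Optional[LoadingProtocol] = None
    init: Optional[InitialCondition] = None
    pdf_callable: Optional[Callable[[np.ndarray], np.ndarray]] = dc_field(
        default=None, repr=False
    )

    def to_table(self):
        """Export (force, pdf, survival, rate) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "force_pN": self.force,
                "pdf_per_pN": self.pdf,
                "survival": self.survival,
                "rate_per_s": self.rate,
            }
        )


def evaluate_theory(
    model: BondModel,
    protocol: LoadingProtocol,
    force_grid=None,
    init: InitialCondition = InitialCondition.boltzmann(),
    n_grid: int = 1024,
) -> TheoryEvaluation:
    """Evaluate p, S and k on a force grid (auto-sized if not given)."""
    if force_grid is None:
        f_hi = force_support(model, protocol, init)
        force_grid = np.linspace(0.0, f_hi, n_grid)
    force_grid = np.asarray(force_grid, dtype=float)
    if np.any(np.diff(force_grid) <= 0):
        raise ValueError("force grid must be strictly increasing")
    pdf_fn = lambda f: pdf_general(f, model, protocol, init)
    p = np.atleast_1d(pdf_fn(force_grid))
    if protocol.is_linear:
        s = np.atleast_1d(survival_linear(force_grid, model, protocol, init))
    else:
        s = 1.0 - cumulative_trapezoid(p, force_grid, initial=0.0)
    k = np.atleast_1d(escape_rate(model, protocol, force=force_grid, init=init))
    return TheoryEvaluation(
        force=force_grid, pdf=p, survival=s, rate=k,
        model=model, protocol=protocol, init=init, pdf_callable=pdf_fn,
    )


def force_support(
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
    tail: float = 1e-10,
) -> float:
    """Upper force at which the survival has decayed to ``tail``."""
    _require_linear(protocol)
    f_t = truncation_force(model, protocol, init)
    if math.isfinite(f_t):
        return f_t
    rate = protocol.nominal_rate
    f_hi = max(
        model.critical_force,
        6.0 * math.sqrt(2.0 * model.gamma * rate * model.barrier_position),
        1e-6,
    )
    while survival_linear(f_hi, model, protocol, init) > tail:
        f_hi *= 2.0
        if f_hi > 1e300:  # pragma: no cover - unreachable for sane input
            raise RuntimeError("survival does not decay")
    lo_candidates = f_hi / 2.0
    return brentq(
        lambda f: survival_linear(f, model, protocol, init) - tail,
        lo_candidates * 1e-12, f_hi, xtol=1e-12, rtol=1e-12,
    )


def _renormalization(eval_: TheoryEvaluation, f_hi: float) -> float:
    """Integral of the raw pdf over [0, f_hi] by Gauss-Legendre quadrature."""
    x, w = np.polynomial.legendre.leggauss(512)
    f = 0.5 * f_hi * (x + 1.0)
    p = np.clip(np.atleast_1d(eval_.pdf_callable(f)), 0.0, None)
    return float(np.sum(0.5 * f_hi * w * p))


def truncate(eval_: TheoryEvaluation) -> TheoryEvaluation:
    """Truncate p(F) at its first zero crossing beyond the mode and renormalize.

    Returns a new :class:`TheoryEvaluation` with p set to zero beyond the
    truncation force and rescaled so that it integrates to one; if the
    distribution has no zero crossing within its support the evaluation is
    returned unchanged (f_trunc = +inf, norm_const = 1).
    """
    p = eval_.pdf
    i_mode = int(np.argmax(p))
    if i_mode == len(p) - 1 and p[i_mode] > 0:
        raise ValueError("force grid does not extend beyond the mode of p(F)")
    if eval_.protocol is not None and eval_.protocol.is_linear:
        f_t = truncation_force(eval_.model, eval_.protocol, eval_.init)
    else:  # grid-based detection for non-linear protocols
        neg = np.flatnonzero(p[i_mode:] < 0)
        if neg.size:
            j = i_mode + neg[0]
            f_t = brentq(eval_.pdf_callable, eval_.force[j - 1], eval_.force[j])
        else:
            f_t = math.inf
    if not math.isfinite(f_t):
        return TheoryEvaluation(
            force=eval_.force, pdf=np.clip(p, 0.0, None),
            survival=eval_.survival, rate=eval_.rate,
            f_trunc=math.inf, norm_const=1.0, truncated=False,
            breakdown=False, model=eval_.model, protocol=eval_.protocol,
            init=eval_.init, pdf_callable=eval_.pdf_callable,
        )
    z = _renormalization(eval_, f_t)
    p_new = np.where(eval_.force <= f_t, np.clip(p, 0.0, None) / z, 0.0)
    truncated_mass = max(0.0, 1.0 - z)
    return TheoryEvaluation(
        force=eval_.force, pdf=p_new, survival=eval_.survival, rate=eval_.rate,
        f_trunc=f_t, norm_const=z, truncated=True,
        breakdown=truncated_mass > BREAKDOWN_MASS,
        model=eval_.model, protocol=eval_.protocol, init=eval_.init,
        pdf_callable=eval_.pdf_callable,
    )


# ---------------------------------------------------------------------------
# mean rupture force
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanForceResult:
    """Mean rupture force with the method used and dimensionless diagnostics."""

    mean: float                 # pN
    method: str                 # numeric | asymptotic-low | asymptotic-high | asymptotic-combined
    q: float = 1.0              # exp(beta dG (1 - chi))
    x_factor: float = float("nan")  # sqrt(chi) k0 / (beta Edot x_b)


def mean_force_numeric(
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
) -> MeanForceResult:
    """First moment of the truncated, renormalized distribution (quadrature)."""
    _require_linear(protocol)
    f_hi = force_support(model, protocol, init)
    x, w = np.polynomial.legendre.leggauss(1024)
    f = 0.5 * f_hi * (x + 1.0)
    wts = 0.5 * f_hi * w
    p = np.clip(np.atleast_1d(pdf_general(f, model, protocol, init)), 0.0, None)
    z = float(np.sum(wts * p))
    if z <= 0:
        raise RuntimeError("quadrature failure: vanishing probability mass")
    mean = float(np.sum(wts * f * p)) / z
    chi = chi_factor(model, protocol)
    k0 = kramers_rate_k0(model, chi)
    return MeanForceResult(
        mean=mean,
        method="numeric",
        q=math.exp(model.barrier_kT * (1.0 - chi)),
        x_factor=math.sqrt(chi) * k0
        / (model.beta * protocol.nominal_rate * model.barrier_position),
    )


def _mean_force_high(model: BondModel, protocol: LoadingProtocol) -> float:
    """Deterministic (ballistic) high-rate mean, exact Boltzmann average.

    <F> = sqrt(2 gamma Edot) E[sqrt(x_b - x0)] with x0 drawn from the well
    equilibrium; the expectation evaluates in closed form to

        sqrt(x_b) Gamma(3/2) e^{-z} D_{-3/2}(-sqrt(4 z)) / (sqrt(2 pi) z^{1/4}),

    z = beta dG / 2, equivalently a combination of modified Bessel
    functions I_{+-1/4}(z) of half the reduced barrier height.
    """
    sig = model.sigma0
    y = model.barrier_position / sig
    d_m32 = special.pbdv(-1.5, -y)[0]
    m_sqrt = (
        sig ** 1.5 * special.gamma(1.5) * math.exp(-y * y / 4.0) * d_m32
        / math.sqrt(2.0 * math.pi * sig * sig)
    )
    return math.sqrt(2.0 * model.gamma * protocol.nominal_rate) * m_sqrt


def _mean_force_low(model: BondModel, protocol: LoadingProtocol) -> float:
    """Kramers-regime mean from the exponential-integral (Bell-type) estimate.

    <F> = chi / (beta x_b) * exp(X) E1(X), X = chi k0(chi) / (beta Edot x_b):
    the linearized low-force escape rate integrates to this closed form and
    tends to Edot / k0 (the force at the spontaneous unbinding time) as
    Edot -> 0.
    """
    chi = chi_factor(model, protocol)
    k0 = kramers_rate_k0(model, chi)
    x = chi * k0 / (model.beta * protocol.nominal_rate * model.barrier_position)
    # exp(X) E1(X) overflows for tiny rates; use the asymptotic series there.
    if x > 600.0:
        ex_e1 = (1.0 - 1.0 / x + 2.0 / x**2) / x
    else:
        ex_e1 = math.exp(x) * special.exp1(x)
    return chi / (model.beta * model.barrier_position) * ex_e1


def mean_force_asymptotic(
    model: BondModel,
    protocol: LoadingProtocol,
    branch: str = "combined",
    mu: float = 1.0,
) -> MeanForceResult:
    """Closed-form asymptotic mean rupture force for a constant loading rate.

    ``branch`` selects the Kramers-regime estimate (``low``), the ballistic
    deterministic mean (``high``) or their sum (``combined``), which is
    exact in both limits because each branch vanishes relative to the other
    outside its own regime.  Valid for Boltzmann initial conditions with
    mu = 1 only.
    """
    _require_linear(protocol)
    if mu != 1.0:
        raise ValueError(
            "the asymptotic mean is derived for an equilibrium start (mu = 1)"
        )
    chi = chi_factor(model, protocol)
    k0 = kramers_rate_k0(model, chi)
    q = math.exp(model.barrier_kT * (1.0 - chi))
    x_factor = math.sqrt(chi) * k0 / (
        model.beta * protocol.nominal_rate * model.barrier_position
    )
    if branch == "low":
        mean = _mean_force_low(model, protocol)
    elif branch == "high":
        mean = _mean_force_high(model, protocol)
    elif branch == "combined":
        mean = _mean_force_low(model, protocol) + _mean_force_high(model, protocol)
    else:
        raise ValueError("branch must be 'low', 'high' or 'combined'")
    return MeanForceResult(
        mean=mean, method=f"asymptotic-{branch}", q=q, x_factor=x_factor
    )


# ---------------------------------------------------------------------------
# stiff force transducers
# ---------------------------------------------------------------------------

def transducer_mean_position(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
):
    """Mean bound-particle position <x>_G(t) from the barrier-truncated Gaussian.

    The boundary-free Gaussian is cut at x_b (particles beyond the cliff are
    no longer bound), so <x>_G = m - s phi(alpha)/Phi(alpha) with
    alpha = (x_b - m)/s; it is bounded above by x_b for all times.
    """
    t = np.asarray(t, dtype=float)
    m = mean_path(t, model, protocol, init)
    s = np.sqrt(gaussian_variance(t, model, protocol, init))
    alpha = (model.barrier_position - m) / s
    # inverse Mills ratio: log-CDF form in the bulk, asymptotic series far
    # past the barrier where the log difference loses precision
    with np.errstate(over="ignore"):
        mills = np.where(
            alpha > -20.0,
            np.exp(norm.logpdf(alpha) - special.log_ndtr(alpha)),
            -alpha - 1.0 / np.where(alpha < 0, alpha, -1.0),
        )
    out = np.minimum(m - s * mills, model.barrier_position)
    return float(out) if out.ndim == 0 else out


def transducer_force_slow(t, model: BondModel, protocol: LoadingProtocol):
    """Quasi-static measured force from the series-spring force balance.

    kappa_m <x> = kappa (y - <x>) gives <x>_slow = kappa y / (kappa_m+kappa)
    and a measured force kappa (y - <x>_slow) = chi kappa y(t).
    """
    if protocol.mode != "spring":
        raise InvalidProtocolError("force-balance mapping applies to spring mode")
    t = np.asarray(t, dtype=float)
    y = protocol.speed * t
    x_slow = protocol.kappa * y / (model.kappa_m + protocol.kappa)
    out = protocol.kappa * (y - x_slow)
    return float(out) if out.ndim == 0 else out


def transducer_force_map(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = InitialCondition.boltzmann(),
):
    """Measured transducer force kappa [y(t) - <x>_G(t)] (pN) in spring mode.

    Interpolates between the quasi-static force balance at low pulling
    speeds (where <x>_G coincides with <x>_slow) and the moment-of-rupture
    convention kappa [y(t) - x_b] at high speeds, where the trap position
    dwarfs the barrier position.
    """
    if protocol.mode != "spring":
        raise InvalidProtocolError("transducer mapping applies to spring mode")
    t = np.asarray(t, dtype=float)
    y = protocol.speed * t
    out = protocol.kappa * (y - transducer_mean_position(t, model, protocol, init))
    return float(out) if out.ndim == 0 else out
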