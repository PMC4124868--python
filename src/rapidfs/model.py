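"""Cusp-potential bond model and its boundary-free Gaussian dynamics.

The bond is a Brownian particle in the cusp-shaped binding potential

    U(x) = dG * (x / x_b)**2 ,   x < x_b,

i.e. a harmonic well of stiffness ``kappa_m = 2 dG / x_b**2`` terminated by
an absorbing cliff at the barrier position ``x_b``.  Pulling is applied
either as a prescribed external force F(t) ("field" mode, which also covers
soft springs) or through a moving harmonic transducer of stiffness kappa
("spring" mode).  Because the total potential is at most parabolic, the
boundary-free dynamics is an Ornstein--Uhlenbeck process whose mean,
variance and autocorrelation are available in closed form; the absorbing
boundary is reintroduced through a corrected flux in which the diffusive
component at ``x_b`` is doubled (a perfect absorber suppresses the random
backscattering of diffusing particles, see :func:`flux_jstar`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from .constants import thermal_energy

__all__ = [
    "BondModel",
    "LoadingProtocol",
    "InitialCondition",
    "GaussianState",
    "chi_factor",
    "critical_force",
    "kramers_rate_k0",
    "mean_path",
    "autocorrelation_c",
    "gaussian_variance",
    "gaussian_density",
    "gaussian_state",
    "drift_field",
    "flux_jstar",
    "escape_rate",
]


class InvalidModelError(ValueError):
    """Raised for non-physical bond parameters."""


class InvalidProtocolError(ValueError):
    """Raised for non-physical loading protocols."""


@dataclass(frozen=True)
class BondModel:
    """Three-parameter cusp bond: barrier height, barrier position, diffusivity.

    Parameters
    ----------
    barrier_height:
        Activation energy dG of the bond in pN nm.
    barrier_position:
        Attraction range x_b in nm (location of the absorbing cliff).
    diffusivity:
        Diffusion coefficient D of the reaction coordinate in nm^2/s.
    temperature:
        Bath temperature in K.
    """

    barrier_height: float
    barrier_position: float
    diffusivity: float
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not (self.barrier_height > 0):
            raise InvalidModelError("barrier height must be positive")
        if not (self.barrier_position > 0):
            raise InvalidModelError("barrier position must be positive")
        if not (self.diffusivity > 0):
            raise InvalidModelError("diffusivity must be positive")
        if not (self.temperature > 0):
            raise InvalidModelError("temperature must be positive")

    @classmethod
    def from_kT(
        cls,
        barrier_kT: float,
        barrier_position: float,
        diffusivity: float,
        temperature: float = 300.0,
    ) -> "BondModel":
        """Build a model with the barrier height given in units of k_B T."""
        return cls(
            barrier_height=barrier_kT * thermal_energy(temperature),
            barrier_position=barrier_position,
            diffusivity=diffusivity,
            temperature=temperature,
        )

    # -- derived constants -------------------------------------------------
    @property
    def kT(self) -> float:
        """Thermal energy k_B T (pN nm)."""
        return thermal_energy(self.temperature)

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T) (1/(pN nm))."""
        return 1.0 / self.kT

    @property
    def barrier_kT(self) -> float:
        """Barrier height in units of k_B T."""
        return self.barrier_height / self.kT

    @property
    def kappa_m(self) -> float:
        """Molecular (well) stiffness 2 dG / x_b^2 (pN/nm)."""
        return 2.0 * self.barrier_height / self.barrier_position**2

    @property
    def gamma(self) -> float:
        """Friction coefficient k_B T / D (pN s / nm)."""
        return self.kT / self.diffusivity

    @property
    def tau_r(self) -> float:
        """Relaxation time gamma / kappa_m of the unloaded bond (s)."""
        return self.gamma / self.kappa_m

    @property
    def sigma0_sq(self) -> float:
        """Equilibrium positional variance k_B T / kappa_m in the well (nm^2)."""
        return self.kT / self.kappa_m

    @property
    def sigma0(self) -> float:
        """Equilibrium positional standard deviation (nm)."""
        return math.sqrt(self.sigma0_sq)

    @property
    def critical_force(self) -> float:
        """Force 2 dG / x_b that flattens the tilted barrier (pN)."""
        return 2.0 * self.barrier_height / self.barrier_position

    def potential(self, x):
        """Binding potential U(x) = dG (x/x_b)^2 (pN nm), defined for x < x_b."""
        x = np.asarray(x, dtype=float)
        return self.barrier_height * (x / self.barrier_position) ** 2


@dataclass(frozen=True)
class LoadingProtocol:
    """Field- or spring-driven loading.

    ``field`` mode prescribes the pulling force directly, F(t) = rate * t by
    default or an arbitrary monotone schedule; ``spring`` mode retracts a
    harmonic transducer of stiffness ``kappa`` at constant ``speed`` so that
    the trap centre is y(t) = speed * t and the nominal loading rate is
    kappa * speed.
    """

    mode: str
    rate: float = 0.0                     # pN/s (field; nominal for spring)
    kappa: float = 0.0                    # pN/nm (spring stiffness)
    speed: float = 0.0                    # nm/s (trap retraction speed)
    force_schedule: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, compare=False
    )
    rate_schedule: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.mode not in ("field", "spring"):
            raise InvalidProtocolError(f"unknown protocol mode {self.mode!r}")
        if self.kappa < 0:
            raise InvalidProtocolError("spring stiffness must be non-negative")
        if self.mode == "spring":
            if self.kappa == 0:
                raise InvalidProtocolError("spring mode requires kappa > 0")
            if self.speed <= 0:
                raise InvalidProtocolError("spring mode requires speed > 0")
        if self.mode == "field" and self.force_schedule is None and self.rate < 0:
            raise InvalidProtocolError("loading rate must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def field(cls, rate: float) -> "LoadingProtocol":
        """Linearly ramped external force F(t) = rate * t."""
        return cls(mode="field", rate=float(rate))

    @classmethod
    def spring(cls, stiffness: float, speed: float) -> "LoadingProtocol":
        """Moving harmonic transducer: V(x,t) = kappa (x - v t)^2 / 2."""
        return cls(
            mode="spring",
            kappa=float(stiffness),
            speed=float(speed),
            rate=float(stiffness) * float(speed),
        )

    @classmethod
    def custom_field(
        cls,
        force: Callable[[np.ndarray], np.ndarray],
        rate: Callable[[np.ndarray], np.ndarray],
    ) -> "LoadingProtocol":
        """Arbitrary monotone force schedule F(t) with rate dF/dt."""
        return cls(mode="field", force_schedule=force, rate_schedule=rate)

    # -- derived quantities ------------------------------------------------
    @property
    def is_linear(self) -> bool:
        return self.force_schedule is None

    @property
    def nominal_rate(self) -> float:
        """Nominal loading rate (pN/s): rate for fields, kappa * speed for springs."""
        return self.rate

    def chi(self, model: BondModel) -> float:
        """Relative change of the total spring constant, kappa_m/(kappa_m+kappa)."""
        return chi_factor(model, self)

    def total_stiffness(self, model: BondModel) -> float:
        """Combined stiffness of bond plus transducer (pN/nm)."""
        return model.kappa_m + (self.kappa if self.mode == "spring" else 0.0)

    def drive(self, t, model: BondModel = None):
        """Driving force f(t) entering the Langevin drift (pN).

        For fields this is the applied force F(t); for springs it is
        kappa * y(t), the force the trap would exert on a particle at the
        origin.
        """
        t = np.asarray(t, dtype=float)
        if self.mode == "spring":
            return self.kappa * self.speed * t
        if self.force_schedule is not None:
            return self.force_schedule(t)
        return self.rate * t

    def force_of_time(self, t):
        """Nominal pulling force at time t (pN)."""
        t = np.asarray(t, dtype=float)
        if self.mode == "spring":
            return self.rate * t
        if self.force_schedule is not None:
            return self.force_schedule(t)
        return self.rate * t

    def rate_of_time(self, t):
        """Nominal loading rate dF/dt at time t (pN/s)."""
        t = np.asarray(t, dtype=float)
        if self.force_schedule is not None:
            return self.rate_schedule(t)
        return np.broadcast_to(np.asarray(self.rate, dtype=float), t.shape).copy() \
            if t.shape else float(self.rate)

    def time_of_force(self, force):
        """Invert the (monotone) nominal force schedule."""
        force = np.asarray(force, dtype=float)
        if self.force_schedule is None:
            if self.rate <= 0:
                raise InvalidProtocolError("cannot invert a zero loading rate")
            return force / self.rate

        def _invert(f):
            if f <= 0:
                return 0.0
            hi = 1.0
            while self.force_schedule(np.asarray(hi)) < f:
                hi *= 2.0
                if hi > 1e18:
                    raise InvalidProtocolError("force schedule never reaches target")
            return brentq(lambda t: float(self.force_schedule(np.asarray(t))) - f,
                          0.0, hi, xtol=1e-15, rtol=1e-13)

        return np.vectorize(_invert)(force) if force.shape else _invert(float(force))


@dataclass(frozen=True)
class InitialCondition:
    """Initial distribution of the bond coordinate at t = 0.

    ``boltzmann`` draws from the equilibrium distribution of the unloaded
    well (variance mu * k_B T / kappa_m, with the width-ratio parameter
    ``mu`` defaulting to 1); ``point`` starts every trajectory at x0;
    ``gaussian`` prescribes mean and variance explicitly.
    """

    kind: str = "boltzmann"
    x0: float = 0.0
    mean: float = 0.0
    variance: float = 0.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("boltzmann", "point", "gaussian"):
            raise ValueError(f"unknown initial condition {self.kind!r}")
        if self.mu <= 0:
            raise ValueError("width ratio mu must be positive")
        if self.kind == "gaussian" and self.variance <= 0:
            raise ValueError("gaussian initial condition needs variance > 0")

    @classmethod
    def boltzmann(cls, mu: float = 1.0) -> "InitialCondition":
        return cls(kind="boltzmann", mu=mu)

    @classmethod
    def point(cls, x0: float) -> "InitialCondition":
        return cls(kind="point", x0=x0)

    @classmethod
    def gaussian(cls, mean: float, variance: float) -> "InitialCondition":
        return cls(kind="gaussian", mean=mean, variance=variance)

    def moments(self, model: BondModel):
        """Initial mean and variance (nm, nm^2) implied for ``model``."""
        if self.kind == "boltzmann":
            return 0.0, self.mu * model.sigma0_sq
        if self.kind == "point":
            if self.x0 >= model.barrier_position:
                raise ValueError("point initial condition must lie inside the well")
            return self.x0, 0.0
        return self.mean, self.variance


@dataclass(frozen=True)
class GaussianState:
    """Boundary-free Gaussian state of the driven bond at one instant."""

    time: float
    mean: float           # nm
    variance: float       # nm^2
    autocorrelation: float
    density_at_barrier: float  # 1/nm


_DEFAULT_INIT = InitialCondition.boltzmann()


# ---------------------------------------------------------------------------
# elementary model quantities
# ---------------------------------------------------------------------------

def chi_factor(model: BondModel, protocol: LoadingProtocol) -> float:
    """Stiffness ratio kappa_m / (kappa_m + kappa) of the loaded bond.

    Equals 1 for external fields and soft springs and decreases towards 0 as
    the transducer stiffens; it also equals the ratio of the stationary
    positional variance of the combined bond-plus-transducer system to that
    of the bare bond.
    """
    if protocol.mode == "field":
        return 1.0
    return model.kappa_m / (model.kappa_m + protocol.kappa)


def critical_force(model: BondModel) -> float:
    """Critical force 2 dG / x_b (pN) at which the tilted barrier vanishes."""
    return model.critical_force


def kramers_rate_k0(model: BondModel, chi: float = 1.0) -> float:
    """Spontaneous escape rate of the cusp bond (1/s), high-barrier asymptotics.

    For the bare bond (chi = 1) this is

        k0 = sqrt(beta dG / pi) * exp(-beta dG) / tau_r .

    With a transducer of finite stiffness attached (chi < 1) the combined
    well has stiffness kappa_m / chi and barrier dG / chi, giving

        k0(chi) = chi**(-3/2) * sqrt(beta dG / pi) * exp(-beta dG / chi) / tau_r .

    The expression is the leading high-barrier term; its relative error
    against the exact mean first-passage time is O(1/(beta dG)).
    """
    if not (0.0 < chi <= 1.0):
        raise InvalidProtocolError("chi must lie in (0, 1]")
    a = model.barrier_kT
    if a < 2.0:
        warnings.warn(
            "barrier below 2 kT: the high-barrier rate formula is unreliable",
            stacklevel=2,
        )
    return chi ** (-1.5) * math.sqrt(a / math.pi) * math.exp(-a / chi) / model.tau_r


# ---------------------------------------------------------------------------
# Gaussian (boundary-free) dynamics
# ---------------------------------------------------------------------------

def autocorrelation_c(t, model: BondModel, chi: float = 1.0):
    """Normalized positional autocorrelation C(t) = exp(-t / (chi tau_r)).

    chi tau_r = gamma / (kappa_m + kappa) is the relaxation time of the
    combined bond-plus-transducer well; C(0) = 1.
    """
    t = np.asarray(t, dtype=float)
    out = np.exp(-t / (chi * model.tau_r))
    return float(out) if out.ndim == 0 else out


def _relax_time(model: BondModel, protocol: LoadingProtocol) -> float:
    return model.gamma / protocol.total_stiffness(model)


def mean_path(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
):
    """Deterministic mean path of the boundary-free dynamics (nm).

    Solves gamma * dx/dt = f(t) - kappa_s x with f(t) the driving force and
    kappa_s the combined stiffness.  For linear ramps the solution is closed
    form; arbitrary schedules are integrated by quadrature.
    """
    t = np.asarray(t, dtype=float)
    m0, _ = init.moments(model)
    ks = protocol.total_stiffness(model)
    tau = model.gamma / ks
    decay = np.exp(-t / tau)
    if protocol.mode == "spring" or protocol.force_schedule is None:
        r = protocol.kappa * protocol.speed if protocol.mode == "spring" else protocol.rate
        forced = (r / ks) * (t - tau * (1.0 - decay))
    else:
        sched = protocol.force_schedule

        def _forced(ti):
            if ti == 0.0:
                return 0.0
            val, _ = quad(
                lambda s: math.exp(-(ti - s) / tau) * float(sched(np.asarray(s))),
                0.0, ti, limit=200,
            )
            return val / model.gamma

        forced = np.vectorize(_forced)(t)
    out = m0 * decay + forced
    return float(out) if out.ndim == 0 else out


def gaussian_variance(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
):
    """Variance of the boundary-free Gaussian state (nm^2).

    Relaxes from the initial variance towards the stationary value
    chi * k_B T / kappa_m of the combined well on the timescale
    chi tau_r / 2.
    """
    t = np.asarray(t, dtype=float)
    _, v0 = init.moments(model)
    chi = chi_factor(model, protocol)
    vinf = chi * model.sigma0_sq
    out = vinf + (v0 - vinf) * np.exp(-2.0 * t / (chi * model.tau_r))
    return float(out) if out.ndim == 0 else out


def gaussian_density(
    x,
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
):
    """Boundary-free Gaussian density W_G(x, t) (1/nm), normalized over the line."""
    x = np.asarray(x, dtype=float)
    m = mean_path(t, model, protocol, init)
    v = gaussian_variance(t, model, protocol, init)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(-((x - m) ** 2) / (2.0 * v)) / np.sqrt(2.0 * np.pi * v)
    out = np.where(np.asarray(v) > 0, out, 0.0)  # delta limit, off the mean
    return float(out) if out.ndim == 0 else out


def gaussian_state(
    t: float,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
) -> GaussianState:
    """Bundle mean, variance, autocorrelation and W_G(x_b, t) at time ``t``."""
    chi = chi_factor(model, protocol)
    m = mean_path(t, model, protocol, init)
    v = gaussian_variance(t, model, protocol, init)
    w = math.exp(-((model.barrier_position - m) ** 2) / (2.0 * v)) / math.sqrt(
        2.0 * math.pi * v
    )
    return GaussianState(
        time=float(t),
        mean=float(m),
        variance=float(v),
        autocorrelation=autocorrelation_c(float(t), model, chi),
        density_at_barrier=w,
    )


def drift_field(x, t, model: BondModel, protocol: LoadingProtocol):
    """Drift A(x, t) = [f(t) - kappa_s x] / gamma (nm/s) of the loaded bond.

    Single source of truth for the deterministic force: the analytic flux,
    the Brownian-dynamics integrator and the first-passage solver all call
    this function.
    """
    x = np.asarray(x, dtype=float)
    ks = protocol.total_stiffness(model)
    out = (protocol.drive(t) - ks * x) / model.gamma
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# corrected flux and unified escape rate
# ---------------------------------------------------------------------------

def flux_jstar(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
    warn_negative: bool = True,
):
    """Corrected first-passage flux j*(x_b, t) (1/s).

    Sum of the deterministic drift component A(x_b,t) W_G(x_b,t) and twice
    the diffusive component -D dW_G/dx at x_b: inserting a perfect absorber
    suppresses the diffusive backscattering, which doubles the diffusive
    share of the flux.  The same expression is the first iterate of the
    exact renewal (Volterra) equation for the first-passage flux.

    The approximation may turn transiently negative once the mean of W_G
    overtakes the barrier ("phantom" backflow); negative values are
    reported as-is (with a warning) and are dealt with at the distribution
    level by truncation.
    """
    t = np.asarray(t, dtype=float)
    xb = model.barrier_position
    m = mean_path(t, model, protocol, init)
    v = gaussian_variance(t, model, protocol, init)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-((xb - m) ** 2) / (2.0 * v)) / np.sqrt(2.0 * np.pi * v)
        drift = drift_field(xb, t, model, protocol) * w
        diff = model.diffusivity * (xb - m) / v * w
    out = np.where(np.asarray(v) > 0, drift + 2.0 * diff, 0.0)
    if warn_negative and np.any(np.asarray(out) < 0):
        warnings.warn(
            "flux j* is negative at some times (phantom backflow); "
            "truncate the rupture-force distribution before using it",
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def gaussian_survival(
    t,
    model: BondModel,
    protocol: LoadingProtocol,
    init: InitialCondition = _DEFAULT_INIT,
):
    """Gaussian survival S_G(t): mass of W_G left of the barrier."""
    t = np.asarray(t, dtype=float)
    m = mean_path(t, model, protocol, init)
    v = gaussian_variance(t, model, protocol, init)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = norm.cdf((model.barrier_position - m) / np.sqrt(v))
    out = np.where(
        np.asarray(v) > 0,
        out,
        np.asarray(np.asarray(m) < model.barrier_position, dtype=float),
    )
    return float(out) if np.ndim(t) == 0 else out


def escape_rate(
    model: BondModel,
    protocol: LoadingProtocol,
    t=None,
    force=None,
    init: InitialCondition = _DEFAULT_INIT,
):
    """Unified time-dependent escape rate k(t) = j*(x_b, t) / S_G(t) (1/s).

    Exact in both the slow-loading (Kramers/diffusive) and fast-loading
    (ballistic) limits: at zero force it reduces to the cusp Kramers rate
    and far above the critical force it approaches the Gaussian asymptote
    j_G / S_G.  Either ``t`` or ``force`` must be given; forces are mapped
    to times through the protocol's nominal schedule.
    """
    if (t is None) == (force is None):
        raise ValueError("specify exactly one of t or force")
    if t is None:
        t = protocol.time_of_force(force)
    t = np.asarray(t, dtype=float)
    j = flux_jstar(t, model, protocol, init, warn_negative=False)
    sg = gaussian_survival(t, model, protocol, init)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(j) / np.asarray(sg)
    return float(out) if np.ndim(t) == 0 else out
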