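"""Core bond model: derived constants, Gaussian dynamics, flux and rate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from rapidfs import (
    BondModel,
    InitialCondition,
    LoadingProtocol,
    autocorrelation_c,
    chi_factor,
    critical_force,
    dhs_rate,
    drift_field,
    escape_rate,
    flux_jstar,
    gaussian_density,
    gaussian_survival,
    gaussian_variance,
    kramers_rate_k0,
    mean_path,
    mfpt_quadrature,
    sample_initial,
)
from rapidfs.model import InvalidModelError, InvalidProtocolError


class TestBondModel:
    def test_derived_constants_are_consistent(self, ref_model):
        m = ref_model
        assert m.kappa_m * m.barrier_position**2 / 2.0 == pytest.approx(
            m.barrier_height, rel=1e-14
        )
        assert m.tau_r == pytest.approx(m.gamma / m.kappa_m, rel=1e-14)
        assert m.gamma == pytest.approx(m.kT / m.diffusivity, rel=1e-14)
        assert m.barrier_kT == pytest.approx(10.0, rel=1e-14)
        assert m.tau_r > 0

    @given(
        a=st.floats(2.0, 40.0),
        xb=st.floats(0.05, 10.0),
        d=st.floats(1.0, 1e9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariants_hold_across_parameter_space(self, a, xb, d):
        m = BondModel.from_kT(a, xb, d)
        assert m.kappa_m > 0 and m.tau_r > 0 and m.sigma0_sq > 0
        assert m.critical_force == pytest.approx(
            m.kappa_m * m.barrier_position, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(barrier_height=-1.0, barrier_position=1.0, diffusivity=1.0),
            dict(barrier_height=1.0, barrier_position=0.0, diffusivity=1.0),
            dict(barrier_height=1.0, barrier_position=1.0, diffusivity=-5.0),
            dict(barrier_height=1.0, barrier_position=1.0, diffusivity=1.0,
                 temperature=0.0),
        ],
    )
    def test_nonphysical_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidModelError):
            BondModel(**kwargs)


class TestCriticalForceAndChi:
    def test_reference_value(self, ref_model):
        # 2 * 10 k_B T / 1 nm at 300 K
        assert critical_force(ref_model) == pytest.approx(82.839, abs=0.001)

    def test_scaling_in_barrier_position(self):
        m1 = BondModel.from_kT(10.0, 1.0, 1000.0)
        m2 = BondModel.from_kT(10.0, 2.0, 1000.0)
        assert critical_force(m2) == pytest.approx(critical_force(m1) / 2.0)

    def test_vanishing_barrier(self):
        m = BondModel(1e-9, 1.0, 1000.0)
        assert critical_force(m) == pytest.approx(0.0, abs=1e-8)

    def test_chi_field_is_one(self, ref_model):
        assert chi_factor(ref_model, LoadingProtocol.field(100.0)) == 1.0

    def test_chi_soft_spring_limit(self, ref_model):
        soft = LoadingProtocol.spring(1e-9 * ref_model.kappa_m, 10.0)
        assert chi_factor(ref_model, soft) == pytest.approx(1.0, rel=1e-8)

    def test_chi_matches_stationary_variance_of_combined_well(self, ref_model):
        """chi equals var_combined / var_bond for the harmonic pair."""
        m = ref_model
        protocol = LoadingProtocol.spring(m.kappa_m, 10.0)
        chi = chi_factor(m, protocol)
        assert chi == pytest.approx(0.5, rel=1e-12)
        # brute-force Boltzmann variance in the combined potential
        ks = m.kappa_m + protocol.kappa
        z = quad(lambda x: math.exp(-m.beta * ks * x * x / 2), -2, 2)[0]
        var = quad(lambda x: x * x * math.exp(-m.beta * ks * x * x / 2),
                   -2, 2)[0] / z
        assert chi == pytest.approx(var / m.sigma0_sq, rel=1e-6)
        assert 0.0 < chi <= 1.0

    def test_negative_stiffness_rejected(self):
        with pytest.raises(InvalidProtocolError):
            LoadingProtocol(mode="spring", kappa=-1.0, speed=1.0)


class TestKramersRate:
    def test_rate_is_linear_in_diffusivity(self):
        m1 = BondModel.from_kT(10.0, 1.0, 1000.0)
        m2 = BondModel.from_kT(10.0, 1.0, 2000.0)
        assert kramers_rate_k0(m2) == pytest.approx(2.0 * kramers_rate_k0(m1))

    @pytest.mark.parametrize("a", [8.0, 10.0, 12.0, 14.0])
    def test_rate_tracks_inverse_mfpt(self, a):
        """The high-barrier rate overshoots 1/MFPT by O(1/(2 beta dG)).

        The leading asymptotic correction to the Kramers prefactor is
        1/(2 beta dG), so the product k0 * tau decreases towards 1 from
        roughly 1 + 1/(2a); assert that characterized band.
        """
        m = BondModel.from_kT(a, 1.0, 1000.0)
        ratio = kramers_rate_k0(m) * mfpt_quadrature(m)
        assert 1.0 < ratio < 1.0 + 1.4 / a

    def test_rate_ratio_improves_with_barrier(self):
        ratios = [
            kramers_rate_k0(BondModel.from_kT(a, 1.0, 1000.0))
            * mfpt_quadrature(BondModel.from_kT(a, 1.0, 1000.0))
            for a in (8.0, 14.0, 20.0)
        ]
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] == pytest.approx(1.0, abs=0.03)

    def test_barrier_height_ratio_dominated_by_boltzmann_factor(self):
        m10 = BondModel.from_kT(10.0, 1.0, 1000.0)
        m14 = BondModel.from_kT(14.0, 1.0, 1000.0)
        ratio = kramers_rate_k0(m14) / kramers_rate_k0(m10)
        oracle = mfpt_quadrature(m10) / mfpt_quadrature(m14)
        assert ratio == pytest.approx(oracle, rel=0.05)
        # prefactor ~ a^{3/2} (stiffness and attempt frequency both grow with a)
        assert ratio == pytest.approx(math.exp(-4.0) * 1.4**1.5, rel=1e-10)

    def test_low_barrier_warns(self):
        with pytest.warns(UserWarning, match="high-barrier"):
            kramers_rate_k0(BondModel.from_kT(1.5, 1.0, 1000.0))


class TestMeanPath:
    def test_equilibrium_fixed_point(self, ref_model):
        protocol = LoadingProtocol(mode="field", rate=0.0)
        t = np.linspace(0.0, 10 * ref_model.tau_r, 7)
        assert np.allclose(mean_path(t, ref_model, protocol), 0.0)

    def test_matches_ode_integration_field(self, ref_model):
        m = ref_model
        protocol = LoadingProtocol.field(1e6)
        t_eval = np.linspace(0.0, 8 * m.tau_r, 40)
        sol = solve_ivp(
            lambda t, x: drift_field(x[0], t, m, protocol),
            (0.0, t_eval[-1]), [0.0], t_eval=t_eval, rtol=1e-10, atol=1e-14,
        )
        assert np.allclose(
            mean_path(t_eval, m, protocol), sol.y[0], rtol=1e-7, atol=1e-9
        )
        # long-time quasi-static drift with constant lag Edot * tau_r / kappa_m
        t_late = 50 * m.tau_r
        expected = (1e6 * t_late - 1e6 * m.tau_r) / m.kappa_m
        assert mean_path(t_late, m, protocol) == pytest.approx(expected, rel=1e-10)

    def test_stiff_spring_tracks_trap(self, ref_model):
        m = ref_model
        protocol = LoadingProtocol.spring(50.0 * m.kappa_m, 1e5)
        sol = solve_ivp(
            lambda t, x: drift_field(x[0], t, m, protocol),
            (0.0, 20 * m.tau_r), [0.0], t_eval=[20 * m.tau_r],
            rtol=1e-10, atol=1e-14,
        )
        xbar = mean_path(20 * m.tau_r, m, protocol)
        assert xbar == pytest.approx(sol.y[0][-1], rel=1e-7)
        ratio = protocol.kappa / (protocol.kappa + m.kappa_m)
        assert xbar == pytest.approx(
            ratio * protocol.speed * 20 * m.tau_r, rel=0.01
        )

    def test_custom_schedule_agrees_with_linear(self, ref_model):
        rate = 1e5
        lin = LoadingProtocol.field(rate)
        custom = LoadingProtocol.custom_field(
            lambda t: rate * t, lambda t: np.full_like(np.asarray(t, float), rate)
        )
        t = 3.0 * ref_model.tau_r
        assert mean_path(t, ref_model, custom) == pytest.approx(
            mean_path(t, ref_model, lin), rel=1e-7
        )


class TestGaussianState:
    def test_autocorrelation_normalization_and_decay(self, ref_model):
        assert autocorrelation_c(0.0, ref_model) == 1.0
        t = np.linspace(0, 5 * ref_model.tau_r, 50)
        c = autocorrelation_c(t, ref_model)
        assert np.all(np.diff(c) < 0)
        assert autocorrelation_c(40 * ref_model.tau_r, ref_model) < 1e-15
        # spring stiffening shortens the relaxation time
        assert autocorrelation_c(
            ref_model.tau_r, ref_model, chi=0.5
        ) == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_autocorrelation_matches_simulated_autocovariance(self, ref_model):
        """Unloaded bond: empirical lag autocovariance decays like C(t)."""
        m = ref_model
        protocol = LoadingProtocol(mode="field", rate=0.0)
        rng = np.random.default_rng(4)
        n, dt = 4000, m.tau_r / 50
        lag_steps = 50  # one relaxation time
        x = sample_initial(m, InitialCondition.boltzmann(), n, rng)
        amp = math.sqrt(2 * m.diffusivity * dt)
        x0 = x.copy()
        for step in range(lag_steps):
            x = x + dt * drift_field(x, step * dt, m, protocol) + amp * rng.normal(
                0, 1, n
            )
        c_emp = np.mean(x0 * x) / m.sigma0_sq
        expected = autocorrelation_c(lag_steps * dt, m)
        assert c_emp == pytest.approx(expected, abs=3.5 / math.sqrt(n))

    @pytest.mark.parametrize(
        "protocol_factory, t_factor",
        [
            (lambda m: LoadingProtocol.field(1e4), 1.0),
            (lambda m: LoadingProtocol.field(1e8), 0.1),
            (lambda m: LoadingProtocol.spring(0.5 * m.kappa_m, 1e4), 2.0),
        ],
    )
    def test_density_is_normalized(self, ref_model, protocol_factory, t_factor):
        m = ref_model
        protocol = protocol_factory(m)
        t = t_factor * m.tau_r
        total = quad(
            lambda x: gaussian_density(x, t, m, protocol), -np.inf, np.inf,
            limit=200,
        )[0]
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_point_start_concentrates(self, ref_model):
        init = InitialCondition.point(0.3)
        protocol = LoadingProtocol.field(1e3)
        t = 1e-9 * ref_model.tau_r
        assert gaussian_variance(t, ref_model, protocol, init) < 1e-9
        assert mean_path(t, ref_model, protocol, init) == pytest.approx(0.3,
                                                                        abs=1e-9)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
    def test_unloaded_stationary_variance_scales_with_mu(self, ref_model, mu):
        protocol = LoadingProtocol(mode="field", rate=0.0)
        init = InitialCondition.boltzmann(mu=mu)
        v = gaussian_variance(0.7 * ref_model.tau_r, ref_model, protocol, init)
        # variance interpolates between mu sigma0^2 and sigma0^2
        expected = ref_model.sigma0_sq * (
            1.0 + (mu - 1.0) * math.exp(-1.4)
        )
        assert v == pytest.approx(expected, rel=1e-10)
        if mu == 1.0:
            assert v == pytest.approx(ref_model.sigma0_sq, rel=1e-12)


class TestFluxAndRate:
    def test_flux_sign_components_at_equilibrium(self, ref_model):
        """Unloaded symmetric state: restoring drift, positive diffusion."""
        m = ref_model
        protocol = LoadingProtocol(mode="field", rate=0.0)
        xb = m.barrier_position
        assert drift_field(xb, 0.0, m, protocol) < 0
        w = gaussian_density(xb, 0.0, m, protocol)
        diffusive = m.diffusivity * xb / m.sigma0_sq * w
        j = flux_jstar(0.0, m, protocol)
        assert diffusive > 0
        assert j == pytest.approx(drift_field(xb, 0.0, m, protocol) * w
                                  + 2 * diffusive, rel=1e-12)
        assert j > 0

    def test_high_rate_flux_approaches_gaussian_flux(self, ref_model):
        """Where ruptures actually happen at high rates, drift dominates j*."""
        m = ref_model
        protocol = LoadingProtocol.field(1e11)
        # evaluate around the bulk of the ballistic rupture-force distribution
        f_typ = math.sqrt(2.0 * m.gamma * 1e11 * m.barrier_position)
        for frac in (0.85, 0.95, 1.0):
            t = protocol.time_of_force(frac * f_typ)
            j_star = flux_jstar(t, m, protocol)
            w = gaussian_density(m.barrier_position, t, m, protocol)
            mean = mean_path(t, m, protocol)
            var = gaussian_variance(t, m, protocol)
            j_gauss = (
                drift_field(m.barrier_position, t, m, protocol) * w
                + m.diffusivity * (m.barrier_position - mean) / var * w
            )
            assert j_star == pytest.approx(j_gauss, rel=0.005)

    def test_negative_transient_flux_warns_not_clips(self, ref_model):
        protocol = LoadingProtocol.field(1e5)
        t_late = protocol.time_of_force(1.5 * ref_model.critical_force)
        with pytest.warns(UserWarning, match="phantom"):
            j = flux_jstar(t_late, ref_model, protocol)
        assert j < 0

    def test_zero_force_rate_equals_kramers_rate(self, ref_model):
        protocol = LoadingProtocol.field(1e2)
        k = escape_rate(ref_model, protocol, force=0.0)
        assert k == pytest.approx(kramers_rate_k0(ref_model), rel=1e-4)
        # and therefore agrees with the exact inverse MFPT to ~6%
        assert k * mfpt_quadrature(ref_model) == pytest.approx(1.0, abs=0.1)

    def test_low_rate_limit_reproduces_quasi_adiabatic_rate(self, ref_model):
        """Slow loading reduces to the DHS nu=1/2 theory.

        The corrected flux j* matches the DHS rate all the way to 0.8 F_c;
        the unified rate k = j*/S_G carries the Gaussian-survival factor,
        which stays within 2% of unity up to half the critical force (and is
        exactly cancelled in p(F) by the survival's Phi factor).
        """
        m = ref_model
        protocol = LoadingProtocol.field(10.0)
        forces = np.linspace(1.0, 0.8 * m.critical_force, 30)
        reference = dhs_rate(forces, m)
        t = protocol.time_of_force(forces)
        j = np.asarray(flux_jstar(t, m, protocol, warn_negative=False))
        assert np.allclose(j / reference, 1.0, atol=0.02)
        low = forces <= 0.5 * m.critical_force
        k = escape_rate(m, protocol, force=forces[low])
        assert np.allclose(k / reference[low], 1.0, atol=0.02)

    def test_reference_rate_agrees_at_forty_piconewtons(self, ref_model):
        k = escape_rate(ref_model, LoadingProtocol.field(10.0), force=40.0)
        assert k == pytest.approx(dhs_rate(40.0, ref_model), rel=0.02)

    def test_gaussian_survival_near_one_at_low_rates(self, ref_model):
        protocol = LoadingProtocol.field(100.0)
        t = protocol.time_of_force(0.3 * ref_model.critical_force)
        assert gaussian_survival(t, ref_model, protocol) > 0.999

    def test_escape_rate_requires_exactly_one_coordinate(self, ref_model):
        protocol = LoadingProtocol.field(100.0)
        with pytest.raises(ValueError):
            escape_rate(ref_model, protocol)
        with pytest.raises(ValueError):
            escape_rate(ref_model, protocol, t=1.0, force=1.0)
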