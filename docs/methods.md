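# Methods

This note records the model, the derivations behind the closed forms, the
numerical choices, and what the validation suite does and does not
establish.  Symbols: ΔG‡ barrier height, x_b barrier position, D
diffusivity, T temperature, β = 1/k_BT, κ_m = 2ΔG‡/x_b² molecular
stiffness, γ = k_BT/D friction, τ_r = γ/κ_m relaxation time,
σ₀² = k_BT/κ_m well variance, F_c = 2ΔG‡/x_b critical force, Ė loading
rate.  Units are pN, nm, s, K with k_B = 0.0138065 pN·nm/K.

## Model and boundary-free dynamics

The bond coordinate obeys the overdamped Langevin equation
γẋ = −∂ₓ[U(x) + V(x,t)] + ξ, ⟨ξ(t)ξ(t′)⟩ = 2γk_BT δ(t−t′), in the cusp
potential U(x) = ΔG‡(x/x_b)² with an absorbing boundary at x_b.  The
driving V is either −F(t)x (field mode; F(t) = Ėt unless a custom monotone
schedule is given) or κ(x − vt)²/2 (spring mode).  With the boundary
ignored, the process is a time-inhomogeneously forced Ornstein–Uhlenbeck
process in the combined stiffness κ_s = κ_m + κ:

- mean path  x̄(t) = x̄(0)e^(−t/τ̃) + (r/κ_s)[t − τ̃(1 − e^(−t/τ̃))] for a
  linear drive of slope r (r = Ė for fields, κv for springs), τ̃ = γ/κ_s =
  χτ_r with χ = κ_m/κ_s;
- variance  s²(t) = χσ₀² + [s²(0) − χσ₀²] e^(−2t/τ̃);
- autocorrelation  C(t) = e^(−t/(χτ_r)), C(0) = 1.

χ is both the relative change of the total spring constant and the ratio of
the stationary variance of the combined well to that of the bare bond; the
latter identity is what the test suite checks it against.  Initial
conditions are Boltzmann in the bare well (variance μσ₀², with the width
ratio μ = 1 by default), a point mass, or a general Gaussian.

## Corrected flux and unified rate

For a freely diffusing particle, half of the probability flux that reaches
x_b diffusively is scattered back; an absorber removes the backscattering
and doubles the diffusive share.  The corrected flux therefore reads

    j*(x_b,t) = A(x_b,t) W_G(x_b,t) + 2·[−D ∂ₓW_G](x_b,t),

with A(x,t) = [f(t) − κ_s x]/γ the drift field (implemented once and shared
by the analytic core, the simulator and the renewal solver).  Writing
u(t) = (x_b − x̄)/s, the unified escape rate is k(t) = j*/S_G with
S_G = Φ(u) the boundary-free survival.  Two exact reductions anchor it:

- F = 0, Boltzmann start: k equals the high-barrier cusp Kramers rate
  k₀ = √(βΔG‡/π)e^(−βΔG‡)/τ_r identically (with a transducer attached,
  k₀(χ) = χ^(−3/2)√(βΔG‡/π)e^(−βΔG‡/χ)/τ_r, the Kramers rate of the
  combined well of stiffness κ_m/χ and barrier ΔG‡/χ).
- Quasi-adiabatic loading: substituting the stationary width and the
  lag-free mean turns j* into k₀(1 − F/F_c)·exp{βΔG‡[1 − (1 − F/F_c)²]},
  the established ν = 1/2 quasi-adiabatic (DHS) rate, kept in
  `rapidfs.dhs` as an independent comparator.

k₀ is the leading high-barrier asymptotic: its product with the exact mean
first-passage time is ≈ 1 + 1/(2βΔG‡) + O(1/(βΔG‡)²) — 1.08 at 8 k_BT,
1.06 at 10, 1.04 at 14 (computed against the MFPT quadrature below).  This
finite-barrier offset propagates into everything the closed form predicts
at low loading rates; see "Accuracy" below.

## Closed-form survival for linear ramps

S(F) = exp(−∫k/Ḟ) factorizes into an exact part and a quasi-adiabatic
part.  Because Ṡ_G = −j_G for the boundary-free density, the j_G/S_G piece
of k integrates to −ln Φ(u) exactly.  The remaining (doubled) diffusive
piece is integrated in the regime where it matters — slow loading, where
the width is stationary and u̇ ≈ −Ė/(κ_s s∞) — giving

    S(F) = Φ(u)/Φ(u₀) · exp{−c_J [φ(u) − φ(u_ref)]}₊,
    c_J = κ_m σ₀ / (χ^{3/2} τ_r Ė),

with φ the standard normal density, u₀ the initial value of u, and u_ref
the initial mean referenced to the *stationary* width s∞ = √χ σ₀ (for a
Boltzmann μ = 1 start u_ref = u₀ and the subtraction simply enforces
S(0) = 1; for narrower starts the bracket is clipped at zero so early-time
leakage is not double counted — the Φ factor already treats it exactly).
The density is then p(F) = k(F)S(F)/Ė; note the Φ(u) in S cancels the
1/S_G in k, so p is insensitive to the survival-division convention.  In
the ballistic limit S → Φ(u) (exact), in the quasi-adiabatic limit the
exponential factor reproduces the DHS survival (exact as Ė → 0).  The
closed S agrees with high-accuracy numerical integration of ∫k/Ḟ to a few
×10⁻⁴ in survival units at low rates; general (non-linear) schedules use
the numerical integral directly.

## Truncation

p changes sign where A(x_b,t)+2D(x_b−x̄)/s² does; for a linear ramp this
bracket has a single root, located by bisection.  Formally the root exists
at every rate (near F_c + 2Ėτ_r at slow loading), but it constitutes a real
truncation only if the distribution still carries mass there: a root at
which S < 10⁻¹² is reported as F_trunc = +∞.  With the reference bond this
yields +∞ below ~10⁴ pN/s and above ~10⁷ pN/s and a finite truncation in
between, with removed mass peaking at ≈9.5% at 10⁵ pN/s — the breakdown
window.  Truncated densities are renormalized by 512-node Gauss–Legendre
quadrature of the positive part before moments or likelihoods are taken
(a proper distribution is required for both; the renormalization constant
is recorded).  A fit that evaluates any rate with removed mass > 1% carries
a breakdown flag for that rate.

## Mean rupture force

`mean_force_numeric` integrates the truncated, renormalized density
(1024-node Gauss–Legendre on [0, F_sup], F_sup from a survival root-find).
Two closed-form branches are provided for constant Ė and μ = 1:

- high rate: the ballistic rupture force F = √(2γĖ(x_b − x₀)) averaged over
  the Boltzmann start, which evaluates exactly to a parabolic-cylinder
  (equivalently Bessel I±1/4 of βΔG‡/2) expression; verified against direct
  quadrature to 10⁻⁸ and within 0.3% of the numeric moment at 10¹⁰ pN/s;
- low rate: the Bell-linearized exponential-integral result
  ⟨F⟩ = χ/(βx_b) e^X E₁(X), X = χk₀(χ)/(βĖx_b), which tends to Ė/k₀ (the
  force at the spontaneous unbinding time) as Ė → 0.  Its Bell
  linearization omits the quadratic barrier term, which costs ~3% at
  10 pN/s and ~8% at 100 pN/s for the reference bond.

The combined estimate is their sum: each branch vanishes relative to the
other deep in the opposite regime, making the sum asymptotically exact on
both ends, ~5% through the forced-rupture low-rate window and only rough
(~20%) in the crossover decade near 10⁶ pN/s.  Below the forced-rupture
regime (spontaneous unbinding, X ≫ 1) the ballistic term decays only as
√Ė and contaminates the sum; the numeric moment should be used there.

## Stiff transducers

In spring mode the measured force is κ[y(t) − ⟨x⟩(t)].  At low speeds ⟨x⟩
follows the series-spring balance κy/(κ_m+κ) up to a retardation lag vτ̃.
The package's estimate uses the barrier-truncated Gaussian mean,
⟨x⟩_G = x̄ − s·φ(α)/Φ(α) with α = (x_b − x̄)/s, which coincides with the
balance at low speed, is bounded above by x_b always, and crosses over to
the moment-of-rupture convention κ[y − x_b] at high speed.  The inverse
Mills ratio switches to its asymptotic series for α < −20 and the result
is clamped at x_b to keep the mathematical bound under floating-point
error.  The simulator records spring-mode rupture forces with the same
κ[y(t_cross) − x_b] convention.

## Brownian-dynamics simulator

Euler–Maruyama with the shared drift field and noise amplitude √(2Ddt).
Default step dt = min(χτ_r/200, t_ball/2000) with
t_ball = √(2γx_b/Ė) so that both the well relaxation and the ballistic
sweep are resolved; χτ_r/100 for unforced (Ė = 0) runs; a hard validity
bound rejects dt > χτ_r/100.  Crossing detection combines the post-step
threshold with a Brownian-bridge correction: a step from x₀ to x₁ (both
below x_b) hides an excursion across the boundary with probability
exp[−(x_b−x₀)(x_b−x₁)/(Ddt)], and such steps rupture too.  Without the
correction the first-passage time carries an O(√dt) bias that shifts
low-rate force histograms upward by ~1.5 pN at dt = τ_r/200 — larger than
every other error in the pipeline — so the bridge detector is the default
and the plain threshold remains available as `crossing="threshold"`.
A residual few-percent bias remains in spontaneous-escape (Ė = 0) mean
first-passage times at dt = τ_r/100, consistent with the O(dt) error of
the drift-free bridge formula in a curved potential.

Trajectory horizons are set from the theory (1.5× the force at which the
closed-form survival reaches 10⁻¹⁰, or 30/k₀ when unforced); trajectories
exceeding the step budget are recorded as censored, excluded from force
tables and counted in the provenance.  Noise is generated per block with
numpy so that the optional numba kernel and the pure-numpy fallback consume
identical streams and produce bit-identical datasets; every dataset carries
a JSON provenance record (model, protocol, seed, dt, censoring) sufficient
to regenerate it.

Simulated ensembles are the package's synthetic data source.  They emulate
idealized rupture experiments: a memoryless one-dimensional coordinate, a
perfectly linear ramp or ideal harmonic trap, no linker dynamics, no
instrument noise, no rebinding, and rupture defined by first passage at a
known x_b.  Agreement of fits on these data therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to the systematics of real AFM data.

## First-passage oracles

`mfpt_quadrature` evaluates τ = (1/D)∫₀^{x_b}e^{βU(x)}∫_{−∞}^x e^{−βU(y)}dy dx
by nested adaptive quadrature — deterministic and independent of every
approximation above.

`volterra_flux` solves the exact renewal equation for the first-passage
flux of the driven Gauss–Markov process,

    j(x_b,t) = 2ψ(x_b,t|W₀) − 2∫₀^t j(x_b,s) ψ(x_b,t|x_b,s) ds,

where ψ = (A/2)W_G − D∂ₓW_G is the effective flux of the conditional
propagator; the drift coefficient −A/2 in ψ is precisely the choice that
makes the kernel vanish on the diagonal (the leading free-diffusion parts
of drift and diffusion cancel as s → t), so plain product-trapezoidal
stepping is stable without special treatment of a singularity.  The first
iterate 2ψ(x_b,t|W₀) equals j* identically — the closed form is the
first-order truncation of this exact hierarchy — and the converged solution
repairs the phantom backflow, remaining non-negative while bound mass
persists.  Halving the step changes the total ruptured mass by < 0.5% at
the settings used in the tests.  The solver is a public "exact mode", not
just a test fixture.

## Maximum-likelihood inference

The likelihood of (ΔG‡, x_b, D) is the product over events of the
truncated, renormalized closed-form density evaluated under each event's
own protocol, so heterogeneous rates and spring stiffnesses combine in one
global fit.  Events beyond the truncation force of a candidate parameter
set contribute a fixed log-density floor (log 10⁻¹², per pN) instead of
−∞, keeping the surface finite near the breakdown window.  Optimization is
Nelder–Mead in log₁₀(βΔG‡, x_b, D) with bounds βΔG‡ ∈ [2,40],
x_b ∈ [0.05,10] nm, D ∈ [1,10⁹] nm²/s, multi-started (default 8) from a
seeded Latin-hypercube design because the surface has local optima; the
best converged restart is returned with all traces.  μ is fixed at 1
unless explicitly freed (it matters only at high rates).  A least-squares
fit of per-rate histograms is included solely as the conventional
comparator, and profile-likelihood style exploration is left to the user
(the likelihood function is public); no confidence intervals are built in.

## Accuracy of the first-order theory (what the tests show)

Against the exact renewal solution and bridge-corrected simulation with
the reference bond (10 k_BT, 1 nm, 1000 nm²/s, 300 K):

- ballistic regime (≥10⁹ pN/s): closed form exact within sampling error
  (KS ≈ 0.013 at n = 5000, within the 1% critical value);
- quasi-adiabatic regime (≤10³ pN/s): the distribution is shifted by
  ≈ 0.4 pN (≈2% of the mean) because the closed form carries the
  asymptotic-prefactor excess of k₀ (≈6% at this barrier); at n = 5000
  this is statistically resolvable (KS ≈ 0.038 vs critical 0.023), and it
  shrinks with increasing barrier height;
- breakdown window (~10⁵ pN/s): truncation removes ≈9.5% of mass and the
  discrepancy to simulation (KS ≈ 0.03–0.04) is reported, not asserted;
  the Volterra solver is the accurate tool here (KS ≈ 0.011 vs simulation).

Parameter recovery absorbs the low-rate offset into slightly shifted
estimates: global fits of 3200 simulated events across 10²–10⁹ pN/s
typically return ≈(10.1 k_BT, 0.98 nm, 970 nm²/s) for truth
(10, 1, 1000) — a 1–3% bias that is the price of the closed form's speed.

## Problem sizes used by the validation suite

Ensembles of 5000 trajectories at 10³/10⁵/10⁶/10⁹ pN/s for
distribution-level comparisons; 400 events per decade over 10²–10⁹ pN/s
for the global-fit experiment (3200 events; the acceptance script uses the
same design); 6 replicate fits of 900 events (150 per decade, 10⁴–10⁹
pN/s) for the recovery-error statistics; 1200 unforced trajectories for
the spontaneous-escape check.  These sizes make every stochastic assertion
resolvable at its stated tolerance while keeping the full suite at a few
minutes on one CPU.

## Known limitations

- Cusp potential only; no linear-cubic (ν = 2/3) analytic branch — the
  quasi-adiabatic comparator and the μ width-ratio parameter are the only
  accommodations for other well shapes.
- No rebinding after first passage; no polymer-linker force propagation;
  the nominal spring-mode distribution uses the κv ramp with the
  χ-corrected rate, which is a soft-to-moderate stiffness approximation.
- The closed form's low-rate offset described above; use `volterra_flux`
  when sub-percent distribution accuracy matters at moderate barriers.
- The asymptotic mean-force branches are for constant Ė and μ = 1.
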