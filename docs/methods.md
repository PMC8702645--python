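# Methods

This note records the model conventions, numerical choices and known
limitations of `qifbalance`.  Everything quantitative stated here is
computed by the package's tests or by `scripts/acceptance.py`.

## Units and conventions

Time is in ms throughout; population rates are carried internally in
1/ms and converted to Hz only at I/O boundaries.  Synaptic couplings
`g0_ab` index the *postsynaptic* population first.  Eigenvalues and
Lyapunov exponents are computed in 1/ms; user-facing summaries multiply
by the membrane time constant τ_m (20 ms by default), i.e. quote growth
rates per membrane time constant, which is the natural dimensionless
scale of this model family.

## Neural mass model

State (R_e, V_e, R_i, V_i).  With distinct membrane constants, each
population's equations use its own τ_m everywhere: in the rate equation,
in the (πRτ_m)² term, and multiplying both recurrent rates inside the
√K drive bracket.  This is the unique choice consistent with δ-pulse
coupling: a pulse of amplitude g₀/√K arriving at rate K·R produces a
drift τ_m·g₀·√K·R in the postsynaptic potential equation.

### Stationary states

Mean potentials are pinned by structural heterogeneity,
V̄_α = −g₀(αα)Δ₀(αα)/2π.  The rates solve two coupled quadratics; in the
variables z_α = R_α·τ_α the system keeps its equal-τ form after scaling
the off-diagonal couplings by τ ratios.  Two routes are implemented:

- **Exact solve.** z_i is eliminated with the first quadratic, leaving a
  quartic in z_e solved with `numpy.roots`; among the real roots, the one
  with both rates non-negative is selected (over the parameter ranges
  explored there is exactly one; ties are broken toward the order-2
  expansion) and polished with three Newton steps on the 2-D system.
  Residuals are at machine precision (< 1e−12 guaranteed, ~1e−17
  typical).  Root enumeration rather than a seeded Newton matters at
  large DC currents, where a local solver started from the balanced
  expansion converges to unphysical branches.  A fixed point can
  genuinely fail to exist at small K (the balanced branch is
  annihilated); this raises a "no physical fixed point" error rather
  than returning a spurious root.
- **ε-expansion.** Writing R̄ = Σ ε^k R̄_k with ε = 1/√K, each order
  solves the same 2×2 linear balance system with source terms built from
  lower orders (order 0: the DC currents; order 1: V̄² − (π z₀)²; order
  n ≥ 2: −π² Σ_{k<n} z_k z_{n−1−k}).  The recursion was re-derived from
  the stationary system directly; its order-1 consistency identity,
  τ(g₀(ee)R̄₁(e) − g₀(ei)R̄₁(i)) = (πR̄₀(e)τ)² − V̄(e)², is enforced in
  the tests at 1e−12 as an independent oracle.  The series is
  asymptotic: coefficients grow quickly (|R̄₃| ≫ |R̄₂| at the canonical
  couplings), so low orders are accurate for K ≳ 10⁴ but the error gain
  per order is not uniformly a factor ε.

Effective currents are I_eff(α) = √K[I₀(α) + τ_α(g₀(αe)R_e − g₀(αi)R_i)];
their K → ∞ limits follow from the first-order coefficients.  Current
fluctuations use a Poissonian shot-noise estimate with the square root,
ΔI_α = √(τ_α[(g₀(αe))²R_e + (g₀(αi))²R_i]): each neuron receives ~K
independent trains of variance-per-time (g₀/√K)²·R each, and the K's
cancel.

### Linear stability and Hopf location

The 4×4 Jacobian is evaluated analytically at the fixed point and
diagonalized numerically.  Classification: stable/unstable from the sign
of the maximal real part; node vs focus from whether the *leading*
eigenvalue is real or complex.  The large-K reduced linearization keeps
only the 2R̄₀δV terms in the rate rows and the √K coupling terms in the
potential rows; it is diagonalized numerically (its printed closed-form
counterpart is used only as a scaling statement, |Λ| ∝ K^¼ and, with
both DC currents scaled together, Im Λ ∝ √I₀ — both recovered by the
tests with fitted slopes within ±0.02).

Hopf points: bisection on the sign of the maximal eigenvalue real part
as a function of the control parameter, re-solving the exact fixed point
at every step; 60 iterations max, relative tolerance 1e−6, crossing
confirmed as Hopf by |Im Λ| > 1e−6.  When the control is I₀(e), I₀(i)
follows so that the current ratio of the input parameter set (canonically
1.02) is preserved.

### Integration, Lyapunov spectra, regime classification

RK4 with fixed dt = 0.01 ms is the reference protocol for the neural
mass model.  Negative round-off in the rates is clipped at zero and
counted (failure if clips exceed 0.1% of steps).  A trajectory is
declared escaped when |V| or τ_m·R exceeds 1e6; this is a real feature
of the model (beyond saddle-node-of-limit-cycle boundaries the membrane
potential runs away in finite time), verified against an adaptive
implicit integrator at tight tolerance, not a stiffness artifact.

Lyapunov spectra follow the standard tangent-space recipe: four
orthonormal vectors propagated by the linearized flow along the
reference orbit (same RK4 stages), modified Gram–Schmidt
re-orthonormalization every 10 steps, exponents from the mean log
stretch.  Defaults: 200 s of averaging after a 10 s state transient,
tangent frame drawn from an explicit seed.  The first half of the
averaging window is treated as tangent-alignment transient and excluded
from the reported `exponents` (removing the O(1/T) bias that otherwise
masks the neutral exponent of a limit cycle); the plain full-window
average is kept as `exponents_full`.  At a stable focus the spectrum
reproduces the Jacobian eigenvalue real parts to better than 1e−3 per
τ_m.

The chaotic reference point of the period-doubling cut (I₀(e) = 0.00021,
Δ₀(ee) = 2.0, Δ₀(ii) = 0.3, K = 1000) deserves a caveat: it lies close
to a periodic window.  Over the standard 200 s window the full Benettin
average gives λ₁ ≈ 0.0037 per τ_m, independent of the tangent seed; over
much longer windows, or from other initial states, the trajectory is
eventually captured by a nearby periodic orbit and the finite-time
exponent drifts toward zero.  Reported chaotic exponents are therefore
protocol-defined finite-window quantities (protocol stated above).

Regime classification: a stable fixed point is a node (III) or focus
(II) by its leading eigenvalues; otherwise the trajectory is integrated
and the tail-averaged spectrum decides — escape ⇒ unstable focus (I),
λ₁ > 1e−3/τ_m ⇒ chaos (V), |λ₁| ≤ 1e−3/τ_m ⇒ stable limit cycle (IV).
The classifier does not search for the unstable limit cycle coexisting
with the stable focus in region II, nor for bistability; with the
default 100 s window the λ₁ threshold cleanly separates the reference
limit-cycle and chaotic attractors, shorter windows risk
misclassification.

### Peak maps and burst delays

Peak maps collect post-transient local maxima of R_e (2% prominence
floor).  Two counts are reported: *clusters* (maxima merged within 0.5%
relative distance; counts the branches of a period-doubling cascade,
with at least 200 maxima required before chaotic band counting) and
*bands* (gaps exceeding 3% of the total spread of maxima; insensitive to
the within-band continuum of a chaotic attractor — an order of magnitude
above the clustering tolerance).  Near the bifurcation points critical
slowing makes cluster counts sensitive to the transient length; the
default scans discard 30 s.

Burst delays pair each inhibitory rate peak with the closest preceding
excitatory peak and average the per-cycle delays circularly over the
oscillation period, so the estimator lands in (−P/2, P/2] and is
antisymmetric under swapping the traces.  At the PING-like reference
oscillation (I₀(e) = 0.0009 on the period-doubling cut) the peak-to-peak
delay is ≈ 14.5 ms with ≈ 0.05 ms cycle-to-cycle dispersion; measured at
the rising 20%-of-range crossings instead, the same waveform gives
≈ 28 ms — onset-style and peak-style delay definitions differ by almost
a factor two on these wide excitatory bursts, so any quoted delay must
name its definition.  The oscillatory window in τ_m(i) at these
parameters is narrow (≈ 18.9–20.3 ms): below it the focus is stable,
above it the limit cycle is destroyed by escape.  `ping_delay_mf`
reports the peak-to-peak definition and raises "not oscillatory" when
the rate modulation falls below 0.1% of the mean.

## Spiking network

Euler integration (desk-scale default dt = 1e−3 ms, configurable down to
the reference 1e−4 ms).  The spike/reset excursion through ±∞ is
approximated by a finite threshold v_peak = 100: crossing registers a
spike, resets to −v_peak and holds the neuron for 2τ_m/v_peak ms — the
time the exact QIF solution spends beyond ±v_peak — during which inputs
are discarded and the neuron is excluded from mean-potential samples.
With this convention an uncoupled neuron reproduces the closed-form rate
√c/(πτ_m) to better than 1%.

Pulse amplitude: the default jump per presynaptic spike is g₀/√K
(`pulse_factor = 1`), the unique choice consistent with the neural mass
drive; `pulse_factor = 2` is available for the alternative δ-pulse
normalization in which the jump is 2g₀/√K.  Pulses are delivered at the
step after emission (δ-pulses under Euler have no canonical within-step
placement; next-step delivery is deterministic and order-independent).
Initial potentials are uniform in [−v_peak/10, v_peak/10] from an
explicit seed.

Wiring: within-population in-degrees are inverse-CDF Lorentzian draws
(median K, HWHM Δ₀√K) rounded to the nearest integer and
rejection-resampled into [1, N−1]; cross-population in-degrees are
exactly K; partners drawn uniformly without replacement, no
self-connections.  Note the truncation asymmetry: at small K a sizeable
fraction of the lower Lorentzian tail is rejected, so the realized
median exceeds K — one reason the finite-K network sits above the
quenched-disorder mean field (below).

## What the desk-scale runs show — and what they do not

The package's test battery runs the network at K = 256 with N = 2560 per
population for 20 s (plus smaller sanity sizes), not at the
publication-scale K ≈ 16000, N up to 8·10⁴, T = 100 s, which the config
system supports but which exceeds a desk budget by orders of magnitude.
At K = 256 the asynchronous-regime network rates agree with the exact
mean-field fixed point within 15% (excitatory ≈ 11–14% high, inhibitory
within ~3%), and the microscopic structure is as expected: silent
neurons are 3–8% of each population and concentrate entirely in the
correct in-degree tails (low k_ee for excitatory, high k_ii for
inhibitory; sign tests p ≪ 0.01), with ISI CVs ≈ 0.1–0.2.

The excitatory excess is a genuine finite-K effect, not a solver
artifact: it *grows* when N is raised at fixed K (≈ 25% at K = 16 with
N = 160, ≈ 36% with N = 2500), because the mean field treats the
in-degree disorder as full-line Lorentzian quenched coupling disorder
while the network truncates the tails and its high-k_ee outliers are
strongly mean-driven.  Agreement within 15% for the excitatory
population should therefore not be expected below K ≈ 100.  Desk-scale
passing says nothing about the N ≫ K ≫ 1 asymptotics of collective
oscillations, which require the publication-scale runs.

## Seeds and reproducibility

Every stochastic ingredient (wiring, initial potentials, tangent frames)
takes an explicit seed; fixtures refuse to run without one.  Identical
configs produce byte-identical result files; the workbench writes a
manifest (config hash, package version, wall time, collected warnings)
alongside every result set.
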