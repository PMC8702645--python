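# qifbalance

Balanced excitatory–inhibitory networks of quadratic integrate-and-fire
(QIF) neurons, and the exact low-dimensional neural mass model that
describes them — with the analysis toolbox needed to map their dynamical
regimes: asynchronous balanced states, PING-like and fluctuation-driven
collective oscillations, period-doubling cascades, and collective chaos.

It is written for computational neuroscientists who want a desk-scale,
fully reproducible implementation of this class of models: every quantity
(stationary rates, effective currents, bifurcation points, Lyapunov
spectra, spike-train statistics) is computed by code in this package, with
seeds explicit everywhere.

## The model

Two sparse populations of *N*(e) excitatory and *N*(i) inhibitory QIF
neurons, `τ_m v̇ = v² + I`, pulse-coupled by instantaneous δ-synapses.
Each neuron receives exactly *K* connections from the other population and
a Lorentzian-distributed number (median *K*, half-width Δ₀√K) from its
own — the structural heterogeneity.  Couplings scale as g₀/√K and the DC
drive as √K·I₀, the classic balanced scaling: excitation and inhibition
cancel to O(1) effective currents.

Because the in-degree disorder is Lorentzian, the network admits an
*exact* neural mass reduction in terms of each population's firing rate
*R* and mean membrane potential *V* (α ∈ {e, i}, β the other population):

    τ_m Ṙ(α) = R(α) [ 2 V(α) + g₀(αα) Δ₀(αα) / π ]
    τ_m V̇(α) = V(α)² − (π R(α) τ_m)² + √K [ I₀(α) + (g₀(αe) R(e) − g₀(αi) R(i)) τ_m ]

The package implements, on top of these four ODEs:

- **Stationary balanced states** — the mean potentials are pinned by the
  heterogeneity, V̄(α) = −g₀(αα)Δ₀(αα)/2π; the rates solve a quadratic
  system, solved exactly (quartic resultant + Newton polish) and as a
  power series in ε = 1/√K whose leading order is the classic balanced
  rate solution and whose first order gives the asymptotic effective
  currents.
- **Linear stability** — the 4×4 Jacobian, its eigenvalues, the large-K
  reduced system (eigenfrequencies ∝ K^¼ and ∝ √I₀), and Hopf-point
  location by bisection with the fixed point re-solved at every step.
- **Nonlinear dynamics** — RK4 integration, Benettin Lyapunov spectra,
  peak-map bifurcation diagrams, burst-delay measurement, and a regime
  classifier (stable node / stable focus / limit cycle / chaos / escape).
- **The spiking network itself** — numba-compiled Euler integration with
  δ-pulse coupling and finite-threshold spike handling, spike rasters,
  population traces, and per-neuron effective-current accounting.
- **Observables** — coherence ρ, ISI CV, rate distributions with
  log-normal fits, averaged power spectra with fundamental-frequency and
  p:q locking detection.

## Worked example

The canonical asynchronous parameter set (g₀(ee)=0.27, g₀(ii)=0.953939,
g₀(ie)=0.3, g₀(ei)=0.96286, I₀(e)=0.2, I₀(i)=I₀(e)/1.02, Δ₀(ee)=2.5,
Δ₀(ii)=1, τ_m=20 ms) at K = 4096:

```
$ qifbalance mf fixed-point --K 4096
{
 "R_bar_e_hz": 9.672945231154785,
 "R_bar_i_hz": 12.807813231232359,
 "V_bar_e": -0.10742958658702936,
 "V_bar_i": -0.15182410725813955,
 "balance_warning": false,
 "method": "exact-solve",
 "residual": 4.5102810375396984e-17
}
```

The exact stationary rates at this finite K (9.67 and 12.81 Hz) lie above
their K → ∞ balanced limits because the ε = 1/√K corrections are still
sizeable; the mean potentials are fixed purely by the structural
heterogeneity and are sub-threshold (negative).  The headline analytic
quantities of this parameter family:

```
$ qifbalance reproduce --fast
{
 "asymptotic_current_e": 0.028436951402527333,
 "asymptotic_current_i": 0.47909449884763256,
 "balanced_rate_e_hz": 3.182226074810403,
 "balanced_rate_i_hz": 11.27806850445424,
 "current_fluctuation_e": 0.4623391524502225,
 "current_fluctuation_i": 0.4593351358618543,
 "focus_eig_re_fast_per_tau": -0.101531,
 "focus_eig_re_slow_per_tau": -0.02996,
 "hopf_pd_cut_lower_I0e": 0.0014597615510225292,
 "hopf_pd_cut_upper_I0e": 50.64858365058899,
 "hopf_subcritical_I0e": 74.20862913131714
}
```

Reading this: in the K → ∞ limit the populations settle at 3.18 Hz (E)
and 11.28 Hz (I); the excitatory population sits essentially at threshold
(asymptotic effective current ≈ 0.028) while the inhibitory one is
supra-threshold (≈ 0.479); the Poissonian input-current fluctuations
(≈ 0.46) are comparable to or larger than the mean drive, so the bulk of
the neurons is fluctuation-driven.  On the period-doubling cut
(Δ₀(ee)=2.0, Δ₀(ii)=0.3, K=1000) the stable focus exists for
0.00146 < I₀(e) < 50.65, losing stability at a super-critical Hopf below
and at the focus boundary above; on the Δ₀(ee)=1.58 cut a sub-critical
Hopf destabilizes the focus at I₀(e) ≈ 74.21.  Eigenvalue real parts are
quoted per membrane time constant (multiply by 1/τ_m for 1/ms).

Dropping `--fast` adds the Benettin Lyapunov spectrum of the chaotic
attractor at I₀(e) = 0.00021 on the same cut (λ₁ ≈ 0.0037 per τ_m over
the standard 200 s window) — about half a minute of compute.

## Package layout

- `qifbalance.params` — `ModelParams`, validation, balance feasibility.
- `qifbalance.mean_field` — stationary states, rate expansion, stability,
  Hopf bisection, RK4/Lyapunov/peak-map/regime machinery.
- `qifbalance.network` — Lorentzian in-degree sampling, wiring, the Euler
  simulator, per-neuron effective currents.
- `qifbalance.observables` — ρ, CV, rate traces and distributions, power
  spectra, fundamentals/locking, burst delays.
- `qifbalance.workbench` — YAML configs, canonical per-figure fixtures,
  scan orchestration with manifests.
- CLI: `qifbalance mf|net|obs|reproduce|run` (see `--help`).

See `docs/methods.md` for the numerical conventions, parameter defaults
and known limitations.
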