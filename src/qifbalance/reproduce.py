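"""Headline quantities of the balanced E-I study, recomputed from scratch.

Each function runs the package's own machinery on the canonical parameter
sets (couplings g0_ee = 0.27, g0_ii = 0.953939, g0_ie = 0.3,
g0_ei = 0.96286, I0_i = I0_e / 1.02, tau_m = 20 ms) and returns plain
floats.  ``headline_results`` bundles everything into one dict keyed by
descriptive names; eigenvalues and Lyapunov exponents are reported per
membrane time constant (lambda * tau_m), the convention used throughout
the study's tables.
"""

from __future__ import annotations

import numpy as np

from .mean_field import (
    asymptotic_effective_currents,
    current_fluctuations,
    find_hopf,
    jacobian_eigenvalues,
    lyapunov_spectrum,
    rate_expansion,
    stationary_state,
)
from .params import HZ_PER_INV_MS, ModelParams

__all__ = [
    "asynchronous_params",
    "pd_cut_params",
    "subcritical_cut_params",
    "balanced_rates_hz",
    "asymptotic_currents",
    "fluctuation_amplitudes",
    "hopf_points",
    "focus_eigenvalue_real_parts",
    "chaotic_lyapunov",
    "headline_results",
]


def asynchronous_params(K: float = 1000.0) -> ModelParams:
    """The asynchronous-regime parameter set (I0_e = 0.2, d_ee = 2.5, d_ii = 1)."""
    return ModelParams(K=K)


def pd_cut_params(I0_e: float = 0.0009, K: float = 1000.0) -> ModelParams:
    """The period-doubling cut (delta0_ee = 2.0, delta0_ii = 0.3)."""
    return ModelParams(
        I0_e=I0_e, I0_i=I0_e / 1.02, K=K, delta0_ee=2.0, delta0_ii=0.3
    )


def subcritical_cut_params(I0_e: float = 0.128, K: float = 1000.0) -> ModelParams:
    """The sub-critical Hopf cut (delta0_ee = 1.58, delta0_ii = 0.3)."""
    return ModelParams(
        I0_e=I0_e, I0_i=I0_e / 1.02, K=K, delta0_ee=1.58, delta0_ii=0.3
    )


def balanced_rates_hz() -> tuple[float, float]:
    """Zeroth-order (K -> infinity) balanced rates, in Hz."""
    exp = rate_expansion(asynchronous_params(), 0)
    r_e, r_i = exp.partial_sum(0)
    return r_e * HZ_PER_INV_MS, r_i * HZ_PER_INV_MS


def asymptotic_currents() -> tuple[float, float]:
    """Asymptotic effective input currents from the first-order expansion."""
    return asymptotic_effective_currents(asynchronous_params())


def fluctuation_amplitudes() -> tuple[float, float]:
    """Poissonian current-fluctuation amplitudes at the balanced rates."""
    p = asynchronous_params()
    exp = rate_expansion(p, 0)
    r_e, r_i = exp.partial_sum(0)
    return current_fluctuations(p, r_e, r_i)


def hopf_points() -> dict[str, float]:
    """The three Hopf crossings located by eigenvalue bisection."""
    pd = pd_cut_params()
    sub = subcritical_cut_params()
    return {
        "pd_cut_lower": find_hopf(pd, "I0_e", (1e-5, 1e-2)).value,
        "pd_cut_upper": find_hopf(pd, "I0_e", (1.0, 100.0)).value,
        "subcritical": find_hopf(sub, "I0_e", (10.0, 100.0)).value,
    }


def focus_eigenvalue_real_parts(I0_e: float = 0.006) -> tuple[float, float]:
    """Real parts of the two conjugate pairs at the stable focus, per tau_m.

    Returns (slow, fast) = the larger and smaller real part multiplied by
    the membrane time constant.
    """
    p = pd_cut_params(I0_e)
    fp = stationary_state(p, "exact")
    spec = jacobian_eigenvalues(p, fp)
    re = np.unique(np.round(spec.eigenvalues.real * p.tau_m_e, 6))
    return float(re.max()), float(re.min())


def chaotic_lyapunov(I0_e: float = 0.00021, seed: int = 0, T: float = 200_000.0):
    """Lyapunov spectrum on the chaotic attractor of the PD cut, per tau_m.

    Reports the plain full-window Benettin average over the standard
    protocol (dt = 0.01 ms, 200 s after a 10 s transient): the chaotic
    point sits close to a periodic window and its finite-time exponent is a
    protocol-defined quantity.
    """
    p = pd_cut_params(I0_e)
    lyap = lyapunov_spectrum(p, T=T, seed=seed)
    return lyap.exponents_full * p.tau_m_e


def headline_results(seed: int = 0, include_slow: bool = True) -> dict:
    """All headline quantities as a flat dict of floats."""
    r_e, r_i = balanced_rates_hz()
    ia_e, ia_i = asymptotic_currents()
    di_e, di_i = fluctuation_amplitudes()
    out = {
        "balanced_rate_e_hz": r_e,
        "balanced_rate_i_hz": r_i,
        "asymptotic_current_e": ia_e,
        "asymptotic_current_i": ia_i,
        "current_fluctuation_e": di_e,
        "current_fluctuation_i": di_i,
    }
    hopf = hopf_points()
    out["hopf_pd_cut_lower_I0e"] = hopf["pd_cut_lower"]
    out["hopf_pd_cut_upper_I0e"] = hopf["pd_cut_upper"]
    out["hopf_subcritical_I0e"] = hopf["subcritical"]
    lam_slow, lam_fast = focus_eigenvalue_real_parts()
    out["focus_eig_re_slow_per_tau"] = lam_slow
    out["focus_eig_re_fast_per_tau"] = lam_fast
    if include_slow:
        les = chaotic_lyapunov(seed=seed)
        out["chaos_lambda1_per_tau"] = float(les[0])
        out["chaos_lambda2_per_tau"] = float(les[1])
    return out
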