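"""Stationary solutions of the two-population neural mass model.

The 4-D neural mass model for the balanced E-I QIF network reads (time in
ms, rates in 1/ms, alpha in {e, i}, beta the other population)::

    tau_a dR_a/dt = R_a * (2 V_a + g0_aa * delta0_aa / pi)
    tau_a dV_a/dt = V_a^2 - (pi R_a tau_a)^2
                    + sqrt(K) * [I0_a + (g0_ae R_e - g0_ai R_i) * tau_a]

Its fixed points have mean potentials fixed purely by the structural
heterogeneity, ``V_a = -g0_aa * delta0_aa / (2 pi)``, while the stationary
rates solve a pair of coupled quadratics.  For large K the rates admit a
power series in ``eps = 1/sqrt(K)`` whose leading order is the classic
balanced-state rate solution; the first-order coefficients give the
asymptotic effective currents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .._kernels import mf_rhs, pack_params
from ..params import HZ_PER_INV_MS, ModelParams

__all__ = [
    "MacroState",
    "FixedPoint",
    "ExpansionCoeffs",
    "mf_derivative",
    "rate_expansion",
    "stationary_state",
    "effective_currents",
    "asymptotic_effective_currents",
    "current_fluctuations",
]


@dataclass(frozen=True)
class MacroState:
    """Instantaneous macroscopic state (rates in 1/ms, potentials unitless)."""

    R_e: float
    V_e: float
    R_i: float
    V_i: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R_e, self.V_e, self.R_i, self.V_i])

    @classmethod
    def from_array(cls, y) -> "MacroState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    @property
    def rates_hz(self) -> tuple[float, float]:
        return self.R_e * HZ_PER_INV_MS, self.R_i * HZ_PER_INV_MS


@dataclass(frozen=True)
class FixedPoint:
    """A stationary solution of the neural mass model.

    Rates are stored in 1/ms (`R_bar_e`, `R_bar_i`); `rates_hz` converts.
    `method` records how the rates were obtained: "exact-solve" or
    "expansion(order m)".  `residual` is the max-norm of the stationary rate
    equations at the solution and `balance_warning` is set when the
    zeroth-order balance inequalities fail.
    """

    V_bar_e: float
    V_bar_i: float
    R_bar_e: float
    R_bar_i: float
    method: str
    residual: float
    balance_warning: bool = False

    @property
    def rates_hz(self) -> tuple[float, float]:
        return self.R_bar_e * HZ_PER_INV_MS, self.R_bar_i * HZ_PER_INV_MS

    def as_state(self) -> MacroState:
        return MacroState(self.R_bar_e, self.V_bar_e, self.R_bar_i, self.V_bar_i)

    def to_dict(self) -> dict:
        return {
            "V_bar_e": self.V_bar_e,
            "V_bar_i": self.V_bar_i,
            "R_bar_e_hz": self.R_bar_e * HZ_PER_INV_MS,
            "R_bar_i_hz": self.R_bar_i * HZ_PER_INV_MS,
            "method": self.method,
            "residual": self.residual,
            "balance_warning": self.balance_warning,
        }


@dataclass(frozen=True)
class ExpansionCoeffs:
    """Coefficients of the 1/sqrt(K) rate expansion.

    ``coeffs_e[k]`` and ``coeffs_i[k]`` are the order-k rate coefficients in
    1/ms; the physical rate at in-degree K is ``sum_k eps^k coeffs[k]`` with
    ``eps = 1/sqrt(K)``.
    """

    coeffs_e: np.ndarray
    coeffs_i: np.ndarray
    eps: float

    def partial_sum(self, order: int | None = None) -> tuple[float, float]:
        """Rates (1/ms) from the truncated series up to `order` inclusive."""
        if order is None:
            order = len(self.coeffs_e) - 1
        if order < 0 or order >= len(self.coeffs_e):
            raise ValueError(f"order must be in [0, {len(self.coeffs_e) - 1}]")
        powers = self.eps ** np.arange(order + 1)
        return (
            float(self.coeffs_e[: order + 1] @ powers),
            float(self.coeffs_i[: order + 1] @ powers),
        )

    @property
    def coeffs_e_hz(self) -> np.ndarray:
        return self.coeffs_e * HZ_PER_INV_MS

    @property
    def coeffs_i_hz(self) -> np.ndarray:
        return self.coeffs_i * HZ_PER_INV_MS


def mf_derivative(state: MacroState, params: ModelParams) -> MacroState:
    """Time derivative of the neural mass model at `state` (units 1/ms)."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    dy = mf_rhs(y, pack_params(params))
    return MacroState.from_array(dy)


def _coupling_matrix(params: ModelParams) -> np.ndarray:
    """Effective linear balance matrix in the variables z_a = R_a * tau_a.

    With distinct membrane constants the stationary system keeps the
    equal-tau structure after absorbing tau ratios into the off-diagonal
    couplings.
    """
    te, ti = params.tau_m_e, params.tau_m_i
    return np.array(
        [
            [params.g0_ee, -params.g0_ei * te / ti],
            [params.g0_ie * ti / te, -params.g0_ii],
        ]
    )


def rate_expansion(params: ModelParams, max_order: int = 2) -> ExpansionCoeffs:
    """Coefficients of the rate expansion in eps = 1/sqrt(K).

    Order by order, in z_a = R_a * tau_a the stationary system is linear
    with the same coupling matrix and source terms built from lower-order
    coefficients:

        order 0:  G z_0 = -I0
        order 1:  G z_1 = -(V_bar^2 - pi^2 z_0^2)        (per population)
        order n:  G z_n = pi^2 * sum_{k<n} z_k z_{n-1-k}  (n >= 2)
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    G = _coupling_matrix(params)
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    if abs(det) < 1e-14:
        raise ValueError("degenerate coupling matrix")
    vbar2 = np.array([params.v_bar_e**2, params.v_bar_i**2])
    z: list[np.ndarray] = []
    for n in range(max_order + 1):
        if n == 0:
            N = np.array([params.I0_e, params.I0_i])
        elif n == 1:
            N = vbar2 - np.pi**2 * z[0] ** 2
        else:
            N = -(np.pi**2) * sum(z[k] * z[n - 1 - k] for k in range(n))
        z.append(np.linalg.solve(G, -N))
    zs = np.array(z)
    taus = np.array([params.tau_m_e, params.tau_m_i])
    coeffs = zs / taus
    return ExpansionCoeffs(
        coeffs_e=coeffs[:, 0], coeffs_i=coeffs[:, 1], eps=1.0 / params.sqrt_K
    )


def _exact_rates(params: ModelParams) -> tuple[float, float]:
    """Exact stationary rates (1/ms) via the quartic resultant.

    The second quadratic is reduced to a quartic in z_e = R_e * tau_e by
    eliminating z_i with the first; among the real roots exactly one has
    both rates non-negative on the balanced branch (verified over the
    explored parameter ranges); if several qualify, the one closest to the
    order-2 expansion is taken.  The root is polished by two Newton steps on
    the full 2-D system.
    """
    eps = 1.0 / params.sqrt_K
    vbe2, vbi2 = params.v_bar_e**2, params.v_bar_i**2
    te, ti = params.tau_m_e, params.tau_m_i
    gee, gei, gie, gii = params.g0_ee, params.g0_ei, params.g0_ie, params.g0_ii
    # eq1 in z-variables: gee*ze - gei*(te/ti)*zi + I0e - eps*(pi^2 ze^2 - vbe2) = 0
    c = gei * te / ti
    a2 = -eps * np.pi**2 / c
    a1 = gee / c
    a0 = (params.I0_e + eps * vbe2) / c
    zi_poly = np.array([a2, a1, a0])
    poly = -eps * np.pi**2 * np.polymul(zi_poly, zi_poly)
    poly[-3:] += -gii * zi_poly
    poly[-2] += gie * ti / te
    poly[-1] += params.I0_i + eps * vbi2
    roots = np.roots(poly)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    cands = []
    for ze in real:
        zi = np.polyval(zi_poly, ze)
        if ze >= -1e-12 and zi >= -1e-12:
            cands.append((max(ze, 0.0), max(zi, 0.0)))
    if not cands:
        raise ValueError("no physical fixed point")
    if len(cands) > 1:
        exp = rate_expansion(params, 2)
        guess = np.array(exp.partial_sum(2)) * np.array([te, ti])
        cands.sort(key=lambda zz: (zz[0] - guess[0]) ** 2 + (zz[1] - guess[1]) ** 2)
    ze, zi = cands[0]
    # Newton polish on the 2-D system
    for _ in range(3):
        f = np.array(
            [
                gee * ze - c * zi + params.I0_e - eps * (np.pi**2 * ze**2 - vbe2),
                gie * (ti / te) * ze - gii * zi + params.I0_i - eps * (np.pi**2 * zi**2 - vbi2),
            ]
        )
        J = np.array(
            [
                [gee - 2 * eps * np.pi**2 * ze, -c],
                [gie * ti / te, -gii - 2 * eps * np.pi**2 * zi],
            ]
        )
        step = np.linalg.solve(J, -f)
        ze, zi = ze + step[0], zi + step[1]
    if ze < 0 or zi < 0:
        raise ValueError("no physical fixed point")
    return ze / te, zi / ti


def _stationary_residual(params: ModelParams, r_e: float, r_i: float) -> float:
    """Max-norm of the stationary rate equations at (r_e, r_i) [1/ms]."""
    eps = 1.0 / params.sqrt_K
    te, ti = params.tau_m_e, params.tau_m_i
    f1 = (
        (params.g0_ee * r_e - params.g0_ei * r_i) * te
        + params.I0_e
        - eps * ((np.pi * r_e * te) ** 2 - params.v_bar_e**2)
    )
    f2 = (
        (params.g0_ie * r_e - params.g0_ii * r_i) * ti
        + params.I0_i
        - eps * ((np.pi * r_i * ti) ** 2 - params.v_bar_i**2)
    )
    return float(max(abs(f1), abs(f2)))


def stationary_state(
    params: ModelParams, method: str = "exact", order: int = 1
) -> FixedPoint:
    """Stationary solution of the neural mass model.

    Parameters
    ----------
    method
        "exact" solves the full quadratic system; "expansion" truncates the
        1/sqrt(K) series at `order`.
    """
    warn = not params.is_balance_feasible()
    if method == "exact":
        r_e, r_i = _exact_rates(params)
        tag = "exact-solve"
    elif method == "expansion":
        exp = rate_expansion(params, order)
        r_e, r_i = exp.partial_sum(order)
        if r_e < 0 or r_i < 0:
            raise ValueError("no physical fixed point")
        tag = f"expansion(order {order})"
    else:
        raise ValueError(f"unknown method {method!r}")
    return FixedPoint(
        V_bar_e=params.v_bar_e,
        V_bar_i=params.v_bar_i,
        R_bar_e=r_e,
        R_bar_i=r_i,
        method=tag,
        residual=_stationary_residual(params, r_e, r_i),
        balance_warning=warn,
    )


def effective_currents(
    params: ModelParams, r_e: float, r_i: float
) -> tuple[float, float]:
    """Population effective input currents at rates (r_e, r_i) in 1/ms.

    I_eff_a = sqrt(K) * [I0_a + tau_a * (g0_ae R_e - g0_ai R_i)].
    """
    if r_e < 0 or r_i < 0:
        raise ValueError("rates must be non-negative")
    sk = params.sqrt_K
    ie = sk * (params.I0_e + params.tau_m_e * (params.g0_ee * r_e - params.g0_ei * r_i))
    ii = sk * (params.I0_i + params.tau_m_i * (params.g0_ie * r_e - params.g0_ii * r_i))
    return float(ie), float(ii)


def asymptotic_effective_currents(params: ModelParams) -> tuple[float, float]:
    """K -> infinity effective currents from the first-order coefficients.

    Ia_a = tau_a * (g0_ae R1_e - g0_ai R1_i); equivalently
    Ia_a = (pi R0_a tau_a)^2 - V_bar_a^2.
    """
    exp = rate_expansion(params, 1)
    r1e, r1i = exp.coeffs_e[1], exp.coeffs_i[1]
    ia_e = params.tau_m_e * (params.g0_ee * r1e - params.g0_ei * r1i)
    ia_i = params.tau_m_i * (params.g0_ie * r1e - params.g0_ii * r1i)
    return float(ia_e), float(ia_i)


def current_fluctuations(
    params: ModelParams, r_e: float, r_i: float
) -> tuple[float, float]:
    """Poissonian estimate of input-current fluctuation amplitudes.

    Each neuron receives ~K independent Poisson trains per population at
    rates (R_e, R_i); the shot-noise variance of the resulting current gives

        dI_a = sqrt( tau_a * [(g0_ae)^2 R_e + (g0_ai)^2 R_i] ).
    """
    if r_e < 0 or r_i < 0:
        raise ValueError("rates must be non-negative")
    de = math.sqrt(params.tau_m_e * (params.g0_ee**2 * r_e + params.g0_ei**2 * r_i))
    di = math.sqrt(params.tau_m_i * (params.g0_ie**2 * r_e + params.g0_ii**2 * r_i))
    return de, di
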