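"""Linear stability of the neural mass fixed points.

The 4x4 Jacobian of the neural mass flow evaluated at a fixed point yields
four eigenvalues (units 1/ms).  Because the characteristic polynomial is
real they occur as reals or conjugate pairs; a nonzero imaginary pair makes
the fixed point a focus whose relaxation frequency ``Im(L)/2pi`` predicts
the frequency of fluctuation-driven collective oscillations in the sparse
network.  For K >> 1 the linearization reduces to a zero-trace system built
from the zeroth-order balanced rates, giving |L| ~ K^(1/4) and, when both
DC currents are scaled together, a relaxation frequency ~ sqrt(I0_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._kernels import mf_jacobian, pack_params
from ..params import HZ_PER_INV_MS, ModelParams
from .stationary import FixedPoint, rate_expansion, stationary_state

__all__ = [
    "EigenSpectrum",
    "jacobian_matrix",
    "jacobian_eigenvalues",
    "largeK_eigenvalues",
    "find_hopf",
    "HopfPoint",
]

#: residual above which a candidate state is rejected as "not a fixed point"
FP_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues of the linearized neural mass flow at a fixed point.

    `eigenvalues` are sorted by descending real part, units 1/ms.
    `fp_class` is one of "stable node", "stable focus", "unstable focus",
    "saddle-like".  `relaxation_frequencies_hz` are the distinct positive
    values of Im(L)/(2 pi), in Hz.
    """

    eigenvalues: np.ndarray
    fp_class: str

    @property
    def max_real_part(self) -> float:
        return float(self.eigenvalues.real.max())

    @property
    def is_stable(self) -> bool:
        return self.max_real_part < 0

    @property
    def is_focus(self) -> bool:
        return bool(np.any(np.abs(self.eigenvalues.imag) > 1e-12))

    @property
    def relaxation_frequencies_hz(self) -> np.ndarray:
        pos = np.sort(np.unique(np.round(self.eigenvalues.imag[self.eigenvalues.imag > 1e-12], 12)))
        return pos / (2.0 * np.pi) * HZ_PER_INV_MS

    def to_dict(self) -> dict:
        return {
            "eigenvalues_re_per_ms": self.eigenvalues.real.tolist(),
            "eigenvalues_im_per_ms": self.eigenvalues.imag.tolist(),
            "fp_class": self.fp_class,
            "relaxation_frequencies_hz": self.relaxation_frequencies_hz.tolist(),
        }


def _classify(ev: np.ndarray) -> str:
    stable = ev.real.max() < 0
    # leading = eigenvalue(s) with largest real part
    lead = ev[np.argmax(ev.real)]
    focus_lead = abs(lead.imag) > 1e-12
    if stable and not focus_lead:
        return "stable node"
    if stable:
        return "stable focus"
    if focus_lead:
        return "unstable focus"
    return "saddle-like"


def _sorted_spectrum(ev: np.ndarray) -> EigenSpectrum:
    order = np.argsort(-ev.real)
    ev = ev[order]
    return EigenSpectrum(eigenvalues=ev, fp_class=_classify(ev))


def jacobian_matrix(params: ModelParams, fp: FixedPoint) -> np.ndarray:
    """The 4x4 Jacobian at a fixed point, state order (R_e, V_e, R_i, V_i)."""
    return np.asarray(mf_jacobian(fp.as_state().as_array(), pack_params(params)))


def jacobian_eigenvalues(params: ModelParams, fp: FixedPoint) -> EigenSpectrum:
    """Eigenvalues of the linearization at `fp` (must solve the rate system)."""
    if fp.residual > FP_RESIDUAL_TOL:
        raise ValueError(f"not a fixed point (residual {fp.residual:.3g})")
    ev = np.linalg.eigvals(jacobian_matrix(params, fp))
    return _sorted_spectrum(ev)


def largeK_eigenvalues(params: ModelParams) -> EigenSpectrum:
    """Eigenvalues of the K >> 1 reduced linearization.

    In the large-K limit the rate rows retain only the 2*R0*dV terms and
    the potential rows only the sqrt(K)-coupling terms; the reduced matrix
    is built from the zeroth-order balanced rates and diagonalized
    numerically.
    """
    exp = rate_expansion(params, 0)
    r0e, r0i = exp.coeffs_e[0], exp.coeffs_i[0]
    if r0e <= 0 or r0i <= 0:
        raise ValueError("zeroth-order rates are not positive")
    sk = params.sqrt_K
    te, ti = params.tau_m_e, params.tau_m_i
    A = np.zeros((4, 4))
    A[0, 1] = 2.0 * r0e / te
    A[1, 0] = sk * params.g0_ee
    A[1, 2] = -sk * params.g0_ei
    A[2, 3] = 2.0 * r0i / ti
    A[3, 0] = sk * params.g0_ie
    A[3, 2] = -sk * params.g0_ii
    return _sorted_spectrum(np.linalg.eigvals(A))


@dataclass(frozen=True)
class HopfPoint:
    """A Hopf crossing located by bisection on the leading eigenvalue."""

    control: str
    value: float
    frequency_hz: float
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "value": self.value,
            "frequency_hz": self.frequency_hz,
            "n_iter": self.n_iter,
        }


def _with_control(params: ModelParams, control: str, value: float, ratio: float | None) -> ModelParams:
    changes = {control: value}
    if control == "I0_e" and ratio is not None:
        changes["I0_i"] = value / ratio
    return params.replace(**changes)


def find_hopf(
    params: ModelParams,
    control: str,
    bracket: tuple[float, float],
    rel_tol: float = 1e-6,
    max_iter: int = 60,
    lock_current_ratio: bool = True,
) -> HopfPoint:
    """Locate a Hopf bifurcation of the fixed point by bisection.

    Bisects `control` on the sign of the maximal real part of the Jacobian
    eigenvalues, re-solving the exact fixed point at every step.  When the
    control is ``I0_e`` and `lock_current_ratio` is set, ``I0_i`` follows so
    that the current ratio of the input `params` is preserved (the standard
    scan protocol).  The crossing is confirmed as a Hopf (nonzero imaginary
    part); a real-axis crossing raises "non-Hopf crossing".
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")
    ratio = params.I0_e / params.I0_i if (lock_current_ratio and params.I0_i != 0) else None

    def max_re(x: float) -> tuple[float, float]:
        p = _with_control(params, control, x, ratio)
        try:
            fp = stationary_state(p, "exact")
        except ValueError as err:
            raise ValueError("fixed point vanished inside bracket") from err
        spec = jacobian_eigenvalues(p, fp)
        lead = spec.eigenvalues[np.argmax(spec.eigenvalues.real)]
        return float(lead.real), float(abs(lead.imag))

    f_lo, _ = max_re(lo)
    f_hi, _ = max_re(hi)
    if f_lo == 0.0 or f_hi == 0.0 or np.sign(f_lo) == np.sign(f_hi):
        raise ValueError("no crossing: leading real part does not change sign in bracket")
    n = 0
    im_mid = 0.0
    for n in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid, im_mid = max_re(mid)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
        if (hi - lo) <= rel_tol * abs(hi):
            break
    crit = 0.5 * (lo + hi)
    if im_mid <= 1e-6:
        raise ValueError("non-Hopf crossing: leading eigenvalue is real at the crossing")
    return HopfPoint(
        control=control,
        value=float(crit),
        frequency_hz=im_mid / (2.0 * np.pi) * HZ_PER_INV_MS,
        n_iter=n,
    )
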