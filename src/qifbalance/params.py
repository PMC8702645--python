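"""Model parameters for the balanced E-I QIF network and its neural mass limit.

All couplings ``g0_ab`` and DC currents ``I0_e``, ``I0_i`` are the *rescaled*
quantities: the physical per-synapse coupling is ``g0_ab / sqrt(K)`` and the
physical DC drive is ``sqrt(K) * I0``, so that excitation and inhibition
balance to O(1) effective currents as the median in-degree ``K`` grows.

Index convention: ``g0_ab`` couples a *postsynaptic* population ``a`` to a
*presynaptic* population ``b`` (``g0_ei`` = inhibitory synapses onto
excitatory neurons).

Internal units: time in ms, rates in 1/ms.  Conversion to Hz happens only at
reporting boundaries (``HZ_PER_INV_MS``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

HZ_PER_INV_MS = 1000.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-population balanced network / neural mass model.

    Parameters
    ----------
    g0_ee, g0_ei, g0_ie, g0_ii
        Rescaled synaptic coupling magnitudes (dimensionless, all > 0).
        The signs are fixed by the architecture: ``e`` couplings are
        excitatory (depolarizing), ``i`` couplings inhibitory.
    I0_e, I0_i
        Rescaled DC currents onto the two populations.
    K
        Median in-degree.  Real-valued in the mean field; network builders
        require an integer value.
    delta0_ee, delta0_ii
        Structural heterogeneity scales: the within-population in-degrees are
        Lorentzian with median K and half-width ``delta0 * sqrt(K)``.
    tau_m_e, tau_m_i
        Membrane time constants in ms.
    """

    g0_ee: float = 0.27
    g0_ei: float = 0.96286
    g0_ie: float = 0.3
    g0_ii: float = 0.953939
    I0_e: float = 0.2
    I0_i: float = 0.2 / 1.02
    K: float = 1000.0
    delta0_ee: float = 2.5
    delta0_ii: float = 1.0
    tau_m_e: float = 20.0
    tau_m_i: float = 20.0

    def __post_init__(self) -> None:
        for name in ("g0_ee", "g0_ei", "g0_ie", "g0_ii", "K", "tau_m_e", "tau_m_i"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive number, got {v!r}")
        for name in ("delta0_ee", "delta0_ii"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("I0_e", "I0_i"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- derived quantities -------------------------------------------------

    @property
    def sqrt_K(self) -> float:
        return math.sqrt(self.K)

    @property
    def v_bar_e(self) -> float:
        """Stationary mean membrane potential of the excitatory population."""
        return -self.g0_ee * self.delta0_ee / (2.0 * math.pi)

    @property
    def v_bar_i(self) -> float:
        """Stationary mean membrane potential of the inhibitory population."""
        return -self.g0_ii * self.delta0_ii / (2.0 * math.pi)

    @property
    def coupling_determinant(self) -> float:
        """Determinant ``g0_ei*g0_ie - g0_ee*g0_ii`` of the balance system.

        Must be nonzero for the large-K rate expansion to exist.
        """
        return self.g0_ei * self.g0_ie - self.g0_ee * self.g0_ii

    def is_balance_feasible(self) -> bool:
        """Whether the K -> infinity balanced rates are both positive.

        The zeroth-order rates are positive iff the current ratio
        ``I0_e/I0_i`` sits on the same side of both coupling ratios
        ``g0_ei/g0_ii`` and ``g0_ee/g0_ie``:
        either  I0_e/I0_i > g0_ei/g0_ii > g0_ee/g0_ie
        or      I0_e/I0_i < g0_ei/g0_ii < g0_ee/g0_ie.
        """
        if self.I0_i == 0:
            return False
        ratio = self.I0_e / self.I0_i
        a = self.g0_ei / self.g0_ii
        b = self.g0_ee / self.g0_ie
        return (ratio > a > b) or (ratio < a < b)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
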