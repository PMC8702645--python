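"""Time integration and nonlinear diagnostics of the neural mass model.

All trajectories use fixed-step RK4 (default dt = 0.01 ms).  Lyapunov
spectra follow the classic tangent-space recipe: four orthonormal
perturbations evolve under the linearized flow along the reference orbit
and are re-orthonormalized at fixed intervals; the exponents are the mean
logarithmic stretch rates.  On top of these sit the bifurcation-scan tools:
peak maps (distinct local maxima of R_e versus a control parameter), the
E-to-I burst delay of PING-like oscillations, and a regime classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .._kernels import benettin_kernel, integrate_kernel, pack_params
from ..observables import burst_delay
from ..params import ModelParams
from ..records import TraceSet
from .stability import jacobian_eigenvalues
from .stationary import MacroState, stationary_state

__all__ = [
    "TraceSet",
    "final_state",
    "LyapunovResult",
    "RegimeLabel",
    "Regime",
    "TrajectoryEscape",
    "integrate_mf",
    "lyapunov_spectrum",
    "peak_map",
    "ping_delay_mf",
    "classify_regime",
]

#: relative tolerance grouping nearby maxima into one periodic cluster
PEAK_CLUSTER_RTOL = 5e-3
#: band breaks in a peak map: gaps larger than this fraction of the full
#: spread of maxima separate disjoint amplitude bands
PEAK_BAND_GAP_FRAC = 0.03
#: |lambda| below this (in 1/ms, ~1e-3 per tau_m at tau_m=20) counts as zero
LYAP_ZERO_TOL = 5e-5


class TrajectoryEscape(RuntimeError):
    """Raised when |V| or tau_m*R exceeds the overflow guard."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"trajectory escaped at t = {time_ms:.3f} ms")


def final_state(trace: TraceSet) -> MacroState:
    """The last sampled state of a trajectory."""
    return MacroState(
        float(trace.R_e[-1]), float(trace.V_e[-1]), float(trace.R_i[-1]), float(trace.V_i[-1])
    )


@dataclass(frozen=True)
class LyapunovResult:
    """Benettin Lyapunov spectrum (exponents in 1/ms, sorted descending).

    `exponents` averages the log stretch rates over the averaging window
    after dropping its first `discard_fraction` as tangent-alignment
    transient (removes the O(1/T) bias on attractors with a neutral
    direction); `exponents_full` is the plain full-window average.
    """

    exponents: np.ndarray
    exponents_full: np.ndarray
    dt: float
    T: float
    transient: float
    renorm_every: int
    seed: int
    discard_fraction: float = 0.5
    convergence: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def lambda_max(self) -> float:
        return float(self.exponents[0])

    def exponents_per_tau(self, tau_m: float) -> np.ndarray:
        """Exponents in units of the membrane time constant (dimensionless)."""
        return self.exponents * tau_m

    def to_dict(self) -> dict:
        return {
            "exponents_per_ms": self.exponents.tolist(),
            "exponents_full_per_ms": self.exponents_full.tolist(),
            "dt": self.dt,
            "T": self.T,
            "transient": self.transient,
            "renorm_every": self.renorm_every,
            "seed": self.seed,
            "discard_fraction": self.discard_fraction,
        }


class Regime(str, Enum):
    I_UNSTABLE_FOCUS = "I_unstable_focus"
    II_STABLE_FOCUS = "II_stable_focus"
    III_STABLE_NODE = "III_stable_node"
    IV_STABLE_LC = "IV_stable_LC"
    V_CHAOTIC = "V_chaotic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of the macroscopic solution at one parameter point.

    `co_class` is the corresponding collective-oscillation type of the
    finite network: "O_P" for mean-field limit cycles/chaos, "O_F" for
    fluctuation-sustained oscillations around a stable fixed point, "O_S"
    for the abnormally synchronized regime where the mean field has no
    stable solution.  The unstable limit cycle coexisting with a stable
    focus (region II) is not searched for.
    """

    regime: Regime
    co_class: str
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"regime": self.regime.value, "co_class": self.co_class, "detail": self.detail}


def _default_init(params: ModelParams) -> MacroState:
    """A generic off-attractor initial state with positive rates."""
    return MacroState(R_e=5e-3, V_e=-0.1, R_i=1e-2, V_i=-0.05)


def integrate_mf(
    params: ModelParams,
    init: MacroState | None = None,
    dt: float = 0.01,
    T: float = 1000.0,
    transient: float = 0.0,
    stride: int = 10,
    clip_fail_frac: float = 1e-3,
) -> TraceSet:
    """RK4 trajectory of the neural mass model.

    Integrates for `transient + T` ms and returns samples every
    `stride` steps after the transient.  Rates are clipped at zero when
    round-off drives them negative; more than `clip_fail_frac` of clipped
    steps raises (the step size is too large).  Escape raises
    TrajectoryEscape with the escape time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if transient < 0 or T <= 0:
        raise ValueError("need T > 0 and transient >= 0")
    if init is None:
        init = _default_init(params)
    y0 = init.as_array()
    if not np.all(np.isfinite(y0)):
        raise ValueError("non-finite state")
    if y0[0] < 0 or y0[2] < 0:
        raise ValueError("initial rates must be non-negative")
    n_steps = int(round((T + transient) / dt))
    n_skip = int(round(transient / dt))
    status, esc_step, n_clip, samples = integrate_kernel(
        y0, pack_params(params), dt, n_steps, stride, n_skip
    )
    if status == 1:
        raise TrajectoryEscape(esc_step * dt)
    if n_clip > clip_fail_frac * n_steps:
        raise RuntimeError(
            f"negative-rate clipping in {n_clip}/{n_steps} steps; reduce dt"
        )
    t = transient + dt * stride * (1.0 + np.arange(len(samples)))
    return TraceSet(
        t_ms=t,
        R_e=samples[:, 0],
        V_e=samples[:, 1],
        R_i=samples[:, 2],
        V_i=samples[:, 3],
        n_rate_clips=int(n_clip),
    )


def lyapunov_spectrum(
    params: ModelParams,
    init: MacroState | None = None,
    dt: float = 0.01,
    T: float = 200_000.0,
    transient: float = 10_000.0,
    renorm_every: int = 10,
    seed: int = 0,
    discard_fraction: float = 0.5,
) -> LyapunovResult:
    """Four Lyapunov exponents of the neural mass flow (Benettin method).

    Defaults follow the integration protocol used for the reference
    attractors: dt = 0.01 ms, 200 s of averaging after a 10 s transient,
    re-orthonormalization every 10 steps.  The initial orthonormal tangent
    frame is drawn from `seed`; the first `discard_fraction` of the
    averaging window only aligns the frame and is excluded from the
    reported averages (see LyapunovResult).
    """
    if dt <= 0 or T <= 0 or transient < 0:
        raise ValueError("invalid integration settings")
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    if init is None:
        init = _default_init(params)
    rng = np.random.default_rng(seed)
    Q0, _ = np.linalg.qr(rng.standard_normal((4, 4)))
    n_steps = int(round(T / dt))
    status, esc_step, les_full, les_tail, conv = benettin_kernel(
        init.as_array(),
        pack_params(params),
        dt,
        n_steps,
        int(round(transient / dt)),
        renorm_every,
        Q0,
        int(round(discard_fraction * n_steps)),
    )
    if status == 1:
        raise TrajectoryEscape(esc_step * dt)
    return LyapunovResult(
        exponents=np.sort(les_tail)[::-1],
        exponents_full=np.sort(les_full)[::-1],
        dt=dt,
        T=T,
        transient=transient,
        renorm_every=renorm_every,
        seed=seed,
        discard_fraction=discard_fraction,
        convergence=conv,
    )


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    return np.where((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1


def cluster_maxima(values: np.ndarray, rtol: float = PEAK_CLUSTER_RTOL) -> list[np.ndarray]:
    """Group sorted maxima into clusters closer than `rtol` (relative)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return []
    groups = [[v[0]]]
    for a in v[1:]:
        if a - groups[-1][-1] <= rtol * max(abs(a), 1e-300):
            groups[-1].append(a)
        else:
            groups.append([a])
    return [np.array(g) for g in groups]


def count_bands(values: np.ndarray, gap_frac: float = PEAK_BAND_GAP_FRAC) -> int:
    """Number of disjoint amplitude bands among maxima.

    A band break is a gap between consecutive sorted maxima exceeding
    `gap_frac` of the total spread.  This coarse measure is insensitive to
    the within-band continuum of a chaotic attractor.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return 0
    spread = v[-1] - v[0]
    if spread <= 0:
        return 1
    return 1 + int(np.sum(np.diff(v) > gap_frac * spread))


@dataclass(frozen=True)
class PeakMapPoint:
    control_value: float
    maxima: np.ndarray
    n_clusters: int
    n_bands: int
    escaped: bool = False


def peak_map(
    params: ModelParams,
    control: str,
    control_values,
    dt: float = 0.01,
    T: float = 120_000.0,
    transient: float = 15_000.0,
    min_peaks: int = 200,
    lock_current_ratio: bool = True,
) -> list[PeakMapPoint]:
    """Distinct local maxima of R_e(t) along a parameter scan.

    For each control value the post-transient trajectory is integrated and
    the local maxima of R_e collected; `n_clusters` (fine grouping, 0.5%
    relative) counts periodic branches (1 -> 2 -> 4 along a
    period-doubling cascade) and `n_bands` (coarse gaps) counts disjoint
    amplitude bands of chaotic states.  Band counts are reported as 0 when
    fewer than `min_peaks` maxima were observed.  Escaping values are
    flagged, not dropped.
    """
    ratio = params.I0_e / params.I0_i if (lock_current_ratio and params.I0_i != 0) else None
    out = []
    for val in control_values:
        changes = {control: float(val)}
        if control == "I0_e" and ratio is not None:
            changes["I0_i"] = float(val) / ratio
        p = params.replace(**changes)
        try:
            tr = integrate_mf(p, dt=dt, T=T, transient=transient, stride=10)
        except TrajectoryEscape:
            out.append(
                PeakMapPoint(float(val), np.empty(0), 0, 0, escaped=True)
            )
            continue
        x = tr.R_e
        spread = x.max() - x.min()
        if spread < 1e-12 * max(x.max(), 1e-300):
            # converged to a fixed point: single degenerate "maximum"
            out.append(PeakMapPoint(float(val), np.array([x[-1]]), 1, 1))
            continue
        idx = _local_maxima(x)
        # ignore tiny ripples: keep maxima above 2% prominence of the spread
        keep = x[idx] > x.min() + 0.02 * spread
        vals = x[idx][keep]
        if len(vals) and vals.max() - vals.min() <= PEAK_CLUSTER_RTOL * abs(vals.max()):
            # all maxima coincide within the clustering tolerance (period-1)
            n_cl, n_bd = 1, 1
        else:
            n_cl = len(cluster_maxima(vals))
            n_bd = count_bands(vals) if len(vals) >= min_peaks else 0
        out.append(PeakMapPoint(float(val), vals, n_cl, n_bd))
    return out


def ping_delay_mf(
    params: ModelParams,
    dt: float = 0.01,
    T: float = 30_000.0,
    transient: float = 20_000.0,
) -> tuple[float, float]:
    """E-to-I burst delay of PING-like collective oscillations (ms).

    Integrates the neural mass model (each population with its own membrane
    time constant) and returns the mean and cycle-to-cycle dispersion of the
    interval between each inhibitory rate peak and the preceding excitatory
    one.  Raises if the attractor is not oscillatory: fewer than 5 peaks or
    a rate modulation below 0.1% of the mean (a decaying focus ripple).
    """
    tr = integrate_mf(params, dt=dt, T=T, transient=transient, stride=10)
    spread = tr.R_e.max() - tr.R_e.min()
    if spread < 1e-3 * max(tr.R_e.mean(), 1e-300):
        raise ValueError("not oscillatory: rate modulation below 0.1% of the mean")
    return burst_delay(tr.R_e, tr.R_i, tr.dt_sample)


def classify_regime(
    params: ModelParams,
    dt: float = 0.01,
    T: float = 100_000.0,
    transient: float = 10_000.0,
    seed: int = 0,
) -> RegimeLabel:
    """Classify the macroscopic solution at one parameter point.

    Decision tree: a stable fixed point is a node (III) or focus (II)
    according to its leading eigenvalues; when unstable, the trajectory is
    integrated and the Lyapunov spectrum decides between a stable limit
    cycle (IV, lambda_1 = 0), chaos (V, lambda_1 > 0) and escape (I).
    Coexisting unstable limit cycles in region II are not searched for
    (noted in `detail`).
    """
    detail: dict = {"unstable_LC_search": "not attempted"}
    try:
        fp = stationary_state(params, "exact")
        spec = jacobian_eigenvalues(params, fp)
        detail["fp_class"] = spec.fp_class
        detail["max_re_per_ms"] = spec.max_real_part
    except ValueError:
        fp = None
    if fp is not None and spec.is_stable:
        if spec.fp_class == "stable node":
            return RegimeLabel(Regime.III_STABLE_NODE, "O_F", detail)
        return RegimeLabel(Regime.II_STABLE_FOCUS, "O_F", detail)
    try:
        lyap = lyapunov_spectrum(
            params, dt=dt, T=T, transient=transient, seed=seed
        )
    except TrajectoryEscape as esc:
        detail["escape_time_ms"] = esc.time_ms
        return RegimeLabel(Regime.I_UNSTABLE_FOCUS, "O_S", detail)
    detail["lyapunov_per_ms"] = lyap.exponents.tolist()
    if lyap.lambda_max > LYAP_ZERO_TOL:
        return RegimeLabel(Regime.V_CHAOTIC, "O_P", detail)
    if abs(lyap.lambda_max) <= LYAP_ZERO_TOL:
        return RegimeLabel(Regime.IV_STABLE_LC, "O_P", detail)
    # negative lambda_1 with an (apparently) unstable fixed point: the
    # trajectory converged somewhere the linear analysis did not predict
    return RegimeLabel(Regime.INDETERMINATE, "none", detail)
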