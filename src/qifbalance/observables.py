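"""Macroscopic and microscopic diagnostics of network and mean-field runs.

Covers the synchrony indicator rho (variance of the mean membrane potential
relative to the mean single-neuron variance), interspike-interval
regularity (CV), binned population rates, averaged power spectra of the
mean potential with fundamental-frequency extraction and p:q locking
detection, per-neuron rate distributions with log-normal fits, and the
excitatory-to-inhibitory burst delay of PING-like oscillations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .records import SpikeRaster, TraceSet

__all__ = [
    "coherence_rho",
    "isi_cv",
    "population_rate_trace",
    "PowerSpectrum",
    "power_spectrum",
    "FundamentalPair",
    "fundamental_frequencies",
    "RateDistribution",
    "rate_distribution",
    "burst_delay",
    "SILENT_RATE_HZ",
]

#: a neuron is "active" when it fires faster than this (Hz)
SILENT_RATE_HZ = 0.01


# --------------------------------------------------------------------------
# synchrony


def coherence_rho(v_samples: np.ndarray) -> float:
    """Population coherence rho from per-neuron membrane-potential traces.

    Parameters
    ----------
    v_samples
        Array (n_neurons, n_times) of membrane potentials.

    Returns
    -------
    rho = sqrt( Var_t(mean_j v_j(t)) / mean_j Var_t(v_j(t)) ): 1 for fully
    synchronized nonconstant traces, ~N^(-1/2) for independent ones.
    """
    v = np.asarray(v_samples, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 neurons and 2 time samples")
    per_var = v.var(axis=1).mean()
    if per_var <= 0:
        raise ValueError("degenerate traces: all per-neuron variances are zero")
    return float(math.sqrt(v.mean(axis=0).var() / per_var))


# --------------------------------------------------------------------------
# spike statistics


def isi_cv(raster: SpikeRaster, which: str = "e", min_spikes: int = 3):
    """Per-neuron coefficient of variation of interspike intervals.

    Returns (cv, population_CV): `cv` has NaN for neurons with fewer than
    `min_spikes` spikes; the population CV averages the defined values
    (neurons that never reach `min_spikes` spikes are excluded).
    """
    trains = raster.spike_trains(which)
    cv = np.full(len(trains), np.nan)
    for j, tr in enumerate(trains):
        if len(tr) >= min_spikes:
            isi = np.diff(tr)
            m = isi.mean()
            cv[j] = isi.std() / m if m > 0 else np.nan
    defined = cv[np.isfinite(cv)]
    pop_cv = float(defined.mean()) if len(defined) else float("nan")
    return cv, pop_cv


def population_rate_trace(raster: SpikeRaster, bin_ms: float = 1.0) -> TraceSet:
    """Binned population rates (1/ms per neuron) from a raster.

    The integral of each rate trace times N times the bin width recovers
    the exact spike count.  Potentials in the returned TraceSet are zero
    (rasters carry no membrane information).
    """
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    n_bins = max(int(np.ceil(raster.duration_ms / bin_ms)), 1)
    edges = raster.t0_ms + bin_ms * np.arange(n_bins + 1)
    rates = {}
    for which, n in (("e", raster.N_e), ("i", raster.N_i)):
        sub = raster.population(which)
        counts, _ = np.histogram(sub.times_ms, bins=edges)
        rates[which] = counts / (bin_ms * n)
    t = edges[:-1] + bin_ms / 2.0
    z = np.zeros(n_bins)
    return TraceSet(t_ms=t, R_e=rates["e"], V_e=z, R_i=rates["i"], V_i=z.copy())


# --------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class PowerSpectrum:
    """Averaged modulus-squared DFT of mean-removed signal segments."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_realizations: int
    source: str = ""

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def power_spectrum(
    v_trace: np.ndarray,
    sample_interval_ms: float = 10.0,
    segment_length: int = 10_000,
    n_realizations: int | None = None,
    source: str = "",
) -> PowerSpectrum:
    """Power spectrum of a (mean-potential) time series.

    The trace is cut into `segment_length`-sample segments (default 10,000
    samples at 10 ms -> frequency resolution 0.01 Hz); each segment is
    mean-removed, transformed, and the one-sided |DFT|^2 averaged across
    segments.  `n_realizations` limits how many segments are used.

    The spectra are normalized so that the sum over positive-frequency bins
    equals the variance of the analyzed segments (Parseval).
    """
    x = np.atleast_2d(np.asarray(v_trace, dtype=float))
    if x.shape[1] < segment_length:
        raise ValueError("trace shorter than one segment")
    dt_s = sample_interval_ms / 1000.0
    freqs = np.fft.rfftfreq(segment_length, d=dt_s)
    acc = np.zeros(len(freqs))
    n_used = 0
    for row in x:
        for k in range(len(row) // segment_length):
            if n_realizations is not None and n_used >= n_realizations:
                break
            seg = row[k * segment_length : (k + 1) * segment_length]
            seg = seg - seg.mean()
            spec = np.abs(np.fft.rfft(seg)) ** 2 / segment_length**2
            # one-sided: double everything but DC (and Nyquist when present)
            spec[1:] *= 2.0
            if segment_length % 2 == 0:
                spec[-1] /= 2.0
            acc += spec
            n_used += 1
    return PowerSpectrum(
        freqs_hz=freqs, power=acc / n_used, n_realizations=n_used, source=source
    )


@dataclass(frozen=True)
class FundamentalPair:
    """Fundamental frequencies of a (quasi-)periodic collective rhythm."""

    nu1_hz: float
    nu2_hz: float | None
    locked: bool
    locking_order: tuple[int, int] | None

    def to_dict(self) -> dict:
        return {
            "nu1_hz": self.nu1_hz,
            "nu2_hz": self.nu2_hz,
            "locked": self.locked,
            "locking_order": list(self.locking_order) if self.locking_order else None,
        }


def _spectral_peaks(spec: PowerSpectrum, background_factor: float, window_hz: float):
    """Peak bins exceeding `background_factor` x the local median background."""
    p = spec.power
    half = max(int(round(window_hz / spec.resolution_hz)), 5)
    idx, _ = signal.find_peaks(p)
    floor = 1e-10 * p.max()  # ignore numerical ripple of noise-free signals
    out = []
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, len(p))
        bg = np.median(p[lo:hi])
        if bg > 0 and p[i] > background_factor * bg and p[i] > floor:
            out.append(i)
    out.sort(key=lambda i: -p[i])
    return out


def fundamental_frequencies(
    spec: PowerSpectrum,
    background_factor: float = 5.0,
    window_hz: float = 0.5,
    comb_tol: float = 0.01,
    max_order: int = 4,
    max_lock: int = 6,
) -> FundamentalPair:
    """Extract one or two fundamental frequencies from a power spectrum.

    Greedy: nu1 is the strongest significant peak; nu2 the strongest peak
    that is not an integer combination |a*nu1| (a <= `max_order`) of nu1
    within `comb_tol` (relative).  A p:q locking (p, q <= `max_lock`) is
    declared when nu1/nu2 is within 1% of a small rational.
    """
    peaks = _spectral_peaks(spec, background_factor, window_hz)
    if not peaks:
        raise ValueError("no oscillation: no spectral peak above background")
    f = spec.freqs_hz
    nu1 = float(f[peaks[0]])
    nu2 = None
    for i in peaks[1:]:
        cand = float(f[i])
        if cand <= 0:
            continue
        is_harm = any(
            abs(cand - a * nu1) <= comb_tol * max(cand, nu1) for a in range(1, max_order + 1)
        )
        if not is_harm and abs(cand - nu1) > comb_tol * nu1:
            nu2 = cand
            break
    if nu2 is None:
        return FundamentalPair(nu1, None, False, None)
    hi, lo = max(nu1, nu2), min(nu1, nu2)
    frac = Fraction(hi / lo).limit_denominator(max_lock)
    locked = (
        frac.numerator <= max_lock
        and frac.numerator >= 1
        and abs(hi / lo - float(frac)) <= 0.01 * (hi / lo)
    )
    order = (frac.denominator, frac.numerator) if locked else None
    return FundamentalPair(nu1, nu2, locked, order)


# --------------------------------------------------------------------------
# rate distributions


@dataclass(frozen=True)
class RateDistribution:
    """Per-neuron rates with a log-normal fit over the active neurons.

    `mu_log` and `sigma_log` are the maximum-likelihood mean and SD of
    log-rate; `fit_mean_hz` / `fit_sd_hz` are the arithmetic mean and SD of
    the fitted log-normal.
    """

    rates_hz: np.ndarray
    silent_fraction: float
    mu_log: float | None
    sigma_log: float | None

    @property
    def fit_mean_hz(self) -> float | None:
        if self.mu_log is None:
            return None
        return float(np.exp(self.mu_log + self.sigma_log**2 / 2.0))

    @property
    def fit_sd_hz(self) -> float | None:
        if self.mu_log is None:
            return None
        m = self.fit_mean_hz
        return float(m * np.sqrt(np.exp(self.sigma_log**2) - 1.0))


def rate_distribution(raster: SpikeRaster, which: str = "e") -> RateDistribution:
    """Firing-rate distribution of one population with log-normal MLE fit.

    Neurons below the activity threshold (0.01 Hz) count as silent and are
    excluded from the fit; when no neuron is active the fit is skipped.
    """
    rates = raster.rates_hz(which)
    active = rates >= SILENT_RATE_HZ
    silent_fraction = float(1.0 - active.mean()) if len(rates) else 1.0
    if not active.any():
        return RateDistribution(rates, silent_fraction, None, None)
    logr = np.log(rates[active])
    return RateDistribution(rates, silent_fraction, float(logr.mean()), float(logr.std()))


# --------------------------------------------------------------------------
# burst delays


def _trace_peaks(x: np.ndarray, dt_sample: float, prominence_frac: float = 0.1):
    rng = x.max() - x.min()
    if rng <= 0:
        return np.empty(0)
    idx, _ = signal.find_peaks(x, prominence=prominence_frac * rng)
    return idx * dt_sample


def burst_delay(rate_e: np.ndarray, rate_i: np.ndarray, dt_sample: float):
    """Mean E-to-I burst delay (ms) with cycle-to-cycle dispersion.

    For every inhibitory rate peak, the delay to the closest preceding
    excitatory peak is collected; the per-cycle delays are averaged
    *circularly* over the oscillation period, so the result lies in
    (-P/2, P/2] and the estimator is antisymmetric under swapping the two
    traces (a burst arriving just before counts as a small negative delay,
    not as almost a full period).  Returns (mean, SD of wrapped residuals).
    Raises when either trace shows fewer than 5 peaks.
    """
    t_e = _trace_peaks(np.asarray(rate_e, float), dt_sample)
    t_i = _trace_peaks(np.asarray(rate_i, float), dt_sample)
    if len(t_e) < 5 or len(t_i) < 5:
        raise ValueError("not oscillatory: fewer than 5 peaks detected")
    period = float(np.diff(t_e).mean())
    d = []
    for ti in t_i:
        prev = t_e[t_e <= ti]
        if len(prev):
            d.append(ti - prev[-1])
    if len(d) < 5:
        raise ValueError("not oscillatory: too few matched cycles")
    theta = 2.0 * np.pi * np.asarray(d) / period
    mean_angle = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    delay = period * mean_angle / (2.0 * np.pi)
    if delay <= -period / 2.0:
        delay += period
    resid = (np.asarray(d) - delay + period / 2.0) % period - period / 2.0
    return float(delay), float(resid.std())
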