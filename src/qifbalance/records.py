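"""Shared record containers: macroscopic traces and spike rasters.

These are deliberately dependency-free so that the mean-field, network and
observables layers can all exchange them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import HZ_PER_INV_MS

__all__ = ["TraceSet", "SpikeRaster"]


@dataclass(frozen=True)
class TraceSet:
    """A sampled macroscopic trajectory (rates in 1/ms)."""

    t_ms: np.ndarray
    R_e: np.ndarray
    V_e: np.ndarray
    R_i: np.ndarray
    V_i: np.ndarray
    n_rate_clips: int = 0

    @property
    def dt_sample(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if len(self.t_ms) > 1 else 0.0

    def to_csv(self, path) -> None:
        data = np.column_stack(
            [self.t_ms, self.R_e * HZ_PER_INV_MS, self.V_e, self.R_i * HZ_PER_INV_MS, self.V_i]
        )
        np.savetxt(path, data, delimiter=",", header="t_ms,R_e_Hz,V_e,R_i_Hz,V_i", comments="")

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(
            t_ms=data[:, 0],
            R_e=data[:, 1] / HZ_PER_INV_MS,
            V_e=data[:, 2],
            R_i=data[:, 3] / HZ_PER_INV_MS,
            V_i=data[:, 4],
        )


@dataclass(frozen=True)
class SpikeRaster:
    """Recorded spikes: times (ms, non-decreasing), neuron index, population.

    Excitatory neurons carry indices 0..N_e-1 within population "e" and
    inhibitory neurons 0..N_i-1 within "i"; `pop` holds 0 for e, 1 for i.
    `duration_ms` is the length of the recorded window (after any transient)
    and `t0_ms` its start time.
    """

    times_ms: np.ndarray
    neuron: np.ndarray
    pop: np.ndarray
    N_e: int
    N_i: int
    duration_ms: float
    t0_ms: float = 0.0

    def __post_init__(self):
        if len(self.times_ms) and np.any(np.diff(self.times_ms) < 0):
            raise ValueError("spike times must be non-decreasing")
        for p, n, lim in ((0, "e", self.N_e), (1, "i", self.N_i)):
            sel = self.pop == p
            if sel.any() and (self.neuron[sel].min() < 0 or self.neuron[sel].max() >= lim):
                raise ValueError(f"neuron index out of range for population {n}")

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)

    def population(self, which: str) -> "SpikeRaster":
        """Sub-raster of one population ('e' or 'i')."""
        p = {"e": 0, "i": 1}[which]
        sel = self.pop == p
        return SpikeRaster(
            times_ms=self.times_ms[sel],
            neuron=self.neuron[sel],
            pop=self.pop[sel],
            N_e=self.N_e,
            N_i=self.N_i,
            duration_ms=self.duration_ms,
            t0_ms=self.t0_ms,
        )

    def spike_counts(self, which: str) -> np.ndarray:
        """Per-neuron spike counts of one population."""
        p, n = {"e": (0, self.N_e), "i": (1, self.N_i)}[which]
        sel = self.pop == p
        return np.bincount(self.neuron[sel], minlength=n)

    def rates_hz(self, which: str) -> np.ndarray:
        """Per-neuron firing rates (Hz) over the recorded window."""
        return self.spike_counts(which) / (self.duration_ms / 1000.0)

    def spike_trains(self, which: str) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays for one population."""
        p, n = {"e": (0, self.N_e), "i": (1, self.N_i)}[which]
        sel = self.pop == p
        trains: list[list[float]] = [[] for _ in range(n)]
        for t, j in zip(self.times_ms[sel], self.neuron[sel]):
            trains[j].append(t)
        return [np.array(tr) for tr in trains]

    def to_text(self, path) -> None:
        """Write the raster as delimited text: t_ms  neuron_id  pop."""
        with open(path, "w") as fh:
            fh.write("t_ms\tneuron_id\tpop\n")
            for t, j, p in zip(self.times_ms, self.neuron, self.pop):
                fh.write(f"{t:.6f}\t{j}\t{'e' if p == 0 else 'i'}\n")

    @classmethod
    def from_text(cls, path, N_e: int, N_i: int, duration_ms: float, t0_ms: float = 0.0):
        times, neuron, pop = [], [], []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                t, j, p = line.split()
                times.append(float(t))
                neuron.append(int(j))
                pop.append(0 if p == "e" else 1)
        return cls(
            np.asarray(times), np.asarray(neuron, int), np.asarray(pop, int),
            N_e, N_i, duration_ms, t0_ms,
        )
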