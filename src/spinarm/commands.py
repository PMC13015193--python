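"""SET/GO step-command decoding.

A trial is parameterized by one normalized vector in [0, 1]^n, n being the
circuit variant's parameter count.  The vector is ordered as: SET neuron
currents, then SET synapse-gain multipliers, then GO interneuron currents.
Decoding is an affine map into physical ranges: currents span
[-100, +100] (leak-conductance units, i.e. mV of steady offset on a bare
node; the midpoint 0.5 encodes zero current, values below it
hyperpolarize, and the span is wide enough for a SET command to hold a
motoneuron under threshold against strong tonic afferent drive), gains
span [0, 1] x the synapse's maximal conductance.

The schedule itself carries no dynamics: the SET offsets and gains switch
on at t = 1 s, the GO offsets at t = 5 s, and all are held constant to the
trial end at t = 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuits import CircuitTopology

SET_TIME = 1.0  # s
GO_TIME = 5.0  # s
END_TIME = 10.0  # s


@dataclass(frozen=True)
class CommandRanges:
    """Physical ranges of the affine decode."""

    set_current: tuple[float, float] = (-100.0, 100.0)
    go_current: tuple[float, float] = (-100.0, 100.0)
    gain: tuple[float, float] = (0.0, 1.0)  # multiplier on max_conductance


@dataclass(frozen=True)
class CommandVector:
    """Normalized parameter vector for one trial."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("command vector must be one-dimensional")
        if not np.all((arr >= 0.0) & (arr <= 1.0)):
            raise ValueError("command vector values must lie in [0, 1]")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def baseline_vector(topology: CircuitTopology) -> CommandVector:
    """The vector encoding zero currents and zero gains (no movement)."""
    n_neu = len(topology.set_neuron_targets)
    n_syn = len(topology.set_synapse_targets)
    n_go = len(topology.go_targets)
    return CommandVector(tuple([0.5] * n_neu + [0.0] * n_syn + [0.5] * n_go))


@dataclass(frozen=True)
class CommandSchedule:
    """Decoded step-command schedule for one trial."""

    set_currents: dict[str, float]  # per SET-target neuron
    synapse_gains: dict[tuple[str, str], float]  # multiplier in gain range
    go_currents: dict[str, float]  # per GO-target interneuron
    set_time: float = SET_TIME
    go_time: float = GO_TIME
    end_time: float = END_TIME

    def __post_init__(self) -> None:
        if not self.set_time < self.go_time < self.end_time:
            raise ValueError("require set_time < go_time < end_time")


def decode(vector: CommandVector, topology: CircuitTopology,
           ranges: CommandRanges | None = None) -> CommandSchedule:
    """Affine map of the normalized vector onto the command schedule."""
    ranges = ranges or CommandRanges()
    n_neu = len(topology.set_neuron_targets)
    n_syn = len(topology.set_synapse_targets)
    n_go = len(topology.go_targets)
    if len(vector) != n_neu + n_syn + n_go:
        raise ValueError(
            f"vector length {len(vector)} != parameter count "
            f"{topology.parameter_count} of variant {topology.variant}"
        )
    vals = vector.as_array()

    def affine(x: float, lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return lo + x * (hi - lo)

    set_currents = {
        name: affine(vals[i], ranges.set_current)
        for i, name in enumerate(topology.set_neuron_targets)
    }
    synapse_gains = {
        key: affine(vals[n_neu + i], ranges.gain)
        for i, key in enumerate(topology.set_synapse_targets)
    }
    go_currents = {
        name: affine(vals[n_neu + n_syn + i], ranges.go_current)
        for i, name in enumerate(topology.go_targets)
    }
    return CommandSchedule(set_currents, synapse_gains, go_currents)


def command_at(schedule: CommandSchedule, t: float) -> dict:
    """Active offsets at time t: nothing before SET, SET only before GO."""
    if not 0.0 <= t <= schedule.end_time:
        raise ValueError(f"t={t} outside [0, {schedule.end_time}]")
    active_set = t >= schedule.set_time
    active_go = t >= schedule.go_time
    return {
        "set_currents": dict(schedule.set_currents) if active_set else {},
        "synapse_gains": dict(schedule.synapse_gains) if active_set else {},
        "go_currents": dict(schedule.go_currents) if active_go else {},
    }
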