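"""Stimulus construction and sweep management.

The stimulation protocol is a cathodic monophasic rectangular pulse:
−100 μA total electrode current for durations 0.5, 1, 4, 8, 16, 25, 50 and
100 ms (ON cells), with an additional 500 ms duration for OFF cells whose
T-type current develops more slowly.  Because the tissue model is purely
resistive, the field is solved once per geometry for a unit drive and
scaled by the waveform at every time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import field as fld
from .membrane import (CaChannelParams, CaPoolParams, MembraneParams,
                       TraceSet, simulate)
from .morphology import CellMorphology, compartment_centers

__all__ = [
    "StimulusWaveform",
    "SweepSpec",
    "ON_DURATIONS",
    "OFF_DURATIONS",
    "make_waveform",
    "default_tail",
    "run_sweep",
]

ON_DURATIONS: tuple[float, ...] = (0.5, 1.0, 4.0, 8.0, 16.0, 25.0, 50.0, 100.0)
OFF_DURATIONS: tuple[float, ...] = ON_DURATIONS + (500.0,)


@dataclass(frozen=True)
class StimulusWaveform:
    """A cathodic monophasic rectangular pulse (amplitude in μA, times in ms)."""

    amplitude: float = -100.0
    duration: float = 1.0
    onset: float = 1.0
    total_time: float = 60.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.onset + self.duration > self.total_time + 1e-9:
            raise ValueError("pulse must fit within total_time")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def make_waveform(spec: StimulusWaveform) -> np.ndarray:
    """Sample the pulse on the grid t_k = k·dt, k = 0..round(total/dt).

    The value at t_k is the current during [onset, onset + duration); onset
    and offset snap to the nearest step (with a warning if not exactly
    representable).
    """
    n = int(round(spec.total_time / spec.dt))
    k_on = int(round(spec.onset / spec.dt))
    k_off = int(round((spec.onset + spec.duration) / spec.dt))
    if abs(k_on * spec.dt - spec.onset) > 1e-9 or \
            abs(k_off * spec.dt - (spec.onset + spec.duration)) > 1e-9:
        warnings.warn(
            f"pulse edges not representable at dt={spec.dt}; snapped to the grid",
            stacklevel=2)
    wf = np.zeros(n + 1)
    wf[k_on:min(k_off, n + 1)] = spec.amplitude
    return wf


def default_tail(duration: float) -> float:
    """Post-pulse window: long enough for tail currents and decay fits."""
    return max(50.0, 3.0 * duration)


@dataclass(frozen=True)
class SweepSpec:
    """A duration sweep for one cell class at fixed amplitude."""

    cell_class: str = "ON"
    durations: tuple[float, ...] = ON_DURATIONS
    amplitude: float = -100.0
    onset: float = 1.0
    dt: float = 0.01
    tail: float | None = None  # None → default_tail per duration
    record_every: int = 1

    def __post_init__(self) -> None:
        if len(self.durations) == 0:
            raise ValueError("duration list must be non-empty")

    @classmethod
    def for_class(cls, cell_class: str, **kw) -> "SweepSpec":
        durs = ON_DURATIONS if cell_class == "ON" else OFF_DURATIONS
        return cls(cell_class=cell_class, durations=durs, **kw)


def run_sweep(spec: SweepSpec, cohort: Sequence[CellMorphology],
              grid: fld.PotentialGrid, mp: MembraneParams,
              ch: CaChannelParams, pool: CaPoolParams,
              ) -> dict[tuple[str, float], TraceSet]:
    """Simulate every (cell, duration) pair against a solved unit field.

    ``grid`` must be the potential field for a 1 μA drive; the waveform
    carries the physical amplitude.  Results are keyed by
    (cell_id, duration).
    """
    if abs(grid.current - 1.0) > 1e-9:
        raise ValueError("run_sweep expects a unit-drive (1 μA) field solution")
    out: dict[tuple[str, float], TraceSet] = {}
    for cell in cohort:
        ve = fld.sample_potentials(grid, compartment_centers(cell))
        for dur in spec.durations:
            tail = spec.tail if spec.tail is not None else default_tail(dur)
            total = spec.onset + dur + tail
            wf_spec = StimulusWaveform(spec.amplitude, dur, spec.onset, total, spec.dt)
            wf = make_waveform(wf_spec)
            tr = simulate(cell, mp, ch, pool, ve, wf, spec.dt, total,
                          record_every=spec.record_every)
            tr.meta.update({"duration": dur, "onset": spec.onset,
                            "amplitude": spec.amplitude})
            out[(cell.cell_id, dur)] = tr
    return out
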