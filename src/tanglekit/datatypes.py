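"""Core containers shared across the analysis pipeline.

The common currency of every analysis is a *population* of units (neurons,
muscles, or network units) observed over one movement cycle per speed bin.
Because a cycle at 0.8 Hz lasts ~1250 ms while a cycle at 2.1 Hz lasts
~476 ms, per-speed time courses have different lengths; :class:`PopulationRates`
therefore stores one ``(n_units, T_s)`` matrix per speed bin rather than a
rectangular cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Kind = Literal["neural", "muscle", "network"]


@dataclass
class PopulationRates:
    """Per-speed population time courses on a common sampling grid.

    Parameters
    ----------
    values
        One ``(n_units, T_s)`` array per speed bin, in spikes/s for neural
        data or normalized units for muscle/network data.
    time_step
        Sampling interval in ms (> 0).
    speed_bins
        Labels for the speed bins (e.g. base cycling frequency in Hz).
    kind
        What population the rates describe.
    """

    values: list[np.ndarray]
    time_step: float
    speed_bins: Sequence[float]
    kind: Kind = "neural"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if len(self.values) != len(self.speed_bins):
            raise ValueError("one matrix per speed bin required")
        n_units = {v.shape[0] for v in self.values}
        if len(n_units) > 1:
            raise ValueError("all speed bins must share the same unit count")
        for v in self.values:
            if not np.all(np.isfinite(v)):
                raise ValueError("rates contain non-finite values")

    @property
    def n_units(self) -> int:
        return self.values[0].shape[0]

    @property
    def n_speeds(self) -> int:
        return len(self.values)

    def pooled(self) -> np.ndarray:
        """Concatenate all speeds along time: the full-dimensional matrix."""
        return np.concatenate(self.values, axis=1)

    def copy(self) -> "PopulationRates":
        return PopulationRates(
            [v.copy() for v in self.values],
            self.time_step,
            list(self.speed_bins),
            self.kind,
            dict(self.meta),
        )


@dataclass
class FactorProjection:
    """A linear basis plus projected trajectories (factors).

    ``basis`` has orthonormal columns (unit × component); ``projected`` holds
    the component × time coordinates per speed bin.  ``scope`` records whether
    the basis was fit on a single speed or on all speeds pooled.
    """

    basis: np.ndarray
    projected: list[np.ndarray]
    mean_vector: np.ndarray
    variance_explained: np.ndarray
    scope: str  # "per_speed:<s>" or "global"
    time_step: float = 1.0
    speed_bins: Sequence[float] = ()

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        gram = b.T @ b
        if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal (1e-8)")
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(np.diff(ve) > 1e-10):
            raise ValueError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-8:
            raise ValueError("variance_explained sums above 1")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.projected, axis=1)


@dataclass
class Trial:
    """A single trial: continuous traces or a spike indicator on a 1 ms grid."""

    traces: np.ndarray  # unit × time; spike indicator (0/1) or rates
    duration: float  # ms
    position: np.ndarray  # cycle phase (radians, unwrapped) per sample
    speed_bin: int
    is_spikes: bool = False
    spike_times: list[np.ndarray] | None = None  # per unit, ms (spike trials)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")


@dataclass
class TrialSet:
    """Trials grouped by speed bin, feeding alignment and respiking controls."""

    trials: list[Trial]
    time_step: float = 1.0
    meta: dict = field(default_factory=dict)

    def by_speed(self, s: int) -> list[Trial]:
        return [t for t in self.trials if t.speed_bin == s]

    @property
    def speed_bins(self) -> list[int]:
        return sorted({t.speed_bin for t in self.trials})
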