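"""Trajectory containers shared by the pre-simulation and all simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "EnsembleResult", "write_trajectory_csv", "read_trajectory_csv"]


@dataclass
class Trajectory:
    """A time grid and a (grid x species) state matrix.

    ``times`` is strictly increasing with ``times[0] == 0`` for simulations
    started at the origin; ``states[g, s]`` is the value of species ``s`` at
    grid point ``g``.  ``meta`` carries engine-specific run information
    (seed, event counts, clipped-propensity counter, ...).
    """

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.species_names)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{self.times.size} grid points x {len(self.species_names)} species"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain NaN or Inf")

    @property
    def n_grid(self) -> int:
        return self.times.size

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def column(self, name: str) -> np.ndarray:
        """The series of one species by name."""
        return self.states[:, self.species_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df


@dataclass
class EnsembleResult:
    """Replicate trajectories on a shared output grid."""

    trajectories: list[Trajectory]
    seeds: list[int]
    failures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trajectories:
            t0 = self.trajectories[0].times
            for tr in self.trajectories[1:]:
                if not np.array_equal(tr.times, t0):
                    raise ValueError("ensemble replicates must share the output grid")

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def stack(self) -> np.ndarray:
        """(replicate, grid, species) array."""
        return np.stack([tr.states for tr in self.trajectories])


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write as CSV with header ``time,<species...>``."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time', got {df.columns[0]!r}")
    return Trajectory(
        times=df["time"].to_numpy(),
        states=df.iloc[:, 1:].to_numpy(),
        species_names=list(df.columns[1:]),
    )
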