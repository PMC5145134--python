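"""Result containers shared by the deterministic, stochastic and spatial solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "SensitivityResult", "Ensemble", "SpatialResult"]


@dataclass
class Trajectory:
    """A single time series: strictly increasing time grid (seconds) by
    species values (concentrations or copy numbers, per the model's units)."""

    times: np.ndarray  # (T,)
    values: np.ndarray  # (T, n_species)
    species_names: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.ndim != 1 or self.values.shape != (len(self.times), len(self.species_names)):
            raise ValueError("trajectory shape mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values.astype(float))):
            raise ValueError("trajectory contains NaN or Inf")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[:, self.species_names.index(species)]


@dataclass
class SensitivityResult:
    """Forward sensitivities dx_i/dp_j on the trajectory's time grid."""

    trajectory: Trajectory
    parameters: list
    sensitivities: np.ndarray  # (T, n_species, n_parameters)

    def scaled(self) -> np.ndarray:
        """Dimensionless sensitivities (p_j / x_i) * dx_i/dp_j, with 0/0 -> 0."""
        x = self.trajectory.values.astype(float)
        p = np.asarray(self.parameters_values, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = self.sensitivities * p[None, None, :] / x[:, :, None]
        return np.nan_to_num(scaled, nan=0.0, posinf=0.0, neginf=0.0)

    @property
    def parameters_values(self):
        return self.trajectory.metadata["parameter_values"]


@dataclass
class Ensemble:
    """A stack of stochastic replicates on a shared time grid, with per-time
    per-species mean and (population) variance recomputable from the stack."""

    trajectories: list
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        grids = {tuple(t.times) for t in self.trajectories}
        if len(grids) != 1:
            raise ValueError("all replicates must share one time grid")

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def species_names(self) -> list:
        return self.trajectories[0].species_names

    @property
    def n_reps(self) -> int:
        return len(self.trajectories)

    def stack(self) -> np.ndarray:
        return np.stack([t.values for t in self.trajectories]).astype(float)

    def mean(self) -> np.ndarray:
        return self.stack().mean(axis=0)

    def variance(self) -> np.ndarray:
        return self.stack().var(axis=0, ddof=0)

    def end_states(self, species: str) -> np.ndarray:
        j = self.species_names.index(species)
        return np.array([t.values[-1, j] for t in self.trajectories])


@dataclass
class SpatialResult:
    """Voxel-resolved counts: time grid x voxel x species, plus the mesh."""

    times: np.ndarray  # (T,)
    counts: np.ndarray  # (T, n_voxels, n_species) integers
    species_names: list
    mesh: object
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative voxel counts")

    def reduce_to_total(self) -> Trajectory:
        """Sum counts over voxels (integer-exact) into a well-mixed trajectory."""
        totals = self.counts.sum(axis=1)
        return Trajectory(
            times=self.times,
            values=totals,
            species_names=list(self.species_names),
            metadata={"reduced_from": "spatial", **self.metadata},
        )
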