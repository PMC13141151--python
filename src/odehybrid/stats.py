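"""Stationary trajectory statistics and cross-method benchmark tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hybrid import build_hybrid_system, run_ensemble, simulate_hybrid
from .model import OdeModel
from .reference import (ChannelPartition, hr_hybrid, network_from_decomposition,
                        ode_solve, ssa_direct, tau_leap, uniform_grid)
from .trajectory import EnsembleResult, Trajectory

__all__ = ["StatSummary", "stationary_stats", "relative_error", "RunConfig",
           "BenchmarkTable", "compare_methods", "BENCHMARK_METHODS"]

BENCHMARK_METHODS = ("ode", "ssa", "tau_leap", "hr_hybrid", "hybrid")


@dataclass
class StatSummary:
    """Per-species stationary mean and variance (molecules, molecules^2).

    Estimated by ergodic averaging: all grid samples with t >= burn_in are
    pooled across replicates; the variance is the population variance
    (denominator n).  ``n`` is the pooled sample count (time samples are
    autocorrelated, so it overstates the effective sample size).
    """

    species_names: list[str]
    mean: np.ndarray
    variance: np.ndarray
    n: int
    burn_in: float
    window: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "variance": self.variance},
                            index=pd.Index(self.species_names, name="species"))


def stationary_stats(result: EnsembleResult | Trajectory, burn_in: float = 0.0) -> StatSummary:
    """Pool all samples with t >= burn_in and compute mean and population
    variance per species."""
    trajs = result.trajectories if isinstance(result, EnsembleResult) else [result]
    if not trajs:
        raise ValueError("no trajectories to summarise")
    times = trajs[0].times
    keep = times >= burn_in
    if not np.any(keep):
        raise ValueError(f"burn_in={burn_in} leaves an empty stationary window "
                         f"(final time {times[-1]})")
    pooled = np.concatenate([tr.states[keep] for tr in trajs], axis=0)
    return StatSummary(
        species_names=list(trajs[0].species_names),
        mean=pooled.mean(axis=0),
        variance=pooled.var(axis=0),  # population variance, denominator n
        n=int(pooled.shape[0]),
        burn_in=float(burn_in),
        window=(float(times[keep][0]), float(times[-1])),
    )


def relative_error(summary: StatSummary, reference_means: np.ndarray) -> float:
    """Mean absolute relative deviation of stationary means from a reference:
    eps = (1/S) sum_i |mean_i - ref_i| / |ref_i|."""
    ref = np.asarray(reference_means, dtype=float)
    if ref.shape != summary.mean.shape:
        raise ValueError("reference_means length must equal species count")
    if np.any(ref == 0):
        raise ValueError("reference means must be nonzero")
    return float(np.mean(np.abs(summary.mean - ref) / np.abs(ref)))


@dataclass
class RunConfig:
    """Benchmark protocol: model, partition, horizons, seeds, tolerances.

    The default protocol integrates to T=5000 with a 0.1 output grid and a
    burn-in of 50 time units, a single replicate per stochastic method, and
    a 0.1 synchronization interval for the hybrid engine.
    """

    model: OdeModel
    labels: dict[str, int]          # 1 = stochastic, 0 = deterministic
    T: float = 5000.0
    burn_in: float = 50.0
    grid_step: float = 0.1
    dt: float = 0.1                 # hybrid synchronization interval
    tau: float = 0.01               # tau-leaping step
    n_reps: int = 1
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.burn_in < self.T:
            raise ValueError("burn_in must be smaller than T")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def grid(self) -> np.ndarray:
        return uniform_grid(self.T, self.grid_step)


@dataclass
class BenchmarkTable:
    """Rows of (method, stationary summary, relative error vs reference)."""

    rows: list[dict] = field(default_factory=list)
    reference_means: np.ndarray | None = None
    species_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {"method": row["method"]}
            s: StatSummary = row["summary"]
            for i, name in enumerate(s.species_names):
                rec[f"{name}_mean"] = s.mean[i]
                rec[f"{name}_var"] = s.variance[i]
            rec["relative_error"] = row["relative_error"]
            records.append(rec)
        return pd.DataFrame(records)

    def write_csv(self, path: str | Path) -> None:
        # fixed float formatting -> byte-identical CSV for identical configs
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _ode_row(config: RunConfig) -> StatSummary:
    # A deterministic trajectory has zero run-to-run variability: the ODE row
    # reports the steady state reached at T with ensemble variance exactly 0.
    traj = ode_solve(config.model, config.T, rtol=config.rtol, atol=config.atol,
                     t_grid=config.grid())
    return StatSummary(
        species_names=list(traj.species_names),
        mean=traj.states[-1].copy(),
        variance=np.zeros(traj.n_species),
        n=1,
        burn_in=config.burn_in,
        window=(config.burn_in, config.T),
    )


def compare_methods(
    config: RunConfig,
    methods: tuple[str, ...] | list[str] = BENCHMARK_METHODS,
    reference_means: np.ndarray | None = None,
) -> BenchmarkTable:
    """Run the requested methods on one model and tabulate stationary
    statistics and relative errors.

    The reference is the deterministic steady state (the ODE solution at T)
    unless explicit reference means are given.  Every engine derives its
    channels from the same production/degradation decomposition; method
    seeds are offset from ``config.seed`` so the methods are independent.
    """
    unknown = [m for m in methods if m not in BENCHMARK_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {list(BENCHMARK_METHODS)}")
    grid = config.grid()
    if reference_means is None:
        reference_means = ode_solve(config.model, config.T, rtol=config.rtol,
                                    atol=config.atol, t_grid=grid).states[-1]
    table = BenchmarkTable(reference_means=np.asarray(reference_means, float),
                           species_names=config.model.species_names)
    network = None
    if any(m in ("ssa", "tau_leap", "hr_hybrid") for m in methods):
        network = network_from_decomposition(config.model)

    for pos, method in enumerate(methods):
        seed = config.seed + 1000 * (pos + 1)
        if method == "ode":
            summary = _ode_row(config)
        elif method == "ssa":
            traj = ssa_direct(network, config.T, seed=seed, t_grid=grid)
            summary = stationary_stats(traj, config.burn_in)
        elif method == "tau_leap":
            traj = tau_leap(network, config.tau, config.T, seed=seed, t_grid=grid)
            summary = stationary_stats(traj, config.burn_in)
        elif method == "hr_hybrid":
            part = ChannelPartition.from_species_labels(network, config.labels)
            traj = hr_hybrid(network, part, config.T, seed=seed,
                             rtol=config.rtol, atol=config.atol, t_grid=grid)
            summary = stationary_stats(traj, config.burn_in)
        else:  # hybrid
            system = build_hybrid_system(config.model, config.labels,
                                         dt=config.dt, rtol=config.rtol,
                                         atol=config.atol)
            if config.n_reps == 1:
                traj = simulate_hybrid(system, config.T, seed=seed + 1, t_grid=grid)
                summary = stationary_stats(traj, config.burn_in)
            else:
                ens = run_ensemble(system, config.T, config.n_reps,
                                   base_seed=seed, t_grid=grid)
                summary = stationary_stats(ens, config.burn_in)
        table.rows.append({
            "method": method,
            "summary": summary,
            "relative_error": relative_error(summary, reference_means),
        })
    return table
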