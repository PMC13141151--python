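"""Reference engines on explicit reaction networks: exact SSA, tau-leaping,
the Haseltine-Rawlings partitioned hybrid, and plain ODE integration.

Networks are derived from a model's production/degradation decomposition:
two channels per species (a +1 birth and a -1 death), so the exact SSA on the
derived network is the gold-standard stochastic interpretation of the ODE
drift.  The Haseltine-Rawlings solver fires slow channels exactly via the
time-integrated hazard (an auxiliary ODE coordinate accumulates the slow
propensity and a root crossing triggers the jump), which is the
continuous-hazard counterpart to the frozen-propensity hybrid engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .model import OdeModel
from .presim import SimulationError
from .trajectory import Trajectory

__all__ = [
    "Channel",
    "ReactionNetwork",
    "ChannelPartition",
    "network_from_decomposition",
    "uniform_grid",
    "round_half_up",
    "ssa_direct",
    "tau_leap",
    "hr_hybrid",
    "ode_solve",
]


def uniform_grid(T: float, step: float = 0.1) -> np.ndarray:
    """Uniform output grid [0, T] with the given step."""
    n = int(round(T / step))
    return np.linspace(0.0, n * step, n + 1)


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round-half-up to integers (2.5 -> 3), the package's count convention."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class Channel:
    """A reaction channel: integer stoichiometry plus a propensity a(x, t) >= 0."""

    stoich: np.ndarray
    propensity: Callable[[np.ndarray, float], float]
    tag: str = ""

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich, dtype=float)


@dataclass
class ReactionNetwork:
    """Explicit channels over named species with integer initial counts.

    ``bulk_propensities`` is an optional fast path evaluating every channel in
    one call (used by networks built from a drift decomposition); engines fall
    back to looping the per-channel evaluators.
    """

    species_names: list[str]
    channels: list[Channel]
    initial_counts: np.ndarray
    bulk_propensities: Callable[[np.ndarray, float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.initial_counts = round_half_up(self.initial_counts)
        for ch in self.channels:
            if ch.stoich.size != len(self.species_names):
                raise ValueError("channel stoichiometry length != species count")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def stoich_matrix(self) -> np.ndarray:
        return np.array([ch.stoich for ch in self.channels])

    def propensities(self, x: np.ndarray, t: float) -> np.ndarray:
        if self.bulk_propensities is not None:
            return np.asarray(self.bulk_propensities(x, t), dtype=float)
        return np.array([ch.propensity(x, t) for ch in self.channels], dtype=float)


@dataclass
class ChannelPartition:
    """Disjoint, covering split of channel indices into slow (jump) and fast
    (continuous) subsets for the Haseltine-Rawlings solver."""

    slow: list[int]
    fast: list[int]

    def validate(self, n_channels: int) -> None:
        s, f = set(self.slow), set(self.fast)
        if s & f or s | f != set(range(n_channels)):
            raise ValueError(
                f"partition must split channels 0..{n_channels - 1} into "
                f"disjoint covering slow/fast sets"
            )

    @classmethod
    def from_species_labels(
        cls, network: ReactionNetwork, labels: dict[str, int]
    ) -> "ChannelPartition":
        """Channels touching any stochastic-labeled (1) species become slow."""
        stoch = {name for name, lab in labels.items() if lab == 1}
        idx = [network.species_names.index(n) for n in stoch]
        slow, fast = [], []
        for j, ch in enumerate(network.channels):
            (slow if any(ch.stoich[i] != 0 for i in idx) else fast).append(j)
        return cls(slow=slow, fast=fast)


def network_from_decomposition(model: OdeModel) -> ReactionNetwork:
    """Two channels per species from the production/degradation split:
    (+1 e_i, f_plus_i) and (-1 e_i, f_minus_i), in species order with the
    birth before the death.  Initial counts are rounded half-up."""
    decomp = model.decomposition_or_default()
    if not decomp.consistent:
        raise ValueError(
            f"model {model.name!r}: the automatic production/degradation split "
            f"is inconsistent with the drift; supply an explicit decomposition"
        )
    n = model.n_species
    channels: list[Channel] = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        channels.append(Channel(e, lambda x, t, i=i: float(decomp.production(x, t)[i]),
                                tag="production"))
        channels.append(Channel(-e, lambda x, t, i=i: float(decomp.degradation(x, t)[i]),
                                tag="degradation"))

    def bulk(x, t, _d=decomp, _n=n):
        fp, fm = _d.both(x, t)
        out = np.empty(2 * _n)
        out[0::2] = fp
        out[1::2] = fm
        return out

    return ReactionNetwork(
        species_names=model.species_names,
        channels=channels,
        initial_counts=model.initial_state,
        bulk_propensities=bulk,
    )


# ---------------------------------------------------------------------------
# exact SSA (Gillespie direct method)
# ---------------------------------------------------------------------------

def ssa_direct(
    network: ReactionNetwork,
    T: float,
    seed: int,
    t_grid: np.ndarray | None = None,
) -> Trajectory:
    """Gillespie direct method with exact event timing.

    Counts are recorded on the output grid as right-continuous step
    functions.  Zero total propensity freezes the state until ``T`` (not an
    error).  Propensities with explicit time dependence are evaluated at the
    current event time and held between events.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if t_grid is None:
        t_grid = uniform_grid(T)
    rng = np.random.default_rng(seed)
    x = network.initial_counts.astype(float).copy()
    nu = network.stoich_matrix()
    G = t_grid.size
    out = np.empty((G, network.n_species))
    k = 0
    t = 0.0
    n_events = 0
    while True:
        a = network.propensities(x, t)
        np.maximum(a, 0.0, out=a)
        a0 = a.sum()
        t_next = t + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
        t_stop = min(t_next, T)
        while k < G and t_grid[k] <= t_stop:
            out[k] = x
            k += 1
        if t_next >= T:
            break
        r = rng.random() * a0
        j = int(np.searchsorted(np.cumsum(a), r, side="right"))
        j = min(j, a.size - 1)
        x += nu[j]
        np.maximum(x, 0.0, out=x)
        t = t_next
        n_events += 1
    while k < G:
        out[k] = x
        k += 1
    return Trajectory(times=t_grid, states=out, species_names=network.species_names,
                      meta={"engine": "ssa_direct", "seed": seed, "n_events": n_events})


# ---------------------------------------------------------------------------
# tau-leaping
# ---------------------------------------------------------------------------

def tau_leap(
    network: ReactionNetwork,
    tau: float,
    T: float,
    seed: int,
    t_grid: np.ndarray | None = None,
    max_halvings: int = 20,
) -> Trajectory:
    """Fixed-step tau-leaping with Poisson channel counts and frozen
    propensities.

    If an aggregate update would drive any count negative, the step is
    retried at half the leap (recursively, up to ``max_halvings``), then
    falls back to single-event exact SSA for the remainder of that step.
    """
    if tau <= 0 or T <= 0:
        raise ValueError("tau and T must be positive")
    if t_grid is None:
        t_grid = uniform_grid(T)
    rng = np.random.default_rng(seed)
    x = network.initial_counts.astype(float).copy()
    nu = network.stoich_matrix()
    G = t_grid.size
    out = np.empty((G, network.n_species))
    k = 0
    n_fallbacks = 0

    def ssa_span(t0: float, span: float) -> float:
        """Exact single events covering [t0, t0+span]; returns end time."""
        t_loc = t0
        end = t0 + span
        nonlocal x
        while True:
            a = np.maximum(network.propensities(x, t_loc), 0.0)
            a0 = a.sum()
            t_next = t_loc + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
            if t_next >= end:
                return end
            r = rng.random() * a0
            j = int(np.searchsorted(np.cumsum(a), r, side="right"))
            j = min(j, a.size - 1)
            x += nu[j]
            np.maximum(x, 0.0, out=x)
            t_loc = t_next

    def leap(t0: float, span: float, depth: int) -> None:
        nonlocal x, n_fallbacks
        if depth > max_halvings:
            n_fallbacks += 1
            ssa_span(t0, span)
            return
        a = np.maximum(network.propensities(x, t0), 0.0)
        counts = rng.poisson(a * span)
        dx = counts @ nu
        if np.any(x + dx < 0):
            leap(t0, span / 2.0, depth + 1)
            leap(t0 + span / 2.0, span / 2.0, depth + 1)
            return
        x += dx

    t = 0.0
    while t < T - 1e-12:
        step = min(tau, T - t)
        t_new = t + step
        while k < G and t_grid[k] <= t + 1e-12:
            out[k] = x
            k += 1
        leap(t, step, depth=0)
        t = t_new
    while k < G:
        out[k] = x
        k += 1
    return Trajectory(times=t_grid, states=out, species_names=network.species_names,
                      meta={"engine": "tau_leap", "seed": seed, "tau": tau,
                            "n_ssa_fallbacks": n_fallbacks})


# ---------------------------------------------------------------------------
# Haseltine-Rawlings hybrid (integrated hazard, exact slow-channel timing)
# ---------------------------------------------------------------------------

def hr_hybrid(
    network: ReactionNetwork,
    partition: ChannelPartition,
    T: float,
    seed: int,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_grid: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Partitioned hybrid: fast channels form a deterministic drift
    ``sum_fast nu_j a_j``, slow channels fire exactly.

    The state is augmented with the integrated slow hazard
    ``dg/dt = sum_slow a_j(x(t), t)``; a jump fires when ``g`` reaches
    ``-log U`` (located by the solver's event root-finding), the slow channel
    is selected with probability proportional to its propensity at the firing
    time, its stoichiometry is applied, and ``g`` resets.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    partition.validate(network.n_channels)
    if t_grid is None:
        t_grid = uniform_grid(T)
    rng = np.random.default_rng(seed)
    nu = network.stoich_matrix()
    slow = np.asarray(partition.slow, dtype=int)
    fast = np.asarray(partition.fast, dtype=int)
    nu_fast = nu[fast] if fast.size else np.zeros((0, network.n_species))

    def rhs(t, y):
        a = np.maximum(network.propensities(y[:-1], t), 0.0)
        dx = a[fast] @ nu_fast if fast.size else np.zeros(network.n_species)
        dg = a[slow].sum() if slow.size else 0.0
        return np.append(dx, dg)

    x = network.initial_counts.astype(float).copy()
    G = t_grid.size
    out = np.empty((G, network.n_species))
    k = 0
    t = 0.0
    n_events = 0
    while t < T - 1e-12:
        thr = rng.exponential(1.0)

        def hit(tt, y, _thr=thr):
            return y[-1] - _thr

        hit.terminal = True
        hit.direction = 1.0
        seg = t_grid[k:]
        seg = seg[(seg >= t) & (seg <= T)]
        sol = solve_ivp(
            rhs, (t, T), np.append(x, 0.0), method=method,
            t_eval=seg if seg.size else None, events=hit,
            rtol=rtol, atol=atol,
        )
        if sol.status == -1:
            raise SimulationError(
                f"Haseltine-Rawlings integration failed at t={sol.t[-1]:g}: "
                f"{sol.message}", last_time=float(sol.t[-1]))
        n_rec = int(np.size(sol.t))
        if seg.size and n_rec:
            out[k:k + n_rec] = np.asarray(sol.y)[:-1, :].T
            k += n_rec
        if sol.status == 1:  # slow-channel firing located by root-finding
            te = float(sol.t_events[0][0])
            ye = sol.y_events[0][0]
            x = np.asarray(ye[:-1], dtype=float).copy()
            a_slow = np.maximum(network.propensities(x, te), 0.0)[slow]
            tot = a_slow.sum()
            if tot > 0:
                r = rng.random() * tot
                jj = int(np.searchsorted(np.cumsum(a_slow), r, side="right"))
                jj = min(jj, a_slow.size - 1)
                x += nu[slow[jj]]
                np.maximum(x, 0.0, out=x)
                n_events += 1
            t = te
        else:
            t = T
    while k < G:
        out[k] = x
        k += 1
    return Trajectory(times=t_grid, states=out, species_names=network.species_names,
                      meta={"engine": "hr_hybrid", "seed": seed, "n_events": n_events})


# ---------------------------------------------------------------------------
# plain ODE
# ---------------------------------------------------------------------------

def ode_solve(
    model_or_network: OdeModel | ReactionNetwork,
    T: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_grid: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Stiff-capable deterministic integration with dense output on the grid.

    For a :class:`ReactionNetwork` the drift is the propensity-weighted
    stoichiometry sum (the macroscopic rate equation of the network).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if t_grid is None:
        t_grid = uniform_grid(T)
    if isinstance(model_or_network, OdeModel):
        names = model_or_network.species_names
        x0 = model_or_network.initial_state
        fun = lambda t, x: model_or_network.drift(x, t)  # noqa: E731
    else:
        net = model_or_network
        names = net.species_names
        x0 = net.initial_counts.astype(float)
        nu = net.stoich_matrix()
        fun = lambda t, x: net.propensities(x, t) @ nu  # noqa: E731
    sol = solve_ivp(fun, (float(t_grid[0]), T), x0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}",
                              last_time=float(sol.t[-1]) if sol.t.size else None)
    return Trajectory(times=t_grid, states=sol.y.T, species_names=names,
                      meta={"engine": "ode", "rtol": rtol, "atol": atol})
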