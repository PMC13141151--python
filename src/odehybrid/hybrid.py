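"""Event-driven hybrid engine: SSA updates for stochastic species coupled to
stiff ODE integration of the deterministic species.

Each stochastic species carries a birth and a death channel whose
propensities are the production and degradation parts of the ODE drift
evaluated at the current hybrid state.  Between events the deterministic
coordinates advance with LSODA while the stochastic counts are frozen;
propensities are re-evaluated after every event and at least every
synchronization interval ``dt`` (the frozen-propensity approximation --
the integrated-hazard alternative lives in the Haseltine-Rawlings reference
solver).  The partition is fixed for the whole run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .model import Decomposition, OdeModel, default_decomposition
from .reference import round_half_up, uniform_grid
from .trajectory import EnsembleResult, Trajectory

__all__ = ["HybridSystem", "build_hybrid_system", "simulate_hybrid", "run_ensemble"]


@dataclass
class HybridSystem:
    """A partitioned model ready for hybrid simulation.

    ``stochastic_idx``/``deterministic_idx`` are disjoint covering index sets
    over the model's species; the decomposition supplies per-species birth
    and death propensities for the stochastic subset and the reduced drift
    for the deterministic subset (stochastic coordinates frozen between
    events).
    """

    model: OdeModel
    stochastic_idx: np.ndarray
    deterministic_idx: np.ndarray
    decomposition: Decomposition
    dt: float = 0.1
    rtol: float = 1e-6
    atol: float = 1e-9
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("synchronization interval dt must be positive")
        s = set(self.stochastic_idx.tolist())
        d = set(self.deterministic_idx.tolist())
        if s & d or s | d != set(range(self.model.n_species)):
            raise ValueError("stochastic/deterministic sets must be disjoint and cover all species")

    @property
    def initial_hybrid_state(self) -> np.ndarray:
        """Initial full state: stochastic entries rounded half-up to counts."""
        x = self.model.initial_state.astype(float).copy()
        x[self.stochastic_idx] = round_half_up(x[self.stochastic_idx])
        return x


def build_hybrid_system(
    model: OdeModel,
    labels: dict[str, int] | np.ndarray,
    dt: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> HybridSystem:
    """Partition a count-unit model by per-species labels (1 = stochastic).

    Uses the model's own production/degradation decomposition when present,
    else the automatic zero-clamp split; an inconsistent automatic split is a
    hard error because the derived propensities would not reproduce the
    drift.
    """
    if any(k != "count" for k in model.unit_kinds):
        raise ValueError("hybrid simulation requires a count-unit model "
                         "(use convert_to_counts first)")
    if isinstance(labels, dict):
        missing = set(model.species_names) - set(labels)
        if missing:
            raise ValueError(f"labels missing for species {sorted(missing)}")
        lab = np.array([int(labels[n]) for n in model.species_names])
    else:
        lab = np.asarray(labels, dtype=int)
        if lab.shape != (model.n_species,):
            raise ValueError("label vector length must equal species count")
    decomp = model.decomposition
    if decomp is None:
        decomp = default_decomposition(model)
        if not decomp.consistent:
            raise ValueError(
                f"model {model.name!r}: automatic production/degradation split "
                f"is inconsistent with the drift; supply an explicit "
                f"decomposition to simulate stochastically"
            )
    return HybridSystem(
        model=model,
        stochastic_idx=np.flatnonzero(lab == 1),
        deterministic_idx=np.flatnonzero(lab == 0),
        decomposition=decomp,
        dt=dt,
        rtol=rtol,
        atol=atol,
        labels={n: int(v) for n, v in zip(model.species_names, lab)},
    )


def simulate_hybrid(
    system: HybridSystem,
    T: float,
    seed: int,
    t_grid: np.ndarray | None = None,
) -> Trajectory:
    """Run one hybrid realization to time ``T``.

    Loop: evaluate all birth/death propensities at the current hybrid state
    (negatives clipped to zero and counted), draw the next event wait
    tau ~ Exp(total), advance the deterministic coordinates over
    ``h = min(tau, dt, next-input-event gap, T - t)`` with counts frozen,
    then (if the event fired first) pick one channel proportional to its
    frozen propensity -- cumulative-sum inversion in species order, birth
    before death -- and apply +-1 with clamping at zero.  Deterministic
    coordinates are recorded on the output grid by interpolation, counts as
    right-continuous step functions.  Reproducible given the seed: event and
    channel draws consume one stream in fixed order.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if t_grid is None:
        t_grid = uniform_grid(T)
    model = system.model
    S = system.stochastic_idx
    D = system.deterministic_idx
    decomp = system.decomposition
    rng = np.random.default_rng(seed)

    x = system.initial_hybrid_state
    G = t_grid.size
    out = np.empty((G, model.n_species))
    k = 0
    while k < G and t_grid[k] <= 0.0:
        out[k] = x
        k += 1

    input_times = model.input_event_times()
    n_events = 0
    n_clip = 0
    n_prop_evals = 0
    t = 0.0
    have_D = D.size > 0
    xfull = x.copy()  # frozen-state buffer for the reduced drift

    def rhs_D(tt, yD):
        xfull[D] = yD
        return model.drift(xfull, tt)[D]

    while t < T - 1e-12:
        fp, fm = decomp.both(x, t)
        ap = fp[S]
        am = fm[S]
        n_prop_evals += 2 * S.size
        neg = int(np.count_nonzero(ap < 0) + np.count_nonzero(am < 0))
        if neg:
            n_clip += neg
            ap = np.maximum(ap, 0.0)
            am = np.maximum(am, 0.0)
        a0 = ap.sum() + am.sum()
        tau = rng.exponential(1.0 / a0) if a0 > 0 else np.inf

        nxt = input_times[np.searchsorted(input_times, t, side="right"):]
        gap_input = (nxt[0] - t) if nxt.size else np.inf
        h_other = min(system.dt, gap_input, T - t)
        is_event = tau <= h_other
        h = tau if is_event else h_other
        t_new = t + h

        seg = t_grid[k:]
        seg = seg[seg <= t_new + 1e-9]
        if have_D:
            inner = seg[(seg > t + 1e-12) & (seg < t_new - 1e-12)]
            ts = np.concatenate(([t], inner, [t_new]))
            xfull[:] = x
            y = odeint(rhs_D, x[D], ts, tfirst=True,
                       rtol=system.rtol, atol=system.atol)
            if not np.all(np.isfinite(y)):
                raise RuntimeError(
                    f"hybrid ODE advance produced non-finite values near t={t:g}")
            if seg.size:
                m_in = inner.size
                out[k:k + m_in, :][:, D] = y[1:1 + m_in]
                out[k:k + m_in, :][:, S] = x[S]
                for j in range(m_in, seg.size):  # points coinciding with t_new
                    out[k + j, D] = y[-1]
                    out[k + j, S] = x[S]
            x[D] = y[-1]
        else:
            if seg.size:
                out[k:k + seg.size] = x
        k += seg.size

        if is_event:
            arr = np.empty(2 * S.size)
            arr[0::2] = ap
            arr[1::2] = am
            c = np.cumsum(arr)
            r = rng.random() * a0
            j = int(np.searchsorted(c, r, side="right"))
            j = min(j, arr.size - 1)
            sp = S[j // 2]
            x[sp] = max(x[sp] + (1.0 if j % 2 == 0 else -1.0), 0.0)
            n_events += 1
        t = t_new

    while k < G:
        out[k] = x
        k += 1

    if n_prop_evals and n_clip > 1e-3 * n_prop_evals:
        warnings.warn(
            f"{n_clip} of {n_prop_evals} propensity evaluations were negative "
            f"and clipped to zero (> 0.1%); the production/degradation "
            f"decomposition may be unsuitable for this model",
            stacklevel=2,
        )
    return Trajectory(
        times=t_grid, states=out, species_names=model.species_names,
        meta={"engine": "hybrid", "seed": seed, "dt": system.dt,
              "n_events": n_events, "n_clipped_propensities": n_clip,
              "labels": dict(system.labels)},
    )


def run_ensemble(
    system: HybridSystem,
    T: float,
    n_reps: int,
    base_seed: int,
    t_grid: np.ndarray | None = None,
) -> EnsembleResult:
    """Independent replicates; replicate ``r`` uses seed ``base_seed + r``.

    Seeding by replicate index makes the result independent of execution
    order (the replicate loop is trivially parallelizable).  Failed
    replicates are collected in a failure manifest instead of aborting the
    ensemble.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if t_grid is None:
        t_grid = uniform_grid(T)
    trajectories: list[Trajectory] = []
    seeds: list[int] = []
    failures: list[dict] = []
    for r in range(1, n_reps + 1):
        seed = base_seed + r
        try:
            trajectories.append(simulate_hybrid(system, T, seed, t_grid=t_grid))
            seeds.append(seed)
        except Exception as exc:  # noqa: BLE001 - partial results contract
            failures.append({"replicate": r, "seed": seed, "error": repr(exc)})
    return EnsembleResult(trajectories=trajectories, seeds=seeds, failures=failures)
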