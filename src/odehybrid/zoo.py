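"""Canonical models and a seeded generator of random biochemical ODE corpora.

The fixed models are the two-stage gene-expression benchmark (immigration-
death mRNA driving protein synthesis; closed-form stationary moments make it
the oracle for every simulator in the package) and a symmetric repressilator
toy.  ``generate_corpus`` emulates a training corpus of ODE models spanning
low-copy and high-abundance regimes across five model families; it is
first-class, deterministic-by-seed code, not a test fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Decomposition, ModelError, OdeModel, Species, validate_model

__all__ = [
    "BENCHMARK_PARAMS",
    "make_benchmark_model",
    "benchmark_steady_state",
    "benchmark_stationary_variance",
    "make_repressilator",
    "CorpusSpec",
    "Corpus",
    "generate_corpus",
    "FAMILY_BUILDERS",
]

# ---------------------------------------------------------------------------
# two-stage gene expression benchmark
# ---------------------------------------------------------------------------

#: Benchmark rates.  Round numbers chosen so the deterministic steady state is
#: exactly (M*, P*) = (5, 2500) with analytic stationary variances
#: Var(M) = 5 (Poisson) and Var(P) = P* (1 + k2/(d1+d2)) ~ 1.16e5.
BENCHMARK_PARAMS = {"k1": 5.0, "d1": 1.0, "k2": 50.0, "d2": 0.1}


def make_benchmark_model(
    k1: float = 5.0, d1: float = 1.0, k2: float = 50.0, d2: float = 0.1,
    M0: float = 0.0, P0: float = 0.0,
) -> OdeModel:
    """Two-stage gene expression: dM/dt = k1 - d1 M, dP/dt = k2 M - d2 P.

    Count units, exact production/degradation decomposition
    (f+ = (k1, k2 M), f- = (d1 M, d2 P)).
    """

    def drift(x, t):
        M, P = x
        return np.array([k1 - d1 * M, k2 * M - d2 * P])

    def production(x, t):
        M, P = x
        return np.array([k1, k2 * M])

    def degradation(x, t):
        M, P = x
        return np.array([d1 * M, d2 * P])

    return OdeModel(
        species=[Species("M"), Species("P")],
        parameters={"k1": k1, "d1": d1, "k2": k2, "d2": d2},
        drift=drift,
        initial_state=[M0, P0],
        decomposition=Decomposition(production, degradation),
        name="benchmark",
    )


def benchmark_steady_state(
    k1: float = 5.0, d1: float = 1.0, k2: float = 50.0, d2: float = 0.1
) -> np.ndarray:
    """Deterministic fixed point (M*, P*) = (k1/d1, k1 k2/(d1 d2))."""
    return np.array([k1 / d1, k1 * k2 / (d1 * d2)])


def benchmark_stationary_variance(
    k1: float = 5.0, d1: float = 1.0, k2: float = 50.0, d2: float = 0.1
) -> np.ndarray:
    """Exact stationary variances of the two-stage model.

    The mRNA is an immigration-death process, stationarily Poisson(k1/d1), so
    Var(M) = k1/d1.  The protein inherits translational bursting:
    Var(P) = P* (1 + k2/(d1+d2)), from the stationary moment equations of the
    linear birth-death pair.
    """
    Ms, Ps = benchmark_steady_state(k1, d1, k2, d2)
    return np.array([Ms, Ps * (1.0 + k2 / (d1 + d2))])


# ---------------------------------------------------------------------------
# repressilator toy
# ---------------------------------------------------------------------------

def make_repressilator(
    alpha: float = 216.0,
    hill: float = 2.0,
    beta: float = 0.2,
    hill_k: float = 1.0,
    protein_scale: float = 1.0,
    init: list[float] | None = None,
) -> OdeModel:
    """Six-species symmetric repressilator (count units).

    dm_i/dt = alpha / (1 + (p_{i-1}/K)^n) - m_i
    dp_i/dt = beta (protein_scale * m_i - p_i)

    with cyclic repression p3 -| m1, p1 -| m2, p2 -| m3.  Defaults
    (alpha=216, n=2, beta=0.2, K=1) give sustained oscillation from the
    asymmetric initial state (10, 0, 0, 1, 1, 1.2).  ``protein_scale``
    amplifies the protein tier relative to the mRNA tier (its stationary
    gain), which is useful for building mRNA-low / protein-high examples.
    """
    if init is None:
        init = [10.0, 0.0, 0.0, protein_scale * 1.0, protein_scale * 1.0,
                protein_scale * 1.2]
    rep_of = [5, 3, 4]  # index of the protein repressing m1, m2, m3

    def hill_prod(p):
        return alpha / (1.0 + (p / hill_k) ** hill)

    def drift(x, t):
        m = x[:3]
        out = np.empty(6)
        for i in range(3):
            out[i] = hill_prod(x[rep_of[i]]) - m[i]
            out[3 + i] = beta * (protein_scale * m[i] - x[3 + i])
        return out

    def production(x, t):
        out = np.empty(6)
        for i in range(3):
            out[i] = hill_prod(x[rep_of[i]])
            out[3 + i] = beta * protein_scale * x[i]
        return out

    def degradation(x, t):
        out = np.empty(6)
        out[:3] = x[:3]
        out[3:] = beta * x[3:]
        return out

    return OdeModel(
        species=["m1", "m2", "m3", "p1", "p2", "p3"],
        parameters={"alpha": alpha, "hill": hill, "beta": beta,
                    "hill_k": hill_k, "protein_scale": protein_scale},
        drift=drift,
        initial_state=init,
        decomposition=Decomposition(production, degradation),
        name="repressilator",
    )


# ---------------------------------------------------------------------------
# parametric family builders (all count units, exact decompositions)
# ---------------------------------------------------------------------------

def build_birth_death_chain(k0: float, ks: list[float], ds: list[float]) -> OdeModel:
    """Linear chain X1 -> X2 -> ...: dx1 = k0 - d1 x1, dxi = k_i x_{i-1} - d_i xi."""
    ds = [float(d) for d in ds]
    ks = [float(k) for k in ks]
    n = len(ds)
    if len(ks) != n - 1:
        raise ModelError("birth_death_chain needs len(ks) == len(ds) - 1")

    def production(x, t):
        out = np.empty(n)
        out[0] = k0
        out[1:] = np.asarray(ks) * x[:-1]
        return out

    def degradation(x, t):
        return np.asarray(ds) * x

    def drift(x, t):
        return production(x, t) - degradation(x, t)

    return OdeModel(
        species=[f"X{i+1}" for i in range(n)],
        parameters={"k0": k0, "ks": ks, "ds": ds},
        drift=drift,
        initial_state=np.zeros(n),
        decomposition=Decomposition(production, degradation),
        name="birth_death_chain",
    )


def build_expression_cascade(
    km0: float, kact: list[float], dm: list[float], kp: list[float], dp: list[float]
) -> OdeModel:
    """Gene cascade m1 -> p1 -> m2 -> p2 -> ... with linear activation.

    dm_1 = km0 - dm_1 m1; dm_j = kact_{j-1} p_{j-1} - dm_j m_j;
    dp_j = kp_j m_j - dp_j p_j.  Species are ordered (m1, p1, m2, p2, ...).
    """
    G = len(dm)
    if not (len(kp) == len(dp) == G and len(kact) == G - 1):
        raise ModelError("expression_cascade parameter lists are inconsistent")
    dm = np.asarray(dm, float)
    kp = np.asarray(kp, float)
    dp = np.asarray(dp, float)
    kact_a = np.asarray(kact, float)

    def production(x, t):
        m = x[0::2]
        p = x[1::2]
        out = np.empty(2 * G)
        out[0] = km0
        out[2::2] = kact_a * p[:-1]
        out[1::2] = kp * m
        return out

    def degradation(x, t):
        out = np.empty(2 * G)
        out[0::2] = dm * x[0::2]
        out[1::2] = dp * x[1::2]
        return out

    def drift(x, t):
        return production(x, t) - degradation(x, t)

    names: list[str] = []
    for j in range(G):
        names += [f"m{j+1}", f"p{j+1}"]
    return OdeModel(
        species=names,
        parameters={"km0": km0, "kact": list(map(float, kact)),
                    "dm": dm.tolist(), "kp": kp.tolist(), "dp": dp.tolist()},
        drift=drift,
        initial_state=np.zeros(2 * G),
        decomposition=Decomposition(production, degradation),
        name="expression_cascade",
    )


def build_michaelis_menten_module(
    S0: float, vmax: float, km: float, k_in: float,
    ks: list[float], ds: list[float],
) -> OdeModel:
    """Saturable consumption of a substrate bolus feeding a product chain.

    dS  = k_in - vmax S/(km + S)            (S starts at a large bolus S0)
    dP1 = vmax S/(km + S) - d1 P1
    dPi = k_i P_{i-1} - d_i Pi

    The substrate transient makes trajectory mean/median poor predictors of
    the upper quantiles -- the burst regime where abundance heuristics err.
    """
    m = len(ds)
    if len(ks) != m - 1:
        raise ModelError("michaelis_menten_module needs len(ks) == len(ds) - 1")
    ds_a = np.asarray(ds, float)
    ks_a = np.asarray(ks, float)

    def mm_rate(S):
        return vmax * S / (km + S)

    def production(x, t):
        out = np.empty(1 + m)
        out[0] = k_in
        out[1] = mm_rate(x[0])
        out[2:] = ks_a * x[1:-1]
        return out

    def degradation(x, t):
        out = np.empty(1 + m)
        out[0] = mm_rate(x[0])
        out[1:] = ds_a * x[1:]
        return out

    def drift(x, t):
        return production(x, t) - degradation(x, t)

    init = np.zeros(1 + m)
    init[0] = S0
    return OdeModel(
        species=["S"] + [f"P{i+1}" for i in range(m)],
        parameters={"S0": S0, "vmax": vmax, "km": km, "k_in": k_in,
                    "ks": ks_a.tolist(), "ds": ds_a.tolist()},
        drift=drift,
        initial_state=init,
        decomposition=Decomposition(production, degradation),
        name="michaelis_menten_module",
    )


def build_autoregulation(
    alpha: float, K: float, hill: float, dm: float, kp: float, dp: float
) -> OdeModel:
    """Negatively autoregulated gene: protein represses its own transcription.

    dm = alpha / (1 + (p/K)^n) - dm m;  dp = kp m - dp p.
    """

    def production(x, t):
        m, p = x
        return np.array([alpha / (1.0 + (p / K) ** hill), kp * m])

    def degradation(x, t):
        m, p = x
        return np.array([dm * m, dp * p])

    def drift(x, t):
        return production(x, t) - degradation(x, t)

    return OdeModel(
        species=["m", "p"],
        parameters={"alpha": alpha, "K": K, "hill": hill,
                    "dm": dm, "kp": kp, "dp": dp},
        drift=drift,
        initial_state=[0.0, 0.0],
        decomposition=Decomposition(production, degradation),
        name="autoregulation",
    )


def build_repressilator_variant(
    alpha: float, hill: float, beta: float, hill_k: float
) -> OdeModel:
    model = make_repressilator(alpha=alpha, hill=hill, beta=beta, hill_k=hill_k,
                               init=[10.0 * hill_k, 0.0, 0.0,
                                     hill_k, hill_k, 1.2 * hill_k])
    return model.replace(name="repressilator_variant")


#: Registry of parametric builders; the declarative model-file loader and the
#: corpus serializer reconstruct models through this table.
FAMILY_BUILDERS = {
    "benchmark": make_benchmark_model,
    "repressilator": make_repressilator,
    "birth_death_chain": build_birth_death_chain,
    "expression_cascade": build_expression_cascade,
    "repressilator_variant": build_repressilator_variant,
    "michaelis_menten_module": build_michaelis_menten_module,
    "autoregulation": build_autoregulation,
}


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _default_mix() -> dict[str, float]:
    # The cascade family gets double weight: it is the only family that mixes
    # low-copy mRNA and high-abundance protein tiers within one model, and the
    # extra weight keeps the default corpus in the 200-400 total-species range.
    return {
        "birth_death_chain": 1.0,
        "expression_cascade": 2.0,
        "repressilator_variant": 1.0,
        "michaelis_menten_module": 1.0,
        "autoregulation": 1.0,
    }


@dataclass
class CorpusSpec:
    """Specification of a synthetic training corpus.

    Default scale ranges mirror the mRNA/protein copy-number gap: low-copy
    species equilibrate in [1, 120] molecules and abundant species in
    [400, 1e6], leaving the 150-300 band (swept by the labeling-threshold
    sensitivity analysis) essentially unpopulated.
    """

    n_models: int = 40
    seed: int = 0
    family_mix: dict[str, float] = field(default_factory=_default_mix)
    low_copy_scale_range: tuple[float, float] = (1.0, 120.0)
    high_copy_scale_range: tuple[float, float] = (400.0, 1e6)
    presim_horizon: float = 500.0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ModelError("n_models must be positive")
        weights = np.array(list(self.family_mix.values()), float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ModelError("family_mix weights must be non-negative with positive sum")
        unknown = set(self.family_mix) - set(FAMILY_BUILDERS)
        if unknown:
            raise ModelError(f"unknown families in family_mix: {sorted(unknown)}")
        for rng_name in ("low_copy_scale_range", "high_copy_scale_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo < hi):
                raise ModelError(f"{rng_name} must be ordered with positive endpoints")


@dataclass
class Corpus:
    """Generated models plus per-model metadata (family, seed offset, params)."""

    models: list[OdeModel]
    metadata: list[dict]
    spec: CorpusSpec

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def total_species(self) -> int:
        return sum(m.n_species for m in self.models)


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _sample_scale(rng: np.random.Generator, spec: CorpusSpec, low: bool,
                  cap: float | None = None) -> float:
    lo, hi = spec.low_copy_scale_range if low else spec.high_copy_scale_range
    if cap is not None:
        hi = min(hi, cap)
    return float(_loguniform(rng, lo, hi))


def _sample_birth_death_chain(rng, spec):
    n = int(rng.integers(2, 7))
    low = rng.random(n) < 0.5
    s = np.array([_sample_scale(rng, spec, bool(lo)) for lo in low])
    d = _loguniform(rng, 0.2, 2.0, size=n)
    k0 = d[0] * s[0]
    ks = (d[1:] * s[1:] / s[:-1]).tolist()
    return {"k0": float(k0), "ks": ks, "ds": d.tolist()}


def _sample_expression_cascade(rng, spec):
    G = int(rng.integers(3, 7))  # 3-6 genes -> 6-12 species
    s_m = np.array([_sample_scale(rng, spec, low=True) for _ in range(G)])
    s_p = np.array([_sample_scale(rng, spec, low=False) for _ in range(G)])
    dm = _loguniform(rng, 0.2, 2.0, size=G)
    dp = _loguniform(rng, 0.1, 1.0, size=G)
    km0 = dm[0] * s_m[0]
    kact = (dm[1:] * s_m[1:] / s_p[:-1]).tolist()
    kp = (dp * s_p / s_m).tolist()
    return {"km0": float(km0), "kact": kact, "dm": dm.tolist(),
            "kp": kp, "dp": dp.tolist()}


def _sample_repressilator_variant(rng, spec):
    # Amplitude capped well below the low/high gap: every species stays in the
    # low-copy regime (the oscillator stands in for noisy circuit mRNAs).
    c = float(_loguniform(rng, 0.05, 0.55))
    return {"alpha": 216.0 * c, "hill": float(rng.choice([2.0, 3.0])),
            "beta": float(_loguniform(rng, 0.1, 0.5)), "hill_k": c}


def _sample_michaelis_menten_module(rng, spec):
    m = int(rng.integers(2, 5))  # chain of 2-4 products -> 3-5 species
    S0 = float(_loguniform(rng, 3000.0, 9000.0))
    t_burst = float(rng.uniform(5.0, 15.0))
    vmax = S0 / t_burst
    km = float(_loguniform(rng, 20.0, 100.0))
    s1 = float(_loguniform(rng, 1.0, 100.0))
    d1 = float(_loguniform(rng, 0.05, 0.3))
    k_in = d1 * s1
    ds = [d1]
    ks = []
    s_prev = s1
    for _ in range(m - 1):
        low = rng.random() < 0.5
        s_i = _sample_scale(rng, spec, low, cap=100.0 if low else None)
        d_i = float(_loguniform(rng, 0.3, 1.0))
        ks.append(d_i * s_i / s_prev)
        ds.append(d_i)
        s_prev = s_i
    return {"S0": S0, "vmax": vmax, "km": km, "k_in": k_in, "ks": ks, "ds": ds}


def _sample_autoregulation(rng, spec):
    s_m = float(_loguniform(rng, 1.0, 70.0))
    s_p = _sample_scale(rng, spec, low=False)
    dm = float(_loguniform(rng, 0.2, 1.0))
    dp = float(_loguniform(rng, 0.1, 0.5))
    return {"alpha": 2.0 * dm * s_m, "K": s_p,
            "hill": float(rng.choice([1.0, 2.0])),
            "dm": dm, "kp": dp * s_p / s_m, "dp": dp}


_FAMILY_SAMPLERS = {
    "birth_death_chain": _sample_birth_death_chain,
    "expression_cascade": _sample_expression_cascade,
    "repressilator_variant": _sample_repressilator_variant,
    "michaelis_menten_module": _sample_michaelis_menten_module,
    "autoregulation": _sample_autoregulation,
}


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a deterministic corpus of validated count-unit ODE models.

    Each model draws its family from ``spec.family_mix`` and its rate
    constants log-uniformly so that every species' deterministic stationary
    scale lands near a target sampled from the low- or high-copy range.  The
    per-model random stream is seeded from ``(spec.seed, model_index)``, so
    the same spec and seed reproduce the corpus bitwise.
    """
    families = sorted(spec.family_mix)
    weights = np.array([spec.family_mix[f] for f in families], float)
    weights = weights / weights.sum()

    models: list[OdeModel] = []
    metadata: list[dict] = []
    for i in range(spec.n_models):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        family = str(rng.choice(families, p=weights))
        params = _FAMILY_SAMPLERS[family](rng, spec)
        model = FAMILY_BUILDERS[family](**params)
        model = model.replace(name=f"{family}_{i:03d}")
        issues = validate_model(model)
        if issues:  # pragma: no cover - generator invariant
            raise ModelError(f"generated model {model.name} failed validation: {issues}")
        models.append(model)
        metadata.append({
            "model_id": model.name,
            "family": family,
            "seed_offset": i,
            "n_species": model.n_species,
            "params": params,
        })
    return Corpus(models=models, metadata=metadata, spec=spec)
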