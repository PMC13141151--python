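"""Core representation of ODE-defined biochemical models.

A model is a right-hand-side evaluator ``f(x, t)`` over an ordered species
list, together with parameters, initial conditions, optional compartments
(for concentration -> molecule-count conversion) and an optional
production/degradation decomposition ``f = f_plus - f_minus`` of the drift.
The decomposition is what turns an ODE into stochastic birth/death
propensities in the hybrid engine, so its non-negativity and consistency are
checked explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "AVOGADRO",
    "MOLAR_UNIT_FACTORS",
    "Compartment",
    "Species",
    "InputSignal",
    "Decomposition",
    "OdeModel",
    "ConversionReport",
    "ModelError",
    "DecompositionError",
    "validate_model",
    "convert_to_counts",
    "default_decomposition",
]

#: Avogadro constant, molecules per mole (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Supported molar units and their value in mol/L.  Deliberately an enumerated
#: set -- no free-text unit parsing.
MOLAR_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}

# Probe-state convention used by validate_model / default_decomposition:
# the initial state plus 32 states drawn component-wise from the initial
# state scaled by Uniform(0.1, 10), fixed seed.
_PROBE_SEED = 1234
_N_PROBES = 32


class ModelError(ValueError):
    """Raised for structurally invalid models."""


class DecompositionError(ModelError):
    """Raised when a production/degradation split cannot be built or used."""


@dataclass(frozen=True)
class Compartment:
    """A well-mixed compartment with a fixed volume in litres."""

    id: str
    volume: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.volume) and self.volume > 0):
            raise ModelError(
                f"compartment {self.id!r}: volume must be positive and finite, "
                f"got {self.volume!r}"
            )


@dataclass(frozen=True)
class Species:
    """One model species: name, home compartment and unit kind."""

    name: str
    compartment: str = "cell"
    unit_kind: str = "count"  # "count" or "concentration"

    def __post_init__(self) -> None:
        if self.unit_kind not in ("count", "concentration"):
            raise ModelError(
                f"species {self.name!r}: unit_kind must be 'count' or "
                f"'concentration', got {self.unit_kind!r}"
            )


@dataclass(frozen=True)
class InputSignal:
    """A (possibly discontinuous) external input evaluated at local time.

    ``event_times`` lists the discontinuities so that simulators never step
    across one: the hybrid and reference engines cap their step at the next
    event time.
    """

    name: str
    value: Callable[[float], float]
    event_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ts = np.asarray(self.event_times, dtype=float)
        if ts.size and not np.all(np.diff(ts) > 0):
            raise ModelError(
                f"input {self.name!r}: event_times must be strictly increasing"
            )


@dataclass
class Decomposition:
    """Production/degradation split of the drift: ``f = production - degradation``.

    Both evaluators map ``(x, t)`` to a full-length per-species vector and are
    expected to be elementwise non-negative on non-negative states.
    ``consistent`` records whether ``production - degradation == drift`` held on
    the probe states (the automatic split violates it for autocatalytic
    drifts, where production depends on the focal species itself).
    """

    production: Callable[[np.ndarray, float], np.ndarray]
    degradation: Callable[[np.ndarray, float], np.ndarray]
    consistent: bool = True
    source: str = "user"  # "user" or "auto"

    def both(self, x: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate production and degradation together."""
        return (
            np.asarray(self.production(x, t), dtype=float),
            np.asarray(self.degradation(x, t), dtype=float),
        )


class OdeModel:
    """An ODE model: ordered species, parameters, drift, initial state.

    Parameters
    ----------
    species:
        Ordered sequence of :class:`Species` (or bare names, taken as
        count-unit species in the default compartment).
    parameters:
        Mapping of rate-constant names to values; carried for provenance and
        serialization, the drift closure is free to capture them directly.
    drift:
        Callable ``(x, t) -> dx/dt`` returning a vector of the same length
        and order as ``species``.
    initial_state:
        Initial value per species, in the species' own units.
    decomposition:
        Optional explicit :class:`Decomposition` of the drift.
    compartments:
        Mapping id -> :class:`Compartment`; only required for conversion of
        concentration species.
    inputs:
        Optional external :class:`InputSignal` objects (their event times
        bound simulator steps).
    """

    def __init__(
        self,
        species: Sequence[Species | str],
        parameters: Mapping[str, float],
        drift: Callable[[np.ndarray, float], np.ndarray],
        initial_state: Sequence[float],
        decomposition: Decomposition | None = None,
        compartments: Mapping[str, Compartment] | None = None,
        inputs: Sequence[InputSignal] = (),
        name: str = "model",
    ) -> None:
        self.species: tuple[Species, ...] = tuple(
            s if isinstance(s, Species) else Species(str(s)) for s in species
        )
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate species names in {names}")
        self.parameters = dict(parameters)
        self._drift = drift
        self.initial_state = np.asarray(initial_state, dtype=float)
        if self.initial_state.shape != (len(self.species),):
            raise ModelError(
                f"initial_state has length {self.initial_state.size}, "
                f"expected {len(self.species)}"
            )
        self.decomposition = decomposition
        self.compartments = dict(compartments or {})
        self.inputs = tuple(inputs)
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def unit_kinds(self) -> list[str]:
        return [s.unit_kind for s in self.species]

    def drift(self, x: np.ndarray, t: float) -> np.ndarray:
        """Evaluate the right-hand side as a float vector."""
        return np.asarray(self._drift(np.asarray(x, dtype=float), t), dtype=float)

    def input_event_times(self) -> np.ndarray:
        """Merged, sorted discontinuity times of all input signals."""
        ts = sorted({t for sig in self.inputs for t in sig.event_times})
        return np.asarray(ts, dtype=float)

    def decomposition_or_default(self) -> Decomposition:
        """The user decomposition if present, else the automatic zero-clamp one."""
        if self.decomposition is not None:
            return self.decomposition
        return default_decomposition(self)

    def replace(self, **kwargs) -> "OdeModel":
        """A copy of the model with some constructor fields replaced."""
        base = dict(
            species=self.species,
            parameters=self.parameters,
            drift=self._drift,
            initial_state=self.initial_state,
            decomposition=self.decomposition,
            compartments=self.compartments,
            inputs=self.inputs,
            name=self.name,
        )
        base.update(kwargs)
        return OdeModel(**base)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OdeModel({self.name!r}, n_species={self.n_species}, "
            f"units={set(self.unit_kinds)})"
        )


@dataclass
class ConversionReport:
    """Record of a concentration -> molecule-count conversion.

    ``omega`` holds the per-species scale factor (molecules per
    concentration unit); species already expressed in counts carry
    ``omega = 1``.
    """

    omega: np.ndarray
    original_units: list[str]
    converted_initial: np.ndarray
    molar_unit: str = "uM"
    species_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def probe_states(model: OdeModel, n_probes: int = _N_PROBES, seed: int = _PROBE_SEED) -> np.ndarray:
    """Probe states: the initial state plus random componentwise rescalings.

    Each extra probe multiplies the initial state componentwise by
    Uniform(0.1, 10) draws; with a fixed seed this gives cheap, reproducible
    coverage of the non-negative orthant around the initial condition.
    """
    x0 = np.asarray(model.initial_state, dtype=float)
    rng = np.random.default_rng(seed)
    scales = rng.uniform(0.1, 10.0, size=(n_probes, x0.size))
    return np.vstack([x0[None, :], scales * x0[None, :]])


def validate_model(model: OdeModel, t: float = 0.0) -> list[str]:
    """Check the model invariants on a probe set; return human-readable issues.

    An empty list means the model is well formed: the drift returns a finite
    vector of the right length at every probe state and, if a decomposition
    is present, it is elementwise non-negative and reproduces the drift to
    absolute tolerance ``1e-9 * (1 + |f|)``.  Never raises on a misbehaving
    drift -- evaluator exceptions become diagnostics.
    """
    issues: list[str] = []
    states = probe_states(model)
    names = model.species_names
    for k, x in enumerate(states):
        try:
            f = model.drift(x, t)
        except Exception as exc:  # noqa: BLE001 - diagnostics, not crash
            issues.append(f"drift raised at probe state {k}: {exc!r}")
            continue
        if f.shape != (model.n_species,):
            issues.append(
                f"drift length mismatch: got {f.size}, expected {model.n_species}"
            )
            break
        if not np.all(np.isfinite(f)):
            bad = [names[i] for i in np.flatnonzero(~np.isfinite(f))]
            issues.append(f"drift not finite at probe state {k} for species {bad}")
            continue
        if model.decomposition is not None:
            try:
                fp, fm = model.decomposition.both(x, t)
            except Exception as exc:  # noqa: BLE001
                issues.append(f"decomposition raised at probe state {k}: {exc!r}")
                continue
            if fp.shape != f.shape or fm.shape != f.shape:
                issues.append("decomposition length mismatch with drift")
                break
            tol = 1e-9 * (1.0 + np.abs(f))
            err = np.abs(fp - fm - f)
            if np.any(err > tol):
                bad = [names[i] for i in np.flatnonzero(err > tol)]
                issues.append(
                    f"decomposition inconsistent with drift at probe state {k} "
                    f"for species {bad}"
                )
            if np.any(fp < 0) or np.any(fm < 0):
                bad = [
                    names[i]
                    for i in np.flatnonzero((fp < 0) | (fm < 0))
                ]
                issues.append(
                    f"decomposition negative at probe state {k} for species {bad}"
                )
    # deduplicate while keeping order
    seen: set[str] = set()
    unique = [m for m in issues if not (m in seen or seen.add(m))]
    return unique


# ---------------------------------------------------------------------------
# concentration -> count conversion
# ---------------------------------------------------------------------------

def convert_to_counts(model: OdeModel, molar_unit: str = "uM") -> tuple[OdeModel, ConversionReport]:
    """Convert concentration species to molecule counts.

    For a species in compartment ``c`` expressed in the given molar unit the
    scale factor is ``omega = N_A * V_c * u`` (``u`` = mol/L per unit); the
    converted state is ``n = omega * x`` and the converted drift is
    ``dn/dt = omega * f(n / omega, t)``.  Count species pass through with
    ``omega = 1``; time units are unchanged; any decomposition is transformed
    identically.
    """
    if molar_unit not in MOLAR_UNIT_FACTORS:
        raise ModelError(
            f"unknown molar unit {molar_unit!r}; choose from "
            f"{sorted(set(MOLAR_UNIT_FACTORS))}"
        )
    u = MOLAR_UNIT_FACTORS[molar_unit]
    omega = np.ones(model.n_species)
    for i, sp in enumerate(model.species):
        if sp.unit_kind != "concentration":
            continue
        comp = model.compartments.get(sp.compartment)
        if comp is None:
            raise ModelError(
                f"species {sp.name!r} is in concentration units but its "
                f"compartment {sp.compartment!r} has no defined volume"
            )
        omega[i] = AVOGADRO * comp.volume * u

    report = ConversionReport(
        omega=omega.copy(),
        original_units=list(model.unit_kinds),
        converted_initial=omega * model.initial_state,
        molar_unit=molar_unit,
        species_names=model.species_names,
    )
    if np.all(omega == 1.0):
        return model, report

    base_drift = model._drift

    def drift_counts(n: np.ndarray, t: float, _om=omega, _f=base_drift) -> np.ndarray:
        return _om * np.asarray(_f(np.asarray(n, float) / _om, t), dtype=float)

    decomposition = None
    if model.decomposition is not None:
        prod, deg = model.decomposition.production, model.decomposition.degradation

        def prod_counts(n, t, _om=omega, _g=prod):
            return _om * np.asarray(_g(np.asarray(n, float) / _om, t), dtype=float)

        def deg_counts(n, t, _om=omega, _g=deg):
            return _om * np.asarray(_g(np.asarray(n, float) / _om, t), dtype=float)

        decomposition = Decomposition(
            prod_counts,
            deg_counts,
            consistent=model.decomposition.consistent,
            source=model.decomposition.source,
        )

    converted = OdeModel(
        species=[Species(s.name, s.compartment, "count") for s in model.species],
        parameters=model.parameters,
        drift=drift_counts,
        initial_state=report.converted_initial,
        decomposition=decomposition,
        compartments=model.compartments,
        inputs=model.inputs,
        name=model.name,
    )
    return converted, report


# ---------------------------------------------------------------------------
# automatic production/degradation decomposition
# ---------------------------------------------------------------------------

def default_decomposition(model: OdeModel, t_probe: float = 0.0) -> Decomposition:
    """Derive a minimal production/degradation split from the drift.

    The zero-clamp rule: production of species ``i`` is the drift component
    with ``x_i`` clamped to zero (degradation terms typically vanish at zero
    copy number), floored at zero; degradation is the non-negative remainder::

        f_plus_i(x, t)  = max(f_i(x | x_i := 0, t), 0)
        f_minus_i(x, t) = max(f_plus_i(x, t) - f_i(x, t), 0)

    For drifts whose production depends on the focal species itself
    (autocatalysis) the identity ``f_plus - f_minus == f`` fails; this is
    detected on the probe states, a warning is emitted, and the returned
    decomposition carries ``consistent=False`` -- such models need an
    explicit user-supplied split before stochastic simulation.
    """
    if model.decomposition is not None:
        return model.decomposition

    n = model.n_species
    names = model.species_names
    base = model._drift

    def production(x: np.ndarray, t: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        fp = np.empty(n)
        for i in range(n):
            xz = x.copy()
            xz[i] = 0.0
            try:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fi = float(np.asarray(base(xz, t), dtype=float)[i])
            except Exception as exc:
                raise DecompositionError(
                    f"drift is undefined with species {names[i]!r} clamped to "
                    f"zero ({exc!r}); supply an explicit production/"
                    f"degradation decomposition for this model"
                ) from exc
            if not np.isfinite(fi):
                raise DecompositionError(
                    f"drift is undefined (non-finite) with species "
                    f"{names[i]!r} clamped to zero; supply an explicit "
                    f"production/degradation decomposition for this model"
                )
            fp[i] = max(fi, 0.0)
        return fp

    def degradation(x: np.ndarray, t: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = np.asarray(base(x, t), dtype=float)
        return np.maximum(production(x, t) - f, 0.0)

    # consistency check on the probe states
    consistent = True
    for x in probe_states(model):
        f = model.drift(x, t_probe)
        fp = production(x, t_probe)
        fm = degradation(x, t_probe)
        if np.any(np.abs(fp - fm - f) > 1e-9 * (1.0 + np.abs(f))):
            consistent = False
            break
    if not consistent:
        warnings.warn(
            f"automatic production/degradation split of model "
            f"{model.name!r} does not reproduce the drift at probe states "
            f"(production likely depends on the focal species, e.g. "
            f"autocatalysis); degradation was clipped at zero.  Provide an "
            f"explicit decomposition for stochastic simulation.",
            stacklevel=2,
        )
    return Decomposition(production, degradation, consistent=consistent, source="auto")
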