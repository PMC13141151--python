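"""Model validation, concentration->count conversion and the automatic
production/degradation split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odehybrid as oh
from odehybrid.model import (AVOGADRO, Compartment, Decomposition,
                             DecompositionError, OdeModel, Species,
                             default_decomposition)


def _simple_model(drift, n=1, x0=None, decomposition=None, **kw):
    return OdeModel(
        species=[f"x{i}" for i in range(n)],
        parameters={},
        drift=drift,
        initial_state=x0 if x0 is not None else np.ones(n),
        decomposition=decomposition,
        **kw,
    )


class TestValidateModel:
    def test_well_formed_benchmark_has_no_diagnostics(self, benchmark_model):
        assert oh.validate_model(benchmark_model) == []

    def test_short_drift_vector_is_reported(self):
        m = _simple_model(lambda x, t: np.array([1.0]), n=2, x0=[1.0, 2.0])
        issues = oh.validate_model(m)
        assert any("length mismatch" in msg for msg in issues)

    def test_inconsistent_decomposition_names_species(self):
        drift = lambda x, t: -x  # noqa: E731
        bad = Decomposition(lambda x, t: -x + 1.0, lambda x, t: np.zeros_like(x))
        m = _simple_model(drift, n=1, x0=[2.0], decomposition=bad)
        issues = oh.validate_model(m)
        assert any("inconsistent" in msg and "x0" in msg for msg in issues)

    def test_raising_drift_becomes_diagnostic_not_crash(self):
        def drift(x, t):
            raise RuntimeError("boom")

        issues = oh.validate_model(_simple_model(drift, n=1))
        assert issues and "boom" in issues[0]


class TestConvertToCounts:
    def _conc_decay_model(self):
        return OdeModel(
            species=[Species("x", compartment="cell", unit_kind="concentration")],
            parameters={},
            drift=lambda x, t: -x,
            initial_state=[1.0],
            compartments={"cell": Compartment("cell", 1e-15)},
        )

    def test_micromolar_in_femtolitre_gives_602_molecules(self):
        converted, report = oh.convert_to_counts(self._conc_decay_model(), "uM")
        # n = 1e-6 mol/L * 1e-15 L * N_A
        expected = 1e-6 * 1e-15 * AVOGADRO
        assert report.omega[0] == pytest.approx(expected)
        assert converted.initial_state[0] == pytest.approx(602.214076, abs=1e-6)
        assert converted.unit_kinds == ["count"]

    def test_count_model_passes_through_with_unit_omega(self, benchmark_model):
        converted, report = oh.convert_to_counts(benchmark_model, "uM")
        assert converted is benchmark_model
        assert np.all(report.omega == 1.0)

    def test_converted_decay_matches_closed_form(self):
        converted, _ = oh.convert_to_counts(self._conc_decay_model(), "uM")
        traj = oh.ode_solve(converted, 1.0, rtol=1e-10, atol=1e-12,
                            t_grid=np.array([0.0, 1.0]))
        # dn/dt = -n with n(0) ~ 602.214 -> n(1) = n(0)/e ~ 221.54
        assert traj.states[-1, 0] == pytest.approx(602.214076 * np.exp(-1.0),
                                                   rel=1e-6)

    def test_missing_compartment_volume_is_an_error(self):
        m = OdeModel(
            species=[Species("x", compartment="nowhere", unit_kind="concentration")],
            parameters={}, drift=lambda x, t: -x, initial_state=[1.0],
        )
        with pytest.raises(Exception, match="nowhere"):
            oh.convert_to_counts(m, "uM")

    def test_unknown_molar_unit_rejected(self, benchmark_model):
        with pytest.raises(Exception, match="molar unit"):
            oh.convert_to_counts(benchmark_model, "furlongs")

    @given(st.floats(0.1, 50.0), st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conversion_round_trip_for_polynomial_drift(self, x_val, rate):
        m = OdeModel(
            species=[Species("x", unit_kind="concentration")],
            parameters={},
            drift=lambda x, t: rate * x**2 - x,
            initial_state=[x_val],
            compartments={"cell": Compartment("cell", 1e-15)},
        )
        converted, rep = oh.convert_to_counts(m, "nM")
        omega = rep.omega[0]
        n = omega * x_val
        f_n = converted.drift(np.array([n]), 0.0)[0]
        f_x = m.drift(np.array([x_val]), 0.0)[0]
        assert f_n / omega == pytest.approx(f_x, rel=1e-12)


class TestDefaultDecomposition:
    def test_constant_production_linear_decay(self):
        m = _simple_model(lambda x, t: 5.0 - x, n=1, x0=[3.0])
        d = default_decomposition(m)
        x = np.array([3.0])
        assert d.production(x, 0.0)[0] == pytest.approx(5.0)
        assert d.degradation(x, 0.0)[0] == pytest.approx(3.0)
        assert d.consistent

    def test_hill_repression_drift(self):
        # f_m = beta/(1+p^2) - m with beta=10 at (m,p) = (4,3):
        # production = 10/10 = 1 (m clamped to 0), degradation = 1 - (1-4) = 4
        def drift(x, t):
            m, p = x
            return np.array([10.0 / (1.0 + p**2) - m, 0.0])

        m = _simple_model(drift, n=2, x0=[4.0, 3.0])
        d = default_decomposition(m)
        fp, fm = d.both(np.array([4.0, 3.0]), 0.0)
        assert fp[0] == pytest.approx(1.0)
        assert fm[0] == pytest.approx(4.0)

    def test_pure_decay_is_absorbing_at_zero(self):
        m = _simple_model(lambda x, t: -x, n=1, x0=[1.0])
        d = default_decomposition(m)
        fp, fm = d.both(np.array([0.0]), 0.0)
        assert fp[0] == 0.0 and fm[0] == 0.0

    def test_user_decomposition_is_returned_untouched(self, benchmark_model):
        assert default_decomposition(benchmark_model) is benchmark_model.decomposition

    def test_drift_undefined_at_zero_names_species(self):
        m = _simple_model(lambda x, t: 1.0 / x, n=1, x0=[2.0])
        with pytest.raises(DecompositionError, match="x0"):
            default_decomposition(m)

    def test_autocatalytic_drift_flagged_inconsistent(self):
        with pytest.warns(UserWarning, match="autocatalysis"):
            d = default_decomposition(_simple_model(lambda x, t: x, n=1, x0=[1.0]))
        assert not d.consistent

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_mass_action_split_is_exact(self, seed):
        """For dx = A x + b with non-negative off-diagonal/production terms the
        zero-clamp split satisfies f+ - f- = f exactly on non-negative states,
        and degradation vanishes at zero copy number."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        A = rng.uniform(0.0, 2.0, (n, n))
        A[np.diag_indices(n)] = -rng.uniform(0.1, 2.0, n)
        b = rng.uniform(0.0, 5.0, n)
        m = _simple_model(lambda x, t: A @ x + b, n=n,
                          x0=rng.uniform(0.0, 10.0, n))
        d = default_decomposition(m)
        assert d.consistent
        for _ in range(5):
            x = rng.uniform(0.0, 10.0, n)
            i = int(rng.integers(0, n))
            x[i] = 0.0
            fp, fm = d.both(x, 0.0)
            f = m.drift(x, 0.0)
            np.testing.assert_allclose(fp - fm, f, atol=1e-9)
            assert fm[i] == 0.0  # no negative-count pressure at zero
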