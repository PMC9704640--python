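"""Forward-model building blocks: mixing, fractionation shifts, the
case-study equations, source recalculation and expression compilation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isomix import (
    AuxParam,
    AuxVariableSpec,
    Measurement,
    MixingState,
    ModelSpec,
    SignatureSet,
    SourceSpec,
    build_model_from_expression,
    builtin_equation,
    craig_gordon_mu,
    equilibrium_shift,
    invert_evaporation,
    mix_mu0,
    n2o_model,
    nitrite_model,
    open_system_reduced_shift,
    open_system_shift,
    rayleigh_shift,
    recalc_nitrification_source,
)
from isomix.expressions import ExpressionError

simplex3 = st.tuples(
    st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0)
).map(lambda t: np.array(t) / sum(t))


class TestMixMu0:
    def test_river_nitrate_mixture(self):
        # 20% river + 60% fertilizer + 20% manure on d15N
        mu = mix_mu0([0.2, 0.6, 0.2], np.array([[5.0], [-16.5], [3.0]]))
        assert mu[0] == pytest.approx(-8.3, abs=1e-12)

    def test_pure_endmember_identity(self):
        S = np.array([[5.0, 2.5], [-16.5, 11.2], [3.0, 4.5]])
        assert np.allclose(mix_mu0([1.0, 0.0, 0.0], S), S[0])

    def test_equal_thirds(self):
        mu = mix_mu0([1 / 3] * 3, np.array([[0.0], [10.0], [20.0]]))
        assert mu[0] == pytest.approx(10.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            mix_mu0([0.5, 0.5], np.array([[1.0], [2.0], [3.0]]))

    @given(f=simplex3)
    def test_convex_combination(self, f):
        S = np.array([[0.0, 0.0], [10.0, 30.0], [20.0, 0.0]])
        mu = mix_mu0(f, S)
        assert np.all(mu >= S.min(axis=0) - 1e-12)
        assert np.all(mu <= S.max(axis=0) + 1e-12)


class TestFractionationShifts:
    def test_open_system_no_reaction(self):
        mu0 = np.array([3.0, -7.0])
        assert np.allclose(open_system_shift(mu0, np.array([5.0, 5.0]), 1.0), mu0)

    def test_open_system_hand_value(self):
        assert open_system_shift(np.array([10.0]), np.array([-5.0]), 0.5)[0] == 12.5

    def test_open_system_reduced_river_point_C(self):
        # 60% denitrified mixture at river point B
        mu = open_system_reduced_shift(
            np.array([-8.3, 8.1]), np.array([-15.9, -8.0]), 0.6
        )
        assert mu == pytest.approx([1.24, 12.9], abs=1e-12)

    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_open_system_domain(self, r):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            open_system_shift(np.array([0.0]), np.array([1.0]), r)

    def test_rayleigh_identity_at_r1(self):
        mu0 = np.array([-46.62])
        assert np.allclose(rayleigh_shift(mu0, np.array([-7.1]), 1.0), mu0)

    @pytest.mark.parametrize(
        "r,expected", [(0.8, -45.0), (0.2, -35.2)], ids=["x2", "x1"]
    )
    def test_rayleigh_n2o_d15N(self, r, expected):
        mu0 = 0.9 * -47.6 + 0.1 * -37.8
        mu = rayleigh_shift(np.array([mu0]), np.array([-7.1]), r)
        assert round(float(mu[0]), 1) == expected

    def test_rayleigh_domain(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            rayleigh_shift(np.array([0.0]), np.array([1.0]), 0.0)

    def test_equilibrium_endpoints(self):
        mu0, E = np.array([12.65]), np.array([8.6])
        assert np.allclose(equilibrium_shift(mu0, E, 0.0), mu0)
        assert np.allclose(equilibrium_shift(mu0, E, 1.0), E)
        assert equilibrium_shift(mu0, E, 0.25)[0] == pytest.approx(11.6375)

    def test_equilibrium_multiplier_domain(self):
        with pytest.raises(ValueError, match="exceed 1"):
            equilibrium_shift(np.array([0.0]), np.array([1.0]), 0.9,
                              per_signature_multiplier=[2.0])

    @given(r=st.floats(0.01, 1.0))
    def test_no_process_points(self, r):
        """All shifts return mu0 exactly at their no-process point."""
        mu0 = np.array([4.2, -11.0])
        A = np.array([-5.0, -3.0])
        assert np.allclose(open_system_shift(mu0, A, 1.0), mu0)
        assert np.allclose(rayleigh_shift(mu0, A, 1.0), mu0)
        assert np.allclose(equilibrium_shift(mu0, A, 0.0), mu0)
        assert np.allclose(craig_gordon_mu(mu0, A, np.array([5.0, 1.0]), 0.0), mu0)
        # and each shift is continuous/finite elsewhere on its domain
        assert np.all(np.isfinite(rayleigh_shift(mu0, A, r)))


class TestCraigGordon:
    def test_lakewater_d18O(self):
        mu = craig_gordon_mu(np.array([-5.0]), np.array([1.7881]),
                             np.array([5.6063]), 0.2206)
        assert mu[0] == pytest.approx(-2.0, abs=5e-4)

    def test_lakewater_d2H(self):
        mu = craig_gordon_mu(np.array([-34.0]), np.array([1.5824]),
                             np.array([0.2946]), 0.2248)
        assert mu[0] == pytest.approx(-25.0, abs=5e-3)

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            craig_gordon_mu(np.array([-5.0]), np.array([1.0]), np.array([1.0]), -0.1)

    @given(r=st.floats(0.0, 1.0), mu0=st.floats(-50.0, 10.0))
    def test_roundtrip_with_analytic_inverse(self, r, mu0):
        A, D = 1.7881, 5.6063
        mu = float(craig_gordon_mu(np.array([mu0]), np.array([A]), np.array([D]), r)[0])
        assert invert_evaporation(mu, mu0, A, D) == pytest.approx(r, abs=1e-10)


class TestCaseStudyEquations:
    MIDS = np.array([[4.3, 18.4, 18.4], [-13.3, 68.9, 5.4]]).T  # (3 sources, 2 sigs)

    def test_nitrite_reduces_to_mixing(self):
        f = np.array([0.5, 0.1, 0.4])
        mu = nitrite_model(f, self.MIDS, A=np.zeros(2), B=np.zeros(2), C=np.zeros(2))
        assert np.allclose(mu, mix_mu0(f, self.MIDS))

    def test_nitrite_d15N_hand_value(self):
        f = np.array([0.5, 0.1, 0.4])
        mu = nitrite_model(f, self.MIDS, A=np.array([0.0, -10.0]),
                           B=np.array([0.0, 13.0]), C=np.zeros(2))
        assert mu[1] == pytest.approx(5.5)  # 2.4 + 7 - 3.9 on the d15N axis

    def test_nitrite_d18O_with_equilibration(self):
        f = np.array([0.5, 0.1, 0.4])
        mu = nitrite_model(f, self.MIDS, A=np.array([-4.0, 0.0]),
                           B=np.array([5.0, 0.0]), C=np.array([0.25, 0.0]))
        assert mu[0] == pytest.approx(11.6375)

    def test_nitrite_domain(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            nitrite_model(np.array([1.0, 0.0, 0.0]), self.MIDS,
                          A=np.zeros(2), B=np.zeros(2), C=np.array([1.5, 0.0]))

    def test_n2o_is_mixing_plus_rayleigh(self):
        S = np.array([[-47.6], [-56.9], [-37.8], [-56.6]])
        f = np.full(4, 0.25)
        mu = n2o_model(f, S, np.array([-7.1]), 0.5)
        expected = mix_mu0(f, S) + -7.1 * np.log(0.5)
        assert np.allclose(mu, expected)

    def test_n2o_pure_mixing_at_r1(self):
        S = np.array([[-47.6], [-56.9], [-37.8], [-56.6]])
        f = np.array([0.9, 0.0, 0.1, 0.0])
        assert np.allclose(n2o_model(f, S, np.array([-7.1]), 1.0), mix_mu0(f, S))


class TestRecalcNitrificationSource:
    @pytest.mark.parametrize(
        "nh4,water,expected",
        [(0.5, 5.0, (-16.5, 11.2)), (20.0, -5.0, (3.0, 4.5))],
        ids=["fertilizer", "manure"],
    )
    def test_agro_sources(self, nh4, water, expected):
        d15, d18 = recalc_nitrification_source(nh4, -17.0, water, 23.5)
        assert d15 == pytest.approx(expected[0], abs=1e-12)
        assert round(d18, 1) == expected[1]

    def test_river_water_oxygen(self):
        # pristine river nitrate oxygen from water at -8.0 and O2 at 23.5
        _, d18 = recalc_nitrification_source(0.0, 0.0, -8.0, 23.5)
        assert d18 == pytest.approx(2.5, abs=1e-12)

    def test_zero_inputs(self):
        assert recalc_nitrification_source(0.0, 0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            recalc_nitrification_source(np.nan, 0.0, 0.0, 23.5)


class TestExpressionEquations:
    def _grid(self, m, with_r=False, n_points=100):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(m), size=n_points)
        r = {"r": rng.uniform(0.05, 1.0, size=n_points)} if with_r else {}
        return f, r

    def test_mixing_equivalence(self):
        eq = build_model_from_expression("f1*S1 + f2*S2", m=2)
        S = np.array([[2.0], [20.0]])
        f, r = self._grid(2)
        assert np.allclose(eq.mu(f, r, S, {}), mix_mu0(f, S), atol=1e-9)

    def test_postmix_rayleigh_equivalence(self):
        expr = build_model_from_expression(
            "f1*S1 + f2*S2 + f3*S3 + A*ln(r)", m=3, param_names=("A",), var_names=("r",)
        )
        builtin = builtin_equation("rayleigh")
        S = np.array([[0.0, 0.0], [10.0, 30.0], [20.0, 0.0]])
        f, r = self._grid(3, with_r=True)
        params = {"A": np.full((100, 2), -5.0)}
        assert np.allclose(expr.mu(f, r, S, params), builtin.mu(f, r, S, params),
                           atol=1e-9)

    def test_premix_rayleigh_equivalence(self):
        expr = build_model_from_expression(
            "f1*(S1 + A*ln(r)) + f2*S2 + f3*S3", m=3, param_names=("A",), var_names=("r",)
        )
        builtin = builtin_equation("rayleigh_premix")
        S = np.array([[0.0, 0.0], [10.0, 30.0], [20.0, 0.0]])
        f, r = self._grid(3, with_r=True)
        params = {"A": np.full((100, 2), -5.0)}
        assert np.allclose(expr.mu(f, r, S, params), builtin.mu(f, r, S, params),
                           atol=1e-9)

    def test_finite_difference_partials_match_fractions(self):
        eq = build_model_from_expression("f1*S1 + f2*S2", m=2)
        S = np.array([[2.0, 1.0], [20.0, 8.0]])
        f, r = self._grid(2, n_points=10)
        partials = eq.dmu_dS(f, r, S, {})
        assert np.allclose(partials, np.repeat(f[:, :, None], 2, axis=2), atol=1e-6)

    @pytest.mark.parametrize(
        "expr,msg",
        [
            ("f1*S1 + q", "unknown symbol 'q'"),
            ("f1*S1 +", "syntax error"),
            ("__import__('os')", "unknown symbol|function"),
            ("f1.real", "not allowed"),
        ],
    )
    def test_unsafe_expressions_rejected(self, expr, msg):
        with pytest.raises(ExpressionError, match=msg):
            build_model_from_expression(expr, m=2)


class TestDomainTypes:
    def test_signature_set_validation(self):
        with pytest.raises(ValueError, match="unique"):
            SignatureSet(("a", "a"))
        with pytest.raises(ValueError, match="between 1 and 3"):
            SignatureSet(("a", "b", "c", "d"))

    def test_source_mode_exclusivity(self):
        with pytest.raises(ValueError, match="point mode requires sigma"):
            SourceSpec(name="s", mode="point", mean=[1.0], half_range=[1.0])
        with pytest.raises(ValueError, match="range mode requires half_range"):
            SourceSpec(name="s", mode="range", mean=[1.0], sigma=[1.0])

    def test_mixing_state_invariants(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixingState(f=[0.5, 0.6], r=[], likelihood=1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            MixingState(f=[0.5, 0.5], r=[], likelihood=-1.0)

    def test_model_spec_rejects_undeclared_equation_symbols(self):
        with pytest.raises(ValueError, match="undeclared"):
            ModelSpec(
                signatures=SignatureSet(("I1",)),
                sources=[SourceSpec(name="s", mode="point", mean=[0.0], sigma=[1.0])],
                equation=builtin_equation("rayleigh"),
            )

    def test_measurement_validation(self):
        with pytest.raises(ValueError, match=">= 0"):
            Measurement(x=[1.0], sigma_x=[-0.1])

    def test_aux_variable_bounds(self):
        with pytest.raises(ValueError, match="prior_low"):
            AuxVariableSpec(name="r", prior_low=0.9, prior_high=0.1)
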