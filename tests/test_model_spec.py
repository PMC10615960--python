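import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modmedpower as mp
from modmedpower.design import build_factorial_design, add_interaction, \
    covariate_moments
from modmedpower.model import ModelError
from tests.conftest import make_random_recursive_spec


def _simple_spec(a=0.5, b=0.4, c=0.2, psi=(1.0, 1.0)):
    KA = mp.make_parameter_matrix("KA", [["a"], ["c"]], [[a], [c]],
                                  ["M", "Y"], ["X"])
    BE = mp.make_parameter_matrix("BE", [[0.0, 0.0], ["b", 0.0]],
                                  [[0.0, 0.0], [b, 0.0]], ["M", "Y"],
                                  ["M", "Y"])
    PS = mp.make_parameter_matrix("PS", [["pM", 0.0], [0.0, "pY"]],
                                  np.diag(psi), ["M", "Y"], ["M", "Y"])
    return mp.assemble_model({"g1": {"KA": KA, "BE": BE, "PS": PS}},
                             endogenous=["M", "Y"], covariates=["X"],
                             defined=["ab := a*b", "total := c + a*b"])


class TestParameterMatrix:
    def test_fixed_population_disagreement_rejected(self):
        with pytest.raises(ModelError, match="disagrees"):
            mp.make_parameter_matrix("KA", [[0.3]], [[0.5]], ["M"], ["X"])

    def test_dimension_mismatch(self):
        with pytest.raises(ModelError):
            mp.make_parameter_matrix("KA", [["a"], ["c"]], [[0.5]],
                                     ["M", "Y"], ["X"])

    def test_be_diagonal_must_be_zero(self):
        with pytest.raises(ModelError, match="diagonal"):
            mp.make_parameter_matrix("BE", [["s", 0.0], [0.0, 0.0]],
                                     [[0.1, 0.0], [0.0, 0.0]],
                                     ["M", "Y"], ["M", "Y"])

    def test_all_fixed_null_matrix_valid(self):
        m = mp.make_parameter_matrix("BE", np.zeros((2, 2)), np.zeros((2, 2)),
                                     ["M", "Y"], ["M", "Y"])
        assert m.labels() == []


class TestAssembleAndRecursion:
    def test_topological_order_mediator_first(self):
        spec = _simple_spec()
        assert list(spec.topo_order) == ["M", "Y"]

    def test_all_zero_be_returns_declaration_order(self):
        BE = mp.make_parameter_matrix("BE", np.zeros((2, 2)), np.zeros((2, 2)),
                                      ["M", "Y"], ["M", "Y"])
        assert mp.validate_recursive(BE) == ["M", "Y"]

    def test_cycle_detected(self):
        BE = mp.make_parameter_matrix(
            "BE", [[0.0, "u"], ["v", 0.0]], [[0.0, 0.1], [0.1, 0.0]],
            ["M", "Y"], ["M", "Y"])
        with pytest.raises(ModelError, match="recursive"):
            mp.validate_recursive(BE)

    def test_shared_label_is_one_parameter(self):
        # two groups sharing 'b' -> single constrained slope
        def group(b_label):
            KA = mp.make_parameter_matrix("KA", np.zeros((2, 0)),
                                          np.zeros((2, 0)), ["M", "Y"], [])
            BE = mp.make_parameter_matrix("BE", [[0.0, 0.0], [b_label, 0.0]],
                                          [[0.0, 0.0], [0.4, 0.0]],
                                          ["M", "Y"], ["M", "Y"])
            PS = mp.make_parameter_matrix("PS", [["p1", 0.0], [0.0, "p2"]],
                                          np.eye(2), ["M", "Y"], ["M", "Y"])
            return {"KA": KA, "BE": BE, "PS": PS}

        shared = mp.assemble_model({"u": group("b"), "v": group("b")},
                                   ["M", "Y"], [])
        assert len(shared.free_index["b"]) == 2
        # disjoint labels: free-parameter count equals free-cell count
        disjoint = mp.assemble_model({"u": group("b1"), "v": group("b2")},
                                     ["M", "Y"], [])
        assert len(disjoint.free_index) == len(shared.free_index) + 1

    def test_unknown_label_in_defined_rejected(self):
        with pytest.raises(ModelError, match="unknown"):
            KA = mp.make_parameter_matrix("KA", [["a"], ["c"]],
                                          [[0.5], [0.2]], ["M", "Y"], ["X"])
            BE = mp.make_parameter_matrix("BE", np.zeros((2, 2)),
                                          np.zeros((2, 2)), ["M", "Y"],
                                          ["M", "Y"])
            PS = mp.make_parameter_matrix("PS", [["p", 0.0], [0.0, "q"]],
                                          np.eye(2), ["M", "Y"], ["M", "Y"])
            mp.assemble_model({"g": {"KA": KA, "BE": BE, "PS": PS}},
                              ["M", "Y"], ["X"], defined=["z := a*missing"])


class TestStandardizationSolver:
    def test_moderated_mediation_pooled_values(self):
        """Pooled residual variances of the 2x2 moderated-mediation model."""
        study = mp.moderated_mediation_study()
        psi = np.diag(study.population.groups["g1"]["PS"].population)
        assert psi[0] == pytest.approx(0.8718434, abs=1e-6)
        assert psi[1] == pytest.approx(0.8061616, abs=1e-6)

    def test_simple_mediation_by_direct_algebra(self):
        design = build_factorial_design(["X"], 50)
        spec = _simple_spec()
        psi = mp.solve_residual_variances(spec, covariate_moments(design))
        vx = 25 / 99
        assert psi[0] == pytest.approx(1 - 0.25 * vx, abs=1e-10)
        expl_y = 0.04 * vx + 0.16 * 1.0 + 2 * 0.2 * 0.4 * 0.5 * vx
        assert psi[1] == pytest.approx(1 - expl_y, abs=1e-10)

    def test_all_zero_slopes_gives_target(self):
        spec = _simple_spec(a=0.0, b=0.0, c=0.0)
        design = build_factorial_design(["X"], 10)
        psi = mp.solve_residual_variances(spec, covariate_moments(design))
        np.testing.assert_allclose(psi, [1.0, 1.0], atol=1e-12)

    def test_infeasible_slope_names_variable(self):
        spec = _simple_spec(a=1.2, b=1.2, c=0.0)
        design = build_factorial_design(["X"], 50)
        with pytest.raises(ModelError, match="'Y'"):
            mp.solve_residual_variances(spec, covariate_moments(design))

    def test_roundtrip_through_implied_covariance(self):
        design = add_interaction(build_factorial_design(["X", "W"], 25),
                                 "X", "W")
        study = mp.moderated_mediation_study()
        imp = mp.implied_covariance(study.population,
                                    covariate_moments(design))
        np.testing.assert_allclose(np.diag(imp), [1.0, 1.0], atol=1e-10)

    def test_implied_variance_decomposition(self):
        # Var(Y) contribution routed through the mediator is b^2 * psi_M
        design = build_factorial_design(["X"], 50)
        spec = _simple_spec()
        psi = mp.solve_residual_variances(spec, covariate_moments(design))
        assert 0.16 * psi[0] == pytest.approx(0.16 * 0.9368687, abs=1e-6)

    def test_zero_paths_implied_covariance_is_psi(self):
        spec = _simple_spec(a=0.0, b=0.0, c=0.0, psi=(0.7, 0.3))
        design = build_factorial_design(["X"], 10)
        imp = mp.implied_covariance(spec, covariate_moments(design))
        np.testing.assert_allclose(imp, np.diag([0.7, 0.3]), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_roundtrip_property_random_recursive_specs(self, seed):
        rng = np.random.default_rng(seed)
        spec = make_random_recursive_spec(rng)
        design = add_interaction(build_factorial_design(["x0", "x1"], 10),
                                 "x0", "x1", name="z")
        # use only the two factor columns as covariates
        moments = covariate_moments(design).sub(["x0", "x1"])
        psi = mp.solve_residual_variances(spec, moments)
        spec2 = mp.apply_solved_psi(spec, {"g1": psi})
        imp = mp.implied_covariance(spec2, moments)
        np.testing.assert_allclose(np.diag(imp), np.ones(3), atol=1e-10)


class TestGroupTransforms:
    def test_scale_group_variances(self):
        study = mp.multigroup_moderated_mediation_study()
        ps0 = np.diag(study.population.groups["w0"]["PS"].population)
        ps1 = np.diag(study.population.groups["w1"]["PS"].population)
        np.testing.assert_allclose(ps1, 1.5 * ps0, atol=1e-12)
        np.testing.assert_allclose(
            ps1, [1.3077651, 1.2092424], atol=1e-6)

    def test_scale_identity_and_errors(self):
        study = mp.multigroup_moderated_mediation_study()
        spec = study.population
        same = mp.scale_group_variances(spec, 1.0, "w0")
        np.testing.assert_allclose(
            same.groups["w0"]["PS"].population,
            spec.groups["w0"]["PS"].population)
        # scaling one group leaves the other untouched
        scaled = mp.scale_group_variances(spec, 0.5, "w0")
        np.testing.assert_allclose(
            scaled.groups["w1"]["PS"].population,
            spec.groups["w1"]["PS"].population)
        with pytest.raises(ModelError, match="unknown group"):
            mp.scale_group_variances(spec, 2.0, "nope")
        with pytest.raises(ModelError):
            mp.scale_group_variances(spec, -1.0, "w0")

    @pytest.mark.parametrize("effects,expected", [
        ({"M": 0.5}, ([-0.25, 0.0], [0.25, 0.0])),
        ({"Y": 0.2}, ([0.0, -0.1], [0.0, 0.1])),
        ({"M": 0.0}, ([0.0, 0.0], [0.0, 0.0])),
    ])
    def test_intercept_offsets(self, effects, expected):
        ctrl, trt = mp.intercept_offsets(effects, ["M", "Y"])
        np.testing.assert_allclose(ctrl, expected[0])
        np.testing.assert_allclose(trt, expected[1])
        np.testing.assert_allclose(trt - ctrl,
                                   [effects.get("M", 0), effects.get("Y", 0)])


class TestDefinedIdentity:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)))
    def test_index_equals_difference_of_conditional_indirect_effects(self, t):
        """a.mod*b and ind.w1 - ind.w0 are algebraically identical."""
        a_w0, a_mod, b = t
        study = mp.moderated_mediation_study()
        from modmedpower.expressions import resolve_defined
        env = {"a.w0": a_w0, "a.mod": a_mod, "b": b, "c.w0": 0.1,
               "w.m": 0.0, "w.y": 0.0}
        vals = resolve_defined(study.analysis.defined, env)
        assert vals["ind.diff"] == pytest.approx(
            vals["ind.w1"] - vals["ind.w0"], abs=1e-12)
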