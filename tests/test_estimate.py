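import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import modmedpower as mp
from modmedpower.model import ModelError, apply_solved_psi


def _ols_oracle(table):
    """Independent per-equation least-squares fit of the mediation system."""
    xm = sm.add_constant(table[["X"]])
    res_m = sm.OLS(table["M"], xm).fit()
    xy = sm.add_constant(table[["X", "M"]])
    res_y = sm.OLS(table["Y"], xy).fit()
    return res_m, res_y


class TestUnconstrainedFit:
    def test_matches_ols_oracle(self, simple_study, simple_sample, simple_fit):
        res_m, res_y = _ols_oracle(simple_sample.table)
        assert simple_fit.estimates["a"] == pytest.approx(res_m.params["X"],
                                                          abs=1e-8)
        assert simple_fit.estimates["b"] == pytest.approx(res_y.params["M"],
                                                          abs=1e-8)
        assert simple_fit.estimates["c"] == pytest.approx(res_y.params["X"],
                                                          abs=1e-8)
        # ML residual variance uses divisor n
        n = simple_sample.n
        assert simple_fit.estimates["psi.M"] == pytest.approx(
            res_m.ssr / n, abs=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ols_equivalence_property(self, seed):
        study = mp.simple_mediation_study(
            a=0.3 + (seed % 5) * 0.1, b=0.2, c=0.1, n_per_group=30)
        d = mp.generate_sample(study.population, study.design, seed)
        fit = mp.fit_path_model(study.analysis, d)
        res_m, res_y = _ols_oracle(d.table)
        assert fit.estimates["a"] == pytest.approx(res_m.params["X"], abs=1e-8)
        assert fit.estimates["b"] == pytest.approx(res_y.params["M"], abs=1e-8)

    def test_zero_outcome_noise_recovers_slopes_exactly(self, simple_study):
        # psi_Y = 0 makes the Y equation deterministic: b and c are recovered
        # exactly and psi_Y sits on its boundary.  (psi_M must stay positive,
        # else M is collinear with X and the Y equation loses rank.)
        spec = apply_solved_psi(simple_study.population,
                                {"g1": np.array([0.5, 0.0])})
        d = mp.generate_sample(spec, simple_study.design, 3)
        fit = mp.fit_path_model(simple_study.analysis, d)
        assert fit.estimates["b"] == pytest.approx(0.4, abs=1e-8)
        assert fit.estimates["c"] == pytest.approx(0.2, abs=1e-8)
        assert fit.estimates["psi.Y"] == pytest.approx(0.0, abs=1e-9)
        assert fit.boundary  # psi estimated at its zero boundary
        assert fit.vcov is None

    def test_slope_se_matches_ols(self, simple_sample, simple_fit):
        res_m, _ = _ols_oracle(simple_sample.table)
        n = simple_sample.n
        # ML uses psi-hat = SS/n, OLS SS/(n-2): rescale the OLS SE
        expected = res_m.bse["X"] * np.sqrt((n - 2) / n)
        assert simple_fit.se("a") == pytest.approx(expected, rel=1e-8)


class TestConstrainedFit:
    def test_multigroup_equals_single_group_on_shared_data(
            self, simple_study, simple_sample, simple_fit):
        """Constrained multigroup (equal b, equal psi) is a reparameterization
        of the single-group model: identical ab estimate and SE."""
        mg = mp.multigroup_mediation_study()
        tab = simple_sample.table.copy()
        tab["group"] = tab["X"].astype(int) + 1
        data = mp.Dataset(table=tab.drop(columns=["X"]), covariates=(),
                          endogenous=("M", "Y"), group_column="group")
        fit_mg = mp.fit_path_model(mg.analysis, data)
        assert fit_mg.converged
        assert fit_mg.defined_values["ab"] == pytest.approx(
            simple_fit.defined_values["ab"], abs=1e-6)
        assert mp.delta_se(fit_mg, "ab") == pytest.approx(
            mp.delta_se(simple_fit, "ab"), abs=1e-6)
        assert fit_mg.loglik == pytest.approx(simple_fit.loglik, abs=1e-6)

    def test_constrained_loglik_no_higher_than_unconstrained(self,
                                                             simple_sample):
        mg_eq = mp.multigroup_mediation_study(equal_b=True, equal_psi=True)
        mg_free = mp.multigroup_mediation_study(equal_b=False, equal_psi=False)
        tab = simple_sample.table.copy()
        tab["group"] = tab["X"].astype(int) + 1
        data = mp.Dataset(table=tab.drop(columns=["X"]), covariates=(),
                          endogenous=("M", "Y"), group_column="group")
        ll_eq = mp.fit_path_model(mg_eq.analysis, data).loglik
        ll_free = mp.fit_path_model(mg_free.analysis, data).loglik
        assert ll_eq <= ll_free + 1e-6

    def test_shared_b_multigroup_modmed_converges(self):
        study = mp.multigroup_moderated_mediation_study()
        d = mp.generate_multigroup_sample(study.population, study.design, 11)
        fit = mp.fit_path_model(study.analysis, d)
        assert fit.converged
        assert set(fit.estimates) >= {"a.w0", "a.w1", "b", "psi.M.w0",
                                      "psi.M.w1"}
        # shared b: one parameter despite appearing in both groups
        assert sum(1 for l in fit.labels if l == "b") == 1


class TestParameterRecovery:
    def test_large_sample_recovery_within_three_se(self):
        study = mp.simple_mediation_study(n_per_group=5000)
        misses = 0
        n_seeds = 20
        for seed in range(n_seeds):
            d = mp.generate_sample(study.population, study.design,
                                   np.random.SeedSequence([888, seed]))
            fit = mp.fit_path_model(study.analysis, d)
            for lab, truth in (("a", 0.5), ("b", 0.4), ("c", 0.2)):
                if abs(fit.estimates[lab] - truth) > 3 * fit.se(lab):
                    misses += 1
        assert misses <= 1  # ~0.8% expected miss rate over 60 checks


class TestDefinedAndDeltaSE:
    def test_evaluate_defined_arithmetic(self, simple_fit):
        vals = mp.evaluate_defined(simple_fit, simple_fit.defined)
        a, b, c = (simple_fit.estimates[k] for k in ("a", "b", "c"))
        assert vals["ab"] == pytest.approx(a * b, abs=1e-12)
        assert vals["total"] == pytest.approx(c + a * b, abs=1e-12)

    def test_conditional_indirect_effect_values(self):
        study = mp.moderated_mediation_study()
        env = {"a.w0": 0.5, "a.mod": 0.3, "b": 0.4, "c.w0": 0.2,
               "w.m": 0.1, "w.y": -0.1}
        from modmedpower.expressions import resolve_defined
        vals = resolve_defined(study.analysis.defined, env)
        assert vals["ind.w1"] == pytest.approx(0.32)
        assert vals["ind.diff"] == pytest.approx(0.12)

    def test_sobel_closed_form(self, simple_fit):
        """cov(a,b)=0 across equations, so delta SE(ab) = Sobel."""
        a, b = simple_fit.estimates["a"], simple_fit.estimates["b"]
        sea, seb = simple_fit.se("a"), simple_fit.se("b")
        sobel = np.sqrt(b**2 * sea**2 + a**2 * seb**2)
        assert mp.delta_se(simple_fit, "ab") == pytest.approx(sobel, abs=1e-6)

    def test_single_label_delta_se_is_own_se(self, simple_fit):
        from modmedpower.expressions import DefinedParameter
        d = DefinedParameter.from_string("just.a := a")
        assert mp.delta_se(simple_fit, d) == pytest.approx(
            simple_fit.se("a"), abs=1e-9)

    def test_sum_gradient_against_symbolic(self, simple_fit):
        # total = c + a*b: gradient (1, b, a) over (c, a, b)
        labels = ["a", "b", "c"]
        V = simple_fit.vcov_sub(labels)
        a, b = simple_fit.estimates["a"], simple_fit.estimates["b"]
        g = np.array([b, a, 1.0])
        expected = float(np.sqrt(g @ V @ g))
        assert mp.delta_se(simple_fit, "total") == pytest.approx(expected,
                                                                 abs=1e-6)

    def test_delta_se_tracks_empirical_sd(self):
        """Asymptotics sanity: delta SE of ab approximates the Monte Carlo
        SD of the ab estimates at n=100."""
        study = mp.simple_mediation_study(nrep=2000, methods=("delta",))
        abs_, ses = [], []
        for r in range(2000):
            d = mp.generate_sample(study.population, study.design,
                                   np.random.SeedSequence([5150, r]))
            fit = mp.fit_path_model(study.analysis, d)
            abs_.append(fit.defined_values["ab"])
            ses.append(mp.delta_se(fit, "ab"))
        emp_sd = np.std(abs_)
        assert np.mean(ses) == pytest.approx(emp_sd, rel=0.10)

    def test_unknown_defined_parameter(self, simple_fit):
        with pytest.raises(ModelError, match="unknown"):
            mp.delta_se(simple_fit, "nope")
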