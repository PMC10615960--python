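"""Builders for the four canonical study designs.

Each returns a complete :class:`~modmedpower.power.StudySpec` ready for
:func:`~modmedpower.power.run_power_study`:

1. single-group simple mediation (dummy-coded predictor X, mediator M,
   outcome Y; standardized paths a, b, c');
2. the statistically equivalent multigroup formulation (X as grouping
   factor, effects as intercept differences, equal-b and equal-residual-
   variance constraints);
3. single-group moderated mediation (Hayes model 7: a second factor W
   moderates the a path through the product column XW);
4. multigroup moderated mediation (W as grouping factor, shared b,
   optionally heteroskedastic residual variances across W groups).

All slopes are standardized: residual variances are solved so every
endogenous total variance is 1 under the study's own design moments
(unbiased n-1 divisor).
"""

from __future__ import annotations

import numpy as np

from .design import (DesignMatrix, add_interaction, build_factorial_design,
                     covariate_moments)
from .model import (ModelSpec, apply_solved_psi, assemble_model,
                    intercept_offsets, make_parameter_matrix,
                    scale_group_variances, solve_residual_variances)
from .power import StudySpec

__all__ = [
    "simple_mediation_study",
    "multigroup_mediation_study",
    "moderated_mediation_study",
    "multigroup_moderated_mediation_study",
]

_MC_DEFAULTS = dict(nrep=1000, seed=12345, alpha=0.05,
                    methods=("delta", "mcci"), mcci_draws=20_000)


def _mc(kw):
    out = dict(_MC_DEFAULTS)
    out.update(kw)
    return out


def simple_mediation_study(a: float = 0.5, b: float = 0.4, c: float = 0.2,
                           n_per_group: int = 50, **mc) -> StudySpec:
    """Single-group simple mediation: M ~ a*X, Y ~ b*M + c*X."""
    design = build_factorial_design(["X"], n_per_group)
    KA = make_parameter_matrix("KA", [["a"], ["c"]], [[a], [c]],
                               row_labels=["M", "Y"], col_labels=["X"])
    BE = make_parameter_matrix("BE", [[0.0, 0.0], ["b", 0.0]],
                               [[0.0, 0.0], [b, 0.0]],
                               row_labels=["M", "Y"], col_labels=["M", "Y"])
    PS = make_parameter_matrix("PS", [["psi.M", 0.0], [0.0, "psi.Y"]],
                               [[1.0, 0.0], [0.0, 1.0]],
                               row_labels=["M", "Y"], col_labels=["M", "Y"])
    spec = assemble_model({"g1": {"KA": KA, "BE": BE, "PS": PS}},
                          endogenous=["M", "Y"], covariates=["X"],
                          defined=["ab := a*b", "total := c + a*b"])
    psi = solve_residual_variances(spec, covariate_moments(design))
    spec = apply_solved_psi(spec, {"g1": psi})
    return StudySpec(population=spec, analysis=spec, design=design,
                     name="simple_mediation", **_mc(mc))


def multigroup_mediation_study(a: float = 0.5, b: float = 0.4, c: float = 0.2,
                               n_per_group: int = 50, equal_b: bool = True,
                               equal_psi: bool = True, **mc) -> StudySpec:
    """Two-group formulation of simple mediation (X as grouping factor).

    The a and c' effects become intercept differences (+/- effect/2 around
    zero); residual variances take the values that standardize the
    equivalent single-group model, so both formulations are on the same
    scale.  With ``equal_b`` and ``equal_psi`` the model is statistically
    equivalent to the single-group one.
    """
    # residual variances from the equivalent single-group standardization
    single = simple_mediation_study(a, b, c, n_per_group)
    psi = np.diag(single.population.groups["g1"]["PS"].population)

    al_ctrl, al_trt = intercept_offsets({"M": a, "Y": c}, ["M", "Y"])
    groups = {}
    for gname, al_pop, tag in (("control", al_ctrl, "0"),
                               ("treatment", al_trt, "1")):
        AL = make_parameter_matrix("AL", [f"a{tag}", f"c{tag}"], al_pop,
                                   row_labels=["M", "Y"])
        KA = make_parameter_matrix("KA", np.zeros((2, 0)), np.zeros((2, 0)),
                                   row_labels=["M", "Y"], col_labels=[])
        b_lab = "b" if equal_b else f"b{tag}"
        BE = make_parameter_matrix("BE", [[0.0, 0.0], [b_lab, 0.0]],
                                   [[0.0, 0.0], [b, 0.0]],
                                   row_labels=["M", "Y"], col_labels=["M", "Y"])
        m_lab, y_lab = (("eM", "eY") if equal_psi
                        else (f"eM{tag}", f"eY{tag}"))
        PS = make_parameter_matrix("PS", [[m_lab, 0.0], [0.0, y_lab]],
                                   [[psi[0], 0.0], [0.0, psi[1]]],
                                   row_labels=["M", "Y"], col_labels=["M", "Y"])
        groups[gname] = {"KA": KA, "BE": BE, "PS": PS, "AL": AL}
    if equal_b:
        defined = ["ab := (a1 - a0)*b",
                   "total := (c1 - c0) + (a1 - a0)*b"]
    else:
        # without the equality constraint there is one indirect effect per
        # moderator (here: per X group) plus their difference
        defined = ["ab.b0 := (a1 - a0)*b0",
                   "ab.b1 := (a1 - a0)*b1",
                   "b.diff := b1 - b0"]
    spec = assemble_model(groups, endogenous=["M", "Y"], covariates=[],
                          defined=defined, meanstructure=True)
    return StudySpec(population=spec, analysis=spec,
                     design={"control": n_per_group, "treatment": n_per_group},
                     name="multigroup_mediation", **_mc(mc))


def moderated_mediation_study(a_w0: float = 0.5, a_mod: float = 0.3,
                              b: float = 0.4, c_w0: float = 0.2,
                              w_on_m: float = 0.1, w_on_y: float = -0.1,
                              n_per_cell: int = 25, **mc) -> StudySpec:
    """Single-group moderated mediation (W moderates the a path).

    Covariates are the dummy codes X, W and their product XW.  The XW effect
    on Y is fixed to zero (no direct moderation of c'); the index of
    moderated mediation is ind.diff = a.mod*b = ind.w1 - ind.w0.
    """
    design = add_interaction(build_factorial_design(["X", "W"], n_per_cell),
                             "X", "W")
    KA = make_parameter_matrix(
        "KA",
        [["a.w0", "w.m", "a.mod"], ["c.w0", "w.y", 0.0]],
        [[a_w0, w_on_m, a_mod], [c_w0, w_on_y, 0.0]],
        row_labels=["M", "Y"], col_labels=["X", "W", "XW"])
    BE = make_parameter_matrix("BE", [[0.0, 0.0], ["b", 0.0]],
                               [[0.0, 0.0], [b, 0.0]],
                               row_labels=["M", "Y"], col_labels=["M", "Y"])
    PS = make_parameter_matrix("PS", [["psi.M", 0.0], [0.0, "psi.Y"]],
                               [[1.0, 0.0], [0.0, 1.0]],
                               row_labels=["M", "Y"], col_labels=["M", "Y"])
    spec = assemble_model(
        {"g1": {"KA": KA, "BE": BE, "PS": PS}},
        endogenous=["M", "Y"], covariates=["X", "W", "XW"],
        defined=["ind.w0 := a.w0*b",
                 "ind.w1 := (a.w0 + a.mod)*b",
                 "ind.diff := a.mod*b"])
    psi = solve_residual_variances(spec, covariate_moments(design))
    spec = apply_solved_psi(spec, {"g1": psi})
    return StudySpec(population=spec, analysis=spec, design=design,
                     name="moderated_mediation", **_mc(mc))


def multigroup_moderated_mediation_study(
        a_w0: float = 0.5, a_w1: float = 0.8, b: float = 0.4,
        c: float = 0.2, w_variance_ratio: float = 1.5,
        n_per_group: int = 50, constrain_c: bool = False,
        **mc) -> StudySpec:
    """Multigroup moderated mediation: the moderator W is the grouping factor.

    Each W group has a within-group simple mediation model with its own
    X -> M slope (a.w0 vs a.w1); the b path is a single shared parameter.
    Residual variances are the pooled standardizing values in the control
    group and ``w_variance_ratio`` times larger in the treatment group
    (heteroskedasticity across moderator conditions); the analysis model
    estimates them freely per group.  The index of moderated mediation is
    ind.diff = (a.w1 - a.w0)*b.
    """
    # pooled standardizing residual variances from the single-group model
    pooled = moderated_mediation_study(a_w0=a_w0, a_mod=a_w1 - a_w0, b=b,
                                       c_w0=c, n_per_cell=max(n_per_group // 2, 1))
    psi = np.diag(pooled.population.groups["g1"]["PS"].population)

    half = n_per_group // 2
    designs = {
        "w0": build_factorial_design(["X"], [n_per_group - half, half]),
        "w1": build_factorial_design(["X"], [n_per_group - half, half]),
    }
    groups = {}
    for gname, a_val, tag in (("w0", a_w0, "w0"), ("w1", a_w1, "w1")):
        c_lab = "c" if constrain_c else f"c.{tag}"
        KA = make_parameter_matrix("KA", [[f"a.{tag}"], [c_lab]],
                                   [[a_val], [c]],
                                   row_labels=["M", "Y"], col_labels=["X"])
        BE = make_parameter_matrix("BE", [[0.0, 0.0], ["b", 0.0]],
                                   [[0.0, 0.0], [b, 0.0]],
                                   row_labels=["M", "Y"], col_labels=["M", "Y"])
        PS = make_parameter_matrix(
            "PS", [[f"psi.M.{tag}", 0.0], [0.0, f"psi.Y.{tag}"]],
            [[psi[0], 0.0], [0.0, psi[1]]],
            row_labels=["M", "Y"], col_labels=["M", "Y"])
        groups[gname] = {"KA": KA, "BE": BE, "PS": PS}
    spec = assemble_model(groups, endogenous=["M", "Y"], covariates=["X"],
                          defined=["ind.w0 := a.w0*b",
                                   "ind.w1 := a.w1*b",
                                   "ind.diff := ind.w1 - ind.w0"])
    spec = scale_group_variances(spec, w_variance_ratio, "w1")
    return StudySpec(population=spec, analysis=spec, design=designs,
                     name="multigroup_moderated_mediation", **_mc(mc))
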